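"""Conductor surface-charge solver.

The conductor boundary condition (vanishing total potential on the cavity
surface) gives the linear system 0 = Φ + A q, where A is the symmetric
segment-segment Coulomb matrix.  Two discretizations are provided:

* KS — point charges at segment centers, self-interaction diagonal
  1.07·√(4π/s) (Klamt–Schüürmann convention);
* YK — spherical Gaussian smeared charges, which remove Coulomb
  singularities; exponents follow ζ_i = ζ̄/√s_i with ζ̄ calibrated per
  tessellation level to reproduce the exact Born ion energy.

For a finite dielectric the conductor charges are scaled by f_ε.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import brentq
from scipy.sparse.linalg import LinearOperator, cg
from scipy.special import erf

from .cavity import Segment
from .constants import BOHR_PER_ANGSTROM
from .tessellation import get_level, unit_mesh

__all__ = [
    "CoulombMatrix",
    "ScreeningCharges",
    "ScreenOption",
    "KS_DIAGONAL_CONSTANT",
    "DENSE_SOLVER_LIMIT",
    "build_A_ks",
    "build_A_yk",
    "yk_exponents",
    "calibrate_yk",
    "select_solver",
    "solve_screening",
    "scale_factor",
    "apply_scaling",
]

KS_DIAGONAL_CONSTANT = 1.07
DENSE_SOLVER_LIMIT = 7500  # above this many segments `auto` goes iterative


@dataclass
class CoulombMatrix:
    A: np.ndarray  # (m, m), atomic units
    variant: str  # "ks" | "yk"


@dataclass
class ScreeningCharges:
    q: np.ndarray  # e, per segment
    q_N: "np.ndarray | None" = None
    q_e: "np.ndarray | None" = None
    f_eps: float = 1.0


@dataclass
class ScreenOption:
    mode: str = "ideal"  # "ideal" | "ks" | "st"
    eps: float = float("inf")

    def __post_init__(self) -> None:
        if self.mode not in ("ideal", "ks", "st"):
            raise ValueError(f"screen mode must be ideal|ks|st, got {self.mode!r}")


def _centers_bohr(segments: list[Segment]) -> np.ndarray:
    return np.array([s.center for s in segments]) * BOHR_PER_ANGSTROM


def _areas_bohr2(segments: list[Segment]) -> np.ndarray:
    return np.array([s.area for s in segments]) * BOHR_PER_ANGSTROM**2


def build_A_ks(
    segments: list[Segment], diag_constant: float = KS_DIAGONAL_CONSTANT
) -> CoulombMatrix:
    """Point-charge Coulomb matrix: A_ij = 1/r_ij, A_ii = c·√(4π/s_i)."""
    r = _centers_bohr(segments)
    s = _areas_bohr2(segments)
    diff = r[:, None, :] - r[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    m = len(segments)
    off = ~np.eye(m, dtype=bool)
    if np.any(dist[off] < 1e-10):
        i, j = np.argwhere(off & (dist < 1e-10))[0]
        raise ValueError(
            f"segments {i} and {j} have coincident centers; enable segment "
            "merging (mfactor > 0) or use the YK method"
        )
    A = np.zeros((m, m))
    A[off] = 1.0 / dist[off]
    A[np.diag_indices(m)] = diag_constant * np.sqrt(4.0 * np.pi / s)
    return CoulombMatrix(A=A, variant="ks")


def build_A_yk(segments: list[Segment], exponents: np.ndarray) -> CoulombMatrix:
    """Gaussian smeared-charge Coulomb matrix (finite for any geometry).

    A_ij = erf(ζ_ij r_ij)/r_ij with ζ_ij = ζ_i ζ_j/√(ζ_i²+ζ_j²),
    A_ii = ζ_i √(2/π); exponents in Bohr⁻¹.
    """
    zeta = np.asarray(exponents, dtype=float)
    if np.any(zeta <= 0):
        raise ValueError("YK exponents must be positive")
    r = _centers_bohr(segments)
    diff = r[:, None, :] - r[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    zij = zeta[:, None] * zeta[None, :] / np.sqrt(
        zeta[:, None] ** 2 + zeta[None, :] ** 2
    )
    m = len(segments)
    A = np.empty((m, m))
    tiny = dist < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        A = np.where(
            tiny,
            2.0 * zij / np.sqrt(np.pi),  # erf(z r)/r → 2z/√π as r → 0
            erf(zij * dist) / np.where(tiny, 1.0, dist),
        )
    A[np.diag_indices(m)] = zeta * np.sqrt(2.0 / np.pi)
    return CoulombMatrix(A=A, variant="yk")


def yk_exponents(segments: list[Segment], zbar: float) -> np.ndarray:
    """Per-segment exponents ζ_i = ζ̄/√s_i (equal-area ⇒ equal exponents)."""
    return zbar / np.sqrt(_areas_bohr2(segments))


_YK_CACHE: dict[str, float] = {}


def calibrate_yk(level: "str | TessLevel") -> float:  # noqa: F821
    """Dimensionless ζ̄ making the discretized Born energy exact.

    Calibrated on a unit sphere (1 Bohr, unit central charge): with
    ζ_i = ζ̄/√s_i the discrete energy −½ Φᵀ A⁻¹ Φ must equal −1/2.
    The rule is scale invariant, so one constant serves all radii.
    """
    lvl = get_level(level)
    if lvl.label in _YK_CACHE:
        return _YK_CACHE[lvl.label]
    mesh = unit_mesh(lvl)
    s = mesh.face_areas  # Bohr² on the unit sphere
    r = mesh.face_centers  # radius 1 Bohr
    diff = r[:, None, :] - r[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    phi = np.ones(len(s))  # q/R with q = 1, R = 1 Bohr

    def born_energy(zbar: float) -> float:
        zeta = zbar / np.sqrt(s)
        zij = zeta[:, None] * zeta[None, :] / np.sqrt(
            zeta[:, None] ** 2 + zeta[None, :] ** 2
        )
        off = ~np.eye(len(s), dtype=bool)
        A = np.zeros_like(dist)
        A[off] = erf(zij[off] * dist[off]) / dist[off]
        A[np.diag_indices(len(s))] = zeta * np.sqrt(2.0 / np.pi)
        q = cho_solve(cho_factor(A), -phi)
        return 0.5 * float(phi @ q)

    def objective(zbar: float) -> float:
        return born_energy(zbar) + 0.5

    lo, hi = 0.5, 50.0
    if objective(lo) * objective(hi) > 0:
        raise RuntimeError(
            f"YK calibration failed to bracket a root in [{lo}, {hi}]: "
            f"f({lo})={objective(lo):.3e}, f({hi})={objective(hi):.3e}"
        )
    zbar = float(brentq(objective, lo, hi, xtol=1e-13))
    _YK_CACHE[lvl.label] = zbar
    return zbar


def select_solver(m: int, method: str = "auto") -> str:
    """Resolve the linear-solver choice for an m-segment system."""
    if method in ("dense", "iterative"):
        return method
    if method == "auto":
        return "dense" if m <= DENSE_SOLVER_LIMIT else "iterative"
    raise ValueError(f"method must be dense|iterative|auto, got {method!r}")


def _solve(A: np.ndarray, rhs: np.ndarray, how: str) -> np.ndarray:
    if how == "dense":
        factor = cho_factor(A)
        x = cho_solve(factor, rhs)
        for _ in range(2):  # iterative refinement to push the residual down
            r = rhs - A @ x
            if np.linalg.norm(r, np.inf) <= 1e-14 * max(np.linalg.norm(rhs, np.inf), 1e-300):
                break
            x = x + cho_solve(factor, r)
        return x
    # conjugate gradient with Jacobi preconditioning; A is SPD
    m = A.shape[0]
    Minv = 1.0 / np.diag(A)
    precond = LinearOperator((m, m), matvec=lambda x: Minv * x)
    x, info = cg(A, rhs, rtol=1e-13, atol=0.0, maxiter=10 * m, M=precond)
    if info != 0:
        res = np.linalg.norm(A @ x - rhs, np.inf)
        raise RuntimeError(
            f"iterative screening solver did not converge (info={info}, "
            f"residual inf-norm {res:.3e})"
        )
    return x


def solve_screening(
    A: "CoulombMatrix | np.ndarray",
    phi: np.ndarray,
    method: str = "auto",
    phi_N: "np.ndarray | None" = None,
    phi_e: "np.ndarray | None" = None,
) -> ScreeningCharges:
    """Solve 0 = Φ + A q for the conductor screening charges.

    If the nuclear/electronic potential split is supplied, both parts are
    solved with the same matrix and q = q_N + q_e by linearity.
    """
    mat = A.A if isinstance(A, CoulombMatrix) else np.asarray(A)
    phi = np.asarray(phi, dtype=float)
    if mat.shape[0] != phi.shape[0]:
        raise ValueError("potential vector length does not match matrix size")
    how = select_solver(mat.shape[0], method)
    q_N = q_e = None
    if phi_N is not None and phi_e is not None:
        q_N = _solve(mat, -np.asarray(phi_N, dtype=float), how)
        q_e = _solve(mat, -np.asarray(phi_e, dtype=float), how)
        q = q_N + q_e
    else:
        q = _solve(mat, -phi, how)
    res = np.linalg.norm(mat @ q + phi, np.inf)
    # relative contract plus an absolute round-off floor for nearly
    # self-cancelling potentials (neutral solutes)
    q_scale = max(
        np.linalg.norm(q, np.inf),
        0.0 if q_N is None else np.linalg.norm(q_N, np.inf),
        0.0 if q_e is None else np.linalg.norm(q_e, np.inf),
        1e-300,
    )
    floor = 100.0 * np.finfo(float).eps * np.linalg.norm(mat, np.inf) * q_scale
    tol = 1e-10 * max(np.linalg.norm(phi, np.inf), 1e-300) + floor
    if res > tol:
        raise RuntimeError(
            f"screening solve residual {res:.3e} exceeds tolerance {tol:.3e}"
        )
    return ScreeningCharges(q=q, q_N=q_N, q_e=q_e, f_eps=1.0)


def scale_factor(opt: ScreenOption) -> float:
    """Dielectric scaling factor f_ε for the selected screen mode."""
    if opt.mode == "ideal":
        return 1.0
    if opt.eps <= 1.0:
        raise ValueError(
            f"screen {opt.mode!r} requires a dielectric constant > 1, got {opt.eps}"
        )
    if opt.mode == "ks":
        return (opt.eps - 1.0) / (opt.eps + 0.5)
    return (opt.eps - 1.0) / opt.eps  # "st"


def apply_scaling(charges: ScreeningCharges, f_eps: float) -> ScreeningCharges:
    """Scale conductor charges to the finite-dielectric values q_ε = f_ε q."""
    if not (0.0 < f_eps <= 1.0):
        raise ValueError(f"f_eps must lie in (0, 1], got {f_eps}")
    return ScreeningCharges(
        q=f_eps * charges.q,
        q_N=None if charges.q_N is None else f_eps * charges.q_N,
        q_e=None if charges.q_e is None else f_eps * charges.q_e,
        f_eps=f_eps * charges.f_eps,
    )
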