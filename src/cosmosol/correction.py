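"""Outlying-charge corrections and the dielectric energy.

Gauss's law for a conductor requires the screening charges to mirror the
enclosed solute charge exactly (the charge rule −Q = 1ᵀq).  Surface
discretization error and solute charge lying outside the cavity leave a
residual "charge defect" 1ᵀq + Q.  Two correction schemes are provided:

* scale       — separate factors f_N = −Q_N/(1ᵀq_N), f_e = −Q_e/(1ᵀq_e)
                rescale the nuclear and electronic charge components;
* lagrangian  — minimize the energy functional ½qᵀAq + Φᵀq subject to
                1ᵀq = −Q (closed form via a Lagrange multiplier).

After either correction the surface potential is updated to restore the
boundary condition, Φ′ = −A q′, and the dielectric energy is
E_diel = ½ Φ′ᵀ q′.  The legacy behavior (charges corrected, potential
left at the uncorrected Φ) is kept for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .constants import KCAL_PER_HARTREE
from .screening import CoulombMatrix

__all__ = [
    "CorrectionResult",
    "EnergyReport",
    "correct_scale",
    "correct_lagrangian",
    "corrected_potential",
    "dielectric_energy",
    "charge_defect",
]


@dataclass
class CorrectionResult:
    q: np.ndarray  # corrected total charges q′, e
    q_N: "np.ndarray | None"
    q_e: "np.ndarray | None"
    f_N: float = 1.0
    f_e: float = 1.0
    lam: "float | None" = None  # Lagrange multiplier, a.u.
    defect_before: float = 0.0
    defect_after: float = 0.0


@dataclass
class EnergyReport:
    e_diel: float  # Hartree, with corrected potential (unless potcorr)
    e_diel_legacy: float  # Hartree, uncorrected potential + corrected charges
    correction_mode: str = "off"
    potential_corrected: bool = True

    @property
    def e_diel_kcal(self) -> float:
        return self.e_diel * KCAL_PER_HARTREE

    @property
    def e_diel_legacy_kcal(self) -> float:
        return self.e_diel_legacy * KCAL_PER_HARTREE


def charge_defect(q: np.ndarray, Q_total: float) -> float:
    """Signed residual of Gauss's law: 1ᵀq + Q."""
    return float(np.sum(q) + Q_total)


def correct_scale(
    q_N: np.ndarray, q_e: np.ndarray, Q_N: float, Q_e: float
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Enforce the charge rule componentwise by rescaling.

    f = −Q/(1ᵀq) for each component, so that 1ᵀq′ = −Q holds exactly and
    the factors sit near +1 for well-enclosed charge.
    """
    def factor(total: float, Q: float, label: str) -> float:
        if abs(total) < 1e-10:
            if Q == 0.0:
                return 1.0  # component absent (e.g. no clouds): nothing to enforce
            raise ValueError(
                f"scaling correction undefined: {label} screening charges sum to "
                f"zero while the {label} solute charge is {Q}"
            )
        return -Q / total

    f_N = factor(float(np.sum(q_N)), Q_N, "nuclear")
    f_e = factor(float(np.sum(q_e)), Q_e, "electronic")
    return f_N * q_N, f_e * q_e, f_N, f_e


def correct_lagrangian(
    A: "CoulombMatrix | np.ndarray", phi: np.ndarray, Q_total: float
) -> tuple[np.ndarray, float]:
    """Constrained energy minimization: min ½qᵀAq + Φᵀq s.t. 1ᵀq = −Q.

    Closed form q′ = −A⁻¹(Φ + λ1) with λ = (Q − 1ᵀA⁻¹Φ)/(1ᵀA⁻¹1).
    """
    mat = A.A if isinstance(A, CoulombMatrix) else np.asarray(A)
    phi = np.asarray(phi, dtype=float)
    ones = np.ones(len(phi))
    factor = cho_factor(mat)
    Ainv_phi = cho_solve(factor, phi)
    Ainv_one = cho_solve(factor, ones)
    lam = (Q_total - float(ones @ Ainv_phi)) / float(ones @ Ainv_one)
    q = -(Ainv_phi + lam * Ainv_one)
    return q, float(lam)


def corrected_potential(
    A: "CoulombMatrix | np.ndarray", q_prime: np.ndarray, phi_N: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Boundary-condition-consistent potentials for corrected charges.

    Φ′ = −A q′; the electronic part Φ_e′ = Φ′ − Φ_N, since nuclear charge
    never lies outside the cavity.
    """
    mat = A.A if isinstance(A, CoulombMatrix) else np.asarray(A)
    phi_prime = -mat @ np.asarray(q_prime, dtype=float)
    return phi_prime, phi_prime - np.asarray(phi_N, dtype=float)


def dielectric_energy(phi_prime: np.ndarray, q_prime: np.ndarray) -> float:
    """E_diel = ½ Φ′ᵀ q′ in Hartree (negative for any nonzero potential)."""
    return 0.5 * float(np.asarray(phi_prime) @ np.asarray(q_prime))
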