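"""Classical solute charge models: point nuclei plus spherical Gaussian
electron clouds.

A real solute's electron density always leaks outside any reasonable
cavity ("outlying charge").  Gaussian clouds reproduce that feature with
closed-form potentials and enclosed-charge expressions, which makes every
downstream correction scheme testable against analytic oracles.

Units: geometry in Å on the surface API, electrostatics in atomic units
(potentials in Hartree/e, charges in e, Gaussian exponents in Bohr⁻²).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf

from .cavity import Cavity, Sphere
from .constants import BOHR_PER_ANGSTROM

__all__ = [
    "Nucleus",
    "GaussianCloud",
    "SoluteModel",
    "PotentialSplit",
    "nuclear_potential",
    "cloud_potential",
    "total_potential",
    "enclosed_cloud_charge",
    "charge_outside_cavity",
    "make_fixture",
    "FIXTURE_NAMES",
]


@dataclass
class Nucleus:
    position: np.ndarray  # Å
    charge: float  # e, >= 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class GaussianCloud:
    """Spherical Gaussian charge ρ(r) = n (α/π)^{3/2} exp(−α r²), r in Bohr."""

    position: np.ndarray  # Å
    charge: float  # total charge n, e (normally negative)
    exponent: float  # α, Bohr⁻²

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.exponent <= 0:
            raise ValueError(f"cloud exponent must be positive, got {self.exponent}")


@dataclass
class SoluteModel:
    nuclei: list[Nucleus]
    clouds: list[GaussianCloud] = field(default_factory=list)

    @property
    def Q_N(self) -> float:
        return float(sum(n.charge for n in self.nuclei))

    @property
    def Q_e(self) -> float:
        return float(sum(c.charge for c in self.clouds))

    @property
    def total_charge(self) -> float:
        return self.Q_N + self.Q_e

    def to_text(self) -> str:
        lines = ["# cosmosol solute model (positions in Å, charges in e, exponents in Bohr^-2)"]
        for n in self.nuclei:
            x, y, z = n.position
            lines.append(f"nucleus {x:.10f} {y:.10f} {z:.10f} {n.charge:.10f}")
        for c in self.clouds:
            x, y, z = c.position
            lines.append(
                f"cloud {x:.10f} {y:.10f} {z:.10f} {c.charge:.10f} {c.exponent:.10f}"
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "SoluteModel":
        nuclei, clouds = [], []
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if parts[0] == "nucleus" and len(parts) == 5:
                nuclei.append(Nucleus(list(map(float, parts[1:4])), float(parts[4])))
            elif parts[0] == "cloud" and len(parts) == 6:
                clouds.append(
                    GaussianCloud(
                        list(map(float, parts[1:4])), float(parts[4]), float(parts[5])
                    )
                )
            else:
                raise ValueError(f"unrecognized solute model line: {raw!r}")
        return cls(nuclei=nuclei, clouds=clouds)


@dataclass
class PotentialSplit:
    """Solute potentials on the segment centers, split by source (a.u.)."""

    phi_N: np.ndarray
    phi_e: np.ndarray

    @property
    def phi(self) -> np.ndarray:
        return self.phi_N + self.phi_e


def potential_split(solute: SoluteModel, points: np.ndarray) -> PotentialSplit:
    return PotentialSplit(
        phi_N=nuclear_potential(solute, points),
        phi_e=cloud_potential(solute, points),
    )


def nuclear_potential(solute: SoluteModel, points: np.ndarray) -> np.ndarray:
    """Coulomb potential of the point nuclei at `points` (Å), in a.u."""
    pts = np.atleast_2d(np.asarray(points, dtype=float)) * BOHR_PER_ANGSTROM
    phi = np.zeros(len(pts))
    for k, nuc in enumerate(solute.nuclei):
        r = np.linalg.norm(pts - nuc.position * BOHR_PER_ANGSTROM, axis=1)
        bad = np.nonzero(r < 1e-10)[0]
        if bad.size:
            raise ValueError(
                f"evaluation point {int(bad[0])} coincides with nucleus {k}; "
                "potential is singular there"
            )
        phi += nuc.charge / r
    return phi


def cloud_potential(solute: SoluteModel, points: np.ndarray) -> np.ndarray:
    """Potential of the Gaussian clouds at `points` (Å), in a.u.

    One cloud of charge n and exponent α contributes n·erf(√α r)/r, with
    the finite limit n·2√(α/π) at r → 0.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float)) * BOHR_PER_ANGSTROM
    phi = np.zeros(len(pts))
    for c in solute.clouds:
        r = np.linalg.norm(pts - c.position * BOHR_PER_ANGSTROM, axis=1)
        sq = np.sqrt(c.exponent)
        small = r < 1e-12
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(small, 2.0 * sq / np.sqrt(np.pi), erf(sq * r) / np.where(small, 1.0, r))
        phi += c.charge * term
    return phi


def total_potential(solute: SoluteModel, points: np.ndarray) -> np.ndarray:
    return nuclear_potential(solute, points) + cloud_potential(solute, points)


def enclosed_cloud_charge(charge: float, exponent: float, radius_bohr: float) -> float:
    """Cloud charge inside a sphere of `radius_bohr` centered on the cloud.

    Closed form: n·[erf(√α R) − 2√(α/π)·R·exp(−α R²)].
    """
    a, r = exponent, radius_bohr
    return charge * (
        erf(np.sqrt(a) * r) - 2.0 * np.sqrt(a / np.pi) * r * np.exp(-a * r * r)
    )


def charge_outside_cavity(
    solute: SoluteModel,
    cavity: Cavity,
    n_samples: int = 200_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the cloud charge outside the cavity volume.

    Samples each cloud's Gaussian density directly (std 1/√(2α) per axis)
    and tests against the union of cavity spheres.  Returns (charge in e,
    1σ sampling error).
    """
    rng = np.random.default_rng(seed)
    centers = np.array([s.center for s in cavity.spheres])
    radii = np.array([s.radius for s in cavity.spheres])
    total = 0.0
    var = 0.0
    for c in solute.clouds:
        std_angstrom = 1.0 / np.sqrt(2.0 * c.exponent) / BOHR_PER_ANGSTROM
        pts = c.position + rng.normal(scale=std_angstrom, size=(n_samples, 3))
        inside = np.zeros(n_samples, dtype=bool)
        for ctr, rad in zip(centers, radii):
            d2 = np.einsum("ij,ij->i", pts - ctr, pts - ctr)
            inside |= d2 < rad * rad
        p_out = float(np.count_nonzero(~inside)) / n_samples
        total += c.charge * p_out
        var += (c.charge**2) * p_out * (1.0 - p_out) / n_samples
    return total, float(np.sqrt(var))


def _solve_anion_exponent(radius_angstrom: float, fraction_inside: float) -> float:
    """Exponent α putting `1 − fraction_inside` of a centered cloud outside."""
    r_bohr = radius_angstrom * BOHR_PER_ANGSTROM

    def f(a: float) -> float:
        return enclosed_cloud_charge(1.0, a, r_bohr) - fraction_inside

    return brentq(f, 1e-4, 1e3)


FIXTURE_NAMES = ("born_ion", "born_anion", "diatomic", "water_like", "chain9")

_WATER_GEOM = {
    # positions Å, (element radius Å already ×1.18 Rowland–Taylor scaling)
    "O": (np.array([0.0, 0.0, 0.1173]), 1.52 * 1.18, 8.0),
    "H1": (np.array([0.0, 0.7572, -0.4692]), 1.10 * 1.18, 1.0),
    "H2": (np.array([0.0, -0.7572, -0.4692]), 1.10 * 1.18, 1.0),
}


def make_fixture(name: str, seed: int = 0) -> tuple[SoluteModel, list[Sphere]]:
    """Deterministic desk-scale solute/sphere stand-ins.

    born_ion    : +1 point charge centered in a 2 Å sphere (the Born ion).
    born_anion  : Z=8 nucleus + a −9 e cloud tuned so ~1% of the cloud
                  charge lies outside the 2 Å sphere.
    diatomic    : homonuclear two-center model (N₂-like bond length).
    water_like  : 3-center bent model with a polar charge split.
    chain9      : 9 colinear overlapping spheres emulating an n-nonane
                  backbone (area/merging stress test; neutral clouds).
    """
    if name == "born_ion":
        solute = SoluteModel(nuclei=[Nucleus([0.0, 0.0, 0.0], 1.0)])
        return solute, [Sphere([0.0, 0.0, 0.0], 2.0, origin=0)]
    if name == "born_anion":
        radius = 2.0
        alpha = _solve_anion_exponent(radius, 0.99)
        solute = SoluteModel(
            nuclei=[Nucleus([0.0, 0.0, 0.0], 8.0)],
            clouds=[GaussianCloud([0.0, 0.0, 0.0], -9.0, alpha)],
        )
        return solute, [Sphere([0.0, 0.0, 0.0], radius, origin=0)]
    if name == "diatomic":
        bond = 1.10
        radius = 1.55 * 1.18
        solute = SoluteModel(
            nuclei=[
                Nucleus([0.0, 0.0, -bond / 2], 7.0),
                Nucleus([0.0, 0.0, bond / 2], 7.0),
            ],
            clouds=[
                GaussianCloud([0.0, 0.0, -bond / 2], -7.0, 0.5),
                GaussianCloud([0.0, 0.0, bond / 2], -7.0, 0.5),
            ],
        )
        spheres = [
            Sphere([0.0, 0.0, -bond / 2], radius, origin=0),
            Sphere([0.0, 0.0, bond / 2], radius, origin=1),
        ]
        return solute, spheres
    if name == "water_like":
        nuclei, clouds, spheres = [], [], []
        cloud_charge = {"O": -8.4, "H1": -0.8, "H2": -0.8}
        alpha = {"O": 0.8, "H1": 1.2, "H2": 1.2}
        for i, (key, (pos, rad, z)) in enumerate(_WATER_GEOM.items()):
            nuclei.append(Nucleus(pos, z))
            clouds.append(GaussianCloud(pos, cloud_charge[key], alpha[key]))
            spheres.append(Sphere(pos, rad, origin=i))
        return SoluteModel(nuclei=nuclei, clouds=clouds), spheres
    if name == "chain9":
        spacing = 1.53
        radius = 2.0
        nuclei, clouds, spheres = [], [], []
        for i in range(9):
            pos = np.array([i * spacing, 0.0, 0.0])
            nuclei.append(Nucleus(pos, 6.0))
            clouds.append(GaussianCloud(pos, -6.0, 0.6))
            spheres.append(Sphere(pos, radius, origin=i))
        return SoluteModel(nuclei=nuclei, clouds=clouds), spheres
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
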