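"""End-to-end COSMO driver.

radii → spheres → cavity (vdW/SES) → merge → potentials → Coulomb matrix
(KS/YK) → conductor solve → outlying-charge correction → corrected
potential → dielectric scaling → energy → COSMO file record + σ-profile.

Solutes come either from the built-in fixture catalogue or from an XYZ
file, in which case each atom gets its point nucleus plus one neutral
Gaussian cloud (charge −Z) of configurable exponent.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import correction as corr
from . import screening as scr
from .cavity import AUXILIARY, Cavity, CavityParams, Sphere, build_cavity
from .io import CosmoFileRecord, RadiiTable, ROWLAND_TAYLOR_RADII, read_radii_file, read_xyz
from .sigma import SigmaProfile, sigma_profile
from .solute import (
    GaussianCloud,
    Nucleus,
    SoluteModel,
    make_fixture,
    potential_split,
)

__all__ = ["RunConfig", "CosmoResult", "run_cosmo", "Z_BY_ELEMENT"]

logger = logging.getLogger("cosmosol")

Z_BY_ELEMENT = {
    "H": 1, "C": 6, "N": 7, "O": 8, "F": 9,
    "P": 15, "S": 16, "Cl": 17, "Br": 35, "I": 53,
}
ELEMENT_BY_Z = {v: k for k, v in Z_BY_ELEMENT.items()}


@dataclass
class RunConfig:
    """Directives for a single COSMO run (defaults are the out-of-box ones:
    YK method, vdW cavity, fine tessellation, mfactor 1.0, rsolv 1.3 Å,
    radii scale 1.18, ideal screening, Lagrangian charge correction)."""

    fixture: "str | None" = None
    seed: int = 0
    xyz: "str | None" = None
    radii: "str | None" = None
    radii_scale: float = 1.18
    method: str = "yk"  # "ks" | "yk"
    cavity_type: str = "vdw"  # "vdw" | "ses"
    ndiv: str = "fine"
    rsolv: float = 1.3
    mfactor: float = 1.0
    ofac: float = 0.8
    rmin: float = 0.5
    screen: str = "ideal"  # "ideal" | "ks" | "st"
    eps: float = float("inf")
    charge_correction: str = "lagrangian"  # "off" | "scale" | "lagrangian"
    lineq: str = "auto"  # "dense" | "iterative" | "auto"
    potcorr: bool = False  # legacy energy: uncorrected potential
    cloud_exponent: float = 0.6  # Bohr⁻², for XYZ-derived solute models
    gas_energy: float = 0.0  # Hartree, reference energy of the solute model


@dataclass
class CosmoResult:
    energy: corr.EnergyReport
    record: CosmoFileRecord
    profile: SigmaProfile
    cavity: Cavity
    solute: SoluteModel
    q: np.ndarray  # uncorrected conductor charges
    q_prime: np.ndarray  # corrected (and dielectric-scaled) charges
    phi: np.ndarray
    phi_prime: np.ndarray
    defect_before: float
    defect_after: float
    f_N: float
    f_e: float
    lam: "float | None"
    f_eps: float

    def __iter__(self):
        return iter((self.energy, self.record, self.profile))


def _solute_from_xyz(config: RunConfig) -> tuple[SoluteModel, list[Sphere]]:
    atoms = read_xyz(config.xyz)
    table = (
        read_radii_file(config.radii, scale=config.radii_scale)
        if config.radii
        else RadiiTable(dict(ROWLAND_TAYLOR_RADII), scale=config.radii_scale)
    )
    nuclei, clouds, spheres = [], [], []
    for i, (el, pos) in enumerate(atoms):
        if el not in Z_BY_ELEMENT:
            raise ValueError(f"no atomic number known for element {el!r}")
        z = float(Z_BY_ELEMENT[el])
        nuclei.append(Nucleus(pos, z))
        clouds.append(GaussianCloud(pos, -z, config.cloud_exponent))
        spheres.append(Sphere(pos, table.lookup(el), origin=i))
    return SoluteModel(nuclei=nuclei, clouds=clouds), spheres


def _log(stage: str, **payload) -> None:
    logger.info(json.dumps({"stage": stage, **payload}))


def run_cosmo(
    config: RunConfig,
    solute: "SoluteModel | None" = None,
    spheres: "list[Sphere] | None" = None,
) -> CosmoResult:
    """Run the full pipeline; inputs may also be passed in-memory."""
    if solute is None or spheres is None:
        if config.fixture is not None:
            solute, spheres = make_fixture(config.fixture, config.seed)
        elif config.xyz is not None:
            solute, spheres = _solute_from_xyz(config)
        else:
            raise ValueError("run_cosmo needs a fixture name, an XYZ file, or in-memory inputs")

    params = CavityParams(
        cavity_type=config.cavity_type,
        level=config.ndiv,
        rsolv=config.rsolv,
        mfactor=config.mfactor,
        ofac=config.ofac,
        rmin=config.rmin,
    )
    cavity = build_cavity(spheres, params)
    _log(
        "cavity",
        n_spheres=len(cavity.spheres),
        n_segments=len(cavity.segments),
        area=cavity.area,
        volume=cavity.volume,
    )

    split = potential_split(solute, cavity.centers)
    if config.method == "ks":
        A = scr.build_A_ks(cavity.segments)
    elif config.method == "yk":
        zbar = scr.calibrate_yk(config.ndiv)
        A = scr.build_A_yk(cavity.segments, scr.yk_exponents(cavity.segments, zbar))
    else:
        raise ValueError(f"method must be 'ks' or 'yk', got {config.method!r}")

    charges = scr.solve_screening(
        A, split.phi, method=config.lineq, phi_N=split.phi_N, phi_e=split.phi_e
    )
    Q_N, Q_e, Q = solute.Q_N, solute.Q_e, solute.total_charge
    defect_before = corr.charge_defect(charges.q, Q)

    f_N = f_e = 1.0
    lam = None
    if config.charge_correction == "off":
        q_prime = charges.q
        q_N_prime, q_e_prime = charges.q_N, charges.q_e
    elif config.charge_correction == "scale":
        q_N_prime, q_e_prime, f_N, f_e = corr.correct_scale(
            charges.q_N, charges.q_e, Q_N, Q_e
        )
        q_prime = q_N_prime + q_e_prime
    elif config.charge_correction == "lagrangian":
        q_prime, lam = corr.correct_lagrangian(A, split.phi, Q)
        q_N_prime = charges.q_N
        q_e_prime = q_prime - charges.q_N
    else:
        raise ValueError(
            f"charge_correction must be off|scale|lagrangian, got {config.charge_correction!r}"
        )
    defect_after = corr.charge_defect(q_prime, Q)
    _log(
        "correction",
        mode=config.charge_correction,
        defect_before=defect_before,
        defect_after=defect_after,
        f_N=f_N,
        f_e=f_e,
    )

    # with correction off, Φ′ = −Aq = Φ by the solved system: keep it exact
    if config.charge_correction == "off":
        phi_prime, phi_e_prime = split.phi, split.phi_e
    else:
        phi_prime, phi_e_prime = corr.corrected_potential(A, q_prime, split.phi_N)

    f_eps = scr.scale_factor(scr.ScreenOption(config.screen, config.eps))
    q_final = f_eps * q_prime

    # E_diel = ½ Φ′ᵀ q′_ε : solute-side boundary potential times the
    # (corrected, dielectric-scaled) screening charges
    e_corr = corr.dielectric_energy(phi_prime, q_final)
    e_legacy = corr.dielectric_energy(split.phi, q_final)
    energy = corr.EnergyReport(
        e_diel=e_legacy if config.potcorr else e_corr,
        e_diel_legacy=e_legacy,
        correction_mode=config.charge_correction,
        potential_corrected=not config.potcorr,
    )
    _log("energy", e_diel=energy.e_diel, e_diel_legacy=energy.e_diel_legacy)

    record = _make_record(config, solute, cavity, q_final, phi_prime, energy, f_N, f_e)
    profile = sigma_profile(cavity.areas, q_final)
    return CosmoResult(
        energy=energy,
        record=record,
        profile=profile,
        cavity=cavity,
        solute=solute,
        q=charges.q,
        q_prime=q_final,
        phi=split.phi,
        phi_prime=phi_prime,
        defect_before=defect_before,
        defect_after=defect_after,
        f_N=f_N,
        f_e=f_e,
        lam=lam,
        f_eps=f_eps,
    )


def _make_record(
    config: RunConfig,
    solute: SoluteModel,
    cavity: Cavity,
    q: np.ndarray,
    phi: np.ndarray,
    energy: corr.EnergyReport,
    f_N: float,
    f_e: float,
) -> CosmoFileRecord:
    settings = {
        "method": config.method,
        "cavity": config.cavity_type,
        "ndiv": config.ndiv,
        "rsolv": config.rsolv,
        "mfactor": config.mfactor,
        "screen": config.screen,
        "epsilon": "inf" if math.isinf(config.eps) else config.eps,
        "charge_correction": config.charge_correction,
        "f_N": f_N,
        "f_e": f_e,
    }
    energies = {
        "gas": config.gas_energy,
        "solvated": config.gas_energy + energy.e_diel,
        "dielectric": energy.e_diel,
    }
    atoms = []
    for sph in cavity.spheres:
        if sph.origin == AUXILIARY:
            continue
        idx = int(sph.origin)
        z = solute.nuclei[idx].charge if idx < len(solute.nuclei) else 0.0
        el = ELEMENT_BY_Z.get(int(round(z)), "X")
        atoms.append(
            (el, float(sph.center[0]), float(sph.center[1]), float(sph.center[2]),
             float(sph.radius))
        )
    rows = np.empty((len(cavity.segments), 8))
    for i, seg in enumerate(cavity.segments):
        rows[i] = (
            seg.sphere_id + 1,
            seg.center[0],
            seg.center[1],
            seg.center[2],
            seg.area,
            q[i],
            q[i] / seg.area,
            phi[i],
        )
    return CosmoFileRecord(
        settings=settings, energies=energies, atoms=atoms, segments=rows
    )
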