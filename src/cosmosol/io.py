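"""File formats: sectioned COSMO output files, radii tables, XYZ input.

The COSMO file is a line-oriented, sectioned text format in the spirit of
the Turbomole cosmo file: a settings block, an energy block, the molecular
geometry with radii, and one row per surface segment (position, area,
corrected charge, charge density, solute potential).  It is written so
that `read_cosmo_file(write_cosmo_file(x))` recovers every numeric field
at the printed precision.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CosmoFileRecord",
    "RadiiTable",
    "ROWLAND_TAYLOR_RADII",
    "write_cosmo_file",
    "read_cosmo_file",
    "read_radii_file",
    "read_xyz",
]

# Rowland & Taylor crystallographic vdW radii (Å); applied radii are these
# times the table scale (default 1.18, the "rt18" convention).
ROWLAND_TAYLOR_RADII: dict[str, float] = {
    "H": 1.10,
    "C": 1.77,
    "N": 1.64,
    "O": 1.58,
    "F": 1.46,
    "P": 1.80,
    "S": 1.81,
    "Cl": 1.76,
    "Br": 1.87,
    "I": 2.03,
}


@dataclass
class RadiiTable:
    radii: dict[str, float]  # tabulated radii, Å
    scale: float = 1.18

    def lookup(self, element: str) -> float:
        """Applied radius (tabulated × scale) for an element."""
        if element not in self.radii:
            raise ValueError(
                f"element {element!r} is missing from the radii table "
                f"(known: {sorted(self.radii)})"
            )
        return self.radii[element] * self.scale


def read_radii_file(source, scale: float = 1.18) -> RadiiTable:
    """Parse an element→radius table ('El  radius_Å' per line, # comments)."""
    text = _read_text(source)
    radii: dict[str, float] = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"malformed radii line: {raw!r}")
        el, r = parts[0], float(parts[1])
        if el in radii:
            raise ValueError(f"duplicate radii entry for element {el!r}")
        if r <= 0:
            raise ValueError(f"nonpositive radius {r} for element {el!r}")
        radii[el] = r
    return RadiiTable(radii=radii, scale=scale)


def read_xyz(source) -> list[tuple[str, np.ndarray]]:
    """Standard XYZ: count line, comment line, then 'El x y z' rows (Å)."""
    lines = _read_text(source).splitlines()
    if not lines:
        raise ValueError("empty XYZ input")
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise ValueError(f"XYZ count line is not an integer: {lines[0]!r}") from None
    rows = [l for l in lines[2:] if l.strip()]
    if len(rows) < n:
        raise ValueError(f"XYZ declares {n} atoms but only {len(rows)} rows found")
    atoms = []
    for raw in rows[:n]:
        parts = raw.split()
        if len(parts) < 4:
            raise ValueError(f"malformed XYZ row: {raw!r}")
        atoms.append((parts[0], np.array([float(p) for p in parts[1:4]])))
    return atoms


@dataclass
class CosmoFileRecord:
    """Everything the COSMO output file carries."""

    settings: dict[str, object]  # method, cavity, ndiv, rsolv, mfactor,
    #                              screen, epsilon, charge_correction, f_N, f_e
    energies: dict[str, float]  # gas, solvated, dielectric (Hartree)
    atoms: list[tuple[str, float, float, float, float]]  # el, x, y, z, radius
    segments: np.ndarray  # columns: atom_index, x, y, z, area, charge, sigma, phi

    def __post_init__(self) -> None:
        self.segments = np.atleast_2d(np.asarray(self.segments, dtype=float))

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]

    @property
    def total_charge(self) -> float:
        return float(self.segments[:, 5].sum()) if self.n_segments else 0.0


_SETTINGS_ORDER = [
    "method",
    "cavity",
    "ndiv",
    "rsolv",
    "mfactor",
    "screen",
    "epsilon",
    "charge_correction",
    "f_N",
    "f_e",
]

_ENERGY_ORDER = ["gas", "solvated", "dielectric"]


def write_cosmo_file(record: CosmoFileRecord, destination) -> None:
    """Emit the sectioned COSMO text file."""
    if record.n_segments == 0 or record.segments.size == 0:
        raise ValueError("refusing to write a COSMO file with no segments")
    out = []
    out.append("$cosmo")
    for key in _SETTINGS_ORDER:
        if key in record.settings:
            val = record.settings[key]
            if isinstance(val, float):
                out.append(f"  {key} = {val:.8f}")
            else:
                out.append(f"  {key} = {val}")
    out.append(f"  nps = {record.n_segments}")
    out.append("$cosmo_energy")
    for key in _ENERGY_ORDER:
        if key in record.energies:
            out.append(f"  {key} [Hartree] = {record.energies[key]:.10f}")
    out.append("$coord_car")
    out.append("  # element x y z radius [Å]")
    for el, x, y, z, r in record.atoms:
        out.append(f"  {el:<2s} {x:15.8f} {y:15.8f} {z:15.8f} {r:12.8f}")
    out.append("$segment_information")
    out.append("  # n atom x y z area charge sigma potential")
    for k, row in enumerate(record.segments, start=1):
        atom = int(row[0])
        out.append(
            f"  {k:6d} {atom:5d} "
            f"{row[1]:15.8f} {row[2]:15.8f} {row[3]:15.8f} "
            f"{row[4]:14.8f} {row[5]:15.10f} {row[6]:15.10f} {row[7]:15.10f}"
        )
    out.append("$end")
    text = "\n".join(out) + "\n"
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        Path(destination).write_text(text)


def read_cosmo_file(source) -> CosmoFileRecord:
    """Parse a sectioned COSMO file back into a record."""
    text = _read_text(source)
    blocks: dict[str, list[str]] = {}
    current: "str | None" = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("$"):
            current = line[1:].split()[0]
            blocks[current] = []
            continue
        if current is not None:
            blocks[current].append(line)
    for required in ("cosmo", "cosmo_energy", "coord_car", "segment_information"):
        if required not in blocks:
            raise ValueError(f"COSMO file is missing the ${required} block")

    settings: dict[str, object] = {}
    nps = None
    for line in blocks["cosmo"]:
        if "=" not in line:
            raise ValueError(f"malformed settings line in $cosmo block: {line!r}")
        key, val = (p.strip() for p in line.split("=", 1))
        if key == "nps":
            nps = int(val)
            continue
        try:
            settings[key] = float(val)
        except ValueError:
            settings[key] = val
    energies: dict[str, float] = {}
    for line in blocks["cosmo_energy"]:
        key = line.split("[", 1)[0].strip()
        energies[key] = float(line.split("=", 1)[1])
    atoms = []
    for line in blocks["coord_car"]:
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"malformed geometry line: {line!r}")
        atoms.append(
            (parts[0], float(parts[1]), float(parts[2]), float(parts[3]), float(parts[4]))
        )
    rows = []
    for line in blocks["segment_information"]:
        parts = line.split()
        if len(parts) != 9:
            raise ValueError(f"malformed segment line: {line!r}")
        rows.append([float(p) for p in parts[1:]])
    if nps is not None and nps != len(rows):
        raise ValueError(
            f"segment count mismatch: header declares {nps}, found {len(rows)} rows"
        )
    return CosmoFileRecord(
        settings=settings,
        energies=energies,
        atoms=atoms,
        segments=np.asarray(rows),
    )


def _read_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    p = Path(source)
    if p.exists():
        return p.read_text()
    if isinstance(source, str) and "\n" in source:
        return source
    raise FileNotFoundError(f"no such file: {source}")
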