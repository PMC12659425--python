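"""σ-profiles: area-weighted histograms of surface charge densities.

The σ-profile p(σ) is the molecular descriptor consumed by COSMO-RS /
COSMO-SAC activity-coefficient models: each surface segment contributes
its area to the bin containing its charge density σ_i = q_i/s_i.  Tails
beyond the histogram range are clamped into the end bins with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SigmaProfile", "sigma_profile", "DEFAULT_HB_CUTOFF"]

DEFAULT_HB_CUTOFF = 0.0084  # e/Å²; |σ| beyond this marks HB-active surface


@dataclass
class SigmaProfile:
    bin_centers: np.ndarray  # σ, e/Å²
    weights: np.ndarray  # area per bin, Å²
    bin_width: float
    hb_donor_cutoff: float = -DEFAULT_HB_CUTOFF
    hb_acceptor_cutoff: float = DEFAULT_HB_CUTOFF

    @property
    def total_area(self) -> float:
        return float(self.weights.sum())

    def to_csv(self, destination) -> None:
        header = "sigma_e_per_A2,area_A2"
        body = "\n".join(
            f"{s:.6f},{w:.10f}" for s, w in zip(self.bin_centers, self.weights)
        )
        text = header + "\n" + body + "\n"
        if hasattr(destination, "write"):
            destination.write(text)
        else:
            from pathlib import Path

            Path(destination).write_text(text)


def sigma_profile(
    areas: np.ndarray,
    charges: np.ndarray,
    bin_width: float = 0.001,
    sigma_range: tuple[float, float] = (-0.025, 0.025),
    hb_cutoff: float = DEFAULT_HB_CUTOFF,
) -> SigmaProfile:
    """Histogram the charge densities σ_i = q_i/s_i weighted by area s_i."""
    if bin_width <= 0:
        raise ValueError(f"bin width must be positive, got {bin_width}")
    areas = np.asarray(areas, dtype=float)
    charges = np.asarray(charges, dtype=float)
    if areas.shape != charges.shape:
        raise ValueError("areas and charges must have matching shapes")
    lo, hi = sigma_range
    n_bins = int(round((hi - lo) / bin_width))
    sigma = charges / areas
    idx = np.floor((sigma - lo) / bin_width).astype(int)
    if np.any((idx < 0) | (idx >= n_bins)):
        warnings.warn(
            "charge densities outside the histogram range were clamped "
            "into the end bins",
            stacklevel=2,
        )
        idx = np.clip(idx, 0, n_bins - 1)
    weights = np.bincount(idx, weights=areas, minlength=n_bins)
    centers = lo + (np.arange(n_bins) + 0.5) * bin_width
    return SigmaProfile(
        bin_centers=centers,
        weights=weights,
        bin_width=bin_width,
        hb_donor_cutoff=-hb_cutoff,
        hb_acceptor_cutoff=hb_cutoff,
    )
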