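"""Spectrum normalization: TSA, PQN, metabolite-panel scaling and replicate QC.

HSQC intensities depend on both concentration and label incorporation, so
HSQC spectra cannot be normalized on their own area.  Instead, scaling
factors are computed on the paired 1D spectrum of the same sample — total
spectral area (TSA), probabilistic quotient normalization (PQN), or the
summed intensity of a selected metabolite panel — and transferred to the
HSQC quantification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import Spectrum1D

__all__ = [
    "ScalingFactor",
    "tsa_factor",
    "pqn_factor",
    "panel_factor",
    "median_reference",
    "replicate_cv",
]


@dataclass(frozen=True)
class ScalingFactor:
    method: str  # "TSA", "PQN" or "metabolite_panel"
    value: float
    reference_id: str = ""

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"scaling factor must be positive, got {self.value}")


def tsa_factor(spectrum: Spectrum1D, target_area: float = 1.0) -> ScalingFactor:
    """Total-spectral-area factor.

    The factor is the summed absolute intensity outside excluded regions
    divided by ``target_area``; dividing the spectrum by the factor gives
    the target area.  Absolute intensities make the sum robust to small
    negative baseline excursions.
    """
    area = float(np.sum(np.abs(spectrum.intensity[spectrum.exclusion_mask()])))
    if area == 0:
        raise ValueError("cannot TSA-scale an all-zero spectrum")
    return ScalingFactor("TSA", area / target_area)


def pqn_factor(
    spectrum: Spectrum1D,
    reference: Spectrum1D,
    noise_floor: float | None = None,
    min_points: int = 20,
) -> ScalingFactor:
    """Probabilistic quotient normalization factor.

    The factor is the median of point-wise intensity quotients
    spectrum/reference over informative points — those where the reference
    exceeds a noise floor (default 5× the median absolute deviation of the
    reference, which excludes baseline-only quotients).  Both spectra must
    share an axis and should be TSA pre-scaled, the standard PQN
    prerequisite.
    """
    if spectrum.axis.n_points != reference.axis.n_points:
        raise ValueError("spectrum and reference must share a common axis")
    keep = spectrum.exclusion_mask() & reference.exclusion_mask()
    y, r = spectrum.intensity[keep], reference.intensity[keep]
    if noise_floor is None:
        med = np.median(r)
        noise_floor = 5.0 * float(np.median(np.abs(r - med)))
    informative = np.abs(r) > noise_floor
    if informative.sum() < min_points:
        raise ValueError(
            f"only {int(informative.sum())} informative points above the noise floor "
            f"(minimum {min_points})"
        )
    quotients = y[informative] / r[informative]
    return ScalingFactor("PQN", float(np.median(quotients)))


def panel_factor(
    spectrum: Spectrum1D,
    panel: list[tuple[float, float]],
    target_area: float = 1.0,
) -> ScalingFactor:
    """Scaling on the summed intensity of selected metabolite regions.

    Useful when systematic changes affect many metabolites and whole-
    spectrum methods fail; e.g. the summed branched-chain amino acid
    signals can serve as the reference panel.
    """
    if not panel:
        raise ValueError("panel must contain at least one ppm interval")
    lo, hi = spectrum.axis.values.min(), spectrum.axis.values.max()
    total = 0.0
    v = spectrum.axis.values
    for a, b in panel:
        if min(a, b) < lo - 1e-9 or max(a, b) > hi + 1e-9:
            raise ValueError(f"panel interval ({a}, {b}) outside the axis")
        sel = (v >= min(a, b)) & (v <= max(a, b))
        total += float(np.sum(np.abs(spectrum.intensity[sel])))
    return ScalingFactor("metabolite_panel", total / target_area)


def median_reference(spectra: list[Spectrum1D]) -> Spectrum1D:
    """Point-wise median spectrum, the conventional PQN reference."""
    if not spectra:
        raise ValueError("need at least one spectrum")
    stack = np.stack([s.intensity for s in spectra])
    return Spectrum1D(spectra[0].axis, np.median(stack, axis=0),
                      list(spectra[0].excluded_regions), ["median reference"])


def replicate_cv(
    spectra: list[Spectrum1D],
    peak_regions: list[tuple[float, float]],
) -> dict[tuple[float, float], float | None]:
    """Per-region coefficient of variation (%) across TSA-scaled replicates.

    Replicate 1D intensities should agree to within a few percent for a
    quantitative labelled/unlabelled comparison to be meaningful; this
    metric makes that reproducibility requirement checkable.  Regions with
    zero mean are flagged with ``None`` instead of being divided.
    """
    if len(spectra) < 3:
        raise ValueError("replicate CV requires at least 3 replicates")
    out: dict[tuple[float, float], float | None] = {}
    for region in peak_regions:
        integrals = np.array([s.integrate(*region) for s in spectra])
        mean = integrals.mean()
        if mean == 0:
            out[region] = None
        else:
            out[region] = float(100.0 * integrals.std(ddof=1) / mean)
    return out
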