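"""Synthetic paired labelled/unlabelled cell-extract datasets.

Generates mock polar-extract data with the statistical structure the
workflow assumes: a metabolite panel with concentrations, a labelled arm
whose isotopomer distributions follow rule-based precursor presets
(glycolysis, PC/PDH entry into the Krebs cycle, glutaminolysis,
one-carbon metabolism), a natural-abundance control arm at x = 1.1%,
replicate-to-replicate multiplicative intensity jitter at a configurable
CV target, and additive time-domain Gaussian noise.

The labelling rules are single-turn bookkeeping, not a flux model: each
precursor maps to fragment labelling states of the shipped panel through
the textbook atom transitions, mixed by user-supplied pathway weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .metabolites import METABOLITE_TABLE, get_spin_system
from .spectra import (
    Axis,
    DEFAULT_WATER_REGION,
    HSQCComponent,
    HSQCSpectrum,
    Spectrum1D,
    build_hsqc,
    process_1d,
    simulate_fid,
)
from .spin_model import IsotopomerDistribution
from .quantification import NATURAL_ABUNDANCE_13C

__all__ = [
    "ExperimentDesign",
    "ExtractDataset",
    "generate_extract_dataset",
    "preset_labelling",
    "PRECURSORS",
    "natural_abundance_distribution",
    "DEFAULT_PANEL",
]

PRECURSORS = ("U13C_glucose", "glc_1_2_13C", "gln_3_13C", "pyr_3_13C",
              "ac_2_13C", "ser_U13C15N")

#: Default metabolite panel with polar-extract concentrations (mM-scale
#: relative units) typical of a 10–20 million cell extract.
DEFAULT_PANEL: dict[str, float] = {
    "lactate": 5.0,
    "alanine": 2.0,
    "glutamate": 3.0,
    "aspartate": 1.0,
    "malate": 0.8,
    "serine": 1.0,
    "creatine": 1.5,
}

#: 1D ¹H reporter peaks per metabolite: (ppm, relative proton weight).
_PROTON_PEAKS: dict[str, list[tuple[float, float]]] = {
    "lactate": [(1.31, 3.0), (4.10, 1.0)],
    "alanine": [(1.48, 3.0), (3.78, 1.0)],
    "glutamate": [(2.05, 2.0), (2.34, 2.0), (3.75, 1.0)],
    "aspartate": [(2.68, 2.0), (3.89, 1.0)],
    "malate": [(2.37, 2.0), (4.30, 1.0)],
    "serine": [(3.83, 1.0), (3.94, 2.0)],
    "creatine": [(3.03, 3.0), (3.93, 2.0)],
}


def natural_abundance_distribution(system=None) -> IsotopomerDistribution:
    """Isotopomer distribution of an unenriched fragment.

    Conditioned on the reporter carbon being ¹³C, each *existing*
    neighbouring carbon is independently labelled with probability 1.1%.
    Passing the spin system restricts the states to neighbours it actually
    has (e.g. creatine C2 has no higher-numbered carbon).
    """
    p = NATURAL_ABUNDANCE_13C
    p_left = p if (system is None or system.j_cc_left is not None) else 0.0
    p_right = p if (system is None or system.j_cc_right is not None) else 0.0
    fractions = {
        "singlet": (1 - p_left) * (1 - p_right),
        "d_left": p_left * (1 - p_right),
        "d_right": (1 - p_left) * p_right,
        "dd": p_left * p_right,
    }
    return IsotopomerDistribution({s: f for s, f in fractions.items() if f > 0})


@dataclass
class ExperimentDesign:
    """Study conditions for one paired labelled/control dataset."""

    panel: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PANEL))
    labelled_distributions: dict[str, IsotopomerDistribution] = field(default_factory=dict)
    labelled_x: dict[str, float] = field(default_factory=dict)
    n_replicates: int = 6
    cv_target: float = 2.0  # % multiplicative replicate jitter
    noise_snr: float = 200.0  # peak SNR of the 1D spectra
    seed: int = 0
    # 1D sweep matches a 600 MHz NOESY; the HSQC axes cover 0.65–5.15 ppm
    # (¹H) × 15–75 ppm (¹³C) at grid steps fine enough (≳3 points per
    # linewidth) for volume integrals to be quadrature-accurate
    axis_1d: Axis = field(default_factory=lambda: Axis(600.0, 4.8, 7183.9, 16384))
    axis_h: Axis = field(default_factory=lambda: Axis(600.0, 2.9, 2700.0, 1024))
    axis_c: Axis = field(default_factory=lambda: Axis(150.9, 45.0, 9000.0, 8192))

    def __post_init__(self) -> None:
        if not (0 < self.cv_target <= 10):
            raise ValueError("cv_target must be in (0, 10] percent")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        unknown = set(self.panel) - set(_PROTON_PEAKS)
        if unknown:
            raise ValueError(f"no peak table for metabolites: {sorted(unknown)}")


@dataclass
class ExtractDataset:
    """Paired labelled/control replicate spectra plus ground truth."""

    spectra_1d: dict[str, list[Spectrum1D]]  # arm -> replicates
    hsqc: dict[str, HSQCSpectrum]  # arm -> spectrum
    ground_truth: dict

    def save_ground_truth(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.ground_truth, indent=1))


#: Reporter atom quantified for each panel metabolite: the lactate methyl
#: (the calibration resonance), the Hα positions of the amino/hydroxy
#: acids, glutamate C4 (the Krebs-cycle entry reporter) and creatine C2
#: (the glycine-derived methylene).
REPORTER_ATOMS = {
    "lactate": "C3", "alanine": "C2", "glutamate": "C4", "aspartate": "C2",
    "malate": "C2", "serine": "C2", "creatine": "C2",
}


def _reporter_atom(metabolite: str) -> str:
    try:
        return REPORTER_ATOMS[metabolite]
    except KeyError:
        raise KeyError(f"no reporter atom defined for {metabolite}") from None


def generate_extract_dataset(design: ExperimentDesign) -> ExtractDataset:
    """Generate the paired labelled/control dataset for a design.

    Each replicate's per-peak intensities are jittered multiplicatively
    (lognormal-free, plain Gaussian factor with sd = cv_target %) on top
    of a common per-replicate dilution factor; TSA scaling removes the
    dilution, leaving the per-peak jitter as the residual replicate CV.
    Deterministic for a given design seed.
    """
    rng = np.random.default_rng(design.seed)
    nat = {m: natural_abundance_distribution(get_spin_system(m, _reporter_atom(m)))
           for m in design.panel}
    arms = {
        "control": {m: (nat[m], NATURAL_ABUNDANCE_13C) for m in design.panel},
        "labelled": {
            m: (design.labelled_distributions.get(m, nat[m]),
                design.labelled_x.get(m, NATURAL_ABUNDANCE_13C))
            for m in design.panel
        },
    }
    jitter_sd = design.cv_target / 100.0
    spectra_1d: dict[str, list[Spectrum1D]] = {}
    hsqc: dict[str, HSQCSpectrum] = {}
    truth: dict = {
        "design": {"cv_target": design.cv_target, "n_replicates": design.n_replicates,
                   "noise_snr": design.noise_snr, "seed": design.seed},
        "concentrations": dict(design.panel),
        "arms": {},
    }
    peak_max = max(conc * w for m, conc in design.panel.items()
                   for _, w in _PROTON_PEAKS[m])
    noise_sd = peak_max / design.noise_snr / np.sqrt(design.axis_1d.n_points)
    for arm, dists in arms.items():
        reps = []
        for r in range(design.n_replicates):
            dilution = 1.0 + 0.1 * rng.standard_normal()
            peaks = []
            for m, conc in design.panel.items():
                for ppm, weight in _PROTON_PEAKS[m]:
                    jitter = 1.0 + jitter_sd * rng.standard_normal()
                    peaks.append((ppm, conc * weight * dilution * jitter, 3.0))
            fid = simulate_fid(peaks, design.axis_1d, noise_sd,
                               seed=int(rng.integers(2**31)))
            spec = process_1d(fid, design.axis_1d, water_region=DEFAULT_WATER_REGION)
            reps.append(spec)
        spectra_1d[arm] = reps
        components = [
            HSQCComponent(get_spin_system(m, _reporter_atom(m)), dists[m][0],
                          design.panel[m], dists[m][1])
            for m in design.panel
        ]
        spec2d = build_hsqc(components, design.axis_h, design.axis_c)
        if design.noise_snr and np.isfinite(design.noise_snr):
            # SNR is quoted per resonance: the weakest quantified cross-peak
            # (typically a natural-abundance control signal) sits at the
            # design SNR, as required for quantitative comparison
            heights = []
            for comp in components:
                ih = design.axis_h.index_of(comp.system.shift_h)
                ic_lo = design.axis_c.index_of(comp.system.shift_c + 0.1)
                ic_hi = design.axis_c.index_of(comp.system.shift_c - 0.1)
                lo, hi = sorted((ic_lo, ic_hi))
                heights.append(float(np.abs(spec2d.intensity[lo:hi + 1, ih]).max()))
            sd = min(h for h in heights if h > 0) / design.noise_snr
            noise = sd * np.random.default_rng(int(rng.integers(2**31))) \
                .standard_normal(spec2d.intensity.shape)
            spec2d.intensity = spec2d.intensity + noise
        hsqc[arm] = spec2d
        truth["arms"][arm] = {
            m: {"x_label": dists[m][1],
                "fractions": dict(dists[m][0].items())}
            for m in design.panel
        }
    return ExtractDataset(spectra_1d, hsqc, truth)


def _mix(parts: list[tuple[float, dict[str, float]]]) -> IsotopomerDistribution:
    """Weighted mixture of state dictionaries, renormalized."""
    out: dict[str, float] = {}
    for w, states in parts:
        if w <= 0:
            continue
        for s, f in states.items():
            out[s] = out.get(s, 0.0) + w * f
    total = sum(out.values())
    if total <= 0:
        return natural_abundance_distribution()
    return IsotopomerDistribution({s: f / total for s, f in out.items()})


def preset_labelling(
    precursor: str,
    pathway_weights: dict[str, float] | None = None,
) -> dict[str, tuple[IsotopomerDistribution, float]]:
    """Rule-based isotopomer presets for a labelled precursor.

    Returns metabolite → (distribution of the reporter-carbon fragment,
    label incorporation x).  Pathway weights on [0, 1] modulate the branch
    points: ``glycolysis``, ``pc`` and ``pdh`` (Krebs-cycle entry),
    ``glutaminolysis``, ``oxidative_ppp`` and ``one_carbon``.  The rules
    encode single-turn atom bookkeeping:

    * [U-¹³C]glucose: pyruvate-derived lactate/alanine fragments fully
      labelled (DD-dominated); PC transfers the intact C1–C3 backbone to
      oxaloacetate (aspartate/malate C2 → DD) while PDH passes only the
      acetyl C1–C2 unit (C2 → coupling to the carboxyl, D_LEFT).
    * [1,2-¹³C]glucose: pyruvate labelled at C2,C3; PC gives the C2–C3
      pair (D_RIGHT, the smaller coupling), PDH gives C1–C2 (D_LEFT).
    * [3-¹³C]glutamine: glutamate C3 singlet via glutaminolysis.
    * [3-¹³C]pyruvate: lactate/alanine C3 singlets; serine via
      gluconeogenesis (PEP carboxykinase route).
    * [2-¹³C]acetate: glutamate C4 singlet after citrate synthase.
    * [U-¹³C,¹⁵N]serine: serine retains the intact ¹³C₃/¹⁵N skeleton
      (C2 → DD with ¹⁵N); one-carbon metabolism routes the glycine-derived
      C1–C2/¹⁵N moiety into creatine C2 → D_LEFT with ¹⁵N co-label.
    """
    if precursor not in PRECURSORS:
        raise ValueError(f"unknown precursor {precursor!r}; choose from {PRECURSORS}")
    w = {"glycolysis": 1.0, "pc": 0.5, "pdh": 0.5, "glutaminolysis": 1.0,
         "oxidative_ppp": 0.0, "one_carbon": 1.0, "krebs": 1.0}
    w.update(pathway_weights or {})
    for name, val in w.items():
        if not (0.0 <= val <= 1.0):
            raise ValueError(f"pathway weight {name} outside [0, 1]: {val}")

    nat_by_met = {m: natural_abundance_distribution(get_spin_system(m, _reporter_atom(m)))
                  for m in DEFAULT_PANEL}
    out: dict[str, tuple[IsotopomerDistribution, float]] = {
        m: (nat_by_met[m], NATURAL_ABUNDANCE_13C) for m in DEFAULT_PANEL
    }
    gly = w["glycolysis"]

    def x_of(weight: float, ceiling: float = 0.8) -> float:
        # bookkeeping incorporation level: route weight × a realistic ceiling
        return max(weight * ceiling, NATURAL_ABUNDANCE_13C)

    if precursor == "U13C_glucose":
        if gly > 0:
            # lactate methyl reporter pairs with C2 only; alanine Hα sees both
            out["lactate"] = (_mix([(gly, {"d_left": 1.0}),
                                    (1 - gly, nat_by_met["lactate"].fractions)]), x_of(gly))
            out["alanine"] = (_mix([(gly, {"dd": 1.0}),
                                    (1 - gly, nat_by_met["alanine"].fractions)]), x_of(gly))
        entry = w["pc"] + w["pdh"]
        if entry > 0 and gly > 0:
            asp = _mix([(w["pc"], {"dd": 1.0}), (w["pdh"], {"d_left": 1.0})])
            out["aspartate"] = (asp, x_of(gly * entry, 0.5))
            out["malate"] = (asp, x_of(gly * entry, 0.5))
            out["glutamate"] = (IsotopomerDistribution({"dd": 1.0}), x_of(gly * entry, 0.5))
    elif precursor == "glc_1_2_13C":
        if gly > 0:
            # C2,C3-labelled pyruvate: the lactate methyl pairs with C2
            # (d_left); the alanine Hα pairs with its C3 methyl (d_right);
            # oxidative PPP strips glucose C1 and dilutes the labelled pool
            x = x_of(gly * (1 - w["oxidative_ppp"]) / 2, 1.0)
            out["lactate"] = (_mix([(gly, {"d_left": 1.0}),
                                    (1 - gly, nat_by_met["lactate"].fractions)]), x)
            out["alanine"] = (_mix([(gly, {"d_right": 1.0}),
                                    (1 - gly, nat_by_met["alanine"].fractions)]), x)
        entry = w["pc"] + w["pdh"]
        if entry > 0 and gly > 0:
            asp = _mix([(w["pc"], {"d_right": 1.0}), (w["pdh"], {"d_left": 1.0})])
            out["aspartate"] = (asp, x_of(gly * entry, 0.3))
            out["malate"] = (asp, x_of(gly * entry, 0.3))
    elif precursor == "gln_3_13C":
        if w["glutaminolysis"] > 0:
            out["glutamate"] = (IsotopomerDistribution({"singlet": 1.0}),
                                x_of(w["glutaminolysis"], 0.6))
    elif precursor == "pyr_3_13C":
        if gly > 0:  # cytosolic reduction/transamination route weight
            out["lactate"] = (_mix([(gly, {"singlet": 1.0}),
                                    (1 - gly, nat_by_met["lactate"].fractions)]), x_of(gly))
            out["alanine"] = (_mix([(gly, {"singlet": 1.0}),
                                    (1 - gly, nat_by_met["alanine"].fractions)]), x_of(gly, 0.6))
        pck = w.get("gluconeogenesis", w["pc"])
        if pck > 0:
            out["serine"] = (IsotopomerDistribution({"singlet": 1.0}), x_of(pck, 0.2))
    elif precursor == "ac_2_13C":
        if w["krebs"] > 0:
            out["glutamate"] = (IsotopomerDistribution({"singlet": 1.0}),
                                x_of(w["krebs"], 0.4))
    elif precursor == "ser_U13C15N":
        uptake = w.get("uptake", 1.0)
        if uptake > 0:  # the intracellular pool exchanges with the labelled medium
            out["serine"] = (IsotopomerDistribution({"dd+n15": 1.0}), x_of(uptake))
        oc = w["one_carbon"]
        if oc > 0:
            out["creatine"] = (IsotopomerDistribution({"d_left+n15": 1.0}), x_of(oc, 0.3))
    return out
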