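"""Metabolite spin systems and isotopomer multiplet patterns.

In a ¹H,¹³C-HSQC of a ¹³C-tracer experiment, the multiplet observed in the
indirect ¹³C dimension at a given CH position is a superposition of the
resonances of the isotopomers present: an isolated ¹³C gives a singlet, a
¹³C with one labelled neighbour gives a doublet split by the one-bond
¹J_CC coupling to that neighbour, and a ¹³C flanked by two labelled
carbons gives a doublet of doublets.  ¹⁵N co-labelling adds a further
small ¹J_CN splitting and a ¹⁴N/¹⁵N isotope shift of the attached carbon.

This module represents the local three-carbon fragment around one reporter
carbon, renders its stick pattern for a given isotopomer mixture, and
converts sticks into continuous Lorentzian/Gaussian lineshapes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SpinSystem",
    "IsotopomerDistribution",
    "StickPattern",
    "LABEL_STATES",
    "stick_pattern",
    "render_multiplet",
    "apply_echo_antiecho_distortion",
    "lorentzian",
    "gaussian",
]

#: Labelling states of the central carbon of a three-carbon fragment.
#: SINGLET: ¹³C flanked by ¹²C on both sides; D_LEFT: ¹³C-¹³C pair with the
#: lower-numbered neighbour (coupling ``j_cc_left``); D_RIGHT: pair with the
#: higher-numbered neighbour (``j_cc_right``); DD: all three carbons ¹³C.
LABEL_STATES = ("singlet", "d_left", "d_right", "dd")

#: Suffix marking ¹⁵N co-labelling of a state, e.g. ``"dd+n15"``.
N15_SUFFIX = "+n15"


def split_state(state: str) -> tuple[str, bool]:
    """Return (carbon state, has ¹⁵N co-label) for a state key."""
    if state.endswith(N15_SUFFIX):
        base = state[: -len(N15_SUFFIX)]
    else:
        base = state
    if base not in LABEL_STATES:
        raise ValueError(f"unknown labelling state {state!r}")
    return base, state.endswith(N15_SUFFIX)


@dataclass(frozen=True)
class SpinSystem:
    """One reporter CH position of a metabolite.

    Couplings are one-bond scalar couplings in Hz: ``j_cc_left`` to the
    lower-numbered carbon (e.g. ¹J_C1C2 for a C2 reporter), ``j_cc_right``
    to the higher-numbered carbon (¹J_C2C3), and ``j_cn`` to a directly
    bonded nitrogen when ¹⁵N labelling is relevant.  ``multiplicity_x`` is
    the number of attached protons of the CHx group, which enters the
    HSQC transfer-function scaling.
    """

    metabolite_name: str
    atom_label: str
    shift_h: float
    shift_c: float
    multiplicity_x: int = 1
    j_cc_left: float | None = None
    j_cc_right: float | None = None
    j_cn: float | None = None
    shift_n: float | None = None

    def __post_init__(self) -> None:
        for name in ("j_cc_left", "j_cc_right", "j_cn"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.multiplicity_x not in (1, 2, 3):
            raise ValueError(f"multiplicity_x must be 1, 2 or 3, got {self.multiplicity_x}")
        if not (math.isfinite(self.shift_h) and math.isfinite(self.shift_c)):
            raise ValueError("chemical shifts must be finite")

    def to_dict(self) -> dict:
        return {
            "metabolite_name": self.metabolite_name,
            "atom_label": self.atom_label,
            "shift_h": self.shift_h,
            "shift_c": self.shift_c,
            "multiplicity_x": self.multiplicity_x,
            "j_cc_left": self.j_cc_left,
            "j_cc_right": self.j_cc_right,
            "j_cn": self.j_cn,
            "shift_n": self.shift_n,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpinSystem":
        return cls(**d)


@dataclass(frozen=True)
class IsotopomerDistribution:
    """Fractional abundances of the labelling states of one fragment.

    Keys are members of :data:`LABEL_STATES`, optionally suffixed
    ``"+n15"`` for ¹⁵N co-labelled populations.  Fractions refer to the
    molecules carrying ¹³C at the reporter position and must sum to one.
    """

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        for state, f in self.fractions.items():
            split_state(state)
            if not (-1e-12 <= f <= 1 + 1e-9):
                raise ValueError(f"fraction for {state!r} outside [0, 1]: {f}")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {total!r}")

    def __getitem__(self, state: str) -> float:
        return self.fractions.get(state, 0.0)

    def items(self):
        return self.fractions.items()

    def carbon_marginal(self) -> dict[str, float]:
        """Fractions summed over the ¹⁵N co-label, keyed by carbon state."""
        out = dict.fromkeys(LABEL_STATES, 0.0)
        for state, f in self.fractions.items():
            base, _ = split_state(state)
            out[base] += f
        return out


@dataclass
class StickPattern:
    """Delta-function representation of a multiplet.

    ``offsets_hz`` are line positions relative to the reporter carbon's
    chemical shift; ``amplitudes`` are relative weights (complex after
    echo-antiecho phase distortion, real otherwise).
    """

    offsets_hz: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.offsets_hz = np.asarray(self.offsets_hz, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes)
        if self.offsets_hz.shape != self.amplitudes.shape:
            raise ValueError("offsets and amplitudes must have equal length")

    @property
    def total_amplitude(self) -> float:
        return float(np.sum(self.amplitudes).real)

    def merged(self, tol: float = 1e-9) -> "StickPattern":
        """Coalesce lines closer than ``tol`` Hz (sums their amplitudes)."""
        order = np.argsort(self.offsets_hz)
        offs, amps = [], []
        for i in order:
            if offs and abs(self.offsets_hz[i] - offs[-1]) <= tol:
                amps[-1] = amps[-1] + self.amplitudes[i]
            else:
                offs.append(self.offsets_hz[i])
                amps.append(self.amplitudes[i])
        return StickPattern(np.array(offs), np.array(amps))


def _active_couplings(system: SpinSystem, state: str) -> list[float]:
    """Couplings splitting the given labelling state, erroring on gaps."""
    base, n15 = split_state(state)
    names = {"singlet": [], "d_left": ["j_cc_left"], "d_right": ["j_cc_right"],
             "dd": ["j_cc_left", "j_cc_right"]}[base]
    if n15:
        names = names + ["j_cn"]
    js = []
    for name in names:
        j = getattr(system, name)
        if j is None:
            raise ValueError(
                f"state {state!r} requires coupling {name} which is not defined "
                f"for {system.metabolite_name} {system.atom_label}"
            )
        js.append(j)
    return js


def stick_pattern(
    system: SpinSystem,
    dist: IsotopomerDistribution,
    n15_isotope_shift_hz: float = -3.0,
) -> StickPattern:
    """Render the ¹³C-dimension stick pattern of an isotopomer mixture.

    Each state with k active couplings contributes 2^k lines of equal
    amplitude at all ± J/2 sign combinations, so total amplitude is
    conserved under splitting.  ¹⁵N co-labelled states are additionally
    offset by the ¹⁴N/¹⁵N isotope shift of the attached carbon
    (``n15_isotope_shift_hz``; the default −3 Hz ≈ 0.02 ppm upfield at
    150.9 MHz is an arbitrary configuration value, not a literature one).
    """
    offsets: list[float] = []
    amplitudes: list[float] = []
    for state, frac in dist.items():
        if frac == 0:
            continue
        js = _active_couplings(system, state)
        _, n15 = split_state(state)
        center = n15_isotope_shift_hz if n15 else 0.0
        k = len(js)
        amp = frac / (2**k)
        for signs in itertools.product((-1.0, 1.0), repeat=k):
            offsets.append(center + sum(s * j / 2 for s, j in zip(signs, js)))
            amplitudes.append(amp)
    return StickPattern(np.array(offsets), np.array(amplitudes)).merged()


def lorentzian(axis_hz: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-area Lorentzian."""
    hwhm = fwhm / 2.0
    return (hwhm / np.pi) / ((axis_hz - center) ** 2 + hwhm**2)


def gaussian(axis_hz: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-area Gaussian."""
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    return np.exp(-0.5 * ((axis_hz - center) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))


def _lorentzian_complex(axis_hz: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Absorption + i·dispersion Lorentzian (phase-sensitive kernel)."""
    hwhm = fwhm / 2.0
    denom = (axis_hz - center) ** 2 + hwhm**2
    return (hwhm / np.pi) / denom + 1j * ((center - axis_hz) / np.pi) / denom


def _gaussian_complex(axis_hz: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Absorption + i·dispersion Gaussian via the Dawson function."""
    from scipy.special import dawsn

    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    u = (axis_hz - center) / (sigma * math.sqrt(2.0))
    norm = 1.0 / (sigma * math.sqrt(2 * math.pi))
    return norm * (np.exp(-(u**2)) + 1j * (2.0 / math.sqrt(math.pi)) * dawsn(u))


_SHAPES = {"lorentzian": lorentzian, "gaussian": gaussian}
_COMPLEX_SHAPES = {"lorentzian": _lorentzian_complex, "gaussian": _gaussian_complex}


@dataclass
class RenderedMultiplet:
    """Continuous multiplet plus a resolution warning flag."""

    intensity: np.ndarray
    axis_hz: np.ndarray
    undersampled: bool = False

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.intensity, dtype=dtype)


def render_multiplet(
    pattern: StickPattern,
    axis_hz: np.ndarray,
    fwhm: float,
    lineshape: str = "lorentzian",
) -> RenderedMultiplet:
    """Convolve a stick pattern with a unit-area lineshape.

    The numerical integral over a window much wider than the linewidth
    equals the total stick amplitude.  If the axis has fewer than three
    points per FWHM the result is flagged ``undersampled`` rather than
    rejected.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    axis_hz = np.asarray(axis_hz, dtype=float)
    steps = np.abs(np.diff(axis_hz))
    if steps.size and (np.any(steps <= 0) ^ np.all(steps > 0)) and not (
        np.all(np.diff(axis_hz) > 0) or np.all(np.diff(axis_hz) < 0)
    ):
        raise ValueError("axis must be monotone")
    complex_amps = np.iscomplexobj(pattern.amplitudes)
    # phase-rotated lines mix dispersion into the real lineshape, so complex
    # amplitudes are rendered with the phase-sensitive kernel
    shape = (_COMPLEX_SHAPES if complex_amps else _SHAPES)[lineshape]
    out = np.zeros(axis_hz.shape, dtype=complex if complex_amps else float)
    for off, amp in zip(pattern.offsets_hz, pattern.amplitudes):
        out += amp * shape(axis_hz, off, fwhm)
    undersampled = bool(steps.size and steps.max() > fwhm / 3.0)
    return RenderedMultiplet(out, axis_hz, undersampled)


def apply_echo_antiecho_distortion(
    pattern: StickPattern, j2_cc: float, encoding_delay: float
) -> StickPattern:
    """Phase-distort a pattern as echo-antiecho encoding does.

    Gradient coherence selection lets two-bond ²J_CC couplings evolve while
    the encoding gradient is applied, mixing dispersive character into the
    lines.  This is modelled as a single per-line phase rotation of
    π·²J_CC·delay radians — a parameterized approximation, not a
    density-matrix simulation.  A zero delay (or zero ²J_CC) returns the
    pure in-phase pattern, which is why in-phase acquisition in D₂O is the
    recommended mode for isotopomer fitting.
    """
    if encoding_delay < 0:
        raise ValueError("encoding_delay must be >= 0")
    phase = np.pi * j2_cc * encoding_delay
    if phase == 0:
        return replace(pattern)
    amps = pattern.amplitudes.astype(complex) * np.exp(1j * phase)
    return StickPattern(pattern.offsets_hz.copy(), amps)
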