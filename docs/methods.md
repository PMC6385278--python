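# Methods

## Spin model

Each quantified position is a local three-carbon fragment around one
reporter CH(x): the reporter's ¹H/¹³C shifts, the one-bond couplings
`j_cc_left` (to the lower-numbered carbon) and `j_cc_right` (to the
higher-numbered one), an optional `j_cn` to a directly bonded nitrogen,
and the proton multiplicity x ∈ {1,2,3}. Only one-bond couplings are
modelled: HSQC multiplets in the indirect dimension are ¹J-dominated and
long-range J_CC is below the linewidths of interest. Labelling states of
the fragment are `singlet`, `d_left`, `d_right`, `dd`, optionally
¹⁵N co-labelled (`…+n15`). A state with k active couplings contributes
2^k lines of equal weight at every ±J/2 sign combination, so total stick
amplitude is conserved under splitting; a mixture's pattern is the
fraction-weighted superposition. ¹⁵N states are additionally offset by a
¹⁴N/¹⁵N isotope shift of the attached carbon, default −3 Hz
(≈ 0.02 ppm upfield at 150.9 MHz). This default is an arbitrary
configuration value — the effect is real but its magnitude is
compound-dependent and not calibrated here.

Rendering convolves sticks with unit-area Lorentzians (absorption-mode
default) or Gaussians (for apodized spectra). Complex (phase-rotated)
amplitudes are rendered with the phase-sensitive kernel
absorption + i·dispersion, so a rotated line mixes dispersive character
into its real part.

Echo-antiecho coherence selection lets two-bond ²J_CC couplings evolve
while the encoding gradient plays out. We model this as a single per-line
phase rotation of π·²J_CC·τ radians — a deliberate parameterization, not
a density-matrix simulation: the package's recommendation (and the reason
the distortion is modelled at all) is that in-phase acquisition in D₂O
avoids the problem entirely, which the test suite documents by showing
that an absorption-mode isotopomer fit degrades (R² drops from 1.0 to
< 0.95) once the phase twist is switched on.

## Spectrum simulation and processing

FIDs are sums of exponentially damped complex oscillations with additive
complex Gaussian noise; a decay R gives a Lorentzian of FWHM R/π. 1D
processing follows standard metabolomics practice: 0.3 Hz exponential
apodization, zero-fill to 32768 points, FFT (orthonormal, so Parseval
holds exactly), zero-order autophase (maximizing the coherent real
integral — synthetic FIDs are generated in phase, so higher-order phase
correction is out of scope), and low-order polynomial baseline
correction fitted on points within 6 MAD of the median (signal-free
points dominate sparse metabolite spectra, making this selection safe).
The first FID point is halved before transformation to remove the
constant baseline offset. Water exclusion defaults to 4.7–4.9 ppm; the
bounds are an artifact default, as is any region list supplied per
study. ppm axes descend left-to-right and are anchored to the
spectrometer frequency (600 MHz ¹H / 150.9 MHz ¹³C defaults).

HSQC spectra are built directly in the frequency domain: each cross-peak
is the outer product of a ¹H Lorentzian (default FWHM 8 Hz) and the
rendered ¹³C multiplet (default FWHM 1.5 Hz), scaled by
Γ(x)·concentration·x_label. Γ is a per-multiplicity lookup (all 1.0 by
default) rather than an analytic transfer function: the
labelled-vs-control ratio cancels Γ, and absolute concentrations are a
non-goal. Peaks outside the window are collected in a clipping report
rather than dropped silently. Calibration shifts both axes so the
lactate methyl cross-peak reads δ 1.31/22.9 ppm; 1D referencing anchors
TMSP at δ 0.00 ppm. The time-domain path (interferogram simulation)
exists to feed the NUS module; routine HSQC construction is
frequency-domain.

## Normalization

TSA: summed absolute intensity outside excluded regions over a target
area; absolute values make the sum robust to small negative baseline
excursions. PQN: median quotient against a reference spectrum —
conventionally the median spectrum of the control group — over
informative points, i.e. points where the reference exceeds a noise
floor of 5× its median absolute deviation (this excludes baseline-only
quotients); TSA pre-scaling is the standard prerequisite. A
metabolite-panel factor (summed intensity over chosen ppm intervals)
covers the case where systematic changes affect many metabolites and
whole-spectrum methods fail. No automatic TSA/PQN switching is
attempted; the choice is configuration. Replicate quality is the
per-region CV (%) of integrated intensities across ≥ 3 TSA-scaled
replicates; 1–3 % is the working band for quantitative comparisons.

## Quantification

`percent = 100·(I_lab·S_ctl)/(I_ctl·S_lab)/f_NA` with f_NA = 100 by
default (the conventional "total carbon is 100× the observed ¹³C"
round number); `exact_natural_abundance` switches to 1/0.011 ≈ 90.91.
The two differ by a factor 1.1, i.e. the conventional readout
under-reports x by 9.1 % relative; recovery tests against ground truth
therefore use the exact factor, while reports default to the
convention. Values above 100 % are flagged and retained; clamping
happens only in rendered reports.

Cross-peak intensities are **fit-based**, not box integrals: the ¹H
columns within ±0.1 ppm are combined with matched-filter weights (the
expected ¹H lineshape), and the resulting ¹³C trace is fitted as an
isotopomer mixture restricted to a window of (ΣJ)/2 + 15 Hz around the
reporter shift. The reported intensity is the signed least-squares
multiplet area at the fitted shape parameters: the non-negative solution
is kept for fractions, but its positivity constraint rectifies noise
into a systematic upward area bias that matters precisely for the weak
natural-abundance control resonances, whereas the signed area is
unbiased. Labelled and control intensities share window and weights, so
the ¹H-profile factor cancels in their ratio.

The PC/PDH readout is `(f_d_right + f_dd/2)/(f_d_left + f_dd/2)` on the
aspartate/malate C2 fit; the doubly-labelled population is split equally
between the routes since both contribute to it, and a pure-PC pattern
returns an infinity sentinel rather than an error.

## Deconvolution

Variable projection: for trial (centre, FWHM, J…), state amplitudes come
from non-negative least squares; the shape parameters are refined by
bounded trust-region least squares on the projected residual. The
residual surface is multimodal in the centre, so the fit first scans a
coarse ±6 Hz grid (0.5 Hz steps) around the slice's centre of mass and
starts from the best cell; the centre is then bounded to ±3 linewidths.
Couplings are bounded to ±20 % of their configured values.
Initialization: FWHM 2 Hz, uniform fractions. The trace is normalized to
unit maximum before fitting so optimizer tolerances (ftol/xtol 1e-10)
are scale-free — fractions are scale-invariant by construction and
amplitudes are mapped back to data units. Fractions are renormalized to
sum to one; uncertainties come from the linearized covariance at the
optimum (bootstrap was considered and rejected for speed; the linearized
errors are adequate at the SNRs where fits are trusted at all). A
coupling whose supporting states carry < 1 % of the amplitude is
unidentifiable: it keeps its prior value, is listed as such, and gets
infinite uncertainty. Near-equal left/right couplings (within half a
linewidth) set an `unresolved` flag — the individual doublet fractions
are then aliased and only their sum is well determined.

`estimate_couplings` is the model-free cross-check: peak picking with
prominence filtering and three-point parabolic apex interpolation,
symmetric pairing about the median pair midpoint, and closed-form
decomposition of the pair separations (doublet → J; four lines →
(outer±inner)/2; eight lines → doublet of doublets of doublets).
Estimated splittings are assigned to declared couplings by magnitude.

Goodness of fit reports R², the residual spectrum, and a Wald–Wolfowitz
runs test on the residual signs: a wrong model (singlet fitted to a
doublet of doublets) leaves long systematic runs even when R² looks
tolerable.

## Non-uniform sampling

Poisson-gap schedules draw gap lengths from a Poisson law whose mean is
modulated by sin(θ), θ ramping 0 → π/2 across the increments, so early
(high-signal) increments are sampled densely. The gap-scale parameter is
adjusted between fresh draws until the sampled count equals
round(fraction × n_total) exactly; we interpret the generator
"tolerance" (default 0.01) as governing the adjustment step of this
count-matching loop, since its original definition is not public.
Index 0 is always sampled; schedules serialize as plain-text index lists
(one 0-based integer per line) plus JSON metadata.

IST reconstruction operates on the **virtual echo** — the
conjugate-symmetrized 2n-point FID whose transform is the purely
absorptive spectrum. The absorption spectrum is far sparser than the
mixed-phase complex spectrum, which removes the lineshape bias plain IST
shows on Lorentzian tails (correlation with the fully sampled spectrum
improves from ≈ 0.986 to > 0.9999 on the noise-free serine
doublet-of-doublets fixture at 25 % sampling). Each iteration:
FFT → soft-threshold at a geometrically decaying level (0.9×max down to
1e-4×max over 200 iterations by default) → inverse FFT → restore the
measured increments (and the echo midpoint, which is zero by
construction for a decayed FID). With a full schedule the
data-consistency step makes the output exactly the real part of the
plain FT. 2D data are reconstructed per ¹H column.

## Synthetic data

The generator emulates paired labelled/control polar-extract datasets:
a seven-metabolite panel (lactate, alanine, glutamate, aspartate,
malate, serine, creatine) at millimolar-scale relative concentrations,
six replicates, 2 % multiplicative per-peak intensity jitter on top of a
10 % per-replicate dilution factor (TSA removes the dilution; the
per-peak jitter is what survives as replicate CV, landing in the 1–3 %
working band), and additive Gaussian noise. 1D noise is thermal
(time-domain); HSQC noise is set so the **weakest quantified cross-peak**
sits at the design SNR — SNR in NMR is quoted per resonance, and the
binding requirement for incorporation measurements is adequate SNR on
the natural-abundance control signals.

Labelling presets are single-turn atom bookkeeping, not a flux model:
each precursor maps through textbook atom transitions to fragment states
of the panel reporters (lactate C3, alanine C2, glutamate C4,
aspartate/malate C2, serine C2, creatine C2), mixed by pathway weights
(glycolysis, PC, PDH, glutaminolysis, oxidative PPP, one-carbon). E.g.
[1,2-¹³C]glucose → C2,C3-labelled pyruvate → aspartate C2 is `d_right`
under pure PC and `d_left` under pure PDH; [U-¹³C,¹⁵N]serine routes the
glycine-derived ¹³C₂/¹⁵N moiety into creatine C2 (`d_left+n15`).
Incorporation levels x are route weight × a fixed ceiling (0.8 for
direct glycolytic products, lower downstream) — plausible magnitudes,
not kinetics. What passing tests therefore show is that the *analysis*
chain is correct under the stated statistical structure; they do not
validate the biology of the presets, peak overlap from the full
metabolome, solvent artefacts, or field inhomogeneity, none of which the
generator emulates.

## Problem sizes and determinism

Fixtures are desk-scale by choice: 512–1024-point ¹³C slices at
0.25–0.5 Hz resolution, 2048-point interferograms, 1024×8192 HSQC grids
(step ≥ 3 points per linewidth so volume quadrature is accurate),
16384-point 1D FIDs zero-filled to 32768. Every stochastic path takes an
explicit integer seed; the pipeline stamps outputs with a configuration
hash and reruns bit-identically.

## Known limitations

- Local three-carbon fragments only; no long-range couplings, no
  ¹H-dimension multiplet structure, no strong-coupling effects.
- The echo-antiecho distortion is a one-parameter phase model; it
  reproduces the qualitative lineshape pathology, not the quantum
  treatment.
- Γ is a lookup, so absolute concentrations are out of scope.
- Labelling presets are bookkeeping; no kinetic or multi-turn Krebs
  cycle isotope scrambling.
- The vendor raw-data adapter is not included; spectra enter through the
  package's own JSON+CSV container or the simulator.
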