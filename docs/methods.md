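# Methods

## The measurement and its model

A two-pool mixing experiment detects subunit exchange between dodecameric
CaMKII holoenzymes. Each pool is labeled with one dye color; after mixing
under activating conditions, any holoenzyme carrying both colors must have
received subunits from the other pool. The imaging readout is object-based
colocalization: particles detected independently in the two channels of the
same field of view whose centers fall within a small distance of each other.
`smcoloc` implements (i) a generative simulator for this experiment, (ii) the
detection/matching/aggregation pipeline that quantifies it, and (iii) the two
solution-phase companion measurements (FRET ratio, kinase-rate additivity).

## Mixing simulator

**State.** A holoenzyme is 12 subunits arranged as six "vertical dimers"
(subunit pairs spanning the two stacked hexameric rings); each subunit
carries a visible-label state (red, green, or unlabeled) and a Thr286
phosphorylation flag. Labeling efficiency (`label_prob`, default 0.3 — the
assay operates at 20–40%) and the dark-fluorophore fraction (`dark_prob`,
default 0.2) enter only through their product, the probability that a subunit
is *visibly* labeled at t = 0, so both are folded into one draw per subunit.
No photobleaching occurs during a (static) exposure.

**Dynamics.** Activation gates exchange: a configured fraction of
holoenzymes is activated at t = 0 (their subunits start Thr286-
phosphorylated), and exchange events occur on a memoryless clock with
aggregate rate `k_ex × n_activated` per minute. `k_ex` is a free parameter:
no rate law has been established for this process, so the simulator makes no
claim about absolute kinetics — only about the structure of mixing. Each
event swaps one randomly chosen dimer between a randomly chosen activated
donor and a random acceptor (which may itself be activated; acceptors can be
restricted to unactivated holoenzymes, and the exchange unit reduced to a
single subunit, via configuration). Swapping conserves per-color subunit
totals exactly, which the tests assert as an invariant. The simulator
implements only the release/capture picture of exchange; a transient
aggregation intermediate would be indistinguishable at this level of
description and is not modeled.

**Limiting behavior.** With fully labeled 50/50 pools and saturating
exchange, single-subunit exchange randomizes all 12 subunit slots, giving a
dual-color fraction of 1 − 2·(1/2)¹² ≈ 0.99951 (verified against exhaustive
enumeration of the 2¹² colorings). With the default dimer unit and full
labeling, dimers remain internally homogeneous, so the corresponding limit is
over six dimer slots: 1 − 2·(1/2)⁶ = 0.96875. Both limits are tested.

**Ground truth.** `true_colocalization_fraction` mirrors the imaging
statistic on the population: dual-color holoenzymes divided by holoenzymes
containing the rarer color, with every dual particle counted equally
regardless of how many subunits it exchanged. `ground_truth_colocalization`
computes the same number over the spots actually rendered on a field, which
is the correct comparator for end-to-end recovery tests (it shares the
subsampling noise of the field).

**Rendering.** Spots are placed uniformly inside the margin (optionally with
a minimum pairwise separation for controlled fidelity tests); each
holoenzyme contributes an isotropic Gaussian PSF per channel with integrated
intensity `n_visible × unit_brightness`, sampled at pixel centers. Pixel
values are Poisson(signal + background) plus Gaussian read noise, clipped at
zero. Channels are rendered pre-registered; a constant per-channel offset
can be injected to probe matching robustness. Defaults (512² px, σ_PSF
1.5 px, 100 spots, unit brightness 2000 counts, background 100 counts, read
noise 2 counts) give a single visible fluorophore an amplitude ≈ 14× the
background shot noise, comfortably in the single-molecule-detectable regime.
The antibody (pT286) channel marks phosphorylated holoenzymes either
per-holoenzyme (one binding site saturating, the default) or per-subunit
(binomial in the phosphorylated count); which better reflects antibody
stoichiometry is unknown, so both are exposed.

**What the simulator does not emulate.** Real TIRF data have uneven
illumination, camera fixed-pattern noise and EM gain statistics, chromatic
aberration beyond a constant offset, surface-immobilization artifacts, and
day-to-day labeling variability. Passing the recovery tests therefore shows
the analysis is correct for its stated noise model, not that it is robust to
every instrumental effect.

## Detection

Background is estimated as the image median, its spread as 1.4826 × MAD.
After threshold subtraction (`threshold_k` × spread, default 3), the image is
smoothed (Gaussian, σ = 1 px) and candidate positions are found where the
normalized gradient vector field converges: the outward flux of the unit
gradient over each pixel's 3×3 neighbor ring is computed, and pixels with
flux below −2 (a strong sink; the theoretical minimum is −8 at a symmetric
peak) are flagged. Flagged pixels cluster tightly around intensity peaks;
each 8-connected sink cluster contributes one candidate (its brightest
pixel). When two candidates fall within half a fit window, only the brighter
is kept. On exactly-noiseless synthetic images the MAD is zero, so the
effective threshold has a floor of 1% of the smoothed peak; on any noisy
image the MAD term dominates and the floor is inert.

Each candidate is refined by a bounded least-squares fit (`scipy.optimize.
least_squares`, tolerances 1e−8, initialized from the candidate pixel and
image moments) of a rotated elliptical Gaussian plus constant background
over an 11×11 window. A rotated ellipse is fitted rather than axis-aligned
widths, as the more general reading of an "elliptical" spot model.
Non-convergent, non-positive-amplitude or non-positive-width fits are
rejected (`FIT_FAILED`); candidates within the edge margin are rejected
without fitting (`EDGE`).

Filtering applies, in order: the carried-over EDGE/FIT_FAILED rejections;
circularity `σ_major/σ_minor > circularity_max` (default 1.5) → NON_CIRCULAR;
then integrated intensity outside `median ± k·MAD` (defaults k = 5 on both
sides, statistics recomputed per image and channel) → TOO_DIM / TOO_BRIGHT.
The circularity cutoff and brightness bounds are declared defaults, not
community standards — the appropriate values depend on the optical setup —
and all are configuration. A frozen `(median, MAD)` reference can be passed
to make filtering idempotent across runs. Intensity histograms with explicit
under/overflow counts support the aggregation QC check (an emerging
population of extra-bright particles indicates aggregation, which would
masquerade as colocalization).

## Matching and statistics

Matching is mutual nearest neighbor under Euclidean distance with a
threshold (default 1.5 px, sensible range ≈ 1–2.5 px for a ~1.5 px PSF σ):
a pair is kept when each particle is the other's nearest neighbor and their
distance is within threshold, with equidistant ties resolved to the lower
index. The scheme is symmetric under swapping channels and each particle
joins at most one pair. For resolvable fields — distinct spot sites farther
apart than twice the threshold, the physical regime of a sparse
single-molecule field — mutual-NN matching is provably optimal, and the test
suite verifies equality with an exhaustive maximum-matching oracle on
randomly generated instances of that regime (the generator enforces the
separation; for pathological crossing configurations inside one threshold
radius mutual-NN can be suboptimal, which is why the regime is stated).

Percent colocalization uses the less-populated channel as reference (ties go
to channel A, deterministically). Normalization divides by the percent
measured for a doubly labeled positive control; because labeling efficiency
and instrument state vary between experiments, this constant is
per-experiment configuration (62 is a typical measured value and the
default). Normalized values above 100% are flagged, never clamped. The
expected chance colocalization of two independent uniform fields of density
ρ is ≈ 100·(1 − exp(−ρπr²)) — the probability a Poisson field places a point
within r — and the empirical baseline is tested against it.

Three-color analysis positions each dual-color particle at the mean of its
two matched centers and matches antibody-channel particles against those
(and, for time courses, against all kinase particles), reporting both
fractions of the antibody count.

## Aggregation

Per-time-point summaries are the mean and between-image sample (n−1)
standard deviation of the per-image percent over the fields imaged at that
time point (typically ~12 positions); `n_images` is carried explicitly so
QC attrition is visible. Time courses are grouped by condition label and
sorted by time, with duplicate (condition, time) rejected. No curve fitting
is applied by default — the deliverable is the raw curve; a single-
exponential convenience fit exists for exploration and carries no kinetic
interpretation.

## Solution assays

The FRET ratio is acceptor emission at 610 nm over donor emission at 515 nm,
each read by linear interpolation at the exact wavelength with no bandwidth
averaging (the ratio is scale-invariant, so spectrometer units cancel). The
kinase initial rate is the least-squares slope over the longest prefix of
the trace whose linear fit keeps r² ≥ 0.99 (minimum 3 points; a perfectly
flat trace counts as linear with slope 0). "Early data points" admit several
operationalizations; the longest-high-r²-prefix rule is deterministic and
exposed via `min_points`/`r2_min`. If no prefix qualifies the first
`min_points` are used and the result is flagged. Rates stay in instrument
units (Δfluorescence per unit time); no calibration to molar turnover is
attempted. Additivity analysis reports the component-rate sum and the
mixture's fold excess over it.

## Problem sizes and numerical choices

The test suite and acceptance script use 512² fields with 50–100 spots,
populations of 300–10,000 holoenzymes, 10–20 seeds per stochastic check, and
1,000 matching-oracle instances; these sizes give binomial/sampling errors
well below the tolerances being asserted while keeping a full run around a
minute. Stochastic assertions use fixed seeds; exact invariants
(conservation, gating, symmetry, scale/offset invariance) are asserted
exactly or at float tolerance. Degenerate inputs (empty populations, all-zero
images, flat fit windows, empty reference channels, zero donor emission) are
either errors or explicitly flagged undefined results, never silent NaNs.

## Limitations

- Exchange kinetics are phenomenological; `k_ex` cannot be mapped to a
  physical rate constant without a rate model, and none is fitted.
- The dimer exchange unit is a hypothesis; the monomer option exists
  precisely because the data cannot distinguish the two.
- Detection assumes well-separated diffraction-limited spots; it does not
  attempt deconvolution of overlapping particles (they are filtered out via
  circularity instead).
- Mutual-NN matching is optimal only for resolvable fields (see above).
- The brightness filter presumes a unimodal intensity distribution per
  image; fields dominated by aggregates would shift the median itself.
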