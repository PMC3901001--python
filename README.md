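# smcoloc

Single-molecule TIRF colocalization analysis of CaMKII subunit exchange.

CaMKII, the dodecameric Ca²⁺/calmodulin-dependent kinase central to synaptic
plasticity, can exchange subunits between holoenzymes once activated. The
sensitive readout for this is a two-color single-molecule experiment: two
pools of holoenzymes are labeled with spectrally distinct dyes, mixed, and
sparsely immobilized; a holoenzyme that appears in **both** color channels of
a TIRF image must have acquired subunits from the other pool. `smcoloc`
implements the full quantification pipeline for that experiment, plus a
synthetic-data simulator that generates the experiment end to end with known
ground truth, and the two companion solution assays (FRET ratio and
kinase-rate additivity).

## What it computes

**Detection.** Spots are seeded at convergence points of the image gradient
vector field, refined by least-squares fits of a rotated elliptical 2D
Gaussian `A·G(x, y; x₀, y₀, σ_major, σ_minor, θ) + b`, and filtered on
circularity (`σ_major/σ_minor`, rejecting overlapping/misshapen spots) and on
integrated intensity `2π·A·σ_major·σ_minor` relative to the per-image median
(rejecting dim noise and bright aggregates).

**Colocalization.** Accepted particles from two channels are matched by
mutual nearest neighbors within a distance threshold (default 1.5 px). The
statistic is

    percent = 100 · n_matched / n_reference

with the reference channel systematically the one with fewer accepted
particles, optionally normalized by the maximum percent measured for a
doubly-labeled positive control. Three-color analysis reports the fraction of
antibody-channel spots (e.g., anti-phospho-Thr286) colocalized with
dual-color particles.

**Simulation.** Holoenzymes are 12-subunit assemblies (six "vertical
dimers"). Labels are drawn per subunit with probability
`label_prob·(1 − dark_prob)`; exchange events swap one dimer between an
activated donor and a random acceptor on a memoryless clock of rate
`k_ex · n_activated`. Rendering produces per-channel images with Gaussian
PSFs, Poisson shot noise and Gaussian read noise, and a ground-truth table.

**Solution assays.** `fret_ratio` = acceptor emission at 610 nm / donor
emission at 515 nm, interpolated from an emission spectrum.
`initial_rate` extracts the early linear slope of an enzyme-coupled
fluorescence trace; `additivity_analysis` compares a mixture's rate with the
sum of its components' rates.

## Worked example

```python
import smcoloc as smc

cfg = smc.MixingConfig(n_red=300, n_green=300, seed=11, activated_fraction=0.5,
                       k_ex=0.5, duration_min=60.0)
snaps = smc.simulate_mixing(cfg, [0.0, 15.0, 60.0])
for t, pop in snaps.items():
    print(f"t={t:5.1f} min  true dual-color fraction {smc.true_colocalization_fraction(pop):.3f}")

pop = snaps[60.0]
images, records = smc.render_field(pop, smc.FieldSpec(n_spots=100, seed=12))
red, _, _ = smc.detect_particles(images["red"], channel="red")
green, _, _ = smc.detect_particles(images["green"], channel="green")
pairs = smc.match_channels(red, green)
res = smc.percent_colocalization(red, green, pairs, control_max_percent=62.0)
print(f"{res.n_channel_a} red, {res.n_channel_b} green, {res.n_matched} matched")
print(f"percent={res.percent:.1f}  normalized={res.normalized_percent:.1f} (ref={res.reference_channel})")
print(f"ground truth on this field: {100*smc.ground_truth_colocalization(records):.1f}%")
```

prints

```
t=  0.0 min  true dual-color fraction 0.000
t= 15.0 min  true dual-color fraction 0.667
t= 60.0 min  true dual-color fraction 0.742
78 red, 70 green, 56 matched
percent=80.0  normalized=129.0 (ref=b)
ground truth on this field: 77.8%
```

At t = 0 the pools are separate (no dual-color holoenzymes); exchange then
mixes colors into the same holoenzymes. On the rendered field the detected
80% raw colocalization tracks the 77.8% ground truth of the spots actually
placed. The normalized value exceeds 100% because this simulation mixes more
thoroughly than the 62% experimental control it is being scaled against; the
result is flagged (`res.over_control`), never clamped.

A matching command-line interface is available: `smcoloc simulate`,
`smcoloc detect`, `smcoloc colocalize`, `smcoloc timecourse`, `smcoloc fret`
and `smcoloc kinetics rate|additivity` (see `--help` on each).

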