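# Methods

## The measurement problem

An open-ended coaxial probe (OECP) measures the complex reflection at
its aperture, which vendor software converts to the complex relative
permittivity of whatever fills the sensing volume. `oecpkit` works
entirely downstream of that conversion, on the real part ε′(f) sampled
on a linear frequency grid (default 101 points, 0.5–18 GHz). For
irregular solids the probe cannot make flush contact; air in the
sensing volume (ε′ = 1) pulls the measurement down and makes repeats
inconsistent. The package implements and qualifies the coupling-medium
remedy: fill the gap with a glycerin–water liquid and read the sample's
permittivity at the frequencies where the measured medium-on-sample
curve intersects the medium's own curve.

## Dielectric models

All materials are single-pole Cole-Cole relaxations,

    ε*(ω) = ε_inf + Δε / (1 + (jωτ)^(1−α)),

of which only the real part is consumed (α = 0 gives the Debye form;
the saline set carries a static conductivity σ_s that affects only the
imaginary part and is retained for completeness). Parameter sets:

| set | ε_inf | Δε | τ (s) | α | note |
| --- | --- | --- | --- | --- | --- |
| water | 5.2 | 74.9 | 9.3e-12 | 0 | distilled water near 20 °C |
| glycerin | 4.0 | 38.5 | 1.0e-9 | 0.10 | broadened, dispersing below the band |
| saline_0p1M | 5.2 | 72.9 | 9.2e-12 | 0 | 0.1 M NaCl validation reference (σ_s = 1.07 S/m) |

These are representative room-temperature values, not fits to any
specific published dataset; they can be overridden from a YAML/JSON
file via `load_materials`. Temperature is metadata only — no
temperature law is modelled.

A coupling medium at glycerin volume fraction g interpolates the water
and glycerin endpoints: linearly in ε_inf, Δε, α and σ_s, log-linearly
in τ (relaxation times span two decades). The rule is a modelling
convenience, not mixture physics; what matters for the method, and what
the tests assert, is that the family is strictly ordered in g at every
band frequency and that its members' dispersion curves cross a flat
ε′ ≈ 10 target at interior frequencies spread across the band. With
these endpoints the catalogue spans ε′ ≈ 4–59 over the band and a
crown-like target is crossed between roughly 0.5 and 8 GHz.

Synthetic tooth targets are gentle linear trends: crown-like ε′ rising
10 → 11 across the band, root-like falling 9.5 → 8. They match the
plateaus reported for healthy dental hard tissue without claiming any
tissue physics.

## Forward simulator

Measured properties of a heterogeneous load lie between the properties
of its constituents. The simulator uses the simplest law with that
bounding property, a convex combination

    ε′_meas(f) = w_m ε′_medium(f) + w_t ε′_tooth(f) + w_a · 1 + noise,

which is all the estimator may assume. Per acquisition the three
weights receive i.i.d. Gaussian jitter, are clipped at zero and
re-normalised; the noise is additive Gaussian per frequency point.
Every draw is reproducible from `(seed, draw_index)`; each combination
in a study gets its own deterministic sub-seed.

Defaults (dimensionless ε′ units; chosen to reproduce the qualitative
behaviour of bench measurements on teeth, since no quantitative contact
model is available):

- **with medium**: weights (w_m, w_t, w_a) = (0.35, 0.63, 0.02), jitter
  sd 0.01, noise sd 0.05. The liquid displaces nearly all the air, and
  the residual-contact jitter is small enough that the nine-acquisition
  spread rarely reaches the 5% exclusion threshold — bench studies
  report exclusions as rare, band-edge events. The remaining w_a = 0.02
  leaves a deliberate ~2–3% low bias in the estimates.
- **bare**: (0, 0.65, 0.35), jitter sd 0.08, noise sd 0.05. Uncoupled
  contact on an irregular surface leaves a large, highly variable air
  fraction; this yields range variations of roughly 20–30% across nine
  repeats, the regime that motivates the method.

Scenarios perturb the baseline: `test_A_large_amount` /
`test_A_small_amount` shift w_m by ±0.01 (the probe is not moved
between the two amounts, so the sensing-volume composition changes
little); `test_B_delayed` shrinks the medium's Δε by 2% (exposure to
ambient conditions before a delayed measurement); `poor_contact_R2`
shifts (+0.10 medium, +0.05 air) with medium and +0.20 air bare,
emulating a concave site that pools liquid and traps air. The A/B
sizes were set from the convex-mix arithmetic so the induced variation
stays below the 5% acceptability gate, the regime such confounders are
reported to occupy.

A session per combination counts 23 acquisitions — 2 saline
validations bracketing the session, 3 medium-only acquisitions at the
beginning, middle and end of the repeat block, 9 with medium, 9 bare —
plus uncounted air checks between repeats.

## Estimation

Per combination: average the three medium-only spectra point-wise; for
each of the nine with-medium acquisitions form the difference curve
against that average and, if it changes sign (or hits zero) on the
grid, report the intersection at the sampled frequency minimising the
absolute difference (ties to the lowest frequency — no sub-grid
refinement is attempted, so estimates carry a quantisation error of up
to half a grid step times the medium's local slope). The estimate is
the median by value of the intersecting acquisitions' values, taking
the lower-middle element on even counts so the estimate remains an
observed value with a well-defined frequency. Its variability is the
max–min spread of **all nine** with-medium acquisitions at that
frequency; the point is excluded when the spread reaches 5% of the
estimate. Combining media gives one point per intersecting medium,
sorted by frequency. Site comparisons interpolate one site's
non-excluded points piecewise-linearly to the other's frequencies;
extrapolation is refused.

## Variability statistics

The percentage variation Δε′(f) = |ε′_A − ε′_B| / ε′_A × 100 is
deliberately asymmetric; the denominator is always the reference: the
model curve in a calibration validation (pass gate: frequency-averaged
error < 5%), the highest recorded value in a repeatability range (the
acquisition least affected by air), the better-contact site in a site
comparison. The frequency average is unweighted. The
median-acquisition deviation averages |ε′_i − ε′_M| / ε′_M over the
eight non-median repeats. Denominator values below 1e-9 raise an error
rather than returning infinities: ε′ ≥ 1 physically, so tiny values
indicate corrupt input.

## What the synthetic study shows — and what it cannot

Problem sizes: studies use the full 101-point grid, 12 media for the
crown study and the 9 media G[100]–G[60] for the root study, 9 repeats
per combination — the protocol's own dimensions. On these conditions
the package reproduces the phenomenology the method was designed
around: kept crown estimates recover the target within ~3% mean
absolute relative error; bare-contact repeatability variation sits in
the tens of percent; between a good-contact and a poor-contact site
the bare-range variation (~25–30%) far exceeds the change in the
coupling-medium estimates (~8–9%); and the amount-of-medium and
delayed-measurement perturbations stay well under the 5% gate.

The simulator is a convex mixing model, not electromagnetics: it has no
sensing-depth physics, no probe aperture model, no frequency-dependent
contact behaviour, and its tooth targets are smooth trends rather than
layered enamel/dentin structures. Passing tests therefore demonstrate
that the estimation and statistics machinery is correct and behaves as
intended *under the bounding-property assumption*, not that any
specific bench measurement would yield these numbers. Two visible
artefacts of the synthetic family: root-study intersections all fall
below ~4.2 GHz, so the root estimate range (~9.0–9.4) does not reach
the lower plateau of the root target; and estimates carry the small
systematic low bias of the residual air weight.

## Numerical choices and degenerate inputs

Grids must be exactly linear (file reader tolerance: 1e-6 relative);
frequencies are Hz internally and serialised as integers where exact,
with ε′ written at full double precision (`repr` round-trip; files are
re-read with round-trip float parsing). Spectra must be strictly
positive and finite. Jittered weights that clip to a zero sum fall
back to the mean weights. Empty sessions run successfully and produce
empty estimate tables. Pipeline behaviour on a failed validation gate
is configurable: warn (default), skip the combination, or abort.
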