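# Methods

## Problem and model

The package sorts municipalities into six ordered categories of propensity
of violence against women from four criteria: a composite Support and
Protection Index (SPI) built from five binary protection-equipment
indicators, plus HDI, GDP per capita and the Gini index. Sorting uses
ELECTRE TRI-B, an outranking method that compares each alternative with
boundary ("limit") profiles rather than with other alternatives, which
makes the assignment of one municipality independent of the rest of the
sample once the normalisation bounds are fixed.

### Normalisation and the composite index

All criteria are linearly rescaled to [0, 1] via min-max normalisation.
The SPI is the raw sum of the five 0/1 equipment flags (range 0–5)
followed by the same min-max step; because the raw values are integers,
the normalised SPI takes at most six distinct values per dataset. By
default the min/max bounds are taken from the ingested dataset itself;
`build_performance_table(..., bounds=...)` pins them externally so that
the limit profiles keep their meaning when the model is applied to a new
dataset. Values outside pinned bounds are clamped, preserving the [0, 1]
invariant.

Missing data follow two rules. A record with *every* indicator absent
carries no information and is excluded before classification (it appears
in all outputs with an explicit "not classified" marker). An individually
missing indicator is read as "no resource" and enters the performance
table as 0 after normalisation; missing equipment flags likewise
contribute 0 to the SPI sum.

### The outranking chain

For criterion j with weight w_j and thresholds q_j ≤ p_j ≤ v_j the
engine computes partial concordance (1 below the indifference gap q_j, 0
at the preference gap p_j, linear between), weighted global concordance,
partial discordance (0 below p_j, 1 at the veto v_j, linear between) and
the credibility

σ(x, b) = C(x, b) · Π_{j : D_j > C} (1 − D_j) / (1 − C).

The discount product runs only over criteria whose discordance strictly
exceeds the global concordance — the standard credibility formulation. A
criterion at its veto forces σ = 0 regardless of the other criteria.
Outranking is the inclusive cut σ ≥ λ with λ ∈ [0.5, 1].

Degenerate thresholds are handled as limits of the interpolants: q = p
makes concordance a step at p, p = v makes discordance a step at v. The
interpolation branch is used on [q, p), so concordance is continuous at
the indifference gap.

Both classical assignment rules are implemented. The pessimistic rule
(descending scan; first outranked profile fixes the class) is the
reported headline because it is the conservative choice for risk
screening; the optimistic rule is always computed alongside, and
pessimistic ≤ optimistic holds whenever the profiles are ordered, which
the configuration validator enforces. Minimise-direction criteria are
sign-flipped on entry (evaluations and profiles alike) so that the
formulas are written once, for maximisation.

## Study configuration

The default `ModelConfig` carries the published setup: five limit
profiles per criterion on the normalised scale, weights 0.5 (SPI), 1.0
(HDI), 0.3 (GDP per capita), 1.0 (Gini) — sum 2.8 — uniform thresholds
q = 0.1, p = 0.2, v = 1.0, and λ = 0.60. Three choices deserve comment:

* **Profile scale.** The GDP profile values (0.01…0.50) only make sense
  on the normalised scale, so all profiles are interpreted as normalised
  quantities throughout.
* **Gini direction.** The study configuration maximises all four
  criteria, Gini included, and the default follows it as printed.
  Substantively one may argue higher inequality should mean higher risk;
  `default_config(invert_gini=True)` flips C4 to minimise for that
  reading.
* **Veto at 1.0.** On a [0, 1] scale a veto of 1.0 can only bind at the
  extreme corner, so vetoes essentially never annihilate credibility in
  this configuration; the discordance machinery matters for other
  configurations and is fully tested.

With q = 0.1 the three low GDP profiles (0.01, 0.03, 0.04) lie within the
indifference band of almost every alternative, so GDP effectively
discriminates only at the top profile; and the HDI gap b₄→b₅ (0.01) is
far below q, so classes 5 and 6 are separated mainly by the other
criteria. These are properties of the published parameterisation, not of
the implementation.

## Sensitivity protocol

Two deterministic schemes mirror the study's robustness check: the λ cut
moved by ±0.05 (values clamped to [0.5, 1] with a warning), and each
criterion in turn given weight 1.00 with all others at 0.50 — replacing
the whole weight vector, which is the literal reading of the published
scheme. Stability is reported as the count and fraction of municipalities
whose pessimistic class differs from the baseline run, with the full
per-scenario class vectors available for inspection. Raising λ can only
weaken outranking, so each municipality's pessimistic class is
non-increasing in λ; the test suite asserts this per alternative.

## Synthetic data generator

The generator emulates the *structure* of a municipal survey extract
(144 records by default, one of them a fully missing non-respondent), not
any real marginals. A single latent "protection capacity" factor
z ~ N(0, 1) couples all indicators:

| indicator | family | default coupling |
|---|---|---|
| equipment flags | Bernoulli, logit = intercept + 1.2 z | intercepts −1.5…0 (police stations rarest) |
| HDI | 0.40 + 0.45 · Φ(z + ε), ε ~ N(0, 0.5) | increasing in z |
| Gini | 0.35 + 0.50 · Φ(−z + ε) | decreasing in z |
| GDP per capita | log-normal, log-mean 9.6 + 0.4 z, log-sd 0.5 | increasing in z |
| complaints | Poisson, rate 20 · exp(z) | increasing in z |

The single-factor design is the smallest structure that induces the
expected correlations among equipment, development, inequality and
reporting. The complaint model deliberately encodes the reporting-access
paradox: better-protected municipalities record *more* complaints because
victims can actually reach the services, so the best occupied risk
category shows a higher mean complaint count than the worst — an artefact
of access, not of prevalence. The noise scale (0.5 on the probit score,
giving a latent-score correlation of ≈ 0.89 with capacity) makes capacity
the dominant driver of every indicator, which is what the recovery tests
rely on.

What the generator does **not** emulate: spatial autocorrelation between
neighbouring municipalities, calibration to any real region's marginals,
correlated missingness, or measurement error in the survey answers.
Passing tests therefore demonstrate that the pipeline recovers a known
latent ordering under a favourable single-factor world, not that the
published real-data classification is correct.

## Numerical choices and problem sizes

All arithmetic is plain float64; engine results are required to match an
independent straight-line transcription of the formulas to 1e-12. Ties at
thresholds are resolved by the inclusive conventions above. The test and
acceptance runs use survey-scale problems (144–200 municipalities,
1000-instance property sweeps, one 5000-record large-sample check of the
generator's monotonicity), which complete in seconds.

## Known limitations

* The published per-municipality classification cannot be reproduced
  without the original survey indicator values; the package validates the
  method's structure and behaviour on synthetic data instead.
* Gini maximisation as printed partially opposes the latent capacity
  factor, which caps the achievable capacity–class rank correlation and
  populates the bottom class with low-capacity but unusually equal-income
  municipalities.
* The GeoJSON export is a property join (class index and label onto
  features); no geometry processing or map rendering is performed.
* Profile inference from assignment examples and other ELECTRE variants
  are out of scope.
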