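# Methods

## Outcome model

A transfer of `n` embryos with marginal live-birth rates `L_1..L_n` and
universal factors fraction `U ∈ (0, 1]` produces `k` live-born infants
with probability

    P(0) = (1 − U) + U · Π_i (1 − L_i/U)
    P(k ≥ 1) = U · PB(k; L_1/U, …, L_n/U)

where `PB` is the Poisson-binomial pmf. This is the unique distribution
in which (a) no embryo can deliver when transfer-level conditions are
unfavorable, (b) embryos deliver independently when they are favorable,
and (c) each embryo's marginal birth probability is exactly `L_i`. The
construction generalizes the two-embryo tree (twins `L_1·L_2/U`) to any
`n`. Consequences used as test invariants: the distribution is
`Bernoulli(L)` for one embryo regardless of `U`; it reduces to the
independent Poisson-binomial at `U = 1`; the expected number of births is
`Σ L_i` exactly; and as `U` falls toward `max L_i`, probability mass moves
from singleton to multiple outcomes.

`PB` is computed by the O(n²) dynamic-programming convolution rather than
closed-form expressions with binomial coefficients; at clinical `n` (≤ 6)
this is exact to machine precision and has no cancellation issues.
`L_i > U` is a hard validation error, never a clamp: silently clamping
would mask exactly the identifiability failures the fitting stage is
designed to surface. `L_i = U` is legal (certain birth given favorable
conditions). Heterogeneous `L_i` within a transfer are supported by the
model layer even though the fitting layer assigns every embryo its cell's
common rate; this keeps the door open for morphology-graded rates.

## Rate estimation

Each transfer contributes one linear equation `n_i · x = b_i` (births or,
alternatively, fetal heartbeats at 6–8 weeks for the ongoing-pregnancy
outcome). The cell estimate is the least-squares solution
`x = Σ n_i b_i / Σ n_i²`, which weights a k-embryo transfer k times as
heavily as a single transfer; the simplified mode `Σ b_i / Σ n_i` is the
plain pooled ratio a clinic can compute by hand. The two coincide
whenever all transfers in a cell have the same embryo count (property
test). Estimates are invariant to duplicating the record set and always
fall in [0, 1] because `b_i ≤ n_i`.

Cells are indexed by transfer category (fresh/frozen × cleavage/
blastocyst) and age group: ages ≤ 34 pooled (including the occasional
patient under 25), targets 35–43 each using the raw-age window
`target ± 2`. Raw ages feed windows irrespective of pooling, so ages
33–34 contribute to the windows for targets 35–36, and ages 44–45
contribute to the windows for 42–43 even though no cell targets them.
Ages above 45 (and predictions for ages over 43) are out of range: cells
are absent rather than extrapolated. Accepted record ages are 18–50.

95% CIs are percentile bootstraps over `B ≥ 200` resamples drawn with
replacement at the transfer level — transfers, not embryos, are the
independent units of the model. Cells with fewer than two transfers get
no interval (flagged `None`, never fabricated). In very small cells the
percentile interval can fail to bracket the point estimate; bounds are
widened to include it so the table invariant `lo ≤ lbr ≤ hi` always
holds.

## Universal factors fraction

Only multiple-embryo transfers inform `U`. For a transfer of `n` embryos
sharing cell rate `L`, the singleton probability is
`p(U) = n·L·(1 − L/U)^(n−1)`, increasing in `U` on `[L, 1]`; each
transfer contributes a Bernoulli term for its singleton indicator, and
`U` is the argmax of the summed log-likelihood over the grid
`[max L, 1]` at step 0.01 (the scale at which the quantity is clinically
reported), ties broken toward the larger value. A full-multinomial
likelihood over the complete outcome count is available
(`likelihood="multinomial"`) for sensitivity analysis; the singleton
indicator is the default because the singleton count is the quantity the
estimator is anchored to. Transfers in zero-rate cells are dropped: with
no singleton observed they are constant in `U`, and a singleton in such a
cell is impossible under the model (both situations are counted and
surfaced).

The fit is flagged non-identifiable when the likelihood is still rising
at `U = 1` **and** the observed singleton count exceeds the independence
prediction by more than twice its binomial SD. The 2-SD guard exists
because cohorts whose true `U` is exactly 1 sit on the boundary and would
otherwise be flagged about half the time by sampling noise alone; with
the guard, genuine excess-singleton subgroups (which can arise by chance
in small strata, e.g. a few dozen frozen cleavage transfers) are flagged
while truth-at-1 cohorts are flagged ~2% of the time. `U` is fitted
separately for fresh and frozen transfers by default.

`bootstrap_uni_ci` refits the whole pipeline (rate table, then `U`) on
transfer-level resamples and reports percentile bounds; resamples where
`U` is not estimable are skipped, and the CI errors out if more than half
are.

## Cross-validation

Records are assigned to `k = 10` folds by independent uniform draws
(redrawn if any fold is empty), refitting rate table and per-cycle `U` on
the training folds each round. Each held-out transfer's outcome is
simulated `n_bootstrap` times from the refitted model; fold-level rates
of singleton, twin and total live births per transfer are compared with
their bootstrap predictive distributions through the standardized error
`(observed − predictive mean) / predictive SD`. Standardization is at
fold level — one error per fold per outcome — because that is the unit at
which the Z-test sample is defined; the Z-test treats the k errors as
unit-variance draws (`SE = 1/√k`, two-tailed normal). Q-Q points pair the
ordered errors with normal quantiles at positions `(i − 0.5)/m`.

Held-out transfers with no training cell, or multi-embryo transfers whose
cell rate exceeds the applicable `U`, are excluded and counted
(`n_predicted + n_excluded = n_heldout` per fold, asserted in tests). For
held-out single-embryo transfers `U` is lifted to `max(U, L)` since the
single-embryo distribution does not depend on it. Training folds with no
informative multiple-embryo transfer fall back to `U = 1` for that cycle
(counted in `n_uni_fallback`). Zero-SD predictive distributions (e.g.
all-zero rate cells) yield flagged NaN errors, not infinities.
`comparison_mode="uni_equals_1"` evaluates predictions under forced
independence; on data generated with `U < 1` this under-predicts twins
and over-predicts singletons, visible as a positive mean twin-rate error
and negative singleton error (a seeded acceptance test checks both
directions at 3,000 transfers).

## Synthetic cohorts

`ClinicSimConfig` draws each transfer's age, category and embryo count
from configurable mixes, then applies the mechanism directly: favorable
with probability `U` of the cycle, then `Binomial(n, L/U)` births, else
zero. Defaults emulate a mid-size academic clinic: 684 transfers;
embryos-per-transfer mix {1: 0.15, 2: 0.30, 3: 0.55} (mean 2.4);
ages 25–44 weighted by a normal kernel centered at 35 (SD 5); category
mix 35/27/25/13% for fresh blastocyst / fresh cleavage / frozen
blastocyst / frozen cleavage; true `U` 0.68 fresh, 0.75 frozen; rate
curve flat to age 35 then declining 22%/year from category bases
0.40/0.15 (fresh blastocyst/cleavage) and 0.35/0.10 (frozen), putting a
frozen cleavage embryo at age 43 near 1%. Simulated heartbeat counts
equal birth counts, so the ongoing-pregnancy outcome is exercisable on
synthetic data but carries no miscarriage gap. The generator reproduces
the model's own distribution (chi-square checked) — so passing
recovery/calibration tests demonstrate internal consistency of estimator
and mechanism, not that real clinics follow the mechanism; real data add
morphologic heterogeneity, monozygotic twinning, temporal drift and
patient-level covariates the generator does not emulate.

## Sample-size study

`uni_sample_size_study` simulates homogeneous cohorts of two-embryo
transfers (defaults: rate 0.30, `U` 0.70 — values near typical fitted
clinic parameters; no particular cohort composition is canonical for the
question), refits `U` per cohort, bootstraps its 95% CI (200 resamples),
and reports the mean CI half-width at each cohort size over 50
replicates. For this homogeneous design the counts of transfers with 0/1/2
births are sufficient statistics, so bootstrap refits reduce to
multinomial draws plus the grid search (`_fit_uni_from_counts`, verified
against the record-level fit to 1e-12). The crossing size for a target
half-width is interpolated linearly in log-log space between bracketing
grid points (half-widths scale near `1/√n`), with a least-squares log-log
fit used only when the target lies outside the measured range.

## Numerical notes and limitations

All randomness flows through `numpy.random.default_rng` with explicit
seeds; nested procedures derive child seeds via `SeedSequence.spawn`, so
every public operation is reproducible bit-for-bit under a fixed seed.
Probability logs are clipped at 1e-300 to keep impossible observations at
−inf without overflow warnings; the `U` grid always includes both
endpoints `max L` and 1. The model counts infants from distinct embryos:
monozygotic splitting (an additive ~1–2% multiples risk in counseling),
vanishing twins, donor-oocyte cycles and embryo-morphology covariates are
out of scope. Default problem sizes in the test suite (cohorts of
2,000–5,000, 10 folds, 200–500 bootstrap draws, 50 replicates per grid
point) are chosen so estimator noise is small relative to the tolerances
being asserted while the whole suite stays fast.
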