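# embryotx

Predicting singleton, twin and total live-birth rates after human embryo
transfer, for IVF clinics deciding how many embryos to place in a single
procedure. Transferring more embryos raises the chance of a delivery but
also the risk of a multiple gestation, with its attendant maternal and
neonatal morbidity; `embryotx` fits an outcome model to a clinic's own
transfer records and renders the predictions as counseling tables.

## The model

Embryos placed together do not implant independently: conditions that act
on the whole transfer — endometrial receptivity, uterine anatomy, transfer
technique, culture conditions — affect every embryo at once. The model
treats these *universal factors* as favorable with probability `UNI`
(a fraction between 0 and 1, per cycle type). When unfavorable, no embryo
can implant; when favorable, each embryo independently delivers a
live-born infant with probability `LBR / UNI`, where `LBR` is its marginal
live-birth rate. For a transfer of `n` embryos the number of live births
is then a zero-inflated Poisson-binomial:

    P(k >= 1 births) = UNI x P[Poisson-binomial(LBR_i / UNI) = k]
    P(twins | 2 embryos) = LBR_1 x LBR_2 / UNI

Each embryo's marginal birth probability stays exactly `LBR_i`, but
siblings are positively correlated, so twins are more frequent than the
independence model (`UNI = 1`) predicts — which is what clinic data show.

Fitting uses two estimators:

* **LBR per embryo**, by age group and transfer category (fresh/frozen ×
  cleavage/blastocyst): least squares on the per-transfer equations
  `n_embryos x LBR = n_live_births`, pooling ages ≤ 34 and using 5-year
  moving windows for ages 35–43. A simplified mode (births ÷ embryos) is
  also provided.
* **UNI**, by maximizing the likelihood of the singleton indicator over
  multiple-embryo transfers on a grid `[max LBR, 1]` — only transfers of
  two or more embryos carry information about shared conditions.

Validation is tenfold cross-validation with parametric-bootstrap
predictive distributions, standardized fold-level errors, Z-tests and
normal Q-Q diagnostics.

## Worked example

Simulate a 2,000-transfer clinic (true UNI 0.68 fresh / 0.75 frozen),
fit it, and build counseling tables:

```bash
embryotx simulate -n 2000 --seed 7 -o clinic.csv
embryotx predict clinic.csv -o fit --seed 1
cat fit/uni.json
```

```json
{
  "fresh":  { "value": 0.63, "non_identifiable": false, "n_multiple_transfers": 1005 },
  "frozen": { "value": 0.79, "non_identifiable": false, "n_multiple_transfers": 642 }
}
```

The fitted fractions land near the generating values, with sampling noise
appropriate to a cohort of this size. `fit/lbr_table.csv` holds the
per-embryo rates with bootstrap 95% CIs (e.g. fresh blastocysts at target
age 35: 0.347, CI 0.304–0.394, from 287 transfers), and
`fit/prediction_tables.csv` one counseling table per age/category cell.

A single table for chosen parameters prints directly:

```bash
embryotx predict --lbr 0.30 --uni 0.70
```

```
 n    LBR   % mult.   % twins  % trip. or >  band
 1    30%        0%        0%            0%  green
 2    47%       27%       27%            0%  red
 3    57%       48%       39%           10%  gray
 4    63%       64%       40%           24%  gray
```

Reading the `n = 2` row: transferring two embryos with a per-embryo
live-birth rate of 30% under `UNI = 0.70` gives a 47% chance of at least
one live birth, but 27% of those deliveries would be twins — a "red"
multiples-risk band (bands: 0–9% green, 10–19% yellow, 20–29% red,
≥ 30% gray). Cross-validate a fitted model with
`embryotx validate clinic.csv -o val --seed 1` (add
`--uni-mode independence` to see how a `UNI = 1` model under-predicts
twins), and run the sample-size study with `embryotx power`.

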