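"""K-fold cross-validation of the fitted transfer-outcome model.

Each transfer is assigned to one of k folds by independent uniform draws.
For every fold the rate table and the universal factors fraction are refit
on the remaining folds, the held-out transfers' outcomes are simulated
from the refitted model (a parametric bootstrap), and the fold's observed
rates of singleton, twin, and total live births per transfer are compared
with their bootstrap predictive distributions.  The standardized error of
a fold-level rate is (observed - predictive mean) / predictive SD; under a
correctly specified model these errors are approximately standard normal,
which is checked with two-tailed Z-tests on their means and with
quantile-quantile points against the normal distribution.

Setting ``comparison_mode="uni_equals_1"`` replaces the fitted universal
factors fraction with 1 (independent implantation).  On data where shared
transfer-level conditions matter, that comparison under-predicts twins and
over-predicts singletons, which the standardized errors expose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .estimation import (
    AgeGroupScheme,
    LbrTable,
    TransferRecord,
    fit_lbr_table,
    fit_uni,
)
from .model import Cycle, TransferSpec, outcome_distribution

__all__ = [
    "FoldAssignment",
    "FoldPrediction",
    "ValidationReport",
    "assign_folds",
    "cross_validate",
    "qq_points",
]

OUTCOMES = ("singleton", "twin", "total")


@dataclass
class FoldAssignment:
    """Fold membership (ids 0..k-1) for each record, reproducible from seed."""

    folds: np.ndarray
    k: int
    seed: Optional[int]


def assign_folds(
    records: Sequence[TransferRecord], k: int = 10, seed: Optional[int] = None
) -> FoldAssignment:
    """Assign each transfer to a fold by independent uniform draws.

    Folds may be unequal in size; an assignment that leaves any fold empty
    is redrawn so every training and test set is usable.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(records) < k:
        raise ValueError(f"cannot split {len(records)} records into {k} folds")
    rng = np.random.default_rng(seed)
    while True:
        folds = rng.integers(0, k, size=len(records))
        if len(np.unique(folds)) == k:
            return FoldAssignment(folds=folds, k=k, seed=seed)


@dataclass
class FoldPrediction:
    """Observed vs bootstrap-predicted fold-level rates for one fold."""

    fold: int
    n_heldout: int
    n_predicted: int
    n_excluded: int
    observed: Dict[str, float]
    predicted_mean: Dict[str, float]
    predicted_sd: Dict[str, float]
    n_bootstrap: int


@dataclass
class ValidationReport:
    """Cross-validation summary across folds.

    ``standardized_errors`` holds one error per fold per outcome (NaN where
    the predictive SD was zero and the error is undefined);
    ``z_pvalues`` are two-tailed normal p-values for the mean standardized
    error of each outcome being zero.
    """

    folds: List[FoldPrediction]
    standardized_errors: Dict[str, List[float]]
    z_pvalues: Dict[str, float]
    qq: Dict[str, List[Tuple[float, float]]]
    comparison_mode: str
    k: int
    n_records: int
    n_unpredictable: int
    n_uni_fallback: int

    def to_dict(self) -> dict:
        return {
            "comparison_mode": self.comparison_mode,
            "k": self.k,
            "n_records": self.n_records,
            "n_unpredictable": self.n_unpredictable,
            "n_uni_fallback": self.n_uni_fallback,
            "z_pvalues": self.z_pvalues,
            "standardized_errors": {
                o: list(v) for o, v in self.standardized_errors.items()
            },
            "folds": [
                {
                    "fold": f.fold,
                    "n_heldout": f.n_heldout,
                    "n_predicted": f.n_predicted,
                    "n_excluded": f.n_excluded,
                    "observed": f.observed,
                    "predicted_mean": f.predicted_mean,
                    "predicted_sd": f.predicted_sd,
                }
                for f in self.folds
            ],
        }

    def errors_frame(self):
        import pandas as pd

        rows = []
        for f in self.folds:
            for o in OUTCOMES:
                rows.append(
                    {
                        "fold": f.fold,
                        "outcome": o,
                        "observed": f.observed[o],
                        "predicted_mean": f.predicted_mean[o],
                        "predicted_sd": f.predicted_sd[o],
                        "standardized_error": self.standardized_errors[o][f.fold],
                    }
                )
        return pd.DataFrame(rows)

    def qq_frame(self):
        import pandas as pd

        rows = []
        for o, pts in self.qq.items():
            for theo, emp in pts:
                rows.append(
                    {"outcome": o, "theoretical": theo, "empirical": emp}
                )
        return pd.DataFrame(rows, columns=["outcome", "theoretical", "empirical"])


def qq_points(standardized_errors: Sequence[float]) -> List[Tuple[float, float]]:
    """Normal quantile-quantile points at plotting positions (i - 0.5) / n."""
    errs = np.sort(np.asarray(standardized_errors, dtype=float))
    m = len(errs)
    if m < 3:
        raise ValueError("need at least 3 errors for a Q-Q plot")
    theo = stats.norm.ppf((np.arange(1, m + 1) - 0.5) / m)
    return list(zip(theo.tolist(), errs.tolist()))


def _fit_fold_unis(
    train: Sequence[TransferRecord],
    table: LbrTable,
    comparison_mode: str,
    grid_step: float,
    outcome: str,
) -> Tuple[Dict[Cycle, float], int]:
    """Fitted uni per cycle type (or 1.0 in the independence comparison)."""
    unis: Dict[Cycle, float] = {}
    n_fallback = 0
    for cycle in Cycle:
        if comparison_mode == "uni_equals_1":
            unis[cycle] = 1.0
            continue
        multiples = [
            t
            for t in train
            if t.n_embryos >= 2
            and t.category.cycle == cycle
            and table.rate_for(t.age_at_retrieval, t.category) is not None
        ]
        try:
            unis[cycle] = fit_uni(multiples, table, grid_step, outcome).value
        except ValueError:
            # no informative multiple-embryo transfers in this training set
            unis[cycle] = 1.0
            n_fallback += 1
    return unis, n_fallback


def cross_validate(
    records: Sequence[TransferRecord],
    k: int = 10,
    n_bootstrap: int = 1000,
    seed: Optional[int] = None,
    comparison_mode: str = "fitted_uni",
    scheme: AgeGroupScheme = AgeGroupScheme(),
    outcome: str = "live_birth",
    mode: str = "least_squares",
    grid_step: float = 0.01,
) -> ValidationReport:
    """K-fold cross-validation with parametric-bootstrap predictions.

    Held-out transfers whose age/category cell is absent from the training
    fit (or whose cell rate exceeds the applicable uni, so the model is
    ill-formed for them) are excluded and counted in ``n_unpredictable``;
    for every fold the predicted and excluded counts add up to the held-out
    count.
    """
    if comparison_mode not in ("fitted_uni", "uni_equals_1"):
        raise ValueError(f"unknown comparison_mode {comparison_mode!r}")
    records = list(records)
    ss = np.random.SeedSequence(seed)
    fold_seed, sim_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)
    )
    assignment = assign_folds(records, k, fold_seed)
    rng = np.random.default_rng(sim_seed)

    folds: List[FoldPrediction] = []
    errors: Dict[str, List[float]] = {o: [] for o in OUTCOMES}
    total_unpredictable = 0
    total_fallback = 0

    for f in range(k):
        train = [r for r, g in zip(records, assignment.folds) if g != f]
        test = [r for r, g in zip(records, assignment.folds) if g == f]
        table = fit_lbr_table(train, scheme, outcome, mode, n_bootstrap=0)
        unis, n_fallback = _fit_fold_unis(
            train, table, comparison_mode, grid_step, outcome
        )
        total_fallback += n_fallback

        specs: List[Tuple[int, float, float]] = []
        observed_counts: List[int] = []
        excluded = 0
        for t in test:
            rate = table.rate_for(t.age_at_retrieval, t.category)
            uni = unis[t.category.cycle]
            if rate is None:
                excluded += 1
                continue
            if t.n_embryos >= 2 and rate > uni + 1e-12:
                excluded += 1
                continue
            # uni is irrelevant for a single embryo; lift it so the spec is
            # well-formed when a high-rate cell never entered the uni fit
            uni_eff = max(uni, rate) if t.n_embryos == 1 else uni
            specs.append((t.n_embryos, rate, uni_eff))
            observed_counts.append(t.outcome_count(outcome))
        total_unpredictable += excluded

        m = len(specs)
        obs_k = np.asarray(observed_counts, dtype=float)
        observed = {
            "singleton": float((obs_k == 1).mean()) if m else float("nan"),
            "twin": float((obs_k == 2).mean()) if m else float("nan"),
            "total": float(obs_k.mean()) if m else float("nan"),
        }

        pred_mean = {o: float("nan") for o in OUTCOMES}
        pred_sd = {o: float("nan") for o in OUTCOMES}
        if m:
            outcomes = np.empty((n_bootstrap, m), dtype=np.int64)
            uniq: Dict[Tuple[int, float, float], List[int]] = {}
            for j, s in enumerate(specs):
                uniq.setdefault(s, []).append(j)
            for (n_emb, rate, uni_eff), cols in uniq.items():
                probs = outcome_distribution(
                    TransferSpec.homogeneous(rate, n_emb, uni_eff)
                )
                draws = rng.choice(
                    len(probs), size=(n_bootstrap, len(cols)), p=probs
                )
                outcomes[:, cols] = draws
            sim = {
                "singleton": (outcomes == 1).mean(axis=1),
                "twin": (outcomes == 2).mean(axis=1),
                "total": outcomes.mean(axis=1),
            }
            for o in OUTCOMES:
                pred_mean[o] = float(sim[o].mean())
                pred_sd[o] = float(sim[o].std(ddof=1))

        for o in OUTCOMES:
            sd = pred_sd[o]
            if m and sd > 0:
                errors[o].append((observed[o] - pred_mean[o]) / sd)
            else:
                errors[o].append(float("nan"))  # flagged: undefined error

        folds.append(
            FoldPrediction(
                fold=f,
                n_heldout=len(test),
                n_predicted=m,
                n_excluded=excluded,
                observed=observed,
                predicted_mean=pred_mean,
                predicted_sd=pred_sd,
                n_bootstrap=n_bootstrap,
            )
        )

    z_pvalues: Dict[str, float] = {}
    qq: Dict[str, List[Tuple[float, float]]] = {}
    for o in OUTCOMES:
        errs = np.asarray(errors[o], dtype=float)
        errs = errs[np.isfinite(errs)]
        if len(errs) == 0:
            z_pvalues[o] = float("nan")
            continue
        z = errs.mean() * np.sqrt(len(errs))  # each error ~ N(0, 1)
        z_pvalues[o] = float(2.0 * stats.norm.sf(abs(z)))
        if len(errs) >= 3:
            qq[o] = qq_points(errs)

    return ValidationReport(
        folds=folds,
        standardized_errors=errors,
        z_pvalues=z_pvalues,
        qq=qq,
        comparison_mode=comparison_mode,
        k=k,
        n_records=len(records),
        n_unpredictable=total_unpredictable,
        n_uni_fallback=total_fallback,
    )
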