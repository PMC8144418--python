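"""Fitting the model to clinic transfer records.

Two quantities are estimated from a flat table of embryo transfers:

* per-embryo live-birth rates (LBR) for each combination of a moving age
  group and one of the four transfer categories, by least squares on the
  per-transfer equations ``n_embryos * LBR = n_live_births``; and
* the universal factors fraction (UNI) of each cycle type, by a grid search
  maximizing the likelihood of the singleton indicator over transfers of
  two or more embryos -- the only transfers that carry information about
  UNI.

Ages 35-43 use five-year moving windows centered on the target age (the
window for 35 is ages 33-37); younger patients are pooled into a single
group.  Confidence intervals come from a percentile bootstrap that
resamples whole transfers, the independent sampling units of the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .model import EmbryoCategory, TransferSpec, outcome_distribution

__all__ = [
    "TransferRecord",
    "AgeGroupScheme",
    "LbrCell",
    "LbrTable",
    "UniEstimate",
    "assign_age_group",
    "estimate_lbr",
    "estimate_lbr_simplified",
    "fit_lbr_table",
    "bootstrap_lbr_ci",
    "uni_log_likelihood",
    "fit_uni",
    "bootstrap_uni_ci",
]

AGE_MIN, AGE_MAX = 18, 50

Outcome = str  # "live_birth" | "ongoing_pregnancy"


@dataclass(frozen=True)
class TransferRecord:
    """One embryo transfer: a patient age, a category, and its outcome counts."""

    age_at_retrieval: int
    category: EmbryoCategory
    n_embryos: int
    n_live_births: int
    n_fetal_heartbeats: Optional[int] = None

    def __post_init__(self) -> None:
        if not (AGE_MIN <= self.age_at_retrieval <= AGE_MAX):
            raise ValueError(
                f"age_at_retrieval {self.age_at_retrieval} outside "
                f"[{AGE_MIN}, {AGE_MAX}]"
            )
        if self.n_embryos < 1:
            raise ValueError("n_embryos must be >= 1")
        if not (0 <= self.n_live_births <= self.n_embryos):
            raise ValueError(
                f"n_live_births {self.n_live_births} outside "
                f"[0, n_embryos={self.n_embryos}]"
            )
        if self.n_fetal_heartbeats is not None and not (
            0 <= self.n_fetal_heartbeats <= self.n_embryos
        ):
            raise ValueError(
                f"n_fetal_heartbeats {self.n_fetal_heartbeats} outside "
                f"[0, n_embryos={self.n_embryos}]"
            )

    def outcome_count(self, outcome: Outcome = "live_birth") -> int:
        if outcome == "live_birth":
            return self.n_live_births
        if outcome == "ongoing_pregnancy":
            if self.n_fetal_heartbeats is None:
                raise ValueError(
                    "record has no n_fetal_heartbeats; cannot use the "
                    "ongoing_pregnancy outcome"
                )
            return self.n_fetal_heartbeats
        raise ValueError(f"unknown outcome {outcome!r}")


@dataclass(frozen=True)
class AgeGroupScheme:
    """Moving age groups used to pool transfers for LBR estimation.

    Ages up to ``pooled_young_max`` form a single pooled group.  Each target
    age in ``[moving_min, moving_max]`` uses the window of raw ages within
    ``window_half_width`` of the target (five years wide by default), with
    windows at the edges extending symmetrically into neighboring ages that
    have records.  Ages above ``moving_max + window_half_width`` contribute
    to no group.
    """

    pooled_young_max: int = 34
    window_half_width: int = 2
    moving_min: int = 35
    moving_max: int = 43

    @property
    def pooled_label(self) -> str:
        return f"<={self.pooled_young_max}"

    def target_labels(self) -> List[str]:
        return [self.pooled_label] + [
            str(a) for a in range(self.moving_min, self.moving_max + 1)
        ]

    def label_for_age(self, age: int) -> Optional[str]:
        """Label of the group used to predict for a patient of this age."""
        if age <= self.pooled_young_max:
            return self.pooled_label
        if self.moving_min <= age <= self.moving_max:
            return str(age)
        return None

    def contains(self, age: int, target: Union[int, str]) -> bool:
        """Whether ``age`` belongs to the group estimated for ``target``."""
        if isinstance(target, str) and not target.lstrip("<=").strip().isdigit():
            raise ValueError(f"unknown age-group target {target!r}")
        if isinstance(target, str):
            if target == self.pooled_label:
                return age <= self.pooled_young_max
            target = int(target.lstrip("<=").strip())
        if target <= self.pooled_young_max:
            return age <= self.pooled_young_max
        if not (self.moving_min <= target <= self.moving_max):
            raise ValueError(
                f"target age {target} outside the supported range "
                f"[{self.moving_min}, {self.moving_max}]"
            )
        return abs(age - target) <= self.window_half_width


def assign_age_group(
    age: int, scheme: AgeGroupScheme, target: Union[int, str]
) -> bool:
    """True iff a record of ``age`` is used when estimating for ``target``."""
    return scheme.contains(age, target)


@dataclass
class LbrCell:
    """Fitted per-embryo rate for one (age group, category) combination."""

    lbr: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    n_transfers: int
    n_embryos: int


@dataclass
class LbrTable:
    """Per-embryo live-birth (or ongoing-pregnancy) rates by group and category.

    ``cells`` maps ``(age_group_label, category)`` to a fitted cell; groups
    with no transfers are simply absent.
    """

    cells: Dict[Tuple[str, EmbryoCategory], LbrCell]
    scheme: AgeGroupScheme
    outcome: Outcome = "live_birth"
    mode: str = "least_squares"

    def cell_for(self, age: int, category: EmbryoCategory) -> Optional[LbrCell]:
        label = self.scheme.label_for_age(age)
        if label is None:
            return None
        return self.cells.get((label, category))

    def rate_for(self, age: int, category: EmbryoCategory) -> Optional[float]:
        cell = self.cell_for(age, category)
        return None if cell is None else cell.lbr

    def to_frame(self):
        import pandas as pd

        rows = []
        for (label, cat), cell in sorted(
            self.cells.items(), key=lambda kv: (kv[0][1], kv[0][0])
        ):
            rows.append(
                {
                    "age_group": label,
                    "embryo_stage": cat.stage.value,
                    "cycle_type": cat.cycle.value,
                    "lbr": cell.lbr,
                    "ci_low": cell.ci_low,
                    "ci_high": cell.ci_high,
                    "n_transfers": cell.n_transfers,
                    "n_embryos": cell.n_embryos,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "age_group",
                "embryo_stage",
                "cycle_type",
                "lbr",
                "ci_low",
                "ci_high",
                "n_transfers",
                "n_embryos",
            ],
        )


def _arrays(
    records: Sequence[TransferRecord], outcome: Outcome
) -> Tuple[np.ndarray, np.ndarray]:
    n = np.array([r.n_embryos for r in records], dtype=float)
    b = np.array([r.outcome_count(outcome) for r in records], dtype=float)
    return n, b


def estimate_lbr(
    records: Sequence[TransferRecord], outcome: Outcome = "live_birth"
) -> float:
    """Least-squares per-embryo rate for one group-by-category cell.

    Each transfer contributes the equation ``n_i * x = b_i``; the stacked
    system's least-squares solution is ``x = sum(n_i b_i) / sum(n_i^2)``.
    With only single-embryo transfers this reduces to the sample mean.
    """
    if len(records) == 0:
        raise ValueError("cannot estimate a rate from zero records")
    n, b = _arrays(records, outcome)
    return float(np.dot(n, b) / np.dot(n, n))


def estimate_lbr_simplified(
    records: Sequence[TransferRecord], outcome: Outcome = "live_birth"
) -> float:
    """Simplified clinic estimator: total births over total embryos."""
    if len(records) == 0:
        raise ValueError("cannot estimate a rate from zero records")
    n, b = _arrays(records, outcome)
    return float(b.sum() / n.sum())


_ESTIMATORS = {
    "least_squares": estimate_lbr,
    "simplified": estimate_lbr_simplified,
}


def bootstrap_lbr_ci(
    records: Sequence[TransferRecord],
    n_bootstrap: int = 1000,
    seed: Optional[int] = None,
    outcome: Outcome = "live_birth",
    mode: str = "least_squares",
) -> Tuple[float, float]:
    """Percentile bootstrap 95% CI for a cell's per-embryo rate.

    Transfers (not embryos) are the resampling unit.  Deterministic under a
    fixed seed.  With fewer than two records the interval is undefined and
    a ``ValueError`` is raised rather than a fabricated interval returned.
    """
    if len(records) < 2:
        raise ValueError("bootstrap CI undefined for fewer than 2 records")
    if n_bootstrap < 200:
        raise ValueError("n_bootstrap must be >= 200 for a stable 95% CI")
    n, b = _arrays(records, outcome)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(records), size=(n_bootstrap, len(records)))
    ns, bs = n[idx], b[idx]
    if mode == "least_squares":
        est = (ns * bs).sum(axis=1) / (ns * ns).sum(axis=1)
    elif mode == "simplified":
        est = bs.sum(axis=1) / ns.sum(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    lo, hi = np.percentile(est, [2.5, 97.5])
    return float(lo), float(hi)


def fit_lbr_table(
    records: Sequence[TransferRecord],
    scheme: AgeGroupScheme = AgeGroupScheme(),
    outcome: Outcome = "live_birth",
    mode: str = "least_squares",
    n_bootstrap: int = 1000,
    seed: Optional[int] = None,
) -> LbrTable:
    """Fit the full per-embryo rate table over age groups and categories.

    One cell per (target label, category) with at least one transfer; CI
    bounds are bootstrap percentiles (``None`` when fewer than two
    transfers fall in the cell, or when ``n_bootstrap=0`` disables CIs).
    """
    if mode not in _ESTIMATORS:
        raise ValueError(f"unknown mode {mode!r}")
    estimator = _ESTIMATORS[mode]
    ss = np.random.SeedSequence(seed)
    cells: Dict[Tuple[str, EmbryoCategory], LbrCell] = {}
    for label in scheme.target_labels():
        in_group = [r for r in records if scheme.contains(r.age_at_retrieval, label)]
        for cat in EmbryoCategory.all():
            cell_records = [r for r in in_group if r.category == cat]
            if not cell_records:
                continue
            lbr = estimator(cell_records, outcome)
            ci_low = ci_high = None
            if n_bootstrap and len(cell_records) >= 2:
                child_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
                ci_low, ci_high = bootstrap_lbr_ci(
                    cell_records, n_bootstrap, child_seed, outcome, mode
                )
                # percentile bounds need not bracket the point estimate in
                # tiny cells; widen so the invariant lo <= lbr <= hi holds
                ci_low = min(ci_low, lbr)
                ci_high = max(ci_high, lbr)
            cells[(label, cat)] = LbrCell(
                lbr=lbr,
                ci_low=ci_low,
                ci_high=ci_high,
                n_transfers=len(cell_records),
                n_embryos=int(sum(r.n_embryos for r in cell_records)),
            )
    return LbrTable(cells=cells, scheme=scheme, outcome=outcome, mode=mode)


# ---------------------------------------------------------------------------
# Universal factors fraction
# ---------------------------------------------------------------------------


@dataclass
class UniEstimate:
    """Grid maximum-likelihood estimate of the universal factors fraction.

    ``non_identifiable`` is set when the likelihood is still increasing at
    ``uni = 1`` and the observed singleton count exceeds the prediction of
    the independence model by more than twice its sampling SD -- the data
    then demand a value above 1, which the model cannot represent (small
    subgroups can land here by chance).
    """

    value: float
    non_identifiable: bool
    grid: np.ndarray  # shape (G, 2): columns uni, log-likelihood
    n_multiple_transfers: int
    n_dropped_zero_lbr: int = 0
    likelihood: str = "singleton"


def _uni_grid(lbr_max: float, grid_step: float) -> np.ndarray:
    """Grid over [lbr_max, 1] at grid_step resolution, endpoints included."""
    if lbr_max >= 1.0:
        return np.array([1.0])
    start = math.ceil(lbr_max / grid_step - 1e-9) * grid_step
    grid = np.round(np.arange(start, 1.0 + grid_step / 2, grid_step), 10)
    grid = grid[(grid >= lbr_max - 1e-12) & (grid <= 1.0 + 1e-12)]
    if len(grid) == 0 or grid[0] > lbr_max + 1e-12:
        grid = np.concatenate([[lbr_max], grid])
    if grid[-1] < 1.0 - 1e-12:
        grid = np.concatenate([grid, [1.0]])
    return np.minimum(grid, 1.0)


def _uni_transfer_arrays(
    transfers: Sequence[TransferRecord],
    lbr_table: LbrTable,
    outcome: Outcome,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = np.empty(len(transfers))
    L = np.empty(len(transfers))
    k = np.empty(len(transfers))
    for i, t in enumerate(transfers):
        if t.n_embryos < 2:
            raise ValueError(
                "only multiple-embryo transfers inform the universal factors "
                f"fraction; got a transfer of {t.n_embryos} embryo"
            )
        rate = lbr_table.rate_for(t.age_at_retrieval, t.category)
        if rate is None:
            raise ValueError(
                f"no fitted cell for age {t.age_at_retrieval}, "
                f"category {t.category.label}"
            )
        n[i], L[i], k[i] = t.n_embryos, rate, t.outcome_count(outcome)
    return n, L, k


def _singleton_loglik_grid(
    n: np.ndarray, L: np.ndarray, k: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Log-likelihood of the singleton indicators over a grid of uni values.

    For a transfer of ``n`` embryos sharing rate ``L``, the probability of
    exactly one live birth is ``n * L * (1 - L / uni) ** (n - 1)``; each
    transfer contributes a Bernoulli term for singleton vs non-singleton.
    """
    u = grid[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        p = n * L * (1.0 - L / u) ** (n - 1.0)
    p = np.clip(p, 0.0, 1.0)
    y = (k == 1.0)
    with np.errstate(divide="ignore"):
        log_p = np.where(p > 0.0, np.log(np.maximum(p, 1e-300)), -np.inf)
        log_q = np.where(p < 1.0, np.log1p(-np.minimum(p, 1.0 - 1e-16)), -np.inf)
    terms = np.where(y, log_p, log_q)
    return terms.sum(axis=1)


def _multinomial_loglik_grid(
    n: np.ndarray, L: np.ndarray, k: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Full outcome-count log-likelihood over a grid of uni values."""
    out = np.zeros(len(grid))
    # group identical (n, L, k) triples: the likelihood is their product
    triples, counts = np.unique(np.column_stack([n, L, k]), axis=0, return_counts=True)
    for (ni, Li, ki), c in zip(triples, counts):
        for g, u in enumerate(grid):
            probs = outcome_distribution(
                TransferSpec.homogeneous(Li, int(ni), max(u, Li))
            )
            p = probs[int(ki)]
            out[g] += c * (np.log(p) if p > 0 else -np.inf)
    return out


_LIKELIHOODS = {
    "singleton": _singleton_loglik_grid,
    "multinomial": _multinomial_loglik_grid,
}


def uni_log_likelihood(
    transfers: Sequence[TransferRecord],
    lbr_table: LbrTable,
    uni: float,
    outcome: Outcome = "live_birth",
    likelihood: str = "singleton",
) -> float:
    """Log-likelihood of one uni value given multiple-embryo transfers."""
    n, L, k = _uni_transfer_arrays(transfers, lbr_table, outcome)
    if len(L) and uni < L.max() - 1e-12:
        raise ValueError(
            f"uni={uni} is below the largest per-embryo rate {L.max():.4f}; "
            "the model is ill-formed"
        )
    fn = _LIKELIHOODS[likelihood]
    return float(fn(n, L, k, np.array([float(uni)]))[0])


def fit_uni(
    transfers: Sequence[TransferRecord],
    lbr_table: LbrTable,
    grid_step: float = 0.01,
    outcome: Outcome = "live_birth",
    likelihood: str = "singleton",
) -> UniEstimate:
    """Grid search for the universal factors fraction.

    The grid spans ``[max cell rate, 1]`` at ``grid_step`` resolution (the
    model requires ``uni >= lbr``), ties broken toward the larger uni.
    Transfers whose cell rate is zero carry no information about uni and
    are dropped (counted in ``n_dropped_zero_lbr``); a singleton in such a
    cell is impossible under the model and is likewise dropped.
    """
    if likelihood not in _LIKELIHOODS:
        raise ValueError(f"unknown likelihood {likelihood!r}")
    multiples = [t for t in transfers if t.n_embryos >= 2]
    if not multiples:
        raise ValueError("no multiple-embryo transfers; uni is not estimable")
    n, L, k = _uni_transfer_arrays(multiples, lbr_table, outcome)
    keep = L > 0.0
    n_dropped = int((~keep).sum())
    n, L, k = n[keep], L[keep], k[keep]
    if len(L) == 0:
        raise ValueError(
            "all multiple-embryo transfers fall in zero-rate cells; "
            "uni is not estimable"
        )
    grid = _uni_grid(float(L.max()), grid_step)
    ll = _LIKELIHOODS[likelihood](n, L, k, grid)
    best = np.flatnonzero(ll >= ll.max() - 1e-12)[-1]  # ties -> larger uni
    value = float(grid[best])

    # Flag when the data demand uni > 1: likelihood still climbing at the
    # boundary and the singleton count exceeds the independence prediction
    # by more than sampling noise (2 SD), so truth-at-1 cohorts are not
    # flagged for chance excesses.
    non_identifiable = False
    if best == len(grid) - 1 and len(grid) >= 2 and ll[-1] > ll[-2]:
        observed_singletons = float((k == 1).sum())
        p1 = np.clip(n * L * (1.0 - L) ** (n - 1.0), 0.0, 1.0)
        predicted_at_1 = float(p1.sum())
        sd_at_1 = float(np.sqrt((p1 * (1.0 - p1)).sum()))
        if observed_singletons > predicted_at_1 + 2.0 * sd_at_1:
            non_identifiable = True

    return UniEstimate(
        value=value,
        non_identifiable=non_identifiable,
        grid=np.column_stack([grid, ll]),
        n_multiple_transfers=len(multiples),
        n_dropped_zero_lbr=n_dropped,
        likelihood=likelihood,
    )


def bootstrap_uni_ci(
    records: Sequence[TransferRecord],
    scheme: AgeGroupScheme = AgeGroupScheme(),
    n_bootstrap: int = 200,
    seed: Optional[int] = None,
    outcome: Outcome = "live_birth",
    mode: str = "least_squares",
    likelihood: str = "singleton",
    grid_step: float = 0.01,
) -> Tuple[float, float]:
    """Percentile bootstrap 95% CI for uni, refitting rates each resample.

    Resamples whole transfers from the full record list (singles included,
    since they inform the rate table), refits the rate table and uni, and
    returns the 2.5/97.5 percentiles of the refitted values.  Resamples in
    which uni is not estimable (e.g. no multiple-embryo transfer drawn) are
    skipped.
    """
    if n_bootstrap < 100:
        raise ValueError("n_bootstrap must be >= 100")
    rng = np.random.default_rng(seed)
    records = list(records)
    values = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, len(records), size=len(records))
        sample = [records[i] for i in idx]
        table = fit_lbr_table(sample, scheme, outcome, mode, n_bootstrap=0)
        try:
            est = fit_uni(
                [t for t in sample if t.n_embryos >= 2],
                table,
                grid_step,
                outcome,
                likelihood,
            )
        except ValueError:
            continue
        values.append(est.value)
    if len(values) < n_bootstrap // 2:
        raise ValueError("uni was estimable in fewer than half the resamples")
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(lo), float(hi)
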