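"""Synthetic clinic cohorts and the uni sample-size study.

Real transfer-level registries are clinic-private, so tests and worked
examples run on synthetic cohorts drawn from the same mechanism the model
assumes: for each transfer an age, category, and embryo count are drawn
from configurable mixes; transfer-level conditions are favorable with
probability ``uni`` of the cycle type; when favorable each embryo delivers
independently at rate ``lbr / uni``, otherwise no embryo delivers.  The
default cohort mirrors a mid-size academic IVF clinic over a few years:
684 transfers averaging 2.4 embryos per transfer across the four transfer
categories, ages 25-44, with per-embryo rates that fall steeply after the
mid-thirties (about 40% for a fresh blastocyst in the pooled young group
down to about 1% for a frozen cleavage-stage embryo at 43).

The generator emulates sampling noise and cohort sparsity; it does not
emulate morphologic heterogeneity between embryos in one transfer,
monozygotic splitting, or drift in clinic practice over time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .estimation import TransferRecord
from .model import Cycle, EmbryoCategory, Stage, TransferSpec, outcome_distribution

__all__ = [
    "default_lbr_curve",
    "ClinicSimConfig",
    "simulate_clinic",
    "uni_sample_size_study",
    "sample_size_for_half_width",
]

_BASE_LBR = {
    (Stage.BLASTOCYST, Cycle.FRESH): 0.40,
    (Stage.BLASTOCYST, Cycle.FROZEN): 0.35,
    (Stage.CLEAVAGE, Cycle.FRESH): 0.15,
    (Stage.CLEAVAGE, Cycle.FROZEN): 0.10,
}


def default_lbr_curve(age: int, category: EmbryoCategory) -> float:
    """Age- and category-dependent per-embryo live-birth rate.

    Flat through age 35, then an exponential decline of about 22% per year,
    putting a frozen cleavage-stage embryo at 43 near 1%.
    """
    base = _BASE_LBR[(category.stage, category.cycle)]
    return base * math.exp(-0.25 * max(0, age - 35))


def _default_age_weights() -> Dict[int, float]:
    ages = np.arange(25, 45)
    w = np.exp(-0.5 * ((ages - 35) / 5.0) ** 2)
    w /= w.sum()
    return {int(a): float(x) for a, x in zip(ages, w)}


def _default_category_mix() -> Dict[EmbryoCategory, float]:
    return {
        EmbryoCategory(Stage.BLASTOCYST, Cycle.FRESH): 0.35,
        EmbryoCategory(Stage.CLEAVAGE, Cycle.FRESH): 0.27,
        EmbryoCategory(Stage.BLASTOCYST, Cycle.FROZEN): 0.25,
        EmbryoCategory(Stage.CLEAVAGE, Cycle.FROZEN): 0.13,
    }


@dataclass
class ClinicSimConfig:
    """Cohort composition and true parameters for a synthetic clinic.

    Defaults: 684 transfers; embryos-per-transfer mix {1: 0.15, 2: 0.30,
    3: 0.55} (mean 2.4); ages 25-44 weighted toward the mid-thirties; true
    universal factors fractions 0.68 (fresh) and 0.75 (frozen).
    """

    n_transfers: int = 684
    age_distribution: Dict[int, float] = field(default_factory=_default_age_weights)
    category_mix: Dict[EmbryoCategory, float] = field(
        default_factory=_default_category_mix
    )
    embryos_per_transfer_distribution: Dict[int, float] = field(
        default_factory=lambda: {1: 0.15, 2: 0.30, 3: 0.55}
    )
    true_lbr_curve: Callable[[int, EmbryoCategory], float] = default_lbr_curve
    true_uni: Dict[Cycle, float] = field(
        default_factory=lambda: {Cycle.FRESH: 0.68, Cycle.FROZEN: 0.75}
    )
    seed: Optional[int] = 0

    def validate(self) -> None:
        if self.n_transfers < 1:
            raise ValueError("n_transfers must be >= 1")
        for name, dist in (
            ("age_distribution", self.age_distribution),
            ("category_mix", self.category_mix),
            ("embryos_per_transfer_distribution", self.embryos_per_transfer_distribution),
        ):
            weights = np.array(list(dist.values()), dtype=float)
            if len(weights) == 0 or (weights < 0).any() or weights.sum() <= 0:
                raise ValueError(f"{name}: weights must be non-negative with a positive sum")
        for n in self.embryos_per_transfer_distribution:
            if n < 1:
                raise ValueError("embryos_per_transfer_distribution: counts must be >= 1")
        for cycle, uni in self.true_uni.items():
            if not (0.0 < uni <= 1.0):
                raise ValueError(f"true_uni[{cycle}] must be in (0, 1], got {uni}")
        for age, w_age in self.age_distribution.items():
            if w_age == 0:
                continue
            for cat, w_cat in self.category_mix.items():
                if w_cat == 0:
                    continue
                lbr = self.true_lbr_curve(age, cat)
                uni = self.true_uni[cat.cycle]
                if not (0.0 <= lbr <= uni):
                    raise ValueError(
                        f"true_lbr_curve(age={age}, {cat.label}) = {lbr} "
                        f"violates 0 <= lbr <= uni ({uni})"
                    )

    def mean_embryos_per_transfer(self) -> float:
        ns = np.array(list(self.embryos_per_transfer_distribution.keys()), dtype=float)
        ws = np.array(list(self.embryos_per_transfer_distribution.values()), dtype=float)
        return float((ns * ws).sum() / ws.sum())


def _draw_from(rng: np.random.Generator, dist: Dict, size: int) -> np.ndarray:
    keys = list(dist.keys())
    w = np.array([dist[k] for k in keys], dtype=float)
    idx = rng.choice(len(keys), size=size, p=w / w.sum())
    return np.array(keys, dtype=object)[idx]


def simulate_clinic(
    config: ClinicSimConfig, seed: Optional[int] = None
) -> List[TransferRecord]:
    """Draw a synthetic cohort of transfer records.

    ``seed`` overrides ``config.seed`` when given; identical seeds yield
    identical cohorts.  Fetal-heartbeat counts are set equal to live-birth
    counts (every simulated ongoing pregnancy is carried to delivery),
    which keeps both outcome variants usable on synthetic data.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    m = config.n_transfers
    ages = _draw_from(rng, config.age_distribution, m).astype(int)
    cats = _draw_from(rng, config.category_mix, m)
    n_emb = _draw_from(rng, config.embryos_per_transfer_distribution, m).astype(int)

    lbr = np.array(
        [config.true_lbr_curve(int(a), c) for a, c in zip(ages, cats)]
    )
    uni = np.array([config.true_uni[c.cycle] for c in cats])
    favorable = rng.random(m) < uni
    cond = np.divide(lbr, uni, out=np.zeros_like(lbr), where=uni > 0)
    births = np.where(favorable, rng.binomial(n_emb, np.clip(cond, 0, 1)), 0)

    return [
        TransferRecord(
            age_at_retrieval=int(a),
            category=c,
            n_embryos=int(n),
            n_live_births=int(b),
            n_fetal_heartbeats=int(b),
        )
        for a, c, n, b in zip(ages, cats, n_emb, births)
    ]


# ---------------------------------------------------------------------------
# Sample-size study for the universal factors fraction
# ---------------------------------------------------------------------------


def _fit_uni_from_counts(
    n0: int, n1: int, n2: int, grid_step: float = 0.01
) -> float:
    """Grid-search uni fit for a homogeneous two-embryo cohort.

    (n0, n1, n2) are the numbers of transfers with 0, 1 and 2 live births.
    These counts are sufficient: the least-squares cell rate is
    ``L = (n1 + 2 n2) / (2 N)`` and the singleton-indicator log-likelihood
    is ``n1 log p + (N - n1) log(1 - p)`` with
    ``p(uni) = 2 L (1 - L / uni)``.  Equivalent to building the records and
    calling :func:`embryotx.estimation.fit_uni`, but fast enough for the
    nested bootstrap of the sample-size study.
    """
    from .estimation import _uni_grid  # shared grid construction

    N = n0 + n1 + n2
    if N == 0:
        return float("nan")
    L = (n1 + 2 * n2) / (2.0 * N)
    if L <= 0.0:
        return float("nan")
    grid = _uni_grid(L, grid_step)
    p = np.clip(2.0 * L * (1.0 - L / grid), 0.0, 1.0)
    with np.errstate(divide="ignore"):
        ll = np.where(
            p > 0, n1 * np.log(np.maximum(p, 1e-300)), (0.0 if n1 == 0 else -np.inf)
        ) + (N - n1) * np.log1p(-np.minimum(p, 1.0 - 1e-16))
    best = np.flatnonzero(ll >= ll.max() - 1e-12)[-1]
    return float(grid[best])


def uni_sample_size_study(
    true_lbr: float = 0.30,
    true_uni: float = 0.70,
    n_grid: Sequence[int] = (1250, 2500, 5000, 10000, 20000),
    n_replicates: int = 50,
    n_bootstrap: int = 200,
    seed: Optional[int] = None,
    grid_step: float = 0.01,
) -> pd.DataFrame:
    """Bootstrap CI half-width for uni as a function of cohort size.

    For each cohort size ``n``, simulates ``n_replicates`` cohorts of ``n``
    two-embryo transfers with a common per-embryo rate, fits uni to each,
    bootstraps a percentile 95% CI (resampling transfers, refitting the
    rate and uni), and records the mean CI half-width.  Homogeneous
    two-embryo cohorts are used because no particular cohort composition is
    canonical for this question; the defaults (rate 0.30, uni 0.70) sit
    near typical fitted clinic values.
    """
    if sorted(n_grid) != list(n_grid):
        raise ValueError("n_grid must be sorted ascending")
    if n_replicates < 50:
        raise ValueError("n_replicates must be >= 50")
    spec = TransferSpec.homogeneous(true_lbr, 2, true_uni)
    probs = outcome_distribution(spec)
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_grid:
        half_widths = np.empty(n_replicates)
        for r in range(n_replicates):
            counts = rng.multinomial(n, probs)
            boot = rng.multinomial(n, counts / n, size=n_bootstrap)
            vals = np.array(
                [_fit_uni_from_counts(*c, grid_step=grid_step) for c in boot]
            )
            vals = vals[np.isfinite(vals)]
            lo, hi = np.percentile(vals, [2.5, 97.5])
            half_widths[r] = (hi - lo) / 2.0
        rows.append(
            {
                "n_transfers": int(n),
                "mean_ci_half_width": float(half_widths.mean()),
                "sd_ci_half_width": float(half_widths.std(ddof=1)),
                "n_replicates": int(n_replicates),
            }
        )
    return pd.DataFrame(rows)


def sample_size_for_half_width(
    study: pd.DataFrame, target: float = 0.05
) -> float:
    """Cohort size at which the mean CI half-width crosses ``target``.

    Interpolates linearly in log(half-width) vs log(n) between the two grid
    points bracketing the target; if the target is outside the measured
    range, extrapolates from a least-squares line through all points
    (half-widths scale close to 1/sqrt(n), so the log-log relation is
    nearly straight).
    """
    n = study["n_transfers"].to_numpy(dtype=float)
    hw = study["mean_ci_half_width"].to_numpy(dtype=float)
    order = np.argsort(n)
    n, hw = n[order], hw[order]
    log_n, log_hw = np.log(n), np.log(hw)
    # half-width decreases with n; find a bracketing pair
    for i in range(len(n) - 1):
        lo_hw, hi_hw = hw[i + 1], hw[i]
        if min(lo_hw, hi_hw) <= target <= max(lo_hw, hi_hw):
            t = (math.log(target) - log_hw[i]) / (log_hw[i + 1] - log_hw[i])
            return float(math.exp(log_n[i] + t * (log_n[i + 1] - log_n[i])))
    slope, intercept = np.polyfit(log_n, log_hw, 1)
    return float(math.exp((math.log(target) - intercept) / slope))
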