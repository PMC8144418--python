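"""Exact outcome model for transfer of one or more embryos.

Each transfer is modeled as a two-stage experiment.  Transfer-level
conditions -- the "universal factors": endometrial receptivity, uterine
anatomy, transfer technique, culture conditions and everything else that
acts on all embryos placed together -- are favorable with probability
``uni``.  When they are unfavorable no embryo can implant.  When they are
favorable each embryo independently results in a live-born infant with
probability ``lbr_i / uni``, where ``lbr_i`` is that embryo's marginal
live-birth rate.

The construction keeps each embryo's marginal birth probability at exactly
``lbr_i`` while making sibling embryos positively correlated: the twin rate
for two embryos is ``lbr_1 * lbr_2 / uni``, above the independence
prediction ``lbr_1 * lbr_2``.  With ``uni = 1`` (conditions always
favorable) the model collapses to independent implantation, i.e. the
Poisson-binomial distribution of the per-embryo rates; with one embryo the
distribution is ``Bernoulli(lbr)`` for any ``uni``.

The number of live births for ``n`` embryos is therefore a zero-inflated
Poisson-binomial.  Probabilities are computed by the standard dynamic
programming convolution (O(n^2)), which is numerically stable and exact to
machine precision for the handful of embryos ever transferred clinically.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Tuple

import numpy as np

__all__ = [
    "Stage",
    "Cycle",
    "EmbryoCategory",
    "TransferSpec",
    "outcome_distribution",
    "delivery_rate",
    "multiples_fractions",
]

# absolute slack for float comparisons of probabilities
_EPS = 1e-12


class Stage(str, Enum):
    """Embryo developmental stage at transfer (day 3 vs day 5/6)."""

    CLEAVAGE = "cleavage"
    BLASTOCYST = "blastocyst"


class Cycle(str, Enum):
    """Transfer cycle type."""

    FRESH = "fresh"
    FROZEN = "frozen"


@dataclass(frozen=True, order=True)
class EmbryoCategory:
    """One of the four transfer categories: stage crossed with cycle type."""

    stage: Stage
    cycle: Cycle

    def __post_init__(self) -> None:
        object.__setattr__(self, "stage", Stage(self.stage))
        object.__setattr__(self, "cycle", Cycle(self.cycle))

    @property
    def label(self) -> str:
        return f"{self.cycle.value} {self.stage.value}"

    @classmethod
    def all(cls) -> Tuple["EmbryoCategory", ...]:
        return tuple(
            cls(stage, cycle) for cycle in Cycle for stage in Stage
        )


@dataclass(frozen=True)
class TransferSpec:
    """Parameters of a single embryo transfer.

    Parameters
    ----------
    per_embryo_lbr
        Marginal live-birth rate of each transferred embryo, one entry per
        embryo.  Entries may differ (e.g. embryos of different quality
        transferred together).
    uni
        Universal factors fraction in (0, 1].  Every ``lbr`` must satisfy
        ``lbr <= uni`` for the conditional rate ``lbr / uni`` to be a
        probability; ``lbr == uni`` is legal (certain birth when conditions
        are favorable), ``lbr > uni`` is a hard error rather than a clamp so
        that identifiability failures surface instead of being hidden.
    """

    per_embryo_lbr: Tuple[float, ...]
    uni: float = 1.0

    def __post_init__(self) -> None:
        lbrs = tuple(float(x) for x in self.per_embryo_lbr)
        object.__setattr__(self, "per_embryo_lbr", lbrs)
        object.__setattr__(self, "uni", float(self.uni))
        if len(lbrs) == 0:
            raise ValueError("a transfer must contain at least one embryo")
        if not (0.0 < self.uni <= 1.0):
            raise ValueError(
                f"universal factors fraction must be in (0, 1], got {self.uni}"
            )
        for i, lbr in enumerate(lbrs):
            if not (0.0 <= lbr <= 1.0):
                raise ValueError(f"per-embryo LBR must be in [0, 1], got {lbr}")
            if lbr > self.uni + _EPS:
                raise ValueError(
                    f"embryo {i}: LBR {lbr} exceeds universal factors "
                    f"fraction {self.uni}; the model is ill-formed "
                    "(conditional implantation rate would exceed 1)"
                )

    @classmethod
    def homogeneous(cls, lbr: float, n_embryos: int, uni: float = 1.0) -> "TransferSpec":
        """Transfer of ``n_embryos`` embryos sharing one live-birth rate."""
        if n_embryos < 1:
            raise ValueError("n_embryos must be >= 1")
        return cls((float(lbr),) * int(n_embryos), uni)

    @property
    def n_embryos(self) -> int:
        return len(self.per_embryo_lbr)


def _poisson_binomial(p: np.ndarray) -> np.ndarray:
    """PMF of the number of successes among independent Bernoulli(p_i)."""
    probs = np.zeros(len(p) + 1)
    probs[0] = 1.0
    for pi in p:
        probs[1:] = probs[1:] * (1.0 - pi) + probs[:-1] * pi
        probs[0] *= 1.0 - pi
    return probs


def outcome_distribution(spec: TransferSpec) -> np.ndarray:
    """Exact probability of each number of live-born infants.

    Returns
    -------
    numpy.ndarray
        Vector ``probs`` of length ``n_embryos + 1`` where ``probs[k]`` is
        the probability of exactly ``k`` live births.  Entries are
        non-negative and sum to 1 to machine precision.
    """
    lbr = np.asarray(spec.per_embryo_lbr, dtype=float)
    cond = np.clip(lbr / spec.uni, 0.0, 1.0)
    probs = spec.uni * _poisson_binomial(cond)
    probs[0] += 1.0 - spec.uni
    return probs


def delivery_rate(spec: TransferSpec) -> float:
    """Probability of at least one live birth (total delivery rate)."""
    return float(1.0 - outcome_distribution(spec)[0])


def multiples_fractions(spec: TransferSpec) -> Tuple[float, float, float]:
    """Fractions of deliveries that are multiples, twins, triplets-or-more.

    All three are conditional on at least one live birth: twin deliveries
    are exactly two infants, triplet-or-more are three or more, and the
    multiples fraction is their sum.  Only dizygotic multiples (distinct
    embryos) are represented; monozygotic splitting is outside the model.

    Raises
    ------
    ValueError
        If the delivery rate is zero, in which case the fractions are
        undefined.
    """
    probs = outcome_distribution(spec)
    p_delivery = 1.0 - probs[0]
    if p_delivery <= 0.0:
        raise ValueError(
            "multiples fractions are undefined when the delivery rate is 0"
        )
    p_twin = probs[2] if len(probs) > 2 else 0.0
    p_trip = float(probs[3:].sum()) if len(probs) > 3 else 0.0
    return (
        float((p_twin + p_trip) / p_delivery),
        float(p_twin / p_delivery),
        float(p_trip / p_delivery),
    )
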