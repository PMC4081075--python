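"""Survival estimation and subgroup/mutation association.

Kaplan-Meier product-limit curves and the log-rank test compare overall
survival between expression-defined subgroups; Fisher's exact test (one-sided,
enrichment direction) asks whether mutations (e.g. MYD88-L265P) concentrate
in one quadrant.  Estimation is delegated to lifelines; this module defines
the record/curve containers and the association bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .enrichment import EnrichmentResult

__all__ = [
    "SurvivalRecord",
    "SurvivalCurve",
    "km_estimate",
    "logrank_test",
    "mutation_association",
    "DEFAULT_COLLAPSE_RULE",
]


@dataclass(frozen=True)
class SurvivalRecord:
    sample: str
    time: float  # months
    event: int  # 1 = death, 0 = censored
    group: str = ""

    def __post_init__(self) -> None:
        if not (self.time > 0 and np.isfinite(self.time)):
            raise ValueError(f"time must be positive and finite, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass
class SurvivalCurve:
    """Product-limit estimate at the observed event times."""

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event times must be strictly ascending")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")

    def at(self, t: float) -> float:
        """S(t): step-function value just after time t."""
        i = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])


def _records_to_arrays(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=int)
    return t, e


def km_estimate(records: Sequence[SurvivalRecord]) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate for one group.

    Censored times reduce the risk set only; ties between deaths and
    censorings at the same instant are resolved events-first (the standard
    convention, as implemented by lifelines).
    """
    if not records:
        raise ValueError("no records")
    times, events = _records_to_arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    mask = table["observed"] > 0
    event_times = table.index[mask].to_numpy(dtype=float)
    return SurvivalCurve(
        event_times=event_times,
        at_risk=table.loc[mask, "at_risk"].to_numpy(dtype=int),
        events=table.loc[mask, "observed"].to_numpy(dtype=int),
        survival=kmf.survival_function_at_times(event_times).to_numpy(dtype=float),
    )


def logrank_test(groups: Mapping[str, Sequence[SurvivalRecord]]) -> tuple[float, float, int]:
    """Log-rank comparison of two or more groups.

    Returns (chi-squared statistic, p, degrees of freedom = groups - 1).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    times, events, labels = [], [], []
    for label, records in groups.items():
        if not records:
            raise ValueError(f"group {label!r} has no records")
        t, e = _records_to_arrays(records)
        times.append(t)
        events.append(e)
        labels.extend([label] * len(records))
    if sum(e.sum() for e in events) == 0:
        raise ValueError("no events in any group")
    res = multivariate_logrank_test(
        np.concatenate(times), np.asarray(labels), np.concatenate(events)
    )
    return float(res.test_statistic), float(res.p_value), len(groups) - 1


#: Clinical-scenario collapse: targeted L265P testing calls every non-L265P
#: sequence change (status "other") wild type.
DEFAULT_COLLAPSE_RULE: Mapping[str, str] = {
    "L265P": "mutated",
    "wild_type": "wild_type",
    "other": "wild_type",
}


def mutation_association(quadrants: pd.Series, mutation_status: pd.Series,
                         collapse_rule: Mapping[str, str] = DEFAULT_COLLAPSE_RULE,
                         ) -> dict[str, EnrichmentResult]:
    """Per-quadrant one-sided Fisher enrichment of mutated samples.

    For each quadrant the 2x2 table is (in-quadrant vs rest) x (mutated vs
    not).  ``collapse_rule`` maps raw status labels to ``mutated`` /
    ``wild_type`` / ``drop``; a status missing from the rule is an error.
    """
    quadrants = quadrants.dropna()
    mutation_status = mutation_status.reindex(quadrants.index)
    if mutation_status.isna().any():
        missing = list(mutation_status.index[mutation_status.isna()])
        raise ValueError(f"samples without mutation status: {missing[:5]}")
    collapsed = {}
    for sample, status in mutation_status.items():
        if status not in collapse_rule:
            raise ValueError(f"unknown mutation status {status!r} (no collapse rule)")
        collapsed[sample] = collapse_rule[status]
    keep = [s for s, v in collapsed.items() if v != "drop"]
    mutated = pd.Series({s: collapsed[s] == "mutated" for s in keep})
    quadrants = quadrants.loc[keep]

    N = len(keep)
    K = int(mutated.sum())
    out: dict[str, EnrichmentResult] = {}
    for quadrant in sorted(quadrants.unique()):
        in_q = quadrants == quadrant
        n = int(in_q.sum())
        k = int((in_q & mutated).sum())
        table = [[k, n - k], [K - k, (N - n) - (K - k)]]
        p = float(stats.fisher_exact(table, alternative="greater")[1])
        out[quadrant] = EnrichmentResult(
            k=k, n=n, K=K, N=N, p_value=p,
            direction="enriched" if k * N >= n * K else "depleted",
        )
    return out
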