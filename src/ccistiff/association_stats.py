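"""Association between CCI and joint-stiffness time series.

For every (DOF, pair, formulation, EMG variant) the Pearson correlation
between the 101-point CCI and stiffness series is computed *within each gait
cycle*, then summarized by mean and sample standard deviation across cycles.
Mean correlations are classified by magnitude: negligible < 0.3 ≤ weak
< 0.5 ≤ moderate < 0.7 ≤ strong (half-open intervals; the sign is reported
separately so a strongly negative association is still "strong").

Formulations are compared by a two-sided Wilcoxon rank-sum (Mann–Whitney)
test on their per-cycle correlation sets, exact for small samples without
ties, at significance level 0.05.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cci import CciSeries
from .joint_stiffness import StiffnessSeries

__all__ = [
    "ALPHA",
    "CorrelationRecord",
    "RankSumResult",
    "pearson",
    "classify_strength",
    "correlate_per_cycle",
    "rank_sum_test",
    "best_pair_report",
]

log = logging.getLogger(__name__)

ALPHA = 0.05
#: |r| thresholds separating negligible / weak / moderate / strong.
STRENGTH_EDGES = (0.3, 0.5, 0.7)


@dataclass(frozen=True)
class CorrelationRecord:
    """Per-cycle correlations of one (dof, pair, formulation, variant) cell."""

    dof: str
    pair: tuple[str, str]
    formulation: str
    variant: str
    r_per_cycle: tuple[float, ...]
    r_mean: float
    r_sd: float
    strength: str


@dataclass(frozen=True)
class RankSumResult:
    statistic: float
    p_value: float
    method: str

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two equal-length series.

    Returns NaN (with a logged warning) when either series has zero variance —
    the correlation is undefined there, not zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("pearson needs two equal-length 1-D series of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("zero-variance series: correlation undefined, reporting NaN")
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def classify_strength(r_mean: float) -> str:
    """Strength class of a mean correlation, by magnitude.

    Half-open intervals: negligible [0, 0.3), weak [0.3, 0.5),
    moderate [0.5, 0.7), strong [0.7, 1].  Negative means are classified by
    |r_mean|; the sign lives in ``r_mean`` itself.
    """
    m = abs(r_mean)
    if math.isnan(m):
        return "undefined"
    if m < STRENGTH_EDGES[0]:
        return "negligible"
    if m < STRENGTH_EDGES[1]:
        return "weak"
    if m < STRENGTH_EDGES[2]:
        return "moderate"
    return "strong"


def correlate_per_cycle(
    cci: list[CciSeries],
    stiffness: list[StiffnessSeries],
    dof: str | None = None,
) -> CorrelationRecord:
    """One Pearson r per gait cycle between matched CCI and stiffness series."""
    if not cci or not stiffness:
        raise ValueError("need at least one CCI and one stiffness cycle")
    by_cycle = {s.cycle_index: s for s in stiffness}
    rs = []
    for c in cci:
        if c.cycle_index not in by_cycle:
            raise ValueError(f"no stiffness series for cycle {c.cycle_index}")
        rs.append(pearson(c.values, by_cycle[c.cycle_index].k_joint))
    rs_arr = np.asarray(rs, dtype=float)
    valid = rs_arr[~np.isnan(rs_arr)]
    r_mean = float(np.mean(valid)) if valid.size else float("nan")
    if valid.size >= 2:
        r_sd = float(np.std(valid, ddof=1))
    else:
        log.warning("fewer than 2 valid cycles: correlation SD undefined")
        r_sd = float("nan")
    c0 = cci[0]
    return CorrelationRecord(
        dof=dof if dof is not None else stiffness[0].dof,
        pair=c0.pair,
        formulation=c0.formulation,
        variant=c0.variant,
        r_per_cycle=tuple(rs),
        r_mean=r_mean,
        r_sd=r_sd,
        strength=classify_strength(r_mean),
    )


def rank_sum_test(r1, r2) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test on two samples.

    The exact null distribution is used for combined n ≤ 20 without ties;
    otherwise the normal approximation with tie correction.
    """
    x = np.asarray(r1, dtype=float)
    y = np.asarray(r2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank-sum test needs two non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return RankSumResult(
        statistic=float(res.statistic), p_value=float(res.pvalue), method=method
    )


def best_pair_report(records: list[CorrelationRecord]) -> pd.DataFrame:
    """Best pair per (dof, formulation, variant), plus CCI1-vs-CCI2 contrasts.

    Returns a table with one row per (dof, formulation, variant) holding the
    record with the highest r_mean (ties broken by lexicographically first
    pair name, logged), and — for each dof/variant — the difference between
    the best CCI1 and best CCI2 mean correlations with the rank-sum p value
    of their per-cycle r sets.
    """
    if not records:
        raise ValueError("no correlation records")
    rows = []
    best: dict[tuple[str, str, str], CorrelationRecord] = {}
    for rec in records:
        key = (rec.dof, rec.formulation, rec.variant)
        cur = best.get(key)
        if cur is None:
            best[key] = rec
            continue
        a = -np.inf if math.isnan(rec.r_mean) else rec.r_mean
        b = -np.inf if math.isnan(cur.r_mean) else cur.r_mean
        if a > b or (a == b and rec.pair < cur.pair):
            if a == b:
                log.info("r_mean tie at %s: keeping %s over %s", key, rec.pair, cur.pair)
            best[key] = rec
    for (dof, form, variant), rec in sorted(best.items()):
        rows.append(
            {
                "dof": dof,
                "formulation": form,
                "variant": variant,
                "muscle_a": rec.pair[0],
                "muscle_b": rec.pair[1],
                "r_mean": rec.r_mean,
                "r_sd": rec.r_sd,
                "strength": rec.strength,
                "n_cycles": len(rec.r_per_cycle),
            }
        )
    report = pd.DataFrame(rows)
    contrasts = []
    for (dof, _f, variant) in sorted({(d, f, v) for (d, f, v) in best}):
        k1, k2 = (dof, "CCI1", variant), (dof, "CCI2", variant)
        if k1 in best and k2 in best and _f == "CCI1":
            b1, b2 = best[k1], best[k2]
            r1 = [r for r in b1.r_per_cycle if not math.isnan(r)]
            r2 = [r for r in b2.r_per_cycle if not math.isnan(r)]
            rs = rank_sum_test(r1, r2) if r1 and r2 else None
            contrasts.append(
                {
                    "dof": dof,
                    "variant": variant,
                    "r1_mean": b1.r_mean,
                    "r2_mean": b2.r_mean,
                    "r1_minus_r2": b1.r_mean - b2.r_mean,
                    "ranksum_p": rs.p_value if rs else float("nan"),
                    "significant": bool(rs.significant) if rs else False,
                }
            )
    report.attrs["contrasts"] = pd.DataFrame(contrasts)
    return report
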