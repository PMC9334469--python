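"""Study-level analysis: best-PEEP identification, recovery metrics,
relative treatment effects, rank-sum comparisons and cohort summaries.

Best PEEP is the argmax of a chosen endpoint (dynamic compliance, PaO2 or
oxygen delivery) over the measured steps of a decremental PEEP trial;
group-level best PEEP takes the argmax of the across-animal mean curve,
restricted to PEEP levels measured in every animal.  Ties break toward
the lower PEEP (less exposure for equal benefit).

The relative treatment effect (RTE) of a subgroup is the probability that
a value drawn from the pooled data is smaller than (or, for ties, half
equal to) a value drawn from the subgroup -- computed from pooled
mid-ranks.  The Mann-Whitney U comparison uses an exact permutation null
for small samples and the tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .protocol import ExperimentLog, PeepTrialResult

__all__ = [
    "BestPeepResult",
    "RTEResult",
    "best_peep",
    "group_best_peep",
    "deviation_from_lavage",
    "relative_treatment_effect",
    "rank_sum_test",
    "cohort_summary",
]

CRITERIA = {"max_crs": "crs", "max_pao2": "pao2", "max_do2": "do2"}
EXACT_N_MAX = 12  # combined sample size up to which the permutation null is exact


@dataclass(frozen=True)
class BestPeepResult:
    criterion: str
    best_peep: float
    best_value: float
    per_step_curve: tuple[tuple[float, float], ...]  # (peep, value), as measured


@dataclass(frozen=True)
class RTEResult:
    label: str
    rte: float
    n: int


def _curve(trial: PeepTrialResult, criterion: str) -> list[tuple[float, float]]:
    attr = CRITERIA[criterion]
    return [(s.peep, getattr(s, attr)) for s in trial.steps]


def _argmax_low_tie(curve: Sequence[tuple[float, float]]) -> tuple[float, float]:
    best_value = max(v for _, v in curve)
    best_peep = min(p for p, v in curve if v == best_value)
    return best_peep, best_value


def best_peep(trial: PeepTrialResult, criterion: str = "max_crs") -> BestPeepResult:
    """Best PEEP for one animal's trial under the given criterion."""
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {sorted(CRITERIA)}")
    if not trial.steps:
        raise ValueError("trial has no measured steps")
    curve = _curve(trial, criterion)
    peep, value = _argmax_low_tie(curve)
    return BestPeepResult(criterion, peep, value, tuple(curve))


def group_best_peep(
    trials: Sequence[PeepTrialResult], criterion: str = "max_crs"
) -> BestPeepResult:
    """Group-level best PEEP from the mean curve across animals.

    Only PEEP levels measured in every animal enter the mean curve (early
    hypoxemic terminations truncate individual ladders).
    """
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {sorted(CRITERIA)}")
    if not trials or any(not t.steps for t in trials):
        raise ValueError("every trial must have measured steps")
    curves = [dict(_curve(t, criterion)) for t in trials]
    common = set(curves[0])
    for c in curves[1:]:
        common &= set(c)
    if not common:
        raise ValueError("no PEEP level was measured in all animals")
    mean_curve = sorted(
        (p, float(np.mean([c[p] for c in curves]))) for p in common
    )
    peep, value = _argmax_low_tie(mean_curve)
    return BestPeepResult(criterion, peep, value, tuple(mean_curve))


def deviation_from_lavage(post_rm_value: float, post_lavage_value: float) -> float:
    """Relative deviation (%) of a post-RM value from its post-lavage value."""
    if post_lavage_value <= 0:
        raise ValueError("post-lavage reference must be positive")
    return 100.0 * (post_rm_value - post_lavage_value) / post_lavage_value


def relative_treatment_effect(
    values: Sequence[float], labels: Sequence[str]
) -> list[RTEResult]:
    """RTE of each subgroup from pooled mid-ranks.

    RTE(g) = (mean mid-rank of g - 1/2) / N.  The size-weighted mean of
    the RTEs over all subgroups is exactly 1/2.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.size < 2:
        raise ValueError("need at least two observations")
    if values.size != labels.size:
        raise ValueError("values and labels must align")
    ranks = stats.rankdata(values)  # mid-ranks
    out = []
    for lab in dict.fromkeys(labels.tolist()):  # preserve first-seen order
        mask = labels == lab
        if not mask.any():
            raise ValueError(f"empty subgroup {lab!r}")
        rte = (float(ranks[mask].mean()) - 0.5) / values.size
        out.append(RTEResult(str(lab), rte, int(mask.sum())))
    return out


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of sample ``a`` from pooled mid-ranks."""
    na = a.size
    ranks = stats.rankdata(np.concatenate([a, b]))
    return float(ranks[:na].sum() - na * (na + 1) / 2.0)


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U test; returns (U of sample a, two-sided p).

    Combined n <= 12 uses the exact permutation distribution of U over all
    label assignments (valid under ties); larger samples use the
    tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    na, nb = a.size, b.size
    u_obs = _u_statistic(a, b)
    n = na + nb
    if n <= EXACT_N_MAX:
        pooled = np.concatenate([a, b])
        mid = na * nb / 2.0
        dev = abs(u_obs - mid)
        count = 0
        total = 0
        for idx in combinations(range(n), na):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mid) >= dev - 1e-12:
                count += 1
        return u_obs, count / total
    # tie-corrected normal approximation
    pooled = np.concatenate([a, b])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    mu = na * nb / 2.0
    sigma2 = na * nb / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return u_obs, 1.0
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)
    return u_obs, float(2.0 * stats.norm.sf(max(z, 0.0)))


# -- cohort summaries -----------------------------------------------------

SNAPSHOT_VARS = ["pip", "peep", "dp", "crs", "mp", "pao2", "paco2", "co", "pf"]


def _snapshot_row(log: ExperimentLog, label: str) -> dict | None:
    for s in log.snapshots:
        if s.label == label:
            return {
                "arm": log.arm,
                "pig_id": log.pig_id,
                "instant": label,
                "pip": s.peep + s.dp,
                "peep": s.peep,
                "dp": s.dp,
                "crs": s.crs,
                "mp": s.mp,
                "pao2": s.bg.pao2,
                "paco2": s.bg.paco2,
                "co": s.co,
                "pf": s.bg.pf_ratio,
            }
    return None


def cohort_summary(logs: Sequence[ExperimentLog]) -> dict[str, pd.DataFrame]:
    """Group mean +/- SD tables at protocol instants and per phase hour.

    Returns ``{"instants": ..., "phases": ..., "tidy": ...}`` where tidy is
    one row per pig x instant x variable and the other two aggregate to
    mean and SD per arm.
    """
    if not logs:
        raise ValueError("no experiment logs supplied")
    rows = []
    for log in logs:
        for label in ("baseline", "post_lavage", "post_rm1", "post_rm2", "post_rm3"):
            row = _snapshot_row(log, label)
            if row is not None:
                rows.append(row)
    tidy = pd.DataFrame(rows)
    instants = (
        tidy.groupby(["arm", "instant"])[SNAPSHOT_VARS]
        .agg(["mean", "std"])
        .sort_index()
    )

    phase_rows = []
    for log in logs:
        for label, t0, t1 in log.phase_labels:
            for b in log.breaths:
                if t0 <= b.time_s < t1:
                    hour = int((b.time_s - t0) // 3600.0) + 1
                    phase_rows.append(
                        {
                            "arm": log.arm,
                            "pig_id": log.pig_id,
                            "phase": label,
                            "hour": hour,
                            "pip": b.pip,
                            "peep": b.peep,
                            "dp": b.dp,
                            "vt_per_kg": np.nan,  # filled by caller if BW known
                            "vt_ml": b.vt_ml,
                            "rr": b.rr,
                            "mp": b.mp,
                            "crs": b.crs_dyn,
                            "pao2": b.pao2,
                            "paco2": b.paco2,
                            "co": b.co,
                        }
                    )
    phases = pd.DataFrame(phase_rows)
    if not phases.empty:
        per_pig = phases.groupby(["arm", "phase", "hour", "pig_id"]).mean(numeric_only=True)
        phases = per_pig.groupby(["arm", "phase", "hour"]).agg(["mean", "std"])
    return {"instants": instants, "phases": phases, "tidy": tidy}
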