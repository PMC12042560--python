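"""Longitudinal responsiveness: per-region change vectors and the
standardised response mean (SRM) with percentile-bootstrap confidence
intervals.

The SRM is mean(change) / SD(change) with the sample SD (n-1
denominator).  Change is follow-up minus baseline, so cartilage loss
drives mean thickness change negative and area-percentage / score change
positive.  Reader-score change honours the within-grade ±0.5 codes via
:func:`qmoaks.scoring.moaks_numeric_change`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ValidationError
from .scoring import moaks_numeric_change

#: Measures understood by :func:`paired_change` / :func:`responsiveness_table`.
SCORE_MEASURES = ("ThMCM", "dMCM")
QUANT_MEASURES = {"ThQCM%": "thqcm_pct", "dQCM%": "dqcm_pct", "ThCtAB": "thctab_mm"}
ALL_MEASURES = SCORE_MEASURES + tuple(QUANT_MEASURES)


@dataclass(frozen=True)
class ChangeVector:
    """Complete-case change scores for one region/measure/interval."""

    region: str
    measure: str
    interval: tuple[int, int]
    deltas: np.ndarray
    n_dropped: int = 0

    def __post_init__(self) -> None:
        deltas = np.asarray(self.deltas, dtype=float)
        if deltas.ndim != 1:
            raise ValidationError("deltas must be a 1-D vector")
        object.__setattr__(self, "deltas", deltas)

    @property
    def n(self) -> int:
        return len(self.deltas)


@dataclass(frozen=True)
class SrmResult:
    mean_change: float
    sd_change: float
    srm: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n: int = 0
    n_boot: int = 0
    seed: int | None = None


def paired_change(
    results: pd.DataFrame,
    moaks: pd.DataFrame,
    measure: str,
    region: str,
    interval: tuple[int, int],
    *,
    chained_within_grade: bool = False,
    drop_improvements: bool = False,
) -> ChangeVector:
    """Follow-up minus baseline change, complete cases only.

    Quantitative measures (``ThQCM%``, ``dQCM%``, ``ThCtAB``) difference
    the relevant column of the results table.  Reader-score measures
    (``ThMCM``, ``dMCM``) resolve within-grade codes; with
    ``chained_within_grade`` the change over a multi-visit interval is
    accumulated step by step through the intermediate visits instead of
    read directly off the final record.  ``drop_improvements`` removes
    -0.5 within-grade improvements before differencing.
    """
    base_month, follow_month = interval
    if follow_month <= base_month:
        raise ValidationError(f"interval must go forward in time, got {interval}")
    if measure in QUANT_MEASURES:
        column = QUANT_MEASURES[measure]
        sub = results[results["region"] == region]
        base = sub[sub["visit_month"] == base_month].set_index("knee_id")[column]
        follow = sub[sub["visit_month"] == follow_month].set_index("knee_id")[column]
        common = base.index.intersection(follow.index)
        deltas = (follow.loc[common] - base.loc[common]).to_numpy(dtype=float)
        dropped = len(base.index.union(follow.index)) - len(common)
    elif measure in SCORE_MEASURES:
        sub = moaks[(moaks["region"] == region) & (moaks["measure"] == measure)]
        per_visit = {
            month: group.set_index("knee_id")["score"]
            for month, group in sub.groupby("visit_month")
        }
        if base_month not in per_visit or follow_month not in per_visit:
            raise DegenerateDataError(
                f"no records at months {interval} for {region}/{measure}"
            )
        base = per_visit[base_month]
        follow = per_visit[follow_month]
        if chained_within_grade:
            steps = sorted(m for m in per_visit if base_month < m <= follow_month)
            common = base.index
            for month in steps:
                common = common.intersection(per_visit[month].index)
            deltas_list = []
            for knee in common:
                total, prev = 0.0, float(base.loc[knee])
                for month in steps:
                    record = float(per_visit[month].loc[knee])
                    total += moaks_numeric_change(prev, record)
                    if record not in (0.5, -0.5):
                        prev = record
                deltas_list.append(total)
            deltas = np.asarray(deltas_list)
            dropped = len(base.index.union(per_visit[follow_month].index)) - len(common)
        else:
            common = base.index.intersection(follow.index)
            deltas = np.asarray(
                [
                    moaks_numeric_change(float(base.loc[k]), float(follow.loc[k]))
                    for k in common
                ]
            )
            dropped = len(base.index.union(follow.index)) - len(common)
        if drop_improvements:
            deltas = deltas[deltas != -0.5]
    else:
        raise ValidationError(
            f"unknown measure {measure!r}; valid measures are {ALL_MEASURES}"
        )
    if len(deltas) == 0:
        raise DegenerateDataError(f"no complete cases for {region}/{measure} {interval}")
    return ChangeVector(
        region=region, measure=measure, interval=interval, deltas=deltas, n_dropped=dropped
    )


def srm(changes: ChangeVector) -> SrmResult:
    """SRM point estimate: mean / sample SD of the change vector."""
    if changes.n < 2:
        raise ValidationError(f"need >= 2 changes, got {changes.n}")
    mean = float(np.mean(changes.deltas))
    sd = float(np.std(changes.deltas, ddof=1))
    if sd == 0:
        raise DegenerateDataError("SRM undefined: zero SD of change")
    return SrmResult(mean_change=mean, sd_change=sd, srm=mean / sd, n=changes.n)


def bootstrap_srm_ci(
    changes: ChangeVector, n_boot: int = 1000, seed: int = 0
) -> tuple[float, float, int]:
    """Percentile 95% bootstrap CI for the SRM.

    Resamples knees with replacement ``n_boot`` times; resamples with
    zero SD are skipped and their count returned.  Deterministic for a
    fixed seed.
    """
    if changes.n < 2:
        raise ValidationError(f"need >= 2 changes, got {changes.n}")
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, changes.n, size=(n_boot, changes.n))
    samples = changes.deltas[idx]
    means = samples.mean(axis=1)
    sds = samples.std(axis=1, ddof=1)
    valid = sds > 0
    n_skipped = int(n_boot - valid.sum())
    if not valid.any():
        raise DegenerateDataError("all bootstrap resamples degenerate (zero SD)")
    srms = means[valid] / sds[valid]
    lo, hi = np.percentile(srms, [2.5, 97.5])
    return float(lo), float(hi), n_skipped


def srm_with_ci(
    changes: ChangeVector, n_boot: int = 1000, seed: int = 0
) -> SrmResult:
    point = srm(changes)
    lo, hi, _ = bootstrap_srm_ci(changes, n_boot=n_boot, seed=seed)
    return SrmResult(
        mean_change=point.mean_change,
        sd_change=point.sd_change,
        srm=point.srm,
        ci_low=lo,
        ci_high=hi,
        n=changes.n,
        n_boot=n_boot,
        seed=seed,
    )


def responsiveness_table(
    results: pd.DataFrame,
    moaks: pd.DataFrame,
    regions: Sequence[str],
    intervals: Sequence[tuple[int, int]] = ((0, 12), (0, 24)),
    *,
    measures: Sequence[str] = ALL_MEASURES,
    n_boot: int = 1000,
    seed: int = 0,
    chained_within_grade: bool = False,
) -> pd.DataFrame:
    """SRM (with bootstrap CI) per (region, measure, interval).

    Cells whose SRM is undefined (zero variance, missing records) are
    kept as NaN rows with ``undefined=True`` so report renderers can
    print "n/a" rather than dropping the cell.
    """
    rows = []
    for region in regions:
        for measure in measures:
            for interval in intervals:
                row = {
                    "region": region,
                    "measure": measure,
                    "baseline_month": interval[0],
                    "followup_month": interval[1],
                }
                try:
                    changes = paired_change(
                        results,
                        moaks,
                        measure,
                        region,
                        interval,
                        chained_within_grade=chained_within_grade,
                    )
                    result = srm_with_ci(changes, n_boot=n_boot, seed=seed)
                    row.update(
                        mean_change=result.mean_change,
                        sd_change=result.sd_change,
                        srm=result.srm,
                        ci_low=result.ci_low,
                        ci_high=result.ci_high,
                        n=result.n,
                        undefined=False,
                    )
                except DegenerateDataError:
                    row.update(
                        mean_change=np.nan,
                        sd_change=np.nan,
                        srm=np.nan,
                        ci_low=np.nan,
                        ci_high=np.nan,
                        n=0,
                        undefined=True,
                    )
                rows.append(row)
    return pd.DataFrame(rows)
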