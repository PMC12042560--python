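"""Cross-sectional agreement between ordinal reader scores and banded
quantitative scores: 4x4 cross-tabulations, row-wise concordance
proportions, tie-corrected Spearman correlation with Fisher-z confidence
intervals, and tidy boxplot-data export.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DegenerateDataError, ValidationError

_SCORES = (0, 1, 2, 3)

#: Band-edge reference values exported with boxplot data.
BAND_THRESHOLDS = (0.0, 10.0, 75.0)


@dataclass(frozen=True)
class CrossTab:
    """4x4 contingency table; rows = reader score, cols = banded score."""

    counts: np.ndarray
    region: str | None = None
    measure: str | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (4, 4):
            raise ValidationError("cross-tabulation must be 4x4")
        if np.any(counts < 0):
            raise ValidationError("cross-tabulation counts must be >= 0")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def expand(self) -> tuple[np.ndarray, np.ndarray]:
        """Expand counts back into paired score vectors (row-major order)."""
        rows, cols = [], []
        for i in _SCORES:
            for j in _SCORES:
                k = int(self.counts[i, j])
                rows.extend([i] * k)
                cols.extend([j] * k)
        return np.asarray(rows, dtype=float), np.asarray(cols, dtype=float)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    ci_low: float
    ci_high: float
    n: int


def crosstab(
    pairs: Iterable[tuple[float, float]],
    region: str | None = None,
    measure: str | None = None,
) -> CrossTab:
    """Tabulate paired whole-grade scores into a 4x4 table.

    Within-grade ±0.5 codes are change markers, not states, and are
    rejected here.
    """
    counts = np.zeros((4, 4), dtype=np.int64)
    for x, y in pairs:
        xi, yi = float(x), float(y)
        if xi not in (0.0, 1.0, 2.0, 3.0) or yi not in (0.0, 1.0, 2.0, 3.0):
            raise ValidationError(
                f"cross-sectional scores must be whole grades 0-3, got ({x}, {y})"
            )
        counts[int(xi), int(yi)] += 1
    return CrossTab(counts=counts, region=region, measure=measure)


def row_concordance(tab: CrossTab, row: int, col: int) -> float:
    """Proportion of row-``row`` knees landing in column ``col``."""
    if row not in _SCORES or col not in _SCORES:
        raise ValidationError("row and col must be scores 0-3")
    total = int(tab.row_totals[row])
    if total == 0:
        raise DegenerateDataError(f"row {row} has zero total")
    return tab.counts[row, col] / total


def spearman_midrank(
    x: Sequence[float] | CrossTab, y: Sequence[float] | None = None
) -> float:
    """Tie-corrected Spearman rho: Pearson correlation of midranks.

    Accepts either two equal-length score vectors or a single
    :class:`CrossTab` (expanded to pairs internally).
    """
    if isinstance(x, CrossTab):
        if y is not None:
            raise ValidationError("pass either a CrossTab or two vectors, not both")
        xv, yv = x.expand()
    else:
        xv = np.asarray(x, dtype=float)
        yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValidationError("inputs must be equal-length 1-D vectors")
    if len(xv) < 3:
        raise ValidationError(f"need at least 3 pairs, got {len(xv)}")
    rx, ry = rankdata(xv), rankdata(yv)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise DegenerateDataError("correlation undefined: zero variance in a margin")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


def spearman_ci(rho: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval: tanh(atanh(rho) ± z*/sqrt(n-3))."""
    if n < 4:
        raise ValidationError(f"need n >= 4 for a Fisher-z interval, got {n}")
    if not -1 < rho < 1:
        raise ValidationError(f"rho must lie strictly inside (-1, 1), got {rho}")
    from scipy.stats import norm

    zcrit = norm.ppf(0.5 + level / 2)
    z = np.arctanh(rho)
    half = zcrit / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def correlate(tab: CrossTab, level: float = 0.95) -> CorrelationResult:
    """Midrank Spearman with Fisher-z CI for one cross-tabulation."""
    rho = spearman_midrank(tab)
    lo, hi = spearman_ci(rho, tab.n, level)
    return CorrelationResult(rho=rho, ci_low=lo, ci_high=hi, n=tab.n)


def pair_scores(
    results: pd.DataFrame,
    moaks: pd.DataFrame,
    region: str,
    measure: str,
    visit_month: int = 0,
) -> pd.DataFrame:
    """Join reader scores with banded quantitative scores for one region.

    ``measure`` selects ThMCM vs dMCM on the reader side and the matching
    banded score column on the quantitative side.  Knees present on only
    one side raise, naming the offending ids.
    """
    if measure not in ("ThMCM", "dMCM"):
        raise ValidationError(f"unknown measure {measure!r}")
    score_col = "thqcm_score" if measure == "ThMCM" else "dqcm_score"
    pct_col = "thqcm_pct" if measure == "ThMCM" else "dqcm_pct"
    left = moaks[
        (moaks["region"] == region)
        & (moaks["measure"] == measure)
        & (moaks["visit_month"] == visit_month)
    ][["knee_id", "score"]]
    right = results[
        (results["region"] == region) & (results["visit_month"] == visit_month)
    ][["knee_id", score_col, pct_col]]
    merged = left.merge(right, on="knee_id", how="outer", indicator=True)
    bad = merged[merged["_merge"] != "both"]["knee_id"].tolist()
    if bad:
        raise ValidationError(f"unmatched knees in join for {region}/{measure}: {bad[:5]}")
    out = merged.drop(columns="_merge").rename(
        columns={"score": "moaks_score", score_col: "qmoaks_score", pct_col: "qmoaks_pct"}
    )
    return out.sort_values("knee_id").reset_index(drop=True)


def boxplot_export(
    results: pd.DataFrame,
    moaks: pd.DataFrame,
    region: str,
    measure: str,
    visit_month: int = 0,
) -> pd.DataFrame:
    """Tidy (moaks_score, qmoaks_pct) rows plus band-threshold columns."""
    paired = pair_scores(results, moaks, region, measure, visit_month)
    out = paired[["knee_id", "moaks_score", "qmoaks_pct"]].copy()
    out["region"] = region
    out["measure"] = measure
    for name, value in zip(("band_none", "band_low", "band_high"), BAND_THRESHOLDS):
        out[name] = value
    return out


def concordance_tables(
    results: pd.DataFrame,
    moaks: pd.DataFrame,
    regions: Sequence[str],
    visit_month: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-tabulations and correlations for every (region, measure).

    Returns a long crosstab table (one row per cell) and a correlation
    table; degenerate margins yield NaN correlation with an ``undefined``
    flag rather than an error, mirroring printed "n/a" cells.
    """
    ct_rows, corr_rows = [], []
    for region in regions:
        for measure in ("ThMCM", "dMCM"):
            paired = pair_scores(results, moaks, region, measure, visit_month)
            tab = crosstab(
                zip(paired["moaks_score"], paired["qmoaks_score"]), region, measure
            )
            for i in _SCORES:
                for j in _SCORES:
                    ct_rows.append(
                        {
                            "region": region,
                            "measure": measure,
                            "moaks_score": i,
                            "qmoaks_score": j,
                            "count": int(tab.counts[i, j]),
                        }
                    )
            try:
                corr = correlate(tab)
                corr_rows.append(
                    {
                        "region": region,
                        "measure": measure,
                        "rho": corr.rho,
                        "ci_low": corr.ci_low,
                        "ci_high": corr.ci_high,
                        "n": corr.n,
                        "undefined": False,
                    }
                )
            except (DegenerateDataError, ValidationError):
                corr_rows.append(
                    {
                        "region": region,
                        "measure": measure,
                        "rho": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "n": tab.n,
                        "undefined": True,
                    }
                )
    return pd.DataFrame(ct_rows), pd.DataFrame(corr_rows)


def round_half_up_percent(proportion: float) -> int:
    """Round a proportion to the nearest integer percent, half away from zero."""
    from decimal import Decimal, ROUND_HALF_UP

    return int(
        Decimal(repr(float(proportion) * 100)).quantize(
            Decimal("1"), rounding=ROUND_HALF_UP
        )
    )
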