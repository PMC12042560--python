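"""Per-subregion quantitative area scores and regional mean thickness.

For each knee/visit/region this module computes:

* ``thqcm_pct`` — percentage of included region area where thickness is
  strictly below the loss threshold (thinned or denuded);
* ``dqcm_pct`` — percentage strictly below the denudation threshold;
* ``thqcm_score`` / ``dqcm_score`` — those percentages banded onto the
  ordinal 0-3 scale (0: none, 1: 0-10%, 2: 10-75%, 3: >75%);
* ``thctab_mm`` — area-weighted mean thickness over the whole region
  (unmasked by default; ``masked=True`` restricts to included landmarks).

All threshold comparisons use strict ``<``.  Band boundaries are
left-open/right-closed, with score 0 reserved for exactly 0%.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .atlas import (
    MEASURES,
    MoaksRecord,
    RegionAtlas,
    ThicknessMap,
    VALID_BASELINE_SCORES,
    VALID_FOLLOWUP_SCORES,
)
from .errors import ValidationError
from .normative import NormativeModel

NORMAL, THINNED, DENUDED = "normal", "thinned", "denuded"

#: Upper band edges: (0, 10] -> 1, (10, 75] -> 2, (75, 100] -> 3.
BAND_EDGES = (10.0, 75.0)

RESULT_COLUMNS = (
    "knee_id",
    "visit_month",
    "region",
    "thqcm_pct",
    "dqcm_pct",
    "thqcm_score",
    "dqcm_score",
    "thctab_mm",
)


def classify_landmark(
    thickness_mm: float, model: NormativeModel, atlas: RegionAtlas, landmark_id: int
) -> str:
    """Classify one landmark as normal / thinned / denuded.

    Denuded whenever thickness < denudation threshold, else thinned when
    thickness < loss threshold (strict inequalities).  Raises on excluded
    landmarks — callers must apply the inclusion mask first.
    """
    pos = atlas.position(landmark_id)
    if not model.included[pos]:
        raise ValidationError(
            f"landmark {landmark_id} is excluded (normative mean below "
            f"{model.min_normative_mm} mm); mask before classifying"
        )
    if thickness_mm < model.denudation_threshold[pos]:
        return DENUDED
    if thickness_mm < model.loss_threshold[pos]:
        return THINNED
    return NORMAL


def region_percents(
    tmap: ThicknessMap,
    atlas: RegionAtlas,
    model: NormativeModel,
    region: str,
) -> tuple[float, float]:
    """Area percentages of loss and denudation over one subregion.

    Percent = 100 x (sum of area weights of affected included landmarks)
    / (sum of area weights of included landmarks).  Denuded landmarks
    count toward both percentages.
    """
    mask = atlas.region_mask(region) & model.included
    if not mask.any():
        raise ValidationError(f"region {region} has no normative cartilage cover")
    weights = atlas.area_weights[mask]
    total = weights.sum()
    if total <= 0:
        raise ValidationError(f"region {region}: total area weight is zero")
    thickness = tmap.thickness[mask]
    lost = thickness < model.loss_threshold[mask]
    denuded = thickness < model.denudation_threshold[mask]
    # guard against float round-off pushing a full-cover ratio past 1
    thqcm_pct = min(100.0 * weights[lost].sum() / total, 100.0)
    dqcm_pct = min(100.0 * weights[denuded].sum() / total, 100.0)
    return float(thqcm_pct), float(dqcm_pct)


def band(pct: float) -> int:
    """Band an area percentage onto the ordinal 0-3 scale.

    0 iff pct == 0; 1 iff 0 < pct <= 10; 2 iff 10 < pct <= 75; 3 iff
    pct > 75.  Out-of-range input is rejected.
    """
    if not np.isfinite(pct) or pct < 0 or pct > 100:
        raise ValidationError(f"percentage {pct} outside [0, 100]")
    if pct == 0:
        return 0
    if pct <= BAND_EDGES[0]:
        return 1
    if pct <= BAND_EDGES[1]:
        return 2
    return 3


def thctab(
    tmap: ThicknessMap,
    atlas: RegionAtlas,
    region: str,
    model: NormativeModel | None = None,
    *,
    masked: bool = False,
) -> float:
    """Area-weighted mean thickness (mm) over a subregion.

    By default all region landmarks contribute; with ``masked=True`` the
    model's inclusion mask is applied first (sensitivity-analysis mode).
    """
    mask = atlas.region_mask(region)
    if masked:
        if model is None:
            raise ValidationError("masked thctab requires a normative model")
        mask = mask & model.included
    if not mask.any():
        raise ValidationError(f"region {region} is empty")
    weights = atlas.area_weights[mask]
    total = weights.sum()
    if total <= 0:
        raise ValidationError(f"region {region}: total area weight is zero")
    return float(np.sum(weights * tmap.thickness[mask]) / total)


def score_map(
    tmap: ThicknessMap, atlas: RegionAtlas, model: NormativeModel
) -> list[dict]:
    """All per-region results for one thickness map, in canonical order."""
    rows = []
    for region in atlas.present_regions:
        th_pct, d_pct = region_percents(tmap, atlas, model, region)
        rows.append(
            {
                "knee_id": tmap.knee_id,
                "visit_month": tmap.visit_month,
                "region": region,
                "thqcm_pct": th_pct,
                "dqcm_pct": d_pct,
                "thqcm_score": band(th_pct),
                "dqcm_score": band(d_pct),
                "thctab_mm": thctab(tmap, atlas, region),
            }
        )
    return rows


def score_cohort(
    maps: Iterable[ThicknessMap], atlas: RegionAtlas, model: NormativeModel
) -> pd.DataFrame:
    """Score a whole cohort: one row per (knee, visit, region).

    Rows are ordered by (knee_id, visit_month, canonical region order).
    """
    rows: list[dict] = []
    for tmap in sorted(maps, key=lambda m: (m.knee_id, m.visit_month)):
        if len(tmap.thickness) != atlas.n_landmarks:
            raise ValidationError(
                f"knee {tmap.knee_id}: map length does not match atlas"
            )
        rows.extend(score_map(tmap, atlas, model))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def moaks_numeric_change(prev_score: float, followup_record: float) -> float:
    """Signed score change between visits, honouring within-grade codes.

    A follow-up record of 0-3 yields the whole-grade difference; the
    special codes +0.5 / -0.5 stand for within-grade worsening /
    improvement and are returned as-is.
    """
    if float(prev_score) not in VALID_BASELINE_SCORES:
        raise ValidationError(f"invalid previous score {prev_score}")
    followup = float(followup_record)
    if followup not in VALID_FOLLOWUP_SCORES:
        raise ValidationError(f"invalid follow-up record {followup_record}")
    if followup in (0.5, -0.5):
        return followup
    return followup - float(prev_score)
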