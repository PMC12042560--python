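"""Landmark-indexed surface domain: subregions, atlases and table I/O.

The knee tibiofemoral cartilage plate is represented as a flat list of
corresponded bone-surface landmarks, each assigned to exactly one of the
ten tibiofemoral subregions (four femoral, six tibial).  All geometry is
assumed resolved upstream; correspondence is purely by shared landmark id.

Three CSV formats are defined here and used everywhere else:

* atlas:      ``landmark_id,region[,area_weight]``
* thickness:  ``knee_id,visit_month,landmark_id,thickness_mm`` (long format)
* scores:     ``knee_id,visit_month,region,measure,score``
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: The ten tibiofemoral subregion codes: central/posterior femur and
#: anterior/central/posterior tibia, each medial and lateral.  The anterior
#: femur is excluded by construction.
REGION_CODES: tuple[str, ...] = (
    "cMF", "cLF", "pMF", "pLF",
    "aMT", "cMT", "pMT", "aLT", "cLT", "pLT",
)

#: Ordinal score measures: any-thickness loss area and denudation area.
MEASURES: tuple[str, ...] = ("ThMCM", "dMCM")

#: Whole-grade ordinal scores.
VALID_BASELINE_SCORES = frozenset({0.0, 1.0, 2.0, 3.0})
#: Follow-up additionally allows the within-grade change codes.
VALID_FOLLOWUP_SCORES = frozenset({0.0, 1.0, 2.0, 3.0, 0.5, -0.5})

#: Default visit schedule in months.
DEFAULT_VISITS: tuple[int, ...] = (0, 12, 24)

#: Numeric precision (decimal places) at which table round-trips are exact.
TABLE_PRECISION = 6


def region_bone(code: str) -> str:
    """Return ``'femur'`` or ``'tibia'`` for a subregion code."""
    _check_region(code)
    return "femur" if code.endswith("F") else "tibia"


def region_side(code: str) -> str:
    """Return ``'medial'`` or ``'lateral'`` for a subregion code."""
    _check_region(code)
    return "medial" if code[1] == "M" else "lateral"


def _check_region(code: str) -> None:
    if code not in REGION_CODES:
        raise ValidationError(
            f"unknown region code {code!r}; valid codes are {', '.join(REGION_CODES)}"
        )


@dataclass(frozen=True)
class RegionAtlas:
    """Assignment of every landmark to one subregion, with area weights.

    Parameters
    ----------
    landmark_ids
        Unique integer landmark ids, in file order.
    regions
        Subregion code per landmark (same length as ``landmark_ids``).
    area_weights
        Nonnegative dimensionless area weight per landmark (default 1).
    """

    landmark_ids: np.ndarray
    regions: np.ndarray
    area_weights: np.ndarray
    _index: dict[int, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        ids = np.asarray(self.landmark_ids, dtype=np.int64)
        regions = np.asarray(self.regions, dtype=object)
        weights = np.asarray(self.area_weights, dtype=float)
        if not (len(ids) == len(regions) == len(weights)):
            raise ValidationError("atlas column lengths differ")
        if len(ids) == 0:
            raise ValidationError("atlas is empty")
        if len(np.unique(ids)) != len(ids):
            dupes = ids[pd.Index(ids).duplicated()]
            raise ValidationError(f"duplicate landmark ids: {sorted(set(dupes.tolist()))}")
        for row, code in enumerate(regions):
            if code not in REGION_CODES:
                raise ValidationError(
                    f"row {row}: unknown region code {code!r}; "
                    f"valid codes are {', '.join(REGION_CODES)}"
                )
        if not np.all(np.isfinite(weights)) or np.any(weights < 0):
            raise ValidationError("area weights must be finite and nonnegative")
        object.__setattr__(self, "landmark_ids", ids)
        object.__setattr__(self, "regions", regions)
        object.__setattr__(self, "area_weights", weights)
        object.__setattr__(self, "_index", {int(l): i for i, l in enumerate(ids)})

    @property
    def n_landmarks(self) -> int:
        return len(self.landmark_ids)

    @property
    def present_regions(self) -> tuple[str, ...]:
        """Region codes present in this atlas, in canonical order."""
        present = set(self.regions.tolist())
        return tuple(c for c in REGION_CODES if c in present)

    def position(self, landmark_id: int) -> int:
        """Array position of a landmark id; raises on unknown ids."""
        try:
            return self._index[int(landmark_id)]
        except KeyError:
            raise ValidationError(f"unknown landmark id {landmark_id}") from None

    def region_mask(self, region: str) -> np.ndarray:
        """Boolean mask over landmark positions for one subregion."""
        _check_region(region)
        return self.regions == region

    def region_sizes(self) -> dict[str, int]:
        return {c: int(np.sum(self.regions == c)) for c in self.present_regions}


@dataclass(frozen=True)
class ThicknessMap:
    """One knee-visit's per-landmark cartilage thickness vector (mm)."""

    knee_id: str
    visit_month: int
    thickness: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.thickness, dtype=float)
        if values.ndim != 1:
            raise ValidationError("thickness must be a 1-D vector")
        if not np.all(np.isfinite(values)):
            raise ValidationError(
                f"knee {self.knee_id} visit {self.visit_month}: non-finite thickness"
            )
        if np.any(values < 0):
            raise ValidationError(
                f"knee {self.knee_id} visit {self.visit_month}: negative thickness"
            )
        object.__setattr__(self, "thickness", values)


@dataclass(frozen=True)
class MoaksRecord:
    """One semi-quantitative ordinal score for a knee/visit/region.

    ``score`` is 0-3 at baseline; at follow-up it may additionally be
    +0.5 / -0.5, recording within-grade worsening / improvement relative
    to the previous visit without a whole-grade transition.
    """

    knee_id: str
    visit_month: int
    region: str
    measure: str
    score: float
    baseline_month: int = 0

    def __post_init__(self) -> None:
        _check_region(self.region)
        if self.measure not in MEASURES:
            raise ValidationError(
                f"unknown measure {self.measure!r}; valid measures are {MEASURES}"
            )
        score = float(self.score)
        if self.visit_month <= self.baseline_month:
            if score not in VALID_BASELINE_SCORES:
                if score in {0.5, -0.5}:
                    raise ValidationError(
                        f"knee {self.knee_id} {self.region} {self.measure}: "
                        "within-grade value at baseline"
                    )
                raise ValidationError(
                    f"knee {self.knee_id} {self.region} {self.measure}: "
                    f"invalid baseline score {score}"
                )
        elif score not in VALID_FOLLOWUP_SCORES:
            raise ValidationError(
                f"knee {self.knee_id} visit {self.visit_month} {self.region} "
                f"{self.measure}: invalid score {score}"
            )
        object.__setattr__(self, "score", score)

    @property
    def is_within_grade(self) -> bool:
        return self.score in (0.5, -0.5)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def load_atlas(path: str | Path) -> RegionAtlas:
    """Load a region atlas from CSV.

    Expects header columns ``landmark_id,region`` and optional
    ``area_weight`` (missing values default to 1).
    """
    frame = _read_csv(path, required={"landmark_id", "region"})
    if "area_weight" in frame.columns:
        weights = frame["area_weight"].fillna(1.0).to_numpy(dtype=float)
    else:
        weights = np.ones(len(frame))
    return RegionAtlas(
        landmark_ids=frame["landmark_id"].to_numpy(dtype=np.int64),
        regions=frame["region"].to_numpy(dtype=object),
        area_weights=weights,
    )


def write_atlas(atlas: RegionAtlas, path: str | Path) -> None:
    pd.DataFrame(
        {
            "landmark_id": atlas.landmark_ids,
            "region": atlas.regions,
            "area_weight": atlas.area_weights,
        }
    ).to_csv(path, index=False, float_format=f"%.{TABLE_PRECISION}f")


def load_thickness_table(path: str | Path, atlas: RegionAtlas) -> list[ThicknessMap]:
    """Load long-format thickness CSV into one map per (knee, visit).

    Every (knee, visit) group must cover all atlas landmarks exactly once.
    Maps are returned sorted by ``(knee_id, visit_month)``.
    """
    frame = _read_csv(
        path, required={"knee_id", "visit_month", "landmark_id", "thickness_mm"}
    )
    frame["knee_id"] = frame["knee_id"].astype(str)
    maps: list[ThicknessMap] = []
    expected = set(atlas.landmark_ids.tolist())
    for (knee, visit), group in frame.groupby(["knee_id", "visit_month"], sort=True):
        seen = set(group["landmark_id"].astype(int).tolist())
        missing = expected - seen
        if missing:
            raise ValidationError(
                f"knee {knee} visit {visit}: missing landmarks {sorted(missing)[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        extra = seen - expected
        if extra:
            raise ValidationError(
                f"knee {knee} visit {visit}: landmarks not in atlas {sorted(extra)[:5]}"
            )
        if len(group) != atlas.n_landmarks:
            raise ValidationError(f"knee {knee} visit {visit}: duplicate landmark rows")
        values = np.empty(atlas.n_landmarks, dtype=float)
        positions = [atlas.position(l) for l in group["landmark_id"].astype(int)]
        values[positions] = group["thickness_mm"].to_numpy(dtype=float)
        maps.append(ThicknessMap(knee_id=str(knee), visit_month=int(visit), thickness=values))
    return maps


def write_thickness_table(
    maps: Iterable[ThicknessMap], atlas: RegionAtlas, path: str | Path
) -> None:
    rows = []
    for tmap in sorted(maps, key=lambda m: (m.knee_id, m.visit_month)):
        rows.append(
            pd.DataFrame(
                {
                    "knee_id": tmap.knee_id,
                    "visit_month": tmap.visit_month,
                    "landmark_id": atlas.landmark_ids,
                    "thickness_mm": np.round(tmap.thickness, TABLE_PRECISION),
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(
        path, index=False, float_format=f"%.{TABLE_PRECISION}f"
    )


def load_moaks_table(path: str | Path, baseline_month: int = 0) -> list[MoaksRecord]:
    """Load and validate semi-quantitative score records from CSV.

    Within-grade codes (±0.5) are accepted only at visits after
    ``baseline_month``.  Records are returned sorted by
    (knee, visit, region, measure).
    """
    frame = _read_csv(
        path, required={"knee_id", "visit_month", "region", "measure", "score"}
    )
    records = [
        MoaksRecord(
            knee_id=str(row.knee_id),
            visit_month=int(row.visit_month),
            region=str(row.region),
            measure=str(row.measure),
            score=float(row.score),
            baseline_month=baseline_month,
        )
        for row in frame.itertuples()
    ]
    records.sort(key=lambda r: (r.knee_id, r.visit_month, r.region, r.measure))
    return records


def write_moaks_table(records: Iterable[MoaksRecord], path: str | Path) -> None:
    rows = sorted(records, key=lambda r: (r.knee_id, r.visit_month, r.region, r.measure))
    pd.DataFrame(
        {
            "knee_id": [r.knee_id for r in rows],
            "visit_month": [r.visit_month for r in rows],
            "region": [r.region for r in rows],
            "measure": [r.measure for r in rows],
            "score": [r.score for r in rows],
        }
    ).to_csv(path, index=False)


def _read_csv(path: str | Path, required: set[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    frame = pd.read_csv(path)
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing required columns {sorted(missing)}")
    return frame
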