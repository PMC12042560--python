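"""Synthetic control and progressing cohorts with exact ground truth.

Nothing here tries to be anatomically realistic.  The aim is a generative
model with the statistical structure the downstream analysis assumes:

* a smooth positive per-landmark normative thickness field, laid out on a
  u x v parameter grid within each subregion;
* control knees = field x per-subject multiplicative scale (log-normal)
  + i.i.d. Gaussian measurement noise, clamped at zero;
* progressor knees additionally carry focal lesions: radial discs with a
  cosine depth taper that deepen and/or widen across visits;
* an optional simulated ordinal reader with a confusion matrix
  (optionally biased toward overcalling higher bands) and a within-grade
  change sensitivity.

Ground truth per knee/visit/region is obtained by scoring the noise-free
maps with the same threshold contract as :mod:`qmoaks.scoring`, so the
generator and the scorer agree by construction.

Randomness: every knee draws from its own substream spawned from
``(seed, namespace, knee_index)``, so changing the cohort size never
reshuffles earlier knees.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import MoaksRecord, RegionAtlas, ThicknessMap, REGION_CODES
from .errors import ValidationError
from .normative import NormativeModel
from .scoring import band, score_cohort

_CONTROL_NS, _PROGRESSOR_NS, _READER_NS, _FIELD_NS = 0, 1, 2, 3

TRUTH_COLUMNS = (
    "knee_id",
    "visit_month",
    "region",
    "true_thqcm_pct",
    "true_dqcm_pct",
    "true_thctab_mm",
)


@dataclass(frozen=True)
class FieldParams:
    """Normative-field and measurement-noise parameters."""

    grid_shape: tuple[int, int] = (8, 8)
    base_mean: float = 2.2
    spatial_amplitude: float = 0.3
    subject_scale_sd: float = 0.10
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        u, v = self.grid_shape
        if u < 1 or v < 1:
            raise ValidationError("grid_shape dimensions must be >= 1")
        if self.base_mean <= 0:
            raise ValidationError("base_mean must be > 0")
        if self.spatial_amplitude < 0 or self.subject_scale_sd < 0 or self.noise_sd < 0:
            raise ValidationError("amplitude and SDs must be >= 0")
        if self.spatial_amplitude >= self.base_mean:
            raise ValidationError("spatial_amplitude must be < base_mean (positive field)")


@dataclass(frozen=True)
class LesionParams:
    """Focal-lesion geometry and growth.

    With the default ``cosine`` profile, depth at grid distance ``r``
    from the lesion center is ``depth * 0.5 * (1 + cos(pi * r / radius))``
    for ``r < radius`` and 0 beyond — a radially decreasing taper.  The
    ``flat`` profile removes the full depth over the whole disc (useful
    for constructing exact-area lesions).  ``radius_growth_per_year`` and
    ``depth_growth_per_year`` select wider-only, deeper-only, or mixed
    growth modes.  ``center`` fixes the lesion center in grid units;
    ``None`` samples it uniformly over the region grid.
    """

    region_probs: Mapping[str, float] = dc_field(
        default_factory=lambda: {"cMF": 0.5, "cMT": 0.5}
    )
    center: tuple[float, float] | None = None
    initial_radius: float = 2.5
    initial_depth_fraction: float = 0.5
    radius_growth_per_year: float = 0.5
    depth_growth_per_year: float = 0.2
    depth_profile: str = "cosine"
    lesions_per_knee: int = 1

    def __post_init__(self) -> None:
        if self.depth_profile not in ("cosine", "flat"):
            raise ValidationError("depth_profile must be 'cosine' or 'flat'")
        if self.initial_radius < 0 or self.radius_growth_per_year < 0:
            raise ValidationError("lesion radius and radius growth must be >= 0")
        if not 0 <= self.initial_depth_fraction <= 1:
            raise ValidationError("initial_depth_fraction must be in [0, 1]")
        if self.lesions_per_knee < 1:
            raise ValidationError("lesions_per_knee must be >= 1")
        probs = dict(self.region_probs)
        if not probs:
            raise ValidationError("region_probs must not be empty")
        for code, p in probs.items():
            if code not in REGION_CODES:
                raise ValidationError(f"unknown region code {code!r} in region_probs")
            if p < 0:
                raise ValidationError("region probabilities must be >= 0")
        if sum(probs.values()) <= 0:
            raise ValidationError("region probabilities must sum to > 0")

    def radius_at(self, years: float) -> float:
        return self.initial_radius + self.radius_growth_per_year * years

    def depth_at(self, years: float) -> float:
        return float(
            np.clip(self.initial_depth_fraction + self.depth_growth_per_year * years, 0.0, 1.0)
        )


@dataclass(frozen=True)
class ReaderParams:
    """Simulated ordinal reader: band confusion + within-grade sensitivity."""

    confusion: np.ndarray
    within_grade_sensitivity: float = 0.0

    def __post_init__(self) -> None:
        matrix = np.asarray(self.confusion, dtype=float)
        if matrix.shape != (4, 4):
            raise ValidationError("confusion matrix must be 4x4")
        if np.any(matrix < 0):
            raise ValidationError("confusion entries must be >= 0")
        if np.any(np.abs(matrix.sum(axis=1) - 1.0) > 1e-9):
            raise ValidationError("confusion rows must sum to 1 within 1e-9")
        if not 0 <= self.within_grade_sensitivity <= 1:
            raise ValidationError("within_grade_sensitivity must be in [0, 1]")
        object.__setattr__(self, "confusion", matrix)

    @classmethod
    def identity(cls, within_grade_sensitivity: float = 0.0) -> "ReaderParams":
        return cls(np.eye(4), within_grade_sensitivity)

    @classmethod
    def with_overcall(
        cls, overcall_bias: float, within_grade_sensitivity: float = 0.0
    ) -> "ReaderParams":
        """Identity reader that moves mass ``overcall_bias`` up one band."""
        if not 0 <= overcall_bias <= 1:
            raise ValidationError("overcall_bias must be in [0, 1]")
        matrix = (1 - overcall_bias) * np.eye(4)
        for true_band in range(4):
            matrix[true_band, min(true_band + 1, 3)] += overcall_bias
        return cls(matrix, within_grade_sensitivity)


def _knee_rng(seed: int, namespace: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, namespace, index)))


def make_grid_atlas(grid_shape: tuple[int, int] = (8, 8)) -> RegionAtlas:
    """Atlas with every subregion carrying a full u x v landmark grid."""
    u, v = grid_shape
    per_region = u * v
    n = per_region * len(REGION_CODES)
    regions = np.repeat(np.asarray(REGION_CODES, dtype=object), per_region)
    return RegionAtlas(
        landmark_ids=np.arange(n, dtype=np.int64),
        regions=regions,
        area_weights=np.ones(n),
    )


def _grid_coords(atlas: RegionAtlas, grid_shape: tuple[int, int]) -> dict[str, np.ndarray]:
    """Per-region (k, 2) array of grid coordinates, in landmark order."""
    u, v = grid_shape
    coords: dict[str, np.ndarray] = {}
    for region in atlas.present_regions:
        k = int(np.sum(atlas.regions == region))
        if k != u * v:
            raise ValidationError(
                f"region {region} has {k} landmarks, expected {u}x{v}={u * v} "
                "for grid-based generation"
            )
        idx = np.arange(k)
        coords[region] = np.column_stack([idx // v, idx % v]).astype(float)
    return coords


def make_mean_field(atlas: RegionAtlas, params: FieldParams, seed: int) -> np.ndarray:
    """Smooth positive normative field: one low-frequency wave per region.

    Values stay within ``base_mean ± spatial_amplitude`` by construction.
    """
    coords = _grid_coords(atlas, params.grid_shape)
    u, v = params.grid_shape
    rng = _knee_rng(seed, _FIELD_NS, 0)
    out = np.empty(atlas.n_landmarks)
    for region in atlas.present_regions:
        freq_u, freq_v = rng.uniform(0.5, 1.5, size=2)
        phase = rng.uniform(0, 2 * np.pi)
        xy = coords[region]
        x = xy[:, 0] / max(u - 1, 1)
        y = xy[:, 1] / max(v - 1, 1)
        wave = np.sin(2 * np.pi * (freq_u * x + freq_v * y) + phase)
        out[atlas.region_mask(region)] = params.base_mean + params.spatial_amplitude * wave
    return out


def generate_controls(
    n: int, atlas: RegionAtlas, params: FieldParams, seed: int
) -> tuple[list[ThicknessMap], np.ndarray]:
    """Baseline-only control knees drawn around the normative field.

    Returns the maps and the underlying truth field.
    """
    if n <= 0:
        raise ValidationError(f"cohort size must be >= 1, got {n}")
    field = make_mean_field(atlas, params, seed)
    maps = []
    for i in range(n):
        rng = _knee_rng(seed, _CONTROL_NS, i)
        scale = float(np.exp(rng.normal(0.0, params.subject_scale_sd)))
        noise = rng.normal(0.0, params.noise_sd, size=atlas.n_landmarks)
        values = np.clip(field * scale + noise, 0.0, None)
        maps.append(ThicknessMap(knee_id=f"ctrl{i:04d}", visit_month=0, thickness=values))
    return maps, field


@dataclass(frozen=True)
class ProgressionCohort:
    """Generated progressor maps plus exact ground truth."""

    maps: list[ThicknessMap]
    noise_free_maps: list[ThicknessMap]
    truth: pd.DataFrame
    truth_field: np.ndarray
    truth_model: NormativeModel


def generate_progression_cohort(
    n: int,
    atlas: RegionAtlas,
    field_params: FieldParams,
    lesion_params: LesionParams,
    visits: Sequence[int],
    seed: int,
    *,
    loss_fraction: float = 0.95,
    denudation_fraction: float = 0.05,
    min_normative_mm: float = 0.1,
) -> ProgressionCohort:
    """Progressor knees with growing focal lesions over the visit schedule.

    Each knee carries ``lesions_per_knee`` lesions with fixed centers;
    radius and depth advance with elapsed years.  The truth table holds
    the loss/denudation area fractions and mean thickness obtained by
    scoring the noise-free maps against the truth field with the given
    threshold contract.
    """
    if n <= 0:
        raise ValidationError(f"cohort size must be >= 1, got {n}")
    visits = list(visits)
    if not visits:
        raise ValidationError("visit list must not be empty")
    if sorted(visits) != visits or visits[0] != 0:
        raise ValidationError("visits must be sorted ascending and start at 0")

    field = make_mean_field(atlas, field_params, seed)
    coords = _grid_coords(atlas, field_params.grid_shape)
    u, v = field_params.grid_shape
    region_names = sorted(lesion_params.region_probs)
    probs = np.asarray([lesion_params.region_probs[r] for r in region_names], dtype=float)
    probs = probs / probs.sum()

    maps: list[ThicknessMap] = []
    clean: list[ThicknessMap] = []
    for i in range(n):
        rng = _knee_rng(seed, _PROGRESSOR_NS, i)
        knee_id = f"knee{i:04d}"
        scale = float(np.exp(rng.normal(0.0, field_params.subject_scale_sd)))
        subject_field = field * scale
        lesions = []
        for _ in range(lesion_params.lesions_per_knee):
            region = region_names[rng.choice(len(region_names), p=probs)]
            if lesion_params.center is not None:
                center = np.asarray(lesion_params.center, dtype=float)
            else:
                center = rng.uniform([0.0, 0.0], [u - 1.0, v - 1.0])
            lesions.append((region, center))
        for month in visits:
            years = month / 12.0
            radius = lesion_params.radius_at(years)
            depth = lesion_params.depth_at(years)
            removal = np.zeros(atlas.n_landmarks)
            for region, center in lesions:
                mask = atlas.region_mask(region)
                dist = np.linalg.norm(coords[region] - center, axis=1)
                if lesion_params.depth_profile == "flat":
                    taper = np.where(dist < radius, depth, 0.0)
                else:
                    taper = np.where(
                        dist < radius,
                        depth * 0.5 * (1 + np.cos(np.pi * dist / max(radius, 1e-12))),
                        0.0,
                    )
                removal[mask] = np.maximum(removal[mask], taper)
            noise_free = subject_field * (1.0 - removal)
            noise = rng.normal(0.0, field_params.noise_sd, size=atlas.n_landmarks)
            clean.append(
                ThicknessMap(knee_id=knee_id, visit_month=month, thickness=noise_free)
            )
            maps.append(
                ThicknessMap(
                    knee_id=knee_id,
                    visit_month=month,
                    thickness=np.clip(noise_free + noise, 0.0, None),
                )
            )

    truth_model = NormativeModel(
        normative_mean=field,
        n_controls=0,
        loss_fraction=loss_fraction,
        denudation_fraction=denudation_fraction,
        min_normative_mm=min_normative_mm,
    )
    scored = score_cohort(clean, atlas, truth_model)
    truth = scored.rename(
        columns={
            "thqcm_pct": "true_thqcm_pct",
            "dqcm_pct": "true_dqcm_pct",
            "thctab_mm": "true_thctab_mm",
        }
    )[list(TRUTH_COLUMNS)]
    return ProgressionCohort(
        maps=maps,
        noise_free_maps=clean,
        truth=truth,
        truth_field=field,
        truth_model=truth_model,
    )


def simulate_sq_reader(
    truth: pd.DataFrame, reader: ReaderParams, seed: int
) -> list[MoaksRecord]:
    """Sample ordinal reader scores from the ground-truth table.

    The true band is computed from the true area fraction and pushed
    through the confusion matrix.  At follow-up visits, when the true
    fraction rose but the true band did not, a +0.5 within-grade record
    is emitted with probability ``within_grade_sensitivity`` instead of
    the sampled band.
    """
    required = set(TRUTH_COLUMNS)
    if not required.issubset(truth.columns):
        raise ValidationError(f"truth table missing columns {sorted(required - set(truth.columns))}")
    records: list[MoaksRecord] = []
    grouped = truth.sort_values(["knee_id", "region", "visit_month"])
    baseline_month = int(truth["visit_month"].min())
    for idx, ((knee, region), group) in enumerate(grouped.groupby(["knee_id", "region"], sort=True)):
        rng = _knee_rng(seed, _READER_NS, idx)
        for measure, column in (("ThMCM", "true_thqcm_pct"), ("dMCM", "true_dqcm_pct")):
            prev_pct: float | None = None
            prev_band: int | None = None
            for row in group.itertuples():
                pct = float(getattr(row, column))
                true_band = band(pct)
                reported = float(rng.choice(4, p=reader.confusion[true_band]))
                month = int(row.visit_month)
                if (
                    month > baseline_month
                    and prev_pct is not None
                    and pct > prev_pct
                    and true_band == prev_band
                    and rng.uniform() < reader.within_grade_sensitivity
                ):
                    reported = 0.5
                records.append(
                    MoaksRecord(
                        knee_id=str(knee),
                        visit_month=month,
                        region=str(region),
                        measure=measure,
                        score=reported,
                        baseline_month=baseline_month,
                    )
                )
                prev_pct, prev_band = pct, true_band
    records.sort(key=lambda r: (r.knee_id, r.visit_month, r.region, r.measure))
    return records


def truth_to_csv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False, float_format="%.6f")
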