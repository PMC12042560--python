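"""Per-landmark normative thickness model and the loss/denudation rule.

The model stores the arithmetic mean thickness of a control cohort at
every landmark.  Thinning is flagged where thickness falls below
``loss_fraction`` (default 0.95) of the normative value, denudation below
``denudation_fraction`` (default 0.05) of it.  Two threshold modes exist:

* ``fraction_of_mean`` (default): thresholds are fixed fractions of the
  per-landmark mean.
* ``percentile_of_controls``: thresholds are empirical per-landmark
  percentiles of the control distribution (linear interpolation,
  inclusive endpoints).

Landmarks whose normative mean falls below ``min_normative_mm`` sit at
the edge of cartilage cover where a 5% threshold is vacuous; they are
excluded from all area denominators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .atlas import RegionAtlas, ThicknessMap
from .errors import ValidationError

MODES = ("fraction_of_mean", "percentile_of_controls")


@dataclass(frozen=True)
class NormativeModel:
    """Normative thickness per landmark plus the threshold rule.

    ``loss_threshold`` / ``denudation_threshold`` are per-landmark vectors
    in mm; ``included`` masks landmarks with usable normative cover.
    """

    normative_mean: np.ndarray
    n_controls: int
    loss_fraction: float = 0.95
    denudation_fraction: float = 0.05
    mode: str = "fraction_of_mean"
    min_normative_mm: float = 0.1
    percentile_low: np.ndarray | None = None
    percentile_high: np.ndarray | None = None

    def __post_init__(self) -> None:
        mean = np.asarray(self.normative_mean, dtype=float)
        if np.any(~np.isfinite(mean)) or np.any(mean < 0):
            raise ValidationError("normative means must be finite and nonnegative")
        if self.mode not in MODES:
            raise ValidationError(f"unknown mode {self.mode!r}; valid modes are {MODES}")
        if not 0 < self.loss_fraction <= 1:
            raise ValidationError("loss_fraction must be in (0, 1]")
        if not 0 <= self.denudation_fraction < self.loss_fraction:
            raise ValidationError("denudation_fraction must be in [0, loss_fraction)")
        if self.min_normative_mm < 0:
            raise ValidationError("min_normative_mm must be >= 0")
        if self.mode == "percentile_of_controls" and (
            self.percentile_low is None or self.percentile_high is None
        ):
            raise ValidationError("percentile mode requires stored percentiles")
        object.__setattr__(self, "normative_mean", mean)

    @property
    def n_landmarks(self) -> int:
        return len(self.normative_mean)

    @property
    def included(self) -> np.ndarray:
        """Mask of landmarks retained in area denominators."""
        return self.normative_mean >= self.min_normative_mm

    @property
    def loss_threshold(self) -> np.ndarray:
        if self.mode == "fraction_of_mean":
            return self.loss_fraction * self.normative_mean
        return np.asarray(self.percentile_high, dtype=float)

    @property
    def denudation_threshold(self) -> np.ndarray:
        if self.mode == "fraction_of_mean":
            return self.denudation_fraction * self.normative_mean
        return np.asarray(self.percentile_low, dtype=float)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mode": self.mode,
            "n_controls": self.n_controls,
            "loss_fraction": self.loss_fraction,
            "denudation_fraction": self.denudation_fraction,
            "min_normative_mm": self.min_normative_mm,
            "normative_mean": self.normative_mean.tolist(),
            "percentile_low": None
            if self.percentile_low is None
            else np.asarray(self.percentile_low).tolist(),
            "percentile_high": None
            if self.percentile_high is None
            else np.asarray(self.percentile_high).tolist(),
            "included": self.included.astype(int).tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormativeModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            normative_mean=np.asarray(payload["normative_mean"], dtype=float),
            n_controls=int(payload["n_controls"]),
            loss_fraction=float(payload["loss_fraction"]),
            denudation_fraction=float(payload["denudation_fraction"]),
            mode=payload["mode"],
            min_normative_mm=float(payload["min_normative_mm"]),
            percentile_low=None
            if payload["percentile_low"] is None
            else np.asarray(payload["percentile_low"], dtype=float),
            percentile_high=None
            if payload["percentile_high"] is None
            else np.asarray(payload["percentile_high"], dtype=float),
        )


def build_normative(
    controls: Sequence[ThicknessMap],
    atlas: RegionAtlas,
    *,
    loss_fraction: float = 0.95,
    denudation_fraction: float = 0.05,
    mode: str = "fraction_of_mean",
    min_normative_mm: float = 0.1,
) -> NormativeModel:
    """Average a control cohort into a per-landmark normative model.

    Requires at least 2 controls, all on the given atlas.  In percentile
    mode the empirical per-landmark control percentiles at
    ``100*denudation_fraction`` / ``100*loss_fraction`` are stored as the
    thresholds (linear interpolation between order statistics).
    """
    if len(controls) < 2:
        raise ValidationError(f"need at least 2 controls, got {len(controls)}")
    stack = []
    for cmap in controls:
        if len(cmap.thickness) != atlas.n_landmarks:
            raise ValidationError(
                f"knee {cmap.knee_id}: thickness length {len(cmap.thickness)} "
                f"does not match atlas ({atlas.n_landmarks} landmarks)"
            )
        stack.append(cmap.thickness)
    matrix = np.vstack(stack)
    mean = matrix.mean(axis=0)
    p_low = p_high = None
    if mode == "percentile_of_controls":
        p_low = np.percentile(matrix, 100 * denudation_fraction, axis=0)
        p_high = np.percentile(matrix, 100 * loss_fraction, axis=0)
    return NormativeModel(
        normative_mean=mean,
        n_controls=len(controls),
        loss_fraction=loss_fraction,
        denudation_fraction=denudation_fraction,
        mode=mode,
        min_normative_mm=min_normative_mm,
        percentile_low=p_low,
        percentile_high=p_high,
    )


def thresholds_at(
    model: NormativeModel, atlas: RegionAtlas, landmark_id: int
) -> tuple[float, float, bool]:
    """Return (loss_threshold_mm, denudation_threshold_mm, included)."""
    pos = atlas.position(landmark_id)
    return (
        float(model.loss_threshold[pos]),
        float(model.denudation_threshold[pos]),
        bool(model.included[pos]),
    )
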