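"""Volume-level ROI plumbing and the subjects × (regions × tracers) table.

Covers the late sum-window images, gray-matter-masked atlas sampling,
pons-normalised uptake ratios, the global cortical-to-cerebellar amyloid
ratio with its positivity cutoff, and assembly of the feature table that
feeds the multivariate model and the ROI statistics.

Voxel grids are treated in index space; affines are the caller's concern
(NIfTI I/O in :mod:`multipet.io` carries them through unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import protocol
from .tac import FrameSchedule

__all__ = [
    "LabelAtlas",
    "GrayMatterMask",
    "sum_window",
    "sample_regions",
    "pons_ratio",
    "global_pib",
    "classify_pib",
    "build_feature_table",
    "feature_matrix",
]


@dataclass(frozen=True)
class LabelAtlas:
    """Integer label volume plus a label → region-name map (0 = background)."""

    labels: np.ndarray
    names: dict[int, str]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        if labels.min() < 0:
            raise ValueError("atlas labels must be >= 0")
        present = set(np.unique(labels)) - {0}
        configured = set(self.names)
        if present != configured:
            raise ValueError(
                f"atlas labels {sorted(present)} do not match configured set {sorted(configured)}"
            )
        object.__setattr__(self, "labels", labels)

    @property
    def region_names(self) -> list[str]:
        return [self.names[k] for k in sorted(self.names)]


@dataclass(frozen=True)
class GrayMatterMask:
    """Gray-matter probability volume; the binary mask is probability > 0.5
    (strictly — a voxel at exactly 0.5 is excluded)."""

    probabilities: np.ndarray
    threshold: float = 0.5

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.min() < 0 or p.max() > 1:
            raise ValueError("gray-matter probabilities must lie in [0, 1]")
        object.__setattr__(self, "probabilities", p)

    @property
    def binary(self) -> np.ndarray:
        return self.probabilities > self.threshold


def sum_window(
    dynamic: np.ndarray, schedule: FrameSchedule, window_min: tuple[float, float]
) -> np.ndarray:
    """Duration-weighted mean of the frames whose midpoints fall in the window.

    ``dynamic`` has frames along the first axis. Weights are the frame
    durations normalised to sum to 1.
    """
    dyn = np.asarray(dynamic, dtype=float)
    if dyn.shape[0] != schedule.n_frames:
        raise ValueError(
            f"dynamic series has {dyn.shape[0]} frames but schedule defines {schedule.n_frames}"
        )
    lo, hi = window_min
    if hi > schedule.total_duration_min + 1e-9:
        raise ValueError(f"window {window_min} extends beyond schedule span")
    sel = (schedule.midpoints_min >= lo) & (schedule.midpoints_min <= hi)
    if not sel.any():
        raise ValueError(f"no frame midpoints inside window {window_min}")
    w = schedule.durations_s[sel]
    w = w / w.sum()
    return np.tensordot(w, dyn[sel], axes=(0, 0))


def sample_regions(
    image: np.ndarray, atlas: LabelAtlas, gm: GrayMatterMask
) -> dict[str, float]:
    """Mean image value per atlas region over gray-matter voxels only."""
    img = np.asarray(image, dtype=float)
    if img.shape != atlas.labels.shape or img.shape != gm.probabilities.shape:
        raise ValueError("image, atlas and gray-matter grids must share one shape")
    mask = gm.binary
    means: dict[str, float] = {}
    empty: list[str] = []
    for label in sorted(atlas.names):
        vox = (atlas.labels == label) & mask
        if not vox.any():
            empty.append(atlas.names[label])
            continue
        means[atlas.names[label]] = float(img[vox].mean())
    if empty:
        raise ValueError(f"regions with no gray-matter voxels: {', '.join(empty)}")
    return means


def pons_ratio(region_means: Mapping[str, float], pons_mean: float) -> dict[str, float]:
    """Normalise regional uptake by the pons mean (SUVR-style ratio)."""
    if pons_mean <= 0:
        raise ValueError(f"pons mean must be > 0, got {pons_mean}")
    return {region: value / pons_mean for region, value in region_means.items()}


def global_pib(
    region_values: Mapping[str, float],
    cortical_set: Iterable[str] = protocol.CORTICAL_COMPOSITE,
    cerebellum: str = protocol.CEREBELLUM_REGION,
) -> float:
    """Global cortical-to-cerebellar amyloid ratio.

    Mean of the cortical composite divided by the cerebellar gray-matter
    value. Because both numerator and denominator come from the same table,
    any common normalisation (e.g. the pons) cancels.
    """
    cortical = list(cortical_set)
    if not cortical:
        raise ValueError("cortical set must be non-empty")
    if cerebellum not in region_values:
        raise ValueError(f"cerebellar reference region '{cerebellum}' missing")
    cereb = region_values[cerebellum]
    if cereb <= 0:
        raise ValueError("cerebellar reference value must be > 0")
    missing = [r for r in cortical if r not in region_values]
    if missing:
        raise ValueError(f"cortical regions missing from values: {', '.join(missing)}")
    return float(np.mean([region_values[r] for r in cortical]) / cereb)


def classify_pib(global_ratio: float, cutoff: float = protocol.PIB_CUTOFF) -> bool:
    """Amyloid positivity: True iff the global ratio strictly exceeds the cutoff."""
    return global_ratio > cutoff


def build_feature_table(
    measures: Mapping[str, Mapping[str, Mapping[str, float]]],
    groups: Mapping[str, str],
    regions: Iterable[str] = protocol.ATLAS_REGIONS,
    tracers: Iterable[str] = protocol.TRACERS,
) -> pd.DataFrame:
    """Assemble the subjects × (regions × tracers) feature table.

    ``measures[subject][tracer][region]`` holds one value. Columns are ordered
    region-major, tracer-minor (``{region}_{tracer}``); a ``group`` column
    carries the cohort label. Missing entries raise, naming the offender.
    """
    regions = list(regions)
    tracers = list(tracers)
    columns = [f"{r}_{t}" for r in regions for t in tracers]
    rows = {}
    for subject, per_tracer in measures.items():
        if subject not in groups:
            raise ValueError(f"no group label for subject {subject}")
        row = {}
        for r in regions:
            for t in tracers:
                try:
                    row[f"{r}_{t}"] = float(per_tracer[t][r])
                except KeyError:
                    raise ValueError(
                        f"missing measure: subject={subject} region={r} tracer={t}"
                    ) from None
        rows[subject] = row
    table = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    table.insert(0, "group", [groups[s] for s in table.index])
    table.index.name = "subject"
    return table


def feature_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Numeric feature block of a feature table (drops the group column)."""
    return table.drop(columns=["group"]) if "group" in table.columns else table
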