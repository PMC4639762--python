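"""Acquisition protocol and analysis constants.

Frame schedules, sum-image windows, the reference-Patlak settings, the
amyloid-positivity cutoff, and the default region configuration live here so
that every stage of the pipeline reads the same numbers. ``default_protocol``
serialises the lot to a plain dict for YAML/JSON round-trips.
"""

from __future__ import annotations

from typing import Any

import yaml

from .tac import FrameSchedule

# Dynamic acquisition schedules, seconds. DED: 19 frames over 60 min,
# PIB: 24 frames over 60 min, FDG: 7 frames over 45 min.
FRAME_SCHEDULES: dict[str, FrameSchedule] = {
    "DED": FrameSchedule.from_durations([30.0] * 4 + [60.0] * 8 + [300.0] * 4 + [600.0] * 3),
    "PIB": FrameSchedule.from_durations([30.0] * 4 + [60.0] * 9 + [180.0] * 3 + [300.0] * 8),
    "FDG": FrameSchedule.from_durations([60.0] + [1140.0] + [300.0] * 5),
}

# Late sum-image windows, minutes.
SUM_WINDOWS_MIN: dict[str, tuple[float, float]] = {
    "PIB": (40.0, 60.0),
    "FDG": (30.0, 45.0),
    "DED": (10.0, 60.0),  # native-space summed DED used only for registration
}

# Reference-Patlak settings for DED quantification: cerebellar gray matter
# reference, fixed trapping correction in the reference region, and the
# linear-fit window in minutes.
K3_REF_PER_MIN: float = 0.01
PATLAK_WINDOW_MIN: tuple[float, float] = (20.0, 60.0)

# Global cortical-to-cerebellar PIB ratio above which a subject is amyloid
# positive (strict >; the boundary value itself classifies negative).
PIB_CUTOFF: float = 1.41

# Individual z-scores against the non-carrier reference group are called
# abnormal at |z| > 1.645 (strict; fifth percentile).
Z_ABNORMAL: float = 1.645

# Default 24-region bilateral gray-matter atlas (labels 1..24). The pons is a
# separate reference structure (label 25): it normalises PIB/FDG uptake and is
# deliberately not a table region, so every table column can carry variance.
ATLAS_REGIONS: tuple[str, ...] = (
    "frontal_cortex",
    "orbitofrontal_cortex",
    "sensorimotor_cortex",
    "parietal_cortex",
    "precuneus",
    "temporal_cortex",
    "medial_temporal_cortex",
    "occipital_cortex",
    "lingual_gyrus",
    "fusiform_gyrus",
    "anterior_cingulate",
    "posterior_cingulate",
    "insula",
    "parahippocampal_gyrus",
    "hippocampus",
    "amygdala",
    "caudate_nucleus",
    "putamen",
    "globus_pallidus",
    "nucleus_accumbens",
    "thalamus",
    "midbrain",
    "cerebellar_cortex",
    "cerebellar_vermis",
)

PONS_REGION: str = "pons"
PONS_LABEL: int = 25
CEREBELLUM_REGION: str = "cerebellar_cortex"

#: label -> region name for the full atlas volume (24 regions + pons reference)
ATLAS_LABELS: dict[int, str] = {i + 1: name for i, name in enumerate(ATLAS_REGIONS)}
ATLAS_LABELS[PONS_LABEL] = PONS_REGION

# The 11 bilateral ROIs entering the nonparametric group comparisons.
STAT_ROIS: tuple[str, ...] = (
    "frontal_cortex",
    "parietal_cortex",
    "temporal_cortex",
    "occipital_cortex",
    "anterior_cingulate",
    "posterior_cingulate",
    "caudate_nucleus",
    "putamen",
    "thalamus",
    "hippocampus",
    "cerebellar_cortex",
)

# Cortical composite feeding the global PIB ratio: all cortical regions,
# excluding limbic/subcortical structures and the cerebellum. Configurable.
CORTICAL_COMPOSITE: tuple[str, ...] = (
    "frontal_cortex",
    "orbitofrontal_cortex",
    "sensorimotor_cortex",
    "parietal_cortex",
    "precuneus",
    "temporal_cortex",
    "medial_temporal_cortex",
    "occipital_cortex",
    "lingual_gyrus",
    "fusiform_gyrus",
    "anterior_cingulate",
    "posterior_cingulate",
    "insula",
)

TRACERS: tuple[str, ...] = ("pib", "fdg", "ded")

#: Cohort group labels in severity-table order.
GROUPS: tuple[str, ...] = (
    "sAD",
    "MCI_PIB+",
    "MCI_PIB-",
    "non_carrier",
    "presymptomatic_carrier",
    "symptomatic_carrier",
)

#: Default per-group sample sizes of the study cohort.
GROUP_SIZES: dict[str, int] = {
    "sAD": 7,
    "MCI_PIB+": 8,
    "MCI_PIB-": 3,
    "non_carrier": 12,
    "presymptomatic_carrier": 6,
    "symptomatic_carrier": 3,
}


def default_protocol() -> dict[str, Any]:
    """Return the full protocol configuration as a plain serialisable dict."""
    return {
        "schedules": {
            name: [[float(s), float(d)] for s, d in sched.frames]
            for name, sched in FRAME_SCHEDULES.items()
        },
        "sum_windows_min": {k: list(v) for k, v in SUM_WINDOWS_MIN.items()},
        "k3_ref_per_min": K3_REF_PER_MIN,
        "patlak_window_min": list(PATLAK_WINDOW_MIN),
        "pib_cutoff": PIB_CUTOFF,
        "z_abnormal": Z_ABNORMAL,
        "atlas_regions": list(ATLAS_REGIONS),
        "pons_region": PONS_REGION,
        "cerebellum_region": CEREBELLUM_REGION,
        "stat_rois": list(STAT_ROIS),
        "cortical_composite": list(CORTICAL_COMPOSITE),
        "group_sizes": dict(GROUP_SIZES),
    }


def save_protocol(path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(default_protocol(), fh, sort_keys=False)


def load_protocol(path: str) -> dict[str, Any]:
    with open(path) as fh:
        return yaml.safe_load(fh)
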