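"""CSV and NIfTI I/O helpers.

TAC tables use the columns ``frame_start_s, frame_duration_s, value_kBq_ml``
(optionally with ``subject``/``region`` columns in long format). Feature
tables round-trip as decimal text at 10 significant digits. NIfTI volumes are
read/written through nibabel with affines passed through unmodified.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tac import FrameSchedule, TimeActivityCurve

TAC_COLUMNS = ["frame_start_s", "frame_duration_s", "value_kBq_ml"]


def tac_to_frame(tac: TimeActivityCurve, **extra) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "frame_start_s": tac.schedule.starts_s,
            "frame_duration_s": tac.schedule.durations_s,
            "value_kBq_ml": tac.values,
        }
    )
    for key, value in extra.items():
        df.insert(0, key, value)
    return df


def write_tac(tac: TimeActivityCurve, path) -> None:
    tac_to_frame(tac).to_csv(path, index=False, float_format="%.10g")


def read_tac(path) -> TimeActivityCurve:
    df = pd.read_csv(path)
    missing = [c for c in TAC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"TAC file {path} lacks columns: {', '.join(missing)}")
    return frame_to_tac(df)


def frame_to_tac(df: pd.DataFrame) -> TimeActivityCurve:
    schedule = FrameSchedule(
        tuple(zip(df["frame_start_s"].astype(float), df["frame_duration_s"].astype(float)))
    )
    return TimeActivityCurve(schedule, df["value_kBq_ml"].to_numpy(dtype=float))


def write_long_tacs(tacs: dict[str, dict[str, TimeActivityCurve]], path) -> None:
    """Long-format TAC table: subject, region, frame columns."""
    parts = [
        tac_to_frame(tac, region=region, subject=subject)
        for subject, regions in tacs.items()
        for region, tac in regions.items()
    ]
    pd.concat(parts, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


def read_long_tacs(path) -> dict[str, dict[str, TimeActivityCurve]]:
    df = pd.read_csv(path)
    out: dict[str, dict[str, TimeActivityCurve]] = {}
    for (subject, region), block in df.groupby(["subject", "region"], sort=False):
        out.setdefault(str(subject), {})[str(region)] = frame_to_tac(
            block.sort_values("frame_start_s")
        )
    return out


def write_features(table: pd.DataFrame, path) -> None:
    table.to_csv(path, float_format="%.10g")


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject")


def load_volume(path):
    """Return (data array, affine, header) from a NIfTI file."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine, img.header


def save_volume(data: np.ndarray, path, affine=None, header=None) -> None:
    import nibabel as nib

    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data), affine, header), str(path))
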