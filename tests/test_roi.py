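"""Sum windows, masked atlas sampling, ratios and the feature table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multipet import io, protocol, roi
from multipet.tac import FrameSchedule


@pytest.fixture(scope="module")
def pib_schedule():
    return protocol.FRAME_SCHEDULES["PIB"]


class TestSumWindow:
    def test_single_frame_window_returns_that_frame(self, pib_schedule):
        dyn = np.arange(24, dtype=float).reshape(24, 1, 1, 1)
        mid = pib_schedule.midpoints_min[10]
        out = roi.sum_window(dyn, pib_schedule, (mid - 0.01, mid + 0.01))
        assert out.item() == pytest.approx(10.0)

    def test_pib_late_window_selects_midpoints_and_normalises(self, pib_schedule):
        sel = (pib_schedule.midpoints_min >= 40) & (pib_schedule.midpoints_min <= 60)
        dyn = np.zeros((24, 2, 2, 2))
        dyn[sel] = 1.0
        out = roi.sum_window(dyn, pib_schedule, protocol.SUM_WINDOWS_MIN["PIB"])
        assert np.allclose(out, 1.0)  # weights sum to 1 over selected frames

    def test_constant_series(self, pib_schedule):
        dyn = np.full((24, 3, 3, 3), 2.5)
        assert np.allclose(roi.sum_window(dyn, pib_schedule, (40, 60)), 2.5)

    def test_empty_window_rejected(self, pib_schedule):
        dyn = np.zeros((24, 1, 1, 1))
        with pytest.raises(ValueError):
            roi.sum_window(dyn, pib_schedule, (0.05, 0.1))

    def test_frame_reordering_invariance(self, pib_schedule):
        """Permuting frames and re-sorting by start time leaves the pipeline
        output unchanged."""
        rng = np.random.default_rng(3)
        dyn = rng.random((24, 4, 4, 4))
        perm = rng.permutation(24)
        starts = pib_schedule.starts_s[perm]
        order = np.argsort(starts)
        restored = dyn[perm][order]
        assert np.array_equal(
            roi.sum_window(dyn, pib_schedule, (40, 60)),
            roi.sum_window(restored, pib_schedule, (40, 60)),
        )


class TestSampleRegions:
    def test_uniform_image(self, toy_atlas):
        atlas, gm = toy_atlas
        means = roi.sample_regions(np.full(atlas.labels.shape, 1.8), atlas, gm)
        assert set(means) == set(atlas.names.values())
        assert all(v == pytest.approx(1.8) for v in means.values())

    def test_matches_brute_force_voxel_oracle(self, toy_atlas):
        atlas, gm = toy_atlas
        rng = np.random.default_rng(11)
        img = rng.random(atlas.labels.shape)
        means = roi.sample_regions(img, atlas, gm)
        # brute force: collect voxel values region by region (C order, so the
        # summation order matches and equality is exact)
        collected: dict[str, list[float]] = {}
        for idx in np.ndindex(*atlas.labels.shape):
            label = int(atlas.labels[idx])
            if label == 0 or not gm.probabilities[idx] > 0.5:
                continue
            collected.setdefault(atlas.names[label], []).append(img[idx])
        for name, values in collected.items():
            assert means[name] == np.asarray(values).mean()

    def test_probability_exactly_half_excluded(self):
        labels = np.ones((2, 1, 1), dtype=np.int32)
        atlas = roi.LabelAtlas(labels, {1: "r1"})
        gm = roi.GrayMatterMask(np.array([[[0.5]], [[0.9]]]))
        img = np.array([[[100.0]], [[1.0]]])
        assert roi.sample_regions(img, atlas, gm)["r1"] == 1.0

    def test_empty_region_listed_in_error(self):
        labels = np.array([[[1, 2]]], dtype=np.int32)
        atlas = roi.LabelAtlas(labels, {1: "kept", 2: "starved"})
        gm = roi.GrayMatterMask(np.array([[[0.9, 0.1]]]))
        with pytest.raises(ValueError, match="starved"):
            roi.sample_regions(np.ones((1, 1, 2)), atlas, gm)

    def test_atlas_label_set_validated(self):
        with pytest.raises(ValueError):
            roi.LabelAtlas(np.array([[[1, 3]]], dtype=np.int32), {1: "a", 2: "b"})


class TestRatios:
    def test_pons_ratio_and_arithmetic(self):
        ratios = roi.pons_ratio({"pons": 2.0, "frontal_cortex": 2.82}, pons_mean=2.0)
        assert ratios["pons"] == 1.0
        assert ratios["frontal_cortex"] == pytest.approx(1.41)

    def test_nonpositive_pons_rejected(self):
        with pytest.raises(ValueError):
            roi.pons_ratio({"a": 1.0}, 0.0)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.floats(0.1, 10.0))
    def test_scale_invariance(self, scale):
        means = {"a": 1.2, "b": 3.4, "pons": 2.0}
        base = roi.pons_ratio(means, means["pons"])
        scaled = roi.pons_ratio(
            {k: v * scale for k, v in means.items()}, means["pons"] * scale
        )
        for k in means:
            assert scaled[k] == pytest.approx(base[k], rel=1e-12)


class TestGlobalPib:
    def _values(self, cortical=2.0, cereb=1.0):
        vals = {r: cortical for r in protocol.CORTICAL_COMPOSITE}
        vals[protocol.CEREBELLUM_REGION] = cereb
        return vals

    def test_boundary_value_is_negative(self):
        g = roi.global_pib(self._values(cortical=1.41, cereb=1.0))
        assert g == pytest.approx(1.41)
        assert roi.classify_pib(g) is False  # strict >

    def test_clearly_elevated_is_positive(self):
        assert roi.classify_pib(roi.global_pib(self._values(cortical=2.0))) is True

    def test_missing_cerebellum_rejected(self):
        vals = {r: 2.0 for r in protocol.CORTICAL_COMPOSITE}
        with pytest.raises(ValueError, match="cerebellar"):
            roi.global_pib(vals)


class TestFeatureTable:
    def _measures(self, subjects, regions):
        return {
            s: {t: {r: float(hash((s, t, r)) % 97 + 1) for r in regions} for t in protocol.TRACERS}
            for s in subjects
        }

    def test_full_atlas_gives_72_columns(self):
        subjects = ["s1", "s2"]
        table = roi.build_feature_table(
            self._measures(subjects, protocol.ATLAS_REGIONS), {s: "sAD" for s in subjects}
        )
        assert table.shape == (2, 73)  # 72 features + group
        assert list(table.columns[:4]) == [
            "group",
            "frontal_cortex_pib",
            "frontal_cortex_fdg",
            "frontal_cortex_ded",
        ]

    def test_single_region_gives_three_columns(self):
        table = roi.build_feature_table(
            self._measures(["s1", "s2"], ["thalamus"]),
            {"s1": "sAD", "s2": "sAD"},
            regions=["thalamus"],
        )
        assert table.shape[1] == 4

    def test_missing_measure_names_offender(self):
        measures = self._measures(["s1"], protocol.ATLAS_REGIONS)
        del measures["s1"]["ded"]["thalamus"]
        with pytest.raises(ValueError, match="subject=s1 region=thalamus tracer=ded"):
            roi.build_feature_table(measures, {"s1": "sAD"})

    def test_csv_round_trip_preserves_decimal_text(self, tmp_path, default_features):
        path = tmp_path / "features.csv"
        io.write_features(default_features, path)
        back = io.read_features(path)
        reread = pd.read_csv(path)  # parse the text twice: identical floats
        io.write_features(back, tmp_path / "again.csv")
        assert (tmp_path / "again.csv").read_text() == path.read_text()
        assert back.shape == default_features.shape
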