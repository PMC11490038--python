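import math

import numpy as np
import pandas as pd
import pytest

from bvquant.classify import NONVIABLE, VIABLE, ClassMap, class_counts, classify_stack
from bvquant.epithelial import (
    ExclusionReport,
    exclude_epithelial,
    find_red_components_stack,
    flag_epithelial,
)
from bvquant.viability import (
    FieldSummary,
    SliceViability,
    compute_mft,
    field_summary,
    harmonised_layer_thickness,
    sample_summary,
    slice_viability,
    split_layers,
)


class TestSliceViability:
    def test_bv_formula(self):
        s = slice_viability((75, 25, 0), pixel_size_um=1.0)
        assert s.bv_pct == pytest.approx(75.0)

    def test_area_gate_excludes_small_slices(self):
        s = slice_viability((120, 120, 0), pixel_size_um=1.0)  # 240 um^2
        assert not s.included

    def test_4750_pixels_at_default_pixel_size_pass_the_gate(self):
        from bvquant.stacks import DEFAULT_PIXEL_SIZE_UM

        s = slice_viability((4750, 0, 0), pixel_size_um=DEFAULT_PIXEL_SIZE_UM)
        assert s.aggregate_area_um2 == pytest.approx(250, rel=0.01)
        assert s.included

    def test_empty_slice_undefined_and_excluded(self):
        s = slice_viability((0, 0, 100), pixel_size_um=1.0)
        assert math.isnan(s.bv_pct)
        assert not s.included


def _classmap_with_aggregates(slices_with_blobs, n_slices=14, blob=30):
    """Stack where the given slices contain one solid blob of `blob`^2 px."""
    lab = np.zeros((n_slices, 64, 64), dtype=np.uint8)
    for s in slices_with_blobs:
        lab[s, 10 : 10 + blob, 10 : 10 + blob] = VIABLE
    return ClassMap(lab)


class TestMFT:
    def test_full_stack_thickness(self):
        cm = _classmap_with_aggregates(range(14), n_slices=14)
        assert compute_mft(cm, 0.71, 250) == pytest.approx(14 * 0.71)

    def test_aggregates_only_at_base(self):
        cm = _classmap_with_aggregates([13], n_slices=14)
        assert compute_mft(cm, 0.71, 250) == pytest.approx(0.71)

    def test_empty_stack(self):
        cm = _classmap_with_aggregates([], n_slices=5)
        assert compute_mft(cm, 0.71, 250) == 0.0

    def test_small_clusters_ignored(self):
        cm = _classmap_with_aggregates([0], n_slices=10, blob=10)  # 100 px
        cm2 = _classmap_with_aggregates([4], n_slices=10, blob=30)
        cm.labels[4] = cm2.labels[4]
        # topmost qualifying slice is 4, not 0
        assert compute_mft(cm, 0.71, 250) == pytest.approx(6 * 0.71)

    def test_mft_nonincreasing_in_cluster_gate(self):
        cm = _classmap_with_aggregates([0, 5, 9], n_slices=10)
        gates = [1, 100, 500, 901, 5000]
        mfts = [compute_mft(cm, 0.71, g) for g in gates]
        assert mfts == sorted(mfts, reverse=True)


def _slices(n, bv=50.0):
    return [
        SliceViability(i, viable_px=500, nonviable_px=500, aggregate_area_um2=1000,
                       bv_pct=bv, included=True)
        for i in range(n)
    ]


class TestLayers:
    def test_even_split(self):
        up, lo = split_layers(_slices(14), 14 * 0.71, 0.71)
        assert [s.slice_index for s in up] == list(range(7))
        assert [s.slice_index for s in lo] == list(range(7, 14))

    def test_odd_split_middle_to_upper(self):
        up, lo = split_layers(_slices(13), 13 * 0.71, 0.71)
        assert len(up) == 7 and len(lo) == 6

    def test_partition(self):
        sl = _slices(9)
        up, lo = split_layers(sl, 9 * 0.71, 0.71)
        assert up + lo == sl

    def test_zero_mft_degenerate(self):
        assert split_layers(_slices(5), 0.0, 0.71) == ([], [])


def _field_inputs(bvs, pixel_size=1.0, blob=30):
    """Build classmap + slices where slice i has viability bvs[i] (in %)."""
    n = len(bvs)
    lab = np.zeros((n, 64, 64), dtype=np.uint8)
    slices = []
    for i, bv in enumerate(bvs):
        total = blob * blob
        v = int(round(total * bv / 100))
        flat = np.zeros(64 * 64, dtype=np.uint8)
        flat[:v] = VIABLE
        flat[v:total] = NONVIABLE
        lab[i] = flat.reshape(64, 64)
        slices.append(
            slice_viability((v, total - v, 0), pixel_size_um=pixel_size, slice_index=i)
        )
    cm = ClassMap(lab)
    report = ExclusionReport(
        per_slice=pd.DataFrame(
            {
                "slice_index": range(n),
                "bv_before": [s.bv_pct for s in slices],
                "bv_after": [s.bv_pct for s in slices],
                "excluded_px": 0,
                "n_flagged": 0,
            }
        )
    )
    return slices, cm, report


class TestFieldAndSample:
    def test_mean_of_included_slices(self):
        slices, cm, rep = _field_inputs([40, 60])
        fs = field_summary(slices, cm, rep, z_step_um=0.71, min_aggregate_px=250)
        assert fs.mean_bv_pct == pytest.approx(50.0)

    def test_all_slices_below_gate_excludes_field(self):
        slices, cm, rep = _field_inputs([40, 60], blob=10)  # 100 px < 250
        fs = field_summary(slices, cm, rep, z_step_um=0.71, min_aggregate_px=250)
        assert fs.excluded
        assert math.isnan(fs.mean_bv_pct)

    def test_layer_means_match_brute_force(self):
        bvs = [90, 80, 70, 60, 50, 40, 30, 20, 10, 5]
        slices, cm, rep = _field_inputs(bvs)
        fs = field_summary(slices, cm, rep, z_step_um=0.71, min_aggregate_px=250)
        assert fs.mft_um == pytest.approx(10 * 0.71)
        assert fs.upper_bv_pct == pytest.approx(np.mean(bvs[:5]))
        assert fs.lower_bv_pct == pytest.approx(np.mean(bvs[5:]))

    def test_layers_recombine_to_full_mean(self):
        bvs = [90, 70, 55, 40, 30, 20, 10]
        slices, cm, rep = _field_inputs(bvs)
        fs = field_summary(slices, cm, rep, z_step_um=0.71, min_aggregate_px=250)
        n_up, n_lo = 4, 3
        recombined = (fs.upper_bv_pct * n_up + fs.lower_bv_pct * n_lo) / 7
        assert recombined == pytest.approx(fs.mean_bv_pct)

    def test_pixel_pooled_layer_mode(self):
        slices, cm, rep = _field_inputs([90, 10])
        fs = field_summary(
            slices, cm, rep, z_step_um=0.71, min_aggregate_px=250,
            layer_bv_mode="pixel_pooled",
        )
        # single-slice layers: pooled equals per-slice BV
        assert fs.upper_bv_pct == pytest.approx(90.0)
        assert fs.lower_bv_pct == pytest.approx(10.0)

    def test_sample_mean_across_fields(self):
        def mk(bv):
            slices, cm, rep = _field_inputs([bv])
            return field_summary(slices, cm, rep, z_step_um=0.71, min_aggregate_px=250)

        summ = sample_summary([mk(20), mk(40)], "S1", "TEST", "BIOFILM", "BASAL")
        assert summ.mean_bv_pct == pytest.approx(30.0)
        assert not summ.missing

    def test_single_field_sample_identity(self):
        slices, cm, rep = _field_inputs([65])
        fs = field_summary(slices, cm, rep, z_step_um=0.71, min_aggregate_px=250)
        summ = sample_summary([fs], "S1", "TEST", "BIOFILM", "BASAL")
        assert summ.mean_bv_pct == pytest.approx(fs.mean_bv_pct)
        assert summ.mean_thickness_um == pytest.approx(fs.mft_um)

    def test_six_field_sample_matches_reaggregation_oracle(self, rng):
        fields = []
        for _ in range(6):
            bvs = list(rng.uniform(0, 100, rng.integers(3, 8)))
            slices, cm, rep = _field_inputs(bvs)
            fields.append(
                field_summary(slices, cm, rep, z_step_um=0.71, min_aggregate_px=250)
            )
        summ = sample_summary(fields, "S1", "TEST", "BIOFILM", "BASAL")
        assert summ.mean_bv_pct == pytest.approx(
            np.mean([f.mean_bv_pct for f in fields])
        )
        assert summ.upper_bv_pct == pytest.approx(
            np.mean([f.upper_bv_pct for f in fields])
        )

    def test_all_fields_excluded_flags_sample_missing(self):
        slices, cm, rep = _field_inputs([50], blob=10)
        fs = field_summary(slices, cm, rep, z_step_um=0.71, min_aggregate_px=250)
        summ = sample_summary([fs], "S1", "TEST", "BIOFILM", "BASAL")
        assert summ.missing


def test_harmonised_thickness_is_min_of_group_medians():
    groups = {
        ("TEST", "BASAL"): [10.0, 12.0, 14.0],
        ("CONTROL", "BASAL"): [16.0, 18.0, 20.0],
    }
    assert harmonised_layer_thickness(groups) == 12.0


def test_end_to_end_field_on_synthetic_truth(synthetic_field):
    """Pipeline mean BV matches the generator's realised viable fraction."""
    stack, truth, cm = synthetic_field
    flagged = flag_epithelial(find_red_components_stack(cm, stack.red))
    cm2, rep = exclude_epithelial(cm, flagged)
    slices = [
        slice_viability(class_counts(cm2.labels[i]), stack.pixel_size_um, slice_index=i)
        for i in range(cm2.n_slices)
    ]
    fs = field_summary(slices, cm2, rep, z_step_um=stack.z_step_um, min_aggregate_px=250)
    expected = 100 * np.mean(truth.viable_fraction)
    assert fs.mean_bv_pct == pytest.approx(expected, abs=1.0)
    assert fs.mft_um == pytest.approx(truth.thickness_um)
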