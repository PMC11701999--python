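"""BED conversion and DVH metric extraction."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bedntcp import (
    CF_SCHEME,
    DVH,
    DoseMetricSpec,
    FractionationScheme,
    HF_SCHEME,
    RadiobiologyParams,
    alpha_beta_crossover,
    bed_transform_dvh,
    compute_metric,
    d_xcm3,
    eud,
    physical_to_bed,
    read_dvh_csv,
    v_d,
    write_dvh_csv,
)
from conftest import random_dvh

AB3 = RadiobiologyParams(3.0)


class TestPhysicalToBed:
    @pytest.mark.parametrize(
        "dose, scheme, ab, expected",
        [
            (70.0, CF_SCHEME, 3.0, 111.9),  # V70 physical -> V111.9 threshold
            (75.0, CF_SCHEME, 2.0, 147.1),  # V75 physical -> V147.1 at alpha/beta 2
            (78.0, CF_SCHEME, 3.0, 130.0),  # 78*(1 + 2/3)
            (0.0, HF_SCHEME, 3.0, 0.0),
        ],
    )
    def test_known_conversions(self, dose, scheme, ab, expected):
        assert round(physical_to_bed(dose, scheme, RadiobiologyParams(ab)), 1) == expected

    def test_rejects_negative_dose_and_alpha_beta(self):
        with pytest.raises(ValueError):
            physical_to_bed(-1.0, CF_SCHEME, AB3)
        with pytest.raises(ValueError):
            RadiobiologyParams(0.0)

    @given(st.lists(st.floats(0.01, 120.0), min_size=2, max_size=50, unique=True))
    @settings(deadline=None, max_examples=50)
    def test_monotone_and_dominates_physical(self, doses):
        d = np.sort(np.asarray(doses))
        bed = physical_to_bed(d, CF_SCHEME, AB3)
        assert np.all(np.diff(bed) > 0)
        assert np.all(bed > d)


class TestBedTransform:
    def test_uniform_dvh_maps_to_closed_form(self):
        out = bed_transform_dvh(DVH([78.0], [60.0]), CF_SCHEME, AB3)
        assert out.dose_kind == "bed"
        assert out.bin_dose[0] == pytest.approx(130.0)
        assert out.bin_volume[0] == 60.0

    def test_large_alpha_beta_limit_is_identity(self, rng):
        dvh = random_dvh(rng)
        out = bed_transform_dvh(dvh, CF_SCHEME, RadiobiologyParams(1e9))
        np.testing.assert_allclose(out.bin_dose, dvh.bin_dose, rtol=1e-4)

    def test_volume_conserved_and_order_preserved(self, rng):
        for _ in range(20):
            dvh = random_dvh(rng)
            out = bed_transform_dvh(dvh, HF_SCHEME, AB3)
            assert out.total_volume == pytest.approx(dvh.total_volume, rel=1e-12)
            assert np.all(np.diff(out.bin_dose) > 0)

    def test_rejects_already_bed_input(self):
        bed = DVH([10.0], [1.0], dose_kind="bed")
        with pytest.raises(ValueError):
            bed_transform_dvh(bed, CF_SCHEME, AB3)


class TestEUD:
    def test_uniform_dose_is_identity(self):
        for n in (0.05, 0.1, 0.5, 1.0):
            assert eud(DVH([64.0], [42.0]), n) == pytest.approx(64.0)

    def test_two_bin_examples(self, two_bin_dvh):
        assert eud(two_bin_dvh, 1.0) == pytest.approx(70.0)
        assert eud(two_bin_dvh, 0.1) == pytest.approx(75.05269145784877)

    def test_matches_expanded_voxel_power_mean(self, rng):
        # oracle: expand each bin into unit sub-voxels and take the raw power mean
        for _ in range(10):
            n_bins = int(rng.integers(2, 30))
            doses = np.sort(rng.uniform(1, 90, n_bins)) + np.arange(n_bins) * 1e-6
            counts = rng.integers(1, 20, n_bins)
            dvh = DVH(doses, counts.astype(float))
            voxels = np.repeat(doses, counts)
            for n in (0.1, 0.2, 0.7, 1.0):
                a = 1.0 / n
                oracle = np.mean(voxels**a) ** n
                assert eud(dvh, n) == pytest.approx(oracle, rel=1e-9)

    def test_bounded_by_mean_and_max_and_monotone_in_n(self, rng):
        for _ in range(20):
            dvh = random_dvh(rng)
            ns = [0.05, 0.1, 0.3, 0.6, 1.0]
            vals = [eud(dvh, n) for n in ns]
            assert vals[-1] == pytest.approx(dvh.mean_dose, rel=1e-9)
            for v in vals:
                assert dvh.mean_dose - 1e-9 <= v <= dvh.max_dose + 1e-9
            assert np.all(np.diff(vals) <= 1e-9)  # non-increasing in n

    def test_small_n_approaches_max_dose(self, rng):
        for _ in range(10):
            dvh = random_dvh(rng)
            assert eud(dvh, 1e-3) == pytest.approx(dvh.max_dose, rel=0.01)

    def test_invalid_inputs(self, two_bin_dvh):
        with pytest.raises(ValueError):
            eud(two_bin_dvh, 0.0)
        with pytest.raises(ValueError):
            eud(DVH([10.0], [0.0]), 0.1)


class TestVDAndDx:
    def test_v_d_bin_sum_rule(self):
        dvh = DVH([100.0, 120.0], [30.0, 10.0])
        assert v_d(dvh, 110.0) == pytest.approx(25.0)  # 10 of 40 cm3
        assert v_d(dvh, 100.0) == pytest.approx(100.0)  # inclusive threshold
        assert v_d(dvh, 0.0) == pytest.approx(100.0)
        assert v_d(dvh, 121.0) == 0.0

    def test_v_d_non_increasing_in_threshold(self, rng):
        dvh = random_dvh(rng)
        grid = np.linspace(0, dvh.max_dose * 1.1, 50)
        vals = [v_d(dvh, t) for t in grid]
        assert np.all(np.diff(vals) <= 1e-12)

    def test_d_xcm3_interpolation_example(self):
        # cumulative points V(70)=4, V(75)=1 -> x=2 interpolates to 73.33
        dvh = DVH.from_cumulative([70.0, 75.0], [4.0, 1.0])
        assert d_xcm3(dvh, 2.0) == pytest.approx(70 + (4 - 2) / (4 - 1) * 5)
        assert d_xcm3(dvh, dvh.total_volume) == pytest.approx(70.0)

    def test_d_xcm3_uniform_and_bounds(self):
        uniform = DVH([66.0], [50.0])
        assert d_xcm3(uniform, 0.1) == 66.0
        assert d_xcm3(uniform, 50.0) == 66.0
        with pytest.raises(ValueError, match="organ volume"):
            d_xcm3(uniform, 51.0)

    def test_nested_hot_volumes_are_monotone(self, rng):
        for _ in range(20):
            dvh = random_dvh(rng)
            assert d_xcm3(dvh, 0.1) >= d_xcm3(dvh, min(2.0, dvh.total_volume)) - 1e-12

    def test_v_d_d_xcm3_mutual_consistency(self, rng):
        # v_d at the dose of the hottest x cm3 recovers x within one bin's volume
        for _ in range(20):
            dvh = random_dvh(rng)
            x = 0.5 * dvh.total_volume
            dstar = d_xcm3(dvh, x)
            vol_back = v_d(dvh, dstar) * dvh.total_volume / 100.0
            assert abs(vol_back - x) <= dvh.bin_volume.max() + 1e-9


class TestComputeMetric:
    def test_boundary_inclusive_v_threshold(self):
        # uniform 70 Gy physical sits exactly on the BED threshold it defines
        # (111.9 Gy at one decimal); the inclusive >= rule keeps all volume
        dvh = DVH([70.0], [55.0])
        spec = DoseMetricSpec("V_D", physical_to_bed(70.0, CF_SCHEME, AB3))
        assert round(spec.parameter, 1) == 111.9
        assert compute_metric(dvh, spec, CF_SCHEME, AB3) == pytest.approx(100.0)

    def test_uniform_eud_composition(self):
        dvh = DVH([78.0], [60.0])
        val = compute_metric(dvh, DoseMetricSpec("EUD", 0.1), CF_SCHEME, AB3)
        assert val == pytest.approx(130.0)

    def test_rejects_bed_input(self):
        bed = DVH([100.0], [10.0], dose_kind="bed")
        with pytest.raises(ValueError):
            compute_metric(bed, DoseMetricSpec("EUD", 0.1), CF_SCHEME, AB3)


class TestCrossover:
    def test_trial_schemes_cross_at_4p7(self):
        assert round(alpha_beta_crossover(CF_SCHEME, HF_SCHEME), 1) == 4.7
        assert round(alpha_beta_crossover(HF_SCHEME, CF_SCHEME), 1) == 4.7

    def test_hand_algebra_case(self):
        a = FractionationScheme(39, 78.0)
        b = FractionationScheme(20, 60.0)
        assert alpha_beta_crossover(a, b) == pytest.approx(4.0 / 3.0)

    def test_equal_totals_have_no_positive_solution(self):
        a = FractionationScheme(30, 60.0)
        b = FractionationScheme(20, 60.0)
        assert alpha_beta_crossover(a, b) is None

    def test_identical_schemes_rejected(self):
        with pytest.raises(ValueError):
            alpha_beta_crossover(CF_SCHEME, CF_SCHEME)

    def test_crossover_equalizes_prescription_bed(self):
        x = alpha_beta_crossover(CF_SCHEME, HF_SCHEME)
        rb = RadiobiologyParams(x)
        assert physical_to_bed(78.0, CF_SCHEME, rb) == pytest.approx(
            physical_to_bed(64.6, HF_SCHEME, rb)
        )


class TestDVHContainerAndIO:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            DVH([10.0, 10.0], [1.0, 1.0])  # not strictly increasing
        with pytest.raises(ValueError):
            DVH([10.0], [-1.0])
        with pytest.raises(ValueError):
            DVH([], [])

    def test_cumulative_curve_properties(self, rng):
        dvh = random_dvh(rng)
        dose, cum = dvh.cumulative()
        assert cum[0] == pytest.approx(dvh.total_volume)
        assert np.all(np.diff(cum) <= 0)

    def test_csv_round_trip_differential(self, rng, tmp_path):
        dvh = random_dvh(rng)
        path = tmp_path / "p1.csv"
        write_dvh_csv(dvh, path)
        back = read_dvh_csv(path)
        assert back == dvh

    def test_cumulative_flavor_read(self):
        text = "# dvh_kind: cumulative\ndose_gy,cum_volume_cm3\n10.0,50.0\n20.0,30.0\n30.0,5.0\n"
        dvh = read_dvh_csv(io.StringIO(text))
        np.testing.assert_allclose(dvh.bin_volume, [20.0, 25.0, 5.0])
        assert dvh.total_volume == pytest.approx(50.0)
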