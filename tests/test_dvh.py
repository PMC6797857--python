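"""Cumulative DVH algebra: compositing, EQD2 conversion, dose metrics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ntcpval import (DoseVolumeHistogram, FractionationScheme,
                     combine_bilateral, to_eqd2, read_dvh_csv, write_dvh_csv)
from ntcpval.dvh import DVHError, ScaleError

from conftest import random_dvh


def step_dvh(points, volume=3.0, structure="s", scale="physical"):
    doses, fracs = zip(*points)
    return DoseVolumeHistogram(structure, np.array(doses), np.array(fracs),
                               volume, scale)


# -- validation ----------------------------------------------------------

@pytest.mark.parametrize("doses,fracs,message", [
    ([0, 5, 5, 10], [1, 0.8, 0.5, 0], "duplicate"),
    ([0, 10, 5], [1, 0.5, 0.2], "strictly increasing"),
    ([1, 5], [1, 0.5], "start at 0"),
    ([0, 5], [0.9, 0.5], "must be 1.0"),
    ([0, 5, 10], [1.0, 0.4, 0.6], "non-increasing"),
    ([0, 5], [1.0, -0.2], "outside"),
])
def test_invalid_dvhs_rejected(doses, fracs, message):
    with pytest.raises(DVHError, match=message):
        DoseVolumeHistogram("s", np.array(doses, float), np.array(fracs, float), 2.0)


def test_non_positive_volume_rejected():
    with pytest.raises(DVHError, match="volume_cc"):
        step_dvh([(0, 1.0), (10, 0.0)], volume=0.0)


# -- compositing ---------------------------------------------------------

def test_combine_identical_structures_is_identity():
    a = step_dvh([(0, 1.0), (10, 0.6), (20, 0.0)])
    b = step_dvh([(0, 1.0), (10, 0.6), (20, 0.0)])
    comp = combine_bilateral(a, b)
    np.testing.assert_allclose(comp.volume_fraction, a.volume_fraction)
    np.testing.assert_allclose(comp.dose_gy, a.dose_gy)
    assert comp.volume_cc == a.volume_cc + b.volume_cc


def test_combine_full_and_empty_coverage_halves():
    left = step_dvh([(0, 1.0), (10, 1.0)], volume=2.0)      # 100% up to 10 Gy
    right = step_dvh([(0, 1.0), (1e-6, 0.0)], volume=2.0)   # nothing above 0 Gy
    comp = combine_bilateral(left, right)
    probe = np.array([0.5, 3.0, 9.99])
    np.testing.assert_allclose(comp.fraction_at_dose(probe), 0.5, atol=1e-6)
    assert comp.volume_cc == 4.0


def test_combine_scale_mismatch_raises():
    a = step_dvh([(0, 1.0), (10, 0.0)], scale="physical")
    b = step_dvh([(0, 1.0), (10, 0.0)], scale="eqd2")
    with pytest.raises(ScaleError):
        combine_bilateral(a, b)


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_combine_matches_pooled_voxel_oracle(seed):
    """Compositing equals pooling pseudo-voxels resampled from each curve."""
    rng = np.random.default_rng(seed)
    left, right = random_dvh(rng, "L"), random_dvh(rng, "R")
    comp = combine_bilateral(left, right)

    n_total = 100_000
    voxels = []
    for dvh in (left, right):
        n = int(round(n_total * dvh.volume_cc / comp.volume_cc))
        u = (np.arange(n) + 0.5) / n * 100.0
        voxels.append([dvh.dose_at_volume(x) for x in u])
    pooled = np.concatenate(voxels)
    probes = rng.uniform(0, comp.dose_gy[-1], 25)
    for d in probes:
        expected = np.mean(pooled >= d)
        assert comp.fraction_at_dose(d) == pytest.approx(expected, abs=2e-3)


@given(st.integers(0, 10_000))
def test_combine_output_is_valid_and_conserves_volume(seed):
    rng = np.random.default_rng(seed)
    left, right = random_dvh(rng, "L"), random_dvh(rng, "R")
    comp = combine_bilateral(left, right)  # constructor revalidates invariants
    assert comp.volume_cc == left.volume_cc + right.volume_cc
    assert comp.volume_fraction[0] == 1.0
    assert np.all(np.diff(comp.volume_fraction) <= 1e-12)


# -- EQD2 ----------------------------------------------------------------

def test_eqd2_of_prescription_dose():
    dvh = step_dvh([(0, 1.0), (50.4, 0.0)])
    out = to_eqd2(dvh, FractionationScheme(28, 1.8, alpha_beta=2.0))
    # 50.4 Gy in 28 fx: 50.4 * (1.8 + 2) / 4
    assert out.dose_gy[-1] == pytest.approx(47.88)
    assert out.dose_gy[0] == 0.0
    assert out.dose_scale == "eqd2"
    np.testing.assert_array_equal(out.volume_fraction, dvh.volume_fraction)


def test_eqd2_identity_at_two_gy_per_fraction():
    dvh = step_dvh([(0, 1.0), (30, 0.5), (60, 0.0)])
    out = to_eqd2(dvh, FractionationScheme(30, 2.0))
    assert out.dose_gy[2] == pytest.approx(60.0)  # d = 60/30 = 2 Gy/fx


@given(st.integers(0, 10_000))
def test_eqd2_monotone_and_direction(seed):
    rng = np.random.default_rng(seed)
    dvh = random_dvh(rng)
    scheme = FractionationScheme(int(rng.integers(5, 40)))
    out = to_eqd2(dvh, scheme)
    assert np.all(np.diff(out.dose_gy) > 0)
    d = dvh.dose_gy[1:]
    per_fx = d / scheme.n_fractions
    below = per_fx < 2.0
    assert np.all(out.dose_gy[1:][below] < d[below])
    assert np.all(out.dose_gy[1:][~below] >= d[~below])


def test_eqd2_rejects_already_converted_input():
    dvh = step_dvh([(0, 1.0), (10, 0.0)], scale="eqd2")
    with pytest.raises(ScaleError):
        to_eqd2(dvh, FractionationScheme(28))


# -- Dx% and mean dose ---------------------------------------------------

def test_dose_at_volume_interpolates_single_segment():
    dvh = step_dvh([(0, 1.0), (10, 0.0)])
    assert dvh.dose_at_volume(40) == pytest.approx(6.0)


def test_dose_at_volume_exact_knots_and_round_trip():
    dvh = step_dvh([(0, 1.0), (4, 0.7), (9, 0.35), (15, 0.05)])
    for d, f in zip(dvh.dose_gy, dvh.volume_fraction):
        if 0 < f < 1:
            assert dvh.dose_at_volume(100 * f) == pytest.approx(d, abs=1e-9)


def test_dose_at_volume_below_curve_minimum_returns_max_dose():
    dvh = step_dvh([(0, 1.0), (10, 0.3)])
    assert dvh.dose_at_volume(5) == 10.0


def test_dose_at_volume_domain_errors():
    dvh = step_dvh([(0, 1.0), (10, 0.0)])
    for x in (0, 100, -5, 120):
        with pytest.raises(DVHError):
            dvh.dose_at_volume(x)


@pytest.mark.parametrize("seed", [11, 12, 13])
def test_dose_at_volume_matches_dense_grid_scan(seed):
    """Dx% agrees with a brute-force scan over a densely resampled curve."""
    rng = np.random.default_rng(seed)
    dvh = random_dvh(rng)
    dense = np.linspace(0, dvh.dose_gy[-1], 10_000)
    frac = dvh.fraction_at_dose(dense)
    spacing = dense[1] - dense[0]
    for x in rng.uniform(1, 99, 20):
        f = x / 100.0
        idx = np.argmax(frac <= f) if (frac <= f).any() else len(dense) - 1
        assert abs(dvh.dose_at_volume(x) - dense[idx]) <= spacing


@given(st.integers(0, 10_000))
def test_dose_at_volume_non_increasing_in_x(seed):
    rng = np.random.default_rng(seed)
    dvh = random_dvh(rng)
    xs = np.sort(rng.uniform(1, 99, 10))
    doses = [dvh.dose_at_volume(x) for x in xs]
    assert np.all(np.diff(doses) <= 1e-12)


def test_mean_dose_uniform_structure():
    dvh = step_dvh([(0, 1.0), (12.5, 1.0)])
    assert dvh.mean_dose() == pytest.approx(12.5)


def test_mean_dose_two_bin_hand_integration():
    dvh = step_dvh([(0, 1.0), (10, 0.5), (20, 0.0)])
    # half the volume at the 5 Gy midpoint, half at 15 Gy
    assert dvh.mean_dose() == pytest.approx(10.0)


@given(st.integers(0, 10_000))
def test_mean_dose_invariant_under_grid_refinement(seed):
    rng = np.random.default_rng(seed)
    dvh = random_dvh(rng)
    mids = 0.5 * (dvh.dose_gy[:-1] + dvh.dose_gy[1:])
    grid = np.sort(np.concatenate([dvh.dose_gy, mids]))
    refined = DoseVolumeHistogram(dvh.structure, grid, dvh.fraction_at_dose(grid),
                                  dvh.volume_cc)
    assert refined.mean_dose() == pytest.approx(dvh.mean_dose(), abs=1e-9)


# -- CSV interchange -----------------------------------------------------

def test_dvh_csv_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    original = {name: random_dvh(rng, name) for name in ("left", "right")}
    path = tmp_path / "plan.csv"
    write_dvh_csv(path, original)
    back = read_dvh_csv(path)
    assert set(back) == {"left", "right"}
    for name in back:
        np.testing.assert_allclose(back[name].dose_gy, original[name].dose_gy)
        np.testing.assert_allclose(back[name].volume_fraction,
                                   original[name].volume_fraction)
        assert back[name].volume_cc == pytest.approx(original[name].volume_cc)


def test_dvh_csv_missing_volume_requires_override(tmp_path):
    path = tmp_path / "plan.csv"
    path.write_text("structure,dose_gy,volume_fraction\ns,0,1.0\ns,10,0.0\n")
    with pytest.raises(DVHError, match="volume_cc"):
        read_dvh_csv(path)
    dvh = read_dvh_csv(path, volume_cc=3.5)["s"]
    assert dvh.volume_cc == 3.5


def test_dvh_csv_absolute_volumes_normalised_on_read(tmp_path):
    path = tmp_path / "plan.csv"
    path.write_text("structure,dose_gy,volume_fraction,volume_cc\n"
                    "s,0,4.0,4.0\ns,10,2.0,4.0\ns,20,0.0,4.0\n")
    dvh = read_dvh_csv(path)["s"]
    np.testing.assert_allclose(dvh.volume_fraction, [1.0, 0.5, 0.0])
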