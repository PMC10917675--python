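"""Fiber filtering: candidates, peak matrix, r weights, scoring, controls."""

import math

import numpy as np
import pytest

from stimmap.fiberfilter import (
    FiberFilter,
    PeakMatrix,
    build_peak_matrix,
    fit_fiber_model,
    gaussian_contact_control,
    select_candidates,
    specificity_ratio,
)
from stimmap.imaging import StreamlineSet, sample_along_streamline

from conftest import make_efield


def _line(a, b):
    return np.array([a, b], dtype=float)


def _peaks_matrix(values):
    values = np.asarray(values, float)
    labels = [(f"p{j}", "left") for j in range(values.shape[1])]
    return PeakMatrix(values, labels, np.arange(values.shape[0]))


# ------------------------------------------------------------- candidates

def test_candidate_rule_is_strict_fraction():
    """Exactly 0.5% of fields above threshold does NOT qualify."""
    n_fields = 200  # 1 field = exactly 0.5%
    peaks = np.zeros((3, n_fields))
    peaks[0, :2] = 900.0     # 1.0% -> candidate
    peaks[1, :1] = 900.0     # exactly 0.5% -> not
    peaks[2, :] = 1000.0     # everywhere -> candidate
    flags = select_candidates(None, None, 800.0, 0.005,
                              peaks=_peaks_matrix(peaks))
    assert flags.tolist() == [True, False, True]


def test_candidate_monotone_in_magnitude_threshold(rng):
    peaks = _peaks_matrix(rng.random((30, 40)) * 1200)
    lo = select_candidates(None, None, 600.0, 0.005, peaks=peaks)
    hi = select_candidates(None, None, 900.0, 0.005, peaks=peaks)
    assert np.all(hi <= lo)


def test_streamline_outside_all_fields_not_candidate(rng):
    sset = StreamlineSet([_line([50, 50, 50], [60, 60, 60]),
                          _line([1, 1, 1], [3, 3, 3])])
    efields = [make_efield(rng.random((5, 5, 5)) * 2000, patient_id=f"p{i}")
               for i in range(4)]
    flags = select_candidates(sset, efields, 800.0, 0.005)
    assert not flags[0]
    assert flags[1]


# ------------------------------------------------------------ peak matrix

def test_peak_matrix_constant_field():
    sset = StreamlineSet([_line([1, 1, 1], [3, 3, 3])])
    ef = make_efield(np.full((5, 5, 5), 123.0))
    pm = build_peak_matrix(sset, [ef])
    assert pm.values[0, 0] == pytest.approx(123.0)


def test_peak_matrix_linear_in_field_amplitude(rng):
    sset = StreamlineSet([rng.uniform(0, 4, (5, 3)) for _ in range(6)])
    data = rng.random((5, 5, 5)) * 500
    one = build_peak_matrix(sset, [make_efield(data)])
    two = build_peak_matrix(sset, [make_efield(2 * data)])
    np.testing.assert_allclose(two.values, 2 * one.values, rtol=1e-12)


def test_peak_matrix_matches_pointwise_bruteforce(rng):
    sset = StreamlineSet([rng.uniform(0, 4, (4, 3)) for _ in range(8)])
    efields = [make_efield(rng.random((5, 5, 5)) * 300, patient_id=f"p{i}")
               for i in range(5)]
    pm = build_peak_matrix(sset, efields, step_mm=0.5)
    for i, sl in enumerate(sset):
        for j, ef in enumerate(efields):
            brute = np.max(sample_along_streamline(ef.volume, sl, 0.5))
            assert pm.values[i, j] == pytest.approx(brute, abs=1e-9)


# ------------------------------------------------------------------- fit

def test_perfectly_predictive_streamline_is_sweet(rng):
    peaks = rng.random((10, 8)) * 500
    improvements = np.argsort(np.argsort(peaks[3])) * 7.0 + 10  # monotone in row 3
    res = fit_fiber_model(_peaks_matrix(peaks), improvements)
    assert res.r[3] == pytest.approx(1.0)
    assert 3 in res.sweet_ids


def test_top_one_percent_counts_two_of_200(rng):
    peaks = rng.normal(500, 100, size=(200, 30)).clip(min=0)
    improvements = rng.normal(50, 10, 30)
    res = fit_fiber_model(_peaks_matrix(peaks), improvements)
    # oracle: r >= 99th percentile of candidate r, positive side only
    expected = np.where((res.r >= np.quantile(res.r, 0.99)) & (res.r > 0))[0]
    np.testing.assert_array_equal(res.sweet_ids, expected)
    assert len(np.unique(np.sort(res.r)[-3:])) == 3  # top values distinct...
    assert res.sweet_ids.size == 2                   # ...so top 1% of 200 is 2


def test_fit_invariant_to_monotone_transform_and_reordering(rng):
    peaks = rng.random((15, 10)) * 600
    y = rng.normal(50, 10, 10)
    a = fit_fiber_model(_peaks_matrix(peaks), y)
    b = fit_fiber_model(_peaks_matrix(peaks), np.exp(y / 25))
    np.testing.assert_allclose(a.r, b.r, atol=1e-12)
    order = rng.permutation(10)
    c = fit_fiber_model(_peaks_matrix(peaks[:, order]), y[order])
    np.testing.assert_allclose(a.r, c.r, atol=1e-12)


def test_fit_rejects_constant_improvements(rng):
    peaks = rng.random((5, 8)) * 600
    with pytest.raises(ValueError, match="constant"):
        fit_fiber_model(_peaks_matrix(peaks), np.full(8, 5.0))


def test_certainty_is_neg_log10_p(rng):
    peaks = rng.random((6, 12)) * 600
    res = fit_fiber_model(_peaks_matrix(peaks), rng.normal(50, 10, 12))
    ok = ~np.isnan(res.p)
    np.testing.assert_allclose(res.certainty[ok], -np.log10(res.p[ok]))


# ----------------------------------------------------------------- scoring

def _fitted_model_with_sweet(rng, n_sweet=30):
    r = rng.uniform(0.1, 0.9, n_sweet)
    res = fit_fiber_model(
        _peaks_matrix(rng.random((n_sweet, 10)) * 600),
        rng.normal(50, 10, 10))
    # override to a fully sweet model for scoring arithmetic tests
    res.r = r
    res.sweet_ids = np.arange(n_sweet)
    return res


def test_score_zero_when_field_touches_nothing(rng):
    res = _fitted_model_with_sweet(rng)
    assert res.score_efield(None, peaks_row=np.zeros(30)) == 0.0


def test_score_peak5_of_20_is_single_max(rng):
    res = _fitted_model_with_sweet(rng, n_sweet=30)
    peaks_row = np.zeros(30)
    touched = rng.choice(30, size=20, replace=False)
    peaks_row[touched] = rng.uniform(100, 900, 20)
    w = res.r[touched] * peaks_row[touched]
    got = res.score_efield(None, peaks_row=peaks_row)
    assert math.ceil(0.05 * 20) == 1
    assert got == pytest.approx(w.max())


def test_score_matches_bruteforce_enumeration(rng):
    for _ in range(20):
        n_sweet = rng.integers(5, 50)
        res = _fitted_model_with_sweet(rng, n_sweet=int(n_sweet))
        peaks_row = np.where(rng.random(n_sweet) < 0.5,
                             rng.uniform(10, 900, n_sweet), 0.0)
        got = res.score_efield(None, peaks_row=peaks_row)
        touched = peaks_row > 0
        if not touched.any():
            assert got == 0.0
            continue
        w = sorted(res.r[touched] * peaks_row[touched], reverse=True)
        k = max(1, math.ceil(0.05 * len(w)))
        assert got == pytest.approx(sum(w[:k]), abs=1e-9)


def test_score_empty_sweet_set_errors(rng):
    res = fit_fiber_model(_peaks_matrix(rng.random((5, 8)) * 600),
                          rng.normal(50, 10, 8))
    res.sweet_ids = np.array([], dtype=int)
    with pytest.raises(ValueError, match="sweet"):
        res.score_efield(None, peaks_row=np.zeros(0))


# -------------------------------------------------------------- specificity

def _results_with_r(r):
    from stimmap.fiberfilter import FiberFilterResults
    r = np.asarray(r, float)
    return FiberFilterResults(
        r=r, p=np.full(r.size, 0.5), candidate=np.ones(r.size, bool),
        sweet_threshold=0.0, sweet_ids=np.array([], int),
        params={}, n_observations=6)


def test_specificity_ratio_arithmetic():
    res = {
        "A": _results_with_r([0.6]),
        "B": _results_with_r([0.2]),
        "C": _results_with_r([0.1]),
        "D": _results_with_r([0.3]),
    }
    df = specificity_ratio(res)
    assert df.loc[0, "A"] == pytest.approx(0.6 / 0.2)  # 3.0


def test_specificity_zero_self_and_undefined_denominator():
    res = {"A": _results_with_r([0.0, 0.5]),
           "B": _results_with_r([0.2, 0.0]),
           "C": _results_with_r([0.2, 0.0])}
    df = specificity_ratio(res)
    assert df.loc[0, "A"] == 0.0          # r_self = 0 -> 0
    assert np.isnan(df.loc[1, "A"])       # others mean 0 -> undefined, not inf


def test_specificity_single_model_errors():
    with pytest.raises(ValueError):
        specificity_ratio({"A": _results_with_r([0.5])})


# --------------------------------------------------- gaussian contact ROI

def test_gaussian_control_degenerate_contacts_select_local_only():
    contacts = np.tile([2.0, 2.0, 2.0], (6, 1))  # all at one point -> ridge
    sset = StreamlineSet([
        _line([2.0, 2.0, 0.0], [2.0, 2.0, 4.0]),   # passes through the point
        _line([10.0, 10.0, 0.0], [10.0, 10.0, 4.0]),
    ])
    sel = gaussian_contact_control({"X": contacts}, sset, mahalanobis_cut=2.0)
    assert sel["X"].tolist() == [True, False]


def test_gaussian_control_infinite_cut_selects_all(rng):
    contacts = rng.normal(0, 2, (8, 3))
    sset = StreamlineSet([rng.normal(0, 30, (5, 3)) for _ in range(6)])
    sel = gaussian_contact_control({"X": contacts}, sset,
                                   mahalanobis_cut=np.inf)
    assert sel["X"].all()


def test_gaussian_control_rotation_equivariant(rng):
    from scipy.spatial.transform import Rotation
    contacts = rng.normal(0, 1.5, (12, 3))
    sls = [rng.normal(0, 4, (6, 3)) for _ in range(10)]
    sel = gaussian_contact_control({"X": contacts}, StreamlineSet(sls),
                                   mahalanobis_cut=2.0)
    R = Rotation.from_euler("xyz", [30, -45, 60], degrees=True).as_matrix()
    sel_rot = gaussian_contact_control(
        {"X": contacts @ R.T}, StreamlineSet([s @ R.T for s in sls]),
        mahalanobis_cut=2.0)
    assert sel["X"].tolist() == sel_rot["X"].tolist()


def test_gaussian_control_needs_four_contacts(rng):
    with pytest.raises(ValueError):
        gaussian_contact_control({"X": rng.normal(size=(3, 3))},
                                 StreamlineSet([]), 2.0)


# -------------------------------------------------------- model-object API

def test_fiberfilter_end_to_end_smoke(rng):
    sset = StreamlineSet([rng.uniform(0, 4, (5, 3)) for _ in range(20)])
    efields = [make_efield(rng.random((5, 5, 5)) * 1200, patient_id=f"p{i}")
               for i in range(8)]
    ff = FiberFilter(sset, efields, rng.normal(50, 10, 8))
    res = ff.fit()
    assert res.r.size == 20
    assert "Fiber-filtering" in res.summary()
    df = res.to_frame()
    assert {"streamline_id", "r", "p", "certainty", "candidate", "sweet"} <= set(df.columns)
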