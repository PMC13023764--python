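"""Synthetic cohorts, TGI arithmetic and the AAD-TGI correlation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from xpdtsim.invivo import (
    CohortDesign,
    GroupOutcome,
    TumorMeasurement,
    correlate_aad_tgi,
    pearson,
    recover_effect_slope,
    simulate_cohort,
    tgi,
    tumor_volume,
)

AADS = {40: 0.55, 80: 1.0, 120: 0.8, 160: 0.6}


def test_tumor_volume_printed_formula():
    assert tumor_volume(TumorMeasurement(10.0, 10.0)) == pytest.approx(50.0)
    assert tumor_volume(TumorMeasurement(10.0, 4.0), formula="lww") == pytest.approx(80.0)
    with pytest.raises(ValueError):
        tumor_volume(TumorMeasurement(10.0, 4.0), formula="ellipsoid")


@given(st.floats(1.0, 30.0), st.floats(0.1, 1.0), st.floats(0.5, 3.0))
def test_tumor_volume_homogeneity(length, frac, c):
    width = length * frac
    base = tumor_volume(TumorMeasurement(length, width))
    scaled = tumor_volume(TumorMeasurement(c * length, c * width))
    assert scaled == pytest.approx(c**2 * base, rel=1e-9)


def test_measurement_validation():
    with pytest.raises(ValueError):
        TumorMeasurement(3.0, 5.0)
    with pytest.raises(ValueError):
        TumorMeasurement(3.0, 0.0)


def test_tgi_worked_examples():
    assert tgi(100.0, 150.0, 100.0, 300.0) == pytest.approx(75.0)
    assert tgi(80.0, 80.0, 100.0, 250.0) == pytest.approx(100.0)  # static tumor
    assert tgi(100.0, 300.0, 100.0, 300.0) == pytest.approx(0.0)  # same as control
    with pytest.raises(ZeroDivisionError):
        tgi(100.0, 150.0, 120.0, 120.0)


@given(st.floats(0.5, 20.0))
def test_tgi_scale_invariance(c):
    assert tgi(100.0 * c, 180.0 * c, 90.0 * c, 400.0 * c) == pytest.approx(
        tgi(100.0, 180.0, 90.0, 400.0), rel=1e-9)


def test_cohort_no_effect_gives_zero_tgi():
    design = CohortDesign(noise_cv=0.0, dose_effect_slope=0.0, seed=4)
    outcomes, _ = simulate_cohort(design, {g: 0.5 for g in (40, 80, 120, 160)})
    for o in outcomes:
        if o.tgi is not None:
            assert o.tgi == pytest.approx(0.0, abs=1e-9)


def test_cohort_full_suppression_gives_full_tgi():
    design = CohortDesign(noise_cv=0.0, dose_effect_slope=1.0, seed=4)
    outcomes, _ = simulate_cohort(design, {g: 1.0 for g in (40, 80, 120, 160)})
    for o in outcomes:
        if o.tgi is not None:
            assert o.tgi == pytest.approx(100.0, abs=1e-9)


def test_cohort_deterministic_and_structured():
    design = CohortDesign(seed=11)
    o1, m1 = simulate_cohort(design, AADS)
    o2, m2 = simulate_cohort(design, AADS)
    assert o1 == o2
    assert m1.equals(m2)
    assert len(m1) == 25
    assert set(m1["group"]) == {"control", "40", "80", "120", "160"}
    lo, hi = design.start_volume_range
    # true start volumes lie in range; measured ones carry noise around it
    assert m1["v_start_mm3"].between(lo * 0.5, hi * 1.7).all()


def test_cohort_monotone_dose_response_zero_noise():
    design = CohortDesign(noise_cv=0.0, dose_effect_slope=0.9, seed=2)
    aads = {40: 0.2, 80: 0.5, 120: 0.8, 160: 1.0}
    outcomes, _ = simulate_cohort(design, aads)
    by_group = {o.label: o.tgi for o in outcomes if o.tgi is not None}
    ordered = [by_group[g] for g in (40, 80, 120, 160)]
    assert np.all(np.diff(ordered) > 0)


def test_cohort_missing_or_invalid_aad():
    design = CohortDesign(seed=1)
    with pytest.raises(ValueError, match="missing"):
        simulate_cohort(design, {40: 0.5, 80: 0.5, 120: 0.5})
    with pytest.raises(ValueError, match="outside"):
        simulate_cohort(design, {40: 0.5, 80: 0.5, 120: 0.5, 160: 1.5})


def test_effect_slope_recovery_zero_noise():
    """Inverting the exponential-growth model on noise-free outcomes
    recovers the generative slope exactly."""
    design = CohortDesign(noise_cv=0.0, dose_effect_slope=0.63, seed=9)
    outcomes, _ = simulate_cohort(design, AADS)
    got = recover_effect_slope(outcomes, AADS, design)
    assert got == pytest.approx(0.63, abs=1e-6)


def test_pearson_worked_examples():
    assert pearson([1, 2, 3], [3, 5, 7]) == pytest.approx(1.0)
    assert pearson([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)
    assert pearson([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        pearson([1, 2, 3], [2, 2, 2])
    with pytest.raises(ValueError):
        pearson([1, 2], [3, 4])


def test_correlation_perfect_by_construction():
    """TGI generated linearly from the AAD with zero noise correlates
    perfectly with the generating AAD."""
    design = CohortDesign(noise_cv=0.0, dose_effect_slope=0.4, seed=5)
    outcomes, _ = simulate_cohort(design, AADS)
    aad_by_kvp = {float(k): v for k, v in AADS.items()}
    r = correlate_aad_tgi(aad_by_kvp, outcomes)
    assert r > 0.99


def test_correlation_constant_aad_rejected():
    design = CohortDesign(noise_cv=0.0, seed=5)
    outcomes, _ = simulate_cohort(design, AADS)
    with pytest.raises(ValueError):
        correlate_aad_tgi({40.0: 1.0, 80.0: 1.0, 120.0: 1.0, 160.0: 1.0}, outcomes)


def test_correlation_needs_three_points():
    outcomes = [GroupOutcome("control", 90.0, 900.0, None),
                GroupOutcome(40, 90.0, 500.0, 40.0),
                GroupOutcome(80, 90.0, 400.0, 55.0)]
    with pytest.raises(ValueError, match="3"):
        correlate_aad_tgi({40.0: 0.5, 80.0: 1.0}, outcomes)


def test_generating_aad_beats_permuted_aad():
    """Across replicate noisy cohorts the generating AAD profile
    correlates better with TGI than a permuted profile (median over
    200 replicates)."""
    aads = {40: 0.55, 80: 1.0, 120: 0.8, 160: 0.6}
    perm = {40: 0.8, 80: 0.6, 120: 0.55, 160: 1.0}  # shuffled values
    r_true, r_perm = [], []
    for rep in range(200):
        design = CohortDesign(noise_cv=0.15, dose_effect_slope=0.8, seed=1000 + rep)
        outcomes, _ = simulate_cohort(design, aads)
        r_true.append(correlate_aad_tgi({float(k): v for k, v in aads.items()}, outcomes))
        r_perm.append(correlate_aad_tgi({float(k): v for k, v in perm.items()}, outcomes))
    assert np.median(r_true) > np.median(r_perm)
    assert np.median(r_true) > 0.8
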