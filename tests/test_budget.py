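"""Loss budgets: forward predictions, inversions, and feasibility."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbcmat.budget import (
    Vesicle,
    feasibility_report,
    fraction_lost_table,
    predicted_loss,
    required_radius,
    required_rate,
)


def test_predicted_volume_loss_closed_form():
    # 4/day for 50 days of 100-nm spheres
    expect = 4 * 50 * (4.0 / 3.0) * math.pi * 0.1**3
    assert predicted_loss("volume", 4.0, 50.0, 100.0) == pytest.approx(expect)
    assert expect == pytest.approx(0.838, abs=1e-3)


def test_area_roundtrip_with_geometric_bound():
    """Area shed at the geometry-derived rate reproduces the area budget."""
    from rbcmat.rates import geometric_rate_bound

    f = geometric_rate_bound(130.0, radius_nm=83.5, lifespan=120.0)
    assert predicted_loss("area", f, 120.0, 83.5) == pytest.approx(130.0)


def test_zero_rate_zero_loss():
    for q, conc in (("volume", None), ("hb", 33.0), ("area", None)):
        assert predicted_loss(q, 0.0, 50.0, 100.0, conc) == 0.0


def test_hb_requires_concentration():
    with pytest.raises(ValueError, match="conc"):
        predicted_loss("hb", 4.0, 50.0, 100.0)
    with pytest.raises(ValueError, match="conc"):
        required_radius("hb", 2.9, 4.0, 50.0)


def test_required_radius_matches_infeasibility_bound():
    r = required_radius("volume", 16.4238095238, 8.97, 50.0)
    assert r == pytest.approx(206.0, abs=0.1)
    assert r > 185.0


def test_required_rate_exceeds_empirical_estimates():
    f = required_rate("volume", 16.4238095238, 93.0, 50.0)
    assert f == pytest.approx(97.5, abs=0.1)
    assert f > 75.0


def test_required_radius_scaling():
    r1 = required_radius("area", 100.0, 2.0, 50.0)
    r2 = required_radius("area", 100.0, 8.0, 50.0)
    assert r2 == pytest.approx(r1 / 2.0)


@given(
    f=st.floats(min_value=0.1, max_value=20.0),
    age=st.floats(min_value=1.0, max_value=120.0),
    r=st.floats(min_value=20.0, max_value=300.0),
)
@settings(max_examples=50, deadline=None)
def test_inversions_are_roundtrips(f, age, r):
    for q, conc in (("volume", None), ("hb", 33.0), ("area", None)):
        loss = predicted_loss(q, f, age, r, conc)
        assert required_radius(q, loss, f, age, conc) == pytest.approx(r, rel=1e-9)
        assert required_rate(q, loss, r, age, conc) == pytest.approx(f, rel=1e-9)


@given(
    f=st.floats(min_value=0.1, max_value=20.0),
    age=st.floats(min_value=1.0, max_value=120.0),
    r=st.floats(min_value=20.0, max_value=300.0),
)
@settings(max_examples=50, deadline=None)
def test_predicted_loss_monotone(f, age, r):
    base = predicted_loss("volume", f, age, r)
    assert predicted_loss("volume", f * 1.5, age, r) > base
    assert predicted_loss("volume", f, age * 1.5, r) > base
    assert predicted_loss("volume", f, age, r * 1.5) > base


def test_radius_distribution_uses_third_moment(rng):
    """With a radius sample the r^3 moment enters, not the cube of the mean;
    cross-checked against the closed-form lognormal moment."""
    mu, sigma = math.log(80.0), 0.3
    radii = rng.lognormal(mu, sigma, size=1_000_000)
    loss = predicted_loss("volume", 1.0, 1.0, radii)
    moment3 = math.exp(3 * mu + 4.5 * sigma**2)  # E[r^3], nm^3
    expect = (4.0 / 3.0) * math.pi * moment3 * 1e-9
    assert loss == pytest.approx(expect, rel=5e-3)
    naive = predicted_loss("volume", 1.0, 1.0, float(radii.mean()))
    assert loss > naive * 1.1  # skew matters


def test_fraction_lost_table_printed_values(cohort):
    table = fraction_lost_table(cohort, [4.0, 10.0], radius_nm=100.0, mean_age=50.0)
    assert table.loc[4.0, "volume_pct_mean"] == pytest.approx(5.2, abs=0.05)
    assert table.loc[4.0, "volume_pct_std"] == pytest.approx(0.7, abs=0.05)
    assert table.loc[10.0, "volume_pct_mean"] == pytest.approx(13.0, abs=0.05)
    assert table.loc[4.0, "hb_pct_mean"] == pytest.approx(10.5, abs=0.05)
    # f enters linearly: the f=10 row is 2.5x the f=4 row
    assert table.loc[10.0, "hb_pct_mean"] == pytest.approx(
        2.5 * table.loc[4.0, "hb_pct_mean"]
    )


def test_fraction_lost_excludes_bad_subjects(cohort):
    from rbcmat.population import SubjectSummary

    with pytest.warns(UserWarning):
        bad = SubjectSummary("bad", 90.0, 90.0, 30.0, 30.0, 33.0, 33.0)
    with pytest.warns(UserWarning, match="excluded"):
        table = fraction_lost_table(list(cohort) + [bad], [4.0])
    assert table.loc[4.0, "n_subjects"] == 21


def test_feasibility_verdicts(cohort):
    verdicts = feasibility_report(
        {"volume": 16.4, "hb": 2.9, "area": 23.3},
        mean_age=50.0,
        cell_conc_gdl=34.4,
    )
    assert not verdicts["volume"].feasible
    assert not verdicts["hb"].feasible
    assert verdicts["area"].feasible
    # vesiculation explains <20% of the volume loss inside the box
    assert verdicts["volume"].fraction_explained_pct < 20.0


def test_zero_loss_trivially_feasible():
    v = feasibility_report({"volume": 0.0})["volume"]
    assert v.feasible


def test_vesicle_derived_quantities():
    v = Vesicle(radius_nm=100.0, hb_conc_gdl=33.0)
    assert v.volume_fl == pytest.approx((4 / 3) * math.pi * 1e-3)
    assert v.area_um2 == pytest.approx(4 * math.pi * 1e-2)
    assert v.hb_mass_pg == pytest.approx(v.volume_fl * 0.33)
    with pytest.raises(ValueError):
        Vesicle(radius_nm=-1.0)
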