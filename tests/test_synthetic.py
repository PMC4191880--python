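"""Synthetic-data generators: moment targets, determinism, invariants."""

import numpy as np
import pytest

from rbcmat.constants import DEFAULT_CONSTANTS
from rbcmat.geometry import min_sphere_area
from rbcmat.population import SubjectSummary, maturation_deltas
from rbcmat.synthetic import (
    PopulationSpec,
    RadiusDistributionSpec,
    gen_advia_population,
    gen_clearance_curve,
    gen_smr_cloud,
    gen_subject_cohort,
    gen_vesicle_radii,
    gen_volume_area_reference,
    radius_sampler,
)
from rbcmat.rates import fit_clearance, remaining_fraction_model


def test_advia_population_moments():
    spec = PopulationSpec(
        n_cells=40_000, mean_volume=104.9, mean_hb=33.5, label="reticulocyte"
    )
    df = gen_advia_population(spec, seed=1)
    se_v = spec.mean_volume * spec.cv_volume / 100.0 / np.sqrt(spec.n_cells)
    se_h = spec.mean_hb * spec.cv_hb / 100.0 / np.sqrt(spec.n_cells)
    assert df["volume_fl"].mean() == pytest.approx(104.9, abs=3 * se_v)
    assert df["hb_pg"].mean() == pytest.approx(33.5, abs=3 * se_h)
    cv_v = df["volume_fl"].std() / df["volume_fl"].mean() * 100.0
    assert cv_v == pytest.approx(spec.cv_volume, rel=0.05)
    corr = np.corrcoef(df["volume_fl"], df["hb_pg"])[0, 1]
    assert corr == pytest.approx(spec.volume_hb_correlation, abs=0.02)


def test_advia_zero_cv_and_zero_correlation():
    spec = PopulationSpec(n_cells=100, mean_volume=90.0, mean_hb=30.0,
                          cv_volume=0.0, cv_hb=0.0)
    df = gen_advia_population(spec, seed=0)
    assert (df["volume_fl"] == 90.0).all()
    spec0 = PopulationSpec(
        n_cells=20_000, mean_volume=90.0, mean_hb=30.0,
        volume_hb_correlation=0.0,
    )
    df0 = gen_advia_population(spec0, seed=2)
    corr = np.corrcoef(df0["volume_fl"], df0["hb_pg"])[0, 1]
    assert abs(corr) < 3.0 / np.sqrt(spec0.n_cells)


def test_vesicle_radii_mean_on_target():
    spec = RadiusDistributionSpec()
    r = gen_vesicle_radii(spec, 100_000, seed=3)
    assert abs(r.mean() - 83.5) < 1.0
    lo, hi = spec.bounds
    assert r.min() >= lo and r.max() <= hi


def test_vesicle_radii_degenerate_and_bimodal():
    const = gen_vesicle_radii(
        RadiusDistributionSpec(cv=0.0), 100, seed=0
    )
    assert np.allclose(const, 83.5)
    uni_like = gen_vesicle_radii(
        RadiusDistributionSpec(kind="bimodal", nano_weight=1.0, mode_cv=0.1),
        50_000,
        seed=1,
    )
    # weight 1 on the nano mode collapses to a unimodal sample at its mean
    assert uni_like.mean() == pytest.approx(40.0, rel=0.02)


def test_radius_sampler_protocol(rng):
    sampler = radius_sampler(RadiusDistributionSpec())
    out = sampler(rng, 100)
    assert out.shape == (100,)
    assert sampler(rng, 0).shape == (0,)


def test_clearance_curve_exact_when_noiseless():
    t = np.linspace(0.0, 10.0, 20)
    curve = gen_clearance_curve(1.0, 0.01, 0.944, t, noise_cv=0.0, seed=0)
    assert np.allclose(
        curve.remaining_fraction, remaining_fraction_model(t, 1.0, 0.01, 0.944)
    )
    assert curve.remaining_fraction[0] == pytest.approx(1.0)


def test_clearance_recovery_loop():
    t = np.linspace(0.0, 8.0, 30)
    curve = gen_clearance_curve(1.0, 0.01, 0.944, t, noise_cv=0.0, seed=0)
    fit = fit_clearance(curve, mode="two_param", seed=0)
    assert fit.alpha_r == pytest.approx(1.0, rel=1e-3)


def test_smr_cloud_cvs():
    df = gen_smr_cloud(10_000, seed=4)
    cv_mass = df["dry_mass_pg"].std() / df["dry_mass_pg"].mean() * 100.0
    cv_dens = df["dry_density_pgfl"].std() / df["dry_density_pgfl"].mean() * 100.0
    assert cv_mass == pytest.approx(16.9, rel=0.1)
    assert cv_dens == pytest.approx(0.3, rel=0.1)
    c = DEFAULT_CONSTANTS
    assert df["dry_density_pgfl"].between(c.rho_s, c.rho_hb).all()


def test_smr_cloud_validation():
    with pytest.raises(ValueError, match="mean density"):
        gen_smr_cloud(100, mean_density=1.5)
    point = gen_smr_cloud(50, cv_mass=0.0, cv_density=0.0, seed=0)
    assert point["dry_mass_pg"].nunique() == 1


def test_volume_area_reference_geometry():
    df = gen_volume_area_reference(2000, jitter=2.0, seed=5)
    assert (df["area_um2"] >= min_sphere_area(df["volume_fl"].to_numpy())).all()
    exact = gen_volume_area_reference(200, jitter=0.0, seed=5)
    assert np.allclose(exact["area_um2"], 1.7 * exact["volume_fl"])
    # S/V 1.7 at 110 fl gives the familiar ~187 µm²
    assert 1.7 * 110.0 == pytest.approx(187.0)


def test_subject_cohort_is_valid_and_healthy():
    subs = gen_subject_cohort(seed=6)
    assert len(subs) == 21
    assert all(isinstance(s, SubjectSummary) for s in subs)
    d = maturation_deltas(subs, "volume")
    assert d.mean_change > 0


@pytest.mark.parametrize(
    "gen",
    [
        lambda s: gen_advia_population(
            PopulationSpec(n_cells=500, mean_volume=90.0, mean_hb=30.0), s
        ).to_csv(),
        lambda s: gen_vesicle_radii(RadiusDistributionSpec(), 500, s).tobytes(),
        lambda s: gen_smr_cloud(500, seed=s).to_csv(),
        lambda s: gen_volume_area_reference(500, seed=s).to_csv(),
    ],
)
def test_generators_are_seed_deterministic(gen):
    assert gen(99) == gen(99)
    assert gen(99) != gen(100)
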