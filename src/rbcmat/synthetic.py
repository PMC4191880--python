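"""Seeded generators for every input the pipeline consumes.

Real inputs are summary tables and instrument clouds (flow-cytometry
volume/Hb clouds, vesicle-radius histograms, reinfusion clearance curves,
dry-mass/dry-density clouds).  These generators emulate their statistical
shape — lognormal marginals for sizes (structurally positive and
right-skewed), stated coefficients of variation, bi-exponential clearance —
so every stage is testable without instrument data.  They reproduce none of
the instruments' noise physics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .geometry import min_sphere_area
from .population import SubjectSummary
from .rates import ClearanceCurve, remaining_fraction_model

#: mean vesicle radius (nm) of the unimodal (NMR-like) source distribution
DEFAULT_MEAN_RADIUS_NM = 83.5
#: default relative spread of vesicle radii; sizes this CV keeps the
#: truncated-lognormal mean within ~0.1 nm of the target
DEFAULT_RADIUS_CV = 0.25
DEFAULT_RADIUS_BOUNDS_NM = (20.0, 400.0)

#: measured coefficients of variation of the dry-mass/dry-density cloud (%)
SMR_CV_MASS_PCT = 16.9
SMR_CV_DENSITY_PCT = 0.3

#: cohort means of the packaged 21-subject table, used as generator defaults
RETIC_MEAN_VOLUME_FL = 104.9
RETIC_MEAN_HB_PG = 33.5
TOTAL_MEAN_VOLUME_FL = 88.8
TOTAL_MEAN_HB_PG = 30.4


@dataclass(frozen=True)
class PopulationSpec:
    """Moments of a bivariate single-cell (volume, Hb) cloud."""

    n_cells: int
    mean_volume: float
    mean_hb: float
    cv_volume: float = 13.0  # %
    cv_hb: float = 12.0  # %
    volume_hb_correlation: float = 0.85
    label: str = "total"

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.cv_volume < 0 or self.cv_hb < 0:
            raise ValueError("CVs must be nonnegative")
        if not -1.0 < self.volume_hb_correlation < 1.0:
            raise ValueError("correlation must lie strictly inside (-1, 1)")


@dataclass(frozen=True)
class RadiusDistributionSpec:
    """Vesicle-radius distribution: unimodal lognormal or a two-mode
    (nano + micro) lognormal mixture, truncated to positive bounds."""

    kind: str = "unimodal"
    mean_radius: float = DEFAULT_MEAN_RADIUS_NM
    cv: float = DEFAULT_RADIUS_CV
    bounds: tuple = DEFAULT_RADIUS_BOUNDS_NM
    # bimodal only; the mode weights of merged nano/micro histograms are
    # not recoverable from published figures — these defaults are arbitrary
    nano_mean: float = 40.0
    micro_mean: float = 120.0
    nano_weight: float = 0.5
    mode_cv: float = 0.2

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if not 0 < lo < hi:
            raise ValueError("bounds must be positive and ordered")
        if self.kind == "unimodal" and not lo <= self.mean_radius <= hi:
            raise ValueError("mean radius must lie within the bounds")
        if not 0.0 <= self.nano_weight <= 1.0:
            raise ValueError("nano_weight must be in [0, 1]")


def _lognormal_params(mean: float, cv_frac: float) -> tuple:
    """(mu, sigma) of a lognormal with the given mean and fractional CV."""
    sigma2 = np.log1p(cv_frac**2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def gen_advia_population(
    spec: PopulationSpec, seed: int | np.random.Generator
):
    """Bivariate lognormal (volume, Hb) cloud with the requested moments.

    Means and CVs are matched exactly by moment transformation; the
    requested Pearson correlation is mapped to the underlying normal
    correlation.  Returns a DataFrame with ``volume_fl``, ``hb_pg``, and
    the derived per-cell ``conc_gdl``.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    cv_v = spec.cv_volume / 100.0
    cv_h = spec.cv_hb / 100.0
    if cv_v == 0 or cv_h == 0:
        vol = np.full(spec.n_cells, spec.mean_volume)
        hb = np.full(spec.n_cells, spec.mean_hb)
    else:
        mu_v, s_v = _lognormal_params(spec.mean_volume, cv_v)
        mu_h, s_h = _lognormal_params(spec.mean_hb, cv_h)
        rho = spec.volume_hb_correlation
        inner = 1.0 + rho * cv_v * cv_h
        if inner <= 0:
            raise ValueError("infeasible correlation for the given CVs")
        rho_n = np.log(inner) / (s_v * s_h)
        if not -1.0 < rho_n < 1.0:
            raise ValueError("infeasible correlation for the given CVs")
        cov = np.array([[s_v**2, rho_n * s_v * s_h], [rho_n * s_v * s_h, s_h**2]])
        z = rng.multivariate_normal([mu_v, mu_h], cov, size=spec.n_cells)
        vol = np.exp(z[:, 0])
        hb = np.exp(z[:, 1])
    return pd.DataFrame(
        {
            "volume_fl": vol,
            "hb_pg": hb,
            "conc_gdl": hb / vol * 100.0,
            "label": spec.label,
        }
    )


def gen_vesicle_radii(
    spec: RadiusDistributionSpec, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Sample vesicle radii (nm) from the spec's truncated distribution."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = spec.bounds

    def draw_mode(mean, cv, size):
        if cv == 0:
            return np.full(size, mean)
        mu, s = _lognormal_params(mean, cv)
        return rng.lognormal(mu, s, size=size)

    out = np.empty(0)
    while out.size < n:
        need = n - out.size
        m = int(need * 1.3) + 16
        if spec.kind == "unimodal":
            r = draw_mode(spec.mean_radius, spec.cv, m)
        elif spec.kind == "bimodal":
            pick = rng.random(m) < spec.nano_weight
            r = np.where(
                pick,
                draw_mode(spec.nano_mean, spec.mode_cv, m),
                draw_mode(spec.micro_mean, spec.mode_cv, m),
            )
        else:
            raise ValueError(f"unknown kind {spec.kind!r}")
        out = np.concatenate([out, r[(r >= lo) & (r <= hi)]])
    return out[:n]


def radius_sampler(spec: RadiusDistributionSpec):
    """Adapt a spec to the ``(rng, n) -> radii`` sampler protocol used by
    the shedding simulators."""

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        if n == 0:
            return np.empty(0)
        return gen_vesicle_radii(spec, n, rng)

    return sample


def gen_clearance_curve(
    alpha_r: float,
    alpha_p: float,
    purity_p: float,
    t_grid: Sequence[float],
    noise_cv: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> ClearanceCurve:
    """Bi-exponential clearance curve with multiplicative lognormal noise.

    ``noise_cv`` is in percent; 0 gives exact model values.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(t_grid, dtype=float)
    y = remaining_fraction_model(t, alpha_r, alpha_p, purity_p)
    if noise_cv > 0:
        mu, s = _lognormal_params(1.0, noise_cv / 100.0)
        y = y * rng.lognormal(mu, s, size=t.shape)
    return ClearanceCurve(times=t, remaining_fraction=y)


def gen_smr_cloud(
    n: int,
    mean_dry_mass: float = 32.0,
    cv_mass: float = SMR_CV_MASS_PCT,
    cv_density: float = SMR_CV_DENSITY_PCT,
    mean_density: float = 1.34,
    seed: int | np.random.Generator = 0,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """Dry-mass/dry-density cloud with the stated marginal CVs.

    Density values are redrawn until all fall inside (ρ_s, ρ_hb); a mean
    density outside that interval is rejected outright.
    """
    import pandas as pd

    if not constants.rho_s < mean_density < constants.rho_hb:
        raise ValueError(
            f"mean density must lie in ({constants.rho_s}, {constants.rho_hb})"
        )
    rng = np.random.default_rng(seed)
    if cv_mass == 0:
        mass = np.full(n, mean_dry_mass)
    else:
        mu, s = _lognormal_params(mean_dry_mass, cv_mass / 100.0)
        mass = rng.lognormal(mu, s, size=n)
    if cv_density == 0:
        dens = np.full(n, mean_density)
    else:
        mu, s = _lognormal_params(mean_density, cv_density / 100.0)
        dens = rng.lognormal(mu, s, size=n)
        for _ in range(100):
            bad = (dens <= constants.rho_s) | (dens >= constants.rho_hb)
            if not bad.any():
                break
            dens[bad] = rng.lognormal(mu, s, size=int(bad.sum()))
    return pd.DataFrame({"dry_mass_pg": mass, "dry_density_pgfl": dens})


def gen_volume_area_reference(
    n: int,
    sv_ratio: float = 1.7,
    volume_range: tuple = (60.0, 110.0),
    jitter: float = 2.0,
    seed: int | np.random.Generator = 0,
):
    """Single-cell (volume, area) reference table for volume-matching.

    Area = sv_ratio × volume with multiplicative lognormal jitter (percent);
    rows violating the isoperimetric inequality are resampled.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    lo, hi = volume_range
    if not 0 < lo < hi:
        raise ValueError("invalid volume range")
    vols = np.empty(0)
    areas = np.empty(0)
    while vols.size < n:
        need = n - vols.size
        v = rng.uniform(lo, hi, size=need * 2 + 8)
        a = sv_ratio * v
        if jitter > 0:
            mu, s = _lognormal_params(1.0, jitter / 100.0)
            a = a * rng.lognormal(mu, s, size=v.shape)
        keep = a >= min_sphere_area(v)
        vols = np.concatenate([vols, v[keep]])
        areas = np.concatenate([areas, a[keep]])
    return pd.DataFrame({"volume_fl": vols[:n], "area_um2": areas[:n]})


#: per-column (retic, total) means and between-subject SDs mirroring the
#: packaged cohort's column spreads
_COHORT_COLUMNS = {
    "retic_volume": (RETIC_MEAN_VOLUME_FL, 3.9),
    "total_volume": (TOTAL_MEAN_VOLUME_FL, 4.0),
    "retic_hb": (RETIC_MEAN_HB_PG, 1.5),
    "total_hb": (TOTAL_MEAN_HB_PG, 1.4),
    "retic_conc": (31.9, 1.1),
    "total_conc": (34.3, 1.1),
}


def gen_subject_cohort(
    n_subjects: int = 21, seed: int | np.random.Generator = 0
):
    """Fresh per-subject summary cohort for pipeline tests.

    Between-subject variation is matched to the packaged table's column
    spreads; reticulocyte and total-population columns are drawn with high
    within-subject correlation so per-subject deltas stay positive.
    """
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n_subjects):
        z = rng.normal()  # shared subject-level factor
        vals = {}
        for name, (mean, sd) in _COHORT_COLUMNS.items():
            vals[name] = mean + sd * (0.8 * z + 0.6 * rng.normal())
        # enforce healthy-donor orderings
        vals["retic_volume"] = max(vals["retic_volume"], vals["total_volume"] + 5.0)
        vals["retic_hb"] = max(vals["retic_hb"], vals["total_hb"] + 0.5)
        vals["total_conc"] = max(vals["total_conc"], vals["retic_conc"] + 0.5)
        subjects.append(
            SubjectSummary(
                subject_id=str(i + 1),
                retic_volume=vals["retic_volume"],
                total_volume=vals["total_volume"],
                retic_hb=vals["retic_hb"],
                total_hb=vals["total_hb"],
                retic_conc=vals["retic_conc"],
                total_conc=vals["total_conc"],
            )
        )
    return subjects
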