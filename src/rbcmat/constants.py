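"""Physical constants, unit conversions, and run configuration.

Internal unit conventions
-------------------------
* volume: femtoliters (1 fl = 1 µm³)
* area: µm²
* radius: nanometers at API boundaries, converted to µm internally
* Hb concentration: stored as pg/fl, rendered as g/dL (1 pg/fl = 100 g/dL)
* rates: vesicles/cell/day; clearance in 1/day or 1/minute (conversion here)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: 1 pg/fl = 100 g/dL
GDL_PER_PG_FL = 100.0

#: minutes per day, for bridging clearance-rate units
MINUTES_PER_DAY = 1440.0

NM_PER_UM = 1000.0


def gdl_to_pg_fl(conc_gdl: float) -> float:
    """Convert a hemoglobin concentration from g/dL to pg/fl."""
    return conc_gdl / GDL_PER_PG_FL


def pg_fl_to_gdl(conc_pg_fl: float) -> float:
    """Convert a hemoglobin concentration from pg/fl to g/dL."""
    return conc_pg_fl * GDL_PER_PG_FL


def per_minute_to_per_day(rate_per_min: float) -> float:
    """Convert a first-order rate from 1/minute to 1/day."""
    return rate_per_min * MINUTES_PER_DAY


def per_day_to_per_minute(rate_per_day: float) -> float:
    """Convert a first-order rate from 1/day to 1/minute."""
    return rate_per_day / MINUTES_PER_DAY


def sphere_volume_fl(radius_nm):
    """Volume of a sphere of the given radius (nm), in fl (µm³).

    Accepts scalars or numpy arrays.
    """
    r_um = radius_nm / NM_PER_UM
    return (4.0 / 3.0) * math.pi * r_um**3


def sphere_area_um2(radius_nm):
    """Surface area of a sphere of the given radius (nm), in µm²."""
    r_um = radius_nm / NM_PER_UM
    return 4.0 * math.pi * r_um**2


#: Membrane volume per unit area as tabulated upstream, fl/µm².  Taken at
#: face value this makes membrane mass exceed Hb mass, contradicting the
#: well-established fact that Hb is ~95–97% of RBC dry mass; see
#: PhysicalConstants for the corrected default.
V_S_RAW_TABLE = 1.009
#: Rescaled membrane volume per area (fl/µm²), treating the tabulated value
#: as a 10² scale misprint.  Gives membrane ≈3–5% of dry mass.
V_S_RESCALED = 1.009e-2


@dataclass(frozen=True)
class PhysicalConstants:
    """Densities and membrane geometry entering the dry-mass model.

    Attributes
    ----------
    rho_s : float
        Membrane (surface) density, pg/fl.
    rho_hb : float
        Hemoglobin solution density, pg/fl.  Must exceed ``rho_s`` for dry
        density to increase monotonically along shedding trajectories.
    v_s : float
        Membrane volume per unit membrane area, fl/µm².  The default is the
        rescaled value ``V_S_RESCALED``; the raw tabulated value is exposed
        as ``V_S_RAW_TABLE`` for sensitivity analyses.
    """

    rho_s: float = 1.15
    rho_hb: float = 1.36
    v_s: float = V_S_RESCALED

    def __post_init__(self) -> None:
        if not self.rho_s < self.rho_hb:
            raise ValueError(
                "membrane density rho_s must be below Hb density rho_hb "
                f"(got rho_s={self.rho_s}, rho_hb={self.rho_hb})"
            )


DEFAULT_CONSTANTS = PhysicalConstants()


@dataclass
class RunConfig:
    """Configuration for the end-to-end pipeline.

    Defaults reproduce the packaged analysis: mean circulating age 50 d,
    lifespan 120 d, vesicle clearance 1425/day, rescaled membrane
    volume/area, and a 50 g/dL physiological ceiling on vesicle [Hb].
    """

    mean_age_days: float = 50.0
    lifespan_days: float = 120.0
    alpha_per_day: float = 1425.0
    v_s_mode: str = "rescaled"  # or "raw_table"
    infeasible_conc_gdl: float = 50.0
    seed: int = 0
    outdir: str = "rbcmat_out"

    def constants(self) -> PhysicalConstants:
        v_s = V_S_RAW_TABLE if self.v_s_mode == "raw_table" else V_S_RESCALED
        return PhysicalConstants(v_s=v_s)
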