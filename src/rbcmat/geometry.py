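"""Isoperimetric surface-to-volume constraints on maturation.

If shedding of fixed-size spherical vesicles were the only loss mechanism
and the fractional area and volume losses are equal (as observed), the
cell's surface-to-volume ratio would have to equal the vesicle's 3/r.
For a vesicle of radius ~100 nm that is ~30 µm⁻¹, while RBCs sit near
1.7 µm⁻¹ — more than an order of magnitude apart — so shedding cannot be
the sole volume-loss mechanism.  The sphere minimizes surface area for a
given volume (isoperimetric inequality), which anchors the comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

ISOPERIMETRIC_RTOL = 1e-9


def min_sphere_area(volume_fl: float) -> float:
    """Minimal surface area (µm²) enclosing the given volume: a sphere.

    4π·(3V/4π)^(2/3), with V in fl (= µm³).
    """
    v = np.asarray(volume_fl, dtype=float)
    if np.any(v <= 0):
        raise ValueError("volume must be positive")
    out = 4.0 * math.pi * (3.0 * v / (4.0 * math.pi)) ** (2.0 / 3.0)
    return float(out) if np.isscalar(volume_fl) else out


@dataclass(frozen=True)
class CellGeometry:
    """A cell's volume (fl) and membrane area (µm²).

    Construction enforces the isoperimetric inequality: the area cannot be
    below that of the volume-equivalent sphere.
    """

    volume: float
    area: float

    def __post_init__(self) -> None:
        if self.volume <= 0 or self.area <= 0:
            raise ValueError("volume and area must be positive")
        min_area = min_sphere_area(self.volume)
        if self.area < min_area * (1.0 - ISOPERIMETRIC_RTOL):
            raise ValueError(
                f"geometrically impossible cell: area {self.area} µm² is below "
                f"the minimal sphere area {min_area:.2f} µm² for {self.volume} fl"
            )

    @property
    def sv_ratio(self) -> float:
        """Surface-to-volume ratio, 1/µm."""
        return self.area / self.volume

    @property
    def equivalent_sphere_radius(self) -> float:
        """Radius (µm) of the sphere with the same volume."""
        return (3.0 * self.volume / (4.0 * math.pi)) ** (1.0 / 3.0)


def sv_consistency_error(
    area_pct: Sequence[float], volume_pct: Sequence[float]
) -> tuple:
    """Discrepancy |ΔS/S₀ − ΔV/V₀| in percentage points.

    Takes per-subject percent changes of area and volume (signed, as
    reported) and returns (per-subject array, mean).  Invariant under a
    common rescaling of all areas and volumes, since only the fractional
    changes enter.
    """
    a = np.asarray(area_pct, dtype=float)
    v = np.asarray(volume_pct, dtype=float)
    if a.shape != v.shape:
        raise ValueError("area and volume percent arrays must align")
    per_subject = np.abs(a - v)
    return per_subject, float(per_subject.mean())


def sv_consistency_error_from_deltas(
    area_lost: Sequence[float],
    volume_lost: Sequence[float],
    area_initial: Sequence[float],
    volume_initial: Sequence[float],
) -> tuple:
    """As :func:`sv_consistency_error`, from raw losses and initial values."""
    a0 = np.asarray(area_initial, dtype=float)
    v0 = np.asarray(volume_initial, dtype=float)
    if np.any(a0 <= 0) or np.any(v0 <= 0):
        raise ValueError("initial values must be positive")
    a_pct = np.asarray(area_lost, dtype=float) / a0 * 100.0
    v_pct = np.asarray(volume_lost, dtype=float) / v0 * 100.0
    return sv_consistency_error(a_pct, v_pct)


@dataclass(frozen=True)
class SoleMechanismVerdict:
    """Comparison of cell and vesicle surface-to-volume ratios."""

    cell_sv: float
    vesicle_sv: float
    ratio: float
    feasible: bool


def sole_mechanism_test(
    cell: CellGeometry, vesicle_radius_nm: float, factor: float = 2.0
) -> SoleMechanismVerdict:
    """Can shedding alone carry both the area and volume loss?

    Requires the cell's S/V to match the vesicle's 3/r.  The verdict is
    infeasible when they differ by more than ``factor`` (default 2); the
    physiological discrepancy is over an order of magnitude.
    """
    if vesicle_radius_nm <= 0:
        raise ValueError("vesicle radius must be positive")
    vesicle_sv = 3.0 / (vesicle_radius_nm / 1000.0)  # 1/µm
    ratio = vesicle_sv / cell.sv_ratio
    feasible = (1.0 / factor) <= ratio <= factor
    return SoleMechanismVerdict(
        cell_sv=cell.sv_ratio,
        vesicle_sv=vesicle_sv,
        ratio=ratio,
        feasible=feasible,
    )
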