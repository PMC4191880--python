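"""Paired reticulocyte/mature-population statistics of RBC maturation.

A cohort of subjects each contributes paired means: the mean cell volume,
Hb mass, and Hb concentration ([Hb]) of their reticulocytes (cells <~2 days
old) and of their total circulating RBC population.  The difference between
the two is the per-subject maturation loss (volume, Hb mass) or gain ([Hb]).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

QUANTITIES = ("volume", "hb", "conc")

#: physiological [Hb] range in g/dL; values outside trigger a warning
CONC_RANGE_GDL = (20.0, 50.0)


@dataclass(frozen=True)
class SubjectSummary:
    """Paired reticulocyte/total-population means for one subject.

    Volumes in fl, Hb masses in pg, concentrations in g/dL.
    """

    subject_id: str
    retic_volume: float
    total_volume: float
    retic_hb: float
    total_hb: float
    retic_conc: float
    total_conc: float

    def __post_init__(self) -> None:
        vals = (
            self.retic_volume,
            self.total_volume,
            self.retic_hb,
            self.total_hb,
            self.retic_conc,
            self.total_conc,
        )
        if any(v <= 0 for v in vals):
            raise ValueError(
                f"subject {self.subject_id}: all quantities must be positive"
            )
        if self.retic_volume <= self.total_volume or self.retic_hb <= self.total_hb:
            warnings.warn(
                f"subject {self.subject_id}: reticulocyte volume/Hb not above "
                "total-population mean (atypical for healthy donors)",
                stacklevel=2,
            )
        lo, hi = CONC_RANGE_GDL
        for name, c in (("retic", self.retic_conc), ("total", self.total_conc)):
            if not lo <= c <= hi:
                warnings.warn(
                    f"subject {self.subject_id}: {name} [Hb] {c} g/dL outside "
                    f"physiological range [{lo}, {hi}]",
                    stacklevel=2,
                )

    def delta(self, quantity: str) -> float:
        """Maturation change, oriented so that the healthy-donor sign is
        positive: loss for volume/hb, gain for conc."""
        if quantity == "volume":
            return self.retic_volume - self.total_volume
        if quantity == "hb":
            return self.retic_hb - self.total_hb
        if quantity == "conc":
            return self.total_conc - self.retic_conc
        raise ValueError(f"unknown quantity {quantity!r}; expected {QUANTITIES}")

    def pct_change(self, quantity: str) -> float:
        """Signed percent change (X − X0)/X0 × 100 with X0 the reticulocyte
        (initial) value: negative for losses, positive for gains."""
        if quantity == "volume":
            x0, x = self.retic_volume, self.total_volume
        elif quantity == "hb":
            x0, x = self.retic_hb, self.total_hb
        elif quantity == "conc":
            x0, x = self.retic_conc, self.total_conc
        else:
            raise ValueError(f"unknown quantity {quantity!r}; expected {QUANTITIES}")
        return (x - x0) / x0 * 100.0


@dataclass(frozen=True)
class MaturationDelta:
    """Cohort-level maturation change for one quantity.

    ``mean_change`` is the mean per-subject difference (oriented as a
    loss for volume/hb and a gain for conc, matching how the magnitudes
    are conventionally reported); ``pct_change`` is the signed mean of the
    per-subject relative changes.
    """

    quantity: str
    mean_change: float
    ci_low: float
    ci_high: float
    pct_change: float
    n: int

    def __post_init__(self) -> None:
        if not self.ci_low <= self.mean_change <= self.ci_high:
            raise ValueError("confidence interval must bracket the mean")


def maturation_deltas(
    subjects: Sequence[SubjectSummary],
    quantity: str,
    confidence: float = 0.95,
) -> MaturationDelta:
    """Mean maturation change with a Student-t confidence interval.

    The CI is a t interval with n−1 degrees of freedom on the per-subject
    paired differences.  ``pct_change`` averages the per-subject relative
    changes (not the ratio of cohort means).

    Parameters
    ----------
    subjects : sequence of SubjectSummary
        At least two subjects.
    quantity : {"volume", "hb", "conc"}
    confidence : float
        Two-sided confidence level, in (0, 1).
    """
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects for a cohort delta")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie in (0, 1)")
    diffs = np.array([s.delta(quantity) for s in subjects])
    pcts = np.array([s.pct_change(quantity) for s in subjects])
    n = len(diffs)
    mean = float(diffs.mean())
    se = float(diffs.std(ddof=1)) / np.sqrt(n)
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, n - 1)
    return MaturationDelta(
        quantity=quantity,
        mean_change=mean,
        ci_low=mean - tcrit * se,
        ci_high=mean + tcrit * se,
        pct_change=float(pcts.mean()),
        n=n,
    )


def maturation_report(
    subjects: Sequence[SubjectSummary], confidence: float = 0.95
):
    """Cohort maturation summary across all three quantities.

    Returns a DataFrame with one row per quantity, values at full precision
    (round only for display).
    """
    import pandas as pd

    rows = []
    labels = {
        "volume": ("Volume lost", "fl"),
        "hb": ("Hb mass lost", "pg"),
        "conc": ("[Hb] increase", "g/dL"),
    }
    for q in QUANTITIES:
        d = maturation_deltas(subjects, q, confidence)
        name, unit = labels[q]
        rows.append(
            {
                "quantity": q,
                "label": name,
                "unit": unit,
                "mean_change": d.mean_change,
                "ci_low": d.ci_low,
                "ci_high": d.ci_high,
                "pct_change": d.pct_change,
                "n": d.n,
            }
        )
    return pd.DataFrame(rows)


def format_report(report, decimals: int = 1) -> str:
    """Human-readable rendering of :func:`maturation_report` output."""
    lines = []
    for _, r in report.iterrows():
        lines.append(
            f"{r['label']:<14} {r['mean_change']:.{decimals}f} ({r['unit']})  "
            f"95% CI ({r['ci_low']:.{decimals}f}, {r['ci_high']:.{decimals}f})  "
            f"{r['pct_change']:+.{decimals}f}%"
        )
    return "\n".join(lines)
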