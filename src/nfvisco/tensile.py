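"""Stress-strain curve assembly and strain-rate-dependent stiffness.

Unfolding and stretching of the pulled sidearm overlap throughout the
tensile test, so no automatic changepoint detection is attempted: the
stiffness of a curve is an ordinary least-squares slope over a
user-specified strain window.  Comparing the windows across nominal
pulling rates quantifies the qualitative observation that the filament is
stiffer at higher strain rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AlignmentError, InsufficientDataError, ParameterError
from .models import (
    GroupStressSeries,
    StiffnessEstimate,
    StrainSeries,
    StressStrainCurve,
)

#: default reporting windows per nominal rate: the recorded strain ranges are
#: ~220% at 1e8/s and ~360% at 1e9/s
DEFAULT_WINDOWS = {1e8: (0.0, 2.17), 1e9: (0.0, 3.6)}


def build_curve(
    stress: GroupStressSeries,
    strain: StrainSeries,
    rate: float,
    label: str = "synthetic",
) -> StressStrainCurve:
    """Pair axial stress with strain on the strain series' time grid.

    If the grids coincide the series are zipped; otherwise stress is
    linearly interpolated onto the strain grid over the overlapping time
    range.  Disjoint or empty time ranges raise :class:`AlignmentError`.
    """
    if len(stress) == 0 or len(strain) == 0:
        raise AlignmentError("cannot build a curve from an empty series")
    t_lo = max(stress.time[0], strain.time[0])
    t_hi = min(stress.time[-1], strain.time[-1])
    if t_lo > t_hi:
        raise AlignmentError(
            f"stress ({stress.time[0]}..{stress.time[-1]} ps) and strain "
            f"({strain.time[0]}..{strain.time[-1]} ps) time ranges are disjoint"
        )
    if len(stress) == len(strain) and np.array_equal(stress.time, strain.time):
        eps, sig = strain.strain, stress.axial_stress
    else:
        mask = (strain.time >= t_lo) & (strain.time <= t_hi)
        eps = strain.strain[mask]
        sig = np.interp(strain.time[mask], stress.time, stress.axial_stress)
    order = np.argsort(eps, kind="stable")
    return StressStrainCurve(
        strain=eps[order], stress=sig[order], strain_rate=rate, label=label
    )


def stiffness(
    curve: StressStrainCurve, window: tuple[float, float]
) -> StiffnessEstimate:
    """OLS slope/intercept of stress vs strain over a strain window (GPa)."""
    lo, hi = window
    if lo >= hi:
        raise ParameterError(f"window must satisfy lo < hi, got {window}")
    mask = (curve.strain >= lo) & (curve.strain <= hi)
    n = int(mask.sum())
    if n < 3:
        raise InsufficientDataError(
            f"need >= 3 points inside window {window}, found {n}"
        )
    x, y = curve.strain[mask], curve.stress[mask]
    fit = stats.linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    return StiffnessEstimate(
        window=(float(lo), float(hi)),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_points=n,
    )


@dataclass(frozen=True)
class RateComparison:
    """Stiffness per curve sorted by nominal rate, with ordering diagnostics."""

    table: pd.DataFrame  # columns: label, strain_rate, slope, ...
    monotone: bool  # stiffness non-decreasing with rate across distinct rates
    violations: tuple[tuple[float, float], ...]  # (lower rate, higher rate) pairs
    ties: tuple[float, ...]  # rates shared by more than one curve


def compare_rates(
    curves: list[StressStrainCurve], window: tuple[float, float] | None = None
) -> RateComparison:
    """Stiffness per curve, sorted by nominal strain rate.

    All curves are fitted over a common window (default: the intersection
    of their strain ranges).  Curves sharing a nominal rate are kept as
    separate labeled rows, never merged; the monotonicity check then uses
    the mean stiffness per distinct rate.
    """
    if len(curves) < 2:
        raise ParameterError("need at least two curves to compare rates")
    if window is None:
        lo = max(c.strain[0] for c in curves)
        hi = min(c.strain[-1] for c in curves)
        if lo >= hi:
            raise AlignmentError("curves have no common strain window")
        window = (lo, hi)

    rows = []
    for c in sorted(curves, key=lambda c: c.strain_rate):
        est = stiffness(c, window)
        rows.append(
            {
                "label": c.label,
                "strain_rate_per_s": c.strain_rate,
                "slope_GPa": est.slope,
                "intercept_GPa": est.intercept,
                "residual_rms_GPa": est.residual_rms,
                "n_points": est.n_points,
            }
        )
    table = pd.DataFrame(rows)

    by_rate = table.groupby("strain_rate_per_s")["slope_GPa"].mean()
    rates = by_rate.index.to_numpy()
    slopes = by_rate.to_numpy()
    violations = tuple(
        (float(rates[i]), float(rates[i + 1]))
        for i in range(len(rates) - 1)
        if slopes[i + 1] < slopes[i]
    )
    tie_counts = table["strain_rate_per_s"].value_counts()
    ties = tuple(float(r) for r in tie_counts.index[tie_counts > 1])
    return RateComparison(
        table=table,
        monotone=not violations,
        violations=violations,
        ties=ties,
    )
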