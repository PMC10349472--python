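"""Cutinase activity quantification from photometric assay data.

The assay follows hydrolysis of 4-nitrophenyl palmitate: released
4-nitrophenol absorbs at 410 nm, so the initial rate of absorbance
increase is proportional to enzymatic activity. One unit (U) is the
amount of enzyme converting 1 µmol of substrate per minute; activities
are reported per assay volume as

    EA [U/mL] = dA410/dt [a.u./min] * (1 / m_standard [a.u./mM]) * DF

with m_standard the slope of a 4-nitrophenol standard curve from linear
regression and DF the unitless supernatant dilution factor. The unit
audit: (a.u./min) * (mM/a.u.) = mM/min = µmol/(mL*min) = U/mL.

The standard curve is fitted with an intercept, so a constant blank in
the standards does not bias the slope; likewise the kinetic slope is an
OLS slope over the initial linear window, insensitive to constant blank
offsets. The linear window defaults to the first 10 reads or the longest
prefix with R^2 >= 0.995, whichever is shorter, which excises the
saturating tail when substrate or chromophore limits the reaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mass_balance import ParameterError

__all__ = [
    "StandardCurve",
    "ActivityResult",
    "fit_standard_curve",
    "kinetic_slope",
    "activity",
    "aggregate",
    "technical_duplicate_error",
]


@dataclass(frozen=True)
class StandardCurve:
    """Linear 4-nitrophenol standard: absorbance = m*conc + intercept."""

    m_standard: float          # a.u. per mM
    intercept: float           # a.u.
    r_squared: float
    points: tuple[tuple[float, float], ...]  # (concentration mM, absorbance)

    @property
    def valid(self) -> bool:
        return self.m_standard > 0


@dataclass(frozen=True)
class ActivityResult:
    """One activity determination with its replicate lineage."""

    EA_U_per_mL: float
    dA410_per_min: float
    DF: float
    m_standard: float
    clamped: bool = False      # True if a negative raw EA was reported as 0
    lineage: Mapping[str, object] = field(default_factory=dict)


def fit_standard_curve(
    points: Sequence[tuple[float, float]] | pd.DataFrame,
) -> StandardCurve:
    """Ordinary least squares fit of absorbance against concentration.

    ``points`` is a sequence of (concentration_mM, absorbance) pairs or a
    DataFrame with columns ``concentration_mM`` and ``absorbance``. At
    least three points over at least two distinct concentrations are
    required.
    """
    if isinstance(points, pd.DataFrame):
        conc = points["concentration_mM"].to_numpy(dtype=float)
        absb = points["absorbance"].to_numpy(dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("points must be (concentration, absorbance) pairs")
        conc, absb = arr[:, 0], arr[:, 1]
    if len(conc) < 3:
        raise ValueError(f"need >= 3 standard points, got {len(conc)}")
    if np.ptp(conc) == 0:
        raise ValueError("all standard concentrations identical: rank-deficient")
    res = stats.linregress(conc, absb)
    return StandardCurve(
        m_standard=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        points=tuple(zip(conc.tolist(), absb.tolist())),
    )


def _prefix_r2(t: np.ndarray, a: np.ndarray) -> float:
    """R^2 of the OLS line through the given prefix; 1.0 for flat data."""
    sst = float(np.sum((a - a.mean()) ** 2))
    if sst < 1e-300:
        return 1.0
    res = stats.linregress(t, a)
    pred = res.intercept + res.slope * t
    return 1.0 - float(np.sum((a - pred) ** 2)) / sst


def kinetic_slope(
    kinetics: pd.DataFrame,
    max_window: int = 10,
    r2_min: float = 0.995,
) -> float:
    """Initial-rate slope dA410/dt in a.u./min over the linear prefix.

    ``kinetics`` must hold columns ``time_min`` and ``absorbance`` for one
    well, time-sorted. The fit window is the first ``max_window`` reads or
    the longest prefix (>= 3 reads) whose OLS fit keeps R^2 >= ``r2_min``,
    whichever is shorter. If even the first 3 reads break the R^2 rule the
    3-read slope is returned (there is no shorter defensible window).
    """
    t = kinetics["time_min"].to_numpy(dtype=float)
    a = kinetics["absorbance"].to_numpy(dtype=float)
    if len(t) < 3:
        raise ValueError(f"need >= 3 reads, got {len(t)}")
    order = np.argsort(t)
    t, a = t[order], a[order]
    window = 3
    for w in range(3, min(max_window, len(t)) + 1):
        if _prefix_r2(t[:w], a[:w]) >= r2_min:
            window = w
        else:
            break
    return float(stats.linregress(t[:window], a[:window]).slope)


def activity(
    dA410_per_min: float,
    curve: StandardCurve,
    DF: float = 1.0,
    lineage: Mapping[str, object] | None = None,
) -> ActivityResult:
    """Enzymatic activity EA = dA410 * (1/m_standard) * DF, in U/mL.

    A negative kinetic slope (downward drift of a blank-level read) would
    yield a negative activity; it is reported as 0 with ``clamped=True``
    since negative enzyme activity is not physical.
    """
    if curve.m_standard <= 0:
        raise ParameterError(
            f"standard slope must be > 0, got {curve.m_standard}"
        )
    if DF < 1:
        raise ParameterError(f"dilution factor must be >= 1, got {DF}")
    ea = dA410_per_min / curve.m_standard * DF
    clamped = ea < 0
    return ActivityResult(
        EA_U_per_mL=max(ea, 0.0),
        dA410_per_min=float(dA410_per_min),
        DF=float(DF),
        m_standard=curve.m_standard,
        clamped=bool(clamped),
        lineage=dict(lineage or {}),
    )


def technical_duplicate_error(values: Sequence[float]) -> tuple[float, float]:
    """Centre and error measure for a technical duplicate.

    Returns (mean, half the absolute difference) — the per-batch display
    convention for duplicate measurements.
    """
    if len(values) != 2:
        raise ValueError(f"expected exactly 2 values, got {len(values)}")
    a, b = float(values[0]), float(values[1])
    return (a + b) / 2.0, abs(a - b) / 2.0


def aggregate(
    results: Sequence[ActivityResult] | pd.DataFrame,
    grouping: Sequence[str] = ("strain", "iptg_uM"),
) -> pd.DataFrame:
    """Mean, SD and n of activities per replicate group.

    Accepts either :class:`ActivityResult` objects (their lineage fields
    become columns) or a DataFrame with an ``activity_U_per_mL`` column.
    For groups of size 2 (technical duplicates) the reported error is half
    the absolute difference; larger groups report the sample SD.
    """
    if isinstance(results, pd.DataFrame):
        df = results.copy()
        value_col = "activity_U_per_mL"
    else:
        if not results:
            raise ValueError("no activity results to aggregate")
        df = pd.DataFrame(
            [{**r.lineage, "activity_U_per_mL": r.EA_U_per_mL} for r in results]
        )
        value_col = "activity_U_per_mL"
    missing = set(grouping) - set(df.columns)
    if missing:
        raise ValueError(f"grouping keys absent from lineage: {sorted(missing)}")
    if df.empty:
        raise ValueError("no activity results to aggregate")

    def _stats(g: pd.Series) -> pd.Series:
        vals = g.to_numpy(dtype=float)
        if len(vals) == 2:
            err = abs(vals[0] - vals[1]) / 2.0
        elif len(vals) > 2:
            err = float(np.std(vals, ddof=1))
        else:
            err = 0.0
        return pd.Series({"mean_U_per_mL": float(np.mean(vals)),
                          "sd_U_per_mL": err, "n": len(vals)})

    out = (
        df.groupby(list(grouping))[value_col]
        .apply(_stats)
        .unstack()
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out
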