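"""Relative cross-coalescence rate curves and divergence-time estimates.

MSMC-style rate tables carry time in scaled units (per-site mutation
units) and coalescence rates lambda on the matching inverse scale.
Conversions use a per-year mutation rate nu and generation time g, with
the per-generation rate mu = nu * g:

    years = scaled_time / nu          diploid N_e = (1 / lambda) / (2 mu)

The relative cross-coalescence rate in a bin is

    RCCR = 2 lambda_cross / (lambda_within_1 + lambda_within_2),

close to 1 while the two populations still share a panmictic ancestor and
dropping to 0 after complete separation. The divergence time is the first
present-to-past upcrossing of 0.5 (with 0.25 and 0.75 crossings bracketing
it), located by linear interpolation between bin-midpoint times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class ScalingParams:
    """Mutation-rate scaling: nu per site per year, g years per generation."""

    nu: float = 4.3e-10
    g: float = 29.0

    def __post_init__(self) -> None:
        if self.nu <= 0 or self.g <= 0:
            raise ValueError("nu and g must be positive")

    @property
    def mu(self) -> float:
        """Per-generation mutation rate, mu = nu * g."""
        return self.nu * self.g


@dataclass
class RateCurve:
    """Binned coalescence rates for within-pop-1, cross, within-pop-2 pairs.

    Boundaries are in scaled time and must be strictly increasing; rates
    are non-negative with NaN marking bins with no information.
    """

    left: np.ndarray
    right: np.ndarray
    lam_within1: np.ndarray
    lam_cross: np.ndarray
    lam_within2: np.ndarray

    def __post_init__(self) -> None:
        for name in ("left", "right", "lam_within1", "lam_cross", "lam_within2"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.left.size
        if any(getattr(self, f).size != n for f in ("right", "lam_within1", "lam_cross", "lam_within2")):
            raise ValueError("all rate-curve columns must have equal length")
        if np.any(self.right <= self.left):
            raise ValueError("bin boundaries must satisfy left < right")
        if np.any(np.diff(self.left) <= 0) or np.any(self.right[:-1] > self.left[1:] + 1e-12 * np.abs(self.left[1:])):
            raise ValueError("bins must be non-overlapping and increasing")
        for f in ("lam_within1", "lam_cross", "lam_within2"):
            v = getattr(self, f)
            if np.any(v[~np.isnan(v)] < 0):
                raise ValueError("rates must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.left.size

    def midpoints(self, open_ended_last: bool = True) -> np.ndarray:
        """Representative bin times: arithmetic midpoints; the last bin of an
        open-ended curve is represented by its left boundary."""
        mid = 0.5 * (self.left + self.right)
        if open_ended_last and np.isinf(self.right[-1]):
            mid[-1] = self.left[-1]
        return mid


def write_rate_table(curve: RateCurve, path: str | Path) -> None:
    """MSMC final-rate text layout: time_index, boundaries, lambda_00/01/11."""
    with open(path, "w") as fh:
        fh.write("time_index\tleft_time_boundary\tright_time_boundary\tlambda_00\tlambda_01\tlambda_11\n")
        for i in range(curve.n_bins):
            vals = (curve.left[i], curve.right[i], curve.lam_within1[i],
                    curve.lam_cross[i], curve.lam_within2[i])
            fh.write(f"{i}\t" + "\t".join(repr(float(v)) for v in vals) + "\n")


def read_rate_table(path: str | Path) -> RateCurve:
    """Parse a whitespace-delimited MSMC-style final-rate table.

    Rows must be in time order with strictly increasing boundaries;
    shuffled or malformed files are rejected.
    """
    df = pd.read_csv(path, sep=r"\s+")
    expected = ["time_index", "left_time_boundary", "right_time_boundary", "lambda_00", "lambda_01", "lambda_11"]
    if list(df.columns) != expected:
        raise ValueError(f"rate table must have columns {expected}, got {list(df.columns)}")
    if not np.array_equal(df["time_index"].to_numpy(), np.arange(len(df))):
        raise ValueError("rate table rows out of order (time_index must be 0..n-1)")
    return RateCurve(
        df["left_time_boundary"].to_numpy(),
        df["right_time_boundary"].to_numpy(),
        df["lambda_00"].to_numpy(),
        df["lambda_01"].to_numpy(),
        df["lambda_11"].to_numpy(),
    )


@dataclass
class RccrCurve:
    """Per-bin RCCR with bin times carried from the source rate curve."""

    left: np.ndarray
    right: np.ndarray
    values: np.ndarray  # NaN where undefined (zero within-rate sum)

    def midpoints(self) -> np.ndarray:
        mid = 0.5 * (self.left + self.right)
        if np.isinf(self.right[-1]):
            mid[-1] = self.left[-1]
        return mid


def compute_rccr(curve: RateCurve) -> RccrCurve:
    """RCCR = 2 lambda_cross / (lambda_within_1 + lambda_within_2) per bin.

    Bins where the within-rate sum is zero (or any input NaN) are flagged
    undefined; values above 1 from estimation noise are retained.
    """
    wsum = curve.lam_within1 + curve.lam_within2
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = 2.0 * curve.lam_cross / wsum
    vals = np.where(wsum == 0, np.nan, vals)
    if np.all(np.isnan(vals)):
        raise ValueError("RCCR undefined in every bin")
    return RccrCurve(curve.left.copy(), curve.right.copy(), vals)


def scale_time(scaled_time, params: ScalingParams):
    """Scaled (per-site mutation) time -> years: t / nu (== t * g / mu)."""
    return np.asarray(scaled_time, dtype=float) / params.nu


def scale_ne(lam, params: ScalingParams):
    """Scaled coalescence rate -> diploid effective size: (1/lambda) / (2 mu)."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("coalescence rate must be positive to invert to N_e")
    return (1.0 / lam) / (2.0 * params.mu)


@dataclass
class DivergenceEstimate:
    """Threshold-crossing times in years (NaN where the curve never crosses)."""

    t25: float
    t50: float
    t75: float
    extra_crossings: dict = field(default_factory=dict)

    def report(self) -> str:
        """Divergence line in the '~t50 (t75–t25) kya' reporting convention."""

        def kya(t):
            return "NA" if np.isnan(t) else f"{t / 1000.0:.0f}"

        return f"~{kya(self.t50)} ({kya(self.t75)}–{kya(self.t25)}) kya"


def crossing_time(times: np.ndarray, values: np.ndarray, threshold: float) -> tuple[float, list[float]]:
    """First present-to-past upcrossing of ``threshold``, linearly interpolated.

    ``times`` ascend from present to past. Requires the curve to sit below
    the threshold at its most recent defined point; returns NaN when it
    never rises through the threshold. Additional later upcrossings are
    returned for logging, not reporting.
    """
    ok = ~np.isnan(values)
    t, v = times[ok], values[ok]
    if t.size < 2:
        return float("nan"), []
    crossings = []
    for k in range(t.size - 1):
        if v[k] < threshold <= v[k + 1]:
            frac = (threshold - v[k]) / (v[k + 1] - v[k])
            crossings.append(float(t[k] + frac * (t[k + 1] - t[k])))
    if not crossings or v[0] >= threshold:
        return float("nan"), crossings
    return crossings[0], crossings[1:]


def divergence_estimate(
    rccr: RccrCurve,
    params: ScalingParams,
    thresholds: tuple[float, float, float] = (0.25, 0.5, 0.75),
) -> DivergenceEstimate:
    """Threshold crossings of the RCCR curve, converted to years."""
    times = rccr.midpoints()
    out = {}
    extras = {}
    for th in thresholds:
        t, rest = crossing_time(times, rccr.values, th)
        out[th] = float(scale_time(t, params)) if not np.isnan(t) else float("nan")
        if rest:
            extras[th] = [float(scale_time(r, params)) for r in rest]
    return DivergenceEstimate(
        t25=out.get(0.25, float("nan")),
        t50=out.get(0.5, float("nan")),
        t75=out.get(0.75, float("nan")),
        extra_crossings=extras,
    )
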