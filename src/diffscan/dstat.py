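"""The per-site, per-group d statistic and empirical outlier calling.

For a focal group i the statistic sums, over every other group j, the
squared deviation of the site's pairwise F_ST from that pair's genome-wide
mean, divided by the pair's genome-wide standard deviation:

    d_i = sum_{j != i} (F_ST(i,j) - E[F_ST(i,j)])^2 / sd[F_ST(i,j)]

Note the numerator is squared while the sd in the denominator is not; the
classic unsquared standardized sum (sum of (F - E)/sd) is available via
``squared=False`` for comparison but is off by default.

Large d flags sites unusually differentiated in the focal group relative
to the genome-wide background of every pair involving it.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .fst import PairFstTable

logger = logging.getLogger(__name__)


class DScanError(RuntimeError):
    """Raised when a group's scan cannot proceed (e.g. a degenerate pair sd)."""


def d_values(
    table: PairFstTable,
    summary: pd.DataFrame,
    group: str,
    squared: bool = True,
) -> np.ndarray:
    """Per-site d for ``group``; NaN where any required pair is undefined.

    A pair with sd == 0 (or unusable moments) makes the whole scan for this
    group meaningless, so it aborts with a diagnostic naming the pair.
    """
    if group not in table.groups:
        raise KeyError(f"unknown group {group!r}")
    d = np.zeros(table.values.shape[0])
    undef = np.zeros(table.values.shape[0], dtype=bool)
    summ = summary.set_index(["group_i", "group_j"])
    for other in table.groups:
        if other == group:
            continue
        k = table.pair_index(group, other)
        gi, gj = table.pairs[k]
        row = summ.loc[(gi, gj)]
        if not bool(row["usable"]) or row["sd_fst"] == 0 or np.isnan(row["sd_fst"]):
            raise DScanError(
                f"pair ({gi}, {gj}) has degenerate F_ST moments "
                f"(sd={row['sd_fst']!r}); cannot standardize d for group {group!r}"
            )
        v = table.values[:, k]
        dev = v - row["mean_fst"]
        term = dev**2 / row["sd_fst"] if squared else dev / row["sd_fst"]
        undef |= np.isnan(v)
        d += np.where(np.isnan(term), 0.0, term)
    d[undef] = np.nan
    n_undef = int(undef.sum())
    if n_undef:
        logger.info("group %s: %d sites dropped (undefined pair F_ST)", group, n_undef)
    return d


def percentiles(d: np.ndarray) -> np.ndarray:
    """Percent of variants with a strictly higher d; NaN-preserving.

    0 for the single largest value, approaching 100 for the smallest.
    """
    out = np.full(d.shape, np.nan)
    ok = ~np.isnan(d)
    v = d[ok]
    order = np.sort(v)
    # number strictly greater = n - rank of rightmost occurrence
    n_higher = v.size - np.searchsorted(order, v, side="right")
    out[ok] = 100.0 * n_higher / v.size
    return out


def call_outliers(d: np.ndarray, top_fraction: float = 0.001) -> np.ndarray:
    """Sites strictly above the (1 - top_fraction) empirical d quantile.

    The threshold is the order statistic at rank n - floor(n * top_fraction);
    with no ties this selects exactly floor(n * top_fraction) sites. Ties at
    the threshold are all excluded (conservative).
    """
    ok = ~np.isnan(d)
    n = int(ok.sum())
    out = np.zeros(d.shape, dtype=bool)
    if n == 0:
        return out
    if n < 1.0 / top_fraction:
        warnings.warn(
            f"only {n} defined d values for top_fraction={top_fraction}; "
            "outlier threshold is degenerate",
            stacklevel=2,
        )
    k = int(np.floor(n * top_fraction))
    if k == 0:
        return out
    v = d[ok]
    thr = np.partition(v, n - k - 1)[n - k - 1]
    n_ties = int((v == thr).sum()) + int((v > thr).sum()) - k
    if n_ties > 0:
        logger.info("outlier threshold ties excluded: %d values at %g", n_ties, thr)
    out[ok] = v > thr
    return out


def d_table(
    table: PairFstTable,
    summary: pd.DataFrame,
    top_fraction: float = 0.001,
    squared: bool = True,
) -> dict[str, pd.DataFrame]:
    """Per-group table of chrom, pos, d, percentile and outlier flag."""
    out: dict[str, pd.DataFrame] = {}
    for g in table.groups:
        d = d_values(table, summary, g, squared=squared)
        out[g] = pd.DataFrame(
            {
                "chrom": table.chrom,
                "pos": table.pos,
                "d": d,
                "percentile": percentiles(d),
                "outlier": call_outliers(d, top_fraction),
            }
        )
    return out
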