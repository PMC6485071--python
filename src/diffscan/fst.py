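"""Per-site pairwise F_ST between meta-ancestry groups.

The estimator is Hudson's per-site F_ST with unbiased (n-1 corrected)
within-group heterozygosity, the standard small-sample-adjusted choice:

    F_ST = [ (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1) ]
           / [ p1(1-p2) + p2(1-p1) ]

with p the alternate-allele frequency and n the number of called alleles
(2 x non-missing diploids) in each group. Negative per-site values are
retained deliberately: the d statistic standardizes each pair against its
own genome-wide mean and standard deviation, and clipping would bias both.
Sites monomorphic for the same allele in both groups have a zero
denominator and are undefined for that pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix


def missingness_filter(gm: GenotypeMatrix, max_missing: float = 0.20) -> np.ndarray:
    """Boolean site mask: retained iff missing fraction <= max_missing in EVERY group.

    The criterion is per group, not overall: a single group exceeding the
    threshold drops the site even when all other groups are complete.
    """
    keep = np.ones(gm.n_sites, dtype=bool)
    miss = gm.missing_mask()
    for g, idx in gm.group_indices().items():
        frac = miss[:, idx].mean(axis=1)
        keep &= frac <= max_missing
    return keep


def allele_counts(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per site x group (called allele count, alternate allele count).

    Called counts are 2 x the number of non-missing diploid calls, hence
    always even; allele counts are the sufficient statistic for F_ST.
    """
    groups = gm.group_names
    n_sites = gm.n_sites
    called = np.zeros((n_sites, len(groups)), dtype=np.int64)
    alt = np.zeros((n_sites, len(groups)), dtype=np.int64)
    for k, (g, idx) in enumerate(gm.group_indices().items()):
        sub = gm.dosages[:, idx]
        present = sub != MISSING
        called[:, k] = 2 * present.sum(axis=1)
        alt[:, k] = np.where(present, sub, 0).sum(axis=1)
    return called, alt


def _hudson(p1, n1, p2, n2):
    """Vectorized Hudson F_ST; NaN where undefined (zero denominator or n<2)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        out = num / den
    out = np.where((den == 0) | (n1 < 2) | (n2 < 2), np.nan, out)
    return out


def hudson_fst(p1, n1, p2, n2):
    """Hudson per-site F_ST for allele frequencies p and called-allele counts n.

    Raises on n < 2 (the unbiased heterozygosity needs at least two called
    alleles); returns NaN when both groups are monomorphic for the same
    allele (denominator zero).
    """
    if np.any(np.asarray(n1) < 2) or np.any(np.asarray(n2) < 2):
        raise ValueError("hudson_fst requires at least 2 called alleles per group")
    res = _hudson(p1, n1, p2, n2)
    if np.ndim(res) == 0:
        return float(res)
    return res


@dataclass
class PairFstTable:
    """Per-site F_ST for every unordered group pair over the retained sites.

    ``values`` is sites x pairs with NaN flagging undefined entries;
    ``pairs`` lists (group_i, group_j) tuples in sorted-group order.
    """

    chrom: np.ndarray
    pos: np.ndarray
    groups: list[str]
    pairs: list[tuple[str, str]]
    values: np.ndarray

    def pair_index(self, gi: str, gj: str) -> int:
        key = tuple(sorted((gi, gj)))
        for k, p in enumerate(self.pairs):
            if tuple(sorted(p)) == key:
                return k
        raise KeyError(f"no pair {gi}/{gj}")


def pairwise_fst(gm: GenotypeMatrix, site_mask: np.ndarray | None = None) -> PairFstTable:
    """Hudson F_ST for all group pairs at the retained sites."""
    if site_mask is not None:
        gm = gm.subset_sites(site_mask)
    groups = gm.group_names
    called, alt = allele_counts(gm)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(called > 0, alt / np.maximum(called, 1), np.nan)
    pairs = list(combinations(groups, 2))
    vals = np.empty((gm.n_sites, len(pairs)))
    for k, (gi, gj) in enumerate(pairs):
        i, j = groups.index(gi), groups.index(gj)
        vals[:, k] = _hudson(freq[:, i], called[:, i], freq[:, j], called[:, j])
    return PairFstTable(gm.chrom, gm.pos, groups, pairs, vals)


def pair_summaries(table: PairFstTable) -> pd.DataFrame:
    """Genome-wide mean, sample sd (n-1), and site count per group pair.

    Undefined per-site values are excluded. Pairs with fewer than two
    defined sites are flagged unusable (``usable`` = False); their moments
    are NaN.
    """
    rows = []
    for k, (gi, gj) in enumerate(table.pairs):
        v = table.values[:, k]
        v = v[~np.isnan(v)]
        usable = v.size >= 2
        rows.append(
            {
                "group_i": gi,
                "group_j": gj,
                "mean_fst": float(np.mean(v)) if usable else np.nan,
                "sd_fst": float(np.std(v, ddof=1)) if usable else np.nan,
                "n_sites": int(v.size),
                "usable": usable,
            }
        )
    return pd.DataFrame(rows)
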