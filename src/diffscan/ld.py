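"""LD clumping of outliers and selection-window construction.

r^2 is the squared Pearson correlation of genotype dosages over
pairwise-complete samples (composite LD on unphased calls). Clumping is
the greedy index-variant procedure: candidates passing the stringent
percentile cutoff are visited in order of increasing percentile
(decreasing d, lower coordinate first on ties); each unclaimed index
claims every unclaimed variant passing the lenient cutoff within the
distance window and above the r^2 threshold. Selection windows span, for
each tag, all variants within the distance horizon in strong LD with it;
overlapping windows are merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING


def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared dosage correlation over pairwise-complete samples.

    NaN when fewer than 2 complete pairs or either vector is constant.
    """
    return float(genotype_r2_many(x, np.atleast_2d(y))[0])


def genotype_r2_many(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """r^2 of one dosage vector against each row of ``Y`` (pairwise-complete).

    Vectorized masked-moment computation; NaN where fewer than 2 complete
    pairs or a vector is constant over the complete pairs.
    """
    x = np.asarray(x, dtype=float)
    Y = np.asarray(Y, dtype=float)
    vx = (x != MISSING) & ~np.isnan(x)
    VY = (Y != MISSING) & ~np.isnan(Y)
    M = VY & vx[None, :]
    c = M.sum(axis=1).astype(float)
    xz = np.where(vx, x, 0.0)
    Yz = np.where(VY, Y, 0.0)
    sx = M @ xz
    sy = (Yz * M).sum(axis=1)
    sxx = M @ (xz * xz)
    syy = (Yz * Yz * M).sum(axis=1)
    sxy = (Yz * M * xz[None, :]).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sxy / c - (sx / c) * (sy / c)
        varx = sxx / c - (sx / c) ** 2
        vary = syy / c - (sy / c) ** 2
        r2 = cov * cov / (varx * vary)
    # dosages are O(1), so variance below 1e-12 is numerically constant
    bad = (c < 2) | (varx <= 1e-12) | (vary <= 1e-12)
    return np.where(bad, np.nan, r2)


@dataclass
class Clump:
    """One LD clump: the tag (index) variant plus its claimed members."""

    tag: int  # variant index into the input arrays
    members: list[int] = field(default_factory=list)
    member_r2: list[float] = field(default_factory=list)


def clump(
    percentile: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    dosages: np.ndarray,
    p1: float = 0.001,
    p2: float = 0.01,
    window_kb: float = 1000.0,
    r2_thresh: float = 0.5,
) -> list[Clump]:
    """Greedy LD clumping of ranked variants.

    ``percentile`` is the fraction of variants with a higher d (so
    p1=0.001 selects the top 0.1% as candidate index variants and p2=0.01
    the top 1% as claimable members). Distances are measured tag-to-member.
    """
    percentile = np.asarray(percentile, dtype=float)
    pos = np.asarray(pos, dtype=np.int64)
    chrom = np.asarray(chrom, dtype=object)
    n = percentile.size
    if not (len(chrom) == len(pos) == n and dosages.shape[0] == n):
        raise ValueError("percentile/chrom/pos/dosages site dimensions disagree")
    window_bp = int(round(window_kb * 1000))

    cand1 = percentile < p1
    cand2 = percentile < p2
    # canonical order: percentile, then position (lower coordinate on ties)
    order = np.lexsort((pos, _chrom_rank(chrom), percentile))
    claimed = np.zeros(n, dtype=bool)
    clumps: list[Clump] = []
    for i in order:
        if not cand1[i] or claimed[i]:
            continue
        claimed[i] = True
        c = Clump(tag=int(i))
        near = np.flatnonzero(
            ~claimed
            & cand2
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= window_bp)
        )
        if near.size:
            r2s = genotype_r2_many(dosages[i], dosages[near])
            for j, r2 in zip(near, r2s):
                if not np.isnan(r2) and r2 > r2_thresh:
                    claimed[j] = True
                    c.members.append(int(j))
                    c.member_r2.append(float(r2))
        clumps.append(c)
    return clumps


def _chrom_rank(chrom: np.ndarray) -> np.ndarray:
    uniq = sorted(set(chrom.tolist()))
    lut = {c: k for k, c in enumerate(uniq)}
    return np.array([lut[c] for c in chrom], dtype=np.int64)


def ld_partners(
    tag: int,
    chrom: np.ndarray,
    pos: np.ndarray,
    dosages: np.ndarray,
    ld_thresh: float = 0.8,
    horizon: int = 1_000_000,
) -> np.ndarray:
    """Indices of variants within the horizon and r^2 > ld_thresh with the tag.

    The tag itself is always included.
    """
    pos = np.asarray(pos, dtype=np.int64)
    chrom = np.asarray(chrom, dtype=object)
    near = np.flatnonzero((chrom == chrom[tag]) & (np.abs(pos - pos[tag]) <= horizon))
    r2s = genotype_r2_many(dosages[tag], dosages[near])
    hits = near[(~np.isnan(r2s)) & (r2s > ld_thresh)].tolist()
    return np.unique(hits + [tag])


def selection_windows(
    tags: list[int] | np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    dosages: np.ndarray,
    ld_thresh: float = 0.8,
    horizon: int = 1_000_000,
) -> pd.DataFrame:
    """Merged genomic intervals spanning each tag's strong-LD partners.

    Returns a BED-style frame (chrom, start, end, n_tags) in 0-based
    half-open coordinates. A tag with no LD partners yields a 1-bp
    interval at its own position. Overlapping intervals are merged.
    """
    pos = np.asarray(pos, dtype=np.int64)
    chrom = np.asarray(chrom, dtype=object)
    raw = []
    for t in tags:
        part = ld_partners(int(t), chrom, pos, dosages, ld_thresh, horizon)
        lo, hi = pos[part].min(), pos[part].max()
        raw.append((chrom[t], int(lo) - 1, int(hi)))  # 1-based span -> BED
    return merge_intervals(pd.DataFrame(raw, columns=["chrom", "start", "end"]))


def merge_intervals(bed: pd.DataFrame) -> pd.DataFrame:
    """Merge strictly overlapping half-open intervals per chromosome."""
    out = []
    for c, sub in bed.groupby("chrom", sort=True):
        sub = sub.sort_values(["start", "end"])
        cur_s = cur_e = None
        n = 0
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e, n = s, e, 1
            elif s < cur_e:  # half-open: touching intervals do not overlap
                cur_e = max(cur_e, e)
                n += 1
            else:
                out.append((c, cur_s, cur_e, n))
                cur_s, cur_e, n = s, e, 1
        if cur_s is not None:
            out.append((c, cur_s, cur_e, n))
    return pd.DataFrame(out, columns=["chrom", "start", "end", "n_tags"])


def clump_table(
    clumps: list[Clump], chrom: np.ndarray, pos: np.ndarray, d: np.ndarray
) -> pd.DataFrame:
    """Flat TSV-ready view of a clump result (tag rows with member lists)."""
    rows = []
    for c in clumps:
        rows.append(
            {
                "tag_chrom": chrom[c.tag],
                "tag_pos": int(pos[c.tag]),
                "tag_d": float(d[c.tag]),
                "n_members": len(c.members),
                "member_pos": ",".join(str(int(pos[m])) for m in c.members),
            }
        )
    return pd.DataFrame(rows)
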