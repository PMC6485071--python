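"""Independent oracles used to check the implementation.

Everything here is deliberately written from first principles (quadrature,
exhaustive enumeration, naive loops) rather than calling into the package,
so agreement between the two routes is informative.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, stats


# ---------------------------------------------------------------------------
# Balding-Nichols expected mean per-site Hudson F_ST
# ---------------------------------------------------------------------------

def bn_expected_mean_fst(
    F: float,
    n_diploids: int,
    freq_range: tuple[float, float] = (0.05, 0.95),
    n_outer: int = 20_000,
    seed: int = 987_654_321,
) -> float:
    """E[mean per-site Hudson F_ST over defined sites] under the generative model.

    Monte Carlo over (ancestral p, group frequencies q1, q2), with the
    binomial allele-count sampling integrated exactly by enumerating all
    (k1, k2) outcomes. Sites undefined for the estimator (both groups
    monomorphic for the same allele) are excluded, mirroring the
    retained-site mean: E[F 1_def] / E[1_def].
    """
    rng = np.random.default_rng(seed)
    n_alleles = 2 * n_diploids
    p = rng.uniform(*freq_range, n_outer)
    a = p * (1 - F) / F
    b = (1 - p) * (1 - F) / F
    q1 = rng.beta(a, b)
    q2 = rng.beta(a, b)

    k = np.arange(n_alleles + 1)
    ph = k / n_alleles
    p1g, p2g = np.meshgrid(ph, ph, indexing="ij")
    m = n_alleles - 1
    num = (p1g - p2g) ** 2 - p1g * (1 - p1g) / m - p2g * (1 - p2g) / m
    den = p1g * (1 - p2g) + p2g * (1 - p1g)
    defined = den != 0
    fmat = np.where(defined, num / np.where(defined, den, 1.0), 0.0)

    pmf1 = stats.binom.pmf(k[None, :], n_alleles, q1[:, None])
    pmf2 = stats.binom.pmf(k[None, :], n_alleles, q2[:, None])
    e_f = np.einsum("ik,kl,il->i", pmf1, fmat * defined, pmf2)
    e_def = np.einsum("ik,kl,il->i", pmf1, defined.astype(float), pmf2)
    return float(e_f.sum() / e_def.sum())


# ---------------------------------------------------------------------------
# Clean-split coalescent: closed-form binned hazards and RCCR crossing
# ---------------------------------------------------------------------------

def split_survival_within(t, T, N_deme, N_anc):
    t = np.asarray(t, dtype=float)
    early = np.exp(-t / (2 * N_deme))
    late = np.exp(-T / (2 * N_deme)) * np.exp(-(t - T) / (2 * N_anc))
    return np.where(t <= T, early, late)


def split_survival_cross(t, T, N_anc):
    t = np.asarray(t, dtype=float)
    return np.where(t <= T, 1.0, np.exp(-(t - T) / (2 * N_anc)))


def binned_hazard_from_survival(survival, edges) -> np.ndarray:
    """Expected binned hazard: (S(a) - S(b)) / integral_a^b S(t) dt per bin."""
    edges = np.asarray(edges, dtype=float)
    out = np.empty(edges.size - 1)
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        mass = float(survival(lo) - survival(hi))
        expo, _ = integrate.quad(lambda t: float(survival(t)), lo, hi, limit=400)
        out[i] = mass / expo if expo > 0 else np.nan
    return out


def closed_form_rccr_crossing(
    T: float, N_deme: float, N_anc: float, edges, threshold: float = 0.5
) -> float:
    """Exact binned-hazard RCCR threshold crossing (generations).

    Uses bin-midpoint linear interpolation on the exact per-bin hazards,
    coded independently of the package's crossing routine.
    """
    hw = binned_hazard_from_survival(
        lambda t: split_survival_within(t, T, N_deme, N_anc), edges
    )
    hc = binned_hazard_from_survival(lambda t: split_survival_cross(t, T, N_anc), edges)
    rccr = 2 * hc / (hw + hw)
    edges = np.asarray(edges, dtype=float)
    mids = 0.5 * (edges[:-1] + edges[1:])
    ok = ~np.isnan(rccr)
    mids, rccr = mids[ok], rccr[ok]
    if rccr[0] >= threshold:
        return float("nan")
    for i in range(rccr.size - 1):
        if rccr[i] < threshold <= rccr[i + 1]:
            f = (threshold - rccr[i]) / (rccr[i + 1] - rccr[i])
            return float(mids[i] + f * (mids[i + 1] - mids[i]))
    return float("nan")


# ---------------------------------------------------------------------------
# Brute-force LD clump / window re-derivation
# ---------------------------------------------------------------------------

def pearson_r2(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (x >= 0) & (y >= 0)
    xs, ys = x[ok], y[ok]
    if xs.size < 2 or xs.std() == 0 or ys.std() == 0:
        return float("nan")
    c = float(np.mean((xs - xs.mean()) * (ys - ys.mean())) / (xs.std() * ys.std()))
    return c * c


def brute_force_clump(percentile, chrom, pos, dosages, p1, p2, window_bp, r2_thresh):
    """Naive re-derivation of the greedy clump rule; returns [(tag, members)]."""
    n = len(percentile)
    order = sorted(range(n), key=lambda i: (percentile[i], str(chrom[i]), pos[i]))
    claimed = [False] * n
    result = []
    for i in order:
        if percentile[i] >= p1 or claimed[i]:
            continue
        claimed[i] = True
        members = []
        for j in range(n):
            if claimed[j] or percentile[j] >= p2:
                continue
            if chrom[j] != chrom[i] or abs(int(pos[j]) - int(pos[i])) > window_bp:
                continue
            r2 = pearson_r2(dosages[i], dosages[j])
            if not np.isnan(r2) and r2 > r2_thresh:
                claimed[j] = True
                members.append(j)
        result.append((i, sorted(members)))
    return result


def brute_force_windows(tags, chrom, pos, dosages, ld_thresh, horizon):
    """Naive tag-span computation + merge; returns [(chrom, start, end)] BED."""
    spans = []
    for t in tags:
        hits = [int(pos[t])]
        for j in range(len(pos)):
            if j == t or chrom[j] != chrom[t] or abs(int(pos[j]) - int(pos[t])) > horizon:
                continue
            r2 = pearson_r2(dosages[t], dosages[j])
            if not np.isnan(r2) and r2 > ld_thresh:
                hits.append(int(pos[j]))
        spans.append((chrom[t], min(hits) - 1, max(hits)))
    spans.sort(key=lambda s: (str(s[0]), s[1], s[2]))
    merged = []
    for c, s, e in spans:
        if merged and merged[-1][0] == c and s < merged[-1][2]:
            merged[-1] = (c, merged[-1][1], max(merged[-1][2], e))
        else:
            merged.append((c, s, e))
    return merged


# ---------------------------------------------------------------------------
# Exact enumeration for the circular-shift permutation test
# ---------------------------------------------------------------------------

def exact_shift_p(loci_local, observed: int) -> float:
    """Exact P(score >= observed) under independent uniform integer shifts.

    ``loci_local`` is a list of (snp_rel, intervals, span_length) with
    0-based relative SNP positions and [(a, b), ...] relative intervals.
    Per locus the overlap probability over all span offsets is exact; the
    score is Poisson-binomial, convolved by dynamic programming.
    """
    qs = []
    for snp_rel, intervals, L in loci_local:
        hits = 0
        for o in range(L):
            ok = any(
                a <= (r - o) % L < b for r in snp_rel for (a, b) in intervals
            )
            hits += ok
        qs.append(hits / L)
    dist = np.array([1.0])
    for q in qs:
        dist = np.convolve(dist, [1 - q, q])
    return float(dist[observed:].sum())
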