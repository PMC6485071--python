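"""Synthetic data with known ground truth for every pipeline stage.

Two generators are provided. The first draws multi-group genotype
matrices under the Balding–Nichols model: each site has an ancestral
frequency p, each group's frequency is Beta-distributed with mean p and
variance p(1-p)F (so F directly controls between-group differentiation),
and genotypes are binomial draws from the group frequency. Optional
"spike-ins" shift the focal group's frequency at chosen sites to plant
high-differentiation loci with recorded ground truth. The second samples
pairwise coalescence times under a clean two-deme split (panmictic demes
of size N_deme merging into an ancestor of size N_anc at T_split
generations), which is the simplest model with a known cross-coalescence
signal for divergence-time recovery.

A single global seed fans out to per-stage substreams so each stage can
be rerun independently and reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix
from .rccr import RateCurve, ScalingParams


@dataclass
class SpikeConfig:
    """Planted high-differentiation sites in one focal group.

    ``freq_shift`` is added to the focal group's Balding–Nichols frequency
    (clamped to [0, 1]) before genotypes are drawn.
    """

    n_spiked: int
    focal_group: str
    freq_shift: float

    def __post_init__(self) -> None:
        if not 0 < self.freq_shift <= 1:
            raise ValueError("freq_shift must be in (0, 1]")
        if self.n_spiked < 1:
            raise ValueError("n_spiked must be >= 1")


@dataclass
class BNConfig:
    """Balding–Nichols genotype-matrix configuration.

    ``F`` may be a single value shared by all groups or one value per
    group, each strictly inside (0, 1). The ancestral frequency is drawn
    uniformly inside ``ancestral_freq_range`` (default (0.05, 0.95), which
    avoids near-fixed sites and keeps F_ST moments stable). Missingness is
    applied independently per genotype call.
    """

    n_groups: int
    samples_per_group: int
    n_sites: int
    F: float | tuple[float, ...] = 0.03
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.0
    spike: SpikeConfig | None = None
    seed: int = 0
    chrom: str = "1"
    pos_spacing: int = 1000

    def __post_init__(self) -> None:
        if self.n_groups < 2 or self.samples_per_group < 1 or self.n_sites < 1:
            raise ValueError("need >=2 groups, >=1 sample/group, >=1 site")
        F = self.F if np.ndim(self.F) else (float(self.F),) * self.n_groups
        F = tuple(float(f) for f in np.atleast_1d(np.asarray(F, dtype=float)))
        if len(F) != self.n_groups:
            raise ValueError("F must be scalar or one value per group")
        if any(not 0 < f < 1 for f in F):
            raise ValueError("all F must be in (0, 1) (F >= 1 degenerates the Beta)")
        self.F = F
        lo, hi = self.ancestral_freq_range
        if not (0 < lo < hi < 1):
            raise ValueError("ancestral_freq_range must be inside (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.spike is not None and self.spike.n_spiked > self.n_sites:
            raise ValueError("n_spiked cannot exceed n_sites")

    @property
    def group_names(self) -> list[str]:
        return [f"G{k + 1}" for k in range(self.n_groups)]


def simulate_genotypes(config: BNConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Balding–Nichols genotypes plus a spiked-site truth table.

    The truth table has one row per spiked site (empty without a spike),
    recording the ancestral frequency and the focal group's frequency
    before and after the shift.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_freq, rng_geno, rng_miss, rng_spike = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    groups = config.group_names
    lo, hi = config.ancestral_freq_range
    p_anc = rng_freq.uniform(lo, hi, size=config.n_sites)

    # group frequencies: Beta with mean p, variance p(1-p)F
    q = np.empty((config.n_sites, config.n_groups))
    for k, f in enumerate(config.F):
        alpha = p_anc * (1 - f) / f
        beta = (1 - p_anc) * (1 - f) / f
        q[:, k] = rng_freq.beta(alpha, beta)

    spiked_sites = np.array([], dtype=np.int64)
    truth_rows = []
    if config.spike is not None:
        sp = config.spike
        if sp.focal_group not in groups:
            raise ValueError(f"unknown focal group {sp.focal_group!r}")
        k = groups.index(sp.focal_group)
        spiked_sites = np.sort(
            rng_spike.choice(config.n_sites, size=sp.n_spiked, replace=False)
        )
        base = q[spiked_sites, k].copy()
        q[spiked_sites, k] = np.clip(base + sp.freq_shift, 0.0, 1.0)
        for s, b in zip(spiked_sites, base):
            truth_rows.append(
                {
                    "site_index": int(s),
                    "chrom": config.chrom,
                    "pos": int((s + 1) * config.pos_spacing),
                    "ancestral_freq": float(p_anc[s]),
                    "focal_group": sp.focal_group,
                    "base_focal_freq": float(b),
                    "spiked_focal_freq": float(q[s, k]),
                }
            )

    n_per = config.samples_per_group
    dosages = np.empty((config.n_sites, config.n_groups * n_per), dtype=np.int8)
    for k in range(config.n_groups):
        cols = slice(k * n_per, (k + 1) * n_per)
        dosages[:, cols] = rng_geno.binomial(2, q[:, k][:, None], size=(config.n_sites, n_per))
    if config.missing_rate > 0:
        miss = rng_miss.random(dosages.shape) < config.missing_rate
        dosages[miss] = MISSING

    samples = [f"{g}_s{i + 1:03d}" for g in groups for i in range(n_per)]
    group_map = {s: s.split("_")[0] for s in samples}
    pos = (np.arange(config.n_sites, dtype=np.int64) + 1) * config.pos_spacing
    gm = GenotypeMatrix(
        dosages,
        np.array([config.chrom] * config.n_sites, dtype=object),
        pos,
        samples,
        group_map,
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "site_index", "chrom", "pos", "ancestral_freq",
            "focal_group", "base_focal_freq", "spiked_focal_freq",
        ],
    )
    return gm, truth


def block_copy_variants(
    gm: GenotypeMatrix,
    source_index: int,
    n_copies: int,
    flip_prob: float = 0.0,
    spacing: int = 100,
    seed: int = 0,
) -> GenotypeMatrix:
    """Insert noisy copies of one site's genotypes to create a known LD block.

    Balding–Nichols sites are independent, so LD fixtures are built by
    duplicating a column: each copy flips every call (dosage -> 2 - dosage)
    independently with probability ``flip_prob``, degrading r^2 in a
    controlled way. Copies are placed at ``spacing``-bp steps after the
    source position; the result is re-sorted by position.
    """
    rng = np.random.default_rng(seed)
    src = gm.dosages[source_index]
    new_rows, new_pos = [], []
    for c in range(n_copies):
        row = src.copy()
        flip = (row != MISSING) & (rng.random(row.shape) < flip_prob)
        row[flip] = 2 - row[flip]
        new_rows.append(row)
        new_pos.append(int(gm.pos[source_index]) + (c + 1) * spacing)
    dosages = np.vstack([gm.dosages, np.array(new_rows, dtype=np.int8)])
    chrom = np.concatenate([gm.chrom, [gm.chrom[source_index]] * n_copies])
    pos = np.concatenate([gm.pos, np.array(new_pos, dtype=np.int64)])
    order = np.lexsort((pos, np.array([str(c) for c in chrom])))
    return GenotypeMatrix(dosages[order], chrom[order], pos[order], list(gm.samples), dict(gm.groups))


@dataclass
class SplitConfig:
    """Clean two-deme population split for pairwise coalescence sampling.

    Times are in generations; sizes are diploid. ``time_bins`` are the
    increasing bin edges (starting at 0) used to estimate binned hazards.
    """

    T_split: float
    N_deme: float
    N_anc: float
    n_pairs: int
    time_bins: np.ndarray | list[float]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T_split < 0:
            raise ValueError("T_split must be >= 0")
        if self.N_deme <= 0 or self.N_anc <= 0:
            raise ValueError("population sizes must be positive")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        edges = np.asarray(self.time_bins, dtype=float)
        if edges.size < 2 or edges[0] != 0 or np.any(np.diff(edges) <= 0):
            raise ValueError("time_bins must be strictly increasing edges from 0")
        self.time_bins = edges


@dataclass
class CoalescenceSamples:
    """Pairwise coalescence times (generations) for the three pair categories."""

    within1: np.ndarray
    within2: np.ndarray
    cross: np.ndarray


def simulate_pair_coalescence(config: SplitConfig) -> CoalescenceSamples:
    """Sample pair coalescence times under the clean split.

    Within a deme the pair coalesces at rate 1/(2 N_deme) until T_split,
    then at rate 1/(2 N_anc) in the merged ancestor. A cross-deme pair
    cannot coalesce before T_split and is exponential with rate
    1/(2 N_anc) thereafter.
    """
    ss = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(3)]
    T, n = config.T_split, config.n_pairs

    def within(rng):
        t = rng.exponential(2 * config.N_deme, size=n)
        late = t > T
        t[late] = T + rng.exponential(2 * config.N_anc, size=int(late.sum()))
        return t

    cross = T + rngs[2].exponential(2 * config.N_anc, size=n)
    return CoalescenceSamples(within(rngs[0]), within(rngs[1]), cross)


def rates_from_times(times: np.ndarray, time_bins: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned hazard: coalescences per unit lineage-pair exposure in each bin.

    A pair still uncoalesced through a bin contributes the full bin width
    of exposure; a pair coalescing mid-bin contributes exposure up to its
    coalescence time (exact within-bin survival accounting). Bins with zero
    exposure get NaN hazard. Returns (hazard, counts, exposure).
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("need at least one coalescence-time sample")
    edges = np.asarray(time_bins, dtype=float)
    left, right = edges[:-1], edges[1:]
    counts = np.histogram(times, bins=edges)[0].astype(float)
    # exposure of each pair in bin [a, b) = clip(min(t, b) - a, 0, b - a)
    exposure = np.clip(np.minimum(times[:, None], right[None, :]) - left[None, :], 0, None).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        hazard = counts / exposure
    hazard = np.where(exposure == 0, np.nan, hazard)
    return hazard, counts, exposure


def rate_curve_from_samples(
    samples: CoalescenceSamples,
    time_bins: np.ndarray,
    scaling: ScalingParams | None = None,
) -> RateCurve:
    """MSMC-style scaled rate curve from raw coalescence-time samples.

    Generation-unit times and per-generation hazards are converted to the
    scaled units of the rate-table format (time x mu, hazard / mu) so that
    synthetic and real rate tables are consumed identically downstream.
    """
    scaling = scaling or ScalingParams()
    edges = np.asarray(time_bins, dtype=float)
    h1, _, _ = rates_from_times(samples.within1, edges)
    hc, _, _ = rates_from_times(samples.cross, edges)
    h2, _, _ = rates_from_times(samples.within2, edges)
    mu = scaling.mu
    return RateCurve(edges[:-1] * mu, edges[1:] * mu, h1 / mu, hc / mu, h2 / mu)
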