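"""End-to-end orchestration: filter -> F_ST -> d -> outliers -> clump ->
windows -> enrichment, with a reproducibility manifest.

Stage parameter defaults are the study's stated values: 20% per-group
missingness ceiling, top 0.1% outliers, clumping at 0.001/0.01 with a
1000-kb window and r^2 > 0.5, selection windows from r^2 > 0.8 partners
within 1 Mb, 10,000 shift permutations, FWER 0.05, nu = 4.3e-10/year and
g = 29 years.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dstat import d_table
from .enrichment import build_loci, enrich_categories, load_bed
from .fst import missingness_filter, pair_summaries, pairwise_fst
from .io import read_vcf, sha256_file, write_bed, write_table
from .ld import clump, clump_table, selection_windows

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters plus inputs; defaults are the study's values."""

    vcf: str = ""
    groups: str = ""
    out_dir: str = "diffscan_out"
    annotations: list[str] = field(default_factory=list)
    max_missing: float = 0.20
    top_fraction: float = 0.001
    squared_d: bool = True
    clump_p1: float = 0.001
    clump_p2: float = 0.01
    clump_kb: float = 1000.0
    clump_r2: float = 0.5
    window_r2: float = 0.8
    window_horizon: int = 1_000_000
    locus_pad: int = 50_000
    n_perm: int = 10_000
    fwer_alpha: float = 0.05
    nu: float = 4.3e-10
    g: float = 29.0
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (0 <= self.max_missing < 1, "max_missing in [0,1)"),
            (0 < self.top_fraction < 1, "top_fraction in (0,1)"),
            (0 < self.clump_p1 <= self.clump_p2 < 1, "clump_p1 <= clump_p2 in (0,1)"),
            (0 < self.clump_r2 <= 1 and 0 < self.window_r2 <= 1, "r2 thresholds in (0,1]"),
            (self.n_perm >= 1, "n_perm >= 1"),
            (0 < self.fwer_alpha < 1, "fwer_alpha in (0,1)"),
            (self.nu > 0 and self.g > 0, "nu and g positive"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: expected {msg}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full selection scan; returns the manifest dict.

    Writes per-stage TSV/BED outputs plus ``manifest.json`` into
    ``config.out_dir``. With a fixed seed and inputs, all stage outputs are
    byte-identical across runs (the manifest's timestamp is the one
    intentionally non-reproducible field).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    def fail(stage, exc):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    try:
        gm, skipped = read_vcf(config.vcf, config.groups)
    except Exception as exc:  # noqa: BLE001
        fail("read_vcf", exc)
    counts["sites_input"] = gm.n_sites
    counts.update({f"skipped_{k}": v for k, v in skipped.items()})

    try:
        keep = missingness_filter(gm, config.max_missing)
    except Exception as exc:  # noqa: BLE001
        fail("missingness_filter", exc)
    counts["sites_retained"] = int(keep.sum())
    counts["sites_dropped_missingness"] = int((~keep).sum())
    logger.info(
        "missingness filter: %d in = %d retained + %d dropped",
        counts["sites_input"], counts["sites_retained"], counts["sites_dropped_missingness"],
    )

    try:
        table = pairwise_fst(gm, keep)
        summary = pair_summaries(table)
    except Exception as exc:  # noqa: BLE001
        fail("fst", exc)
    write_table(
        summary, out / "fst_pair_summary.tsv",
        "per-pair genome-wide Hudson F_ST moments over retained sites",
    )

    try:
        dtabs = d_table(table, summary, config.top_fraction, config.squared_d)
    except Exception as exc:  # noqa: BLE001
        fail("d_scan", exc)

    retained = gm.subset_sites(keep)
    windows_all = []
    for g, dt in dtabs.items():
        write_table(dt, out / f"d_{g}.tsv", f"d statistic for focal group {g}")
        counts[f"outliers_{g}"] = int(dt["outlier"].sum())
        try:
            clumps = clump(
                dt["percentile"].to_numpy() / 100.0,
                retained.chrom, retained.pos, retained.dosages,
                config.clump_p1, config.clump_p2, config.clump_kb, config.clump_r2,
            )
        except Exception as exc:  # noqa: BLE001
            fail(f"clump[{g}]", exc)
        write_table(
            clump_table(clumps, retained.chrom, retained.pos, dt["d"].to_numpy()),
            out / f"clumps_{g}.tsv", f"LD clumps for focal group {g}",
        )
        counts[f"clumps_{g}"] = len(clumps)
        tags = [c.tag for c in clumps]
        if tags:
            try:
                win = selection_windows(
                    tags, retained.chrom, retained.pos, retained.dosages,
                    config.window_r2, config.window_horizon,
                )
            except Exception as exc:  # noqa: BLE001
                fail(f"windows[{g}]", exc)
            write_bed(win, out / f"windows_{g}.bed", f"merged selection windows, group {g}")
            win = win.assign(group=g)
            windows_all.append(win)

        if config.annotations and tags:
            try:
                loci = build_loci(
                    tags, retained.chrom, retained.pos, retained.dosages,
                    config.window_r2, config.window_horizon, config.locus_pad,
                )
                tracks = [load_bed(p) for p in config.annotations]
                enr = enrich_categories(
                    loci, tracks, config.n_perm,
                    seed=config.seed + _stable_offset(g), alpha=config.fwer_alpha,
                )
            except Exception as exc:  # noqa: BLE001
                fail(f"enrichment[{g}]", exc)
            write_table(enr, out / f"enrichment_{g}.tsv", f"annotation-shift enrichment, group {g}")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "inputs": {
            p: sha256_file(p)
            for p in [config.vcf, config.groups, *config.annotations]
            if p and Path(p).exists()
        },
        "counts": counts,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _stable_offset(name: str) -> int:
    # deterministic per-group seed offset, independent of hash randomization
    return sum((i + 1) * ord(c) for i, c in enumerate(name)) % 100_000
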