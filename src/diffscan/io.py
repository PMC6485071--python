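"""Genotype container and file formats.

Coordinate conventions are fixed package-wide and converted only here:
variant tables carry 1-based positions (VCF convention); every interval
output is 0-based half-open BED. Chromosome names pass through verbatim —
no ``chr`` prefix normalization is attempted.
"""

from __future__ import annotations

import hashlib
import io as _io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix over biallelic SNPs.

    ``dosages`` is sites x samples with values in {0, 1, 2} counting
    alternate alleles, and -1 marking a missing call. Positions are
    1-based. Every sample must be assigned to exactly one group.
    """

    dosages: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    samples: list[str]
    groups: dict[str, str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (sites x samples)")
        n_sites, n_samples = self.dosages.shape
        if len(self.chrom) != n_sites or len(self.pos) != n_sites:
            raise ValueError("chrom/pos length must match number of sites")
        if len(self.samples) != n_samples:
            raise ValueError("sample list length must match dosage columns")
        bad = set(np.unique(self.dosages)) - {-1, 0, 1, 2}
        if bad:
            raise ValueError(f"invalid dosage values: {sorted(bad)}")
        missing_assignment = [s for s in self.samples if s not in self.groups]
        if missing_assignment:
            raise ValueError(f"samples without group assignment: {missing_assignment}")

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    @property
    def group_names(self) -> list[str]:
        return sorted({self.groups[s] for s in self.samples})

    def group_indices(self) -> dict[str, np.ndarray]:
        """Column indices of each group's samples, keyed by group name."""
        out: dict[str, np.ndarray] = {}
        for g in self.group_names:
            out[g] = np.array(
                [i for i, s in enumerate(self.samples) if self.groups[s] == g],
                dtype=np.int64,
            )
            if out[g].size == 0:
                raise ValueError(f"group {g!r} has no samples")
        return out

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            self.dosages[mask],
            self.chrom[mask],
            self.pos[mask],
            list(self.samples),
            dict(self.groups),
        )

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING


def write_group_table(groups: dict[str, str], path: str | Path, samples=None) -> None:
    """Two-column sample -> group TSV with header."""
    samples = list(samples) if samples is not None else sorted(groups)
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for s in samples:
            fh.write(f"{s}\t{groups[s]}\n")


def read_group_table(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample", "group"]:
        raise ValueError("group table must have columns 'sample' and 'group'")
    return dict(zip(df["sample"], df["group"]))


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Minimal GT-only biallelic-SNP VCF (``./.`` for missing calls)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(gm.chrom):  # insertion order, dedup
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for i in range(gm.n_sites):
            gts = "\t".join(_GT_STRINGS[int(d)] for d in gm.dosages[i])
            fh.write(f"{gm.chrom[i]}\t{gm.pos[i]}\t.\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path: str | Path, group_tsv: str | Path) -> tuple[GenotypeMatrix, dict]:
    """Load biallelic SNP genotypes from a VCF plus a sample->group table.

    Multiallelic and non-SNP records are skipped; counts of skipped records
    are returned alongside the matrix.
    """
    from cyvcf2 import VCF

    groups = read_group_table(group_tsv)
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    unassigned = [s for s in samples if s not in groups]
    if unassigned:
        raise ValueError(f"VCF samples missing from group table: {unassigned}")

    dosage_rows, chroms, positions = [], [], []
    skipped = {"multiallelic": 0, "non_snp": 0}
    for variant in vcf:
        if len(variant.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        if len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            skipped["non_snp"] += 1
            continue
        gt = variant.gt_types.astype(np.int8)  # 0/1/2, 3 = unknown
        gt[gt == 3] = MISSING
        dosage_rows.append(gt)
        chroms.append(variant.CHROM)
        positions.append(variant.POS)
    vcf.close()

    dos = np.array(dosage_rows, dtype=np.int8) if dosage_rows else np.empty((0, len(samples)), np.int8)
    gm = GenotypeMatrix(dos, np.array(chroms, dtype=object), np.array(positions), samples, groups)
    return gm, skipped


def write_bed(intervals: pd.DataFrame, path: str | Path, comment: str | None = None) -> None:
    """Write 0-based half-open intervals as BED (chrom, start, end first)."""
    with open(path, "w") as fh:
        fh.write("# coordinates: 0-based half-open (BED)\n")
        if comment:
            fh.write(f"# {comment}\n")
        intervals.to_csv(fh, sep="\t", header=False, index=False)


def write_table(df: pd.DataFrame, path: str | Path, comment: str | None = None) -> None:
    """TSV with a leading comment header stating the coordinate convention."""
    with open(path, "w") as fh:
        fh.write("# positions: 1-based (VCF)\n")
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
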