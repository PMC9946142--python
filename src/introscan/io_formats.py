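"""Readers and writers for the tabular and variant formats the pipeline touches.

Coordinate conventions are fixed package-wide: everything internal and every
BED-style output is 0-based half-open; VCF input positions are 1-based and
converted on read.  Chromosome names must match exactly across inputs — no
aliasing is attempted, because silently mismatched naming is the dominant
failure mode when mixing window tables, VCFs and gene coordinate files.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from math import isnan
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .segments import SegmentBlock

log = logging.getLogger(__name__)

HITS_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

_BASES = {"A", "C", "G", "T"}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GenomicWindow:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(f"window {self.chrom}:{self.start}-{self.end} has start >= end")


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNP call: 1-based VCF position, single-base alleles."""
    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str  # 'hom_alt' | 'het'
    depth: int | None = None


@dataclass
class WindowCountTable:
    """Per-window mapped-read counts for one sample plus its genome-wide total.

    ``frame`` has columns chrom, start, end, count.  The total is the mapped
    read count post duplicate removal for the whole sample (supplied via a
    manifest when the windows do not tile the full genome); it defaults to
    the sum of the window counts.
    """

    frame: pd.DataFrame
    total_reads: int

    def __post_init__(self) -> None:
        f = self.frame
        missing = [c for c in ("chrom", "start", "end", "count") if c not in f.columns]
        if missing:
            raise FormatError(f"window table missing columns {missing}")
        if len(f) and (f["start"] >= f["end"]).any():
            bad = f.index[f["start"] >= f["end"]][0]
            raise FormatError(f"window row {bad}: start >= end")
        if len(f) and (f["count"] < 0).any():
            bad = f.index[f["count"] < 0][0]
            raise FormatError(f"window row {bad}: negative count")
        if len(f) and (f["count"] > self.total_reads).any():
            raise FormatError("window count exceeds total_reads")
        for chrom, grp in f.groupby("chrom"):
            s = grp.sort_values("start")
            if (s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]).any():
                raise FormatError(f"overlapping windows on {chrom}")

    def grid(self) -> pd.DataFrame:
        return self.frame[["chrom", "start", "end"]]


def make_windows(chrom_lengths: Mapping[str, int], width: int) -> pd.DataFrame:
    """Tile each chromosome with half-open windows of ``width`` bp; the last
    window of a chromosome may be short."""
    rows = []
    for chrom in chrom_lengths:
        length = int(chrom_lengths[chrom])
        for start in range(0, length, width):
            rows.append((chrom, start, min(start + width, length)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def read_window_counts(
    path: str | Path,
    total_reads: int | None = None,
    has_header: bool = True,
) -> WindowCountTable:
    """Read a TSV of per-window counts (chrom, start, end, count).

    ``total_reads`` comes from the sample manifest when available; otherwise
    the window counts are summed.  Malformed rows raise :class:`FormatError`
    naming the offending line.
    """
    path = Path(path)
    names = None if has_header else ["chrom", "start", "end", "count"]
    try:
        frame = pd.read_csv(path, sep="\t", header=0 if has_header else None,
                            names=names, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        frame = pd.DataFrame(columns=["chrom", "start", "end", "count"])
    if list(frame.columns) != ["chrom", "start", "end", "count"]:
        raise FormatError(
            f"{path}: expected columns chrom/start/end/count, got {list(frame.columns)}"
        )
    offset = 2 if has_header else 1
    for col in ("start", "end", "count"):
        converted = pd.to_numeric(frame[col], errors="coerce")
        if converted.isna().any():
            line = int(frame.index[converted.isna()][0]) + offset
            raise FormatError(f"{path}:{line}: non-numeric {col!r}")
        frame[col] = converted.astype(np.int64)
    if total_reads is None:
        total_reads = int(frame["count"].sum())
    return WindowCountTable(frame.reset_index(drop=True), total_reads)


def write_window_counts(table: WindowCountTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def read_vcf_snps(path: str | Path, sample: str | None = None) -> list[SnpRecord]:
    """Read biallelic SNPs for one sample from a VCF.

    GT 1/1 maps to ``hom_alt`` and 0/1 or 1/0 to ``het``; homozygous-reference
    and missing genotypes, indels and multiallelic records are skipped with a
    logged tally.  Site depth is taken from FORMAT/DP when present.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF has no genotype (GT) columns")
    if sample is None:
        if len(samples) != 1:
            raise FormatError(f"{path}: multiple samples; specify one of {samples}")
        idx = 0
    else:
        if sample not in samples:
            raise FormatError(f"{path}: sample {sample!r} not in {samples}")
        idx = samples.index(sample)

    records: list[SnpRecord] = []
    skipped: Counter[str] = Counter()
    for v in vcf:
        if len(v.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        ref, alt = v.REF, v.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            skipped["indel_or_nonacgt"] += 1
            continue
        gt = v.genotypes[idx]
        a, b = gt[0], gt[1]
        if a < 0 or b < 0:
            skipped["missing_gt"] += 1
            continue
        if a == 0 and b == 0:
            skipped["hom_ref"] += 1
            continue
        genotype = "hom_alt" if (a == 1 and b == 1) else "het"
        depth: int | None = None
        dp = v.format("DP")
        if dp is not None:
            d = int(dp[idx][0])
            depth = d if d >= 0 else None
        records.append(SnpRecord(v.CHROM, int(v.POS), ref, alt, genotype, depth))
    if skipped:
        log.info("read_vcf_snps(%s): skipped %s", path, dict(skipped))
    return records


def snps_to_frame(records: Iterable[SnpRecord]) -> pd.DataFrame:
    rows = [(r.chrom, r.pos, r.ref, r.alt, r.genotype, r.depth) for r in records]
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "genotype", "depth"])


def write_snps_vcf(
    snps: pd.DataFrame,
    path: str | Path,
    sample: str,
    chrom_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write SNP records (columns chrom, pos, ref, alt, genotype, depth) as a
    minimal single-sample VCF with GT and DP."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if chrom_lengths:
            for chrom, length in chrom_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={int(length)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        ordered = snps.sort_values(["chrom", "pos"], kind="mergesort")
        for row in ordered.itertuples(index=False):
            gt = "1/1" if row.genotype == "hom_alt" else "0/1"
            dp = "." if row.depth is None or (isinstance(row.depth, float) and isnan(row.depth)) else str(int(row.depth))
            fh.write(
                f"{row.chrom}\t{int(row.pos)}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT:DP\t{gt}:{dp}\n"
            )


SEGMENT_BED_COLUMNS = [
    "chrom", "start", "end", "origin", "zygosity",
    "support_fraction", "hom_snp_density", "hom_het_ratio", "mean_deviation",
]


def write_segments_bed(blocks: Sequence[SegmentBlock], path: str | Path) -> None:
    """Write called blocks as BED6+ (0-based half-open) with a header comment."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(SEGMENT_BED_COLUMNS) + "\n")
        for b in sorted(blocks, key=lambda b: (b.chrom, b.start)):
            fh.write(
                f"{b.chrom}\t{b.start}\t{b.end}\t{b.origin}\t{b.zygosity}\t"
                f"{b.support_fraction:.6g}\t{b.hom_snp_density:.6g}\t"
                f"{b.hom_het_ratio:.6g}\t{b.mean_deviation:.6g}\n"
            )


def read_segments_bed(path: str | Path) -> list[SegmentBlock]:
    blocks: list[SegmentBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(SEGMENT_BED_COLUMNS):
                raise FormatError(f"{path}:{lineno}: expected {len(SEGMENT_BED_COLUMNS)} columns")
            blocks.append(
                SegmentBlock(
                    chrom=parts[0], start=int(parts[1]), end=int(parts[2]),
                    origin=parts[3], zygosity=parts[4],
                    support_fraction=float(parts[5]),
                    hom_snp_density=float(parts[6]),
                    hom_het_ratio=float(parts[7]),
                    mean_deviation=float(parts[8]),
                )
            )
    return blocks


def write_deviation_track(track: pd.DataFrame, path: str | Path) -> None:
    """Write a deviation track as BEDgraph-style TSV (value in column 4,
    chosen parent and window class carried in extra columns)."""
    cols = ["chrom", "start", "end", "deviation"]
    extra = [c for c in ("parent", "label") if c in track.columns]
    track[cols + extra].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_deviation_track(path: str | Path) -> pd.DataFrame:
    track = pd.read_csv(path, sep="\t")
    missing = [c for c in ("chrom", "start", "end", "deviation") if c not in track.columns]
    if missing:
        raise FormatError(f"{path}: deviation track missing columns {missing}")
    return track


def write_snp_profile(profile: pd.DataFrame, path: str | Path) -> None:
    profile[["chrom", "start", "end", "hom", "het"]].to_csv(path, sep="\t", index=False)


def read_snp_profile(path: str | Path) -> pd.DataFrame:
    profile = pd.read_csv(path, sep="\t")
    missing = [c for c in ("chrom", "start", "end", "hom", "het") if c not in profile.columns]
    if missing:
        raise FormatError(f"{path}: SNP profile missing columns {missing}")
    return profile


def write_donor_set(donor_set: Iterable[tuple[str, int, str]], path: str | Path) -> None:
    """Persist a donor-specific SNP set as a sorted 3-column TSV
    (chrom, 1-based position, alt allele)."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\talt\n")
        for chrom, pos, alt in sorted(donor_set):
            fh.write(f"{chrom}\t{pos}\t{alt}\n")


def read_donor_set(path: str | Path) -> set[tuple[str, int, str]]:
    frame = pd.read_csv(path, sep="\t")
    return {(r.chrom, int(r.pos), r.alt) for r in frame.itertuples(index=False)}


def read_hits_table(
    path: str | Path,
    query_lengths: Mapping[str, int] | pd.Series | str | Path | None = None,
) -> pd.DataFrame:
    """Read a 12-column tabular protein-alignment hits file (outfmt-6 layout).

    ``query_lengths`` (mapping, Series, or 2-column TSV of id/length) is
    merged in as a ``qlen`` column, needed for query-coverage filtering.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        frame = pd.DataFrame(columns=range(12))
    if len(frame) and frame.shape[1] != 12:
        raise FormatError(f"{path}: expected 12 columns, found {frame.shape[1]}")
    frame.columns = HITS_COLUMNS
    numeric = ["pident", "length", "mismatch", "gapopen", "qstart", "qend",
               "sstart", "send", "evalue", "bitscore"]
    for col in numeric:
        converted = pd.to_numeric(frame[col], errors="coerce")
        if len(frame) and converted.isna().any():
            line = int(frame.index[converted.isna()][0]) + 1
            raise FormatError(f"{path}:{line}: non-numeric {col!r}")
        frame[col] = converted
    if query_lengths is not None:
        if isinstance(query_lengths, (str, Path)):
            ql = pd.read_csv(query_lengths, sep="\t", header=None,
                             names=["qseqid", "qlen"], dtype={0: str})
            lengths = ql.set_index("qseqid")["qlen"]
        elif isinstance(query_lengths, pd.Series):
            lengths = query_lengths
        else:
            lengths = pd.Series(dict(query_lengths))
        frame["qlen"] = frame["qseqid"].map(lengths)
    return frame


def read_orthogroups(path: str | Path) -> pd.DataFrame:
    """Read an orthogroup membership table (orthogroup, species, gene)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("orthogroup", "species", "gene") if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: orthogroup table missing columns {missing}")
    return frame


def read_triads(path: str | Path) -> pd.DataFrame:
    """Read a homoeologue triad table with gene-id columns A, B, D."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("A", "B", "D") if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: triad table missing columns {missing}")
    return frame


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format differential expression table
    (gene, comparison, log2fc, padj)."""
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in ("gene", "comparison", "log2fc", "padj") if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: DE table missing columns {missing}")
    return frame


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression matrix (first column = gene id)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index.name = "gene"
    return frame


def read_gene_positions(path: str | Path) -> pd.DataFrame:
    """Read gene coordinates from BED (gene id in column 4) or GFF3 (ID= from
    gene features); returns columns gene, chrom, start (0-based)."""
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9 or parts[2] != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                )
                gene = attrs.get("ID")
                if gene is None:
                    raise FormatError(f"{path}: gene feature without ID attribute")
                rows.append((gene, parts[0], int(parts[3]) - 1))
        return pd.DataFrame(rows, columns=["gene", "chrom", "start"])
    frame = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if frame.shape[1] < 4:
        raise FormatError(f"{path}: BED gene file needs >= 4 columns")
    out = frame.iloc[:, [3, 0, 1]].copy()
    out.columns = ["gene", "chrom", "start"]
    out["start"] = out["start"].astype(np.int64)
    return out
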