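"""Synthetic parent/line datasets with planted structural and expression truth.

The generator works at the window-count and SNP-record level — the exact
summaries the detection method consumes — rather than simulating reads.  It
emulates a small hexaploid-like genome (three subgenome chromosomes), wheat
parents sequenced to a configurable depth with Poisson counting noise, a
diverged donor genome carrying species-specific SNPs at a configurable rate,
and an introgression line in which planted events (donor introgressions,
deletions, duplications; homozygous or heterozygous) rescale the wheat read
counts per window.  Donor reads from introgressed segments that aberrantly
map onto wheat background produce heterozygous donor-allele matches at a low
scatter rate, and a small residual mapping rate inside introgressions keeps
deviation near, not exactly at, zero — both mirroring the signatures the
block-assignment rules rely on.

The expression generator emulates homoeologue triads with negative-binomial
counts, donor orthologues replacing introgressed D homoeologues (with
planted fold-change effects), deleted D homoeologues at zero counts, and
differential-expression result tables computed by a per-gene Wald test on
the log2 fold change (using the generative dispersion) with
Benjamini-Hochberg correction — a stand-in with the same table schema as an
external DE engine.

All randomness flows from one seed through named streams, so adding an
output type never perturbs existing ones and a fixed seed is bit-stable.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .config import Thresholds, DEFAULT
from .io_formats import (
    SnpRecord,
    WindowCountTable,
    make_windows,
    snps_to_frame,
    write_segments_bed,
    write_snps_vcf,
    write_window_counts,
)
from .segments import SegmentBlock

_BASES = np.array(["A", "C", "G", "T"])

EVENT_KINDS = ("introgression", "deletion", "duplication")
_ORIGIN_OF_KIND = {
    "introgression": "donor_introgression",
    "deletion": "deletion",
    "duplication": "duplication",
}


def stream(seed: int, name: str) -> np.random.Generator:
    """Named random stream derived from the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


@dataclass(frozen=True)
class PlantedEvent:
    chrom: str
    start: int
    end: int
    kind: str  # introgression | deletion | duplication
    zygosity: str = "hom"  # hom | het

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.zygosity not in ("hom", "het"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if self.end <= self.start:
            raise ValueError("event end must exceed start")

    def truth_block(self) -> SegmentBlock:
        return SegmentBlock(
            chrom=self.chrom,
            start=self.start,
            end=self.end,
            origin=_ORIGIN_OF_KIND[self.kind],
            zygosity="homozygous" if self.zygosity == "hom" else "heterozygous_or_monosomic",
        )


@dataclass(frozen=True)
class ExpressionParams:
    """Study conditions for the expression simulation."""
    n_triads: int = 600
    frac_introgressed: float = 0.25   # leading triads: D replaced by donor gene
    frac_deleted: float = 0.15        # next triads: D homoeologue deleted
    n_reps: int = 3
    dispersion: float = 0.05          # NB dispersion (1/size)
    base_log2_mean: float = 5.5       # log2 of triad mean expression count
    base_log2_sd: float = 1.5
    homoeologue_log2_sd: float = 0.4
    de_fraction: float = 0.25         # introgressed D genes with a planted effect
    down_weight: float = 0.7          # fraction of planted effects downregulated
    lfc_magnitude: tuple[float, float] = (1.5, 3.0)
    identity_range: tuple[float, float] = (85.0, 100.0)
    gene_spacing: int = 50_000
    gene_offset: int = 1_000_000


def _default_events() -> tuple[PlantedEvent, ...]:
    return (
        PlantedEvent("chr1D", 5_000_000, 25_000_000, "introgression", "hom"),
        PlantedEvent("chr1A", 8_000_000, 16_000_000, "deletion", "hom"),
        PlantedEvent("chr1A", 30_000_000, 36_000_000, "deletion", "het"),
        PlantedEvent("chr1B", 12_000_000, 20_000_000, "duplication", "hom"),
    )


@dataclass(frozen=True)
class SimConfig:
    """Simulation conditions: a 3 x 50 Mbp toy hexaploid genome sequenced to
    5x with 150 bp reads, a donor diverged at 5e-3 SNPs/bp, and planted
    events of every class at >= 5 Mbp scale."""
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1A": 50_000_000, "chr1B": 50_000_000, "chr1D": 50_000_000}
    )
    window: int = 1_000_000
    fine_window: int = 100_000
    depth: float = 5.0
    read_length: int = 150
    parents: tuple[str, ...] = ("Paragon", "Pavon76")
    donor: str = "muticum"
    line: str = "DH_sim"
    donor_snp_rate: float = 5e-3
    parent_snp_rate: float = 1e-3
    parent_shared_fraction: float = 0.05  # parent SNPs colliding with donor alleles
    residual_rate: float = 0.05           # residual wheat-mapping inside introgressions
    deletion_residual: float = 0.02
    hom_detect_rate: float = 0.9          # donor sites recovered as hom calls in the line
    het_detect_rate: float = 0.6
    scatter_het_rate: float = 0.002       # false het matches outside introgressions
    hom_event_het_rate: float = 0.01      # het matches inside hom introgressions
    high_depth_site_rate: float = 0.01    # collapsed-repeat sites (3x filter targets)
    events: tuple[PlantedEvent, ...] = field(default_factory=_default_events)
    expression: ExpressionParams = field(default_factory=ExpressionParams)
    seed: int = 0

    def validate(self) -> None:
        for ev in self.events:
            if ev.chrom not in self.chrom_lengths:
                raise ValueError(f"event chromosome {ev.chrom!r} not in genome")
            if ev.end > self.chrom_lengths[ev.chrom]:
                raise ValueError(f"event {ev} exceeds chromosome bounds")
        by_chrom: dict[str, list[PlantedEvent]] = {}
        for ev in self.events:
            by_chrom.setdefault(ev.chrom, []).append(ev)
        for chrom, evs in by_chrom.items():
            evs = sorted(evs, key=lambda e: e.start)
            for a, b in zip(evs[:-1], evs[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping events on {chrom}: {a} / {b}")
        if self.expression.n_triads < 10:
            raise ValueError("n_triads must be >= 10 for the triad tests")


@dataclass
class SimTruth:
    """Ground truth for one simulated line."""
    blocks: list[SegmentBlock]
    donor_specific: set[tuple[str, int, str]]
    de_truth: pd.DataFrame | None = None


@dataclass
class LineDataset:
    """In-memory simulated dataset: window counts for the line and parents at
    both tiers, SNP frames for donor, parents and line, and the truth."""
    config: SimConfig
    counts: dict[str, WindowCountTable]
    counts_fine: dict[str, WindowCountTable]
    snps: dict[str, pd.DataFrame]
    truth: SimTruth


@dataclass
class ExpressionDataset:
    """Simulated expression study: counts and TPM (genes x samples), triads,
    orthologue pairs, gene positions/contigs, a deviation track and truth
    segment blocks for the expression genome, per-comparison DE tables, and
    per-gene truth."""
    config: SimConfig
    counts: pd.DataFrame
    tpm: pd.DataFrame
    triads: pd.DataFrame
    pairs: pd.DataFrame
    gene_positions: pd.DataFrame
    donor_contigs: pd.Series
    dev_track: pd.DataFrame
    segments: list[SegmentBlock]
    de_tables: dict[str, pd.DataFrame]
    truth: pd.DataFrame


def _copy_ratio(ev: PlantedEvent, cfg: SimConfig) -> float:
    """Expected wheat copy ratio of a window fully inside the event."""
    if ev.kind == "introgression":
        full = cfg.residual_rate
    elif ev.kind == "deletion":
        full = cfg.deletion_residual
    else:  # duplication
        full = 2.0
    if ev.zygosity == "het":
        return 0.5 + 0.5 * full if ev.kind != "duplication" else 1.5
    return full


def _window_ratios(windows: pd.DataFrame, cfg: SimConfig) -> np.ndarray:
    """Per-window expected copy ratio, with partial overlap for sub-window
    event boundaries."""
    ratios = np.ones(len(windows), dtype=float)
    starts = windows["start"].to_numpy(np.int64)
    ends = windows["end"].to_numpy(np.int64)
    chroms = windows["chrom"].to_numpy()
    for ev in cfg.events:
        r = _copy_ratio(ev, cfg)
        on = chroms == ev.chrom
        ov = np.minimum(ends, ev.end) - np.maximum(starts, ev.start)
        frac = np.clip(ov, 0, None) / (ends - starts)
        ratios = np.where(on, ratios + frac * (r - 1.0), ratios)
    return ratios


def _simulate_counts(
    cfg: SimConfig, windows: pd.DataFrame, tier: str
) -> dict[str, WindowCountTable]:
    widths = (windows["end"] - windows["start"]).to_numpy(np.int64)
    lam = cfg.depth * widths / cfg.read_length
    out: dict[str, WindowCountTable] = {}
    for parent in cfg.parents:
        rng = stream(cfg.seed, f"counts:{tier}:{parent}")
        frame = windows.copy()
        frame["count"] = rng.poisson(lam)
        out[parent] = WindowCountTable(frame, int(frame["count"].sum()))
    rng = stream(cfg.seed, f"counts:{tier}:{cfg.line}")
    frame = windows.copy()
    frame["count"] = rng.poisson(lam * _window_ratios(windows, cfg))
    out[cfg.line] = WindowCountTable(frame, int(frame["count"].sum()))
    return out


def _draw_positions(rng: np.random.Generator, length: int, rate: float) -> np.ndarray:
    n = rng.poisson(length * rate)
    pos = np.unique(rng.integers(1, length + 1, size=n))  # 1-based
    return pos


def _snp_frame(chroms, positions, refs, alts, genotypes, depths) -> pd.DataFrame:
    frame = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "ref": refs, "alt": alts,
         "genotype": genotypes, "depth": depths}
    )
    return frame.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def simulate_line(config: SimConfig, with_snps: bool = True) -> LineDataset:
    """Simulate one introgression line with its parents and donor.

    Parent window counts are Poisson around the configured depth; line counts
    are rescaled per window by the planted copy ratio.  Donor-specific SNPs
    are emitted as homozygous line calls inside introgressed intervals (at
    the detection rate), heterozygous calls inside heterozygous
    introgressions, and sparse heterozygous false matches elsewhere.  Site
    depths are Poisson around the line depth, with a small fraction of
    collapsed-repeat sites at ~8x depth that the 3x coverage filter removes.
    """
    config.validate()
    coarse = make_windows(config.chrom_lengths, config.window)
    fine = make_windows(config.chrom_lengths, config.fine_window)
    counts = _simulate_counts(config, coarse, "coarse")
    counts_fine = _simulate_counts(config, fine, "fine")
    if not with_snps:  # coverage-only dataset (e.g. downsampling analyses)
        truth = SimTruth(blocks=[ev.truth_block() for ev in config.events],
                         donor_specific=set())
        return LineDataset(config, counts, counts_fine, {}, truth)

    # donor SNPs vs the wheat reference
    rng = stream(config.seed, "donor_snps")
    donor_chroms: list[np.ndarray] = []
    donor_pos: list[np.ndarray] = []
    donor_ref: list[np.ndarray] = []
    donor_alt: list[np.ndarray] = []
    for chrom, length in config.chrom_lengths.items():
        pos = _draw_positions(rng, int(length), config.donor_snp_rate)
        ref_idx = rng.integers(0, 4, size=len(pos))
        alt_idx = (ref_idx + rng.integers(1, 4, size=len(pos))) % 4
        donor_chroms.append(np.full(len(pos), chrom, dtype=object))
        donor_pos.append(pos)
        donor_ref.append(_BASES[ref_idx])
        donor_alt.append(_BASES[alt_idx])
    d_chrom = np.concatenate(donor_chroms)
    d_pos = np.concatenate(donor_pos)
    d_ref = np.concatenate(donor_ref)
    d_alt = np.concatenate(donor_alt)
    d_depth = stream(config.seed, "donor_depth").poisson(2 * config.depth, size=len(d_pos)) + 1
    donor_frame = _snp_frame(d_chrom, d_pos, d_ref, d_alt,
                             np.full(len(d_pos), "hom_alt", dtype=object), d_depth)

    # parent SNPs: own variants plus a fraction colliding with donor alleles
    snps: dict[str, pd.DataFrame] = {config.donor: donor_frame}
    shared_mask_any = np.zeros(len(d_pos), dtype=bool)
    for parent in config.parents:
        rng_p = stream(config.seed, f"parent_snps:{parent}")
        shared = rng_p.random(len(d_pos)) < config.parent_shared_fraction
        shared_mask_any |= shared
        p_chroms = [d_chrom[shared]]
        p_pos = [d_pos[shared]]
        p_ref = [d_ref[shared]]
        p_alt = [d_alt[shared]]
        for chrom, length in config.chrom_lengths.items():
            pos = _draw_positions(rng_p, int(length), config.parent_snp_rate)
            ref_idx = rng_p.integers(0, 4, size=len(pos))
            alt_idx = (ref_idx + rng_p.integers(1, 4, size=len(pos))) % 4
            p_chroms.append(np.full(len(pos), chrom, dtype=object))
            p_pos.append(pos)
            p_ref.append(_BASES[ref_idx])
            p_alt.append(_BASES[alt_idx])
        pc = np.concatenate(p_chroms)
        pp = np.concatenate(p_pos)
        depth_p = rng_p.poisson(config.depth, size=len(pp)) + 1
        snps[parent] = _snp_frame(
            pc, pp, np.concatenate(p_ref), np.concatenate(p_alt),
            np.full(len(pp), "hom_alt", dtype=object), depth_p,
        )

    specific = ~shared_mask_any
    donor_specific = set(zip(
        d_chrom[specific].tolist(), d_pos[specific].tolist(), d_alt[specific].tolist()
    ))

    # line SNPs at donor positions
    rng_l = stream(config.seed, "line_snps")
    in_hom_intro = np.zeros(len(d_pos), dtype=bool)
    in_het_intro = np.zeros(len(d_pos), dtype=bool)
    for ev in config.events:
        if ev.kind != "introgression":
            continue
        mask = (d_chrom == ev.chrom) & (d_pos - 1 >= ev.start) & (d_pos - 1 < ev.end)
        if ev.zygosity == "hom":
            in_hom_intro |= mask
        else:
            in_het_intro |= mask
    u = rng_l.random(len(d_pos))
    emit_hom = in_hom_intro & (u < config.hom_detect_rate)
    emit_het = (
        (in_het_intro & (u < config.het_detect_rate))
        | (~in_hom_intro & ~in_het_intro & (u < config.scatter_het_rate))
        | (in_hom_intro & ~emit_hom & (u < config.hom_detect_rate + config.hom_event_het_rate))
    )
    emit = emit_hom | emit_het
    genotypes = np.where(emit_hom, "hom_alt", "het")[emit]
    l_depth = rng_l.poisson(config.depth, size=int(emit.sum())) + 1
    high = rng_l.random(len(l_depth)) < config.high_depth_site_rate
    l_depth[high] = rng_l.poisson(8 * config.depth, size=int(high.sum())) + 1
    line_frame = _snp_frame(
        d_chrom[emit], d_pos[emit], d_ref[emit], d_alt[emit], genotypes, l_depth
    )
    snps[config.line] = line_frame

    truth = SimTruth(
        blocks=[ev.truth_block() for ev in config.events],
        donor_specific=donor_specific,
    )
    return LineDataset(config, counts, counts_fine, snps, truth)


def frame_to_records(frame: pd.DataFrame) -> list[SnpRecord]:
    """Convert a SNP frame (chrom,pos,ref,alt,genotype,depth) to records."""
    return [
        SnpRecord(r.chrom, int(r.pos), r.ref, r.alt, r.genotype,
                  None if pd.isna(r.depth) else int(r.depth))
        for r in frame.itertuples(index=False)
    ]


def write_line_dataset(ds: LineDataset, outdir: str | Path) -> Path:
    """Write a simulated dataset as the pipeline's on-disk inputs: window
    count TSVs (both tiers), single-sample VCFs, a truth BED, and a manifest
    YAML recording totals, depths, roles and paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = ds.config
    manifest: dict = {
        "seed": cfg.seed,
        "window": cfg.window,
        "fine_window": cfg.fine_window,
        "samples": {},
    }
    for name, table in ds.counts.items():
        role = "line" if name == cfg.line else "parent"
        entry: dict = {
            "role": role,
            "counts": f"{name}.counts.tsv",
            "counts_fine": f"{name}.counts.100kb.tsv",
            "total_reads": int(table.total_reads),
            "total_reads_fine": int(ds.counts_fine[name].total_reads),
            "mean_depth": float(cfg.depth),
        }
        if role == "line":
            entry["parents"] = list(cfg.parents)
        write_window_counts(table, outdir / entry["counts"])
        write_window_counts(ds.counts_fine[name], outdir / entry["counts_fine"])
        manifest["samples"][name] = entry
    for name, frame in ds.snps.items():
        vcf_path = f"{name}.vcf"
        write_snps_vcf(frame, outdir / vcf_path, name, cfg.chrom_lengths)
        entry = manifest["samples"].setdefault(name, {"role": "donor"})
        entry["vcf"] = vcf_path
    write_segments_bed(ds.truth.blocks, outdir / "truth.bed")
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return outdir / "manifest.yaml"


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    return stats.false_discovery_control(p, method="bh")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws parameterized by mean and dispersion
    (variance = mu + dispersion * mu^2); dispersion -> 0 degenerates to
    Poisson."""
    mean = np.clip(mean, 1e-12, None)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_expression(config: SimConfig) -> ExpressionDataset:
    """Simulate the expression study for one line against two wheat parents.

    Triads are laid out along the three chromosomes at fixed spacing.  The
    leading ``frac_introgressed`` of triads fall in a donor-introgression
    block on the D chromosome: their wheat D gene is silenced in the line and
    a donor orthologue (own gene id, on its own contig) is expressed instead,
    shifted by a planted log2 fold change for a ``de_fraction`` subset
    (downregulated with probability ``down_weight``).  The next
    ``frac_deleted`` triads fall in a deletion: their D gene has zero counts
    in the line.  A and B homoeologues are never perturbed, so the
    triad-balancing null holds by construction.  DE tables for both parental
    comparisons are computed on the merged count matrix with a per-gene Wald
    test on the log2 fold change and BH adjustment.
    """
    config.validate()
    xp = config.expression
    chroms = list(config.chrom_lengths)
    if len(chroms) != 3:
        raise ValueError("expression simulation expects a 3-chromosome genome")
    chromA, chromB, chromD = chroms
    n = xp.n_triads
    needed = xp.gene_offset + n * xp.gene_spacing
    if needed > min(config.chrom_lengths.values()):
        raise ValueError("chromosomes too short for the requested triad count")

    n_intro = int(round(xp.frac_introgressed * n))
    n_del = int(round(xp.frac_deleted * n))
    idx = np.arange(n)
    status_d = np.where(idx < n_intro, "introgressed",
                        np.where(idx < n_intro + n_del, "deleted", "normal"))

    genes_a = [f"TaA{i:04d}" for i in idx]
    genes_b = [f"TaB{i:04d}" for i in idx]
    genes_d = [f"TaD{i:04d}" for i in idx]
    donor_genes = [f"Tm{i:04d}" for i in range(n_intro)]
    triads = pd.DataFrame({"A": genes_a, "B": genes_b, "D": genes_d})

    positions = pd.DataFrame(
        {
            "gene": genes_a + genes_b + genes_d,
            "chrom": [chromA] * n + [chromB] * n + [chromD] * n,
            "start": list(xp.gene_offset + idx * xp.gene_spacing) * 3,
        }
    )
    donor_contigs = pd.Series(
        {g: f"contig{i:04d}" for i, g in enumerate(donor_genes)}, name="contig"
    )

    rng = stream(config.seed, "expression")
    triad_mean = 2.0 ** rng.normal(xp.base_log2_mean, xp.base_log2_sd, size=n)
    factors = 2.0 ** rng.normal(0.0, xp.homoeologue_log2_sd, size=(n, 3))
    mu = triad_mean[:, None] * factors  # columns A, B, D

    planted_lfc = np.zeros(n_intro)
    has_effect = rng.random(n_intro) < xp.de_fraction
    mags = rng.uniform(*xp.lfc_magnitude, size=n_intro)
    signs = np.where(rng.random(n_intro) < xp.down_weight, -1.0, 1.0)
    planted_lfc[has_effect] = (mags * signs)[has_effect]

    samples = (
        [f"{config.line}_rep{r+1}" for r in range(xp.n_reps)]
        + [f"{p}_rep{r+1}" for p in config.parents for r in range(xp.n_reps)]
    )
    line_cols = samples[: xp.n_reps]
    parent_cols = {p: samples[xp.n_reps * (i + 1): xp.n_reps * (i + 2)]
                   for i, p in enumerate(config.parents)}

    all_genes = genes_a + genes_b + genes_d + donor_genes
    mean_matrix = np.zeros((len(all_genes), len(samples)))
    gene_index = {g: i for i, g in enumerate(all_genes)}
    for i in range(n):
        for h, gene_list in enumerate((genes_a, genes_b, genes_d)):
            g = gene_index[gene_list[i]]
            mean_matrix[g, xp.n_reps:] = mu[i, h]  # both parents
            if h < 2 or status_d[i] == "normal":
                mean_matrix[g, : xp.n_reps] = mu[i, h]
            else:
                mean_matrix[g, : xp.n_reps] = 0.0  # introgressed or deleted D
    for i, g in enumerate(donor_genes):
        gi = gene_index[g]
        mean_matrix[gi, : xp.n_reps] = mu[i, 2] * 2.0 ** planted_lfc[i]
        mean_matrix[gi, xp.n_reps:] = 0.0  # donor genes absent from parents

    counts = pd.DataFrame(
        _nb_draw(rng, mean_matrix, xp.dispersion),
        index=pd.Index(all_genes, name="gene"),
        columns=samples,
    )

    lengths = rng.integers(600, 3000, size=len(all_genes))
    rate = counts.to_numpy() / lengths[:, None]
    tpm = pd.DataFrame(
        1e6 * rate / np.maximum(rate.sum(axis=0, keepdims=True), 1e-12),
        index=counts.index, columns=counts.columns,
    )

    identities = rng.uniform(*xp.identity_range, size=n_intro)
    pairs = pd.DataFrame(
        {"donor_gene": donor_genes, "wheat_gene": genes_d[:n_intro],
         "identity": identities}
    )

    # deviation track and truth blocks for the expression genome
    intro_start = xp.gene_offset + 0 * xp.gene_spacing
    intro_end = xp.gene_offset + n_intro * xp.gene_spacing
    del_start = xp.gene_offset + n_intro * xp.gene_spacing
    del_end = xp.gene_offset + (n_intro + n_del) * xp.gene_spacing
    blocks = []
    if n_intro:
        blocks.append(SegmentBlock(chromD, intro_start, intro_end,
                                   origin="donor_introgression", zygosity="homozygous"))
    if n_del:
        blocks.append(SegmentBlock(chromD, del_start, del_end,
                                   origin="deletion", zygosity="homozygous"))
    windows = make_windows(config.chrom_lengths, config.window)
    dev = np.full(len(windows), 1.0)
    starts = windows["start"].to_numpy(np.int64)
    ends = windows["end"].to_numpy(np.int64)
    wchrom = windows["chrom"].to_numpy()
    for b, level in zip(blocks, (config.residual_rate, config.deletion_residual)):
        ov = np.clip(np.minimum(ends, b.end) - np.maximum(starts, b.start), 0, None)
        frac = ov / (ends - starts)
        dev = np.where(wchrom == b.chrom, dev + frac * (level - 1.0), dev)
    dev = dev + stream(config.seed, "expression_dev_noise").normal(0, 0.02, size=len(dev))
    dev_track = windows.copy()
    dev_track["deviation"] = np.clip(dev, 0.0, None)

    # merged matrix (as the DE engine sees it) and per-comparison DE tables
    from .expression import merge_orthologue_counts

    # Wald test on the log2 fold change with the generative NB dispersion:
    # var(log mean) ~ (1/mu + dispersion)/n by the delta method.  At 3
    # replicates this has usable power, unlike a per-gene t test, and plays
    # the role an external DE engine would.
    merged = merge_orthologue_counts(counts, positions, blocks, pairs)
    de_tables: dict[str, pd.DataFrame] = {}
    ln2_sq = np.log(2.0) ** 2
    mu_line = merged[line_cols].mean(axis=1).to_numpy() + 0.5
    var_line = (1.0 / mu_line + xp.dispersion) / xp.n_reps / ln2_sq
    for parent in config.parents:
        mu_par = merged[parent_cols[parent]].mean(axis=1).to_numpy() + 0.5
        lfc = np.log2(mu_line) - np.log2(mu_par)
        var_par = (1.0 / mu_par + xp.dispersion) / xp.n_reps / ln2_sq
        z = lfc / np.sqrt(var_line + var_par)
        p = 2.0 * stats.norm.sf(np.abs(z))
        de_tables[parent] = pd.DataFrame(
            {
                "gene": merged.index,
                "comparison": f"{config.line}_vs_{parent}",
                "log2fc": lfc,
                "padj": _bh_adjust(p),
            }
        )

    truth = pd.DataFrame(
        {
            "triad": np.arange(n),
            "gene_D": genes_d,
            "status_D": status_d,
            "donor_gene": donor_genes + [""] * (n - n_intro),
            "planted_lfc": np.concatenate([planted_lfc, np.zeros(n - n_intro)]),
        }
    )
    return ExpressionDataset(
        config=config,
        counts=counts,
        tpm=tpm,
        triads=triads,
        pairs=pairs,
        gene_positions=positions,
        donor_contigs=donor_contigs,
        dev_track=dev_track,
        segments=blocks,
        de_tables=de_tables,
        truth=truth,
    )


def write_expression_dataset(ds: ExpressionDataset, outdir: str | Path) -> Path:
    """Write the expression dataset as TSVs plus a truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.counts.to_csv(outdir / "counts.tsv", sep="\t")
    ds.tpm.to_csv(outdir / "tpm.tsv", sep="\t", float_format="%.6g")
    ds.triads.to_csv(outdir / "triads.tsv", sep="\t", index=False)
    ds.pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False, float_format="%.6g")
    ds.gene_positions.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    de = pd.concat(ds.de_tables.values(), ignore_index=True)
    de.to_csv(outdir / "de.tsv", sep="\t", index=False, float_format="%.8g")
    from .io_formats import write_deviation_track, write_segments_bed as _wsb

    write_deviation_track(ds.dev_track, outdir / "dev.expression.bed")
    _wsb(ds.segments, outdir / "segments.expression.bed")
    ds.truth.to_csv(outdir / "truth.expression.tsv", sep="\t", index=False, float_format="%.6g")
    return outdir


def config_from_yaml(path: str | Path, seed: int | None = None) -> SimConfig:
    """Build a SimConfig from a YAML file; ``seed`` overrides the file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    events = tuple(
        PlantedEvent(
            chrom=e["chrom"], start=int(e["start"]), end=int(e["end"]),
            kind=e["kind"], zygosity=e.get("zygosity", "hom"),
        )
        for e in raw.pop("events", [])
    ) or _default_events()
    expression = ExpressionParams(**raw.pop("expression", {}))
    if "chrom_lengths" in raw:
        raw["chrom_lengths"] = {str(k): int(v) for k, v in raw["chrom_lengths"].items()}
    if "parents" in raw:
        raw["parents"] = tuple(raw["parents"])
    cfg = SimConfig(events=events, expression=expression, **raw)
    if seed is not None:
        cfg = replace(cfg, seed=int(seed))
    cfg.validate()
    return cfg
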