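"""Expression impact of introgression: state calls, orthologue count merging,
differential-expression partitioning and homoeologue-triad balancing tests.

A gene is *expressed* when its mean TPM across replicates exceeds 1.0.  For
differential expression, wheat genes inside donor-introgression blocks are
either dropped (no donor orthologue) or have their counts summed with the
introgressed orthologue, so the merged entry measures the replaced locus as
one unit.  A gene is differentially expressed only when |log2FC| >= 1 with
adjusted p below 0.05 against *both* wheat parents, with agreeing sign.  The
triad-balancing analysis asks whether suppression of the D homoeologue (by
introgression or deletion) is compensated by upregulation of the A or B
homoeologues, using a two-tailed Fisher's exact test on upregulation counts
and a two-tailed t test on homoeologue log2 fold changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import DEFAULT
from .segments import SegmentBlock

log = logging.getLogger(__name__)


def expression_state(
    tpm: pd.DataFrame,
    threshold: float = DEFAULT.tpm_expressed,
) -> pd.Series:
    """Expressed flags per gene: mean TPM across columns strictly greater
    than ``threshold``."""
    return tpm.mean(axis=1) > threshold


DEFAULT_IDENTITY_EDGES = (90.0, 95.0, 99.0)


def bin_by_identity(
    identities: pd.Series,
    expressed: pd.Series,
    edges: Sequence[float] = DEFAULT_IDENTITY_EDGES,
) -> pd.DataFrame:
    """Fraction of genes expressed per protein-identity bin.

    ``identities`` holds the best-hit percent identity per gene, with 0 for
    genes lacking any hit.  Default bins: <90 (including no-hit), [90,95),
    [95,99), >=99.  Empty bins get NaN fractions.
    """
    ident = identities.fillna(0.0)
    bounds = [-np.inf, *edges, np.inf]
    labels = [f"<{edges[0]:g}"] + [
        f"[{lo:g},{hi:g})" for lo, hi in zip(edges[:-1], edges[1:])
    ] + [f">={edges[-1]:g}"]
    binned = pd.cut(ident, bounds, right=False, labels=labels)
    rows = []
    for label in labels:
        genes = ident.index[binned == label]
        n = len(genes)
        frac = float(expressed.loc[genes].mean()) if n else np.nan
        rows.append((label, n, frac))
    return pd.DataFrame(rows, columns=["bin", "n_genes", "fraction_expressed"])


def merge_orthologue_counts(
    counts: pd.DataFrame,
    wheat_gene_positions: pd.DataFrame,
    segments: Sequence[SegmentBlock],
    pairs: pd.DataFrame,
) -> pd.DataFrame:
    """Merge introgressed-orthologue counts onto the wheat genes they replaced.

    Wheat genes starting inside a donor-introgression block are dropped when
    they have no introgressed orthologue; otherwise the donor orthologue's
    counts are added to the wheat gene's row (wheat id retained) and the
    donor row is removed.  Total counts of retained genes are conserved
    exactly.  A donor orthologue missing from the matrix contributes zero
    counts and is logged.
    """
    intro_blocks = [b for b in segments if b.origin == "donor_introgression"]

    def in_introgression(chrom: str, start: int) -> bool:
        return any(b.chrom == chrom and b.start <= start < b.end for b in intro_blocks)

    pos = wheat_gene_positions.set_index("gene")
    donor_of = pairs.set_index("wheat_gene")["donor_gene"]
    out = counts.copy()
    dropped, merged, missing_donor = 0, 0, 0
    for gene in pos.index:
        if gene not in out.index:
            continue
        loc = pos.loc[gene]
        if not in_introgression(str(loc["chrom"]), int(loc["start"])):
            continue
        donor = donor_of.get(gene)
        if donor is None or (isinstance(donor, float) and np.isnan(donor)):
            out = out.drop(index=gene)
            dropped += 1
            continue
        if donor in out.index:
            out.loc[gene] = out.loc[gene] + out.loc[donor]
            out = out.drop(index=donor)
        else:
            missing_donor += 1
        merged += 1
    log.info(
        "merge_orthologue_counts: %d merged, %d unpaired wheat genes dropped, "
        "%d donor orthologues absent from matrix (treated as zero)",
        merged, dropped, missing_donor,
    )
    return out


def classify_de(
    results: pd.DataFrame,
    lfc_min: float = DEFAULT.lfc_min,
    padj_max: float = DEFAULT.padj_max,
) -> pd.Series:
    """DE call per gene from a long-format result table
    (gene, comparison, log2fc, padj) carrying both parental comparisons.

    A gene is DE only when |log2FC| >= ``lfc_min`` and adjusted p <
    ``padj_max`` in both comparisons with agreeing sign; the call is the
    shared direction.  Sign disagreement between significant comparisons is
    logged and returned as ``not_de``.
    """
    comparisons = sorted(results["comparison"].unique())
    if len(comparisons) != 2:
        raise ValueError(f"expected exactly 2 parental comparisons, got {comparisons}")
    lfc = results.pivot(index="gene", columns="comparison", values="log2fc")
    padj = results.pivot(index="gene", columns="comparison", values="padj")
    if lfc.isna().any().any() or padj.isna().any().any():
        raise ValueError("a gene is missing one of the parental comparisons")
    sig = (lfc.abs() >= lfc_min).all(axis=1) & (padj < padj_max).all(axis=1)
    signs_agree = np.sign(lfc.iloc[:, 0]) == np.sign(lfc.iloc[:, 1])
    conflicts = int((sig & ~signs_agree).sum())
    if conflicts:
        log.info("classify_de: %d significant genes with conflicting signs -> not_de", conflicts)
    call = pd.Series("not_de", index=lfc.index, name="call")
    de = sig & signs_agree
    call[de & (lfc.iloc[:, 0] > 0)] = "up"
    call[de & (lfc.iloc[:, 0] < 0)] = "down"
    return call


def _window_deviation(dev_track: pd.DataFrame):
    by_chrom = {}
    for chrom, grp in dev_track.groupby("chrom"):
        order = grp.sort_values("start")
        by_chrom[str(chrom)] = (
            order["start"].to_numpy(np.int64),
            order["end"].to_numpy(np.int64),
            order["deviation"].to_numpy(float),
        )

    def lookup(chrom: str, pos: int) -> float:
        loc = by_chrom.get(chrom)
        if loc is None:
            return np.nan
        starts, ends, dev = loc
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0 or pos >= ends[i]:
            return np.nan
        return float(dev[i])

    return lookup


def partition_de(
    gene_positions: pd.DataFrame,
    segments: Sequence[SegmentBlock],
    dev_track: pd.DataFrame,
    normal_band: tuple[float, float] = DEFAULT.normal_band,
) -> pd.Series:
    """Partition genes into introgressed / background / excluded regions.

    A gene (by its start position) is *introgressed* when inside a
    donor-introgression block, *background* when its window's coverage
    deviation lies in the normal band, and *excluded* otherwise (deleted or
    duplicated regions, undefined windows).
    """
    intro_blocks = [b for b in segments if b.origin == "donor_introgression"]
    lookup = _window_deviation(dev_track)
    lo, hi = normal_band
    out = {}
    for row in gene_positions.itertuples(index=False):
        chrom, start = str(row.chrom), int(row.start)
        if any(b.chrom == chrom and b.start <= start < b.end for b in intro_blocks):
            out[row.gene] = "introgressed"
            continue
        d = lookup(chrom, start)
        out[row.gene] = "background" if (not np.isnan(d) and lo <= d <= hi) else "excluded"
    return pd.Series(out, name="region")


def gene_status(
    gene_positions: pd.DataFrame,
    segments: Sequence[SegmentBlock],
    dev_track: pd.DataFrame,
    normal_band: tuple[float, float] = DEFAULT.normal_band,
) -> pd.Series:
    """Copy-number status per gene: introgressed / deleted / normal / other,
    from its start position against called blocks and the deviation track."""
    lookup = _window_deviation(dev_track)
    lo, hi = normal_band
    by_origin: dict[str, list[SegmentBlock]] = {}
    for b in segments:
        by_origin.setdefault(b.origin, []).append(b)

    def inside(blocks: list[SegmentBlock], chrom: str, start: int) -> bool:
        return any(b.chrom == chrom and b.start <= start < b.end for b in blocks)

    out = {}
    for row in gene_positions.itertuples(index=False):
        chrom, start = str(row.chrom), int(row.start)
        if inside(by_origin.get("donor_introgression", []), chrom, start):
            out[row.gene] = "introgressed"
        elif inside(by_origin.get("deletion", []), chrom, start):
            out[row.gene] = "deleted"
        else:
            d = lookup(chrom, start)
            out[row.gene] = "normal" if (not np.isnan(d) and lo <= d <= hi) else "other"
    return pd.Series(out, name="status")


def select_triad_sets(
    triads: pd.DataFrame,
    status: pd.Series,
    de_calls: pd.Series,
    norm_counts: pd.DataFrame,
    min_norm_count: float = DEFAULT.min_norm_count,
    per_sample: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Select the test and control triad sets for the balancing analysis.

    Test triads: the D homoeologue is introgressed or deleted and called as
    downregulated (a deleted homoeologue is not expressed, so deletion counts
    as downregulation); A and B are in normal copy-number regions; every
    homoeologue has normalized expression count >= ``min_norm_count``, taken
    as the mean across samples (or in every sample with ``per_sample``).
    Control triads satisfy the same conditions except that D is in a normal
    region and is not differentially expressed.
    """
    def counts_ok(gene: str) -> bool:
        if gene not in norm_counts.index:
            return False
        vals = norm_counts.loc[gene]
        return bool((vals >= min_norm_count).all()) if per_sample else bool(vals.mean() >= min_norm_count)

    test_rows, control_rows = [], []
    for row in triads.itertuples(index=False):
        a, b, d = row.A, row.B, row.D
        try:
            st_a, st_b, st_d = status[a], status[b], status[d]
        except KeyError:
            continue
        if not (st_a == "normal" and st_b == "normal"):
            continue
        if not all(counts_ok(g) for g in (a, b, d)):
            continue
        call_d = de_calls.get(d, "not_de")
        if st_d in ("introgressed", "deleted") and (call_d == "down" or st_d == "deleted"):
            test_rows.append(row)
        elif st_d == "normal" and call_d == "not_de":
            control_rows.append(row)
    test = pd.DataFrame(test_rows, columns=triads.columns)
    control = pd.DataFrame(control_rows, columns=triads.columns)
    return test, control


@dataclass
class TriadTestResult:
    """Contingency counts and test p-values for homoeologue balancing."""
    table: list[list[int]]  # [[test_up, test_not], [control_up, control_not]]
    fisher_p: float
    t_p: float
    mean_lfc_test: float
    mean_lfc_control: float
    n_test: int
    n_control: int


def fisher_two_tailed(table: Sequence[Sequence[int]]) -> float:
    """Two-tailed Fisher's exact test p-value for a 2x2 table: the sum of
    hypergeometric probabilities, over tables with the observed margins, of
    all tables no more probable than the observed one."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("Fisher test requires a 2x2 table")
    if (arr < 0).any():
        raise ValueError("contingency counts must be non-negative")
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def t_test_two_tailed(
    x: Sequence[float], y: Sequence[float], equal_var: bool = False
) -> float:
    """Two-sided two-sample t-test p-value (Welch by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    stat, p = stats.ttest_ind(x, y, equal_var=equal_var)
    if np.isnan(p):  # both groups constant and identical
        return 1.0 if np.allclose(x.mean(), y.mean()) else 0.0
    return float(p)


def triad_balance_test(
    test: pd.DataFrame,
    control: pd.DataFrame,
    de_calls: pd.Series,
    lfc: pd.Series,
    equal_var: bool = False,
) -> TriadTestResult:
    """Compare upregulation of A/B homoeologues between test and control triads.

    The 2x2 table counts triads with at least one A or B homoeologue called
    upregulated; its two-tailed Fisher p tests the proportions.  The t test
    compares the pooled A and B log2 fold changes between the sets.
    """
    def n_up(frame: pd.DataFrame) -> int:
        up = 0
        for row in frame.itertuples(index=False):
            if de_calls.get(row.A) == "up" or de_calls.get(row.B) == "up":
                up += 1
        return up

    def lfcs(frame: pd.DataFrame) -> np.ndarray:
        genes = list(frame["A"]) + list(frame["B"])
        vals = lfc.reindex(genes).dropna()
        return vals.to_numpy(dtype=float)

    t_up, c_up = n_up(test), n_up(control)
    table = [[t_up, len(test) - t_up], [c_up, len(control) - c_up]]
    fisher_p = fisher_two_tailed(table)
    x, y = lfcs(test), lfcs(control)
    t_p = t_test_two_tailed(x, y, equal_var=equal_var) if len(x) >= 2 and len(y) >= 2 else np.nan
    return TriadTestResult(
        table=table,
        fisher_p=fisher_p,
        t_p=t_p,
        mean_lfc_test=float(x.mean()) if len(x) else np.nan,
        mean_lfc_control=float(y.mean()) if len(y) else np.nan,
        n_test=len(test),
        n_control=len(control),
    )


def windowed_lfc_profile(
    line_means: pd.Series,
    parent_means: pd.Series,
    gene_positions: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    window: int = DEFAULT.lfc_window,
    pseudocount: float = DEFAULT.pseudocount,
) -> pd.DataFrame:
    """Mean per-gene log2FC of normalized counts in genomic windows.

    Per window the mean over genes of log2((line + c) / (parent + c)) with
    pseudocount ``c``; windows with no genes get NaN.  Mirrors chromosome-scale
    expression-stability profiles across introgressed and deleted regions.
    """
    from .io_formats import make_windows

    windows = make_windows(chrom_lengths, window)
    lookup_rows: dict[tuple[str, int], list[float]] = {}
    pos = gene_positions.set_index("gene")
    common = pos.index.intersection(line_means.index).intersection(parent_means.index)
    for gene in common:
        chrom = str(pos.loc[gene, "chrom"])
        start = int(pos.loc[gene, "start"])
        w = (chrom, (start // window) * window)
        val = np.log2((line_means[gene] + pseudocount) / (parent_means[gene] + pseudocount))
        lookup_rows.setdefault(w, []).append(float(val))
    mean_lfc, n_genes = [], []
    for row in windows.itertuples(index=False):
        vals = lookup_rows.get((row.chrom, row.start), [])
        mean_lfc.append(float(np.mean(vals)) if vals else np.nan)
        n_genes.append(len(vals))
    windows["mean_log2fc"] = mean_lfc
    windows["n_genes"] = n_genes
    return windows
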