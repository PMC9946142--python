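"""Calling and characterizing coverage-deviation blocks.

A *block* is a maximal run of genomic windows whose coverage deviation falls
on the wrong side of a threshold, after nearby runs have been merged and
poorly supported merges discarded.  Reduced-coverage blocks (deviation below
0.7 by default) are candidate introgressions or deletions; donor-specific SNP
evidence decides between the two.  Elevated blocks (deviation >= 1.8)
are duplications.  Borders called on the 1 Mbp grid are refined with a
100 kbp deviation track.

Coordinates are 0-based half-open base pairs throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from math import nan, isnan
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .config import Thresholds, DEFAULT

log = logging.getLogger(__name__)

Origin = Literal["donor_introgression", "deletion", "duplication", "unassigned"]
Zygosity = Literal["homozygous", "heterozygous_or_monosomic"]

ORIGINS = ("donor_introgression", "deletion", "duplication", "unassigned")
ZYGOSITIES = ("homozygous", "heterozygous_or_monosomic")


@dataclass
class SegmentBlock:
    """A called genomic block with its origin, zygosity and support statistics.

    ``support_fraction`` is the fraction of constituent windows satisfying the
    calling predicate; ``hom_snp_density`` is homozygous donor-SNP matches per
    Mbp across the block and ``hom_het_ratio`` the block-wide homozygous to
    heterozygous match ratio (``inf`` when no heterozygous matches exist).
    """

    chrom: str
    start: int
    end: int
    origin: str = "unassigned"
    zygosity: str = "homozygous"
    support_fraction: float = nan
    hom_snp_density: float = nan
    hom_het_ratio: float = nan
    mean_deviation: float = nan

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty block {self.chrom}:{self.start}-{self.end}")
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"unknown zygosity {self.zygosity!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RecoveryResult:
    precision: float
    recall: float
    mean_boundary_error: float
    max_boundary_error: float
    n_truth: int
    n_called: int
    n_matched: int


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Index ranges [i, j) of maximal runs of True in ``mask``."""
    out: list[tuple[int, int]] = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def _call_blocks(
    track: pd.DataFrame,
    predicate,
    merge_gap: int,
    min_fraction: float,
) -> list[SegmentBlock]:
    """Generic run/merge/fraction block caller over a window deviation track.

    ``predicate`` maps the deviation array to a boolean array; NaN deviations
    (windows with no parental coverage) never satisfy it and are excluded from
    the constituent-window count.
    """
    blocks: list[SegmentBlock] = []
    for chrom, grp in track.groupby("chrom", sort=True):
        grp = grp.sort_values("start").reset_index(drop=True)
        dev = grp["deviation"].to_numpy(dtype=float)
        defined = ~np.isnan(dev)
        below = predicate(dev) & defined
        runs = _runs(below)
        if not runs:
            continue
        # merge runs whose bp gap to the previous block is within merge_gap
        merged: list[tuple[int, int]] = [runs[0]]
        for i, j in runs[1:]:
            pi, pj = merged[-1]
            gap_bp = int(grp.loc[i, "start"]) - int(grp.loc[pj - 1, "end"])
            if gap_bp <= merge_gap:
                merged[-1] = (pi, j)
            else:
                merged.append((i, j))
        for i, j in merged:
            constituents = defined[i:j]
            n_const = int(constituents.sum())
            n_below = int(below[i:j].sum())
            if n_const == 0:
                continue
            fraction = n_below / n_const
            if fraction < min_fraction:
                continue
            sel = below[i:j]
            mean_dev = float(dev[i:j][sel].mean()) if sel.any() else nan
            blocks.append(
                SegmentBlock(
                    chrom=str(chrom),
                    start=int(grp.loc[i, "start"]),
                    end=int(grp.loc[j - 1, "end"]),
                    support_fraction=fraction,
                    mean_deviation=mean_dev,
                )
            )
    return blocks


def call_deviation_blocks(
    track: pd.DataFrame,
    threshold: float = DEFAULT.block_threshold,
    merge_gap: int = DEFAULT.merge_gap,
    min_fraction: float = DEFAULT.min_block_fraction,
    hom_zygosity_max_dev: float = DEFAULT.hom_zygosity_max_dev,
) -> list[SegmentBlock]:
    """Call reduced-coverage blocks from a 1 Mbp deviation track.

    Maximal runs of windows with deviation < ``threshold`` are found per
    chromosome; a run starting within ``merge_gap`` bp of the previous block
    is merged into it, the intervening windows becoming block constituents.
    Blocks in which fewer than ``min_fraction`` of constituent windows are
    below threshold are discarded.  Zygosity is set from the mean deviation of
    the below-threshold windows: below ``hom_zygosity_max_dev`` the wheat DNA
    is essentially absent (homozygous event); intermediate values indicate a
    heterozygous or monosomic state.
    """
    blocks = _call_blocks(track, lambda d: d < threshold, merge_gap, min_fraction)
    for b in blocks:
        if not isnan(b.mean_deviation) and b.mean_deviation >= hom_zygosity_max_dev:
            b.zygosity = "heterozygous_or_monosomic"
    return blocks


def detect_copy_number_blocks(
    track: pd.DataFrame,
    dup_threshold: float = DEFAULT.dup_threshold,
    het_band: tuple[float, float] = DEFAULT.het_band,
    merge_gap: int = DEFAULT.merge_gap,
    min_fraction: float = DEFAULT.min_block_fraction,
) -> list[SegmentBlock]:
    """Call duplication blocks (deviation >= ``dup_threshold``) and
    heterozygous/monosomic copy-number blocks (deviation inside ``het_band``),
    using the same run/merge/fraction machinery as reduced-block calling.
    """
    dups = _call_blocks(track, lambda d: d >= dup_threshold, merge_gap, min_fraction)
    for b in dups:
        b.origin = "duplication"
    lo, hi = het_band
    hets = _call_blocks(track, lambda d: (d >= lo) & (d <= hi), merge_gap, min_fraction)
    for b in hets:
        b.zygosity = "heterozygous_or_monosomic"
    return sorted(dups + hets, key=lambda b: (b.chrom, b.start))


def assign_block_origin(
    block: SegmentBlock,
    snp_profile: pd.DataFrame,
    min_hom_density: float = DEFAULT.min_hom_density,
    min_window_fraction: float = DEFAULT.min_window_fraction,
    min_hom_het_ratio: float = DEFAULT.min_hom_het_ratio,
    het_min_density: float = DEFAULT.het_min_density,
) -> SegmentBlock:
    """Decide whether a reduced block is a donor introgression or a deletion.

    A homozygous block is a donor introgression when at least
    ``min_window_fraction`` of its windows carry >= ``min_hom_density``
    homozygous donor-SNP matches per Mbp AND the block-wide hom:het match
    ratio is >= ``min_hom_het_ratio`` (aberrantly mapped donor reads produce
    heterozygous matches, so a low ratio flags a mapping artefact rather than
    an introgression).  A heterozygous block carries donor evidence as
    heterozygous matches instead, so it is assigned by total donor-match
    density >= ``het_min_density`` per Mbp.  Everything else is a deletion.
    """
    rows = snp_profile[
        (snp_profile["chrom"] == block.chrom)
        & (snp_profile["start"] < block.end)
        & (snp_profile["end"] > block.start)
    ]
    if rows.empty:
        block.origin = "deletion"
        block.hom_snp_density = 0.0
        block.hom_het_ratio = nan
        return block
    widths_mbp = (rows["end"] - rows["start"]).to_numpy(dtype=float) / 1e6
    hom = rows["hom"].to_numpy(dtype=float)
    het = rows["het"].to_numpy(dtype=float)
    hom_density = np.divide(hom, widths_mbp, out=np.zeros_like(hom), where=widths_mbp > 0)
    total_hom, total_het = float(hom.sum()), float(het.sum())
    block_mbp = float(widths_mbp.sum())
    block.hom_snp_density = total_hom / block_mbp if block_mbp else 0.0
    block.hom_het_ratio = total_hom / total_het if total_het else float("inf")

    if block.zygosity == "homozygous":
        frac = float((hom_density >= min_hom_density).mean())
        is_donor = frac >= min_window_fraction and block.hom_het_ratio >= min_hom_het_ratio
    else:
        total_density = (total_hom + total_het) / block_mbp if block_mbp else 0.0
        is_donor = total_density >= het_min_density
    block.origin = "donor_introgression" if is_donor else "deletion"
    return block


def refine_borders(
    block: SegmentBlock,
    fine_track: pd.DataFrame,
    threshold: float = DEFAULT.block_threshold,
    search: int = 1_000_000,
    above: bool = False,
) -> SegmentBlock:
    """Refine block borders on a fine (100 kbp) deviation track.

    Each border is moved outward to the outermost contiguous fine window
    satisfying the calling predicate (deviation < ``threshold``, or
    >= ``threshold`` when ``above`` is set, as for duplications), looking at
    most ``search`` bp beyond the coarse edge; when the fine windows just
    inside an edge do not satisfy the predicate the border moves inward to
    the first window that does.  If the fine track does not cover the block,
    refinement is skipped with a warning.
    """
    grp = fine_track[fine_track["chrom"] == block.chrom].sort_values("start")
    grp = grp.reset_index(drop=True)
    if grp.empty or grp["start"].iloc[0] > block.start or grp["end"].iloc[-1] < block.end:
        log.warning(
            "fine track does not cover %s:%d-%d; border refinement skipped",
            block.chrom, block.start, block.end,
        )
        return block
    dev = grp["deviation"].to_numpy(dtype=float)
    ok = (dev >= threshold) if above else (dev < threshold)
    ok &= ~np.isnan(dev)
    starts = grp["start"].to_numpy(dtype=np.int64)
    ends = grp["end"].to_numpy(dtype=np.int64)

    # left border
    i0 = int(np.searchsorted(starts, block.start, side="left"))
    new_start = block.start
    if i0 < len(ok) and ok[i0]:
        j = i0
        while j - 1 >= 0 and ok[j - 1] and starts[j - 1] >= block.start - search:
            j -= 1
        new_start = int(starts[j])
    else:
        j = i0
        while j < len(ok) and ends[j] <= block.end and not ok[j]:
            j += 1
        if j < len(ok) and ends[j] <= block.end:
            new_start = int(starts[j])

    # right border
    i1 = int(np.searchsorted(ends, block.end, side="right")) - 1
    new_end = block.end
    if 0 <= i1 < len(ok) and ok[i1]:
        j = i1
        while j + 1 < len(ok) and ok[j + 1] and ends[j + 1] <= block.end + search:
            j += 1
        new_end = int(ends[j])
    else:
        j = i1
        while j >= 0 and starts[j] >= block.start and not ok[j]:
            j -= 1
        if j >= 0 and starts[j] >= block.start:
            new_end = int(ends[j])

    if new_end <= new_start:  # degenerate refinement; keep coarse borders
        log.warning(
            "refinement of %s:%d-%d collapsed; keeping coarse borders",
            block.chrom, block.start, block.end,
        )
        return block
    return replace(block, start=new_start, end=new_end)


def detect_segments(
    track: pd.DataFrame,
    fine_track: pd.DataFrame | None = None,
    snp_profile: pd.DataFrame | None = None,
    thresholds: Thresholds = DEFAULT,
) -> list[SegmentBlock]:
    """Full segment-calling pass over one line.

    Reduced blocks are called at 1 Mbp, assigned as donor introgression or
    deletion from the donor-SNP window profile (left ``unassigned`` when no
    profile is given, as in coverage-only downsampling analyses), duplication
    blocks are called, and all borders are refined on the fine track when one
    is provided.
    """
    t = thresholds
    reduced = call_deviation_blocks(
        track, t.block_threshold, t.merge_gap, t.min_block_fraction, t.hom_zygosity_max_dev
    )
    if snp_profile is not None:
        for b in reduced:
            assign_block_origin(
                b, snp_profile, t.min_hom_density, t.min_window_fraction,
                t.min_hom_het_ratio, t.het_min_density,
            )
    dups = _call_blocks(
        track, lambda d: d >= t.dup_threshold, t.merge_gap, t.min_block_fraction
    )
    for b in dups:
        b.origin = "duplication"
    blocks = reduced + dups
    if fine_track is not None:
        blocks = [
            refine_borders(
                b, fine_track, t.dup_threshold if b.origin == "duplication" else t.block_threshold,
                search=1_000_000, above=b.origin == "duplication",
            )
            for b in blocks
        ]
    return sorted(blocks, key=lambda b: (b.chrom, b.start))


def downsample_counts(table, fraction: float, seed: int):
    """Binomially downsample a window count table to ``fraction`` of its reads.

    Each window count is replaced by a Binomial(count, fraction) draw and the
    sample total is scaled by the same fraction; the result is deterministic
    for a given seed.
    """
    from .io_formats import WindowCountTable  # local import avoids a cycle

    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    frame = table.frame.copy()
    frame["count"] = rng.binomial(frame["count"].to_numpy(dtype=np.int64), fraction)
    return WindowCountTable(frame, int(round(table.total_reads * fraction)))


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def _reciprocal(a: SegmentBlock, b: SegmentBlock, min_frac: float = 0.5) -> bool:
    if a.chrom != b.chrom:
        return False
    ov = _overlap(a.start, a.end, b.start, b.end)
    return ov >= min_frac * a.length and ov >= min_frac * b.length


def evaluate_recovery(
    truth: Sequence[SegmentBlock],
    called: Sequence[SegmentBlock],
    boundary_tol: int = 100_000,
    match_origin: bool = True,
) -> RecoveryResult:
    """Score called blocks against planted truth.

    A truth block is recovered when a call of the same origin (unless
    ``match_origin`` is off, as in coverage-only analyses) overlaps it
    reciprocally by at least 50%.  Boundary error is the mean absolute
    start/end offset over matched pairs; ``boundary_tol`` is carried in the
    result's contract but not used for matching.
    """
    def compatible(t: SegmentBlock, c: SegmentBlock) -> bool:
        return (not match_origin or t.origin == c.origin) and _reciprocal(t, c)

    matched_pairs = [
        (t, c) for t in truth for c in called if compatible(t, c)
    ]
    matched_truth = {id(t) for t, _ in matched_pairs}
    matched_called = {id(c) for _, c in matched_pairs}
    recall = len(matched_truth) / len(truth) if truth else 1.0
    precision = len(matched_called) / len(called) if called else 1.0
    errors = [abs(t.start - c.start) for t, c in matched_pairs]
    errors += [abs(t.end - c.end) for t, c in matched_pairs]
    mean_err = float(np.mean(errors)) if errors else 0.0
    max_err = float(np.max(errors)) if errors else 0.0
    return RecoveryResult(
        precision=precision,
        recall=recall,
        mean_boundary_error=mean_err,
        max_boundary_error=max_err,
        n_truth=len(truth),
        n_called=len(called),
        n_matched=len(matched_truth),
    )


def segment_overlap(
    a: SegmentBlock, b: SegmentBlock
) -> tuple[tuple[str, int, int] | None, list[tuple[str, int, int]], list[tuple[str, int, int]]]:
    """Interval intersection and differences between two blocks.

    Returns ``(shared, unique_to_a, unique_to_b)``; blocks on different
    chromosomes share nothing and are each wholly unique.  Used to narrow a
    phenotype to the region shared between lines (or unique to one of them).
    """
    if a.chrom != b.chrom:
        return None, [(a.chrom, a.start, a.end)], [(b.chrom, b.start, b.end)]
    lo, hi = max(a.start, b.start), min(a.end, b.end)
    if hi <= lo:
        return None, [(a.chrom, a.start, a.end)], [(b.chrom, b.start, b.end)]
    shared = (a.chrom, lo, hi)
    unique_a = [(a.chrom, s, e) for s, e in ((a.start, lo), (hi, a.end)) if e > s]
    unique_b = [(b.chrom, s, e) for s, e in ((b.start, lo), (hi, b.end)) if e > s]
    return shared, unique_a, unique_b
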