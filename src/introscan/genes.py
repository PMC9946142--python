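"""Orthologue pairing and gene-level classification.

Covers reciprocal-best-hit orthologue pairing between donor and wheat
proteomes (identity >= 90%, alignment covering >= 80% of the query, with
orthogroup agreement), novel-gene and expanded-orthogroup calls from
orthogroup membership, classification of which donor genes are physically
introgressed in each line from mapping depth and contig anchoring, and the
coverage set-logic used to shortlist candidate resistance genes.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT
from .segments import SegmentBlock

log = logging.getLogger(__name__)


def _filter_hits(hits: pd.DataFrame, min_identity: float, min_query_coverage: float) -> pd.DataFrame:
    if "qlen" not in hits.columns or hits["qlen"].isna().any():
        raise ValueError("hits table lacks query lengths (qlen) for coverage filtering")
    keep = (hits["pident"] >= min_identity) & (
        hits["length"] >= min_query_coverage * hits["qlen"]
    )
    return hits[keep]


def _best_hits(hits: pd.DataFrame) -> pd.Series:
    """Best subject per query: highest bitscore, ties broken by lowest
    e-value then lexicographic subject id."""
    if hits.empty:
        return pd.Series(dtype=object)
    ordered = hits.sort_values(
        ["qseqid", "bitscore", "evalue", "sseqid"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    return ordered.groupby("qseqid", sort=False).first()["sseqid"]


def reciprocal_best_hits(
    hits_ab: pd.DataFrame,
    hits_ba: pd.DataFrame,
    min_identity: float = DEFAULT.rbh_min_identity,
    min_query_coverage: float = DEFAULT.rbh_min_query_coverage,
) -> pd.DataFrame:
    """Reciprocal best hits between proteome A (donor) and proteome B (wheat).

    Both directions are filtered by percent identity and query coverage
    before best hits are taken; a pair is kept iff each member is the other's
    best hit.  Returns columns donor_gene, wheat_gene, identity (identity of
    the A->B best hit).
    """
    fab = _filter_hits(hits_ab, min_identity, min_query_coverage)
    fba = _filter_hits(hits_ba, min_identity, min_query_coverage)
    best_ab = _best_hits(fab)
    best_ba = _best_hits(fba)
    pairs = []
    for a, b in best_ab.items():
        if best_ba.get(b) == a:
            ident = fab[(fab["qseqid"] == a) & (fab["sseqid"] == b)]["pident"].max()
            pairs.append((a, b, float(ident)))
    return pd.DataFrame(pairs, columns=["donor_gene", "wheat_gene", "identity"])


def orthologue_pairs(rbh: pd.DataFrame, orthogroups: pd.DataFrame) -> pd.DataFrame:
    """Keep RBH pairs whose members share an orthogroup.

    Genes absent from the orthogroup table are unassigned; their pairs are
    dropped with a logged count.
    """
    membership = orthogroups.set_index("gene")["orthogroup"]
    if not membership.index.is_unique:
        raise ValueError("a gene appears in more than one orthogroup")
    og_a = rbh["donor_gene"].map(membership)
    og_b = rbh["wheat_gene"].map(membership)
    unassigned = og_a.isna() | og_b.isna()
    if unassigned.any():
        log.info("orthologue_pairs: %d pairs dropped (unassigned member)", int(unassigned.sum()))
    kept = rbh[~unassigned & (og_a == og_b)].reset_index(drop=True)
    return kept


def novel_genes(
    orthogroups: pd.DataFrame,
    donor_species: str,
    wheat_species: str | Sequence[str],
    all_donor_genes: Iterable[str] | None = None,
) -> set[str]:
    """Donor genes with no wheat counterpart: members of orthogroups that
    contain no wheat protein, plus (when the full donor gene list is given)
    donor genes assigned to no orthogroup."""
    wheat = {wheat_species} if isinstance(wheat_species, str) else set(wheat_species)
    has_wheat = orthogroups.groupby("orthogroup")["species"].apply(
        lambda s: bool(set(s) & wheat)
    )
    donor_rows = orthogroups[orthogroups["species"] == donor_species]
    novel = set(donor_rows[~donor_rows["orthogroup"].map(has_wheat)]["gene"])
    if all_donor_genes is not None:
        assigned = set(donor_rows["gene"])
        novel |= set(all_donor_genes) - assigned
    return novel


def expanded_orthogroups(
    orthogroups: pd.DataFrame,
    donor_species: str,
    wheat_species: str | Sequence[str],
    min_donor: int = 4,
    expansion_factor: float = 2.0,
) -> set[str]:
    """Orthogroups expanded in the donor: >= ``min_donor`` donor proteins and
    more than ``expansion_factor`` times the wheat protein count."""
    wheat = {wheat_species} if isinstance(wheat_species, str) else set(wheat_species)
    counts = orthogroups.groupby(["orthogroup", "species"])["gene"].count().unstack(fill_value=0)
    donor_n = counts.get(donor_species, pd.Series(0, index=counts.index))
    wheat_n = sum(
        (counts.get(sp, pd.Series(0, index=counts.index)) for sp in wheat),
        start=pd.Series(0, index=counts.index),
    )
    keep = (donor_n >= min_donor) & (donor_n > expansion_factor * wheat_n)
    return set(counts.index[keep])


def classify_introgressed_genes(
    gene_depth: Mapping[str, float] | pd.Series,
    pairs: pd.DataFrame,
    donor_gene_contigs: Mapping[str, str] | pd.Series,
    wheat_gene_positions: pd.DataFrame,
    segments: Sequence[SegmentBlock],
    depth_threshold: float,
) -> set[str]:
    """Donor genes introgressed in one line, by depth and contig anchoring.

    A donor gene is introgressed iff (i) its mean mapping depth across its
    length is >= ``depth_threshold`` (per line; ~0.6x the line's mean
    sequencing depth) and (ii) it sits on a donor contig carrying at least
    one *anchoring* gene — a donor gene in an orthologue pair whose wheat
    partner starts inside a called donor-introgression block and which
    itself passes the depth threshold.  The contig requirement is
    deliberately conservative: depth alone cannot distinguish an introgressed
    gene from a conserved paralogue attracting cross-mapped reads.

    Donor genes with no known contig are excluded and logged.
    """
    depth = pd.Series(gene_depth, dtype=float) if not isinstance(gene_depth, pd.Series) else gene_depth
    contigs = pd.Series(donor_gene_contigs) if not isinstance(donor_gene_contigs, pd.Series) else donor_gene_contigs

    intro_blocks = [b for b in segments if b.origin == "donor_introgression"]

    def in_introgression(chrom: str, start: int) -> bool:
        return any(b.chrom == chrom and b.start <= start < b.end for b in intro_blocks)

    wheat_pos = wheat_gene_positions.set_index("gene")
    anchored_contigs: set[str] = set()
    for row in pairs.itertuples(index=False):
        d, w = row.donor_gene, row.wheat_gene
        if w not in wheat_pos.index or d not in contigs.index:
            continue
        if float(depth.get(d, 0.0)) < depth_threshold:
            continue
        loc = wheat_pos.loc[w]
        if in_introgression(str(loc["chrom"]), int(loc["start"])):
            anchored_contigs.add(contigs[d])

    result: set[str] = set()
    n_no_contig = 0
    for gene, d in depth.items():
        if d < depth_threshold:
            continue
        if gene not in contigs.index:
            n_no_contig += 1
            continue
        if contigs[gene] in anchored_contigs:
            result.add(str(gene))
    if n_no_contig:
        log.info("classify_introgressed_genes: %d genes with unknown contig excluded", n_no_contig)
    return result


RESISTANCE_CLASSES = ("NLR", "protein_kinase", "ABC_transporter", "WAK")


def candidate_resistance_filter(
    depth_matrix: pd.DataFrame,
    positive_lines: Sequence[str],
    negative_lines: Sequence[str],
    gene_classes: Mapping[str, str] | pd.Series,
    min_depth: float = DEFAULT.resistance_min_depth,
    classes: Sequence[str] = RESISTANCE_CLASSES,
) -> pd.DataFrame:
    """Shortlist resistance-gene candidates uniquely covered in the
    phenotype-positive lines.

    Keeps genes of the supplied resistance classes with mean mapping depth
    >= ``min_depth`` in every positive line and < ``min_depth`` in every
    negative line.  The output flags genes for manual review (coverage
    uniformity along the gene cannot be judged from mean depth alone) rather
    than asserting unique introgression.
    """
    if not list(positive_lines):
        raise ValueError("at least one positive line is required")
    cls = pd.Series(gene_classes) if not isinstance(gene_classes, pd.Series) else gene_classes
    genes = depth_matrix.index
    in_class = genes.map(cls).isin(set(classes))
    pos_ok = (depth_matrix[list(positive_lines)] >= min_depth).all(axis=1)
    if list(negative_lines):
        neg_ok = (depth_matrix[list(negative_lines)] < min_depth).all(axis=1)
    else:
        neg_ok = pd.Series(True, index=genes)
    keep = in_class & pos_ok & neg_ok
    out = depth_matrix[keep].copy()
    out.insert(0, "gene_class", genes[keep].map(cls))
    out["review"] = "manual_review_required"
    return out


def novelty_by_identity(
    best_identity: Mapping[str, float] | pd.Series,
    kind: str = "protein",
    threshold: float | None = None,
) -> pd.Series:
    """Flag sequences as novel when their best reference hit falls below the
    identity threshold (85% for NB-ARC domains, 80% for whole proteins; a
    missing hit counts as identity 0 and is always novel)."""
    if threshold is None:
        threshold = {
            "domain": DEFAULT.novelty_domain_identity,
            "protein": DEFAULT.novelty_protein_identity,
        }[kind]
    ident = pd.Series(best_identity, dtype=float) if not isinstance(best_identity, pd.Series) else best_identity
    return ident.fillna(0.0) < threshold
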