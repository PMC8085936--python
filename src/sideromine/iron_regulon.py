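"""Iron-regulon census, cell-surface-signalling clusters and Fur boxes.

Fluorescent pseudomonads devote a sizeable fraction of their coding
capacity to iron homeostasis. This module provides the bookkeeping side
of that analysis: per-category tallies of an already-annotated gene
table expressed as percent of total CDS, grouping of FecI-family ECF
sigma factors with their FecR-type anti-sigma partners and TonB-
dependent receptors into cell-surface-signalling (CSS) clusters, and
scanning promoter DNA for the ~19 bp Fur operator consensus with a
mismatch budget.

The upstream HMM-based iron annotation is consumed as a labelled table
and deliberately not re-implemented; the default Fur consensus is the
classical E. coli operator (GATAATGATAATCATTATC) with up to two
mismatches, both configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io_formats import FeatureRecord, SequenceRecord

FUR_CONSENSUS = "GATAATGATAATCATTATC"
DEFAULT_MAX_MISMATCHES = 2
DEFAULT_MAX_GAP = 500
DEFAULT_PROMOTER_LENGTH = 300

CENSUS_CATEGORIES = (
    "regulation", "acquisition", "storage", "efflux", "ros_defence", "other",
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class CensusError(ValueError):
    """Invalid census input (unknown category, bad totals)."""


@dataclass
class IronCensus:
    total_cds: int
    category_counts: dict[str, int]
    category_percent: dict[str, float]

    @property
    def total_iron_genes(self) -> int:
        return sum(self.category_counts.values())

    @property
    def total_percent(self) -> float:
        return 100.0 * self.total_iron_genes / self.total_cds


@dataclass
class CssCluster:
    cluster_id: str
    sigma_gene: str
    anti_sigma_gene: str | None = None
    receptor_gene: str | None = None
    fur_box_in_promoter: bool = False


@dataclass(frozen=True)
class FurBoxHit:
    seq_id: str
    start: int  # 0-based, forward-strand coordinate of the window
    strand: str
    mismatches: int
    matched_sequence: str  # window read 5'->3' on the hit strand


def census(table: pd.DataFrame, total_cds: int) -> IronCensus:
    """Tally iron-category labels and express them as percent of CDS.

    ``table`` is an annotation table whose ``category`` column uses the
    controlled vocabulary; rows with a null category are ignored.
    """
    categorized = table.dropna(subset=["category"]) if "category" in table else table.iloc[0:0]
    counts = {cat: 0 for cat in CENSUS_CATEGORIES}
    for label in categorized["category"] if not categorized.empty else []:
        if label not in counts:
            raise CensusError(f"unknown iron category {label!r}")
        counts[label] += 1
    n_iron = sum(counts.values())
    if total_cds < n_iron:
        raise CensusError(
            f"total_cds {total_cds} smaller than categorized rows {n_iron}"
        )
    percent = {cat: 100.0 * n / total_cds for cat, n in counts.items()}
    return IronCensus(total_cds=total_cds, category_counts=counts,
                      category_percent=percent)


def group_css_clusters(
    features: list[FeatureRecord],
    roles: dict[str, str],
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[CssCluster]:
    """Group sigma / anti-sigma / receptor genes into CSS clusters.

    Each sigma-factor gene seeds one cluster; unused anti-sigma and
    receptor genes on the same contig are attached when within
    ``max_gap`` bp (inter-gene gap) of a gene already in the cluster —
    so a receptor just past the anti-sigma still joins, mirroring the
    sigma / anti-sigma / receptor operon layout. The sweep is
    left-to-right and deterministic.
    """
    genes = sorted(
        (f for f in features if f.feature_type == "gene"),
        key=lambda f: (f.seq_id, f.start),
    )
    role_of = {
        f.attributes.get("ID", ""): roles.get(f.attributes.get("ID", ""), "other")
        for f in genes
    }
    used: set[str] = set()
    clusters: list[CssCluster] = []

    def gap(a: FeatureRecord, b: FeatureRecord) -> int:
        lo, hi = sorted([a, b], key=lambda f: f.start)
        return max(0, hi.start - lo.end)

    for f in genes:
        gene_id = f.attributes.get("ID", "")
        if role_of[gene_id] != "sigma":
            continue
        cluster = CssCluster(cluster_id=f"css{len(clusters) + 1}",
                             sigma_gene=gene_id)
        members = [f]
        for g in genes:
            other_id = g.attributes.get("ID", "")
            if (other_id == gene_id or g.seq_id != f.seq_id
                    or other_id in used
                    or min(gap(m, g) for m in members) > max_gap):
                continue
            role = role_of[other_id]
            if role == "anti_sigma" and cluster.anti_sigma_gene is None:
                cluster.anti_sigma_gene = other_id
                used.add(other_id)
                members.append(g)
            elif role == "receptor" and cluster.receptor_gene is None:
                cluster.receptor_gene = other_id
                used.add(other_id)
                members.append(g)
        clusters.append(cluster)
    return clusters


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def scan_fur_boxes(
    seq: SequenceRecord,
    consensus: str = FUR_CONSENSUS,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> list[FurBoxHit]:
    """Report every window within ``max_mismatches`` of the consensus.

    Both strands are scanned; a minus-strand hit is reported at the
    forward-strand start of its window with the window read 5'->3' on
    the minus strand. Overlapping hits are allowed. Hits are sorted by
    (seq_id, start, strand).
    """
    if seq.molecule != "dna":
        raise ValueError("scan_fur_boxes expects a DNA record")
    n, w = len(seq.residues), len(consensus)
    if w > n:
        return []
    rc_consensus = reverse_complement(consensus)
    sequence = seq.residues
    hits: list[FurBoxHit] = []
    for start in range(n - w + 1):
        window = sequence[start:start + w]
        mm_fwd = sum(1 for a, b in zip(window, consensus) if a != b)
        if mm_fwd <= max_mismatches:
            hits.append(
                FurBoxHit(seq_id=seq.id, start=start, strand="+",
                          mismatches=mm_fwd, matched_sequence=window)
            )
        mm_rev = sum(1 for a, b in zip(window, rc_consensus) if a != b)
        if mm_rev <= max_mismatches:
            hits.append(
                FurBoxHit(seq_id=seq.id, start=start, strand="-",
                          mismatches=mm_rev,
                          matched_sequence=reverse_complement(window))
            )
    hits.sort(key=lambda h: (h.seq_id, h.start, h.strand))
    return hits


def promoter_region(
    gene: FeatureRecord, contig_length: int,
    length: int = DEFAULT_PROMOTER_LENGTH,
) -> tuple[int, int]:
    """Strand-aware promoter window upstream of a gene start (0-based)."""
    if gene.strand == "+":
        return max(0, gene.start - length), gene.start
    return gene.end, min(contig_length, gene.end + length)
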