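"""The (specificity code -> monomer) knowledge base.

Known pyoverdine and azotobactin structures from the literature are
mapped onto their biosynthetic gene clusters by the colinearity rule:
the i-th peptide-forming module (genes in curated biosynthetic order,
modules N->C within each gene) incorporates the i-th monomer of the
published peptide. Each pairing yields one SpecificityRecord tying the
module's Stachelhaus and extended codes to its monomer.

Monomer labels keep side-chain hydroxylation/acylation exactly as
published (OHAsp vs Asp, OHOrn vs Orn, ...), so a database match
predicts the decorated monomer the source structure asserts.

The packaged default database (``specificity_db.tsv``) is a synthetic
reconstruction — deterministic, well-separated codes, one per monomer
of the controlled vocabulary — not literature codes; see its header
and the methods documentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import data_path
from .adomain_sig import AdenylationDomain

#: Controlled monomer vocabulary: proteinogenic residues the pipeline
#: meets plus the non-proteinogenic and decorated monomers of
#: pyoverdine-type peptides (ornithine and its hydroxy/acyl/cyclo forms,
#: citrulline, homoserine, diaminobutyrate, hydroxy-aspartate).
MONOMER_VOCABULARY = frozenset({
    "Ala", "Arg", "Asn", "Asp", "Cit", "Dab", "Gln", "Glu", "Gly", "His",
    "Hse", "Ile", "Leu", "Lys", "Met", "Orn", "Phe", "Pro", "Ser", "Thr",
    "Trp", "Tyr", "Val",
    "OHAsp", "OHOrn", "cOHOrn", "fOHOrn", "AcOHOrn",
    "Xaa",
})


class KnowledgeBaseError(ValueError):
    """Curation or database construction failure."""


@dataclass(frozen=True)
class SpecificityRecord:
    """One (code -> monomer) fact with its provenance."""

    stachelhaus_code: str
    extended_code: str
    monomer: str
    source_cluster: str
    source_domain: tuple[str, int] = ("", 0)  # (protein_id, module_index)
    ambiguous: bool = False
    extra_sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.monomer not in MONOMER_VOCABULARY:
            raise KnowledgeBaseError(f"monomer {self.monomer!r} not in vocabulary")
        if len(self.stachelhaus_code) != 10:
            raise KnowledgeBaseError(
                f"stachelhaus code {self.stachelhaus_code!r} is not 10 letters"
            )
        if len(self.extended_code) != 34:
            raise KnowledgeBaseError(
                f"extended code for {self.monomer} is not 34 letters"
            )


@dataclass
class CuratedCluster:
    """A literature cluster: gene order plus its published monomer sequence."""

    cluster_id: str
    organism: str
    siderophore_name: str
    ordered_gene_ids: list[str]
    published_monomers: list[str]
    protein_fasta: str | None = None
    skip: bool = False

    def __post_init__(self) -> None:
        if not self.ordered_gene_ids:
            raise KnowledgeBaseError(f"{self.cluster_id}: no genes")
        if not self.published_monomers:
            raise KnowledgeBaseError(f"{self.cluster_id}: no monomers")


def assign_by_colinearity(
    cluster: CuratedCluster,
    domains_by_gene: dict[str, list[AdenylationDomain]],
) -> list[SpecificityRecord]:
    """Pair each peptide-forming domain with its published monomer.

    ``domains_by_gene`` maps each curated gene id to that protein's
    A-domains (module order N->C); genes are concatenated in curated
    order. A count mismatch raises with a per-gene breakdown rather than
    silently truncating.
    """
    flat: list[AdenylationDomain] = []
    per_gene = {}
    for gene_id in cluster.ordered_gene_ids:
        gene_domains = domains_by_gene.get(gene_id, [])
        per_gene[gene_id] = len(gene_domains)
        flat.extend(gene_domains)
    if len(flat) != len(cluster.published_monomers):
        raise KnowledgeBaseError(
            f"{cluster.cluster_id}: {len(cluster.published_monomers)} published "
            f"monomers but {len(flat)} A-domains (per gene: {per_gene})"
        )
    return [
        SpecificityRecord(
            stachelhaus_code=dom.stachelhaus_code,
            extended_code=dom.extended_code,
            monomer=monomer,
            source_cluster=cluster.cluster_id,
            source_domain=(dom.protein_id, dom.module_index),
        )
        for dom, monomer in zip(flat, cluster.published_monomers)
    ]


def build_database(
    assignments: list[list[SpecificityRecord]],
) -> list[SpecificityRecord]:
    """Merge per-cluster assignments into the final database.

    Exact-duplicate (code, monomer) pairs collapse into one record with
    multi-source provenance; identical codes mapped to different
    monomers are all retained and flagged ambiguous. Output order is
    sorted by (code, monomer), so the build is independent of input
    cluster order.
    """
    if not assignments or all(not a for a in assignments):
        raise KnowledgeBaseError("no clusters to build a database from")
    by_key: dict[tuple[str, str], SpecificityRecord] = {}
    sources: dict[tuple[str, str], list[str]] = {}
    for records in assignments:
        for rec in records:
            key = (rec.stachelhaus_code, rec.monomer)
            if key in by_key:
                sources[key].append(rec.source_cluster)
            else:
                by_key[key] = rec
                sources[key] = [rec.source_cluster]
    by_code: dict[str, list[tuple[str, str]]] = {}
    for code, monomer in by_key:
        by_code.setdefault(code, []).append((code, monomer))
    merged = []
    for key, rec in by_key.items():
        ambiguous = len(by_code[key[0]]) > 1
        extra = tuple(sorted(set(sources[key]) - {rec.source_cluster}))
        merged.append(
            SpecificityRecord(
                stachelhaus_code=rec.stachelhaus_code,
                extended_code=rec.extended_code,
                monomer=rec.monomer,
                source_cluster=rec.source_cluster,
                source_domain=rec.source_domain,
                ambiguous=ambiguous,
                extra_sources=extra,
            )
        )
    merged.sort(key=lambda r: (r.stachelhaus_code, r.monomer))
    return merged


def read_curated_table(path) -> list[CuratedCluster]:
    """Read the curation TSV (gene order and monomer list per cluster)."""
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    clusters = []
    for row in table.itertuples(index=False):
        clusters.append(
            CuratedCluster(
                cluster_id=row.cluster_id,
                organism=row.organism,
                siderophore_name=row.siderophore_name,
                ordered_gene_ids=row.gene_order.split(","),
                published_monomers=row.monomers.split(","),
                protein_fasta=row.fasta_path or None,
                skip=str(row.skip) in ("1", "true", "True"),
            )
        )
    return clusters


def read_database(path=None) -> list[SpecificityRecord]:
    """Load a specificity database TSV (default: the packaged one)."""
    path = path if path is not None else data_path("specificity_db.tsv")
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    records = []
    for row in table.itertuples(index=False):
        records.append(
            SpecificityRecord(
                stachelhaus_code=row.stachelhaus_code,
                extended_code=row.extended_code,
                monomer=row.monomer,
                source_cluster=row.source_cluster,
                source_domain=(row.protein_id, int(row.module_index)),
                ambiguous=bool(int(getattr(row, "ambiguous", 0) or 0)),
            )
        )
    if not records:
        raise KnowledgeBaseError(f"empty database {path}")
    return records


def write_database(records: list[SpecificityRecord], path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("stachelhaus_code\textended_code\tmonomer\tsource_cluster\t"
                 "protein_id\tmodule_index\tambiguous\textra_sources\n")
        for r in records:
            fh.write("\t".join([
                r.stachelhaus_code, r.extended_code, r.monomer,
                r.source_cluster, r.source_domain[0], str(r.source_domain[1]),
                str(int(r.ambiguous)), ",".join(r.extra_sources),
            ]) + "\n")
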