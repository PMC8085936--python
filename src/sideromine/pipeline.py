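"""End-to-end orchestration: proteins in, predicted structure out.

Stages: read NRPS proteins -> detect A-domains and extract specificity
codes -> match codes against the knowledge base -> assign E/TE domains
by scaffold alignment -> order modules (chromophore-initiating gene
first) -> assemble and render the structure. Every run writes its
intermediate artifacts plus a manifest (config hash, database/anchor
identity, seed), and identical config + inputs give identical bytes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__, data_path
from .adomain_sig import (
    DEFAULT_MIN_SCORE,
    AdenylationDomain,
    detect_adomains,
    extract_all,
    load_anchor,
)
from .code_knowledgebase import read_database
from .io_formats import SequenceRecord, read_fasta, read_gff3
from .structure_assembly import (
    NrpsModule,
    PredictedStructure,
    TailoringGeneSet,
    assemble,
    order_modules,
    render,
    render_long_style,
)
from .substrate_matching import DEFAULT_THRESHOLD, match_domain
from .synthetic_nrps import load_scaffolds


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending record."""


@dataclass
class PipelineConfig:
    """All knobs of a prediction run, validated before any compute."""

    proteins: str
    database: str | None = None  # None -> packaged knowledge base
    features: str | None = None
    gene_order: list[str] | None = None
    chromophore_gene: str | None = None
    chromophore_module_count: int = 3
    tailoring: set[str] = field(default_factory=set)
    threshold: float = DEFAULT_THRESHOLD
    min_score: float = DEFAULT_MIN_SCORE
    anchor_fasta: str | None = None
    anchor_positions: str | None = None
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        if not 0.0 <= self.threshold <= 100.0:
            raise PipelineError(f"config: threshold {self.threshold} outside [0,100]")
        for name in ("proteins", "database", "features", "anchor_fasta",
                     "anchor_positions"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise PipelineError(f"config: {name} path {value!r} does not exist")

    def manifest_hash(self) -> str:
        # out_dir is where results land, not what they are: exclude it so
        # re-running the same analysis elsewhere reproduces the same stamp
        payload = {k: sorted(v) if isinstance(v, set) else v
                   for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PredictionResult:
    structure: PredictedStructure
    rendered: str
    rendered_long: str
    modules: list[NrpsModule]
    domains: list[AdenylationDomain]
    manifest: dict


def _assign_architecture(
    protein: SequenceRecord,
    a_regions: list[tuple[int, int]],
    scaffolds: dict[str, str],
    min_score: float,
) -> list[set[str]]:
    """Domain complement per module from scaffold alignment hits.

    An E domain belongs to module i when an E-scaffold hit falls between
    A-domain i and the next A-domain; a TE hit after the last A-domain
    marks the terminal module.
    """
    e_record = SequenceRecord(id="E", residues=scaffolds["E"])
    te_record = SequenceRecord(id="TE", residues=scaffolds["TE"])
    e_hits = detect_adomains(protein, e_record, min_score=min_score)
    te_hits = detect_adomains(protein, te_record, min_score=min_score)
    domain_sets: list[set[str]] = []
    for i, (_, a_end) in enumerate(a_regions):
        next_start = (
            a_regions[i + 1][0] if i + 1 < len(a_regions) else len(protein)
        )
        domain_set = {"C", "A", "T"}
        if any(a_end <= s and e <= next_start for s, e in e_hits):
            domain_set.add("E")
        if i + 1 == len(a_regions) and any(s >= a_end for s, _ in te_hits):
            domain_set.add("TE")
        domain_sets.append(domain_set)
    return domain_sets


def run_predict(config: PipelineConfig) -> PredictionResult:
    """Run the full prediction pipeline under one config."""
    config.validate()
    anchor = load_anchor(config.anchor_fasta, config.anchor_positions)
    scaffolds = load_scaffolds()
    db = read_database(config.database)

    proteins = read_fasta(config.proteins, molecule="protein")
    by_id = {p.id: p for p in proteins}

    if config.gene_order:
        missing = [g for g in config.gene_order if g not in by_id]
        if missing:
            raise PipelineError(f"stage order: genes {missing} not in FASTA")
        ordered_ids = list(config.gene_order)
    elif config.features:
        feats = read_gff3(config.features)
        gene_feats = sorted(
            (f for f in feats if f.feature_type == "gene"),
            key=lambda f: (f.seq_id, f.start),
        )
        ordered_ids = [f.attributes.get("ID", "") for f in gene_feats]
    else:
        ordered_ids = [p.id for p in proteins]

    genes: list[tuple[str, list[NrpsModule]]] = []
    all_domains: list[AdenylationDomain] = []
    for gene_id in ordered_ids:
        protein = by_id[gene_id]
        try:
            domains = extract_all(protein, anchor, min_score=config.min_score)
        except ValueError as exc:
            raise PipelineError(f"stage codes: {exc}") from exc
        regions = [d.region for d in domains]
        domain_sets = _assign_architecture(
            protein, regions, scaffolds, config.min_score
        )
        modules = []
        for domain, domain_set in zip(domains, domain_sets):
            result = match_domain(domain, db, threshold=config.threshold)
            modules.append(
                NrpsModule(
                    gene_id=gene_id,
                    module_index_in_gene=domain.module_index,
                    domain_set=domain_set,
                    match=result,
                )
            )
        genes.append((gene_id, modules))
        all_domains.extend(domains)

    ordered = order_modules(genes, chromophore_gene=config.chromophore_gene)
    chromo = (
        config.chromophore_module_count if config.chromophore_gene else 0
    )
    structure = assemble(
        ordered,
        TailoringGeneSet(present=set(config.tailoring)),
        chromophore_modules=chromo,
    )
    manifest = {
        "tool": "sideromine",
        "version": __version__,
        "config_hash": config.manifest_hash(),
        "database": config.database or str(data_path("specificity_db.tsv")),
        "anchor": config.anchor_fasta or str(data_path("synthetic_anchor.fasta")),
        "seed": config.seed,
        "n_proteins": len(proteins),
        "n_domains": len(all_domains),
    }
    result = PredictionResult(
        structure=structure,
        rendered=render(structure),
        rendered_long=render_long_style(structure),
        modules=ordered,
        domains=all_domains,
        manifest=manifest,
    )
    if config.out_dir:
        _write_artifacts(result, config)
    return result


def _write_artifacts(result: PredictionResult, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = result.manifest["config_hash"]
    with open(out / "domains.tsv", "w", newline="\n") as fh:
        fh.write(f"# manifest={stamp}\n")
        fh.write("protein_id\tmodule_index\tstart\tend\tstachelhaus_code\t"
                 "extended_code\tmapped_fraction\talignment_score\n")
        for d in result.domains:
            fh.write(
                f"{d.protein_id}\t{d.module_index}\t{d.region[0]}\t"
                f"{d.region[1]}\t{d.stachelhaus_code}\t{d.extended_code}\t"
                f"{d.mapped_fraction:.4f}\t{d.alignment_score:.1f}\n"
            )
    with open(out / "matches.tsv", "w", newline="\n") as fh:
        fh.write(f"# manifest={stamp}\n")
        fh.write("gene_id\tmodule_index\tbest_monomer\tbest_identity\t"
                 "extended_identity\tties\tdomains\n")
        for m in result.modules:
            fh.write(
                f"{m.gene_id}\t{m.module_index_in_gene}\t"
                f"{m.match.best_monomer}\t{m.match.best_identity:.1f}\t"
                f"{m.match.extended_identity:.1f}\t"
                f"{'|'.join(m.match.ties)}\t"
                f"{','.join(sorted(m.domain_set))}\n"
            )
    structure_payload = {
        "manifest": result.manifest,
        "chromophore": result.structure.chromophore,
        "residues": [
            {"monomer": r.monomer, "d_configured": r.d_configured,
             "decoration": r.decoration}
            for r in result.structure.residues
        ],
        "rendered": result.rendered,
        "rendered_long_style": result.rendered_long,
    }
    with open(out / "structure.json", "w", newline="\n") as fh:
        json.dump(structure_payload, fh, indent=2)
        fh.write("\n")
    with open(out / "manifest.json", "w", newline="\n") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
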