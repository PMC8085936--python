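"""Synthetic NRPS clusters with known ground truth.

Every downstream stage (domain detection, code extraction, database
matching, structure assembly) is testable without downloads because this
module builds multi-modular NRPS proteins from fixed synthetic domain
scaffolds: each module is C + A + T, with the requested monomer's
signature residues substituted into the A scaffold at the anchored
Stachelhaus/extended positions, an E domain appended for epimerized
monomers and a TE domain on the last module. Optional leading
chromophore-precursor modules on the first gene mirror the pvdL-like
gene of real pyoverdine clusters.

Planting edits a fixed scaffold rather than sampling free sequence, so
alignment-based re-extraction is exact at zero mutations — the
generator's ground truth is a construction oracle for the pipeline.
``code_mutations`` randomizes k of the 10 Stachelhaus positions per
domain (the extended code changes consistently at shared positions),
degrading planted identity to exactly 100 - 10k percent.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from . import data_path
from .adomain_sig import ReferenceAnchor, load_anchor
from .code_knowledgebase import SpecificityRecord
from .io_formats import (
    FeatureRecord,
    SequenceRecord,
    read_fasta,
    write_fasta,
    write_gff3,
)
from .structure_assembly import TAILORING_VOCABULARY

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
CONTIG_ID = "synctg1"
GENE_SPACING_NT = 200


class SyntheticSpecError(ValueError):
    """Invalid generator specification."""


@dataclass
class GroundTruthModule:
    monomer: str
    epimerized: bool
    code: str  # 10-letter Stachelhaus code planted
    extended_code: str  # 34-letter extended code planted


@dataclass
class SyntheticSpec:
    """Everything needed to build one cluster deterministically."""

    n_genes: int
    modules_per_gene: list[int]
    ground_truth: list[GroundTruthModule]
    code_mutations: int = 0
    tailoring_genes: set[str] = field(default_factory=set)
    seed: int = 0
    chromophore_monomers: list["GroundTruthModule"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_genes < 1 or len(self.modules_per_gene) != self.n_genes:
            raise SyntheticSpecError("modules_per_gene must have n_genes entries")
        if any(m < 1 for m in self.modules_per_gene):
            raise SyntheticSpecError("each gene needs at least one module")
        if sum(self.modules_per_gene) != len(self.ground_truth):
            raise SyntheticSpecError(
                "sum(modules_per_gene) must equal the ground-truth length"
            )
        if not 0 <= self.code_mutations <= 10:
            raise SyntheticSpecError("code_mutations must be in 0..10")
        unknown = set(self.tailoring_genes) - TAILORING_VOCABULARY
        if unknown:
            raise SyntheticSpecError(f"unknown tailoring genes {sorted(unknown)}")


@dataclass
class SyntheticCluster:
    proteins: list[SequenceRecord]
    features: list[FeatureRecord]
    truth: SyntheticSpec


def load_scaffolds() -> dict[str, str]:
    """The packaged synthetic C/A/T/E/TE domain scaffolds."""
    records = read_fasta(data_path("synthetic_scaffolds.fasta"), "protein")
    return {rec.id.removeprefix("scaffold_"): rec.residues for rec in records}


def mutate_code(code: str, k: int, seed: int) -> str:
    """Substitute exactly k positions of a signature code.

    Each chosen position gets a different residue drawn uniformly from
    the 19 alternatives, so identity(input, output) is exactly
    (len - k) / len x 100.
    """
    if not 0 <= k <= len(code):
        raise SyntheticSpecError(f"k={k} outside 0..{len(code)}")
    rng = random.Random(seed)
    positions = rng.sample(range(len(code)), k)
    out = list(code)
    for pos in positions:
        out[pos] = rng.choice([a for a in AMINO_ACIDS if a != code[pos]])
    return "".join(out)


def truth_from_database(
    monomers: list[str],
    epimerized: list[bool],
    db: list[SpecificityRecord],
) -> list[GroundTruthModule]:
    """Build ground-truth modules by looking up codes in a database."""
    by_monomer = {rec.monomer: rec for rec in db}
    truth = []
    for monomer, epi in zip(monomers, epimerized):
        if monomer not in by_monomer:
            raise SyntheticSpecError(f"monomer {monomer!r} not in database")
        rec = by_monomer[monomer]
        truth.append(
            GroundTruthModule(
                monomer=monomer, epimerized=epi,
                code=rec.stachelhaus_code, extended_code=rec.extended_code,
            )
        )
    return truth


def _plant(
    a_scaffold: str,
    anchor: ReferenceAnchor,
    extended_code: str,
    stachelhaus_code: str,
) -> str:
    """Substitute signature residues into the A scaffold.

    Extended positions are planted first; Stachelhaus positions (a
    subset in the packaged anchor, but handled independently) are then
    planted so that shared positions are edited once, consistently with
    the 10-letter code.
    """
    seq = list(a_scaffold)
    for pos, res in zip(anchor.extended_positions, extended_code):
        seq[pos] = res
    for pos, res in zip(anchor.stachelhaus_positions, stachelhaus_code):
        seq[pos] = res
    return "".join(seq)


def _mutated_codes(
    module: GroundTruthModule, k: int, seed: int,
    anchor: ReferenceAnchor,
) -> tuple[str, str]:
    """Apply k mutations to the 10-code, mirrored into the extended code."""
    mutated = mutate_code(module.code, k, seed)
    ext = list(module.extended_code)
    shared = {
        pos: j for j, pos in enumerate(anchor.extended_positions)
    }
    for i, pos in enumerate(anchor.stachelhaus_positions):
        if pos in shared:
            ext[shared[pos]] = mutated[i]
    return mutated, "".join(ext)


def generate_cluster(
    spec: SyntheticSpec,
    anchor: ReferenceAnchor | None = None,
    scaffolds: dict[str, str] | None = None,
) -> SyntheticCluster:
    """Build the cluster's proteins and feature table from a spec.

    Deterministic given ``spec.seed``: the same spec yields byte-
    identical FASTA/GFF3 output.
    """
    anchor = anchor if anchor is not None else load_anchor()
    scaffolds = scaffolds if scaffolds is not None else load_scaffolds()
    a_scaffold = scaffolds["A"]

    modules = list(spec.ground_truth)
    proteins: list[SequenceRecord] = []
    features: list[FeatureRecord] = []
    genome_offset = 0

    for gene_idx in range(spec.n_genes):
        n_modules = spec.modules_per_gene[gene_idx]
        gene_id = f"nrps{gene_idx + 1}"
        is_last_gene = gene_idx == spec.n_genes - 1

        # chromophore-precursor modules lead the first gene (pvdL-like)
        # and are not part of the peptide ground truth
        all_modules: list[tuple[GroundTruthModule, bool]] = []
        if gene_idx == 0:
            for chromo in spec.chromophore_monomers:
                if not isinstance(chromo, GroundTruthModule):
                    raise SyntheticSpecError(
                        "chromophore_monomers must be GroundTruthModule "
                        "entries; use truth_from_database to build them"
                    )
                all_modules.append((chromo, False))
        start = sum(spec.modules_per_gene[:gene_idx])
        for j in range(n_modules):
            m = modules[start + j]
            all_modules.append((m, m.epimerized))

        seq_parts: list[str] = []
        feats: list[tuple[str, int, int]] = []  # (domain type, aa start, aa end)
        for mod_i, (module, epimerized) in enumerate(all_modules):
            k = spec.code_mutations
            dom_seed = (spec.seed * 1000003 + gene_idx * 101 + mod_i) % (2**31)
            code, ext = (
                _mutated_codes(module, k, dom_seed, anchor)
                if k
                else (module.code, module.extended_code)
            )
            pos = sum(len(p) for p in seq_parts)
            seq_parts.append(scaffolds["C"])
            feats.append(("C_domain", pos, pos + len(scaffolds["C"])))
            pos = sum(len(p) for p in seq_parts)
            seq_parts.append(_plant(a_scaffold, anchor, ext, code))
            feats.append(("A_domain", pos, pos + len(a_scaffold)))
            pos = sum(len(p) for p in seq_parts)
            seq_parts.append(scaffolds["T"])
            feats.append(("T_domain", pos, pos + len(scaffolds["T"])))
            if epimerized:
                pos = sum(len(p) for p in seq_parts)
                seq_parts.append(scaffolds["E"])
                feats.append(("E_domain", pos, pos + len(scaffolds["E"])))
        if is_last_gene:
            pos = sum(len(p) for p in seq_parts)
            seq_parts.append(scaffolds["TE"])
            feats.append(("TE_domain", pos, pos + len(scaffolds["TE"])))

        residues = "".join(seq_parts)
        proteins.append(
            SequenceRecord(id=gene_id, residues=residues, molecule="protein",
                           description=f"synthetic NRPS gene {gene_idx + 1}")
        )
        gene_start = genome_offset
        gene_end = gene_start + 3 * len(residues)
        features.append(
            FeatureRecord(
                seq_id=CONTIG_ID, start=gene_start, end=gene_end, strand="+",
                feature_type="gene",
                attributes={"ID": gene_id, "modules": str(len(all_modules))},
            )
        )
        for dom_type, aa_start, aa_end in feats:
            features.append(
                FeatureRecord(
                    seq_id=CONTIG_ID,
                    start=gene_start + 3 * aa_start,
                    end=gene_start + 3 * aa_end,
                    strand="+",
                    feature_type=dom_type,
                    attributes={"Parent": gene_id},
                )
            )
        genome_offset = gene_end + GENE_SPACING_NT

    return SyntheticCluster(proteins=proteins, features=features, truth=spec)


def expected_rendered(
    spec: SyntheticSpec, tailoring: set[str] | None = None
) -> str:
    """Ground-truth rendering of a spec — the construction oracle.

    Computed directly from the spec's monomers, epimerization flags and
    tailoring genes, independent of alignment or matching.
    """
    from .structure_assembly import (
        PredictedStructure,
        Residue,
        TailoringGeneSet,
        apply_tailoring,
        render,
    )

    tailoring = tailoring if tailoring is not None else set(spec.tailoring_genes)
    residues = [
        Residue(monomer=m.monomer, d_configured=m.epimerized)
        for m in spec.ground_truth
    ]
    residues = apply_tailoring(
        residues, TailoringGeneSet(present=set(tailoring)), terminal_te=True
    )
    return render(
        PredictedStructure(
            chromophore=bool(spec.chromophore_monomers), residues=residues
        )
    )


def write_cluster(cluster: SyntheticCluster, out_dir) -> dict[str, Path]:
    """Write proteins.fasta, features.gff3 and truth.tsv into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteins": out / "proteins.fasta",
        "features": out / "features.gff3",
        "truth": out / "truth.tsv",
    }
    write_fasta(cluster.proteins, paths["proteins"])
    write_gff3(cluster.features, paths["features"])
    with open(paths["truth"], "w", newline="\n") as fh:
        fh.write("module\tmonomer\tepimerized\tcode\textended_code\n")
        for i, m in enumerate(cluster.truth.ground_truth):
            fh.write(
                f"{i}\t{m.monomer}\t{int(m.epimerized)}\t{m.code}\t"
                f"{m.extended_code}\n"
            )
    return paths
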