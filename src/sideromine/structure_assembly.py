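"""Assemble ordered substrate calls into the predicted siderophore string.

Rules implemented:

* Module order — genes in biosynthetic order with the chromophore-
  initiating (pvdL-like) gene first; modules N->C within each gene.
  The first ``chromophore_modules`` modules of the pvdL-like gene build
  the chromophore precursor and are collapsed into the "Chromophore-"
  prefix, excluded from peptide residues.
* Stereochemistry — residue i is D-configured iff its module carries an
  epimerization (E) domain (a dual C/E domain annotated on module i+1
  also epimerizes residue i).
* Ornithine tailoring — with pvdA present, Orn is hydroxylated (OHOrn);
  acetylated on top (AcOHOrn) iff pvdYII is present and pvdF absent;
  formylated (fOHOrn) iff pvdF is present; a terminal OHOrn on a module
  with the thioesterase (TE) is rendered cyclic (cOHOrn). pvdF and
  pvdYII together are contradictory in this model and raise an error.

Rendering grammar (canonical): residues joined by "-"; D-configured
residues prefixed "D-"; decorations as "(Ac)", "f", "c" prepended to
the OHOrn label; "Chromophore-" prefix when a chromophore is present.
A long-name variant mirrors the typography often used in print
(Homoserine, Citrulline, delta-N acetylation marks).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .substrate_matching import MatchResult

ORN_FAMILY = {"Orn", "OHOrn", "AcOHOrn", "fOHOrn", "cOHOrn"}

TAILORING_VOCABULARY = frozenset({
    "pvdA", "pvdF", "pvdYII", "pvdN", "ptaA", "pvdH", "pvdE", "pvdQ",
    "pvdM", "pvdO", "pvdP", "mbtH",
})

_LONG_NAMES = {"Hse": "Homoserine", "Cit": "Citrulline"}


class AssemblyError(ValueError):
    """Inconsistent module architecture or tailoring-gene complement."""


@dataclass
class NrpsModule:
    """One NRPS module: its domain complement and substrate call."""

    gene_id: str
    module_index_in_gene: int
    domain_set: set[str]  # subset of {C, A, T, E, TE, MT}
    match: MatchResult | None = None


@dataclass
class TailoringGeneSet:
    """Tailoring genes present next to the NRPS genes."""

    present: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        unknown = self.present - TAILORING_VOCABULARY
        if unknown:
            raise AssemblyError(f"unknown tailoring genes {sorted(unknown)}")

    def __contains__(self, gene: str) -> bool:
        return gene in self.present


@dataclass
class Residue:
    monomer: str
    d_configured: bool = False
    decoration: str = "none"  # none | acetyl | formyl | cyclo


@dataclass
class PredictedStructure:
    chromophore: bool
    residues: list[Residue]

    @property
    def rendered(self) -> str:
        return render(self)


def order_modules(
    genes: list[tuple[str, list[NrpsModule]]],
    chromophore_gene: str | None = None,
) -> list[NrpsModule]:
    """Flatten genes (biosynthetic order) into one N->C module list.

    When ``chromophore_gene`` names a gene, that gene's modules are
    moved to the front (the pvdL-like gene initiates synthesis).
    A TE domain on a non-final module is recorded as a warning on the
    module list but the supplied order is kept.
    """
    ordered = list(genes)
    if chromophore_gene is not None:
        flagged = [g for g in ordered if g[0] == chromophore_gene]
        if flagged:
            ordered = flagged + [g for g in ordered if g[0] != chromophore_gene]
    modules = [m for _, gene_modules in ordered for m in gene_modules]
    return modules


def apply_stereochemistry(modules: list[NrpsModule]) -> list[bool]:
    """Per-module D-configuration flags from E-domain placement."""
    flags = []
    for i, module in enumerate(modules):
        own_e = "E" in module.domain_set
        dual_ce_next = (
            i + 1 < len(modules) and "C/E" in modules[i + 1].domain_set
        )
        flags.append(own_e or dual_ce_next)
    return flags


def apply_tailoring(
    residues: list[Residue],
    tailoring: TailoringGeneSet,
    terminal_te: bool = True,
) -> list[Residue]:
    """Decorate ornithine-family residues from the tailoring-gene set."""
    if "pvdF" in tailoring and "pvdYII" in tailoring:
        raise AssemblyError(
            "pvdF (formylation) and pvdYII (acetylation) are mutually "
            "exclusive in this model"
        )
    out = []
    last = len(residues) - 1
    for i, res in enumerate(residues):
        monomer, decoration = res.monomer, res.decoration
        if monomer in ORN_FAMILY:
            if "pvdA" in tailoring and monomer == "Orn":
                monomer = "OHOrn"
            if monomer == "OHOrn":
                if i == last and terminal_te:
                    monomer, decoration = "OHOrn", "cyclo"
                elif "pvdYII" in tailoring:
                    monomer, decoration = "OHOrn", "acetyl"
                elif "pvdF" in tailoring:
                    monomer, decoration = "OHOrn", "formyl"
        out.append(Residue(monomer=monomer, d_configured=res.d_configured,
                           decoration=decoration))
    return out


def _decorated(res: Residue) -> str:
    if res.decoration == "acetyl":
        return f"(Ac){res.monomer}"
    if res.decoration == "formyl":
        return f"f{res.monomer}"
    if res.decoration == "cyclo":
        return f"c{res.monomer}"
    return res.monomer


def render(structure: PredictedStructure) -> str:
    """Canonical string, e.g. ``Chromophore-OHAsp-...-D-Ser-cOHOrn``."""
    tokens = []
    if structure.chromophore:
        tokens.append("Chromophore")
    for res in structure.residues:
        token = _decorated(res)
        tokens.append(f"D-{token}" if res.d_configured else token)
    return "-".join(tokens)


def render_long_style(structure: PredictedStructure) -> str:
    """Print-style variant: long monomer names and delta-N acetyl marks."""
    tokens = []
    if structure.chromophore:
        tokens.append("Chromophore")
    for res in structure.residues:
        name = _LONG_NAMES.get(res.monomer, res.monomer)
        if res.decoration == "acetyl":
            token = f"(dAc)d{name}"
        elif res.decoration == "formyl":
            token = f"f{name}"
        elif res.decoration == "cyclo":
            token = f"OHcOrn" if res.monomer == "OHOrn" else f"c{name}"
        else:
            token = name
        tokens.append(f"D-{token}" if res.d_configured else token)
    return "-".join(tokens)


_TOKEN = re.compile(
    r"^(?P<d>D-)?(?P<dec>\(Ac\)|f(?=OHOrn)|c(?=OHOrn))?(?P<mono>\w+)$"
)


def parse(rendered: str) -> PredictedStructure:
    """Inverse of :func:`render` on canonical strings (for round-trip tests)."""
    if rendered == "":
        return PredictedStructure(chromophore=False, residues=[])
    tokens = rendered.split("-")
    merged: list[str] = []
    for tok in tokens:
        if tok == "D":
            merged.append("D-")
        elif merged and merged[-1] == "D-":
            merged[-1] = "D-" + tok
        else:
            merged.append(tok)
    chromophore = merged and merged[0] == "Chromophore"
    if chromophore:
        merged = merged[1:]
    residues = []
    for tok in merged:
        m = _TOKEN.match(tok)
        if not m:
            raise AssemblyError(f"unparseable residue token {tok!r}")
        dec = {"(Ac)": "acetyl", "f": "formyl", "c": "cyclo", None: "none"}[
            m.group("dec")
        ]
        residues.append(
            Residue(monomer=m.group("mono"), d_configured=bool(m.group("d")),
                    decoration=dec)
        )
    return PredictedStructure(chromophore=bool(chromophore), residues=residues)


def assemble(
    modules: list[NrpsModule],
    tailoring: TailoringGeneSet,
    chromophore_modules: int = 0,
) -> PredictedStructure:
    """Full assembly: stereochemistry, chromophore collapse, tailoring."""
    flags = apply_stereochemistry(modules)
    peptide = modules[chromophore_modules:]
    peptide_flags = flags[chromophore_modules:]
    residues = []
    for module, d_flag in zip(peptide, peptide_flags):
        if module.match is None:
            raise AssemblyError(
                f"module {module.gene_id}/{module.module_index_in_gene} "
                "has no substrate call"
            )
        residues.append(Residue(monomer=module.match.best_monomer,
                                d_configured=d_flag))
    terminal_te = bool(peptide) and "TE" in peptide[-1].domain_set
    residues = apply_tailoring(residues, tailoring, terminal_te=terminal_te)
    return PredictedStructure(
        chromophore=chromophore_modules > 0, residues=residues
    )
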