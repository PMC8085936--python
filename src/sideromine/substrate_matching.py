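"""Score query specificity codes against the knowledge base.

The substrate of an unassigned A-domain is called by percent identity of
its 10-residue Stachelhaus code to the database codes, with a >= 90%
acceptance threshold: below it the position is reported as the
placeholder monomer "Xaa". The extended 34-residue code acts only as a
tie-breaker between equally good Stachelhaus hits, never as a caller by
itself. Percent identity uses the full code length as denominator,
including invariant positions; a '-' (unmapped signature position) in
either code counts as a mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .adomain_sig import AdenylationDomain
from .code_knowledgebase import SpecificityRecord

DEFAULT_THRESHOLD = 90.0
UNKNOWN = "Xaa"


def identity(code_a: str, code_b: str) -> float:
    """Percent identity between two equal-length codes.

    100 x (matching positions) / length; a gap character '-' at a
    position in either code counts as a mismatch (even against another
    gap). Unequal lengths are an error.
    """
    if len(code_a) != len(code_b):
        raise ValueError(
            f"code length mismatch: {len(code_a)} vs {len(code_b)}"
        )
    matches = sum(
        1 for a, b in zip(code_a, code_b) if a == b and a != "-"
    )
    return 100.0 * matches / len(code_a)


@dataclass
class MatchResult:
    """Ranked database hits and the substrate call for one A-domain."""

    domain: AdenylationDomain
    best_monomer: str
    best_identity: float
    extended_identity: float
    ties: list[str]
    passed_threshold: bool
    hits: list[tuple[SpecificityRecord, float]] = field(default_factory=list)


def rank_hits(
    domain: AdenylationDomain, db: list[SpecificityRecord]
) -> list[tuple[SpecificityRecord, float]]:
    """All database records ranked by the documented sort keys.

    Primary: Stachelhaus identity (descending); then extended-code
    identity (descending); then monomer name (ascending) for a stable,
    deterministic order.
    """
    scored = [
        (
            rec,
            identity(domain.stachelhaus_code, rec.stachelhaus_code),
            identity(domain.extended_code, rec.extended_code),
        )
        for rec in db
    ]
    scored.sort(key=lambda t: (-t[1], -t[2], t[0].monomer))
    return [(rec, ident) for rec, ident, _ in scored]


def match_domain(
    domain: AdenylationDomain,
    db: list[SpecificityRecord],
    threshold: float = DEFAULT_THRESHOLD,
) -> MatchResult:
    """Call the substrate for one domain.

    The top-ranked monomer is accepted when its Stachelhaus identity
    reaches ``threshold``, otherwise the call is "Xaa". All monomers
    tied with the top hit on both identity keys are reported in
    ``ties`` (ambiguous records at rank 1 propagate every monomer they
    map to); the deterministic ``best_monomer`` is the lexicographically
    first of those.
    """
    if not db:
        raise ValueError("empty specificity database")
    ranked_full = [
        (
            rec,
            identity(domain.stachelhaus_code, rec.stachelhaus_code),
            identity(domain.extended_code, rec.extended_code),
        )
        for rec in db
    ]
    ranked_full.sort(key=lambda t: (-t[1], -t[2], t[0].monomer))
    top_rec, top_ident, top_ext = ranked_full[0]
    tied = sorted({
        rec.monomer
        for rec, ident, ext in ranked_full
        if ident == top_ident and ext == top_ext
    })
    passed = top_ident >= threshold
    return MatchResult(
        domain=domain,
        best_monomer=tied[0] if passed else UNKNOWN,
        best_identity=top_ident,
        extended_identity=top_ext,
        ties=tied,
        passed_threshold=passed,
        hits=[(rec, ident) for rec, ident, _ in ranked_full],
    )


def match_cluster(
    domains: list[AdenylationDomain],
    db: list[SpecificityRecord],
    threshold: float = DEFAULT_THRESHOLD,
) -> list[MatchResult]:
    """Call substrates for an ordered list of domains, order preserved."""
    return [match_domain(d, db, threshold=threshold) for d in domains]
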