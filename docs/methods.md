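# Methods

## Model and procedure

NRPS assembly lines are treated as strictly colinear: genes in
biosynthetic order, modules N→C within each gene, one monomer per
peptide-forming module. Structure prediction is a four-stage procedure:

1. **Detection.** A-domains are found by iterated local alignment of the
   query protein against a packaged reference A-domain: take the best
   local hit scoring at least `min_score`, mask it, and search the
   flanking segments recursively. This yields non-overlapping regions in
   N→C order; overlap conflicts resolve greedily by score, ties by
   leftmost start.
2. **Code extraction.** Each detected region is aligned globally (free
   end gaps) to the full reference, and the query residues aligned to the
   anchored reference positions are read off — `-` where the query has a
   gap. Two codes are produced per domain: the 10-residue Stachelhaus
   code and the 34-residue extended (8 Å) code. `mapped_fraction` records
   how many anchored positions landed on actual query residues.
3. **Matching.** Query codes score against the knowledge base by percent
   identity over the full code length (invariant positions included; gap
   counts as mismatch). A call is accepted at ≥ 90% Stachelhaus identity,
   otherwise the position is `Xaa`. The extended code only breaks ties,
   never calls by itself; residual ties are reported in full and resolved
   deterministically by monomer name — never randomly.
4. **Assembly.** Modules are flattened in gene order with the
   chromophore-initiating (pvdL-like) gene first; its leading
   `chromophore_module_count` modules (default 3) collapse into the
   `Chromophore-` prefix. Residue *i* is D-configured iff module *i*
   carries an E domain (or module *i*+1 an annotated dual C/E domain).
   Ornithine tailoring: pvdA hydroxylates Orn → OHOrn; OHOrn is
   acetylated when pvdYII is present and pvdF absent, formylated when
   pvdF is present; a terminal OHOrn on a TE-bearing final module is
   rendered cyclic (cOHOrn). pvdF together with pvdYII is rejected as
   contradictory: the two modifications compete for the same amine and
   no precedence rule is defensible from genomics alone.

Rendering follows a fixed grammar (`D-` prefix, `(Ac)`/`f`/`c`
decorations, `-` separators); a parser for the canonical form ships for
round-trip testing, and a long-name variant (`Homoserine`, `Citrulline`,
`(dAc)d` marks) mirrors common print typography.

## Reference anchor and knowledge base

The packaged reference anchor (`data/synthetic_anchor.fasta`) is a
**synthetic** 530-residue A-domain scaffold carrying the canonical Phe
signature `DAWTIAAICK` at the canonical pocket positions (235, 236, 239,
278, 299, 301, 322, 330, 331, 517 in reference numbering). The
34-position extended set is a documented superset of the 10 Stachelhaus
positions — 24 additional pocket-proximal positions — which makes the two
codes consistent at shared positions by construction. Positions live in
`data/anchor_positions.json`, not in code, so a curator can substitute a
literature anchor and position list without touching the implementation.

The packaged knowledge base (`data/specificity_db.tsv`) is likewise a
synthetic reconstruction: one code per monomer of the controlled
vocabulary, all starting `D` and ending `K` (the conserved Asp/Lys of
real codes), with pairwise Hamming distance ≥ 6/10 in the variable
positions so that single-code matching is unambiguous at realistic
mutation loads. Extended codes agree with their Stachelhaus codes at the
shared anchor positions. These are *not* literature codes; runs against
real genomes require a curated database built from published clusters
via `builddb` (curation table format: `data/curated_clusters.tsv`).

## Synthetic clusters: what they emulate, what they do not

`synthetic_nrps` builds proteins as concatenated fixed scaffolds
(C 440 aa, A 530 aa, T 85 aa, E 430 aa, TE 245 aa; random sequences at
typical amino-acid frequencies, frozen as package data) with signature
residues substituted into the A scaffold. This emulates the anatomy that
matters for the pipeline — multi-modular architecture, planted
specificity codes at controlled identity, epimerization placement,
chromophore-precursor modules, tailoring complements — and provides exact
ground truth: with zero mutations, extraction must reproduce the planted
codes verbatim, so end-to-end recovery is a true construction oracle.

It does **not** emulate real inter-domain linkers, domain-sequence
divergence between modules, dual C/E domain sequences, nucleotide-level
gene models, or promoter DNA. Passing the recovery tests therefore
demonstrates the correctness of the extraction/matching/assembly logic,
not detection sensitivity on diverged natural NRPS sequences — on real
proteins, detection hinges on genuine homology to the chosen anchor.

## Numerical choices

* Alignment: BLOSUM62, gap open 10 / extend 1; local mode for detection,
  global with free end gaps for extraction (Biopython `PairwiseAligner`).
* `min_score = 150` for detection, calibrated once against the packaged
  anchor: the self-hit scores 2767 while the maximum of 1,000
  residue-shuffled references is 83 (99th percentile 57); 150 sits a
  comfortable margin above noise and far below any true hit. The same
  threshold is used for E/TE scaffold assignment.
* Identity denominator is the full code length (10 or 34), invariant
  positions included; `-` counts as mismatch even opposite another `-`.
* Matching tie-break order: Stachelhaus identity, then extended-code
  identity, then monomer name; fully deterministic.
* Fur scanning: default consensus `GATAATGATAATCATTATC` (the classical
  E. coli operator), ≤ 2 mismatches, both strands, overlapping hits
  allowed, output sorted by (seq_id, start, strand). Promoters default to
  300 bp upstream of the strand-aware gene start. CSS grouping attaches
  unused anti-sigma/receptor genes within 500 bp (inter-gene gap) of a
  gene already in the cluster, in a left-to-right sweep.
* The t-test interprets "±" summaries as sample standard deviations, not
  standard errors — only that reading is internally consistent with the
  reported significance of the foliar-area comparison (pooled t = 3.50 on
  10 df); Welch's variant is available behind a flag. Foliar-area units
  are carried as given in the source summaries (mm), where mm² would be
  expected for an area.
* Species delineation uses strict `<` for "below threshold"; boundary
  equality falls on the same-species side.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` validate recovery on 100
random clusters of 1–2 genes and 1–2 modules per gene (larger clusters
add alignment time but nothing conceptually new; the worked example runs
a 5-gene, 14-module cluster), oracle equivalence of matching on 1,000
random query/database pairs, Fur scanning against an independent
brute-force scan on 100 random 10 kb sequences at 0–3 mismatches, and
extraction fidelity under 100 random ≤ 10-residue indels placed outside
signature columns.

## Known limitations

* Colinearity is assumed strict; iterative or trans-acting modules must
  be excluded at curation time (`skip` flag).
* Dual C/E domains cannot be recognised from code extraction alone; E
  status comes from scaffold-alignment hits (synthetic/real) or an
  annotated domain table.
* The chromophore module cut (default 3 modules of the pvdL-like gene)
  is a configuration choice, not an inference.
* Acylation-site typography (delta-N marks) is rendered as a decoration
  token; the actual modification site is not derivable from genomics.
* Census categories are consumed from an upstream annotation table; the
  HMM-based iron-gene annotation itself is out of scope.
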