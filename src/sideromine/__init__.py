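"""Genome mining of non-ribosomal peptide synthetase (NRPS) clusters.

sideromine extracts the specificity-conferring Stachelhaus (10-residue)
and extended 8 Å (34-residue) codes from adenylation domains, matches
them against a curated (code -> monomer) knowledge base at a percent-
identity threshold, and assembles the ordered substrate calls into a
predicted pyoverdine-type siderophore peptide (chromophore prefix,
D/L stereochemistry from epimerization domains, ornithine side-chain
tailoring). Companion modules compute an iron-regulon census with
Fur-box promoter scanning, and the two scalar study statistics
(species-delineation decision rule, unpaired t-test from summaries).
"""

from importlib.resources import files as _files

__version__ = "0.1.0"


def data_path(name: str):
    """Return a path-like handle to a packaged data file."""
    return _files("sideromine").joinpath("data", name)
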