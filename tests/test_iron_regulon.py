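import random

import pandas as pd
import pytest

from sideromine.io_formats import FeatureRecord, SequenceRecord
from sideromine.iron_regulon import (
    CensusError,
    FUR_CONSENSUS,
    census,
    group_css_clusters,
    promoter_region,
    reverse_complement,
    scan_fur_boxes,
)


def _table(categories):
    rows = [
        {"gene_id": f"g{i}", "product": "p", "category": cat}
        for i, cat in enumerate(categories)
    ]
    return pd.DataFrame(rows)


def brute_force_fur(sequence, consensus, max_mm):
    """Independent window scan: count mismatches per window on both strands."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    rc = "".join(comp[c] for c in reversed(consensus))
    hits = []
    w = len(consensus)
    cap = max_mm + 1
    for start in range(len(sequence) - w + 1):
        window = sequence[start:start + w]
        for strand, target in (("+", consensus), ("-", rc)):
            mm = 0
            for a, b in zip(window, target):
                if a != b:
                    mm += 1
                    if mm >= cap:
                        break
            if mm <= max_mm:
                hits.append((start, strand, mm))
    return hits


class TestCensus:
    def test_overall_percentage_of_cds(self):
        """195 categorized iron genes over 3,900 CDS is 5.0%."""
        cats = ["regulation"] * 84 + ["acquisition"] * 79 + ["other"] * 32
        result = census(_table(cats), total_cds=3900)
        assert result.total_iron_genes == 195
        assert result.total_percent == 5.0
        assert result.category_counts["regulation"] == 84
        assert result.category_counts["acquisition"] == 79

    def test_empty_table_all_zero(self):
        result = census(_table([]), total_cds=1000)
        assert result.total_iron_genes == 0
        assert all(v == 0.0 for v in result.category_percent.values())

    def test_unknown_category_named_in_error(self):
        with pytest.raises(CensusError, match="sulfur"):
            census(_table(["sulfur"]), total_cds=100)

    def test_total_cds_must_cover_rows(self):
        with pytest.raises(CensusError):
            census(_table(["regulation"] * 5), total_cds=3)

    def test_percent_consistency(self):
        rng = random.Random(3)
        cats = rng.choices(
            ["regulation", "acquisition", "storage", "efflux",
             "ros_defence", "other"], k=137,
        )
        result = census(_table(cats), total_cds=4000)
        for cat, pct in result.category_percent.items():
            assert round(pct * 4000 / 100) == result.category_counts[cat]


def _gene(gene_id, start, end, seq_id="ctg1"):
    return FeatureRecord(seq_id, start, end, "+", "gene", {"ID": gene_id})


class TestCssClusters:
    def test_sigma_with_anti_sigma_within_gap(self):
        feats = [_gene("sig1", 1000, 1600), _gene("anti1", 1650, 2600)]
        roles = {"sig1": "sigma", "anti1": "anti_sigma"}
        clusters = group_css_clusters(feats, roles, max_gap=500)
        assert len(clusters) == 1
        assert clusters[0].sigma_gene == "sig1"
        assert clusters[0].anti_sigma_gene == "anti1"

    def test_lone_sigma(self):
        clusters = group_css_clusters([_gene("sig1", 0, 600)], {"sig1": "sigma"})
        assert len(clusters) == 1
        assert clusters[0].anti_sigma_gene is None
        assert clusters[0].receptor_gene is None

    def test_far_gene_not_attached(self):
        feats = [_gene("sig1", 0, 600), _gene("anti1", 5000, 5600)]
        roles = {"sig1": "sigma", "anti1": "anti_sigma"}
        clusters = group_css_clusters(feats, roles, max_gap=500)
        assert clusters[0].anti_sigma_gene is None

    def test_synthetic_genome_layout(self):
        """37 sigma genes, 36 of them with receptors -> 37 clusters."""
        feats, roles = [], {}
        pos = 0
        for i in range(37):
            feats.append(_gene(f"sig{i}", pos, pos + 600))
            roles[f"sig{i}"] = "sigma"
            feats.append(_gene(f"anti{i}", pos + 650, pos + 1600))
            roles[f"anti{i}"] = "anti_sigma"
            if i < 36:
                feats.append(_gene(f"rec{i}", pos + 1700, pos + 3800))
                roles[f"rec{i}"] = "receptor"
            pos += 10000
        clusters = group_css_clusters(feats, roles, max_gap=500)
        assert len(clusters) == 37
        assert sum(1 for c in clusters if c.receptor_gene) == 36
        assert all(c.anti_sigma_gene for c in clusters)


class TestFurScan:
    def test_exact_consensus_forward(self):
        seq = SequenceRecord(
            "p1", "A" * 30 + FUR_CONSENSUS + "C" * 30, molecule="dna"
        )
        hits = scan_fur_boxes(seq, max_mismatches=0)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].strand, hits[0].mismatches) == (30, "+", 0)
        assert hits[0].matched_sequence == FUR_CONSENSUS

    def test_reverse_complement_hit_on_minus_strand(self):
        embedded = reverse_complement(
            "GATCATGATAATCATTATC"  # one mismatch from consensus
        )
        seq = SequenceRecord("p2", "G" * 25 + embedded + "T" * 25, "dna")
        hits = scan_fur_boxes(seq, max_mismatches=1)
        minus = [h for h in hits if h.strand == "-"]
        assert len(minus) == 1
        assert minus[0].start == 25
        assert minus[0].mismatches == 1

    def test_consensus_longer_than_sequence(self):
        seq = SequenceRecord("p3", "ACGT", "dna")
        assert scan_fur_boxes(seq) == []

    @pytest.mark.parametrize("max_mm", [0, 1, 2, 3])
    def test_matches_brute_force_on_random_sequences(self, max_mm):
        rng = random.Random(max_mm)
        for _ in range(10):
            sequence = "".join(rng.choices("ACGT", k=2000))
            # plant a near-consensus site so non-empty cases are covered
            site = list(FUR_CONSENSUS)
            for pos in rng.sample(range(19), max_mm):
                site[pos] = rng.choice([c for c in "ACGT" if c != site[pos]])
            sequence = sequence[:700] + "".join(site) + sequence[719:]
            record = SequenceRecord("r", sequence, "dna")
            hits = scan_fur_boxes(record, max_mismatches=max_mm)
            expected = brute_force_fur(sequence, FUR_CONSENSUS, max_mm)
            assert [(h.start, h.strand, h.mismatches) for h in hits] == \
                sorted(expected)

    def test_strand_symmetry(self):
        rng = random.Random(8)
        sequence = "".join(rng.choices("ACGT", k=1500))
        sequence = sequence[:400] + FUR_CONSENSUS + sequence[419:]
        fwd = scan_fur_boxes(SequenceRecord("f", sequence, "dna"), max_mismatches=2)
        rev = scan_fur_boxes(
            SequenceRecord("f", reverse_complement(sequence), "dna"),
            max_mismatches=2,
        )
        n = len(sequence)
        mirrored = sorted(
            (n - h.start - 19, "+" if h.strand == "-" else "-", h.mismatches)
            for h in rev
        )
        assert mirrored == sorted((h.start, h.strand, h.mismatches) for h in fwd)


class TestPromoterRegion:
    def test_plus_strand_upstream(self):
        gene = FeatureRecord("c", 1000, 2000, "+", "gene", {"ID": "g"})
        assert promoter_region(gene, 5000) == (700, 1000)

    def test_minus_strand_upstream_clipped(self):
        gene = FeatureRecord("c", 4800, 4950, "-", "gene", {"ID": "g"})
        assert promoter_region(gene, 5000) == (4950, 5000)
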