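"""Promoter extraction coordinates, IUPAC scanning, category tallies."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from togcn.exceptions import FormatError, MissingRecordError
from togcn.family import GeneModel, GenomeAnnotation
from togcn.promoter import (
    CREMatch,
    CREMotif,
    categorize_cres,
    category_shares,
    extract_promoters,
    load_motif_table,
    scan_cres,
)
from togcn.utils import IUPAC_CODES, iupac_matches, revcomp


def write_fasta(path, chrom, seq):
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for off in range(0, len(seq), 60):
            fh.write(seq[off:off + 60] + "\n")


@pytest.fixture()
def toy_genome(tmp_path):
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), size=6000))
    fasta = tmp_path / "toy.fa"
    write_fasta(fasta, "chr01", seq)
    return fasta, seq


class TestExtract:
    def test_plus_strand_full_window(self, toy_genome):
        fasta, seq = toy_genome
        ann = GenomeAnnotation()
        ann.genes["g"] = GeneModel("g", "chr01", 3001, 3300, "+")
        prom = extract_promoters(fasta, ann)["g"]
        assert len(prom) == 2000
        assert prom == seq[1000:3000]  # bases 1001..3000, 1-based closed

    def test_plus_strand_truncated_at_start(self, toy_genome):
        fasta, seq = toy_genome
        ann = GenomeAnnotation()
        ann.genes["g"] = GeneModel("g", "chr01", 501, 800, "+")
        prom = extract_promoters(fasta, ann)["g"]
        assert len(prom) == 500
        assert prom == seq[0:500]

    def test_minus_strand_reverse_complemented(self, toy_genome):
        fasta, seq = toy_genome
        ann = GenomeAnnotation()
        ann.genes["g"] = GeneModel("g", "chr01", 1001, 1300, "-")
        prom = extract_promoters(fasta, ann)["g"]
        assert prom == revcomp(seq[1300:3300])  # region [end+1, end+2000]

    def test_minus_strand_truncated_at_chrom_end(self, toy_genome):
        fasta, seq = toy_genome
        ann = GenomeAnnotation()
        ann.genes["g"] = GeneModel("g", "chr01", 5001, 5500, "-")
        prom = extract_promoters(fasta, ann)["g"]
        assert len(prom) == 500  # only 500 bp remain downstream
        assert prom == revcomp(seq[5500:6000])

    def test_missing_chromosome_raises(self, toy_genome):
        fasta, _ = toy_genome
        ann = GenomeAnnotation()
        ann.genes["g"] = GeneModel("g", "chrMISSING", 3001, 3300, "+")
        with pytest.raises(MissingRecordError):
            extract_promoters(fasta, ann)

    def test_planted_minus_strand_motifs_found_only_after_revcomp(self, genome_fixture):
        truth = genome_fixture["truth"]
        ann = genome_fixture["annotation"]
        motifs = genome_fixture["motifs"]
        minus = next(g for g, m in ann.genes.items() if m.strand == "-")
        prom = extract_promoters(genome_fixture["fasta"], ann, gene_ids=[minus])[minus]
        found = {(m.element_name, m.promoter_offset, m.strand)
                 for m in scan_cres(prom, motifs, gene_id=minus)}
        assert found == set(truth.planted_motif_positions[minus])
        assert found  # the gene does carry planted motifs


class TestScan:
    M = [CREMotif("m", "TGACG", "hormone")]

    def test_single_match_offset(self):
        hits = scan_cres("ATGACGT", self.M, both_strands=False)
        assert [(h.promoter_offset, h.strand) for h in hits] == [(1, "+")]

    def test_iupac_wildcards(self):
        hits = scan_cres("CACGTG", [CREMotif("m", "CANNTG", "growth")],
                         both_strands=False)
        assert len(hits) == 1 and hits[0].promoter_offset == 0

    def test_overlapping_matches_all_reported(self):
        hits = scan_cres("AAAA", [CREMotif("m", "AA", "stress")], both_strands=False)
        assert [h.promoter_offset for h in hits] == [0, 1, 2]

    def test_palindrome_reported_once_per_strand(self):
        # ACGT is its own reverse complement
        hits = scan_cres("AACGTA", [CREMotif("m", "ACGT", "growth")])
        assert sorted((h.promoter_offset, h.strand) for h in hits) == [
            (1, "+"), (1, "-")
        ]

    def test_reverse_hit_leftmost_forward_offset(self):
        # revcomp(TGACG) = CGTCA sits at forward offset 2
        hits = scan_cres("AACGTCAA", self.M)
        assert [(h.promoter_offset, h.strand) for h in hits] == [(2, "-")]

    def test_invalid_iupac_rejected(self):
        with pytest.raises(FormatError):
            scan_cres("ACGT", [CREMotif("m", "AXGT", "stress")])

    @settings(deadline=None, max_examples=20)
    @given(
        st.text(alphabet="ACGT", min_size=50, max_size=5000),
        st.sampled_from(["TGACG", "CANNTG", "ACGT", "MYC", "CCWACC", "AGGGG"]),
    )
    def test_matches_naive_scanner(self, seq, pattern):
        motif = CREMotif("m", pattern, "stress")
        got = sorted((h.promoter_offset, h.strand) for h in scan_cres(seq, [motif]))
        expected = []
        for pat, strand in ((pattern, "+"), (revcomp(pattern), "-")):
            for off in range(len(seq) - len(pat) + 1):
                if iupac_matches(pat, seq[off:off + len(pat)]):
                    expected.append((off, strand))
        assert got == sorted(expected)


class TestCategorize:
    def test_paper_style_three_way_split(self):
        shares = category_shares({"stress": 10, "hormone": 11, "growth": 17})
        assert shares == {"stress": 26.3, "hormone": 28.9, "growth": 44.7}

    def test_single_category_is_100(self):
        assert category_shares({"stress": 4}) == {"stress": 100.0}

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=3, max_size=3)
           .filter(lambda xs: sum(xs) > 0))
    def test_shares_sum_to_100(self, tallies):
        shares = category_shares(dict(zip(("stress", "hormone", "growth"), tallies)))
        assert sum(shares.values()) == pytest.approx(100.0, abs=0.11)

    def test_unknown_elements_flagged_other_and_excluded(self):
        matches = [
            CREMatch("g1", "known", "stress", 0, "+"),
            CREMatch("g1", "mystery", "unmapped", 5, "+"),
        ]
        per_gene, summary = categorize_cres(matches)
        row = per_gene.set_index("gene_id").loc["g1"]
        assert row.total == 1 and row.stress_count == 1
        assert summary.distinct_elements.sum() == 1

    def test_synthetic_counts_match_truth(self, genome_fixture):
        truth = genome_fixture["truth"]
        motifs = genome_fixture["motifs"]
        categories = {m.element_name: m.category for m in motifs}
        matches = [
            CREMatch(g, el, categories[el], off, strand)
            for g, planted in truth.planted_motif_positions.items()
            for el, off, strand in planted
        ]
        per_gene, _ = categorize_cres(matches)
        per_gene = per_gene.set_index("gene_id")
        for g, planted in truth.planted_motif_positions.items():
            assert per_gene.loc[g].total == len(planted)


def test_packaged_catalog_has_the_documented_split():
    motifs = load_motif_table()
    by_cat = {}
    for m in motifs:
        by_cat.setdefault(m.category, set()).add(m.element_name)
    assert len(by_cat["stress"]) == 10
    assert len(by_cat["hormone"]) == 11
    assert len(by_cat["growth"]) == 17
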