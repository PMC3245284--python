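"""Spliced mapping, intron comparison, ORF diagnostics and skip rescue."""

from itertools import combinations

import numpy as np
import pytest
from Bio.Seq import Seq

from circdup.genemap import (check_orf, compare_intron_status,
                             exon_skip_rescue, percent_identity, splice_map)
from circdup.locus import GeneModel, Locus
from circdup.simulate import make_gene_locus, simulate_scenario
from conftest import random_dna

_SENSE = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
          if a + b + c not in ("TAA", "TAG", "TGA")]


class TestSpliceMap:
    def test_round_trip_exact(self, default_gene):
        locus, gene = default_gene
        mrna = gene.spliced_mrna(locus.seq)
        aln = splice_map(mrna, locus)
        assert aln.n_exons == 24
        assert tuple((c.genomic_start, c.genomic_end)
                     for c in aln.exon_calls) == gene.exons
        assert aln.overall_identity == 1.0
        assert aln.intron_lengths == gene.intron_lengths()

    def test_retrocopy_single_merged_call(self):
        pair = simulate_scenario("retrocopy", seed=5)
        mrna = pair.gene.spliced_mrna(pair.source_locus.seq)
        aln = splice_map(mrna, pair.target_locus_after)
        assert aln.n_exons == 1
        assert aln.intron_lengths == []

    def test_mutated_duplicate_keeps_all_exons(self):
        pair = simulate_scenario("direct", seed=6, mutation_rate=0.02)
        mrna = pair.gene.spliced_mrna(pair.source_locus.seq)
        aln = splice_map(mrna, pair.target_locus_after)
        assert aln.n_exons == pair.gene.n_exons
        assert 0.97 <= aln.overall_identity <= 0.99

    def test_no_anchors_gives_unmapped_result(self, rng):
        locus = Locus("l", random_dna(rng, 2000))
        aln = splice_map(random_dna(rng, 300), locus)
        assert not aln.mapped and aln.exon_calls == []

    def test_mrna_too_short(self, rng):
        with pytest.raises(ValueError, match="min_exon_anchor"):
            splice_map("ACGT", Locus("l", random_dna(rng, 100)))


class TestCompareIntronStatus:
    def test_direct_duplicate_retains_introns(self):
        pair = simulate_scenario("direct", seed=9)
        mrna = pair.gene.spliced_mrna(pair.source_locus.seq)
        a = splice_map(mrna, pair.source_locus)
        b = splice_map(mrna, pair.target_locus_after)
        tab = compare_intron_status(a, b)
        assert len(tab) == pair.gene.n_exons - 1
        assert tab.present_a.all() and tab.present_b.all()
        assert (tab.length_a == tab.length_b).all()

    def test_retrocopy_all_absent(self):
        pair = simulate_scenario("retrocopy", seed=9)
        mrna = pair.gene.spliced_mrna(pair.source_locus.seq)
        tab = compare_intron_status(splice_map(mrna, pair.source_locus),
                                    splice_map(mrna, pair.target_locus_after))
        assert not tab.present_b.any()

    def test_single_intron_deleted(self, default_gene):
        locus, gene = default_gene
        mrna = gene.spliced_mrna(locus.seq)
        k = 10  # remove intron k entirely, fusing exons k and k+1
        i_start, i_end = gene.exons[k][1], gene.exons[k + 1][0]
        fused = Locus("fused", locus.seq[:i_start] + locus.seq[i_end:])
        tab = compare_intron_status(splice_map(mrna, locus),
                                    splice_map(mrna, fused))
        absent = tab[~tab.present_b]
        assert list(absent.intron_index) == [k]

    def test_mismatched_mrna_rejected(self, default_gene):
        locus, gene = default_gene
        mrna = gene.spliced_mrna(locus.seq)
        a = splice_map(mrna, locus)
        b = splice_map(mrna[:-30], locus)
        with pytest.raises(ValueError, match="different mRNA"):
            compare_intron_status(a, b)


class TestCheckOrf:
    def test_unmutated_gene_intact(self, default_gene):
        locus, gene = default_gene
        aln = splice_map(gene.spliced_mrna(locus.seq), locus)
        rep = check_orf(aln, locus, gene.cds_mrna_span())
        assert rep.is_intact and rep.premature_stops == []
        assert all(rep.frame_ok_per_exon)

    def test_one_bp_deletion_shifts_frame(self, default_gene):
        """A 1 bp loss in a middle coding exon shifts the frame from that
        exon on; the first premature stop lands downstream of it."""
        locus, gene = default_gene
        k = 6
        s, e = gene.exons[k]
        mid = (s + e) // 2
        mutant = Locus("mut", locus.seq[:mid] + locus.seq[mid + 1:])
        aln = splice_map(gene.spliced_mrna(locus.seq), mutant)
        rep = check_orf(aln, mutant, gene.cds_mrna_span())
        assert not rep.is_intact
        assert rep.frame_ok_per_exon.index(False) == k
        assert rep.premature_stops and rep.premature_stops[0][0] >= k

    def test_point_mutation_creates_stop(self, default_gene):
        locus, gene = default_gene
        cs, _ = gene.cds_mrna_span()
        k = 10
        s10, _ = gene.exons[k]
        m10 = gene.mrna_coord(s10)
        in_frame = m10 + (3 - (m10 - cs) % 3) % 3 + 9
        g = s10 + (in_frame - m10)
        mutant = Locus("m2", locus.seq[:g] + "TAA" + locus.seq[g + 3:])
        aln = splice_map(gene.spliced_mrna(locus.seq), mutant)
        rep = check_orf(aln, mutant, gene.cds_mrna_span())
        assert not rep.is_intact
        assert rep.premature_stops[0][0] == k

    def test_cds_start_not_covered(self, default_gene):
        locus, gene = default_gene
        aln = splice_map(gene.spliced_mrna(locus.seq), locus)
        for c in aln.exon_calls:
            pass
        aln.exon_calls = aln.exon_calls[2:]
        with pytest.raises(ValueError, match="CDS start"):
            check_orf(aln, locus, gene.cds_mrna_span())


class TestPercentIdentity:
    def test_perfect(self, default_gene):
        locus, gene = default_gene
        aln = splice_map(gene.spliced_mrna(locus.seq), locus)
        assert percent_identity(aln) == 1.0

    def test_binomial_regime(self):
        pair = simulate_scenario("direct", seed=31, mutation_rate=0.02)
        mrna = pair.gene.spliced_mrna(pair.source_locus.seq)
        aln = splice_map(mrna, pair.target_locus_after)
        assert abs(percent_identity(aln) - 0.98) <= 0.01


# ------------------------------------------------------------ skip rescue

def _make_broken_gene(max_tries: int = 60):
    """A gene whose exon 7 carries an in-frame premature stop such that
    skipping exons {6, 8} (lengths summing to a codon multiple) restores an
    intact ORF, mirroring a short-isoform rescue. Deterministic search over
    construction seeds; candidates are vetted with the independent oracle
    below."""
    exon_lens = [50, 60, 60, 60, 60, 60, 61, 62, 62, 60, 60, 50]
    for seed in range(max_tries):
        rng = np.random.default_rng(10_000 + seed)
        cds_start_exon, cds_start_off = 1, 10
        cds_end_exon = 10
        # coding length from CDS start to the end-exon offset
        lead = exon_lens[cds_start_exon] - cds_start_off
        middle = sum(exon_lens[cds_start_exon + 1:cds_end_exon])
        cds_end_off = exon_lens[cds_end_exon] - 6
        total = lead + middle + cds_end_off
        cds_end_off -= total % 3
        n_codons = (lead + middle + cds_end_off) // 3
        coding = ["ATG"] + [_SENSE[i] for i in
                            rng.integers(0, 61, n_codons - 2)] + ["TAA"]
        mrna_len = sum(exon_lens)
        utr5 = random_dna(rng, sum(exon_lens[:1]) + cds_start_off)
        cds_seq = "".join(coding)
        utr3 = random_dna(rng, mrna_len - len(utr5) - len(cds_seq))
        mrna = utr5 + cds_seq + utr3

        # plant an in-frame TAA fully inside exon 7
        e7_mstart = sum(exon_lens[:7])
        e7_mend = e7_mstart + exon_lens[7]
        cs = len(utr5)
        first_codon = cs + ((e7_mstart - cs + 2) // 3) * 3 + 3
        if first_codon + 3 > e7_mend:
            continue
        mrna = mrna[:first_codon] + "TAA" + mrna[first_codon + 3:]

        parts, exons, pos = [], [], 0
        for i, ln in enumerate(exon_lens):
            exons.append((pos, pos + ln))
            parts.append(mrna[sum(exon_lens[:i]):sum(exon_lens[:i + 1])])
            pos += ln
            if i < len(exon_lens) - 1:
                parts.append("GT" + random_dna(rng, 40) + "AG")
                pos += 44
        locus = Locus("broken", "".join(parts))
        gene = GeneModel("broken", "+", tuple(exons), 1, cds_start_off,
                         cds_end_exon, cds_end_off)
        oracle = _oracle_rescues(locus, gene, max_skip=2)
        if (6, 8) in oracle and not any(len(s) == 1 for s in oracle):
            return locus, gene, oracle
    raise AssertionError("no suitable fixture found")


def _oracle_rescues(locus: Locus, gene: GeneModel, max_skip: int):
    """Independent exhaustive oracle: re-splice from the gene annotation,
    re-translate with Biopython, keep minimal intact subsets."""
    cs, ce = gene.cds_mrna_span()
    coding_exons = [i for i in range(gene.n_exons)
                    if max(gene.mrna_coord(gene.exons[i][0]), cs)
                    < min(gene.mrna_coord(gene.exons[i][1]), ce)]
    internal = coding_exons[1:-1]

    def intact(skip):
        parts = [locus.seq[s:e] for i, (s, e) in enumerate(gene.exons)
                 if i not in skip]
        spliced = "".join(parts)
        skipped_before = sum(gene.exons[i][1] - gene.exons[i][0]
                             for i in skip)
        cds = spliced[cs:ce - skipped_before]
        if len(cds) < 6 or len(cds) % 3:
            return False
        protein = str(Seq(cds).translate())
        return "*" not in protein[:-1] and protein.endswith("*")

    found = []
    for size in range(1, max_skip + 1):
        for subset in combinations(internal, size):
            if any(set(f) <= set(subset) for f in found):
                continue
            if intact(frozenset(subset)):
                found.append(tuple(subset))
    return sorted(found, key=lambda s: (len(s), s))


class TestExonSkipRescue:
    def test_six_eight_rescue_matches_oracle(self):
        locus, gene, oracle = _make_broken_gene()
        aln = splice_map(gene.spliced_mrna(locus.seq), locus)
        rep = check_orf(aln, locus, gene.cds_mrna_span())
        assert not rep.is_intact
        assert rep.premature_stops[0][0] == 7
        rescues = exon_skip_rescue(rep, aln, locus, max_skip=2)
        assert (6, 8) in rescues
        assert rescues == oracle

    def test_intact_input_rejected(self, default_gene):
        locus, gene = default_gene
        aln = splice_map(gene.spliced_mrna(locus.seq), locus)
        rep = check_orf(aln, locus, gene.cds_mrna_span())
        with pytest.raises(ValueError, match="intact"):
            exon_skip_rescue(rep, aln, locus)

    def test_unrescuable_stop_in_last_coding_exon(self, default_gene):
        """A premature stop inside the terminal coding exon cannot be
        removed by skipping internal exons: every subset either leaves the
        stop in frame (skipped length a codon multiple) or breaks the codon
        length — the exhaustive search must come back empty."""
        locus, gene = default_gene
        cs, _ = gene.cds_mrna_span()
        k = gene.cds_end_exon_index
        sk, _ = gene.exons[k]
        mk = gene.mrna_coord(sk)
        in_frame = mk + (3 - (mk - cs) % 3) % 3 + 9
        g = sk + (in_frame - mk)
        mutant = Locus("m", locus.seq[:g] + "TAA" + locus.seq[g + 3:])
        aln = splice_map(gene.spliced_mrna(locus.seq), mutant)
        rep = check_orf(aln, mutant, gene.cds_mrna_span())
        assert not rep.is_intact
        assert exon_skip_rescue(rep, aln, mutant, max_skip=2) == []
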