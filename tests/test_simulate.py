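"""Simulator: gene construction, duplication mechanics, planted features."""

import numpy as np
import pytest
from Bio.Seq import Seq

from circdup.locus import revcomp
from circdup.simulate import (insert_decoy, make_gene_locus,
                              make_random_locus, plant_breakpoint_features,
                              simulate_duplication, simulate_scenario)


class TestMakeGeneLocus:
    def test_default_gene_structure(self, default_gene):
        locus, gene = default_gene
        assert gene.n_exons == 24
        assert len(gene.intron_lengths()) == 23
        assert all(l >= 4 for l in gene.intron_lengths())

    def test_cds_is_translatable(self, default_gene):
        locus, gene = default_gene
        cds = gene.spliced_cds(locus.seq)
        assert len(cds) % 3 == 0
        assert cds.startswith("ATG")
        protein = str(Seq(cds).translate())
        assert "*" not in protein[:-1]
        assert protein.endswith("*")

    def test_introns_have_gt_ag_boundaries(self, default_gene):
        locus, gene = default_gene
        for i in range(gene.n_exons - 1):
            intron = locus.seq[gene.exons[i][1]:gene.exons[i + 1][0]]
            assert intron[:2] == "GT" and intron[-2:] == "AG"

    def test_forced_geometry(self):
        locus, gene = make_gene_locus(n_exons=2, exon_len_range=(30, 30),
                                      intron_len_range=(10, 10), flank_len=0,
                                      seed=7)
        assert len(locus) == 70
        assert gene.exons == ((0, 30), (40, 70))

    def test_seeded_determinism(self):
        a = make_gene_locus(seed=1)
        b = make_gene_locus(seed=1)
        assert a[0].seq == b[0].seq
        assert a[1] == b[1]

    @pytest.mark.parametrize("kwargs", [
        dict(n_exons=1),
        dict(exon_len_range=(5, 5)),
        dict(intron_len_range=(2, 2)),
    ])
    def test_infeasible_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            make_gene_locus(seed=0, **kwargs)


class TestSimulateDuplication:
    def test_circular_rotation_by_construction(self, default_gene):
        locus, gene = default_gene
        target = make_random_locus(5000, seed=2, locus_id="t")
        gs, ge = gene.span
        exc = (gs - 100, ge + 180)
        cut = 100
        pair = simulate_duplication(locus, gene, target,
                                    "circular_intermediate",
                                    excision_interval=exc,
                                    circle_cut_offset=cut,
                                    insertion_point=1000, seed=3)
        excised = locus.seq[exc[0]:exc[1]]
        inserted = pair.target_locus_after.seq[1000:1000 + len(excised)]
        assert inserted == excised[cut:] + excised[:cut]

    def test_direct_copy_identical(self, default_gene):
        locus, gene = default_gene
        target = make_random_locus(5000, seed=2, locus_id="t")
        gs, ge = gene.span
        exc = (gs - 50, ge + 50)
        pair = simulate_duplication(locus, gene, target, "direct",
                                    excision_interval=exc,
                                    insertion_point=100, seed=3)
        excised = locus.seq[exc[0]:exc[1]]
        assert pair.target_locus_after.seq[100:100 + len(excised)] == excised

    def test_retrocopy_is_spliced_mrna(self, default_gene):
        locus, gene = default_gene
        target = make_random_locus(5000, seed=2, locus_id="t")
        pair = simulate_duplication(locus, gene, target, "retrocopy",
                                    insertion_point=500, seed=3)
        # independent splice: concatenate annotated exon sequences
        mrna = "".join(locus.seq[s:e] for s, e in gene.exons)
        assert pair.target_locus_after.seq[500:500 + len(mrna)] == mrna
        assert len(mrna) == sum(e - s for s, e in gene.exons)

    def test_length_bookkeeping(self, default_gene):
        locus, gene = default_gene
        target = make_random_locus(5000, seed=2, locus_id="t")
        gs, ge = gene.span
        pair = simulate_duplication(locus, gene, target, "direct",
                                    excision_interval=(gs, ge),
                                    insertion_point=0, seed=0)
        assert (len(pair.target_locus_after)
                == len(pair.target_locus_before) + (ge - gs))

    def test_kmer_content_conserved_under_rotation(self, default_gene):
        """At rate 0 the rotated copy has the same k-mer multiset as the
        excised segment up to the k-1 junction k-mers."""
        locus, gene = default_gene
        target = make_random_locus(2000, seed=2, locus_id="t")
        gs, ge = gene.span
        exc = (gs - 10, ge + 10)
        pair = simulate_duplication(locus, gene, target,
                                    "circular_intermediate",
                                    excision_interval=exc,
                                    circle_cut_offset=777,
                                    insertion_point=0, seed=0)
        excised = locus.seq[exc[0]:exc[1]]
        inserted = pair.target_locus_after.seq[0:len(excised)]
        k = 8
        kmers = lambda s: sorted(s[i:i + k] for i in range(len(s) - k + 1))
        circular = excised + excised[:k - 1]
        assert set(kmers(inserted)) <= set(kmers(circular))
        diff = len(kmers(excised)) - len(kmers(inserted))
        assert abs(diff) == 0  # same count of k-mers

    def test_rotation_zero_equals_direct(self, default_gene):
        locus, gene = default_gene
        target = make_random_locus(2000, seed=2, locus_id="t")
        gs, ge = gene.span
        exc = (gs, ge)
        a = simulate_duplication(locus, gene, target, "circular_intermediate",
                                 excision_interval=exc, circle_cut_offset=0,
                                 insertion_point=0, seed=0)
        b = simulate_duplication(locus, gene, target, "direct",
                                 excision_interval=exc, insertion_point=0,
                                 seed=0)
        assert a.target_locus_after.seq == b.target_locus_after.seq

    def test_mutation_count_binomial(self, default_gene):
        """Across 100 seeds the substitution count stays within 4 sigma of
        Binomial(L, mu)."""
        locus, gene = default_gene
        target = make_random_locus(1000, seed=2, locus_id="t")
        gs, ge = gene.span
        exc = (gs, ge)
        L = ge - gs
        mu = 0.01
        counts = []
        for seed in range(100):
            pair = simulate_duplication(locus, gene, target, "direct",
                                        excision_interval=exc,
                                        insertion_point=0, mutation_rate=mu,
                                        seed=seed)
            counts.append(pair.truth.n_mutations)
        mean, sigma = L * mu, np.sqrt(L * mu * (1 - mu))
        assert all(abs(c - mean) <= 4 * sigma for c in counts)
        # and the empirical mean is close
        assert abs(np.mean(counts) - mean) <= 4 * sigma / np.sqrt(100)

    def test_errors(self, default_gene):
        locus, gene = default_gene
        target = make_random_locus(1000, seed=2, locus_id="t")
        gs, ge = gene.span
        with pytest.raises(ValueError, match="cut_offset"):
            simulate_duplication(locus, gene, target, "circular_intermediate",
                                 excision_interval=(gs, ge),
                                 circle_cut_offset=ge - gs + 5,
                                 insertion_point=0, seed=0)
        with pytest.raises(ValueError, match="contain the whole gene"):
            simulate_duplication(locus, gene, target, "direct",
                                 excision_interval=(gs + 10, ge),
                                 insertion_point=0, seed=0)
        with pytest.raises(ValueError, match="outside target"):
            simulate_duplication(locus, gene, target, "direct",
                                 excision_interval=(gs, ge),
                                 insertion_point=5000, seed=0)


class TestInsertDecoy:
    def test_length_and_motifs(self, default_gene):
        locus, _ = default_gene
        decoy = "ACGT" * 125
        out = insert_decoy(locus, (1000, 1000), decoy,
                           flanking_motif="GCAAAC", motif_copies=3)
        assert len(out) == len(locus) + 500 + 3 * 6
        from circdup.breakpoints import scan_motif
        window = out.seq[950:950 + 600 + 100]
        before = scan_motif(locus.seq[950:1050], "GCAAAC")
        hits = scan_motif(window, "GCAAAC")
        assert len(hits) >= len(before) + 3

    def test_no_motif_means_no_new_hits(self, default_gene):
        locus, _ = default_gene
        rng = np.random.default_rng(9)
        decoy = "".join("ACGT"[i] for i in rng.integers(0, 4, 500)
                        )
        from circdup.breakpoints import scan_motif
        out = insert_decoy(locus, (1000, 1000), decoy)
        n_before = (len(scan_motif(locus.seq, "GCAAAC"))
                    + len(scan_motif(decoy, "GCAAAC")))
        n_after = len(scan_motif(out.seq, "GCAAAC"))
        assert n_after <= n_before + 1  # at most one chance junction hit

    def test_gene_coordinates_shift(self, default_gene):
        locus, gene = default_gene
        src = type(locus)(locus.id, locus.seq, gene=gene)
        out = insert_decoy(src, (10, 10), "A" * 100)
        assert out.gene.exons[0][0] == gene.exons[0][0] + 100

    def test_position_outside_locus(self, default_gene):
        locus, _ = default_gene
        with pytest.raises(ValueError):
            insert_decoy(locus, (2 * len(locus), 2 * len(locus) + 2), "ACGT")


class TestPlantBreakpointFeatures:
    def _pair(self, default_gene, seed=0):
        locus, gene = default_gene
        target = make_random_locus(2000, seed=2, locus_id="t")
        gs, ge = gene.span
        return simulate_duplication(locus, gene, target, "direct",
                                    excision_interval=(gs - 200, ge + 200),
                                    insertion_point=0, seed=seed)

    def test_inverted_repeat_planted(self, default_gene):
        from circdup.breakpoints import extract_flanks, find_inverted_repeats
        pair = plant_breakpoint_features(self._pair(default_gene),
                                         inverted_repeat_len=8, seed=4)
        s, e = pair.truth.excision_interval
        fa = extract_flanks(pair.source_locus, s, 100)
        fd = extract_flanks(pair.source_locus, e, 100)
        hits = find_inverted_repeats(fa.left + fa.right, fd.left + fd.right,
                                     min_len=8)
        assert hits and hits[0].length >= 8

    def test_no_repeat_when_absent(self, default_gene):
        pair = plant_breakpoint_features(self._pair(default_gene),
                                         inverted_repeat_len=0)
        assert not any(f.kind == "inverted_repeat"
                       for f in pair.truth.planted_features)

    def test_repeat_fragment_annotated(self, default_gene):
        from circdup.breakpoints import annotate_repeats
        rng = np.random.default_rng(11)
        frag = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        pair = plant_breakpoint_features(self._pair(default_gene),
                                         inverted_repeat_len=8,
                                         repeat_fragment=("Expander", frag),
                                         seed=4)
        s, _ = pair.truth.excision_interval
        flank = pair.source_locus.seq[max(0, s - 100):s + 100]
        hits = annotate_repeats(flank, [("Expander", frag)])
        assert hits and hits[0].label == "Expander"
        assert hits[0].identity == 1.0

    def test_feature_longer_than_flank_rejected(self, default_gene):
        locus, gene = default_gene
        target = make_random_locus(2000, seed=2, locus_id="t")
        gs, ge = gene.span
        pair = simulate_duplication(locus, gene, target, "direct",
                                    excision_interval=(0, ge + 10),
                                    insertion_point=0, seed=0)
        with pytest.raises(ValueError, match="flank"):
            plant_breakpoint_features(pair, inverted_repeat_len=8)


class TestScenario:
    def test_deterministic(self):
        a = simulate_scenario("circular_intermediate", seed=5,
                              mutation_rate=0.01)
        b = simulate_scenario("circular_intermediate", seed=5,
                              mutation_rate=0.01)
        assert a.source_locus.seq == b.source_locus.seq
        assert a.target_locus_after.seq == b.target_locus_after.seq
        assert a.truth == b.truth

    def test_reverse_complement_insert(self, default_gene):
        locus, gene = default_gene
        target = make_random_locus(1000, seed=2, locus_id="t")
        gs, ge = gene.span
        pair = simulate_duplication(locus, gene, target, "direct",
                                    excision_interval=(gs, ge),
                                    insertion_point=0, seed=0,
                                    reverse_complement=True)
        assert (pair.target_locus_after.seq[:ge - gs]
                == revcomp(locus.seq[gs:ge]))
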