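"""Simulator unit and property tests: determinism, truth bookkeeping, reads."""

import numpy as np
import pytest

from mosaictrace import simulate as sim
from mosaictrace.io import apply_variants


class TestGenerateParentalPair:
    def test_identity_when_density_zero_and_no_genes(self):
        pair = sim.generate_parental_pair([5000], snp_density=0.0, seed=3,
                                          n_specific_genes=0)
        assert pair.parent_a[0].sequence_str == pair.parent_b[0].sequence_str
        assert pair.true_panel == []

    def test_panel_completeness_by_sequence_diff(self):
        """Brute-force diff of the two parents reproduces the truth panel."""
        pair = sim.generate_parental_pair([30_000], seed=2, n_specific_genes=0)
        a, b = pair.parent_a[0].sequence, pair.parent_b[0].sequence
        diff = np.flatnonzero(a != b)
        assert np.array_equal(diff, pair.snp_pos["chromosome"])
        for rep, pos, allele_a, allele_b in pair.true_panel:
            i = pos - 1
            assert (allele_a, allele_b) == ("ACGT"[a[i]], "ACGT"[b[i]])

    def test_panel_size_matches_binomial_law(self):
        """Panel sizes across seeds follow Binomial(L, density)."""
        L, density, n_seeds = 124_000, 1 / 124, 200
        sizes = [len(sim.generate_parental_pair([L], density, 0, 1000, seed=s)
                     .snp_pos["chromosome"]) for s in range(n_seeds)]
        mean, sd = np.mean(sizes), np.std(sizes)
        expected_sd = np.sqrt(L * density * (1 - density))  # ~31.5
        assert abs(mean - 1000) < 4 * expected_sd / np.sqrt(n_seeds) + 1
        assert 0.8 * expected_sd < sd < 1.25 * expected_sd

    def test_mean_panel_spacing_near_124(self, study_pair):
        core = sum(len(c) for c in study_pair.core.values())
        n = sum(len(p) for p in study_pair.snp_pos.values())
        assert core / n == pytest.approx(124, rel=0.1)

    def test_specific_genes_private_and_flanked(self, small_pair):
        assert not set(small_pair.specific_genes_a) & set(small_pair.specific_genes_b)
        ga = {g[0] for r in small_pair.parent_a for g in r.genes}
        gb = {g[0] for r in small_pair.parent_b for g in r.genes}
        assert set(small_pair.specific_genes_a) <= ga
        assert not set(small_pair.specific_genes_a) & gb

    def test_parameter_validation(self):
        with pytest.raises(sim.ParameterError):
            sim.generate_parental_pair([5000], snp_density=0.5)
        with pytest.raises(sim.ParameterError):
            sim.generate_parental_pair([500])

    def test_determinism(self):
        p1 = sim.generate_parental_pair([20_000], seed=9, n_specific_genes=2,
                                        gene_length=900)
        p2 = sim.generate_parental_pair([20_000], seed=9, n_specific_genes=2,
                                        gene_length=900)
        assert p1.parent_a[0].sequence_str == p2.parent_a[0].sequence_str
        assert p1.parent_b[0].sequence_str == p2.parent_b[0].sequence_str
        assert p1.true_panel == p2.true_panel


class TestSimulateTransjugant:
    def test_no_events_returns_background(self, small_pair):
        tj = sim.simulate_transjugant(small_pair, "A", 0, seed=5)
        assert tj.truth.events == []
        for repl, bg in zip(tj.replicons, small_pair.parent_a):
            assert repl.sequence_str == bg.sequence_str
        assert sim.emit_truth_variants(tj, "A") == []

    def test_fragment_switches_exactly_its_panel_sites(self):
        """Direct sequence diff confirms allele switching inside the fragment."""
        pair = sim.generate_parental_pair([50_000], seed=7, n_specific_genes=0)
        tj = sim.simulate_transjugant(
            pair, "A", 1, fragment_size_sampler=lambda rng: 2000, seed=13)
        (event,) = tj.truth.events
        a = pair.parent_a[0].sequence
        b = pair.parent_b[0].sequence
        clone = tj.replicons[0].sequence
        diff = np.flatnonzero(clone != a)
        inside = (diff >= event.start - 1) & (diff <= event.end - 1)
        assert inside.all()
        assert np.array_equal(clone[diff], b[diff])
        expected = [int(p) for p in pair.snp_pos["chromosome"]
                    if event.start - 1 <= p < event.end]
        assert [int(d) for d in diff] == expected
        assert [(r, p) for r, p in tj.truth.implanted_panel_sites] == \
            [("chromosome", p + 1) for p in expected]

    def test_six_fragments_mirror_six_regions(self, small_pair):
        tj = sim.simulate_transjugant(small_pair, "A", {"chromosome": 6},
                                      seed=21)
        frs = [e for e in tj.truth.events if e.kind == "homologous_fragment"]
        assert len(frs) == 6
        # gap rule guaranteed by construction: fragments pairwise > 1 kbp apart
        iv = sorted((e.start, e.end) for e in frs)
        assert all(iv[i + 1][0] - iv[i][1] > 1000 for i in range(len(iv) - 1))

    def test_background_b_symmetry(self, small_pair):
        tj = sim.simulate_transjugant(small_pair, "B", {"chromosome": 3}, seed=8)
        b = small_pair.parent_b[0].sequence
        a_alleles = {int(p): c for p, c in zip(
            small_pair.panel_positions("B", "chromosome"),
            small_pair.panel_alleles("chromosome")[0])}
        clone = tj.replicons[0].sequence
        for rep, pos in tj.truth.implanted_panel_sites:
            if rep != "chromosome":
                continue
            assert clone[pos - 1] == a_alleles[pos - 1]
            assert clone[pos - 1] != b[pos - 1]

    def test_placement_error_when_overconstrained(self, small_pair):
        with pytest.raises(sim.PlacementError):
            sim.simulate_transjugant(
                small_pair, "A", {"megaplasmid": 40},
                fragment_size_sampler=lambda rng: 1500, seed=3)

    def test_unknown_marker_gene_rejected(self, small_pair, cassette):
        with pytest.raises(sim.ParameterError, match="not found"):
            sim.simulate_transjugant(small_pair, "A", 0,
                                     marker=(cassette[1], "nope"), seed=1)


class TestEmitTruthVariants:
    def test_round_trip_both_frames(self, small_pair, marked_clone):
        for ref_parent in ("A", "B"):
            variants = sim.emit_truth_variants(marked_clone, ref_parent)
            ref = {r.replicon_id: r.sequence_str
                   for r in small_pair.parent(ref_parent)}
            rebuilt = apply_variants(ref, variants)
            assert rebuilt == {r.replicon_id: r.sequence_str
                               for r in marked_clone.replicons}

    def test_snp_records_equal_implanted_sites(self, marked_clone):
        variants = sim.emit_truth_variants(marked_clone, "A")
        snps = {(v.replicon_id, v.pos) for v in variants if v.is_snp}
        implanted = set(marked_clone.truth.implanted_panel_sites)
        # SNPs at structural-edit anchors are folded into the edit record
        anchors = {(rep, e.start0) for rep, edits in marked_clone.edits.items()
                   for e in edits}
        assert snps == {(r, p) for r, p in implanted if (r, p - 1) not in anchors}

    def test_count_arithmetic_vs_donor(self, small_pair):
        """Vs the donor: unswitched panel sites + indels for specific genes."""
        tj = sim.simulate_transjugant(small_pair, "A", {"chromosome": 2},
                                      seed=17)
        variants = sim.emit_truth_variants(tj, "B")
        n_panel = sum(len(p) for p in small_pair.snp_pos.values())
        n_switched = len(tj.truth.implanted_panel_sites)
        snps = [v for v in variants if v.is_snp]
        indels = [v for v in variants if not v.is_snp]
        assert len(snps) == n_panel - n_switched
        assert len(indels) == len(small_pair.specific_genes_a) + \
            len(small_pair.specific_genes_b)


class TestReads:
    def test_error_free_read_is_exact_substring(self, marked_clone):
        reads = sim.simulate_reads(marked_clone.replicons, 80, 0.5, 0.0, seed=5)
        rid, seq, qual = next(reads.reads())
        _, rep, start = rid.split("|")
        genome = next(r for r in marked_clone.replicons
                      if r.replicon_id == rep).sequence_str
        assert genome[int(start):int(start) + 80] == seq
        assert len(qual) == 80

    @pytest.mark.parametrize("coverage", [5.0, 31.0])
    def test_coverage_conservation(self, small_pair, coverage):
        reads = sim.simulate_reads(small_pair.parent_a, 100, coverage, 0.0, seed=2)
        for repl in small_pair.parent_a:
            emitted = len(reads.starts[repl.replicon_id]) * 100
            assert abs(emitted / repl.length - coverage) / coverage < 0.05

    def test_error_rate_binomial(self, small_pair):
        reads = sim.simulate_reads(small_pair.parent_a, 100, 20.0, 0.01, seed=7)
        rep = "chromosome"
        idx = reads.starts[rep][:, None] + np.arange(100)
        mismatch = (reads.bases[rep] != small_pair.parent_a[0].sequence[idx]).mean()
        sd = np.sqrt(0.01 * 0.99 / reads.bases[rep].size)
        assert abs(mismatch - 0.01) < 3 * sd

    def test_read_length_validation(self, small_pair):
        with pytest.raises(sim.ParameterError):
            sim.simulate_reads(small_pair.parent_a, 30_000, 5.0, 0.0, seed=1)

    def test_determinism_byte_identical_outputs(self, small_pair, tmp_path):
        for d in ("x", "y"):
            tj = sim.simulate_transjugant(small_pair, "A", 2, seed=4,
                                          clone_id="c")
            reads = sim.simulate_reads(tj.replicons, 60, 2.0, 0.01, seed=4)
            out = tmp_path / d
            out.mkdir()
            sim.write_genome(tj.replicons, out / "g.fasta", out / "g.gff3")
            sim.write_truth(tj, out)
            from mosaictrace.io import write_fastq
            write_fastq(reads.reads(), out / "r.fastq")
        for name in ("g.fasta", "g.gff3", "c.truth.vcf", "c.truth.bed",
                     "c.truth.json", "r.fastq"):
            assert (tmp_path / "x" / name).read_bytes() == \
                (tmp_path / "y" / name).read_bytes()


class TestPileupCaller:
    def test_recovers_all_implanted_sites_at_30x(self, small_pair, marked_clone):
        reads = sim.simulate_reads(marked_clone.replicons, 100, 30.0, 0.01, seed=6)
        calls = sim.pileup_call(reads, marked_clone)
        called = {(v.replicon_id, v.pos) for v in calls if v.is_snp}
        assert set(marked_clone.truth.implanted_panel_sites) <= called

    def test_truth_consistency_cohort(self, study_pair):
        """Truth variants restricted to panel sites equal the implanted set."""
        for tj in sim.simulate_cohort(study_pair, 5, seed=99):
            variants = sim.emit_truth_variants(tj, tj.background)
            panel_positions = {
                (rep, int(p) + 1)
                for rep in study_pair.replicon_ids
                for p in study_pair.panel_positions(tj.background, rep)}
            on_panel = {(v.replicon_id, v.pos) for v in variants
                        if v.is_snp and (v.replicon_id, v.pos) in panel_positions}
            implanted = set(tj.truth.implanted_panel_sites)
            anchors = {(rep, e.start0 + 1) for rep, edits in tj.edits.items()
                       for e in edits}
            assert on_panel == implanted - anchors
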