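"""Strain-specific gene detection, capture in contigs, marker localization."""

import numpy as np
import pytest

from mosaictrace import capture as cap, simulate as sim


def smith_waterman(query, target, match=1, mismatch=-3, gap=-5):
    """Exhaustive local alignment oracle (tiny inputs only).

    BLAST-like scoring, so random-sequence extension scores negatively and
    the optimum reflects the genuinely homologous block. Returns (aligned
    query length, matches) of the best local alignment for cross-checking
    coverage/identity decisions.
    """
    n, m = len(query), len(target)
    H = np.zeros((n + 1, m + 1))
    best = (0.0, 0, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = H[i - 1, j - 1] + (match if query[i - 1] == target[j - 1]
                                      else mismatch)
            score = max(0.0, diag, H[i - 1, j] + gap, H[i, j - 1] + gap)
            H[i, j] = score
            if score > best[0]:
                best = (score, i, j)
    _, i, j = best
    q_end = i
    matches = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        sub = match if query[i - 1] == target[j - 1] else mismatch
        if H[i, j] == H[i - 1, j - 1] + sub:
            matches += query[i - 1] == target[j - 1]
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] + gap:
            i -= 1
        else:
            j -= 1
    return q_end - i, matches


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestFindSpecificGenes:
    def test_identical_genomes_empty_both_ways(self, small_pair):
        genes = cap.genes_from_genome(small_pair.parent_a)
        genome = {r.replicon_id: r.sequence_str for r in small_pair.parent_a}
        assert cap.find_specific_genes(genes, genome) == []

    def test_recovers_simulator_truth(self, small_pair):
        """At study-like divergence the specific sets equal the implants."""
        genes_a = cap.genes_from_genome(small_pair.parent_a)
        genes_b = cap.genes_from_genome(small_pair.parent_b)
        ga = {r.replicon_id: r.sequence_str for r in small_pair.parent_a}
        gb = {r.replicon_id: r.sequence_str for r in small_pair.parent_b}
        spec_a = cap.find_specific_genes(genes_a, gb, min_identity=0.95)
        spec_b = cap.find_specific_genes(genes_b, ga, min_identity=0.95)
        assert sorted(spec_a) == sorted(small_pair.specific_genes_a)
        assert sorted(spec_b) == sorted(small_pair.specific_genes_b)
        assert not set(spec_a) & set(spec_b)  # anti-symmetry

    @pytest.mark.parametrize("present_frac,expect_specific", [
        (0.30, True),    # below the 40% minimal cover -> specific
        (0.45, False),   # above -> shared
    ])
    def test_coverage_threshold_against_sw_oracle(self, present_frac,
                                                  expect_specific):
        rng = np.random.default_rng(17)
        gene_seq = _random_seq(rng, 600)
        kept = int(len(gene_seq) * present_frac)
        target = _random_seq(rng, 2000) + gene_seq[:kept] + _random_seq(rng, 2000)
        gene = cap.GeneRecord("g1", "c", 1, len(gene_seq), "+", gene_seq)
        specific = cap.find_specific_genes([gene], {"t": target})
        assert (specific == ["g1"]) is expect_specific
        # the exhaustive local-alignment oracle agrees on the decision
        span, matches = smith_waterman(gene_seq, target)
        coverage = span / len(gene_seq)
        identity = matches / span
        assert (coverage < 0.40 or identity < 0.99) is expect_specific

    def test_threshold_monotonicity(self, small_pair):
        genes = cap.genes_from_genome(small_pair.parent_a)[:12]
        gb = {r.replicon_id: r.sequence_str for r in small_pair.parent_b}
        index = cap.KmerIndex(gb)
        previous = None
        for min_cov in (0.2, 0.4, 0.8):
            spec = set(cap.find_specific_genes(genes, gb, min_cov, 0.95,
                                               index=index))
            if previous is not None:
                assert previous <= spec
            previous = spec


@pytest.fixture(scope="module")
def analysis_context(small_pair):
    ga = {r.replicon_id: r.sequence_str for r in small_pair.parent_a}
    return {
        "bg": ga,
        "ann_a": {r.replicon_id: r.genes for r in small_pair.parent_a},
        "ann_b": {r.replicon_id: r.genes for r in small_pair.parent_b},
        "spec_b": [g for g in cap.genes_from_genome(small_pair.parent_b)
                   if g.gene_id in small_pair.specific_genes_b],
    }


class TestDetectGeneHits:
    def test_implanted_gene_and_transposition_modes(self, small_pair,
                                                    marked_clone,
                                                    analysis_context):
        contigs = sim.tile_contigs(marked_clone.replicons)
        hits = cap.detect_gene_hits(
            analysis_context["spec_b"], contigs,
            background_genome=analysis_context["bg"],
            background_annotations=analysis_context["ann_a"],
            donor_annotations=analysis_context["ann_b"])
        modes = {h.gene_id: h.mode for h in hits}
        assert modes["sgB00"] == "homologous_flank"
        assert modes["ISB1"] == "transposition"
        for h in hits:
            assert h.query_coverage >= 0.40 and h.identity >= 0.99

    def test_clone_without_implants_yields_nothing(self, small_pair,
                                                   analysis_context):
        tj = sim.simulate_transjugant(small_pair, "A", 1, seed=5)
        hits = cap.detect_gene_hits(
            analysis_context["spec_b"], sim.tile_contigs(tj.replicons),
            background_genome=analysis_context["bg"],
            background_annotations=analysis_context["ann_a"],
            donor_annotations=analysis_context["ann_b"])
        assert hits == []

    def test_short_contig_is_unplaced(self, small_pair, analysis_context):
        gene = analysis_context["spec_b"][0]
        contigs = {"tiny": gene.sequence}  # no flank to assess
        (hit,) = cap.detect_gene_hits(
            [gene], contigs, background_genome=analysis_context["bg"],
            background_annotations=analysis_context["ann_a"],
            donor_annotations=analysis_context["ann_b"])
        assert hit.mode == "unplaced"

    def test_recovery_cohort(self, small_pair, analysis_context):
        """0-3 implanted genes per clone recovered with precision = recall = 1."""
        rng = np.random.default_rng(23)
        candidates = [g for g in small_pair.specific_genes_b
                      if not g.startswith("IS")]
        for i in range(12):
            k = int(rng.integers(0, 4))
            chosen = sorted(rng.choice(candidates, size=k, replace=False))
            tj = sim.simulate_transjugant(small_pair, "A", 0,
                                          gene_insertions=chosen,
                                          seed=900 + i)
            hits = cap.detect_gene_hits(
                analysis_context["spec_b"], sim.tile_contigs(tj.replicons),
                background_genome=analysis_context["bg"],
                background_annotations=analysis_context["ann_a"],
                donor_annotations=analysis_context["ann_b"])
            assert sorted({h.gene_id for h in hits}) == list(chosen)


class TestLocalizeMarker:
    def test_exact_recovery_from_reads(self, small_pair, marked_clone, cassette):
        cassette_id, cassette_seq = cassette
        reads = sim.simulate_reads(marked_clone.replicons, 150, 30.0, 0.0, seed=9)
        bg = {r.replicon_id: r.sequence_str for r in small_pair.parent_a}
        ann = {r.replicon_id: r.genes for r in small_pair.parent_a}
        locus = cap.localize_marker(reads, cassette_seq, bg, ann,
                                    cassette_id=cassette_id)
        truth = marked_clone.truth.marker
        assert locus.replicon_id == truth["replicon_id"]
        assert abs(locus.insertion_start - truth["replaced_start"]) <= 1
        assert abs(locus.insertion_end - truth["replaced_end"]) <= 1
        assert locus.five_prime_flank_gene == truth["target_gene"]

    def test_no_cassette_is_no_marker_signal(self, small_pair, cassette):
        tj = sim.simulate_transjugant(small_pair, "A", 1, seed=5)
        reads = sim.simulate_reads(tj.replicons, 150, 3.0, 0.0, seed=9)
        bg = {r.replicon_id: r.sequence_str for r in small_pair.parent_a}
        assert cap.localize_marker(reads, cassette[1], bg) is None

    def test_ambiguous_anchor_raises_with_candidates(self):
        rng = np.random.default_rng(3)
        repeat = _random_seq(rng, 300)
        genome = {"c": repeat + _random_seq(rng, 500) + repeat}
        cassette_seq = _random_seq(rng, 400)
        # junction read whose anchor lies inside the duplicated segment
        read = repeat[-80:] + cassette_seq[:60]
        with pytest.raises(cap.AmbiguousLocusError) as err:
            cap.localize_marker([("r1", read)], cassette_seq, genome)
        assert len(err.value.candidates) >= 2
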