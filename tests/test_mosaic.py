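"""Origin classification, gap-rule segmentation, summaries, truth scoring."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mosaictrace import mosaic as mo, panel as pn, simulate as sim
from mosaictrace.io import VariantCall


def brute_force_merge(positions, threshold):
    """O(n^2) transitive-closure clustering; the independent oracle."""
    positions = sorted(positions)
    parent = list(range(len(positions)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(positions)), 2):
        if abs(positions[i] - positions[j]) <= threshold:
            parent[find(i)] = find(j)
    groups = {}
    for i in range(len(positions)):
        groups.setdefault(find(i), []).append(positions[i])
    return sorted((min(g), max(g), len(g)) for g in groups.values())


@pytest.fixture(scope="module")
def small_panel(small_pair):
    return pn.panel_from_pair(small_pair, "A")


class TestClassifyVariants:
    def test_label_definitions(self):
        panel = pn.DiagnosticPanel("A", "B", [pn.DiagnosticSite("chr", 500, "G", "A")])
        cases = {
            "A": mo.FOREIGN,     # other parent's allele
            "G": mo.SELF,        # background allele materialized
            "T": mo.AMBIGUOUS,   # third allele
        }
        for alt, label in cases.items():
            ref = "C" if alt == "G" else "G"
            (cv,) = mo.classify_variants([VariantCall("chr", 500, ref, alt)],
                                         panel, "A")
            assert cv.label == label, alt
        (cv,) = mo.classify_variants([VariantCall("chr", 7, "G", "A")], panel, "A")
        assert cv.label == mo.NOVEL and cv.panel_site is None

    def test_swapped_background(self):
        panel = pn.DiagnosticPanel("A", "B", [pn.DiagnosticSite("chr", 500, "G", "A")])
        (cv,) = mo.classify_variants([VariantCall("chr", 500, "A", "G")],
                                     panel, "B")
        assert cv.label == mo.FOREIGN

    def test_conservation_every_record_labelled_once(self, small_pair, small_panel):
        tj = sim.simulate_transjugant(small_pair, "A", 3, transposition_count=1,
                                      seed=31)
        variants = sim.emit_truth_variants(tj, "A")
        classified = mo.classify_variants(variants, small_panel, "A")
        assert len(classified) == len(variants)
        counts = {}
        for cv in classified:
            counts[cv.label] = counts.get(cv.label, 0) + 1
        assert sum(counts.values()) == len(variants)

    def test_simulated_truth_all_foreign(self, small_pair, small_panel):
        tj = sim.simulate_transjugant(small_pair, "A", {"chromosome": 4}, seed=41)
        variants = sim.emit_truth_variants(tj, "A")
        classified = mo.classify_variants(variants, small_panel, "A")
        labels = [cv.label for cv in classified]
        assert labels.count(mo.FOREIGN) == len(tj.truth.implanted_panel_sites)
        assert labels.count(mo.AMBIGUOUS) == 0

    def test_duplicate_positions_rejected(self, small_panel):
        records = [VariantCall("chromosome", 5, "A", "G")] * 2
        with pytest.raises(mo.ValidationError, match="duplicate"):
            mo.classify_variants(records, small_panel, "A")


class TestSegmentRegions:
    def test_worked_example(self):
        regions = mo.segment_regions([100, 600, 5000], 1000, "chr")
        assert [(r.first_snp, r.last_snp, r.n_snps, r.size) for r in regions] \
            == [(100, 600, 2, 501), (5000, 5000, 1, 1)]
        assert regions[1].single_snp

    def test_empty(self):
        assert mo.segment_regions([], 1000) == []

    def test_boundary_gap_exactly_threshold_merges(self):
        # "more than 1 kbp" is strict: a 1000-bp gap stays in one region
        assert len(mo.segment_regions([100, 1100], 1000)) == 1
        assert len(mo.segment_regions([100, 1101], 1000)) == 2

    def test_unsorted_rejected(self):
        with pytest.raises(mo.ValidationError):
            mo.segment_regions([5, 3], 1000)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 10**6), max_size=200),
           st.sampled_from([1, 500, 1000, 10_000]))
    def test_matches_brute_force_oracle(self, positions, threshold):
        positions = sorted(set(positions))
        regions = mo.segment_regions(positions, threshold)
        assert [(r.first_snp, r.last_snp, r.n_snps) for r in regions] == \
            brute_force_merge(positions, threshold)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 10**6), min_size=1, max_size=100))
    def test_region_count_monotone_in_threshold(self, positions):
        positions = sorted(set(positions))
        counts = [len(mo.segment_regions(positions, t))
                  for t in (1, 500, 1000, 10_000, 10**6)]
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] == 1  # threshold >= span: single region


class TestSummarizeClone:
    def test_marker_only_region(self):
        summary = mo.summarize_clone([], ("megaplasmid", 7000, 7200))
        (region,) = summary.regions("megaplasmid")
        assert region.n_snps == 0 and region.contains_marker
        assert summary.per_replicon["megaplasmid"]["foreign_snps"] == 0

    def test_no_foreign_no_marker_no_regions(self, small_panel):
        novel = mo.classify_variants([VariantCall("chromosome", 4, "A", "C")],
                                     small_panel, "A")
        summary = mo.summarize_clone(novel)
        assert summary.regions("chromosome") == []
        assert summary.per_replicon["chromosome"]["novel_snps"] == 1

    def test_marker_inside_cluster_flags_it(self):
        panel = pn.DiagnosticPanel("A", "B", [
            pn.DiagnosticSite("m", p, "G", "A") for p in (100, 400, 900)])
        classified = mo.classify_variants(
            [VariantCall("m", p, "G", "A") for p in (100, 400, 900)], panel, "A")
        summary = mo.summarize_clone(classified, ("m", 350, 450))
        (region,) = summary.regions("m")
        assert region.contains_marker and region.n_snps == 3
        assert (region.first_snp, region.last_snp) == (100, 900)

    def test_six_fragments_yield_six_regions(self, small_pair, small_panel):
        tj = sim.simulate_transjugant(small_pair, "A", {"chromosome": 6}, seed=21)
        variants = sim.emit_truth_variants(tj, "A")
        classified = mo.classify_variants(variants, small_panel, "A")
        summary = mo.summarize_clone(classified)
        assert len(summary.regions("chromosome")) == 6

    def test_idempotence_on_own_output(self, small_pair, small_panel):
        tj = sim.simulate_transjugant(small_pair, "A", 3, seed=51)
        classified = mo.classify_variants(sim.emit_truth_variants(tj, "A"),
                                          small_panel, "A")
        summary = mo.summarize_clone(classified)
        for rep, d in summary.per_replicon.items():
            merged = [p for r in d["regions"]
                      for p in (r.first_snp, r.last_snp)]
            again = mo.summarize_clone(
                [cv for cv in classified if cv.variant.replicon_id == rep])
            assert [(r.first_snp, r.last_snp) for r in again.regions(rep)] == \
                [(r.first_snp, r.last_snp) for r in d["regions"]]


class TestEvaluateAgainstTruth:
    def _analyse(self, pair, tj):
        panel = pn.panel_from_pair(pair, tj.background)
        classified = mo.classify_variants(
            sim.emit_truth_variants(tj, tj.background), panel, tj.background)
        mk = tj.truth.marker
        locus = (mk["replicon_id"], mk["replaced_start"], mk["replaced_end"]) \
            if mk else None
        summary = mo.summarize_clone(classified, locus, clone_id=tj.clone_id,
                                     background_parent=tj.background)
        return summary, classified

    def test_perfect_input_perfect_scores(self, small_pair, marked_clone):
        summary, classified = self._analyse(small_pair, marked_clone)
        report = mo.evaluate_against_truth(summary, marked_clone.truth, classified)
        assert report.region_precision == 1.0
        assert report.region_recall == 1.0
        assert report.max_boundary_error == 0
        assert report.foreign_count_match
        assert report.label_accuracy == 1.0
        assert sum(report.confusion.values()) == len(classified)

    def test_single_site_fragment_recovered(self, small_pair):
        tj = sim.simulate_transjugant(
            small_pair, "A", {"chromosome": 1},
            fragment_size_sampler=lambda rng: 1, seed=61)
        summary, classified = self._analyse(small_pair, tj)
        (region,) = summary.regions("chromosome")
        assert region.single_snp
        report = mo.evaluate_against_truth(summary, tj.truth, classified)
        assert report.region_recall == 1.0

    def test_sub_threshold_gaps_reported_as_merges(self, small_pair):
        """Fragments placed closer than the gap rule merge and are flagged."""
        tj = sim.simulate_transjugant(small_pair, "A", {"chromosome": 5},
                                      fragment_size_sampler=lambda rng: 400,
                                      gap_bp=200, seed=71)
        summary, classified = self._analyse(small_pair, tj)
        report = mo.evaluate_against_truth(summary, tj.truth, classified)
        fragments = [(e.start, e.end) for e in tj.truth.events
                     if e.kind == "homologous_fragment"]
        # merging can only reduce the region count below the fragment count
        assert len(summary.regions("chromosome")) <= len(fragments)
        if len(summary.regions("chromosome")) < len(fragments):
            assert report.merged_fragment_pairs > 0

    def test_clone_mismatch_is_visible(self, small_pair, marked_clone):
        other = sim.simulate_transjugant(small_pair, "A", 1, seed=81,
                                         clone_id="T9")
        summary, classified = self._analyse(small_pair, other)
        report = mo.evaluate_against_truth(summary, marked_clone.truth, classified)
        assert report.region_recall < 1.0 or report.region_precision < 1.0
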