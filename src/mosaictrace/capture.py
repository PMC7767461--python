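"""Strain-specific gene sets, their capture in progeny, and marker localization.

A gene is *specific* to one parent when no local alignment against the other
parent's genome covers at least ``min_query_cover`` of the gene at
``min_identity``. The classic presence/absence criterion — at least 40%
of the query covered by an essentially exact (zero e-value) match — is
operationalized with a default 40% coverage threshold and 99% identity over
the covered span; e-values depend on the search tool and database size,
identity does not.

Local alignment is seed-and-extend: exact k-mer seeds (default k = 15)
clustered by diagonal band, extended/validated with edlib. An external
aligner can be substituted behind the same hit contract.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .io import FormatError

SEED_K = 15
FLANK_WINDOW = 200        # bp of contig flank needed to assess insertion mode
NEIGHBOR_WINDOW = 5000    # bp around native neighbours counting as "adjacent"
ANCHOR_MIN_LEN = 30       # shortest usable junction anchor (fits a 36-bp read)
MIN_QUERY_COVER = 0.40
MIN_IDENTITY = 0.99


class AmbiguousLocusError(ValueError):
    """An anchor matches several loci equally well; candidates attached."""

    def __init__(self, message: str, candidates: list):
        super().__init__(message)
        self.candidates = candidates


@dataclasses.dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    replicon_id: str
    start: int   # 1-based
    end: int     # inclusive
    strand: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start + 1:
            raise FormatError(f"{self.gene_id}: sequence length != interval length")


@dataclasses.dataclass(frozen=True)
class GeneHit:
    gene_id: str
    target_contig: str
    query_coverage: float
    identity: float
    target_start: int   # 1-based
    target_end: int     # inclusive
    mode: str           # homologous_flank | transposition | unplaced

    def __post_init__(self) -> None:
        if self.target_start > self.target_end:
            raise FormatError("hit interval inverted")


@dataclasses.dataclass(frozen=True)
class MarkerLocus:
    cassette_id: str
    replicon_id: str
    insertion_start: int  # 1-based interval on the background reference
    insertion_end: int
    five_prime_flank_gene: str | None = None
    three_prime_flank_gene: str | None = None

    @property
    def interval(self) -> tuple[int, int]:
        return (self.insertion_start, self.insertion_end)


def genes_from_genome(replicons, annotations: Mapping[str, Sequence] | None = None
                      ) -> list[GeneRecord]:
    """Extract GeneRecords from simulated replicons (or FASTA + GFF3 data)."""
    out = []
    for repl in replicons:
        seq = repl.sequence_str if hasattr(repl, "sequence_str") else str(repl)
        rep_id = repl.replicon_id if hasattr(repl, "replicon_id") else None
        genes = repl.genes if hasattr(repl, "genes") else annotations[rep_id]
        for gid, start, end, strand in genes:
            out.append(GeneRecord(gid, rep_id, start, end, strand,
                                  seq[start - 1:end]))
    return out


# ---------------------------------------------------------------------------
# seed-and-extend local alignment

class KmerIndex:
    """Exact k-mer position index over a set of target sequences."""

    def __init__(self, targets: Mapping[str, str], k: int = SEED_K,
                 max_hits_per_kmer: int = 64):
        self.k = k
        self.targets = dict(targets)
        self.index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in self.targets.items():
            for i in range(len(seq) - k + 1):
                hits = self.index[seq[i:i + k]]
                if len(hits) < max_hits_per_kmer:
                    hits.append((name, i))

    def seeds(self, query: str, step: int = 1) -> dict[tuple[str, int], list[tuple[int, int]]]:
        """Seed matches grouped by (target, banded diagonal)."""
        k = self.k
        groups: dict[tuple[str, int], list[tuple[int, int]]] = defaultdict(list)
        for q in range(0, len(query) - k + 1, step):
            for name, t in self.index.get(query[q:q + k], ()):
                band = (t - q) // 32
                groups[(name, band)].append((q, t))
        merged: dict[tuple[str, int], list[tuple[int, int]]] = defaultdict(list)
        for (name, band), hits in groups.items():
            merged[(name, band)].extend(hits)
            # merge adjacent bands so a band boundary cannot split one locus
            if (name, band + 1) in groups:
                merged[(name, band)].extend(groups[(name, band + 1)])
        return merged


@dataclasses.dataclass(frozen=True)
class LocalHit:
    target: str
    query_start: int   # 0-based half-open span of the aligned query
    query_end: int
    target_start: int  # 0-based half-open
    target_end: int
    coverage: float
    identity: float

    @property
    def score(self) -> float:
        return self.coverage * self.identity


def local_hits(query: str, index: KmerIndex, min_identity: float = MIN_IDENTITY,
               pad: int = 50) -> list[LocalHit]:
    """Candidate local alignments of ``query`` against the indexed targets.

    For each diagonal cluster of exact seeds the full query is first tried as
    an infix alignment of the target window (coverage 1.0 when it reaches
    ``min_identity``); otherwise the seed-supported query span alone is
    aligned and reported with partial coverage.
    """
    out = []
    n = len(query)
    for (name, _), hits in index.seeds(query).items():
        tseq = index.targets[name]
        qs = min(h[0] for h in hits)
        qe = max(h[0] for h in hits) + index.k
        ts = min(h[1] for h in hits)
        te = max(h[1] for h in hits) + index.k
        # full-query attempt
        ws = max(0, ts - qs - pad)
        we = min(len(tseq), te + (n - qe) + pad)
        res = edlib.align(query, tseq[ws:we], mode="HW", task="locations")
        if res["editDistance"] >= 0:
            ident = 1.0 - res["editDistance"] / n
            if ident >= min_identity:
                loc = res["locations"][0]
                out.append(LocalHit(name, 0, n, ws + loc[0], ws + loc[1] + 1,
                                    1.0, ident))
                continue
        # partial: seed-supported span only
        span = query[qs:qe]
        ws = max(0, ts - pad)
        we = min(len(tseq), te + pad)
        res = edlib.align(span, tseq[ws:we], mode="HW", task="locations")
        if res["editDistance"] < 0:
            continue
        ident = 1.0 - res["editDistance"] / len(span)
        loc = res["locations"][0]
        out.append(LocalHit(name, qs, qe, ws + loc[0], ws + loc[1] + 1,
                            (qe - qs) / n, ident))
    out.sort(key=lambda h: (-h.score, h.target, h.target_start))
    return out


def best_local_hit(query: str, index: KmerIndex,
                   min_identity: float = MIN_IDENTITY) -> LocalHit | None:
    hits = local_hits(query, index, min_identity)
    return hits[0] if hits else None


# ---------------------------------------------------------------------------
# operations

def find_specific_genes(genes_a: Sequence[GeneRecord],
                        genome_b: Mapping[str, str],
                        min_query_cover: float = MIN_QUERY_COVER,
                        min_identity: float = MIN_IDENTITY,
                        index: KmerIndex | None = None) -> list[str]:
    """Gene ids of parent A with no adequate match anywhere in genome B.

    A gene is specific iff no local alignment reaches both thresholds;
    genes on replicons absent from B are specific by definition (they simply
    find no alignment). Swap the arguments for B-specific genes.
    """
    index = index or KmerIndex(genome_b)
    specific = []
    for gene in genes_a:
        candidates = local_hits(gene.sequence, index, min_identity)
        if not any(h.coverage >= min_query_cover and h.identity >= min_identity
                   for h in candidates):
            specific.append(gene.gene_id)
    return specific


def detect_gene_hits(specific_genes: Sequence[GeneRecord],
                     progeny_contigs: Mapping[str, str],
                     min_query_cover: float = MIN_QUERY_COVER,
                     min_identity: float = MIN_IDENTITY,
                     background_genome: Mapping[str, str] | None = None,
                     background_annotations: Mapping[str, Sequence] | None = None,
                     donor_annotations: Mapping[str, Sequence] | None = None,
                     flank_window: int = FLANK_WINDOW,
                     keep_secondary: bool = False) -> list[GeneHit]:
    """Best hit per donor-specific gene among progeny contigs, with insertion mode.

    Mode calls need the background reference plus both annotation sets:
    ``homologous_flank`` when a contig flank lands adjacent (within
    ``NEIGHBOR_WINDOW``) to a background homologue of the gene's native
    neighbours, ``transposition`` when the flanks place at an unrelated
    locus, ``unplaced`` when the contig leaves < ``flank_window`` bp of
    assessable flank. Absence of hits is an empty result, not an error.
    """
    if not progeny_contigs:
        return []
    index = KmerIndex(progeny_contigs)
    bg_index = KmerIndex(background_genome) if background_genome else None
    out = []
    for gene in specific_genes:
        hits = [h for h in local_hits(gene.sequence, index, min_identity)
                if h.coverage >= min_query_cover and h.identity >= min_identity]
        if not hits:
            continue
        for h in hits if keep_secondary else hits[:1]:
            mode = _insertion_mode(gene, h, progeny_contigs, bg_index,
                                   background_annotations, donor_annotations,
                                   flank_window)
            out.append(GeneHit(gene.gene_id, h.target, h.coverage, h.identity,
                               h.target_start + 1, h.target_end, mode))
    return out


def _neighbor_positions(gene: GeneRecord,
                        donor_annotations: Mapping[str, Sequence],
                        background_annotations: Mapping[str, Sequence]
                        ) -> list[tuple[str, int]]:
    """Background loci of the donor gene's nearest annotated neighbours."""
    donor_genes = sorted(donor_annotations.get(gene.replicon_id, ()),
                         key=lambda g: g[1])
    ids = [g[0] for g in donor_genes]
    if gene.gene_id not in ids:
        return []
    i = ids.index(gene.gene_id)
    neighbours = [donor_genes[j][0] for j in (i - 1, i + 1)
                  if 0 <= j < len(donor_genes)]
    out = []
    for rep, genes in background_annotations.items():
        for gid, start, end, _ in genes:
            if gid in neighbours:
                out.append((rep, (start + end) // 2))
    return out


def _insertion_mode(gene: GeneRecord, hit: LocalHit,
                    contigs: Mapping[str, str], bg_index: KmerIndex | None,
                    background_annotations, donor_annotations,
                    flank_window: int) -> str:
    contig = contigs[hit.target]
    left = contig[max(0, hit.target_start - flank_window):hit.target_start]
    right = contig[hit.target_end:hit.target_end + flank_window]
    if len(left) < flank_window and len(right) < flank_window:
        return "unplaced"
    if bg_index is None or background_annotations is None or donor_annotations is None:
        return "unplaced"
    placements = []
    for flank in (left, right):
        if len(flank) >= flank_window:
            fh = best_local_hit(flank, bg_index, min_identity=0.9)
            if fh is not None and fh.coverage >= 0.9:
                placements.append((fh.target, (fh.target_start + fh.target_end) // 2))
    if not placements:
        return "unplaced"
    expected = _neighbor_positions(gene, donor_annotations, background_annotations)
    for rep, pos in placements:
        for erep, epos in expected:
            if rep == erep and abs(pos - epos) <= NEIGHBOR_WINDOW:
                return "homologous_flank"
    return "transposition"


def localize_marker(reads_or_contigs: Iterable[tuple[str, str]] | Mapping[str, str],
                    cassette_sequence: str,
                    background_genome: Mapping[str, str],
                    background_annotations: Mapping[str, Sequence] | None = None,
                    anchor_min_len: int = ANCHOR_MIN_LEN,
                    cassette_id: str = "cassette",
                    probe_len: int = 20) -> MarkerLocus | None:
    """Localize a marker cassette from sequences spanning its junctions.

    Reads (or contigs) partially matching a cassette end are split at the
    junction; the non-cassette portion (>= ``anchor_min_len``) is placed on
    the background reference — exactly when possible, tolerantly via edlib
    otherwise (flank anchors may legitimately carry donor alleles at
    diagnostic sites). The insertion interval is bounded by the consensus
    5' and 3' junction placements. Returns None when the cassette is absent
    from every input sequence (no-marker signal).
    """
    if isinstance(reads_or_contigs, Mapping):
        seqs: Iterable[tuple[str, str]] = reads_or_contigs.items()
    elif hasattr(reads_or_contigs, "reads"):
        seqs = ((rid, s) for rid, s, _ in reads_or_contigs.reads())
    else:
        seqs = reads_or_contigs
    head, tail = cassette_sequence[:probe_len], cassette_sequence[-probe_len:]
    five_votes: dict[tuple[str, int], int] = defaultdict(int)
    three_votes: dict[tuple[str, int], int] = defaultdict(int)
    cassette_seen = False
    for _, seq in seqs:
        j = seq.find(head)
        if j >= 0:
            cassette_seen = True
            if j >= anchor_min_len:
                loc = _place_anchor(seq[:j], background_genome, end_anchored=True)
                if loc is not None:
                    five_votes[loc] += 1
        j = seq.find(tail)
        if j >= 0:
            cassette_seen = True
            anchor = seq[j + probe_len:]
            if len(anchor) >= anchor_min_len:
                loc = _place_anchor(anchor, background_genome, end_anchored=False)
                if loc is not None:
                    three_votes[loc] += 1
    if not cassette_seen:
        return None
    five = _consensus_vote(five_votes, "5' junction")
    three = _consensus_vote(three_votes, "3' junction")
    if five is None and three is None:
        return None
    if five is None:
        five = three
    if three is None:
        three = five
    if five[0] != three[0]:
        raise AmbiguousLocusError("cassette junctions on different replicons",
                                  [five, three])
    rep = five[0]
    start_1, end_1 = five[1] + 1, three[1]  # replaced interval, 1-based closed
    if end_1 < start_1:
        end_1 = start_1
    g5 = g3 = None
    if background_annotations:
        genes = sorted(background_annotations.get(rep, ()), key=lambda g: g[1])
        inside = [g for g in genes if g[1] <= end_1 and start_1 <= g[2]]
        if inside:
            g5 = g3 = inside[0][0]
        else:
            before = [g for g in genes if g[2] < start_1]
            after = [g for g in genes if g[1] > end_1]
            g5 = before[-1][0] if before else None
            g3 = after[0][0] if after else None
    return MarkerLocus(cassette_id, rep, start_1, end_1, g5, g3)


def _place_anchor(anchor: str, genome: Mapping[str, str], end_anchored: bool,
                  max_candidates: int = 4) -> tuple[str, int] | None:
    """Locate an anchor; returns (replicon, junction 0-based coordinate).

    For a 5' anchor (``end_anchored``) the junction is the coordinate just
    past the anchor's placement end; for a 3' anchor it is the placement
    start. Exact multi-locus matches raise AmbiguousLocusError.
    """
    exact = []
    for rep, seq in genome.items():
        p = seq.find(anchor)
        while p >= 0 and len(exact) <= max_candidates:
            exact.append((rep, p))
            p = seq.find(anchor, p + 1)
    if len(exact) > 1:
        raise AmbiguousLocusError(f"anchor matches {len(exact)} loci",
                                  exact)
    if exact:
        rep, p = exact[0]
        return (rep, p + len(anchor)) if end_anchored else (rep, p)
    # tolerant placement: donor alleles or sequencing error inside the anchor
    best, best_d = None, None
    for rep, seq in genome.items():
        res = edlib.align(anchor, seq, mode="HW", task="locations")
        d = res["editDistance"]
        if d < 0 or d > max(1, int(0.1 * len(anchor))):
            continue
        if best_d is None or d < best_d:
            loc = res["locations"][0]
            best = (rep, loc[1] + 1) if end_anchored else (rep, loc[0])
            best_d = d
        elif d == best_d:
            best = None  # equally good on two replicons: unusable anchor
    return best


def _consensus_vote(votes: Mapping[tuple[str, int], int], what: str
                    ) -> tuple[str, int] | None:
    if not votes:
        return None
    ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[0][0]


def hits_frame(hits: Sequence[GeneHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.gene_id, h.target_contig, round(h.query_coverage, 4),
          round(h.identity, 4), h.target_start, h.target_end, h.mode)
         for h in hits],
        columns=["gene_id", "contig", "query_coverage", "identity",
                 "target_start", "target_end", "mode"])
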