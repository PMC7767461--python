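"""Synthetic transjugation simulator with full ground truth.

Emulates a mating system between two closely related, highly syntenic
bacterial strains (a chromosome plus a megaplasmid, ~1 differential SNP per
124 bp, strain-specific gene insertions). A simulated transjugant is one
parent's genome ("background") carrying:

* homologous fragments — intervals where diagnostic SNP alleles are switched
  to the other parent's ("donor") alleles, emulating recombination tracts;
* a selection-marker cassette replacing the mid-section of a target gene,
  flanked by donor alleles over a configurable homology tract;
* transposed copies of a donor-specific insertion-sequence (IS) element;
* optionally, donor-specific genes implanted at their homologous locus.

Everything is generated on a shared "core" backbone coordinate system;
strain-specific genes are insertions into one parent only, so each parent
(and each transjugant) carries its own coordinate frame with exact maps
between frames. All public outputs use 1-based coordinates in the frame of
the genome they describe; ground truth is reported in the background
parent's frame.

Genomes are single-copy consensus sequences (the organism is polyploid, but
consensus variant calls are what the analysis consumes). Reads are
single-end, uniform-start, substitution-error-only.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .io import VariantCall, decode_seq, encode_seq, write_fasta, write_fastq, \
    write_gff3, write_vcf, write_bed

DEFAULT_SNP_DENSITY = 1.0 / 124.0  # differential SNPs per bp between parents
DEFAULT_REPLICON_LENGTHS = (200_000, 50_000)  # desk-scale chromosome + megaplasmid
DEFAULT_GAP_BP = 1000            # separation defining distinct transferred regions
DEFAULT_MARKER_FLANK = 1000      # donor homology tract each side of the cassette
DEFAULT_CASSETTE_REPLACE = 200   # bp of target-gene mid-section replaced
_SHARED_GENE_LEN = 900
_SHARED_GENE_PERIOD = 1500
_IS_ELEMENT_LEN = 1066
_EDGE_MARGIN = 300


class ParameterError(ValueError):
    pass


class PlacementError(RuntimeError):
    """Requested events cannot be placed under the spacing constraints."""


# ---------------------------------------------------------------------------
# domain types

@dataclasses.dataclass
class SimulatedReplicon:
    replicon_id: str
    role: str  # chromosome | megaplasmid | plasmid
    sequence: np.ndarray  # uint8 codes
    genes: list[tuple[str, int, int, str]]  # (gene_id, start, end, strand), 1-based

    def __post_init__(self) -> None:
        seen = set()
        for gid, start, end, _ in self.genes:
            if not (1 <= start <= end <= len(self.sequence)):
                raise ParameterError(f"gene {gid} outside [1,{len(self.sequence)}]")
            if gid in seen:
                raise ParameterError(f"duplicate gene id {gid}")
            seen.add(gid)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def sequence_str(self) -> str:
        return decode_seq(self.sequence)


@dataclasses.dataclass(frozen=True)
class _Insertion:
    """Strain-specific content: ``seq`` inserted before core index ``core_pos``."""
    core_pos: int
    seq: np.ndarray
    gene_id: str
    kind: str  # specific_gene | is_element


@dataclasses.dataclass(frozen=True)
class TransferEvent:
    kind: str  # homologous_fragment | marker_insertion | transposition | specific_gene_insertion
    replicon_id: str
    start: int  # 1-based, background-parent frame
    end: int    # 1-based inclusive
    payload_id: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ParameterError("event start > end")


@dataclasses.dataclass
class TransjugantTruth:
    background_parent: str  # "A" | "B"
    events: list[TransferEvent]
    implanted_panel_sites: list[tuple[str, int]]  # background-frame, 1-based
    seed: int
    # extra bookkeeping (beyond the minimal contract)
    marker: dict | None = None  # replicon, replaced span, cassette id, target gene

    def to_json(self) -> dict:
        return {
            "background_parent": self.background_parent,
            "seed": self.seed,
            "events": [dataclasses.asdict(e) for e in self.events],
            "implanted_panel_sites": [list(s) for s in self.implanted_panel_sites],
            "marker": self.marker,
        }


@dataclasses.dataclass(frozen=True)
class _Edit:
    """Structural edit in background frame: replace [start0, end0) by ``seq``."""
    start0: int
    end0: int
    seq: np.ndarray
    payload_id: str
    kind: str
    core_anchor: int  # core index of start0 (edits never sit inside bg insertions)


# ---------------------------------------------------------------------------
# coordinate maps

def _ins_arrays(insertions: Sequence[_Insertion]) -> tuple[np.ndarray, np.ndarray]:
    anchors = np.array([i.core_pos for i in insertions], dtype=np.int64)
    lens = np.array([len(i.seq) for i in insertions], dtype=np.int64)
    order = np.argsort(anchors)
    return anchors[order], np.concatenate([[0], np.cumsum(lens[order])])


def _map_core(positions, anchors: np.ndarray, cum: np.ndarray):
    """Map core coordinates (0-based) into a parent frame with insertions."""
    idx = np.searchsorted(anchors, np.asarray(positions), side="right")
    return np.asarray(positions) + cum[idx]


def _inv_map(pos: int, anchors: np.ndarray, cum: np.ndarray) -> int:
    """Invert ``_map_core`` for a backbone position (undefined inside insertions)."""
    if len(anchors) == 0:
        return pos
    idx = int(np.searchsorted(anchors + cum[:-1], pos, side="right"))
    return pos - int(cum[idx])


def _splice(core: np.ndarray, insertions: Sequence[_Insertion]) -> np.ndarray:
    parts, cursor = [], 0
    for ins in sorted(insertions, key=lambda i: i.core_pos):
        parts.append(core[cursor:ins.core_pos])
        parts.append(ins.seq)
        cursor = ins.core_pos
    parts.append(core[cursor:])
    return np.concatenate(parts) if parts else core.copy()


# ---------------------------------------------------------------------------
# parental pair

@dataclasses.dataclass
class ParentalPair:
    """Two syntenic parental genomes plus the exact diagnostic truth panel."""

    replicon_ids: list[str]
    roles: dict[str, str]
    core: dict[str, np.ndarray]
    snp_pos: dict[str, np.ndarray]   # core frame, 0-based, sorted
    snp_alt: dict[str, np.ndarray]   # parent-B allele codes; A allele = core[pos]
    insertions: dict[str, dict[str, list[_Insertion]]]  # parent -> replicon -> list
    shared_genes: dict[str, list[tuple[str, int, int, str]]]  # core frame, 0-based half-open
    seed: int

    parent_a: list[SimulatedReplicon] = dataclasses.field(default_factory=list)
    parent_b: list[SimulatedReplicon] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.parent_a:
            self.parent_a = [self._build_parent("A", rep) for rep in self.replicon_ids]
            self.parent_b = [self._build_parent("B", rep) for rep in self.replicon_ids]

    # -- construction -------------------------------------------------------
    def _core_with_alleles(self, parent: str, rep: str) -> np.ndarray:
        seq = self.core[rep].copy()
        if parent == "B":
            seq[self.snp_pos[rep]] = self.snp_alt[rep]
        return seq

    def _build_parent(self, parent: str, rep: str) -> SimulatedReplicon:
        ins = self.insertions[parent][rep]
        seq = _splice(self._core_with_alleles(parent, rep), ins)
        anchors, cum = _ins_arrays(ins)
        genes: list[tuple[str, int, int, str]] = []
        for gid, s0, e0, strand in self.shared_genes[rep]:
            ps = int(_map_core(s0, anchors, cum))
            pe = int(_map_core(e0 - 1, anchors, cum))
            genes.append((gid, ps + 1, pe + 1, strand))
        for item in sorted(ins, key=lambda i: i.core_pos):
            ps = int(_map_core(item.core_pos - 1, anchors, cum)) + 1  # first inserted base, 0-based
            genes.append((item.gene_id, ps + 1, ps + len(item.seq), "+"))
        genes.sort(key=lambda g: g[1])
        return SimulatedReplicon(rep, self.roles[rep], seq, genes)

    # -- accessors -----------------------------------------------------------
    def parent(self, which: str) -> list[SimulatedReplicon]:
        return self.parent_a if which == "A" else self.parent_b

    def replicon(self, which: str, rep: str) -> SimulatedReplicon:
        return self.parent(which)[self.replicon_ids.index(rep)]

    def ins_map(self, which: str, rep: str) -> tuple[np.ndarray, np.ndarray]:
        return _ins_arrays(self.insertions[which][rep])

    def panel_positions(self, which: str, rep: str) -> np.ndarray:
        """Diagnostic-site positions in parent ``which``'s frame (0-based)."""
        anchors, cum = self.ins_map(which, rep)
        return _map_core(self.snp_pos[rep], anchors, cum)

    def panel_alleles(self, rep: str) -> tuple[np.ndarray, np.ndarray]:
        """(allele_a, allele_b) code arrays at the replicon's panel sites."""
        return self.core[rep][self.snp_pos[rep]], self.snp_alt[rep]

    @property
    def true_panel(self) -> list[tuple[str, int, str, str]]:
        """(replicon, pos, allele_a, allele_b), 1-based in parent A's frame."""
        out = []
        for rep in self.replicon_ids:
            pos_a = self.panel_positions("A", rep)
            a, b = self.panel_alleles(rep)
            out.extend((rep, int(p) + 1, decode_seq(np.array([x])), decode_seq(np.array([y])))
                       for p, x, y in zip(pos_a, a, b))
        return out

    def specific_genes(self, which: str) -> list[str]:
        return [i.gene_id for rep in self.replicon_ids
                for i in self.insertions[which][rep]]

    @property
    def specific_genes_a(self) -> list[str]:
        return self.specific_genes("A")

    @property
    def specific_genes_b(self) -> list[str]:
        return self.specific_genes("B")

    def is_element(self, which: str) -> _Insertion | None:
        for rep in self.replicon_ids:
            for ins in self.insertions[which][rep]:
                if ins.kind == "is_element":
                    return ins
        return None


def _orf_like(rng: np.random.Generator, length: int) -> np.ndarray:
    """Random ORF-like sequence: ATG + sense codons + TAA, length rounded to 3n."""
    n_codons = max(2, length // 3)
    stops = {"TAA", "TAG", "TGA"}
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = decode_seq(rng.integers(0, 4, size=3).astype(np.uint8))
        if c not in stops:
            codons.append(c)
    codons.append("TAA")
    return encode_seq("".join(codons))


def generate_parental_pair(
    replicon_lengths: Sequence[int] = DEFAULT_REPLICON_LENGTHS,
    snp_density: float = DEFAULT_SNP_DENSITY,
    n_specific_genes: int = 12,
    gene_length: int = 2000,
    seed: int = 0,
    include_is_elements: bool | None = None,
    replicon_ids: Sequence[str] | None = None,
) -> ParentalPair:
    """Generate two syntenic parental genomes differing by SNPs and specific genes.

    Parent B equals parent A with substitutions drawn i.i.d. per position at
    ``snp_density`` (alternate allele uniform over the three non-reference
    bases), plus ``n_specific_genes`` ORF-like insertions private to each
    parent (anchored in intergenic backbone, >= 500 bp of shared flank).
    When ``include_is_elements`` (default: whenever specific genes are
    requested) each parent additionally carries one private IS-like element
    (id ``ISA1`` / ``ISB1``), the substrate for simulated transpositions.
    """
    if not (0.0 <= snp_density <= 0.1):
        raise ParameterError(f"snp_density must be in [0, 0.1], got {snp_density}")
    if any(l < 1000 for l in replicon_lengths):
        raise ParameterError("replicon lengths must be >= 1000 bp")
    if include_is_elements is None:
        include_is_elements = n_specific_genes > 0

    rng = np.random.default_rng(seed)
    if replicon_ids is None:
        names = ["chromosome", "megaplasmid"] + [f"plasmid{i}" for i in range(3, 9)]
        replicon_ids = names[:len(replicon_lengths)]
    roles = {}
    for i, rep in enumerate(replicon_ids):
        roles[rep] = "chromosome" if i == 0 else ("megaplasmid" if i == 1 else "plasmid")

    core, snp_pos, snp_alt, shared_genes = {}, {}, {}, {}
    gaps_by_rep: dict[str, list[int]] = {}
    for rep, L in zip(replicon_ids, replicon_lengths):
        core[rep] = rng.integers(0, 4, size=L).astype(np.uint8)
        hit = rng.random(L) < snp_density
        pos = np.flatnonzero(hit).astype(np.int64)
        snp_pos[rep] = pos
        snp_alt[rep] = ((core[rep][pos] + rng.integers(1, 4, size=len(pos))) % 4).astype(np.uint8)
        genes, gap_mids = [], []
        s = _EDGE_MARGIN
        gi = 0
        while s + _SHARED_GENE_LEN <= L - _EDGE_MARGIN:
            strand = "+" if gi % 2 == 0 else "-"
            genes.append((f"{rep}_g{gi:04d}", s, s + _SHARED_GENE_LEN, strand))
            mid = s + _SHARED_GENE_LEN + (_SHARED_GENE_PERIOD - _SHARED_GENE_LEN) // 2
            if mid + _SHARED_GENE_PERIOD < L - _EDGE_MARGIN:
                gap_mids.append(mid)
            s += _SHARED_GENE_PERIOD
            gi += 1
        shared_genes[rep] = genes
        gaps_by_rep[rep] = gap_mids

    # distribute private insertions over intergenic anchor points
    insertions: dict[str, dict[str, list[_Insertion]]] = {
        "A": {rep: [] for rep in replicon_ids},
        "B": {rep: [] for rep in replicon_ids},
    }
    lengths = np.array(replicon_lengths, dtype=float)
    weights = lengths / lengths.sum()
    free_gaps = {rep: list(g) for rep, g in gaps_by_rep.items()}

    def _place(parent: str, gene_id: str, seq: np.ndarray) -> None:
        for _ in range(200):
            rep = replicon_ids[int(rng.choice(len(replicon_ids), p=weights))]
            if free_gaps[rep]:
                k = int(rng.integers(len(free_gaps[rep])))
                anchor = free_gaps[rep].pop(k)
                insertions[parent][rep].append(_Insertion(anchor, seq, gene_id,
                                                          "is_element" if gene_id.startswith("IS") else "specific_gene"))
                return
        raise PlacementError(f"no intergenic anchor left for {gene_id}")

    for parent in ("A", "B"):
        for g in range(n_specific_genes):
            _place(parent, f"sg{parent}{g:02d}", _orf_like(rng, gene_length))
        if include_is_elements:
            _place(parent, f"IS{parent}1", _orf_like(rng, _IS_ELEMENT_LEN))

    return ParentalPair(list(replicon_ids), roles, core, snp_pos, snp_alt,
                        insertions, shared_genes, seed)


# ---------------------------------------------------------------------------
# transjugant simulation

@dataclasses.dataclass
class Transjugant:
    """A simulated progeny clone plus everything needed to emit exact truth."""

    clone_id: str
    pair: ParentalPair
    background: str  # "A" | "B"
    replicons: list[SimulatedReplicon]
    truth: TransjugantTruth
    edits: dict[str, list[_Edit]]            # background-frame structural edits
    switched_mask: dict[str, np.ndarray]     # per replicon: bool over panel sites
    _switched_seq: dict[str, np.ndarray]     # bg frame, SNPs switched, pre-splice

    @property
    def donor(self) -> str:
        return "B" if self.background == "A" else "A"

    def bg_to_clone(self, rep: str, positions: np.ndarray) -> np.ndarray:
        """Map background-frame 0-based positions to clone frame (-1 if deleted)."""
        edits = sorted(self.edits.get(rep, []), key=lambda e: e.start0)
        starts = np.array([e.start0 for e in edits], dtype=np.int64)
        ends = np.array([e.end0 for e in edits], dtype=np.int64)
        deltas = np.array([len(e.seq) - (e.end0 - e.start0) for e in edits], dtype=np.int64)
        cum = np.concatenate([[0], np.cumsum(deltas)])
        pos = np.asarray(positions, dtype=np.int64)
        idx = np.searchsorted(ends, pos, side="right")
        out = pos + cum[idx]
        if len(edits):
            inside = np.zeros(len(pos), dtype=bool)
            for e in edits:
                inside |= (pos >= e.start0) & (pos < e.end0)
            out[inside] = -1
        return out


def _default_size_sampler(rng: np.random.Generator) -> int:
    """Log-uniform fragment size from 1 bp (single SNP) to ~30 kbp."""
    return int(round(math.exp(rng.uniform(math.log(1.0), math.log(30_000.0)))))


def _make_sampler(spec) -> Callable[[np.random.Generator], int]:
    if spec is None:
        return _default_size_sampler
    if callable(spec):
        return spec
    if isinstance(spec, (tuple, list)) and len(spec) == 2 and all(
            isinstance(x, (int, float)) for x in spec):
        lo, hi = float(spec[0]), float(spec[1])
        return lambda rng: int(round(math.exp(rng.uniform(math.log(max(lo, 1.0)),
                                                          math.log(hi)))))
    if isinstance(spec, (tuple, list)):
        sizes = [int(s) for s in spec]
        return lambda rng: sizes[int(rng.integers(len(sizes)))]
    raise ParameterError(f"unsupported fragment size sampler: {spec!r}")


class _Zones:
    """Closed-interval exclusion zones for event placement."""

    def __init__(self) -> None:
        self.iv: list[tuple[int, int]] = []

    def add(self, start: int, end: int, margin: int = 0) -> None:
        self.iv.append((start - margin, end + margin))

    def clashes(self, start: int, end: int) -> bool:
        return any(s <= end and start <= e for s, e in self.iv)


def pick_marker_target(pair: ParentalPair, replicon: str,
                       flank: int = DEFAULT_MARKER_FLANK,
                       gap_bp: int = DEFAULT_GAP_BP,
                       background: str = "A") -> str:
    """Pick a shared gene on ``replicon`` whose homology tract fits comfortably.

    The tract (gene midpoint +/- ``flank``) must keep > ``gap_bp`` clear of
    every strain-specific insertion in either parent, mirroring the placement
    constraints simulate_transjugant enforces. Genes nearest the replicon
    midpoint are preferred.
    """
    anchors, cum = pair.ins_map(background, replicon)
    donor = _other(background)
    zones = []
    for k, ins in enumerate(sorted(pair.insertions[background][replicon],
                                   key=lambda i: i.core_pos)):
        s = int(ins.core_pos + cum[k])
        zones.append((s - gap_bp, s + len(ins.seq) - 1 + gap_bp))
    for ins in pair.insertions[donor][replicon]:
        p = int(_map_core(ins.core_pos, anchors, cum))
        zones.append((p - gap_bp, p + gap_bp))
    L = pair.replicon(background, replicon).length
    candidates = []
    for gid, s0, e0, _ in pair.shared_genes[replicon]:
        mid = int(_map_core((s0 + e0) // 2, anchors, cum))
        lo, hi = mid - flank, mid + flank - 1
        if lo <= _EDGE_MARGIN or hi >= L - _EDGE_MARGIN:
            continue
        if any(zs <= hi and lo <= ze for zs, ze in zones):
            continue
        candidates.append((abs(mid - L // 2), gid))
    if not candidates:
        raise PlacementError(f"no suitable marker target gene on {replicon}")
    return min(candidates)[1]


def default_cassette(seed: int = 7, length: int = 1236,
                     cassette_id: str = "hph") -> tuple[str, str]:
    """A synthetic resistance-cassette sequence (id, sequence string)."""
    rng = np.random.default_rng(seed)
    return cassette_id, decode_seq(_orf_like(rng, length))


def simulate_transjugant(
    pair: ParentalPair,
    background: str,
    n_fragments: int | Mapping[str, int],
    fragment_size_sampler=None,
    marker: tuple | None = None,
    transposition_count: int = 0,
    seed: int = 0,
    gene_insertions: Sequence[str] = (),
    gap_bp: int = DEFAULT_GAP_BP,
    enforce_gap: bool = True,
    marker_flank: int = DEFAULT_MARKER_FLANK,
    cassette_replace: int = DEFAULT_CASSETTE_REPLACE,
    clone_id: str = "clone",
) -> Transjugant:
    """Implant donor fragments / marker / transpositions into a background parent.

    ``marker`` is ``(cassette_seq, target_gene_id)`` or ``(cassette_id,
    cassette_seq, target_gene_id)``. ``n_fragments`` applies per replicon
    (int) or per named replicon (mapping). With ``enforce_gap`` fragments are
    placed with inter-event gaps > ``gap_bp`` and no internal diagnostic-site
    gap above ``gap_bp``, so each fragment yields exactly one called region;
    set it False to deliberately provoke region merging.
    """
    if background not in ("A", "B"):
        raise ParameterError("background must be 'A' or 'B'")
    donor = "B" if background == "A" else "A"
    rng = np.random.default_rng(seed)
    sampler = _make_sampler(fragment_size_sampler)

    frag_counts = ({rep: int(n_fragments) for rep in pair.replicon_ids}
                   if isinstance(n_fragments, (int, np.integer)) else dict(n_fragments))
    for rep, n in frag_counts.items():
        if n < 0:
            raise ParameterError("fragments per replicon must be >= 0")

    events: list[TransferEvent] = []
    implanted: list[tuple[str, int]] = []
    edits: dict[str, list[_Edit]] = {rep: [] for rep in pair.replicon_ids}
    switched_mask = {rep: np.zeros(len(pair.snp_pos[rep]), dtype=bool)
                     for rep in pair.replicon_ids}
    switched_seq: dict[str, np.ndarray] = {}
    marker_truth = None

    # per-replicon background-frame geometry
    bg_maps = {rep: pair.ins_map(background, rep) for rep in pair.replicon_ids}
    panel_bg = {rep: pair.panel_positions(background, rep) for rep in pair.replicon_ids}

    def to_core(rep: str, bg_pos: int) -> int:
        anchors, cum = bg_maps[rep]
        return _inv_map(bg_pos, anchors, cum)

    zones: dict[str, _Zones] = {rep: _Zones() for rep in pair.replicon_ids}
    for rep in pair.replicon_ids:
        repl = pair.replicon(background, rep)
        anchors, cum = bg_maps[rep]
        # own insertions occupy bg spans; donor insertion anchors are points
        for k, ins in enumerate(sorted(pair.insertions[background][rep],
                                       key=lambda i: i.core_pos)):
            s = int(ins.core_pos + cum[k])
            zones[rep].add(s, s + len(ins.seq) - 1, margin=gap_bp)
        for ins in pair.insertions[donor][rep]:
            p = int(_map_core(ins.core_pos, anchors, cum))
            zones[rep].add(p, p, margin=gap_bp)
        zones[rep].add(0, _EDGE_MARGIN - 1)
        zones[rep].add(repl.length - _EDGE_MARGIN, repl.length - 1)

    # ---- marker cassette ---------------------------------------------------
    if marker is not None:
        if len(marker) == 3:
            cassette_id, cassette_seq, target_gene = marker
        else:
            cassette_seq, target_gene = marker
            cassette_id = "cassette"
        cassette = encode_seq(cassette_seq)
        rep = gs = None
        for r in pair.replicon_ids:
            for gid, s1, e1, _ in pair.replicon(background, r).genes:
                if gid == target_gene:
                    rep, gs, ge = r, s1 - 1, e1  # 0-based half-open, bg frame
        if rep is None:
            raise ParameterError(f"marker target gene {target_gene!r} not found "
                                 f"in background parent")
        mid = (gs + ge) // 2
        half = cassette_replace // 2
        span = (mid - half, mid + half)                 # replaced, 0-based half-open
        tract = (max(0, mid - marker_flank), mid + marker_flank)  # donor homology
        if zones[rep].clashes(tract[0], tract[1] - 1):
            raise PlacementError("marker homology tract clashes with strain-specific "
                                 "content; pick another target gene")
        pos = panel_bg[rep]
        in_tract = (pos >= tract[0]) & (pos < tract[1])
        in_span = (pos >= span[0]) & (pos < span[1])
        switched_mask[rep] |= in_tract & ~in_span
        implanted.extend((rep, int(p) + 1) for p in pos[in_tract & ~in_span])
        edits[rep].append(_Edit(span[0], span[1], cassette, cassette_id, "marker",
                                to_core(rep, span[0])))
        events.append(TransferEvent("marker_insertion", rep, tract[0] + 1, tract[1],
                                    cassette_id))
        zones[rep].add(tract[0], tract[1] - 1, margin=gap_bp)
        marker_truth = {
            "replicon_id": rep,
            "replaced_start": span[0] + 1, "replaced_end": span[1],
            "cassette_id": cassette_id, "target_gene": target_gene,
            "tract_start": tract[0] + 1, "tract_end": tract[1],
        }

    # ---- homologous fragments ---------------------------------------------
    for rep in pair.replicon_ids:
        L = pair.replicon(background, rep).length
        pos = panel_bg[rep]
        for _ in range(frag_counts.get(rep, 0)):
            placed = False
            for _try in range(800):
                size = max(1, min(int(sampler(rng)), L // 3))
                if size == 1:
                    if len(pos) == 0:
                        break
                    site = int(pos[int(rng.integers(len(pos)))])
                    s, e = site, site + 1
                else:
                    s = int(rng.integers(_EDGE_MARGIN, max(_EDGE_MARGIN + 1, L - size - _EDGE_MARGIN)))
                    e = s + size
                if zones[rep].clashes(s, e - 1):
                    continue
                inside = (pos >= s) & (pos < e)
                if not inside.any():
                    continue
                if enforce_gap:
                    sel = pos[inside]
                    if len(sel) > 1 and int(np.diff(sel).max()) > gap_bp:
                        continue
                switched_mask[rep] |= inside
                implanted.extend((rep, int(p) + 1) for p in pos[inside])
                events.append(TransferEvent("homologous_fragment", rep, s + 1, e))
                zones[rep].add(s, e - 1, margin=gap_bp)
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"could not place fragment on {rep} under gap constraints")

    # ---- donor-specific gene implants -------------------------------------
    for gid in gene_insertions:
        found = None
        for rep in pair.replicon_ids:
            for ins in pair.insertions[donor][rep]:
                if ins.gene_id == gid:
                    found = (rep, ins)
        if found is None:
            raise ParameterError(f"{gid!r} is not a {donor}-specific gene")
        rep, ins = found
        anchors, cum = bg_maps[rep]
        p = int(_map_core(ins.core_pos, anchors, cum))  # homologous locus, bg frame
        edits[rep].append(_Edit(p, p, ins.seq, gid, "specific_gene",
                                ins.core_pos))
        events.append(TransferEvent("specific_gene_insertion", rep, p + 1, p + 1, gid))

    # ---- transpositions ----------------------------------------------------
    if transposition_count:
        is_el = pair.is_element(donor)
        if is_el is None:
            raise ParameterError("parental pair has no donor IS element; generate "
                                 "with include_is_elements=True")
        for _ in range(transposition_count):
            for _try in range(800):
                rep = pair.replicon_ids[int(rng.integers(len(pair.replicon_ids)))]
                L = pair.replicon(background, rep).length
                p = int(rng.integers(_EDGE_MARGIN, L - _EDGE_MARGIN))
                anchors, cum = bg_maps[rep]
                # must be on backbone (not inside a background-specific insertion)
                # and clear of every strain-specific anchor point
                core_p = to_core(rep, p)
                back = int(_map_core(core_p, anchors, cum))
                if back != p:
                    continue
                if any(abs(core_p - ins.core_pos) < 2
                       for par in ("A", "B") for ins in pair.insertions[par][rep]):
                    continue
                if any(abs(p - e.start0) < 200 or (e.start0 <= p < e.end0 + 200)
                       for e in edits[rep]):
                    continue
                edits[rep].append(_Edit(p, p, is_el.seq, is_el.gene_id,
                                        "transposition", core_p))
                events.append(TransferEvent("transposition", rep, p + 1, p + 1,
                                            is_el.gene_id))
                break
            else:
                raise PlacementError("could not place IS transposition")

    # ---- materialize the clone genome -------------------------------------
    replicons: list[SimulatedReplicon] = []
    for rep in pair.replicon_ids:
        bg = pair.replicon(background, rep)
        seq = bg.sequence.copy()
        sel = switched_mask[rep]
        a, b = pair.panel_alleles(rep)
        donor_alleles = b if donor == "B" else a
        seq[panel_bg[rep][sel]] = donor_alleles[sel]
        switched_seq[rep] = seq
        reps_edits = sorted(edits[rep], key=lambda e: e.start0)
        parts, cursor = [], 0
        for e in reps_edits:
            parts.append(seq[cursor:e.start0])
            parts.append(e.seq)
            cursor = e.end0
        parts.append(seq[cursor:])
        final = np.concatenate(parts)
        # remap background gene annotation through the structural edits
        starts = np.array([e.start0 for e in reps_edits], dtype=np.int64)
        ends = np.array([e.end0 for e in reps_edits], dtype=np.int64)
        deltas = np.array([len(e.seq) - (e.end0 - e.start0) for e in reps_edits],
                          dtype=np.int64)
        cum = np.concatenate([[0], np.cumsum(deltas)])

        def shift(p0: int) -> int:
            idx = int(np.searchsorted(ends, p0, side="right"))
            return p0 + int(cum[idx])

        genes = []
        for gid, s1, e1, strand in bg.genes:
            genes.append((gid, shift(s1 - 1) + 1, shift(e1 - 1) + 1, strand))
        replicons.append(SimulatedReplicon(rep, bg.role, final, genes))

    implanted_sorted = sorted(set(implanted),
                              key=lambda t: (pair.replicon_ids.index(t[0]), t[1]))
    truth = TransjugantTruth(background, events, implanted_sorted, seed, marker_truth)
    return Transjugant(clone_id, pair, background, replicons, truth, edits,
                       switched_mask, switched_seq)


# ---------------------------------------------------------------------------
# truth variants

def _char(code: int) -> str:
    return decode_seq(np.array([code], dtype=np.uint8))


def emit_truth_variants(transjugant: Transjugant, reference_parent: str,
                        pair: ParentalPair | None = None) -> list[VariantCall]:
    """Exact differences of the clone vs one parent, as VCF-convention records.

    Bypasses read simulation and external calling. Applying the returned
    records to the reference parent reconstructs the clone byte-identically
    (round-trip property, exercised in the test suite).
    """
    tj = transjugant
    pair = pair or tj.pair
    if reference_parent == tj.background:
        return _variants_vs_background(tj)
    if reference_parent == tj.donor:
        return _variants_vs_donor(tj)
    raise ParameterError("reference_parent must be 'A' or 'B'")


def _variants_vs_background(tj: Transjugant) -> list[VariantCall]:
    pair, out = tj.pair, []
    for rep in pair.replicon_ids:
        bg = pair.replicon(tj.background, rep).sequence
        sw = tj._switched_seq[rep]
        pos = pair.panel_positions(tj.background, rep)
        sel = tj.switched_mask[rep]
        anchor_of_edit = {e.start0 - 1 for e in tj.edits[rep]}
        a, b = pair.panel_alleles(rep)
        donor_alleles = b if tj.donor == "B" else a
        bg_alleles = a if tj.background == "A" else b
        for p, ra, aa in zip(pos[sel], bg_alleles[sel], donor_alleles[sel]):
            if int(p) in anchor_of_edit:
                continue  # folded into the structural record anchored here
            out.append(VariantCall(rep, int(p) + 1, _char(ra), _char(aa)))
        for e in sorted(tj.edits[rep], key=lambda x: x.start0):
            anc = e.start0 - 1
            ref = decode_seq(bg[anc:e.end0])
            alt = _char(int(sw[anc])) + decode_seq(e.seq)
            out.append(VariantCall(rep, anc + 1, ref, alt))
    out.sort(key=lambda v: (pair.replicon_ids.index(v.replicon_id), v.pos))
    return out


def _variants_vs_donor(tj: Transjugant) -> list[VariantCall]:
    pair, out = tj.pair, []
    donor, bg = tj.donor, tj.background
    implanted_gene_ids = {e.payload_id for e in tj.truth.events
                          if e.kind == "specific_gene_insertion"}
    for rep in pair.replicon_ids:
        dseq = pair.replicon(donor, rep).sequence
        d_anchors, d_cum = pair.ins_map(donor, rep)
        pos_core = pair.snp_pos[rep]
        pos_d = _map_core(pos_core, d_anchors, d_cum)
        a, b = pair.panel_alleles(rep)
        donor_alleles = b if donor == "B" else a
        bg_alleles = a if bg == "A" else b
        sel = tj.switched_mask[rep]

        # structural records, donor frame
        edit_recs: list[tuple[int, int, np.ndarray, str]] = []  # (d_start0, d_end0, alt_seq, kind)
        for e in tj.edits[rep]:
            if e.kind == "specific_gene" and e.payload_id in implanted_gene_ids:
                continue  # matches the donor's native copy; cancels exactly
            cs = e.core_anchor
            ce = cs + (e.end0 - e.start0)
            ds = int(_map_core(cs, d_anchors, d_cum))
            de = int(_map_core(ce - 1, d_anchors, d_cum)) + 1 if ce > cs else ds
            edit_recs.append((ds, de, e.seq, e.kind))
        # donor-specific insertions absent from the clone -> deletions
        for k, ins in enumerate(sorted(pair.insertions[donor][rep],
                                       key=lambda i: i.core_pos)):
            if ins.gene_id in implanted_gene_ids:
                continue  # implanted at the homologous locus: matches the donor
            ds = int(ins.core_pos + d_cum[k])
            edit_recs.append((ds, ds + len(ins.seq), np.empty(0, dtype=np.uint8),
                              "deletion"))
        # background-specific insertions present in the clone -> insertions
        for ins in pair.insertions[bg][rep]:
            ds = int(_map_core(ins.core_pos, d_anchors, d_cum))
            edit_recs.append((ds, ds, ins.seq, "insertion"))
        edit_recs.sort(key=lambda t: t[0])

        anchor_d = {ds - 1 for ds, _, _, _ in edit_recs}
        covered = np.zeros(len(dseq), dtype=bool)
        for ds, de, _, _ in edit_recs:
            covered[ds:de] = True

        # clone base at a donor-frame backbone position (for anchor folding)
        def clone_base(core_idx: int, d_idx: int) -> int:
            hits = np.searchsorted(pos_core, core_idx)
            if hits < len(pos_core) and pos_core[hits] == core_idx:
                return int(donor_alleles[hits] if sel[hits] else bg_alleles[hits])
            return int(dseq[d_idx])  # backbone base, identical in all frames

        for ds, de, alt_seq, kind in edit_recs:
            anc = ds - 1
            core_anchor = _inv_map(anc, d_anchors, d_cum)
            ref = decode_seq(dseq[anc:de])
            alt = _char(clone_base(core_anchor, anc)) + decode_seq(alt_seq)
            out.append(VariantCall(rep, anc + 1, ref, alt))

        # SNP records: panel sites where the clone carries the background allele
        for i, (p_d, p_c) in enumerate(zip(pos_d, pos_core)):
            if sel[i] or covered[p_d] or int(p_d) in anchor_d:
                continue
            out.append(VariantCall(rep, int(p_d) + 1, _char(donor_alleles[i]),
                                   _char(bg_alleles[i])))
    out.sort(key=lambda v: (pair.replicon_ids.index(v.replicon_id), v.pos))
    return out


def emit_parental_variants(pair: ParentalPair, reference_parent: str = "A"
                           ) -> list[VariantCall]:
    """Differences of the *other* parent vs the chosen reference parent.

    The SNP subset of these records is exactly the truth diagnostic panel;
    strain-specific genes appear as anchored insertion/deletion records.
    """
    trivial = simulate_transjugant(pair, background=_other(reference_parent),
                                   n_fragments=0, seed=0, clone_id="_parent")
    return emit_truth_variants(trivial, reference_parent)


def _other(parent: str) -> str:
    return "B" if parent == "A" else "A"


# ---------------------------------------------------------------------------
# read simulation and the naive pileup caller

@dataclasses.dataclass
class ReadSet:
    """Single-end reads with recorded origin (replicon, 0-based start)."""

    read_length: int
    mean_coverage: float
    error_rate: float
    replicon_ids: list[str]
    starts: dict[str, np.ndarray]   # per replicon, 0-based
    bases: dict[str, np.ndarray]    # per replicon, (n_reads, read_length) codes

    @property
    def n_reads(self) -> int:
        return sum(len(s) for s in self.starts.values())

    @property
    def total_bases(self) -> int:
        return self.n_reads * self.read_length

    def reads(self):
        """Yield (read_id, sequence, qualities); ids encode the true origin."""
        qual = "I" * self.read_length
        i = 0
        for rep in self.replicon_ids:
            for s, row in zip(self.starts[rep], self.bases[rep]):
                yield (f"r{i:07d}|{rep}|{int(s)}", decode_seq(row), qual)
                i += 1

    def subsample(self, fraction: float, seed: int = 0) -> "ReadSet":
        rng = np.random.default_rng(seed)
        starts, bases = {}, {}
        for rep in self.replicon_ids:
            n = len(self.starts[rep])
            keep = rng.random(n) < fraction
            starts[rep] = self.starts[rep][keep]
            bases[rep] = self.bases[rep][keep]
        return ReadSet(self.read_length, self.mean_coverage * fraction,
                       self.error_rate, self.replicon_ids, starts, bases)


def simulate_reads(genome: Sequence[SimulatedReplicon], read_length: int,
                   mean_coverage: float, error_rate: float = 0.0,
                   seed: int = 0, circular: bool = False) -> ReadSet:
    """Uniform-start single-end reads with i.i.d. substitution errors."""
    if mean_coverage <= 0:
        raise ParameterError("coverage must be > 0")
    rng = np.random.default_rng(seed)
    starts, bases = {}, {}
    for repl in genome:
        L = repl.length
        if read_length > L:
            raise ParameterError(f"read_length {read_length} exceeds replicon "
                                 f"{repl.replicon_id} ({L} bp)")
        n = int(round(mean_coverage * L / read_length))
        if circular:
            st = rng.integers(0, L, size=n)
            idx = (st[:, None] + np.arange(read_length)) % L
        else:
            st = rng.integers(0, L - read_length + 1, size=n)
            idx = st[:, None] + np.arange(read_length)
        mat = repl.sequence[idx]
        if error_rate > 0:
            err = rng.random(mat.shape) < error_rate
            shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
            mat[err] = (mat[err] + shift) % 4
        starts[repl.replicon_id] = st.astype(np.int64)
        bases[repl.replicon_id] = mat
    return ReadSet(read_length, mean_coverage, error_rate,
                   [r.replicon_id for r in genome], starts, bases)


def pileup_call(reads: ReadSet, transjugant: Transjugant,
                min_depth: int = 3) -> list[VariantCall]:
    """Naive majority-vote pileup caller over the simulator's read placements.

    Piles each read at its recorded origin (standing in for an external
    aligner), takes the per-position majority base as consensus, maps the
    background parent's backbone through the clone's structural edits, and
    emits a SNP wherever a sufficiently covered consensus base differs from
    the background parent. Positions below ``min_depth`` are uncallable and
    skipped (implicitly reference).
    """
    pair, out = transjugant.pair, []
    for rep in pair.replicon_ids:
        repl = next(r for r in transjugant.replicons if r.replicon_id == rep)
        L = repl.length
        st = reads.starts[rep]
        mat = reads.bases[rep]
        rl = reads.read_length
        idx = (st[:, None] + np.arange(rl)).ravel()
        flat = mat.ravel()
        counts = np.zeros((4, L), dtype=np.int32)
        for c in range(4):
            counts[c] = np.bincount(idx[flat == c], minlength=L)[:L]
        depth = counts.sum(axis=0)
        consensus = counts.argmax(axis=0).astype(np.uint8)

        bgseq = pair.replicon(transjugant.background, rep).sequence
        bg_positions = np.arange(len(bgseq), dtype=np.int64)
        clone_pos = transjugant.bg_to_clone(rep, bg_positions)
        ok = clone_pos >= 0
        callable_ = ok.copy()
        callable_[ok] &= depth[clone_pos[ok]] >= min_depth
        diff = callable_.copy()
        diff[callable_] &= consensus[clone_pos[callable_]] != bgseq[callable_]
        for p in np.flatnonzero(diff):
            out.append(VariantCall(rep, int(p) + 1, _char(int(bgseq[p])),
                                   _char(int(consensus[clone_pos[p]])),
                                   quality=float(depth[clone_pos[p]])))
    return out


def simulate_cohort(pair: ParentalPair, n_clones: int, seed: int = 0,
                    marker_replicon: str | None = None,
                    alternate_background: bool = True,
                    max_attempts: int = 6) -> list[Transjugant]:
    """A cohort of transjugants under the study's mosaicity conditions.

    Per clone: 1-11 homologous fragments on the chromosome and 0-6 on the
    megaplasmid (the observed per-replicon region ranges), fragment sizes
    log-uniform from a single SNP to ~30 kbp, inter-event gaps > 1 kbp, and
    the selection cassette integrated in a mid-replicon gene. Backgrounds
    alternate between the parents when ``alternate_background``. Placement
    of an infeasible draw (e.g. a large fragment exhausting the megaplasmid)
    is retried with a derived seed, deterministically.
    """
    rng = np.random.default_rng(seed)
    marker_replicon = marker_replicon or pair.replicon_ids[-1]
    cassette_id, cassette_seq = default_cassette(seed=seed % (2**31 - 7) + 7)
    clones = []
    for i in range(n_clones):
        background = "A" if (not alternate_background or i % 2 == 0) else "B"
        target = pick_marker_target(pair, marker_replicon, background=background)
        frag_map = {}
        for rep in pair.replicon_ids:
            role = pair.roles[rep]
            frag_map[rep] = int(rng.integers(1, 12)) if role == "chromosome" \
                else int(rng.integers(0, 7))
        clone_seed = int(rng.integers(2**31 - 1))
        for attempt in range(max_attempts):
            try:
                tj = simulate_transjugant(
                    pair, background, frag_map,
                    fragment_size_sampler=(1, 30_000),
                    marker=(cassette_id, cassette_seq, target),
                    seed=clone_seed + attempt, clone_id=f"T{i + 1}")
                break
            except PlacementError:
                if attempt == max_attempts - 1:
                    raise
        clones.append(tj)
    return clones


def tile_contigs(genome: Sequence[SimulatedReplicon], contig_len: int = 9000,
                 step: int = 4500) -> dict[str, str]:
    """Overlapping error-free tiles standing in for an assembly's contigs.

    The overlap (contig_len - step) comfortably exceeds the longest specific
    gene plus both flank-assessment windows, so every implanted gene sits
    fully inside at least one contig.
    """
    out: dict[str, str] = {}
    for repl in genome:
        s = repl.sequence_str
        i = n = 0
        while i < len(s):
            out[f"{repl.replicon_id}_c{n:03d}"] = s[i:i + contig_len]
            i += step
            n += 1
    return out


# ---------------------------------------------------------------------------
# on-disk outputs

def write_genome(genome: Sequence[SimulatedReplicon], fasta_path: str | Path,
                 gff_path: str | Path | None = None) -> None:
    write_fasta({r.replicon_id: r.sequence_str for r in genome}, fasta_path)
    if gff_path is not None:
        write_gff3({r.replicon_id: r.genes for r in genome},
                   {r.replicon_id: r.length for r in genome}, gff_path)


def write_truth(transjugant: Transjugant, outdir: str | Path) -> dict[str, str]:
    """Write truth VCF (vs background), BED of events, and a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tj = transjugant
    contigs = {r.replicon_id: len(tj.pair.core[r.replicon_id])
               for r in tj.pair.parent(tj.background)}
    paths = {
        "vcf": str(outdir / f"{tj.clone_id}.truth.vcf"),
        "bed": str(outdir / f"{tj.clone_id}.truth.bed"),
        "json": str(outdir / f"{tj.clone_id}.truth.json"),
    }
    write_vcf(emit_truth_variants(tj, tj.background), paths["vcf"],
              {r.replicon_id: r.length for r in tj.pair.parent(tj.background)})
    write_bed([(e.replicon_id, e.start, e.end, f"{tj.clone_id}:{e.kind}", 0)
               for e in tj.truth.events], paths["bed"])
    with open(paths["json"], "w") as fh:
        json.dump(tj.truth.to_json(), fh, indent=2, sort_keys=True)
    return paths
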