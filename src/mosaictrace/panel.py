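"""Diagnostic SNP panel construction between two parental strains.

A diagnostic site is a genomic position where the two parents carry
different single-base alleles; the sorted collection of such sites is the
coordinate system for all downstream parenthood calls. Panels can be built
from two parental VCFs against a common reference, or directly from an
anchor-based whole-genome comparison of two syntenic genomes.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import FormatError, VariantCall, encode_seq, read_tsv, write_bed, write_tsv


class CoordinateError(ValueError):
    pass


class SyntenyError(ValueError):
    """No collinear homologous replicon pair could be aligned."""


@dataclasses.dataclass(frozen=True)
class DiagnosticSite:
    replicon_id: str
    pos: int                 # 1-based on the reference parent
    allele_ref: str          # reference parent's base
    allele_alt: str          # other parent's base
    both_nonref: bool = False  # both parents differ from a third public reference

    def __post_init__(self) -> None:
        if len(self.allele_ref) != 1 or len(self.allele_alt) != 1:
            raise FormatError("diagnostic sites are single-base only")
        if self.allele_ref == self.allele_alt:
            raise FormatError("diagnostic site alleles must differ")


@dataclasses.dataclass
class DiagnosticPanel:
    reference_parent: str
    other_parent: str
    sites: list[DiagnosticSite]

    def __post_init__(self) -> None:
        keys = [(s.replicon_id, s.pos) for s in self.sites]
        if keys != sorted(keys):
            self.sites = sorted(self.sites, key=lambda s: (s.replicon_id, s.pos))
            keys = sorted(keys)
        if len(set(keys)) != len(keys):
            raise FormatError("duplicate panel positions")

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def per_replicon_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.sites:
            counts[s.replicon_id] = counts.get(s.replicon_id, 0) + 1
        return counts

    def by_position(self) -> dict[tuple[str, int], DiagnosticSite]:
        return {(s.replicon_id, s.pos): s for s in self.sites}

    def positions(self, replicon_id: str) -> np.ndarray:
        return np.array([s.pos for s in self.sites if s.replicon_id == replicon_id],
                        dtype=np.int64)

    # -- I/O -----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.replicon_id, s.pos, s.allele_ref, s.allele_alt) for s in self.sites],
            columns=["replicon", "pos", "allele_ref", "allele_alt"])

    def write_tsv(self, path: str | Path) -> None:
        write_tsv(self.to_frame(), path)

    def write_bed(self, path: str | Path) -> None:
        write_bed([(s.replicon_id, s.pos, s.pos,
                    f"{s.allele_ref}>{s.allele_alt}", 0) for s in self.sites], path)

    @classmethod
    def from_tsv(cls, path: str | Path, reference_parent: str = "A",
                 other_parent: str = "B") -> "DiagnosticPanel":
        df = read_tsv(path)
        sites = [DiagnosticSite(str(r.replicon), int(r.pos), str(r.allele_ref),
                                str(r.allele_alt)) for r in df.itertuples()]
        return cls(reference_parent, other_parent, sites)


# ---------------------------------------------------------------------------
# operations

def mask_parental_artifacts(parent_variants: Sequence[VariantCall],
                            own_reference_variants: Sequence[VariantCall]
                            ) -> list[VariantCall]:
    """Drop variants a parent carries against its own public reference.

    Laboratory parental stocks differ from their deposited reference genomes
    (domestication or legacy sequencing error); those records would otherwise
    contaminate every progeny comparison, so downstream analysis is re-based
    on the laboratory parental sequences. Idempotent set difference on
    (replicon, pos, alt).
    """
    mask = {v.key for v in own_reference_variants}
    return [v for v in parent_variants if v.key not in mask]


def build_panel_from_vcfs(variants_parent_a: Sequence[VariantCall],
                          variants_parent_b: Sequence[VariantCall],
                          reference_parent: str = "A") -> DiagnosticPanel:
    """Cross-compare two parental variant sets into a diagnostic panel.

    Both inputs are biallelic, decomposed records against the same reference
    genome. A position enters the panel when exactly one parent differs from
    the reference (the reference's base is the other parent's allele), or
    when both differ with *different* alleles (the parents still distinguish
    each other; flagged ``both_nonref``). Indels and shared substitutions are
    excluded.
    """
    def index(variants: Sequence[VariantCall]) -> dict[tuple[str, int], VariantCall]:
        out: dict[tuple[str, int], VariantCall] = {}
        for v in variants:
            k = (v.replicon_id, v.pos)
            if k in out:
                raise FormatError(f"duplicate record at {k[0]}:{k[1]}")
            out[k] = v
        return out

    ia, ib = index(variants_parent_a), index(variants_parent_b)
    sites = []
    for key in sorted(set(ia) | set(ib)):
        va, vb = ia.get(key), ib.get(key)
        if (va is not None and not va.is_snp) or (vb is not None and not vb.is_snp):
            continue
        allele_a = va.alt_allele if va else (vb.ref_allele if vb else None)
        allele_b = vb.alt_allele if vb else (va.ref_allele if va else None)
        if allele_a is None or allele_b is None or allele_a == allele_b:
            continue
        ref_allele, alt_allele = ((allele_a, allele_b) if reference_parent == "A"
                                  else (allele_b, allele_a))
        sites.append(DiagnosticSite(key[0], key[1], ref_allele, alt_allele,
                                    both_nonref=va is not None and vb is not None))
    other = "B" if reference_parent == "A" else "A"
    return DiagnosticPanel(reference_parent, other, sites)


# -- alignment-based panel ---------------------------------------------------

def _unique_kmers(codes: np.ndarray, k: int) -> dict[bytes, int]:
    seq = codes.tobytes()
    index: dict[bytes, int] = {}
    dup: set[bytes] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i:i + k]
        if km in dup:
            continue
        if km in index:
            del index[km]
            dup.add(km)
        else:
            index[km] = i
    return index


def _anchor_chain(a: np.ndarray, b: np.ndarray, k: int) -> list[tuple[int, int]]:
    """Collinear chain of unique shared k-mers (longest increasing subsequence)."""
    ia, ib = _unique_kmers(a, k), _unique_kmers(b, k)
    matches = sorted((pa, ib[km]) for km, pa in ia.items() if km in ib)
    if not matches:
        return []
    # LIS on the b-coordinates (patience sorting)
    import bisect
    tails: list[int] = []
    tails_idx: list[int] = []
    prev = [-1] * len(matches)
    for i, (_, pb) in enumerate(matches):
        j = bisect.bisect_left(tails, pb)
        if j == len(tails):
            tails.append(pb)
            tails_idx.append(i)
        else:
            tails[j] = pb
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j > 0 else -1
    chain = []
    i = tails_idx[-1]
    while i >= 0:
        chain.append(matches[i])
        i = prev[i]
    return chain[::-1]


def _segment_substitutions(seg_a: np.ndarray, seg_b: np.ndarray,
                           offset_a: int) -> list[tuple[int, int, int]]:
    """Substitution columns (pos_a_0based, code_a, code_b) of two aligned segments.

    Equal-length segments are compared column-wise; unequal lengths are
    aligned with edlib and only match/mismatch columns contribute (gap
    columns are strain-specific content and yield no sites).
    """
    if len(seg_a) == len(seg_b):
        diff = np.flatnonzero(seg_a != seg_b)
        return [(offset_a + int(i), int(seg_a[i]), int(seg_b[i])) for i in diff]
    if len(seg_a) == 0 or len(seg_b) == 0:
        return []
    single = _single_gap_columns(seg_a, seg_b)
    if single is not None:
        return [(offset_a + i, ca, cb) for i, ca, cb in single]
    import edlib
    from .io import decode_seq
    res = edlib.align(decode_seq(seg_a), decode_seq(seg_b), task="path", mode="NW")
    out = []
    pa = pb = 0
    for n, op in _cigar_ops(res["cigar"]):
        if op == "=":
            pa += n; pb += n
        elif op == "X":
            for j in range(n):
                out.append((offset_a + pa + j, int(seg_a[pa + j]), int(seg_b[pb + j])))
            pa += n; pb += n
        elif op == "D":   # consumes target (seg_b): insertion in b
            pb += n
        elif op == "I":   # consumes query (seg_a): insertion in a
            pa += n
    return out


def _single_gap_columns(seg_a: np.ndarray, seg_b: np.ndarray
                        ) -> list[tuple[int, int, int]] | None:
    """Substitution columns under the best single-gap alignment, or None.

    Models the common syntenic case of one clean insertion inside the
    segment: the gap point j minimizing the total mismatch count is found in
    O(n) from mismatch prefix sums, which places the gap exactly instead of
    letting an edit-distance aligner absorb adjacent substitutions into it.
    Rejected (None) when the best alignment still looks diverged (>20%
    mismatches), signalling more than one indel.
    """
    swap = len(seg_a) > len(seg_b)
    short, long_ = (seg_b, seg_a) if swap else (seg_a, seg_b)
    d = len(long_) - len(short)
    n = len(short)
    m1 = (short != long_[:n]).astype(np.int64)          # gap after column j
    m2 = (short != long_[d:]).astype(np.int64)          # gap before column j
    pre = np.concatenate([[0], np.cumsum(m1)])
    suf = np.concatenate([np.cumsum(m2[::-1])[::-1], [0]])
    cost = pre + suf
    j = int(np.argmin(cost))
    if cost[j] > max(3.0, 0.2 * n):
        return None
    cols = []
    for i in range(j):
        if m1[i]:
            cols.append((i, int(short[i]), int(long_[i])))
    for i in range(j, n):
        if m2[i]:
            cols.append((i, int(short[i]), int(long_[i + d])))
    if swap:
        # seg_a was the long one: column index in a differs by the gap offset
        out = []
        for i, cs, cl in cols:
            ai = i if i < j else i + d
            out.append((ai, cl, cs))
        return out
    return [(i, cs, cl) for i, cs, cl in cols]


def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def build_panel_from_alignment(genome_a: Mapping[str, str],
                               genome_b: Mapping[str, str],
                               reference_parent: str = "A",
                               k: int = 21) -> DiagnosticPanel:
    """Panel from direct comparison of two syntenic genomes.

    Homologous replicons are paired by name when shared, else by rank.
    Each pair is anchored on unique shared k-mers, chained collinearly, and
    the inter-anchor segments are compared (column diff, or edlib alignment
    when an indel intervenes). Site coordinates are reported in genome A.
    Rearranged or unanchored segments contribute no sites.
    """
    names_a, names_b = list(genome_a), list(genome_b)
    pairs = ([(n, n) for n in names_a if n in genome_b]
             or list(zip(names_a, names_b)))
    if not pairs:
        raise SyntenyError("no homologous replicon pairs to align")
    sites: list[DiagnosticSite] = []
    alphabet = "ACGT"
    for na, nb in pairs:
        a, b = encode_seq(genome_a[na]), encode_seq(genome_b[nb])
        if np.array_equal(a, b):
            continue
        chain = _anchor_chain(a, b, k)
        if not chain:
            raise SyntenyError(f"replicons {na}/{nb} share no unique {k}-mers")
        cols: list[tuple[int, int, int]] = []
        pa_prev = pb_prev = 0
        for pa, pb in chain + [(len(a), len(b))]:
            cols.extend(_segment_substitutions(a[pa_prev:pa], b[pb_prev:pb], pa_prev))
            pa_prev, pb_prev = pa + (k if (pa, pb) != (len(a), len(b)) else 0), \
                pb + (k if (pa, pb) != (len(a), len(b)) else 0)
        for p0, ca, cb in sorted(set(cols)):
            ra, rb = alphabet[ca], alphabet[cb]
            ref, alt = (ra, rb) if reference_parent == "A" else (rb, ra)
            sites.append(DiagnosticSite(na, p0 + 1, ref, alt))
    other = "B" if reference_parent == "A" else "A"
    return DiagnosticPanel(reference_parent, other, sites)


def panel_from_pair(pair, reference_parent: str = "A") -> DiagnosticPanel:
    """Truth panel of a simulated parental pair, in either parent's frame."""
    sites = []
    for rep in pair.replicon_ids:
        pos = pair.panel_positions(reference_parent, rep)
        a, b = pair.panel_alleles(rep)
        alphabet = "ACGT"
        for p, ca, cb in zip(pos, a, b):
            ref, alt = ((alphabet[ca], alphabet[cb]) if reference_parent == "A"
                        else (alphabet[cb], alphabet[ca]))
            sites.append(DiagnosticSite(rep, int(p) + 1, ref, alt))
    other = "B" if reference_parent == "A" else "A"
    return DiagnosticPanel(reference_parent, other, sites)


def panel_density(panel: DiagnosticPanel, aligned_length: int
                  ) -> tuple[float, float]:
    """(SNPs per kbp, mean inter-SNP spacing in bp) over ``aligned_length``."""
    if aligned_length <= 0:
        raise CoordinateError("aligned_length must be > 0")
    n = len(panel)
    snps_per_kbp = 1000.0 * n / aligned_length
    spacing = aligned_length / n if n else math.inf
    return snps_per_kbp, spacing
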