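"""Read recruitment against parental references and background-parent calls.

The recruitment percentage — the fraction of a clone's reads that align to a
reference genome — separates the clone's background parent (≈98% in the
study) from the other parent (≈80–88%), because reads drawn from
strain-specific content find no placement on the other strain's reference.
A read counts as recruited when a full-length placement exists with at most
``max_mismatch_frac`` mismatches (default 0.05: room for the ~0.8%
inter-strain backbone divergence plus sequencing error, while still
rejecting reads from non-homologous content). The built-in matcher is
k-mer-anchored and substitution-only, sufficient for synthetic reads; real
data enters through per-read alignment flags produced by an external
aligner.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import encode_seq
from .simulate import ParameterError, ReadSet

MAX_MISMATCH_FRAC = 0.05
MIN_MARGIN = 5.0  # percentage points


class IdentityError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class RecruitmentStat:
    clone_id: str
    reference_id: str
    n_reads: int
    n_aligned: int

    @property
    def pct_aligned(self) -> float:
        return 100.0 * self.n_aligned / self.n_reads if self.n_reads else 0.0


@dataclasses.dataclass(frozen=True)
class ParentAssignment:
    clone_id: str
    background_parent: str
    margin: float           # percentage points between the two recruitments
    inconclusive: bool = False


class ReferenceIndex:
    """k-mer anchor index of a reference genome for full-length read placement."""

    def __init__(self, reference: Mapping[str, str], k: int = 15):
        if not reference or all(len(s) == 0 for s in reference.values()):
            raise ParameterError("empty reference")
        self.k = k
        self.codes = {rep: encode_seq(seq) for rep, seq in reference.items()}
        self.index: dict[bytes, list[tuple[str, int]]] = defaultdict(list)
        for rep, codes in self.codes.items():
            raw = codes.tobytes()
            for i in range(len(raw) - k + 1):
                hits = self.index[raw[i:i + k]]
                if len(hits) < 16:
                    hits.append((rep, i))

    def min_mismatches(self, read_codes: np.ndarray, max_allowed: int) -> int | None:
        """Best full-length placement mismatch count, or None if no candidate."""
        k, rl = self.k, len(read_codes)
        raw = read_codes.tobytes()
        offsets = (0, rl // 2, rl - k) if rl >= 2 * k else (0,)
        candidates: set[tuple[str, int]] = set()
        for off in offsets:
            for rep, t in self.index.get(raw[off:off + k], ()):
                candidates.add((rep, t - off))
        best: int | None = None
        for rep, start in candidates:
            ref = self.codes[rep]
            if start < 0 or start + rl > len(ref):
                continue
            mm = int(np.count_nonzero(ref[start:start + rl] != read_codes))
            if best is None or mm < best:
                best = mm
                if best == 0:
                    break
        return best


def recruit_reads(reads: ReadSet | Sequence[tuple[str, str, str]],
                  reference: Mapping[str, str] | ReferenceIndex,
                  max_mismatch_frac: float = MAX_MISMATCH_FRAC,
                  clone_id: str = "clone",
                  reference_id: str = "reference") -> RecruitmentStat:
    """Fraction of reads with a full-length placement within the mismatch budget.

    Reads are counted, not bases; a read with no anchored candidate placement
    or only placements above the budget is unaligned. Unplaced read ends are
    failures (no soft clipping).
    """
    index = reference if isinstance(reference, ReferenceIndex) else ReferenceIndex(reference)
    n_reads = n_aligned = 0
    if isinstance(reads, ReadSet):
        budget = int(max_mismatch_frac * reads.read_length)
        for rep in reads.replicon_ids:
            for row in reads.bases[rep]:
                n_reads += 1
                mm = index.min_mismatches(row, budget)
                if mm is not None and mm <= budget:
                    n_aligned += 1
    else:
        for _, seq, *_ in reads:
            n_reads += 1
            codes = encode_seq(seq)
            budget = int(max_mismatch_frac * len(codes))
            mm = index.min_mismatches(codes, budget)
            if mm is not None and mm <= budget:
                n_aligned += 1
    if n_reads == 0:
        raise ParameterError("no reads to recruit")
    return RecruitmentStat(clone_id, reference_id, n_reads, n_aligned)


def recruitment_from_flags(flags: pd.DataFrame, clone_id: str,
                           reference_id: str) -> RecruitmentStat:
    """Adapter for externally produced per-read aligned/unaligned flags.

    Expects a DataFrame with a boolean-like ``aligned`` column (one row per
    read), e.g. parsed from an external aligner's per-read summary.
    """
    aligned = flags["aligned"].astype(bool)
    return RecruitmentStat(clone_id, reference_id, len(aligned), int(aligned.sum()))


def assign_background(stats_vs_a: RecruitmentStat, stats_vs_b: RecruitmentStat,
                      min_margin: float = MIN_MARGIN) -> ParentAssignment:
    """Call the background parent as the better-recruiting reference.

    The margin is the difference in recruitment percentages; below
    ``min_margin`` (default 5 points; study margins are >= 10) the call is
    flagged inconclusive. Exact ties keep the first reference's label with
    the inconclusive flag set.
    """
    if stats_vs_a.clone_id != stats_vs_b.clone_id:
        raise IdentityError(
            f"clone mismatch: {stats_vs_a.clone_id!r} vs {stats_vs_b.clone_id!r}")
    pa, pb = stats_vs_a.pct_aligned, stats_vs_b.pct_aligned
    winner = stats_vs_a if pa >= pb else stats_vs_b
    margin = abs(pa - pb)
    return ParentAssignment(stats_vs_a.clone_id, winner.reference_id, margin,
                            inconclusive=margin < min_margin)


def recruitment_frame(stats: Sequence[RecruitmentStat]) -> pd.DataFrame:
    """Recruitment table, one row per clone, one column per reference."""
    refs = sorted({s.reference_id for s in stats})
    rows: dict[str, dict[str, float]] = {}
    for s in stats:
        rows.setdefault(s.clone_id, {})[s.reference_id] = round(s.pct_aligned, 2)
    return pd.DataFrame(
        [{"clone": cid, **{f"pct_vs_{r}": vals.get(r) for r in refs}}
         for cid, vals in rows.items()])
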