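"""Parental-origin classification and transferred-region segmentation.

Each progeny variant is labelled against the diagnostic panel relative to
the clone's background parent:

* ``FOREIGN``  — a panel site carrying the other parent's allele (evidence of
  transferred, recombined DNA);
* ``SELF``     — a panel site carrying the background allele. Normally
  implicit (no variant record is expected when the clone matches its own
  background) and therefore not materialized;
* ``AMBIGUOUS`` — a panel site carrying a third allele, supporting neither
  parent; reported but excluded from segmentation;
* ``NOVEL``    — any off-panel variant (de novo mutation, sequencing error,
  or structural edit such as a cassette insertion).

FOREIGN sites are then clustered into transferred regions by single linkage:
consecutive sites separated by more than ``gap_threshold`` (default 1 kbp)
start a new region. Region bounds are the boundary SNPs themselves — inner
bounds, since true recombination tract ends between panel sites are
unobservable.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import FormatError, VariantCall
from .panel import DiagnosticPanel

GAP_THRESHOLD_DEFAULT = 1000

FOREIGN = "FOREIGN"
SELF = "SELF"
NOVEL = "NOVEL"
AMBIGUOUS = "AMBIGUOUS"


class ValidationError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class ClassifiedVariant:
    variant: VariantCall
    label: str
    panel_site: object = None  # DiagnosticSite when the variant hits the panel

    def __post_init__(self) -> None:
        if self.label in (FOREIGN, SELF) and self.panel_site is None:
            raise ValidationError(f"{self.label} labels require a panel site")


@dataclasses.dataclass(frozen=True)
class TransferredRegion:
    replicon_id: str
    first_snp: int
    last_snp: int
    n_snps: int               # real FOREIGN sites; 0 only for marker-only regions
    contains_marker: bool = False

    def __post_init__(self) -> None:
        if self.first_snp > self.last_snp:
            raise ValidationError("region bounds inverted")
        if self.n_snps < 1 and not self.contains_marker:
            raise ValidationError("empty region without a marker")

    @property
    def size(self) -> int:
        return self.last_snp - self.first_snp + 1

    @property
    def single_snp(self) -> bool:
        return self.n_snps == 1 and self.size == 1


@dataclasses.dataclass
class OriginSummary:
    clone_id: str
    background_parent: str
    per_replicon: dict[str, dict]
    # per replicon: foreign_snps, regions (list[TransferredRegion]),
    #               novel_snps, ambiguous_snps

    def total(self, field: str) -> int:
        return sum(d[field] if isinstance(d[field], int) else len(d[field])
                   for d in self.per_replicon.values())

    def regions(self, replicon_id: str) -> list[TransferredRegion]:
        return self.per_replicon.get(replicon_id, {}).get("regions", [])


# ---------------------------------------------------------------------------

def classify_variants(progeny_variants: Sequence[VariantCall],
                      panel: DiagnosticPanel,
                      background_parent: str) -> list[ClassifiedVariant]:
    """Label every progeny variant FOREIGN / NOVEL / AMBIGUOUS (SELF implicit).

    Progeny variants must be called against the background parent's genome
    (or a common reference consistent with the panel coordinates). Absence of
    a record at a panel site is implicit SELF and is not materialized; a
    record whose ALT equals the background allele is materialized as SELF.
    """
    seen: set[tuple[str, int]] = set()
    for v in progeny_variants:
        k = (v.replicon_id, v.pos)
        if k in seen:
            raise ValidationError(f"duplicate variant position {k[0]}:{k[1]}")
        seen.add(k)

    sites = panel.by_position()
    if background_parent == panel.reference_parent:
        bg_of = lambda s: s.allele_ref
        other_of = lambda s: s.allele_alt
    else:
        bg_of = lambda s: s.allele_alt
        other_of = lambda s: s.allele_ref

    out = []
    for v in progeny_variants:
        site = sites.get((v.replicon_id, v.pos))
        if site is None or not v.is_snp:
            out.append(ClassifiedVariant(v, NOVEL))
        elif v.alt_allele == other_of(site):
            out.append(ClassifiedVariant(v, FOREIGN, site))
        elif v.alt_allele == bg_of(site):
            out.append(ClassifiedVariant(v, SELF, site))
        else:
            out.append(ClassifiedVariant(v, AMBIGUOUS, site))
    return out


def segment_regions(foreign_positions: Sequence[int],
                    gap_threshold: int = GAP_THRESHOLD_DEFAULT,
                    replicon_id: str = "") -> list[TransferredRegion]:
    """Single-linkage clustering of FOREIGN positions on one replicon.

    Consecutive positions with gap <= ``gap_threshold`` share a region
    (a new region starts when the gap strictly exceeds the threshold).
    Singletons yield
    single-SNP regions of size 1.
    """
    pos = np.asarray(foreign_positions, dtype=np.int64)
    if len(pos) == 0:
        return []
    if np.any(np.diff(pos) <= 0):
        raise ValidationError("positions must be sorted ascending and unique")
    breaks = np.flatnonzero(np.diff(pos) > gap_threshold) + 1
    out = []
    for chunk in np.split(pos, breaks):
        out.append(TransferredRegion(replicon_id, int(chunk[0]), int(chunk[-1]),
                                     len(chunk)))
    return out


def summarize_clone(classified: Sequence[ClassifiedVariant],
                    marker_locus: tuple[str, int, int] | None = None,
                    gap_threshold: int = GAP_THRESHOLD_DEFAULT,
                    clone_id: str = "clone",
                    background_parent: str = "A") -> OriginSummary:
    """Per-replicon FOREIGN counts and transferred regions (one summary row per clone).

    ``marker_locus`` is ``(replicon, start, end)`` of the selection cassette.
    The marker participates in segmentation as a virtual foreign site at its
    midpoint, so a marker with no flanking FOREIGN SNPs still counts as one
    region (with ``n_snps = 0``), and a marker inside an existing cluster
    simply flags that region.
    """
    by_rep: dict[str, dict[str, list]] = {}
    for cv in classified:
        d = by_rep.setdefault(cv.variant.replicon_id,
                              {FOREIGN: [], NOVEL: [], AMBIGUOUS: [], SELF: []})
        d[cv.label].append(cv.variant.pos)
    if marker_locus is not None:
        by_rep.setdefault(marker_locus[0],
                          {FOREIGN: [], NOVEL: [], AMBIGUOUS: [], SELF: []})

    per_replicon = {}
    for rep, d in by_rep.items():
        positions = sorted(d[FOREIGN])
        virtual = None
        if marker_locus is not None and marker_locus[0] == rep:
            virtual = (marker_locus[1] + marker_locus[2]) // 2
        regions = _segment_with_marker(positions, virtual, gap_threshold, rep)
        per_replicon[rep] = {
            "foreign_snps": len(positions),
            "regions": regions,
            "novel_snps": len(d[NOVEL]),
            "ambiguous_snps": len(d[AMBIGUOUS]),
        }
    return OriginSummary(clone_id, background_parent, per_replicon)


def _segment_with_marker(positions: list[int], virtual: int | None,
                         gap_threshold: int, rep: str) -> list[TransferredRegion]:
    if virtual is None:
        return segment_regions(positions, gap_threshold, rep)
    merged = sorted(set(positions) | {virtual})
    raw = segment_regions(merged, gap_threshold, rep)
    out = []
    for r in raw:
        has_marker = r.first_snp <= virtual <= r.last_snp
        real = [p for p in positions if r.first_snp <= p <= r.last_snp]
        if real:
            out.append(TransferredRegion(rep, min(real), max(real), len(real),
                                         contains_marker=has_marker))
        else:
            out.append(TransferredRegion(rep, virtual, virtual, 0,
                                         contains_marker=True))
    return out


# ---------------------------------------------------------------------------
# recovery scoring against simulator truth

@dataclasses.dataclass
class RecoveryReport:
    clone_id: str
    region_precision: float
    region_recall: float
    n_called_regions: int
    n_truth_fragments: int
    boundary_errors: list[int]          # bp, one per recovered called bound
    confusion: dict[str, int]           # predicted label -> count
    label_accuracy: float               # classified records matching truth labels
    merged_fragment_pairs: int          # truth fragments co-called in one region
    foreign_count_match: bool

    @property
    def max_boundary_error(self) -> int:
        return max(self.boundary_errors) if self.boundary_errors else 0


def evaluate_against_truth(summary: OriginSummary, truth,
                           classified: Sequence[ClassifiedVariant] = (),
                           boundary_tolerance: int = 0) -> RecoveryReport:
    """Score called regions and labels against simulator ground truth.

    A truth fragment (homologous fragment or marker homology tract) counts as
    recovered when some called region lies within the fragment extended by
    ``boundary_tolerance``; a called region is a true positive when it lies
    within such an extended fragment. Boundary error is the distance from a
    called bound to the nearest truth panel site inside the fragment.
    """
    truth_iv: dict[str, list[tuple[int, int]]] = {}
    for e in truth.events:
        if e.kind in ("homologous_fragment", "marker_insertion"):
            truth_iv.setdefault(e.replicon_id, []).append((e.start, e.end))
    implanted: dict[str, list[int]] = {}
    for rep, p in truth.implanted_panel_sites:
        implanted.setdefault(rep, []).append(p)
    if truth.marker:
        implanted.setdefault(truth.marker["replicon_id"], []).append(
            (truth.marker["replaced_start"] + truth.marker["replaced_end"]) // 2)

    n_truth = sum(len(v) for v in truth_iv.values())
    n_called = tp = recovered = merged = 0
    boundary_errors: list[int] = []
    for rep, ivs in truth_iv.items():
        regions = summary.regions(rep)
        n_called += len(regions)
        hits = {i: 0 for i in range(len(ivs))}
        for r in regions:
            inside = [i for i, (s, e) in enumerate(ivs)
                      if s - boundary_tolerance <= r.first_snp
                      and r.last_snp <= e + boundary_tolerance]
            overlapping = [i for i, (s, e) in enumerate(ivs)
                           if r.first_snp <= e and s <= r.last_snp]
            if inside:
                tp += 1
                i = inside[0]
                hits[i] += 1
                sites = [p for p in implanted.get(rep, [])
                         if ivs[i][0] <= p <= ivs[i][1]]
                if sites:
                    boundary_errors.append(min(abs(r.first_snp - p) for p in sites))
                    boundary_errors.append(min(abs(r.last_snp - p) for p in sites))
            elif len(overlapping) > 1:
                merged += len(overlapping) - 1
        recovered += sum(1 for v in hits.values() if v > 0)
    for rep in set(r for r in summary.per_replicon) - set(truth_iv):
        n_called += len(summary.regions(rep))

    confusion = {FOREIGN: 0, SELF: 0, NOVEL: 0, AMBIGUOUS: 0}
    implanted_set = set(truth.implanted_panel_sites)
    correct = 0
    for cv in classified:
        confusion[cv.label] += 1
        key = (cv.variant.replicon_id, cv.variant.pos)
        expected = FOREIGN if key in implanted_set else (
            SELF if cv.panel_site is not None else NOVEL)
        correct += cv.label == expected
    label_accuracy = correct / len(classified) if classified else 1.0

    foreign_called = sum(d["foreign_snps"] for d in summary.per_replicon.values())
    report = RecoveryReport(
        clone_id=summary.clone_id,
        region_precision=tp / n_called if n_called else 1.0,
        region_recall=recovered / n_truth if n_truth else 1.0,
        n_called_regions=n_called,
        n_truth_fragments=n_truth,
        boundary_errors=boundary_errors,
        confusion=confusion,
        label_accuracy=label_accuracy,
        merged_fragment_pairs=merged,
        foreign_count_match=foreign_called == len(truth.implanted_panel_sites),
    )
    return report


# ---------------------------------------------------------------------------
# tabular export

def classification_frame(classified: Sequence[ClassifiedVariant]) -> pd.DataFrame:
    rows = [(cv.variant.replicon_id, cv.variant.pos, cv.variant.ref_allele,
             cv.variant.alt_allele, cv.label) for cv in classified]
    return pd.DataFrame(rows, columns=["replicon", "pos", "ref", "alt", "label"])


def regions_bed_rows(summary: OriginSummary) -> list[tuple[str, int, int, str, int]]:
    rows = []
    for rep in summary.per_replicon:
        for i, r in enumerate(summary.regions(rep), start=1):
            rows.append((rep, r.first_snp, r.last_snp,
                         f"{summary.clone_id}:{i}", r.n_snps))
    return rows
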