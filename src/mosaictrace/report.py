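"""Publication-shaped outputs: mosaic track sets, circular figures, tables,
and the end-to-end pipeline runner.

The circular figure mirrors the classic chromosome-painting layout: outer
rings show forward/reverse ORFs of the reference parent, the first internal
ring the diagnostic SNP panel, then one concentric ring per clone with
FOREIGN sites as radial ticks, transferred regions as arcs and the marker
as a labelled glyph. SVG is the canonical format (deterministic, element
counts assertable); PNG rendering goes through matplotlib.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .io import write_tsv, write_bed
from .mosaic import OriginSummary, TransferredRegion


class ValidationError(ValueError):
    pass


@dataclasses.dataclass
class CloneTrack:
    clone_id: str
    foreign_sites: dict[str, list[int]]               # replicon -> positions
    regions: dict[str, list[TransferredRegion]]
    marker: tuple[str, int] | None = None             # (replicon, position)


@dataclasses.dataclass
class MosaicTrackSet:
    reference_layout: list[tuple[str, int]]           # (replicon, length)
    gene_tracks: dict[str, tuple[list, list]]         # replicon -> (fwd, rev) intervals
    panel_track: dict[str, list[int]]
    clone_tracks: list[CloneTrack]                    # outer -> inner

    def __post_init__(self) -> None:
        lengths = dict(self.reference_layout)
        for rep, positions in self.panel_track.items():
            if positions and max(positions) > lengths.get(rep, 0):
                raise ValidationError(f"panel position beyond {rep} length")
        for ct in self.clone_tracks:
            for rep, positions in ct.foreign_sites.items():
                if positions and max(positions) > lengths.get(rep, 0):
                    raise ValidationError(
                        f"{ct.clone_id}: site beyond {rep} length")


def build_tracks(panel, summaries: Sequence[OriginSummary],
                 marker_loci: Mapping[str, object] | None,
                 annotations: Mapping[str, Sequence],
                 reference_layout: Sequence[tuple[str, int]]) -> MosaicTrackSet:
    """Assemble one concentric track per clone over the reference layout.

    ``marker_loci`` maps clone id -> MarkerLocus (or None). Clone order in
    ``summaries`` is preserved outermost to innermost.
    """
    gene_tracks = {}
    for rep, _ in reference_layout:
        genes = annotations.get(rep, ())
        fwd = [(s, e) for _, s, e, strand in genes if strand == "+"]
        rev = [(s, e) for _, s, e, strand in genes if strand == "-"]
        gene_tracks[rep] = (fwd, rev)
    panel_track = {rep: [int(p) for p in panel.positions(rep)]
                   for rep, _ in reference_layout}
    clones = []
    for summ in summaries:
        foreign: dict[str, list[int]] = {}
        regions: dict[str, list[TransferredRegion]] = {}
        marker = None
        for rep, _ in reference_layout:
            regions[rep] = summ.regions(rep)
            foreign[rep] = []  # tick positions come from the classification
        for cv_rep in summ.per_replicon:
            foreign.setdefault(cv_rep, [])
        if marker_loci and summ.clone_id in marker_loci and marker_loci[summ.clone_id]:
            ml = marker_loci[summ.clone_id]
            marker = (ml.replicon_id, (ml.insertion_start + ml.insertion_end) // 2)
        clones.append(CloneTrack(summ.clone_id, foreign, regions, marker))
    return MosaicTrackSet(list(reference_layout), gene_tracks, panel_track, clones)


def tracks_from_results(panel, summaries, classified_by_clone,
                        marker_loci, annotations, reference_layout
                        ) -> MosaicTrackSet:
    """Like build_tracks but fills FOREIGN tick positions from classifications."""
    ts = build_tracks(panel, summaries, marker_loci, annotations, reference_layout)
    from .mosaic import FOREIGN
    for ct in ts.clone_tracks:
        classified = classified_by_clone.get(ct.clone_id, ())
        for cv in classified:
            if cv.label == FOREIGN:
                ct.foreign_sites.setdefault(cv.variant.replicon_id, []).append(
                    cv.variant.pos)
        for rep in ct.foreign_sites:
            ct.foreign_sites[rep] = sorted(ct.foreign_sites[rep])
    MosaicTrackSet.__post_init__(ts)
    return ts


# ---------------------------------------------------------------------------
# rendering

def _angle(pos: int, length: int) -> float:
    return 2.0 * math.pi * (pos - 0.5) / length


def _xy(cx: float, cy: float, radius: float, theta: float) -> tuple[float, float]:
    return (cx + radius * math.sin(theta), cy - radius * math.cos(theta))


def render_circular(tracks: MosaicTrackSet, output_path: str | Path,
                    output_format: str = "SVG",
                    replicon_id: str | None = None) -> Path:
    """Render one replicon's concentric mosaic rings; returns the output path.

    Pure with respect to the track data. SVG output is byte-stable for
    identical input; tick counts can be asserted by parsing the ``class``
    attributes (``panel-tick``, ``snp-tick``, ``region-arc``,
    ``marker-glyph``).
    """
    fmt = output_format.upper()
    if fmt not in ("SVG", "PNG"):
        raise ValidationError(f"unsupported format {output_format!r}")
    rep = replicon_id or tracks.reference_layout[0][0]
    length = dict(tracks.reference_layout)[rep]
    output_path = Path(output_path)
    if fmt == "SVG":
        _render_svg(tracks, rep, length, output_path)
    else:
        _render_png(tracks, rep, length, output_path)
    return output_path


def _render_svg(tracks: MosaicTrackSet, rep: str, length: int, path: Path) -> None:
    W = 640.0
    cx = cy = W / 2
    out = [f'<svg xmlns="http://www.w3.org/2000/svg" width="{W:.0f}" '
           f'height="{W:.0f}" viewBox="0 0 {W:.0f} {W:.0f}">',
           f'<title>{rep} mosaic</title>']

    def arc_path(radius: float, a0: float, a1: float) -> str:
        x0, y0 = _xy(cx, cy, radius, a0)
        x1, y1 = _xy(cx, cy, radius, a1)
        large = 1 if (a1 - a0) % (2 * math.pi) > math.pi else 0
        return (f"M {x0:.2f} {y0:.2f} A {radius:.2f} {radius:.2f} 0 "
                f"{large} 1 {x1:.2f} {y1:.2f}")

    r = 300.0
    fwd, rev = tracks.gene_tracks.get(rep, ([], []))
    for track, color, cls in ((fwd, "#3b6fb6", "gene-fwd"), (rev, "#c23b3b", "gene-rev")):
        for s, e in track:
            out.append(f'<path class="{cls}" d="{arc_path(r, _angle(s, length), _angle(e, length))}" '
                       f'stroke="{color}" stroke-width="6" fill="none"/>')
        r -= 10.0
    r -= 6.0
    for p in tracks.panel_track.get(rep, ()):
        a = _angle(p, length)
        x0, y0 = _xy(cx, cy, r - 4, a)
        x1, y1 = _xy(cx, cy, r + 4, a)
        out.append(f'<line class="panel-tick" x1="{x0:.2f}" y1="{y0:.2f}" '
                   f'x2="{x1:.2f}" y2="{y1:.2f}" stroke="#2e8b57" stroke-width="0.6"/>')
    r -= 16.0
    for ct in tracks.clone_tracks:
        out.append(f'<circle class="clone-ring" cx="{cx:.2f}" cy="{cy:.2f}" '
                   f'r="{r:.2f}" stroke="#dddddd" stroke-width="0.4" fill="none"/>')
        for region in ct.regions.get(rep, ()):
            a0 = _angle(region.first_snp, length)
            a1 = _angle(max(region.last_snp, region.first_snp + length // 720), length)
            out.append(f'<path class="region-arc" data-clone="{ct.clone_id}" '
                       f'd="{arc_path(r, a0, a1)}" stroke="#7bc47b" '
                       f'stroke-width="5" fill="none" stroke-opacity="0.5"/>')
        for p in ct.foreign_sites.get(rep, ()):
            a = _angle(p, length)
            x0, y0 = _xy(cx, cy, r - 4, a)
            x1, y1 = _xy(cx, cy, r + 4, a)
            out.append(f'<line class="snp-tick" data-clone="{ct.clone_id}" '
                       f'x1="{x0:.2f}" y1="{y0:.2f}" x2="{x1:.2f}" y2="{y1:.2f}" '
                       f'stroke="#1d7a1d" stroke-width="0.8"/>')
        if ct.marker and ct.marker[0] == rep:
            a = _angle(ct.marker[1], length)
            x, y = _xy(cx, cy, r, a)
            out.append(f'<circle class="marker-glyph" data-clone="{ct.clone_id}" '
                       f'cx="{x:.2f}" cy="{y:.2f}" r="3.5" fill="#111111"/>')
        r -= 14.0
    out.append(f'<text x="{cx:.2f}" y="{cy:.2f}" text-anchor="middle" '
               f'font-size="13">{rep} ({length:,} bp)</text>')
    out.append("</svg>")
    path.write_text("\n".join(out) + "\n")


def _render_png(tracks: MosaicTrackSet, rep: str, length: int, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig = plt.figure(figsize=(6.4, 6.4))
    ax = fig.add_subplot(projection="polar")
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    theta = lambda p: 2 * math.pi * (p - 0.5) / length
    for p in tracks.panel_track.get(rep, ()):
        ax.plot([theta(p)] * 2, [0.93, 0.97], color="#2e8b57", lw=0.4)
    r = 0.88
    for ct in tracks.clone_tracks:
        for p in ct.foreign_sites.get(rep, ()):
            ax.plot([theta(p)] * 2, [r - 0.02, r + 0.02], color="#1d7a1d", lw=0.6)
        if ct.marker and ct.marker[0] == rep:
            ax.plot([theta(ct.marker[1])], [r], "ko", ms=4)
        r -= 0.05
    ax.set_xticks([]); ax.set_yticks([]); ax.set_ylim(0, 1)
    ax.set_title(f"{rep} ({length:,} bp)")
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# tables

def make_summary_tables(summaries: Sequence[OriginSummary],
                        recruitment_stats: Sequence = (),
                        gene_hits: Mapping[str, Sequence] | None = None,
                        replicon_order: Sequence[str] = ("chromosome", "megaplasmid"),
                        ) -> dict[str, pd.DataFrame]:
    """Parenthood and recruitment tables in the publication row shape.

    One parenthood row per clone: FOREIGN SNPs and region count per replicon
    plus detected donor-specific genes; missing inputs become empty cells.
    """
    gene_hits = gene_hits or {}
    rows = []
    for summ in summaries:
        row: dict[str, object] = {"clone": summ.clone_id,
                                  "background": summ.background_parent}
        for rep in replicon_order:
            d = summ.per_replicon.get(rep)
            row[f"snps_{rep}"] = d["foreign_snps"] if d else 0
            row[f"regions_{rep}"] = len(d["regions"]) if d else 0
        hits = gene_hits.get(summ.clone_id, ())
        row["specific_genes_detected"] = ";".join(
            sorted({h.gene_id for h in hits})) or "-"
        rows.append(row)
    tables = {"parenthood": pd.DataFrame(rows)}
    if recruitment_stats:
        from .recruit import recruitment_frame
        tables["recruitment"] = recruitment_frame(recruitment_stats)
    return tables


# ---------------------------------------------------------------------------
# pipeline runner

_DEFAULT_CONFIG = {
    "outdir": "mosaictrace_run",
    "seed": 0,
    "stages": "simulate,panel,classify,segment,capture,recruit,report,evaluate",
    "replicon_lengths": "200000,50000",
    "snp_density": 1.0 / 124.0,
    "n_specific_genes": 12,
    "gene_length": 2000,
    "n_clones": 3,
    "n_fragments": "4,2",
    "fragment_size_min": 1,
    "fragment_size_max": 30000,
    "with_marker": True,
    "marker_replicon": "megaplasmid",
    "transposition_count": 0,
    "variant_source": "truth",   # truth | reads
    "coverage": 30.0,
    "read_length": 100,
    "error_rate": 0.01,
    "gap_threshold": 1000,
    "recruit_coverage": 3.0,
}


def load_config(path: str | Path) -> dict:
    """Flat key = value config file (``#`` comments allowed)."""
    config = dict(_DEFAULT_CONFIG)
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" in line:
            key, val = line.split("=", 1)
        elif ":" in line:
            key, val = line.split(":", 1)
        else:
            raise ValidationError(f"unparseable config line: {line!r}")
        config[key.strip()] = _coerce(val.strip())
    return config


def _coerce(val: str):
    low = val.lower()
    if low in ("true", "yes", "on"):
        return True
    if low in ("false", "no", "off"):
        return False
    try:
        return int(val)
    except ValueError:
        pass
    try:
        return float(val)
    except ValueError:
        pass
    return val


class DependencyError(RuntimeError):
    pass


def run_pipeline(config: Mapping | str | Path) -> dict:
    """Run simulate -> panel -> classify -> segment -> capture -> recruit ->
    report -> evaluate per the config; returns the JSON-serializable manifest.

    Any suffix of the stage chain may be dropped. Every parameter, seed and
    output path is recorded in ``manifest.json`` under the output directory;
    rerunning with an identical config and seed is byte-reproducible.
    """
    from . import capture as cap, mosaic as mo, panel as pn, recruit as rec, \
        simulate as sim

    if not isinstance(config, Mapping):
        config = load_config(config)
    cfg = dict(_DEFAULT_CONFIG)
    cfg.update(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    stages = [s.strip() for s in str(cfg["stages"]).split(",") if s.strip()]
    order = ["simulate", "panel", "classify", "segment", "capture", "recruit",
             "report", "evaluate"]
    for i, stage in enumerate(stages):
        if stage not in order:
            raise ValidationError(f"unknown stage {stage!r}")
        if i and order.index(stage) <= order.index(stages[i - 1]):
            raise ValidationError("stages must follow pipeline order")
    needed = set(stages)
    manifest = {
        "tool": "mosaictrace",
        "version": __version__,
        "config": {k: cfg[k] for k in sorted(cfg)},
        "config_hash": hashlib.sha256(
            json.dumps({k: cfg[k] for k in sorted(cfg)}, sort_keys=True,
                       default=str).encode()).hexdigest(),
        "seed": cfg["seed"],
        "stages": {},
    }

    def _intlist(v):
        return [int(x) for x in str(v).split(",")]

    state: dict = {}
    if "simulate" not in needed and needed - {"simulate"}:
        raise DependencyError("downstream stages require the simulate stage "
                              "(stage chain must be a prefix)")
    # simulate ---------------------------------------------------------------
    if "simulate" in needed:
        lengths = _intlist(cfg["replicon_lengths"])
        pair = sim.generate_parental_pair(
            lengths, float(cfg["snp_density"]), int(cfg["n_specific_genes"]),
            int(cfg["gene_length"]), seed=int(cfg["seed"]))
        state["pair"] = pair
        outputs = {}
        for which, genome in (("parentA", pair.parent_a), ("parentB", pair.parent_b)):
            fa, gff = outdir / f"{which}.fasta", outdir / f"{which}.gff3"
            sim.write_genome(genome, fa, gff)
            outputs[which] = {"fasta": str(fa), "gff3": str(gff)}
        cassette_id, cassette_seq = sim.default_cassette(seed=int(cfg["seed"]) + 7)
        marker = None
        if cfg["with_marker"]:
            marker_rep = str(cfg["marker_replicon"])
            if marker_rep not in pair.replicon_ids:
                marker_rep = pair.replicon_ids[-1]
            target = sim.pick_marker_target(pair, marker_rep)
            marker = (cassette_id, cassette_seq, target)
        clones = []
        frags = _intlist(cfg["n_fragments"])
        frag_map = dict(zip(pair.replicon_ids, frags + [0] * len(pair.replicon_ids)))
        for i in range(int(cfg["n_clones"])):
            tj = sim.simulate_transjugant(
                pair, "A", frag_map,
                fragment_size_sampler=(float(cfg["fragment_size_min"]),
                                       float(cfg["fragment_size_max"])),
                marker=marker, transposition_count=int(cfg["transposition_count"]),
                seed=int(cfg["seed"]) * 1000 + i + 1, clone_id=f"T{i + 1}",
                gap_bp=int(cfg["gap_threshold"]))
            clones.append(tj)
            fa = outdir / f"{tj.clone_id}.fasta"
            sim.write_genome(tj.replicons, fa)
            truth_paths = sim.write_truth(tj, outdir)
            outputs[tj.clone_id] = {"fasta": str(fa), **truth_paths}
        state["clones"] = clones
        state["cassette"] = (cassette_id, cassette_seq)
        manifest["stages"]["simulate"] = outputs

    # panel ------------------------------------------------------------------
    if "panel" in needed:
        pair = state["pair"]
        parental = sim.emit_parental_variants(pair, "A")
        panel = pn.build_panel_from_vcfs([], parental, "A")
        state["panel"] = panel
        tsv, bed = outdir / "panel.tsv", outdir / "panel.bed"
        panel.write_tsv(tsv)
        panel.write_bed(bed)
        total_len = sum(r.length for r in pair.parent_a)
        snps_kbp, spacing = pn.panel_density(panel, total_len)
        manifest["stages"]["panel"] = {
            "tsv": str(tsv), "bed": str(bed), "n_sites": len(panel),
            "snps_per_kbp": round(snps_kbp, 3), "mean_spacing_bp": round(spacing, 1),
        }

    # classify / segment -----------------------------------------------------
    if "classify" in needed:
        panel = state["panel"]
        state["classified"] = {}
        state["variants"] = {}
        outputs = {}
        for tj in state["clones"]:
            if cfg["variant_source"] == "reads":
                reads = sim.simulate_reads(tj.replicons, int(cfg["read_length"]),
                                           float(cfg["coverage"]),
                                           float(cfg["error_rate"]),
                                           seed=tj.truth.seed + 17)
                variants = sim.pileup_call(reads, tj)
                state.setdefault("reads", {})[tj.clone_id] = reads
            else:
                variants = sim.emit_truth_variants(tj, tj.background)
            state["variants"][tj.clone_id] = variants
            classified = mo.classify_variants(variants, panel, tj.background)
            state["classified"][tj.clone_id] = classified
            path = outdir / f"{tj.clone_id}.classified.tsv"
            write_tsv(mo.classification_frame(classified), path)
            outputs[tj.clone_id] = str(path)
        manifest["stages"]["classify"] = outputs

    if "segment" in needed:
        state["summaries"] = []
        outputs = {}
        for tj in state["clones"]:
            mk = tj.truth.marker
            marker_locus = ((mk["replicon_id"], mk["replaced_start"],
                             mk["replaced_end"]) if mk else None)
            summ = mo.summarize_clone(state["classified"][tj.clone_id],
                                      marker_locus,
                                      gap_threshold=int(cfg["gap_threshold"]),
                                      clone_id=tj.clone_id,
                                      background_parent=tj.background)
            state["summaries"].append(summ)
            bed = outdir / f"{tj.clone_id}.regions.bed"
            write_bed(mo.regions_bed_rows(summ), bed)
            outputs[tj.clone_id] = str(bed)
        manifest["stages"]["segment"] = outputs

    # capture ----------------------------------------------------------------
    if "capture" in needed:
        pair = state["pair"]
        bg_genome = {r.replicon_id: r.sequence_str for r in pair.parent_a}
        ann_a = {r.replicon_id: r.genes for r in pair.parent_a}
        ann_b = {r.replicon_id: r.genes for r in pair.parent_b}
        donor_genes = {g.gene_id: g for g in cap.genes_from_genome(pair.parent_b)}
        spec = [donor_genes[g] for g in pair.specific_genes_b]
        state["gene_hits"] = {}
        state["marker_loci"] = {}
        outputs = {}
        cassette_id, cassette_seq = state["cassette"]
        for tj in state["clones"]:
            contigs = sim.tile_contigs(tj.replicons)
            hits = cap.detect_gene_hits(spec, contigs, background_genome=bg_genome,
                                        background_annotations=ann_a,
                                        donor_annotations=ann_b)
            state["gene_hits"][tj.clone_id] = hits
            path = outdir / f"{tj.clone_id}.gene_hits.tsv"
            write_tsv(cap.hits_frame(hits), path)
            locus = cap.localize_marker(contigs, cassette_seq, bg_genome, ann_a,
                                        cassette_id=cassette_id)
            state["marker_loci"][tj.clone_id] = locus
            jpath = outdir / f"{tj.clone_id}.marker.json"
            with open(jpath, "w") as fh:
                json.dump(dataclasses.asdict(locus) if locus else None, fh,
                          indent=2)
            outputs[tj.clone_id] = {"hits": str(path), "marker": str(jpath)}
        manifest["stages"]["capture"] = outputs

    # recruit ----------------------------------------------------------------
    if "recruit" in needed:
        pair = state["pair"]
        idx = {w: rec.ReferenceIndex({r.replicon_id: r.sequence_str
                                      for r in pair.parent(w)})
               for w in ("A", "B")}
        stats = []
        state["assignments"] = {}
        for tj in state["clones"]:
            reads = sim.simulate_reads(tj.replicons, int(cfg["read_length"]),
                                       float(cfg["recruit_coverage"]), 0.0,
                                       seed=tj.truth.seed + 29)
            pair_stats = [rec.recruit_reads(reads, idx[w], clone_id=tj.clone_id,
                                            reference_id=w) for w in ("A", "B")]
            stats.extend(pair_stats)
            state["assignments"][tj.clone_id] = rec.assign_background(*pair_stats)
        state["recruitment"] = stats
        path = outdir / "recruitment.tsv"
        write_tsv(rec.recruitment_frame(stats), path)
        manifest["stages"]["recruit"] = {
            "tsv": str(path),
            "assignments": {c: a.background_parent
                            for c, a in state["assignments"].items()}}

    # report -----------------------------------------------------------------
    if "report" in needed:
        pair = state["pair"]
        layout = [(r.replicon_id, r.length) for r in pair.parent_a]
        ann = {r.replicon_id: r.genes for r in pair.parent_a}
        tracks = tracks_from_results(state["panel"], state["summaries"],
                                     state["classified"],
                                     state.get("marker_loci"), ann, layout)
        outputs = {}
        for rep, _ in layout:
            svg = outdir / f"mosaic_{rep}.svg"
            render_circular(tracks, svg, "SVG", rep)
            outputs[rep] = str(svg)
        tables = make_summary_tables(state["summaries"], state.get("recruitment", ()),
                                     state.get("gene_hits"),
                                     replicon_order=[r for r, _ in layout])
        for name, df in tables.items():
            path = outdir / f"table_{name}.tsv"
            write_tsv(df, path)
            outputs[name] = str(path)
        manifest["stages"]["report"] = outputs

    # evaluate ---------------------------------------------------------------
    if "evaluate" in needed:
        reports = {}
        for tj, summ in zip(state["clones"], state["summaries"]):
            rep = mo.evaluate_against_truth(summ, tj.truth,
                                            state["classified"][tj.clone_id])
            reports[tj.clone_id] = {
                "region_precision": rep.region_precision,
                "region_recall": rep.region_recall,
                "max_boundary_error": rep.max_boundary_error,
                "foreign_count_match": rep.foreign_count_match,
                "label_accuracy": rep.label_accuracy,
            }
        path = outdir / "evaluation.json"
        with open(path, "w") as fh:
            json.dump(reports, fh, indent=2, sort_keys=True)
        manifest["stages"]["evaluate"] = {"json": str(path), **{
            "mean_precision": sum(r["region_precision"] for r in reports.values())
            / max(len(reports), 1),
            "mean_recall": sum(r["region_recall"] for r in reports.values())
            / max(len(reports), 1)}}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["manifest_path"] = str(outdir / "manifest.json")
    return manifest
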