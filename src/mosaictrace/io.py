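"""File formats and shared primitive types.

Sequences are held internally as numpy uint8 arrays over the alphabet
``ACGT`` (codes 0..3); helpers convert to/from strings at the I/O boundary.
Variants follow VCF conventions throughout: 1-based positions, REF/ALT with
anchor bases for indels, one ALT per record (multi-allelic records must be
decomposed upstream and are rejected by the reader).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = b"ACGT"
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase
_DECODE = np.frombuffer(ALPHABET, dtype=np.uint8)


class FormatError(ValueError):
    """Malformed or unsupported input (undecomposed VCF, bad alphabet...)."""


def encode_seq(seq: str | bytes) -> np.ndarray:
    """Encode an ACGT string to a uint8 code array (case-insensitive)."""
    raw = np.frombuffer(seq.encode() if isinstance(seq, str) else seq, dtype=np.uint8)
    codes = _ENCODE[raw]
    if codes.max(initial=0) > 3:
        bad = chr(int(raw[int(np.argmax(codes > 3))]))
        raise FormatError(f"non-ACGT character in sequence: {bad!r}")
    return codes


def decode_seq(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


@dataclasses.dataclass(frozen=True)
class VariantCall:
    """One VCF-convention variant record (1-based, anchored indels)."""

    replicon_id: str
    pos: int
    ref_allele: str
    alt_allele: str
    quality: float | None = None
    filter: str = "PASS"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"position must be >= 1, got {self.pos}")
        if not self.ref_allele or not self.alt_allele:
            raise FormatError("alleles must be non-empty")

    @property
    def is_snp(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.replicon_id, self.pos, self.alt_allele)


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {record_id: sequence} mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq).upper(), qual))
    return out


# ---------------------------------------------------------------------------
# VCF

_VCF_HEADER = "##fileformat=VCFv4.2\n{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"


def write_vcf(variants: Sequence[VariantCall], path: str | Path,
              contigs: Mapping[str, int] | None = None) -> None:
    """Write sorted variants as uncompressed VCF 4.2."""
    lines = "".join(f"##contig=<ID={c},length={l}>\n" for c, l in (contigs or {}).items())
    recs = sorted(variants, key=lambda v: (v.replicon_id, v.pos, v.alt_allele))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contigs=lines))
        for v in recs:
            q = "." if v.quality is None else f"{v.quality:g}"
            fh.write(f"{v.replicon_id}\t{v.pos}\t.\t{v.ref_allele}\t{v.alt_allele}"
                     f"\t{q}\t{v.filter}\t.\n")


def read_vcf(path: str | Path) -> list[VariantCall]:
    """Read a VCF into VariantCall records via pysam.

    Multi-allelic records are rejected: callers must decompose upstream.
    """
    import pysam

    out: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) != 1:
                raise FormatError(
                    f"undecomposed multi-allelic record at {rec.chrom}:{rec.pos}; "
                    "decompose the VCF before loading")
            flt = ",".join(rec.filter.keys()) or "PASS"
            out.append(VariantCall(rec.chrom, rec.pos, rec.ref, alts[0],
                                   rec.qual, flt))
    return out


def apply_variants(reference: Mapping[str, str],
                   variants: Sequence[VariantCall]) -> dict[str, str]:
    """Apply VCF-convention variants to a reference, returning edited sequences.

    Used for the round-trip check that truth variants reconstruct the genome
    they were emitted from. Records must not overlap.
    """
    result: dict[str, str] = {}
    by_rep: dict[str, list[VariantCall]] = {}
    for v in variants:
        by_rep.setdefault(v.replicon_id, []).append(v)
    for rep, seq in reference.items():
        recs = sorted(by_rep.get(rep, []), key=lambda v: v.pos)
        parts: list[str] = []
        cursor = 0  # 0-based
        for v in recs:
            start = v.pos - 1
            if start < cursor:
                raise FormatError(f"overlapping variants at {rep}:{v.pos}")
            if seq[start:start + len(v.ref_allele)] != v.ref_allele:
                raise FormatError(f"REF mismatch at {rep}:{v.pos}")
            parts.append(seq[cursor:start])
            parts.append(v.alt_allele)
            cursor = start + len(v.ref_allele)
        parts.append(seq[cursor:])
        result[rep] = "".join(parts)
    return result


# ---------------------------------------------------------------------------
# GFF3 / BED / TSV

def write_gff3(genes_by_replicon: Mapping[str, Sequence[tuple[str, int, int, str]]],
               replicon_lengths: Mapping[str, int], path: str | Path) -> None:
    """Write gene annotations ((gene_id, start, end, strand), 1-based) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rep, length in replicon_lengths.items():
            fh.write(f"##sequence-region {rep} 1 {length}\n")
        for rep, genes in genes_by_replicon.items():
            for gid, start, end, strand in genes:
                fh.write(f"{rep}\tmosaictrace\tgene\t{start}\t{end}\t.\t{strand}\t."
                         f"\tID={gid}\n")


def read_gff3(path: str | Path) -> dict[str, list[tuple[str, int, int, str]]]:
    """Read GFF3 gene features back into {replicon: [(id, start, end, strand)]}."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    out: dict[str, list[tuple[str, int, int, str]]] = {}
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = feat.attributes.get("ID", feat.attributes.get("Name", ["?"]))[0]
        out.setdefault(feat.seqid, []).append((gid, feat.start, feat.end,
                                               feat.strand))
    return out


def write_bed(intervals: Sequence[tuple[str, int, int, str, int | float]],
              path: str | Path) -> None:
    """Write (replicon, start_1based, end_1based_incl, name, score) as BED.

    Converts the package's 1-based closed intervals to BED 0-based half-open.
    """
    with open(path, "w") as fh:
        for rep, start, end, name, score in intervals:
            fh.write(f"{rep}\t{start - 1}\t{end}\t{name}\t{score}\n")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
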