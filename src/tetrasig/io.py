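"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions are strict and audited by the test-suite:

* FASTA / GFF3: 1-based, inclusive on both ends.
* BED: 0-based, half-open; :class:`IntervalSet` stores BED convention and
  offers 1-based membership queries for VCF positions.
* FASTQ: Phred+33, 4-line records.

VCF reading/writing lives in :mod:`tetrasig.variants` (it needs the variant
domain types); the functions are re-exported here for convenience.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
from Bio import SeqIO


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class SequenceRecord(NamedTuple):
    """A named nucleotide sequence over the {A,C,G,T,N} alphabet."""

    id: str
    seq: str


class FeatureRecord(NamedTuple):
    """A genomic feature with 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    feature_id: str
    feature_type: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


_VALID_SEQ = re.compile(r"[^ACGTN]")


def _validate_seq(rec_id: str, seq: str) -> str:
    seq = seq.upper()
    m = _VALID_SEQ.search(seq)
    if m:
        raise FormatError(
            f"record {rec_id!r}: illegal character {m.group()!r} at offset {m.start()}"
        )
    if not seq:
        raise FormatError(f"record {rec_id!r}: empty sequence")
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into validated, uppercased records.

    The record id is the first whitespace-delimited token of the header.
    Duplicate ids, empty files/records and characters outside {A,C,G,T,N}
    raise :class:`FormatError`.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, _validate_seq(rec.id, str(rec.seq))))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a FASTQ file into ``(id, seq, quality-string)`` tuples (Phred+33)."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq).upper(), quals))
    return out


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    """Write ``(id, seq, qualities)`` tuples as 4-line FASTQ records."""
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            if len(seq) != len(qual):
                raise FormatError(
                    f"read {rid!r}: sequence length {len(seq)} != quality length {len(qual)}"
                )
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def iter_fastq_seqs(paths: Sequence[str | Path]) -> Iterator[str]:
    """Stream read sequences (uppercased) from one or more FASTQ files."""
    for path in paths:
        path = Path(path)
        if not path.exists():
            raise FormatError(f"FASTQ file not found: {path}")
        with open(path) as fh:
            lineno = 0
            while True:
                header = fh.readline()
                if not header:
                    break
                seq = fh.readline()
                plus = fh.readline()
                qual = fh.readline()
                lineno += 4
                if not qual:
                    raise FormatError(f"{path}: truncated FASTQ record near line {lineno}")
                if not header.startswith("@") or not plus.startswith("+"):
                    raise FormatError(f"{path}: malformed FASTQ record near line {lineno}")
                yield seq.strip().upper()


@dataclass
class IntervalSet:
    """Merged genomic intervals, 0-based half-open (BED convention).

    Supports strand-agnostic membership queries in both conventions.
    """

    _by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple[str, int, int]]) -> "IntervalSet":
        pool: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if not (0 <= start < end):
                raise FormatError(f"invalid interval {chrom}:{start}-{end}")
            pool.setdefault(chrom, []).append((start, end))
        by_chrom = {}
        for chrom, ivs in pool.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            starts = np.array([m[0] for m in merged], dtype=np.int64)
            ends = np.array([m[1] for m in merged], dtype=np.int64)
            by_chrom[chrom] = (starts, ends)
        return cls(by_chrom)

    def contains(self, chrom: str, pos0: int) -> bool:
        """Membership of a 0-based position."""
        if chrom not in self._by_chrom:
            return False
        starts, ends = self._by_chrom[chrom]
        i = int(np.searchsorted(starts, pos0, side="right")) - 1
        return i >= 0 and pos0 < ends[i]

    def contains_1based(self, chrom: str, pos1: int) -> bool:
        return self.contains(chrom, pos1 - 1)

    def __len__(self) -> int:
        return sum(len(s) for s, _ in self._by_chrom.values())

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self._by_chrom):
            starts, ends = self._by_chrom[chrom]
            out.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
        return out


def read_bed(path: str | Path) -> IntervalSet:
    """Read a BED file (>=3 columns, 0-based half-open) into an IntervalSet."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if not (0 <= start < end):
                raise FormatError(f"{path}:{lineno}: invalid BED interval {start}..{end}")
            intervals.append((fields[0], start, end))
    return IntervalSet.from_intervals(intervals)


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_gff3(path: str | Path) -> list[FeatureRecord]:
    """Read GFF3 features (1-based inclusive) with strict coordinate checks."""
    import gffutils

    # light structural pre-scan so errors carry line numbers
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if not (1 <= start <= end):
                raise FormatError(f"{path}:{lineno}: invalid GFF3 span {start}..{end}")

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    records = []
    gene_ids: set[str] = set()
    for feat in db.all_features(order_by=("seqid", "start")):
        rec = FeatureRecord(
            chrom=feat.seqid,
            start=feat.start,
            end=feat.end,
            strand=feat.strand if feat.strand in "+-" else ".",
            feature_id=feat.id,
            feature_type=feat.featuretype,
        )
        if rec.feature_type == "gene":
            if rec.feature_id in gene_ids:
                raise FormatError(f"duplicate gene id {rec.feature_id!r} in {path}")
            gene_ids.add(rec.feature_id)
        records.append(rec)
    return records


def write_gff3(features: Iterable[FeatureRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.chrom}\ttetrasig\t{f.feature_type}\t{f.start}\t{f.end}\t.\t"
                f"{f.strand}\t.\tID={f.feature_id}\n"
            )


def read_tsv_map(path: str | Path, header: bool = False) -> dict[str, tuple[str, ...]]:
    """Read a 2+ column TSV into ``{first column: tuple(remaining columns)}``."""
    mapping: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected >=2 TSV columns")
            if fields[0] in mapping:
                raise FormatError(f"{path}:{lineno}: duplicate key {fields[0]!r}")
            mapping[fields[0]] = tuple(fields[1:])
    return mapping


def write_newick(tree, path: str | Path) -> None:
    """Serialize a tree (anything exposing ``to_newick()``) to a newick file."""
    newick = tree.to_newick() if hasattr(tree, "to_newick") else str(tree)
    with open(path, "w") as fh:
        fh.write(newick.rstrip() + "\n")


# re-exported for the io_formats surface; implemented beside the variant types
from .variants import read_vcf, write_vcf  # noqa: E402,F401
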