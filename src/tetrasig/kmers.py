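"""Canonical k-mer counting over assemblies and read sets.

K-mers are counted under canonicalization: each window is represented by the
lexicographic minimum of itself and its reverse complement, which makes the
table strand-independent. Only odd k is accepted (even k admits
self-reverse-complement palindromes whose counting is ambiguous). Windows
containing N contribute nothing.

Counting is done on 2-bit integer codes with vectorized numpy rolling
products — no external k-mer counter is invoked. For k <= 31 codes fit in
int64.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

from .io import iter_fastq_seqs

if TYPE_CHECKING:
    from .simulate import GenomeMap

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_BASES = np.array(list("ACGT"))

READS_CHROM = "reads"


class KmerError(ValueError):
    pass


def _check_k(k: int) -> None:
    if k % 2 == 0:
        raise KmerError(f"k={k}: palindromic canonicalization undefined for even k")
    if not 3 <= k <= 31:
        raise KmerError(f"k={k} out of supported range [3, 31]")


def encode_seq(seq: str) -> np.ndarray:
    """Map a nucleotide string to int8 codes; invalid bases (incl. N) -> -1."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def window_codes(bases: np.ndarray, k: int) -> np.ndarray:
    """Canonical int64 codes of every valid (N-free) k-window of *bases*."""
    n = bases.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    clean = np.where(bases >= 0, bases, 0).astype(np.int64)
    fwd = np.zeros(n, dtype=np.int64)
    rc = np.zeros(n, dtype=np.int64)
    for j in range(k):
        fwd = (fwd << 2) | clean[j : j + n]
    for j in range(k - 1, -1, -1):
        rc = (rc << 2) | (3 - clean[j : j + n])
    bad = np.concatenate(([0], np.cumsum(bases < 0)))
    valid = (bad[k:] - bad[:-k]) == 0
    return np.minimum(fwd, rc)[valid]


def decode_kmer(code: int, k: int) -> str:
    digits = (int(code) >> (2 * np.arange(k - 1, -1, -1))) & 3
    return "".join(_BASES[digits])


def encode_kmer(kmer: str) -> int:
    bases = encode_seq(kmer)
    if (bases < 0).any():
        raise KmerError(f"k-mer {kmer!r} contains non-ACGT characters")
    code = 0
    for b in bases:
        code = (code << 2) | int(b)
    return code


def revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(seq))


def canonical_kmer(kmer: str) -> str:
    rc = revcomp(kmer)
    return min(kmer, rc)


def canonical_code(kmer: str) -> int:
    return encode_kmer(canonical_kmer(kmer))


@dataclass
class KmerCountTable:
    """Sparse canonical k-mer counts, per chromosome and globally.

    ``codes`` is a sorted int64 vector of canonical 2-bit codes;
    ``counts[i, j]`` is the count of k-mer ``codes[i]`` on chromosome
    ``chroms[j]``.
    """

    k: int
    chroms: list[str]
    chrom_lengths: dict[str, int]
    codes: np.ndarray
    counts: np.ndarray
    source: str = "assembly"

    def __post_init__(self) -> None:
        _check_k(self.k)

    @property
    def n_kmers(self) -> int:
        return int(self.codes.size)

    @property
    def global_counts(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def _row(self, kmer: str) -> int | None:
        code = canonical_code(kmer)
        i = int(np.searchsorted(self.codes, code))
        if i < self.n_kmers and self.codes[i] == code:
            return i
        return None

    def count(self, kmer: str, chrom: str | None = None) -> int:
        i = self._row(kmer)
        if i is None:
            return 0
        if chrom is None:
            return int(self.global_counts[i])
        if chrom not in self.chrom_lengths:
            raise KmerError(f"unknown chromosome {chrom!r}")
        return int(self.counts[i, self.chroms.index(chrom)])

    def kmer_strings(self) -> list[str]:
        return [decode_kmer(c, self.k) for c in self.codes]

    def effective_length(self, chrom: str) -> int:
        return max(self.chrom_lengths[chrom] - self.k + 1, 0)

    def to_tsv(self, path: str | Path) -> None:
        """Dump as sorted ``kmer<TAB>chrom<TAB>count`` rows (interchange format)."""
        with open(path, "w") as fh:
            fh.write(f"#k={self.k}\tsource={self.source}\n")
            for chrom in self.chroms:
                fh.write(f"#chrom_length\t{chrom}\t{self.chrom_lengths[chrom]}\n")
            strings = self.kmer_strings()
            for i, km in enumerate(strings):
                for j, chrom in enumerate(self.chroms):
                    c = int(self.counts[i, j])
                    if c:
                        fh.write(f"{km}\t{chrom}\t{c}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KmerCountTable":
        k = None
        source = "assembly"
        lengths: dict[str, int] = {}
        entries: dict[str, dict[str, int]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#k="):
                    head, src = line[1:].split("\t")
                    k = int(head.split("=")[1])
                    source = src.split("=")[1]
                    continue
                if line.startswith("#chrom_length"):
                    _, chrom, length = line.split("\t")
                    lengths[chrom] = int(length)
                    continue
                if not line or line.startswith("#"):
                    continue
                km, chrom, cnt = line.split("\t")
                entries.setdefault(km, {})[chrom] = int(cnt)
        if k is None:
            raise KmerError(f"{path}: missing #k header")
        chroms = sorted(lengths)
        codes = np.array(sorted(encode_kmer(km) for km in entries), dtype=np.int64)
        counts = np.zeros((codes.size, len(chroms)), dtype=np.int64)
        code_of = {encode_kmer(km): km for km in entries}
        for i, code in enumerate(codes):
            for chrom, cnt in entries[code_of[int(code)]].items():
                counts[i, chroms.index(chrom)] = cnt
        return cls(k, chroms, lengths, codes, counts, source)


def _aggregate(code_chunks: list[np.ndarray], count_chunks: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    if not code_chunks:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    allc = np.concatenate(code_chunks)
    allw = np.concatenate(count_chunks)
    uniq, inv = np.unique(allc, return_inverse=True)
    agg = np.bincount(inv, weights=allw.astype(np.float64)).astype(np.int64)
    return uniq, agg


def count_kmers_assembly(genome: "GenomeMap | Sequence", k: int) -> KmerCountTable:
    """Count canonical k-mers per chromosome of an assembly.

    *genome* is a :class:`~tetrasig.simulate.GenomeMap` or any sequence of
    ``SequenceRecord``-like ``(id, seq)`` pairs.
    """
    _check_k(k)
    records = getattr(genome, "records", genome)
    chroms = [rec.id for rec in records]
    lengths = {rec.id: len(rec.seq) for rec in records}
    per_chrom: list[tuple[np.ndarray, np.ndarray]] = []
    for rec in records:
        codes = window_codes(encode_seq(rec.seq), k)
        if codes.size:
            uniq, cnt = np.unique(codes, return_counts=True)
        else:
            uniq = np.empty(0, dtype=np.int64)
            cnt = np.empty(0, dtype=np.int64)
        per_chrom.append((uniq, cnt.astype(np.int64)))
    all_codes = np.unique(np.concatenate([u for u, _ in per_chrom])) if per_chrom else np.empty(0, np.int64)
    counts = np.zeros((all_codes.size, len(chroms)), dtype=np.int64)
    for j, (uniq, cnt) in enumerate(per_chrom):
        idx = np.searchsorted(all_codes, uniq)
        counts[idx, j] = cnt
    return KmerCountTable(k, chroms, lengths, all_codes, counts, source="assembly")


def count_kmers_reads(
    fastq_paths: Sequence[str | Path] | str | Path,
    k: int,
    min_count_keep: int = 1,
    chunk_reads: int = 20000,
) -> KmerCountTable:
    """Count canonical k-mers globally over one or more FASTQ files.

    Reads are concatenated with ``N`` separators per chunk so no window spans
    two reads; k-mers with final count below *min_count_keep* are dropped.
    The result has a single pseudo-chromosome ``"reads"``.
    """
    _check_k(k)
    if min_count_keep < 1:
        raise KmerError("min_count_keep must be >= 1")
    if isinstance(fastq_paths, (str, Path)):
        fastq_paths = [fastq_paths]
    code_chunks: list[np.ndarray] = []
    count_chunks: list[np.ndarray] = []
    total_bases = 0
    buf: list[str] = []

    def flush() -> None:
        if not buf:
            return
        blob = "N".join(buf)
        codes = window_codes(encode_seq(blob), k)
        if codes.size:
            uniq, cnt = np.unique(codes, return_counts=True)
            code_chunks.append(uniq)
            count_chunks.append(cnt.astype(np.int64))
        buf.clear()

    for seq in iter_fastq_seqs(list(fastq_paths)):
        buf.append(seq)
        total_bases += len(seq)
        if len(buf) >= chunk_reads:
            flush()
    flush()
    codes, counts = _aggregate(code_chunks, count_chunks)
    if min_count_keep > 1:
        keep = counts >= min_count_keep
        codes, counts = codes[keep], counts[keep]
    return KmerCountTable(
        k,
        [READS_CHROM],
        {READS_CHROM: total_bases},
        codes,
        counts.reshape(-1, 1),
        source="reads",
    )


def kmer_density(table: KmerCountTable, kmer: str, chrom: str) -> float:
    """Per-base density: count / (chromosome length - k + 1); 0 when absent."""
    if chrom not in table.chrom_lengths:
        raise KmerError(f"unknown chromosome {chrom!r}")
    eff = table.effective_length(chrom)
    if eff <= 0:
        return 0.0
    return table.count(kmer, chrom) / eff
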