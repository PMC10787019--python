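"""Selection of chromosome-enriched k-mers and the chromosome profile matrix.

A k-mer is kept when (1) its global count reaches ``min_global`` and (2) its
abundance on its best chromosome is at least ``fold`` times the baseline over
the remaining chromosomes. The baseline is either the maximum over the other
chromosomes (strict: the k-mer is effectively private to one chromosome) or
their mean (admits k-mers shared by a few homologous chromosomes). Abundance
is compared as length-normalized density by default; ``raw`` compares plain
counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .kmers import KmerCountTable, decode_kmer


class EnrichmentError(ValueError):
    pass


@dataclass
class EnrichmentParams:
    min_global: int = 1000
    fold: float = 2.0
    baseline: str = "max_other"
    normalize: str = "density"

    def __post_init__(self) -> None:
        if self.min_global < 1:
            raise EnrichmentError("min_global must be >= 1")
        if self.fold <= 1:
            raise EnrichmentError("fold must be > 1")
        if self.baseline not in ("max_other", "mean_other"):
            raise EnrichmentError(f"unknown baseline {self.baseline!r}")
        if self.normalize not in ("density", "raw"):
            raise EnrichmentError(f"unknown normalize {self.normalize!r}")


class EnrichedEntry(NamedTuple):
    kmer: str
    chrom: str
    global_count: int
    fold: float


@dataclass
class EnrichedKmerSet:
    entries: list[EnrichedEntry]
    params: EnrichmentParams
    k: int

    def kmers(self) -> list[str]:
        return [e.kmer for e in self.entries]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#kmer\tchrom\tglobal_count\tfold\n")
            for e in self.entries:
                fold = "inf" if math.isinf(e.fold) else f"{e.fold:.6g}"
                fh.write(f"{e.kmer}\t{e.chrom}\t{e.global_count}\t{fold}\n")


def _values(table: KmerCountTable, normalize: str) -> np.ndarray:
    vals = table.counts.astype(np.float64)
    if normalize == "density":
        eff = np.array([max(table.chrom_lengths[c] - table.k + 1, 1) for c in table.chroms],
                       dtype=np.float64)
        vals = vals / eff
    return vals


def select_enriched(table: KmerCountTable, params: EnrichmentParams | None = None) -> EnrichedKmerSet:
    """Select k-mers enriched on a single chromosome.

    Keeps a k-mer iff its raw global count >= ``min_global`` and its
    (normalized) abundance on the argmax chromosome is >= ``fold`` times the
    baseline over the remaining chromosomes. The achieved fold is recorded
    (infinite when the baseline is zero).
    """
    if params is None:
        params = EnrichmentParams()
    if len(table.chroms) < 2:
        raise EnrichmentError("enrichment undefined for a single-chromosome table")
    if table.n_kmers == 0:
        return EnrichedKmerSet([], params, table.k)
    vals = _values(table, params.normalize)
    glob = table.global_counts
    assigned = np.argmax(vals, axis=1)
    rows = np.arange(vals.shape[0])
    best = vals[rows, assigned]
    if params.baseline == "max_other":
        masked = vals.copy()
        masked[rows, assigned] = -np.inf
        baseline = masked.max(axis=1)
        baseline = np.where(np.isfinite(baseline), baseline, 0.0)
    else:
        baseline = (vals.sum(axis=1) - best) / (vals.shape[1] - 1)
    keep = (glob >= params.min_global) & (best > 0) & (best >= params.fold * baseline)
    with np.errstate(divide="ignore"):
        fold = np.where(baseline > 0, best / np.maximum(baseline, 1e-300), np.inf)
    entries = [
        EnrichedEntry(
            decode_kmer(int(table.codes[i]), table.k),
            table.chroms[int(assigned[i])],
            int(glob[i]),
            float(fold[i]),
        )
        for i in np.nonzero(keep)[0]
    ]
    entries.sort(key=lambda e: e.kmer)
    return EnrichedKmerSet(entries, params, table.k)


@dataclass
class ProfileMatrix:
    """Chromosome x enriched-k-mer abundance matrix (rows in genome order)."""

    chroms: list[str]
    kmers: list[str]
    values: np.ndarray
    normalize: str = "density"

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\t" + "\t".join(self.kmers) + "\n")
            for i, chrom in enumerate(self.chroms):
                row = "\t".join(f"{v:.10g}" for v in self.values[i])
                fh.write(f"{chrom}\t{row}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProfileMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            kmers = header[1:]
            chroms = []
            rows = []
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                chroms.append(fields[0])
                rows.append([float(x) for x in fields[1:]])
        return cls(chroms, kmers, np.array(rows, dtype=np.float64))


def build_profile_matrix(table: KmerCountTable, enriched: EnrichedKmerSet) -> ProfileMatrix:
    """Profile all chromosomes over the selected k-mers (columns lexicographic)."""
    if not enriched.entries:
        raise EnrichmentError("insufficient markers: enriched set is empty")
    vals = _values(table, enriched.params.normalize)
    kmers = sorted(e.kmer for e in enriched.entries)
    strings = table.kmer_strings()
    index = {km: i for i, km in enumerate(strings)}
    cols = [index[km] for km in kmers]
    matrix = vals[cols, :].T.copy()  # rows chroms, cols selected kmers
    return ProfileMatrix(list(table.chroms), kmers, matrix, enriched.params.normalize)
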