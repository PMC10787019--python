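"""Synthetic polyploid genomes, short reads, and variant call sets.

The genome simulator produces the two contrasting architectures the
signature analyses discriminate:

* ``auto`` — per homologous group, one ancestor carrying a group-private
  repeat family, from which all haplotypes diverge recently and equally.
* ``allo`` — per group, two anciently diverged subgenome ancestors; each
  subgenome carries its own private repeat family shared across ALL of that
  subgenome's chromosomes, with two recent haplotypes per subgenome.
* ``diploid`` — the auto architecture with two haplotypes.

Substitutions only (no indels) so k-mer expectations stay analytic. All
randomness flows from a single integer seed via ``numpy.random.default_rng``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .io import IntervalSet, SequenceRecord, read_fasta, read_tsv_map, write_fasta
from .variants import VariantRecord, VariantSet

_BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    mode: str = "auto"
    n_groups: int = 3
    chrom_len: int = 50_000
    n_haplotypes: int = 4
    d_hap: float = 0.005
    d_sub: float = 0.05
    repeat_len: int = 200
    repeat_copies: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("auto", "allo", "diploid"):
            raise SimulationError(f"unknown mode {self.mode!r}")
        if self.mode == "diploid" and self.n_haplotypes != 2:
            raise SimulationError("diploid mode requires n_haplotypes=2")
        if self.mode == "allo" and self.n_haplotypes != 4:
            raise SimulationError("allo mode requires n_haplotypes=4")
        if self.mode == "auto" and self.n_haplotypes < 2:
            raise SimulationError("auto mode requires n_haplotypes>=2")
        if self.n_groups < 1 or self.chrom_len < 1:
            raise SimulationError("n_groups and chrom_len must be positive")
        if not 0 <= self.d_hap <= 0.2:
            raise SimulationError("d_hap must lie in [0, 0.2]")
        if self.mode == "allo" and not self.d_hap < self.d_sub <= 0.2:
            raise SimulationError("allo mode requires d_hap < d_sub <= 0.2")
        if self.chrom_len < 10 * self.repeat_len:
            raise SimulationError("chrom_len must be >= 10 * repeat_len")
        if self.repeat_copies * self.repeat_len > self.chrom_len:
            raise SimulationError("repeat copies do not fit in chrom_len")


@dataclass
class GenomeMap:
    """Chromosome sequences plus chromosome -> (group, haplotype, subgenome) labels."""

    records: list[SequenceRecord]
    labels: dict[str, tuple[str, int, str | None]]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if set(ids) != set(self.labels):
            missing = set(ids) ^ set(self.labels)
            raise SimulationError(f"labels and sequences disagree on chromosomes: {sorted(missing)}")

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for rec in self.records:
            group, _, _ = self.labels[rec.id]
            out.setdefault(group, []).append(rec.id)
        return out

    def group_labels(self) -> dict[str, str]:
        return {chrom: g for chrom, (g, _, _) in self.labels.items()}

    def subgenome_labels(self) -> dict[str, str | None]:
        return {chrom: s for chrom, (_, _, s) in self.labels.items()}

    def write(self, fasta_path: str | Path, map_path: str | Path) -> None:
        write_fasta(self.records, fasta_path)
        with open(map_path, "w") as fh:
            fh.write("#chrom\tgroup\thaplotype\tsubgenome\n")
            for rec in self.records:
                group, hap, sub = self.labels[rec.id]
                fh.write(f"{rec.id}\t{group}\t{hap}\t{sub if sub else '.'}\n")

    @classmethod
    def from_files(cls, fasta_path: str | Path, map_path: str | Path) -> "GenomeMap":
        records = read_fasta(fasta_path)
        raw = read_tsv_map(map_path)
        if not raw:
            raise SimulationError(f"empty label map {map_path}")
        labels: dict[str, tuple[str, int, str | None]] = {}
        for chrom, fields in raw.items():
            if len(fields) < 2:
                raise SimulationError(f"label map row for {chrom!r} needs group and haplotype")
            sub = fields[2] if len(fields) > 2 and fields[2] not in (".", "") else None
            labels[chrom] = (fields[0], int(fields[1]), sub)
        return cls(records, labels)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


def _mutate(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = arr.copy()
    if rate <= 0:
        return out
    mask = rng.random(out.size) < rate
    n = int(mask.sum())
    if n:
        shift = rng.integers(1, 4, size=n, dtype=np.int8)
        out[mask] = (out[mask] + shift) % 4
    return out


def _place_repeats(arr: np.ndarray, motif: np.ndarray, copies: int, rng: np.random.Generator) -> None:
    """Overwrite *copies* non-overlapping uniformly placed copies of *motif* in place."""
    rlen = motif.size
    free = arr.size - copies * rlen
    if free < 0:
        raise SimulationError("repeat copies do not fit in chromosome")
    offsets = np.sort(rng.integers(0, free + 1, size=copies)) + np.arange(copies) * rlen
    for s in offsets:
        arr[s : s + rlen] = motif


def _decode(arr: np.ndarray) -> str:
    return "".join(_BASES[arr])


def simulate_polyploid_genome(config: SimulationConfig) -> tuple[GenomeMap, dict]:
    """Simulate a labeled polyploid genome; returns (GenomeMap, truth record)."""
    rng = np.random.default_rng(config.seed)
    records: list[SequenceRecord] = []
    labels: dict[str, tuple[str, int, str | None]] = {}
    motifs: dict[str, str] = {}

    if config.mode in ("auto", "diploid"):
        for gi in range(1, config.n_groups + 1):
            group = f"g{gi}"
            ancestor = _random_seq(rng, config.chrom_len)
            motif = _random_seq(rng, config.repeat_len)
            _place_repeats(ancestor, motif, config.repeat_copies, rng)
            motifs[group] = _decode(motif)
            for hi in range(1, config.n_haplotypes + 1):
                hap = _mutate(ancestor, config.d_hap, rng)
                name = f"{group}h{hi}"
                records.append(SequenceRecord(name, _decode(hap)))
                labels[name] = (group, hi, None)
    else:  # allo
        motif_a = _random_seq(rng, config.repeat_len)
        motif_b = _random_seq(rng, config.repeat_len)
        motifs["A"] = _decode(motif_a)
        motifs["B"] = _decode(motif_b)
        for gi in range(1, config.n_groups + 1):
            group = f"g{gi}"
            ancestor = _random_seq(rng, config.chrom_len)
            sub_anc = {
                "A": _mutate(ancestor, config.d_sub / 2, rng),
                "B": _mutate(ancestor, config.d_sub / 2, rng),
            }
            _place_repeats(sub_anc["A"], motif_a, config.repeat_copies, rng)
            _place_repeats(sub_anc["B"], motif_b, config.repeat_copies, rng)
            hi = 0
            for sub in ("A", "B"):
                for _ in range(config.n_haplotypes // 2):
                    hi += 1
                    hap = _mutate(sub_anc[sub], config.d_hap, rng)
                    name = f"{group}h{hi}"
                    records.append(SequenceRecord(name, _decode(hap)))
                    labels[name] = (group, hi, sub)

    truth = {
        "mode": config.mode,
        "labels": dict(labels),
        "repeat_motifs": motifs,
        "config": config,
    }
    return GenomeMap(records, labels), truth


def simulate_reads(
    genome: GenomeMap,
    coverage_per_haplotype: float,
    read_len: int = 150,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str, str]]:
    """Simulate uniform-coverage substitution-error short reads.

    Expected read count per chromosome is ``coverage * chrom_len / read_len``
    (realized by rounding); start positions are uniform, strands random,
    substitution errors i.i.d. at *error_rate*. Returns
    ``(id, seq, qualities)`` tuples ready for :func:`tetrasig.io.write_fastq`.
    """
    if coverage_per_haplotype <= 0:
        raise SimulationError("coverage must be positive")
    if read_len < 21:
        raise SimulationError("read_len must be >= 21")
    rng = np.random.default_rng(seed)
    from .kmers import encode_seq  # local import to avoid cycle at module load

    reads: list[tuple[str, str, str]] = []
    qual = "I" * read_len
    for rec in genome.records:
        L = len(rec.seq)
        if read_len > L:
            raise SimulationError(f"read_len {read_len} exceeds chromosome {rec.id} length {L}")
        arr = encode_seq(rec.seq).astype(np.int8)
        n_reads = int(round(coverage_per_haplotype * L / read_len))
        starts = rng.integers(0, L - read_len + 1, size=n_reads)
        strands = rng.random(n_reads) < 0.5
        for i in range(n_reads):
            frag = arr[starts[i] : starts[i] + read_len]
            if strands[i]:
                frag = (3 - frag)[::-1]
            if error_rate > 0:
                frag = _mutate(frag, error_rate, rng)
            reads.append((f"{rec.id}_r{i}", _decode(frag), qual))
    return reads


# ---------------------------------------------------------------------------
# VCF simulation with a constructed per-rule truth table
# ---------------------------------------------------------------------------

@dataclass
class VcfSimSpec:
    """Generative spec for a filter-cascade test VCF; covers all six rules."""

    n_samples: int = 6
    chroms: tuple[str, ...] = ("chr1", "chr2")
    chrom_len: int = 1_000_000
    depth_mean: float = 30.0
    p_low_depth: float = 0.06
    p_high_depth: float = 0.04
    p_depth_unknown: float = 0.03
    p_sample_dp_only: float = 0.10
    p_multiallelic: float = 0.06
    p_high_missing: float = 0.08
    repeat_fraction: float = 0.10
    repeat_interval_len: int = 2_000
    p_close_pair: float = 0.08
    depth_min: int = 5
    depth_max: int = 1000
    max_missing: float = 0.40
    min_spacing: int = 5

    def __post_init__(self) -> None:
        if self.p_low_depth + self.p_high_depth + self.p_depth_unknown >= 1:
            raise SimulationError("depth category probabilities must sum to < 1")
        if not 0 <= self.repeat_fraction < 1:
            raise SimulationError("repeat_fraction must lie in [0, 1)")
        if self.n_samples < 1:
            raise SimulationError("need at least one sample")


@dataclass
class VcfSimResult:
    variants: VariantSet
    truth: list[str]  # per record: first failing rule name, or "pass"
    repeat_mask: IntervalSet
    spec: VcfSimSpec
    seed: int


def simulate_vcf(n_records: int, spec: VcfSimSpec | None = None, seed: int = 0) -> VcfSimResult:
    """Simulate a sorted VCF plus a constructed truth table for rules 2-6.

    The truth marks each record with the first cascade rule that removes it
    (depth, biallelic, missing, repeat, proximity) or "pass"; it is computed
    from the generated attributes, independently of
    :func:`tetrasig.variants.apply_filters`.
    """
    if spec is None:
        spec = VcfSimSpec()
    if n_records < 1:
        raise SimulationError("n_records must be positive")
    rng = np.random.default_rng(seed)

    # repeat mask
    intervals = []
    for chrom in spec.chroms:
        n_iv = int(spec.repeat_fraction * spec.chrom_len / spec.repeat_interval_len)
        if n_iv:
            free = spec.chrom_len - n_iv * spec.repeat_interval_len
            starts = np.sort(rng.integers(0, free + 1, size=n_iv)) + np.arange(n_iv) * spec.repeat_interval_len
            intervals.extend(
                (chrom, int(s), int(s) + spec.repeat_interval_len) for s in starts
            )
    mask = IntervalSet.from_intervals(intervals) if intervals else IntervalSet()

    # positions: widely spaced anchors, plus deliberate close partners
    n_pairs = int(round(spec.p_close_pair * n_records / 2))
    n_anchor = n_records - n_pairs
    per_chrom = np.array_split(np.arange(n_anchor), len(spec.chroms))
    positions: list[tuple[str, int]] = []
    for chrom, idx in zip(spec.chroms, per_chrom):
        m = len(idx)
        if m == 0:
            continue
        # cumulative gaps >= 2*min_spacing keep anchors non-adjacent
        gaps = rng.integers(2 * spec.min_spacing, 60, size=m)
        pos = np.cumsum(gaps) + rng.integers(1, 1000)
        positions.extend((chrom, int(p)) for p in pos)
    anchors_for_pairs = rng.choice(len(positions), size=n_pairs, replace=False) if n_pairs else []
    for ai in anchors_for_pairs:
        chrom, p = positions[ai]
        positions.append((chrom, p + int(rng.integers(1, spec.min_spacing))))
    positions.sort()

    pos_list_by_chrom: dict[str, list[int]] = {}
    for chrom, p in positions:
        pos_list_by_chrom.setdefault(chrom, []).append(p)

    bases = "ACGT"
    records: list[VariantRecord] = []
    truth: list[str] = []
    max_ok_missing = int(np.floor(spec.max_missing * spec.n_samples))

    for chrom, pos in positions:
        u = rng.random()
        if u < spec.p_low_depth:
            depth: int | None = int(rng.integers(0, spec.depth_min))
        elif u < spec.p_low_depth + spec.p_high_depth:
            depth = int(rng.integers(spec.depth_max + 1, spec.depth_max * 3))
        elif u < spec.p_low_depth + spec.p_high_depth + spec.p_depth_unknown:
            depth = None
        else:
            depth = int(np.clip(rng.poisson(spec.depth_mean), spec.depth_min, spec.depth_max))

        ref = bases[rng.integers(0, 4)]
        others = [b for b in bases if b != ref]
        if rng.random() < spec.p_multiallelic:
            alts = tuple(rng.choice(others, size=2, replace=False))
        else:
            alts = (others[rng.integers(0, 3)],)

        if rng.random() < spec.p_high_missing:
            k_missing = int(rng.integers(max_ok_missing + 1, spec.n_samples + 1))
        else:
            k_missing = int(rng.integers(0, max_ok_missing + 1))
        gts = []
        missing_slots = set(rng.choice(spec.n_samples, size=k_missing, replace=False))
        for si in range(spec.n_samples):
            if si in missing_slots:
                gts.append("./.")
            else:
                a = int(rng.integers(0, len(alts) + 1))
                b = int(rng.integers(0, len(alts) + 1))
                gts.append(f"{min(a, b)}/{max(a, b)}")

        sample_depths: tuple[int | None, ...] | None = None
        if depth is not None and rng.random() < spec.p_sample_dp_only:
            splits = rng.multinomial(depth, np.full(spec.n_samples, 1 / spec.n_samples))
            sample_depths = tuple(int(x) for x in splits)

        records.append(
            VariantRecord(chrom, pos, ref, alts, depth=depth, genotypes=tuple(gts),
                          sample_depths=sample_depths)
        )

        # constructed truth, cascade order 2 -> 6
        if depth is None or depth < spec.depth_min or depth > spec.depth_max:
            truth.append("depth")
        elif len(alts) != 1:
            truth.append("biallelic")
        elif k_missing / spec.n_samples > spec.max_missing:
            truth.append("missing")
        elif mask.contains_1based(chrom, pos):
            truth.append("repeat")
        else:
            plist = pos_list_by_chrom[chrom]
            close = any(q != pos and abs(q - pos) < spec.min_spacing for q in plist)
            truth.append("proximity" if close else "pass")

    samples = tuple(f"s{i+1}" for i in range(spec.n_samples))
    vs = VariantSet(records, samples=samples, provenance="single")
    return VcfSimResult(vs, truth, mask, spec, seed)
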