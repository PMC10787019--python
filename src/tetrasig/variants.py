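"""Variant domain types, VCF reading/writing, and the six-rule hard-filter cascade.

The cascade applies, in order: call-set intersection (rule 1, via
:func:`intersect_callsets`), then per-record rules 2-6 of
:func:`apply_filters` — depth bounds, biallelic, missing rate, repeat mask,
and proximity to any other variant of the *original* input. Each record is
removed at most once, at its first failing rule.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np


class VariantError(ValueError):
    pass


MISSING_GT = "./."

#: cascade order of the per-record rules (rule 1 is the intersection step)
RULES = ("depth", "biallelic", "missing", "repeat", "proximity")


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    depth: int | None = None  # site depth; None = depth-unknown
    genotypes: tuple[str, ...] = ()
    sample_depths: tuple[int | None, ...] | None = None
    record_id: str = "."

    @property
    def missing_fraction(self) -> float:
        if not self.genotypes:
            return 0.0
        missing = sum(1 for g in self.genotypes if _gt_is_missing(g))
        return missing / len(self.genotypes)

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    def key(self) -> tuple[str, int, str, frozenset]:
        return (self.chrom, self.pos, self.ref, frozenset(self.alts))


def _gt_is_missing(gt: str) -> bool:
    alleles = gt.replace("|", "/").split("/")
    return all(a == "." for a in alleles)


@dataclass
class VariantSet:
    records: list[VariantRecord]
    samples: tuple[str, ...] = ()
    provenance: str = "single"

    def __len__(self) -> int:
        return len(self.records)

    def is_sorted(self) -> bool:
        keys = [(r.chrom, r.pos) for r in self.records]
        return keys == sorted(keys)

    def sort(self) -> "VariantSet":
        self.records.sort(key=lambda r: (r.chrom, r.pos))
        return self


def _prescan_vcf(path: str | Path) -> None:
    """Cheap structural check so malformed lines fail with a line number."""
    with open(path) as fh:
        saw_fileformat = False
        for lineno, line in enumerate(fh, 1):
            if line.startswith("##"):
                if line.startswith("##fileformat"):
                    saw_fileformat = True
                continue
            if line.startswith("#CHROM"):
                continue
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise VariantError(
                    f"{path}:{lineno}: malformed VCF line ({len(fields)} fields, need >=8)"
                )
            try:
                int(fields[1])
            except ValueError as exc:
                raise VariantError(f"{path}:{lineno}: non-integer POS {fields[1]!r}") from exc
        if not saw_fileformat:
            raise VariantError(f"{path}: missing ##fileformat header")


def read_vcf(path: str | Path) -> VariantSet:
    """Read a VCF 4.x file.

    Site depth resolves INFO/DP first, else the sum of per-sample FORMAT/DP;
    records with neither are depth-unknown (``depth=None``).
    """
    from cyvcf2 import VCF

    _prescan_vcf(path)
    vcf = VCF(str(path))
    samples = tuple(vcf.samples)
    records: list[VariantRecord] = []
    for v in vcf:
        info_dp = v.INFO.get("DP")
        sample_depths: tuple[int | None, ...] | None = None
        fmt_dp = None
        try:
            fmt_dp = v.format("DP")
        except KeyError:
            fmt_dp = None
        if fmt_dp is not None:
            flat = fmt_dp.reshape(-1)
            sample_depths = tuple(int(d) if d >= 0 else None for d in flat)
        if info_dp is not None:
            depth = int(info_dp)
        elif sample_depths is not None and any(d is not None for d in sample_depths):
            depth = sum(d for d in sample_depths if d is not None)
        else:
            depth = None
        gts = []
        for g in v.genotypes:
            alleles = g[:-1]
            sep = "|" if g[-1] else "/"
            gts.append(sep.join("." if a < 0 else str(a) for a in alleles))
        records.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alts=tuple(v.ALT),
                depth=depth,
                genotypes=tuple(gts),
                sample_depths=sample_depths,
                record_id=v.ID or ".",
            )
        )
    vcf.close()
    return VariantSet(records, samples=samples)


def write_vcf(
    vs: VariantSet,
    path: str | Path,
    reasons: Sequence[str | None] | None = None,
) -> None:
    """Write a minimal VCF 4.2 file; *reasons* annotates the FILTER column."""
    chroms: list[str] = []
    for r in vs.records:
        if r.chrom not in chroms:
            chroms.append(r.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Sample read depth">\n')
        for rule in RULES:
            fh.write(f'##FILTER=<ID={rule},Description="Removed by {rule} rule">\n')
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if vs.samples:
            cols += ["FORMAT", *vs.samples]
        fh.write("\t".join(cols) + "\n")
        for i, r in enumerate(vs.records):
            filt = "."
            if reasons is not None:
                filt = reasons[i] if reasons[i] else "PASS"
            has_sample_dp = r.sample_depths is not None
            if has_sample_dp:
                info = "."
                fmt = "GT:DP"
                sample_cols = [
                    f"{gt}:{'.' if d is None else d}"
                    for gt, d in zip(r.genotypes, r.sample_depths)
                ]
            else:
                info = "." if r.depth is None else f"DP={r.depth}"
                fmt = "GT"
                sample_cols = list(r.genotypes)
            row = [r.chrom, str(r.pos), r.record_id, r.ref, ",".join(r.alts), ".", filt, info]
            if vs.samples:
                row.append(fmt)
                row.extend(sample_cols)
            fh.write("\t".join(row) + "\n")


def intersect_callsets(a: VariantSet, b: VariantSet) -> VariantSet:
    """Keep records present in both call sets on (chrom, pos, ref, alt-set).

    Depth and genotypes are taken from *a*. Both inputs must be sorted.
    """
    for name, vs in (("a", a), ("b", b)):
        if not vs.is_sorted():
            raise VariantError(f"call set {name!r} is not sorted by (chrom, pos)")
    keys_b = {r.key() for r in b.records}
    kept = [r for r in a.records if r.key() in keys_b]
    return VariantSet(kept, samples=a.samples, provenance="intersection")


@dataclass
class FilterParams:
    depth_min: int = 5
    depth_max: int = 1000
    max_missing: float = 0.40
    min_spacing: int = 5
    repeat_mask: object | None = None  # IntervalSet (duck-typed: contains_1based)
    neighbors_snps_only: bool = False

    def __post_init__(self) -> None:
        if self.depth_min >= self.depth_max:
            raise VariantError("depth_min must be < depth_max")
        if not 0 < self.max_missing < 1:
            raise VariantError("max_missing must lie in (0, 1)")
        if self.min_spacing < 1:
            raise VariantError("min_spacing must be >= 1")


@dataclass
class FilterReport:
    input_count: int
    removed: dict[str, int]
    depth_unknown: int
    survivors: VariantSet
    reasons: list[str | None]
    params: FilterParams

    def to_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "removed_per_rule": dict(self.removed),
            "depth_unknown": self.depth_unknown,
            "surviving": len(self.survivors),
            "params": {
                "depth_min": self.params.depth_min,
                "depth_max": self.params.depth_max,
                "max_missing": self.params.max_missing,
                "min_spacing": self.params.min_spacing,
                "repeat_mask_intervals": (
                    len(self.params.repeat_mask) if self.params.repeat_mask is not None else 0
                ),
            },
        }


def _is_snp(r: VariantRecord) -> bool:
    return len(r.ref) == 1 and all(len(a) == 1 for a in r.alts)


def apply_filters(vs: VariantSet, params: FilterParams) -> FilterReport:
    """Apply hard-filter rules 2-6 as an ordered cascade.

    Rules, in order: depth outside [depth_min, depth_max] (depth-unknown
    fails, counted separately); non-biallelic; missing-genotype fraction
    above max_missing; position inside the repeat mask; and proximity —
    another record of the ORIGINAL input (both members of a close pair)
    within ``min_spacing`` - 1 bp on the same chromosome.
    """
    records = vs.records
    reasons: list[str | None] = [None] * len(records)
    removed = {rule: 0 for rule in RULES}
    depth_unknown = 0

    # proximity is measured against every record of the original input
    neighbor_pool = records if not params.neighbors_snps_only else [r for r in records if _is_snp(r)]
    pos_by_chrom: dict[str, list[int]] = {}
    for r in neighbor_pool:
        pos_by_chrom.setdefault(r.chrom, []).append(r.pos)
    for positions in pos_by_chrom.values():
        positions.sort()

    def has_close_neighbor(r: VariantRecord) -> bool:
        positions = pos_by_chrom.get(r.chrom, [])
        lo = bisect.bisect_left(positions, r.pos - params.min_spacing + 1)
        hi = bisect.bisect_right(positions, r.pos + params.min_spacing - 1)
        n_in_window = hi - lo
        # subtract self (present in the pool unless restricted to SNPs)
        if not params.neighbors_snps_only or _is_snp(r):
            n_in_window -= 1
        return n_in_window > 0

    for i, r in enumerate(records):
        if r.depth is None:
            reasons[i] = "depth"
            depth_unknown += 1
        elif r.depth < params.depth_min or r.depth > params.depth_max:
            reasons[i] = "depth"
        elif not r.is_biallelic:
            reasons[i] = "biallelic"
        elif r.missing_fraction > params.max_missing:
            reasons[i] = "missing"
        elif params.repeat_mask is not None and params.repeat_mask.contains_1based(r.chrom, r.pos):
            reasons[i] = "repeat"
        elif has_close_neighbor(r):
            reasons[i] = "proximity"
        if reasons[i] is not None:
            removed[reasons[i]] += 1

    survivors = VariantSet(
        [r for i, r in enumerate(records) if reasons[i] is None],
        samples=vs.samples,
        provenance=vs.provenance,
    )
    return FilterReport(
        input_count=len(records),
        removed=removed,
        depth_unknown=depth_unknown,
        survivors=survivors,
        reasons=reasons,
        params=params,
    )
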