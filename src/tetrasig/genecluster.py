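"""Tandem gene-cluster calling: maximal runs of family genes within a gap cap.

A cluster is a maximal chain of >= ``min_size`` consecutive family genes on
one chromosome whose successive gaps never exceed ``max_gap`` (defaults: 3
genes, 0.8 Mb). "Consecutive" means consecutive among the FAMILY members in
coordinate order — non-family genes may be interleaved unless
``strict_adjacency`` is set. Strand is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import FeatureRecord


class GeneClusterError(ValueError):
    pass


@dataclass(frozen=True)
class GeneCluster:
    chrom: str
    members: tuple[str, ...]  # gene ids in coordinate order
    start: int  # 1-based, first member start
    end: int  # 1-based, last member end
    max_gap_observed: int

    @property
    def n_members(self) -> int:
        return len(self.members)


def _gap(prev: FeatureRecord, nxt: FeatureRecord, gap_mode: str) -> int:
    if gap_mode == "start_to_start":
        return nxt.start - prev.start
    return max(nxt.start - prev.end - 1, 0)  # end_to_start, floor 0 for overlaps


def find_clusters(
    features: Sequence[FeatureRecord],
    family_ids: Iterable[str],
    min_size: int = 3,
    max_gap: int = 800_000,
    gap_mode: str = "end_to_start",
    strict_adjacency: bool = False,
) -> list[GeneCluster]:
    """Call maximal family gene clusters per chromosome.

    Raises :class:`GeneClusterError` when a family id is absent from the
    features, listing the missing ids.
    """
    if gap_mode not in ("end_to_start", "start_to_start"):
        raise GeneClusterError(f"unknown gap_mode {gap_mode!r}")
    if min_size < 1:
        raise GeneClusterError("min_size must be >= 1")
    family = set(family_ids)
    genes = [f for f in features if f.feature_type == "gene"]
    known = {g.feature_id for g in genes}
    missing = sorted(family - known)
    if missing:
        raise GeneClusterError(f"family ids absent from features: {missing}")

    by_chrom: dict[str, list[FeatureRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    clusters: list[GeneCluster] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.feature_id))
        fam_genes = [g for g in ordered if g.feature_id in family]
        if not fam_genes:
            continue
        if strict_adjacency:
            # break chains wherever a non-family gene interleaves
            index_of = {g.feature_id: i for i, g in enumerate(ordered)}
            adjacent_ok = [
                index_of[b.feature_id] - index_of[a.feature_id] == 1
                for a, b in zip(fam_genes, fam_genes[1:])
            ]
        else:
            adjacent_ok = [True] * (len(fam_genes) - 1)

        chain: list[FeatureRecord] = [fam_genes[0]]
        gaps: list[int] = []

        def flush() -> None:
            if len(chain) >= min_size:
                clusters.append(
                    GeneCluster(
                        chrom=chrom,
                        members=tuple(g.feature_id for g in chain),
                        start=chain[0].start,
                        end=chain[-1].end,
                        max_gap_observed=max(gaps) if gaps else 0,
                    )
                )

        for i, nxt in enumerate(fam_genes[1:]):
            g = _gap(chain[-1], nxt, gap_mode)
            if g <= max_gap and adjacent_ok[i]:
                chain.append(nxt)
                gaps.append(g)
            else:
                flush()
                chain = [nxt]
                gaps = []
        flush()
    return clusters


def clusters_to_tsv(clusters: Sequence[GeneCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tn_members\tmax_gap\tmembers\n")
        for c in clusters:
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.n_members}\t{c.max_gap_observed}\t"
                + ",".join(c.members)
                + "\n"
            )


def clusters_to_bed(clusters: Sequence[GeneCluster], path) -> None:
    with open(path, "w") as fh:
        for c in clusters:
            fh.write(f"{c.chrom}\t{c.start - 1}\t{c.end}\t{'|'.join(c.members)}\n")
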