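"""Chromosome clustering on enriched-k-mer profiles and the ploidy-origin call.

Chromosomes are clustered by average-linkage (UPGMA) on a profile distance
(Bray-Curtis by default). A homologous group is *monophyletic* when some
clade's leaf set equals exactly the group's chromosomes; the fraction of
monophyletic groups S drives the verdict: auto when every group co-clusters
(S >= threshold), allo when the 2-cut of the tree splits each group into two
equal halves (chromosomes cluster by subgenome instead), else ambiguous.
A seeded permutation null (group labels shuffled over leaves) calibrates S.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from .enrich import ProfileMatrix


class ClusterError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ClusterError("distance matrix shape does not match labels")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\t" + "\t".join(self.labels) + "\n")
            for i, lab in enumerate(self.labels):
                fh.write(lab + "\t" + "\t".join(f"{x:.10g}" for x in self.values[i]) + "\n")


METRICS = ("braycurtis", "jaccard_presence", "one_minus_spearman")


def chromosome_distance(profile: ProfileMatrix, metric: str = "braycurtis") -> DistanceMatrix:
    """Pairwise chromosome distances over the profile matrix, in [0, 1]."""
    if metric not in METRICS:
        raise ClusterError(f"unknown metric {metric!r}; choose from {METRICS}")
    rows = np.asarray(profile.values, dtype=np.float64)
    if rows.shape[0] < 2:
        raise ClusterError("need at least 2 chromosomes")
    zero = np.nonzero(rows.sum(axis=1) == 0)[0]
    if zero.size:
        raise ClusterError(f"all-zero profile row for chromosome {profile.chroms[int(zero[0])]!r}")
    if metric == "braycurtis":
        dist = squareform(pdist(rows, metric="braycurtis"))
    elif metric == "jaccard_presence":
        dist = squareform(pdist(rows > 0, metric="jaccard"))
    else:
        rho = spearmanr(rows, axis=1).statistic
        rho = np.atleast_2d(rho)
        if rho.shape != (rows.shape[0], rows.shape[0]):  # 2-row case returns a scalar
            r = float(rho.ravel()[0])
            rho = np.array([[1.0, r], [r, 1.0]])
        dist = (1.0 - rho) / 2.0
        np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(list(profile.chroms), np.clip(dist, 0.0, 1.0))


@dataclass
class TreeNode:
    height: float
    name: str | None = None
    children: tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> frozenset:
        if self.is_leaf:
            return frozenset([self.name])
        out: set = set()
        for c in self.children:
            out |= c.leaves()
        return frozenset(out)

    def to_newick(self) -> str:
        return self._newick_inner(parent_height=None) + ";"

    def _newick_inner(self, parent_height: float | None) -> str:
        if self.is_leaf:
            body = _quote_label(self.name)
        else:
            inner = ",".join(c._newick_inner(self.height) for c in self.children)
            body = f"({inner})"
        if parent_height is None:
            return body
        return f"{body}:{max(parent_height - self.height, 0.0):.10g}"


def _quote_label(name: str) -> str:
    if any(ch in name for ch in "(),:;'\" \t[]"):
        return "'" + name.replace("'", "''") + "'"
    return name


@dataclass
class ChromosomeTree:
    """Rooted ultrametric hierarchy over chromosomes (UPGMA heights)."""

    root: TreeNode
    leaf_names: list[str]

    def clades(self) -> set[frozenset]:
        out: set[frozenset] = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.add(node.leaves())
            stack.extend(node.children)
        return out

    def two_cut(self) -> tuple[frozenset, frozenset]:
        if self.root.is_leaf or len(self.root.children) != 2:
            raise ClusterError("tree root is not a binary split")
        a, b = self.root.children
        return a.leaves(), b.leaves()

    def cophenetic_matrix(self) -> DistanceMatrix:
        n = len(self.leaf_names)
        idx = {name: i for i, name in enumerate(self.leaf_names)}
        dist = np.zeros((n, n))

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            sets = [walk(c) for c in node.children]
            for sa, sb in itertools.combinations(sets, 2):
                for x in sa:
                    for y in sb:
                        dist[idx[x], idx[y]] = dist[idx[y], idx[x]] = 2.0 * node.height
            return frozenset().union(*sets)

        walk(self.root)
        return DistanceMatrix(list(self.leaf_names), dist)

    def to_newick(self) -> str:
        return self.root.to_newick()


def cluster_chromosomes(dist: DistanceMatrix) -> ChromosomeTree:
    """Average-linkage (UPGMA) tree with deterministic lexicographic tie-breaking."""
    n = len(dist.labels)
    if n < 2:
        raise ClusterError("need at least 2 leaves to cluster")
    # active clusters: id -> (min leaf label, size, node)
    clusters: dict[int, tuple[str, int, TreeNode]] = {
        i: (lab, 1, TreeNode(0.0, name=lab)) for i, lab in enumerate(dist.labels)
    }
    d: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = float(dist.values[i, j])
    next_id = n
    while len(clusters) > 1:
        best = None
        for (i, j), val in d.items():
            li = min(clusters[i][0], clusters[j][0])
            lj = max(clusters[i][0], clusters[j][0])
            key = (val, li, lj)
            if best is None or key < best[0]:
                best = (key, i, j)
        (val, _, _), i, j = best
        li, ni, nodei = clusters[i]
        lj, nj, nodej = clusters[j]
        first, second = (nodei, nodej) if li <= lj else (nodej, nodei)
        merged = TreeNode(val / 2.0, children=(first, second))
        new_id = next_id
        next_id += 1
        del clusters[i], clusters[j]
        newd: dict[tuple[int, int], float] = {}
        for (a, b), v in d.items():
            if i in (a, b) or j in (a, b):
                continue
            newd[(a, b)] = v
        for kid, (_, nk, _) in clusters.items():
            dik = d[(min(i, kid), max(i, kid))]
            djk = d[(min(j, kid), max(j, kid))]
            newd[(min(kid, new_id), max(kid, new_id))] = (ni * dik + nj * djk) / (ni + nj)
        clusters[new_id] = (min(li, lj), ni + nj, merged)
        d = newd
    (_, _, root) = next(iter(clusters.values()))
    return ChromosomeTree(root, list(dist.labels))


@dataclass
class PloidyCall:
    verdict: str  # auto | allo | ambiguous
    per_group: dict[str, bool]
    score: float
    subgenome_score: float
    permutation_p: float
    n_permutations: int
    auto_threshold: float

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "per_group_monophyletic": dict(sorted(self.per_group.items())),
            "score": self.score,
            "subgenome_score": self.subgenome_score,
            "permutation_p": self.permutation_p,
            "n_permutations": self.n_permutations,
            "auto_threshold": self.auto_threshold,
        }


def _monophyly_score(groups: Mapping[str, frozenset], clades: set[frozenset]) -> tuple[float, dict[str, bool]]:
    per_group = {g: (leafset in clades) for g, leafset in groups.items()}
    score = sum(per_group.values()) / len(per_group)
    return score, per_group


def classify_origin(
    tree: ChromosomeTree,
    group_labels: Mapping[str, str],
    auto_threshold: float = 1.0,
    n_permutations: int = 1000,
    seed: int = 0,
    subgenome_labels: Mapping[str, str | None] | None = None,
) -> PloidyCall:
    """Classify a clustered genome as auto-, allo-polyploid or ambiguous.

    *group_labels* maps every leaf to its homologous group. When
    *subgenome_labels* is given the subgenome score uses those truth labels;
    otherwise the candidate subgenomes from the tree's 2-cut are used.
    """
    leaves = list(tree.leaf_names)
    unlabeled = [lf for lf in leaves if lf not in group_labels]
    if unlabeled:
        raise ClusterError(f"unlabeled leaves: {unlabeled}")
    groups: dict[str, frozenset] = {}
    for leaf in leaves:
        groups.setdefault(group_labels[leaf], set()).add(leaf)  # type: ignore[arg-type]
    groups = {g: frozenset(m) for g, m in groups.items()}
    small = [g for g, m in groups.items() if len(m) < 2]
    if small:
        raise ClusterError(f"groups of size 1 cannot be tested: {small}")

    clades = tree.clades()
    score, per_group = _monophyly_score(groups, clades)

    if score >= auto_threshold:
        verdict = "auto"
    else:
        c1, c2 = tree.two_cut()
        ok = 0
        for leafset in groups.values():
            if len(leafset) % 2 == 0 and len(leafset & c1) == len(leafset) // 2:
                ok += 1
        verdict = "allo" if ok / len(groups) >= auto_threshold else "ambiguous"

    # subgenome score: fraction of leaves whose nearest neighbour shares a subgenome
    if subgenome_labels is not None and any(v for v in subgenome_labels.values()):
        sub_of = {lf: subgenome_labels.get(lf) for lf in leaves}
    else:
        c1, c2 = tree.two_cut()
        sub_of = {lf: ("S1" if lf in c1 else "S2") for lf in leaves}
    coph = tree.cophenetic_matrix()
    order = {lab: i for i, lab in enumerate(coph.labels)}
    hits = 0
    for leaf in leaves:
        i = order[leaf]
        d = coph.values[i].copy()
        d[i] = np.inf
        # deterministic nearest neighbour: min distance, ties by label
        cands = np.nonzero(d == d.min())[0]
        nn = min(coph.labels[int(c)] for c in cands)
        if sub_of[nn] is not None and sub_of[nn] == sub_of[leaf]:
            hits += 1
    subgenome_score = hits / len(leaves)

    # permutation null: shuffle group labels over leaves, preserving sizes
    rng = np.random.default_rng(seed)
    label_vec = [group_labels[lf] for lf in leaves]
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(leaves))
        shuffled: dict[str, set] = {}
        for pos, leaf_idx in enumerate(perm):
            shuffled.setdefault(label_vec[pos], set()).add(leaves[leaf_idx])
        s_star = sum(frozenset(m) in clades for m in shuffled.values()) / len(shuffled)
        if s_star >= score - 1e-12:
            exceed += 1
    permutation_p = exceed / n_permutations if n_permutations else float("nan")

    return PloidyCall(
        verdict=verdict,
        per_group=per_group,
        score=score,
        subgenome_score=subgenome_score,
        permutation_p=permutation_p,
        n_permutations=n_permutations,
        auto_threshold=auto_threshold,
    )
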