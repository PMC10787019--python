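"""Heterozygous k-mer pair ("smudge") analysis of read k-mer tables.

Pairs are two k-mers that differ at exactly one (by default, the middle)
position after orientation canonicalization, both within a coverage window
[L, U]. Each pair is summarized by its total coverage T = covA + covB and
minor fraction f = covB / T; a genome of n copies with the minor allele on b
copies concentrates pairs near (n*c, b/n) where c is the 1x (per-copy)
k-mer coverage. The dominant pattern over all tested pairs is the ploidy
signature (AAAB for a highly heterozygous auto-tetraploid, AB for a
diploid, AABB for an allo-tetraploid with diverged subgenomes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .kmers import KmerCountTable, decode_kmer


class SmudgeError(ValueError):
    pass


@dataclass(frozen=True)
class KmerPair:
    kmerA: str  # dominant
    kmerB: str  # minor
    covA: int
    covB: int

    def __post_init__(self) -> None:
        if not self.covA >= self.covB >= 1:
            raise SmudgeError("pair requires covA >= covB >= 1")

    @property
    def total(self) -> int:
        return self.covA + self.covB

    @property
    def minor_fraction(self) -> float:
        return self.covB / (self.covA + self.covB)


def pattern_name(n: int, b: int) -> str:
    return "A" * (n - b) + "B" * b


def _patterns(max_n: int = 8) -> list[tuple[int, int]]:
    out = []
    for n in range(2, max_n + 1):
        for b in range(1, n // 2 + 1):
            out.append((n, b))
    return out


def _revcomp_codes(codes: np.ndarray, length: int) -> np.ndarray:
    res = np.zeros_like(codes)
    c = codes.copy()
    for _ in range(length):
        res = (res << 2) | (3 - (c & 3))
        c >>= 2
    return res


def _mask_position(codes: np.ndarray, k: int, pos: int) -> np.ndarray:
    """Remove the base at 0-based position *pos* (from the left) of each code."""
    right = k - 1 - pos  # digits to the right of pos
    lo = codes & ((np.int64(1) << (2 * right)) - 1) if right else np.zeros_like(codes)
    hi = codes >> (2 * (right + 1))
    return (hi << (2 * right)) | lo


def find_het_pairs(
    read_table: KmerCountTable,
    L: int = 10,
    U: int = 1000,
    pairing: str = "middle_only",
) -> list[KmerPair]:
    """Extract heterozygous k-mer pairs from a read k-mer table.

    Considers only k-mers with count in [L, U]; groups them by the
    orientation-canonicalized sequence with the paired position masked and
    emits one pair per mask family of exactly two members. The dominant
    member A is the higher-count k-mer (ties: lexicographically smaller is A).
    """
    if not 1 <= L < U:
        raise SmudgeError("require 1 <= L < U")
    if pairing not in ("middle_only", "any_position"):
        raise SmudgeError(f"unknown pairing {pairing!r}")
    k = read_table.k
    counts = read_table.global_counts
    sel = (counts >= L) & (counts <= U)
    codes = read_table.codes[sel]
    cnts = counts[sel]
    if codes.size < 2:
        return []
    positions = [k // 2] if pairing == "middle_only" else list(range(k))
    seen: set[tuple[int, int]] = set()
    pairs: list[KmerPair] = []
    for pos in positions:
        masked = _mask_position(codes, k, pos)
        rc_masked = _revcomp_codes(masked, k - 1)
        key = np.minimum(masked, rc_masked)
        order = np.argsort(key, kind="stable")
        sk = key[order]
        # run boundaries
        boundaries = np.nonzero(np.diff(sk))[0] + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [sk.size]))
        for s, e in zip(starts, ends):
            if e - s != 2:
                continue
            i, j = order[s], order[e - 1]
            ci, cj = int(cnts[i]), int(cnts[j])
            codei, codej = int(codes[i]), int(codes[j])
            if (ci, -codei) < (cj, -codej):
                i, j = j, i
                ci, cj = cj, ci
                codei, codej = codej, codei
            pk = (min(codei, codej), max(codei, codej))
            if pk in seen:
                continue
            seen.add(pk)
            pairs.append(KmerPair(decode_kmer(codei, k), decode_kmer(codej, k), ci, cj))
    pairs.sort(key=lambda p: (p.kmerA, p.kmerB))
    return pairs


def _match_fraction(T: np.ndarray, f: np.ndarray, c: float, tol: float, max_n: int) -> float:
    matched = np.zeros(T.size, dtype=bool)
    for n, b in _patterns(max_n):
        exp_t = n * c
        exp_f = b / n
        ok = (np.abs(T - exp_t) <= tol * exp_t) & (np.abs(f - exp_f) <= tol * exp_f)
        matched |= ok
    return float(matched.mean())


def peak_coverage_estimate(pairs: Sequence[KmerPair]) -> float:
    """Anchor c at the smoothed mode of the minor coverage covB.

    In the dominant smudge of most genomes (AB, AAB, AAAB, ...) the minor
    allele sits on a single genome copy, so the covB mode estimates the 1x
    coverage directly. This sidesteps the scale ambiguity of pure pattern
    grid fitting, where every pattern (n, b) at coverage c is mimicked
    exactly by (2n, 2b) at c/2 and grids drift toward small c. Known
    limitation: a genome whose dominant smudge has a 2-copy minor (balanced
    AABB) is read at half its true coverage.
    """
    minor = np.array([p.covB for p in pairs], dtype=np.int64)
    hist = np.bincount(minor)
    sm = np.convolve(hist, np.ones(5), mode="same") if hist.size > 5 else hist.astype(float)
    return float(max(int(np.argmax(sm)), 2))


def default_coverage_grid(pairs: Sequence[KmerPair], span: tuple[float, float] = (0.95, 1.05)) -> np.ndarray:
    """Narrow grid of candidate 1x coverages around the peak-anchored estimate."""
    c0 = peak_coverage_estimate(pairs)
    step = max(0.25, c0 / 200.0)
    return np.arange(span[0] * c0, span[1] * c0 + step, step)


def estimate_1x_coverage(
    pairs: Sequence[KmerPair],
    c_grid: np.ndarray | Sequence[float] | None = None,
    tol: float = 0.2,
    max_n: int = 8,
    min_pairs: int = 100,
) -> float:
    """Grid-fit the 1x coverage: argmax over c of the fraction of pairs within
    relative tolerance *tol* of some pattern point (n*c, b/n), n <= max_n.
    Ties return the smaller c. With ``c_grid=None`` the grid comes from
    :func:`default_coverage_grid`.
    """
    if len(pairs) < min_pairs:
        raise SmudgeError(f"too few pairs ({len(pairs)} < {min_pairs}) to estimate coverage")
    if c_grid is None:
        # the peak anchor alone; wider grids drift low because smaller c offers
        # more pattern points per pair (see peak_coverage_estimate)
        return peak_coverage_estimate(pairs)
    c_grid = np.asarray(c_grid, dtype=np.float64)
    if c_grid.size == 0:
        raise SmudgeError("empty coverage grid")
    T = np.array([p.total for p in pairs], dtype=np.float64)
    f = np.array([p.minor_fraction for p in pairs], dtype=np.float64)
    best_c, best_frac = None, -1.0
    for c in np.sort(c_grid):
        frac = _match_fraction(T, f, float(c), tol, max_n)
        if frac > best_frac + 1e-12:  # strict improvement: ties keep smaller c
            best_c, best_frac = float(c), frac
    return best_c


@dataclass
class SmudgeReport:
    c_hat: float
    n_pairs_tested: int
    counts: dict[str, int]  # pattern name -> assigned pairs
    unassigned: int
    dominant: str | None
    params: dict
    #: c_hat rescaled from k-mer coverage to per-copy read depth by the
    #: edge factor read_len / (read_len - k + 1); set by the pipeline when
    #: the read length is known.
    c_hat_base: float | None = None

    @property
    def proportions(self) -> dict[str, float]:
        if self.n_pairs_tested == 0:
            return {}
        return {name: c / self.n_pairs_tested for name, c in self.counts.items()}

    def to_dict(self) -> dict:
        return {
            "c_hat": self.c_hat,
            "c_hat_base": self.c_hat_base,
            "n_pairs_tested": self.n_pairs_tested,
            "pattern_counts": dict(sorted(self.counts.items())),
            "pattern_proportions": {k: v for k, v in sorted(self.proportions.items())},
            "unassigned": self.unassigned,
            "dominant_pattern": self.dominant,
            "params": self.params,
        }


def assign_patterns(
    pairs: Sequence[KmerPair],
    c_hat: float,
    tol: float = 0.2,
    max_n: int = 8,
) -> SmudgeReport:
    """Assign each pair to the nearest pattern (n, b), n <= max_n.

    Distance is max(|T - n*c|/(n*c), |f - b/n|/(b/n)); pairs farther than
    *tol* from every pattern stay unassigned. Ties prefer the smaller n,
    then the smaller b.
    """
    if c_hat <= 0:
        raise SmudgeError("c_hat must be positive")
    T = np.array([p.total for p in pairs], dtype=np.float64)
    f = np.array([p.minor_fraction for p in pairs], dtype=np.float64)
    n_pairs = len(pairs)
    best_d = np.full(n_pairs, np.inf)
    best_idx = np.full(n_pairs, -1)
    pats = _patterns(max_n)
    for pi, (n, b) in enumerate(pats):  # pats ordered by (n, b): first win = smallest
        exp_t = n * c_hat
        exp_f = b / n
        d = np.maximum(np.abs(T - exp_t) / exp_t, np.abs(f - exp_f) / exp_f)
        better = d < best_d - 1e-12
        best_d[better] = d[better]
        best_idx[better] = pi
    counts: dict[str, int] = {}
    unassigned = 0
    for i in range(n_pairs):
        if best_idx[i] < 0 or best_d[i] > tol:
            unassigned += 1
            continue
        n, b = pats[int(best_idx[i])]
        name = pattern_name(n, b)
        counts[name] = counts.get(name, 0) + 1
    dominant = None
    if counts:
        dominant = max(sorted(counts), key=lambda nm: counts[nm])
    return SmudgeReport(
        c_hat=float(c_hat),
        n_pairs_tested=n_pairs,
        counts=counts,
        unassigned=unassigned,
        dominant=dominant,
        params={"tol": tol, "max_n": max_n},
    )


def smudge_histogram(
    pairs: Sequence[KmerPair],
    T_bins: int = 40,
    f_bins: int = 25,
    T_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2D histogram over (total coverage, minor fraction); counts are conserved."""
    if T_bins < 1 or f_bins < 1:
        raise SmudgeError("bin counts must be positive")
    T = np.array([p.total for p in pairs], dtype=np.float64)
    f = np.array([p.minor_fraction for p in pairs], dtype=np.float64)
    if T_range is None:
        upper = float(T.max()) if T.size else 1.0
        T_range = (0.0, upper)
    H, T_edges, f_edges = np.histogram2d(
        T, f, bins=[T_bins, f_bins], range=[T_range, (0.0, 0.5)]
    )
    return H, T_edges, f_edges
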