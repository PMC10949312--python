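"""Pairwise structural alignment, TM-score, and fold-level clustering.

TM-score is the length-normalized similarity sum(1/(1+(d_i/d0)^2))/L_norm
with d0(L) = 1.24*(L-15)^(1/3) - 1.8, so 1.0 is self-identity and >= 0.5
marks the same fold. Alignments are sequential (no rewiring): seeds come
from gapless threading and from dynamic programming over the two backbone
conformation (ABEGO) strings, then each seed is refined TM-align style by
alternating superposition with distance-matrix dynamic programming.
Clustering is exact all-vs-all single linkage at a TM threshold — desk-scale
fidelity rather than web-scale search.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .abego import abego_string
from .structure_io import Structure
from .superpose import RigidTransform, kabsch


def d0_from_length(length: int) -> float:
    """Normalization distance d0(L) = 1.24 (L-15)^(1/3) - 1.8 (Angstrom)."""
    if length <= 15:
        raise ValueError("d0 is defined for normalization lengths >= 16")
    return 1.24 * (length - 15) ** (1.0 / 3.0) - 1.8


@dataclass
class AlignmentResult:
    pairs: list[tuple[int, int]]   # strictly increasing in both columns
    transform: RigidTransform      # applied to structure A
    tm_by_A: float                 # normalized by len(A)
    tm_by_B: float                 # normalized by len(B)

    def tm(self, mode: str = "min") -> float:
        if mode == "min":
            return min(self.tm_by_A, self.tm_by_B)
        if mode == "max":
            return max(self.tm_by_A, self.tm_by_B)
        if mode == "avg":
            return 0.5 * (self.tm_by_A + self.tm_by_B)
        if mode == "query":
            return self.tm_by_A
        raise ValueError(f"unknown TM normalization mode {mode!r}")


def _tm_terms(dists: np.ndarray, d0: float) -> np.ndarray:
    return 1.0 / (1.0 + (dists / d0) ** 2)


def tm_score(
    pairs: list[tuple[int, int]],
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    normalize_length: int,
    superpose: bool = True,
) -> float:
    """TM-score of an alignment between two coordinate sets.

    With ``superpose`` the superposition is chosen to (approximately)
    maximize the score: starting from the all-pair least-squares fit, the fit
    is repeated on the subset of pairs closer than an inclusion cutoff until
    the subset reaches a fixed point, and the best score over the iterations
    is kept. With ``superpose=False`` the coordinates are scored as given.
    """
    if not pairs:
        raise ValueError("alignment has no pairs")
    d0 = d0_from_length(normalize_length)
    ia = np.fromiter((p[0] for p in pairs), int)
    ib = np.fromiter((p[1] for p in pairs), int)
    A = np.asarray(coords_a, float)[ia]
    B = np.asarray(coords_b, float)[ib]

    if not superpose:
        d = np.linalg.norm(A - B, axis=1)
        return float(_tm_terms(d, d0).sum() / normalize_length)

    best = 0.0
    included = np.ones(len(A), bool)
    seen: set[bytes] = set()
    for _ in range(50):
        if included.sum() < 3:
            break
        tr, _ = kabsch(A[included], B[included])
        d = np.linalg.norm(tr.apply(A) - B, axis=1)
        best = max(best, float(_tm_terms(d, d0).sum() / normalize_length))
        cut = d0
        new = d < cut
        while new.sum() < 3:
            cut += 0.5
            new = d < cut
        key = new.tobytes()
        if key in seen:
            break
        seen.add(key)
        included = new
    if best == 0.0:  # fewer than 3 pairs: score the raw coordinates
        d = np.linalg.norm(A - B, axis=1)
        best = float(_tm_terms(d, d0).sum() / normalize_length)
    return best


def _dp_align(score: np.ndarray, gap: float = 0.0) -> list[tuple[int, int]]:
    """Global DP over a similarity matrix; returns matched index pairs."""
    n, m = score.shape
    F = np.zeros((n + 1, m + 1))
    P = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    for i in range(1, n + 1):
        diag = F[i - 1, :-1] + score[i - 1]
        up = F[i - 1, 1:] - gap
        F[i, 0] = F[i - 1, 0] - gap
        row = F[i]
        prev_left = row[0]
        for j in range(1, m + 1):
            d, u = diag[j - 1], up[j - 1]
            left = prev_left - gap
            if d >= u and d >= left:
                row[j] = d
                P[i, j] = 0
            elif u >= left:
                row[j] = u
                P[i, j] = 1
            else:
                row[j] = left
                P[i, j] = 2
            prev_left = row[j]
    pairs = []
    i, j = n, m
    while i > 0 and j > 0:
        p = P[i, j]
        if p == 0:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif p == 1:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


def _abego_seed(abego_a: str, abego_b: str) -> list[tuple[int, int]]:
    """Seed alignment from the two conformation strings (+2/-1/-1 scoring)."""
    a = np.frombuffer(abego_a.encode(), dtype=np.uint8)
    b = np.frombuffer(abego_b.encode(), dtype=np.uint8)
    score = np.where(a[:, None] == b[None, :], 2.0, -1.0)
    return _dp_align(score, gap=1.0)


def _threading_seeds(na: int, nb: int, min_overlap: int) -> list[list[tuple[int, int]]]:
    seeds = []
    for offset in range(-(na - min_overlap), nb - min_overlap + 1):
        lo_a = max(0, -offset)
        hi_a = min(na, nb - offset)
        if hi_a - lo_a >= min_overlap:
            seeds.append([(i, i + offset) for i in range(lo_a, hi_a)])
    return seeds


def align_pair(sa: Structure, sb: Structure, max_refine_seeds: int = 6) -> AlignmentResult:
    """Sequential structural alignment of two structures.

    Seeds (gapless threadings at every offset plus a conformation-string
    alignment) are ranked by a quick TM evaluation; the best few are refined
    by alternating optimal superposition with zero-gap dynamic programming on
    the score matrix 1/(1+(d/d0)^2) until the pair set stops changing. The
    highest-scoring alignment is returned with both normalizations.
    """
    A = sa.ca_coords()
    B = sb.ca_coords()
    na, nb = len(A), len(B)
    if na < 20 or nb < 20:
        raise ValueError("alignment requires at least 20 residues per structure")
    if np.linalg.matrix_rank(A - A.mean(0), tol=1e-6) < 2:
        raise ValueError("degenerate (collinear) coordinates")
    lmin = min(na, nb)
    d0 = d0_from_length(lmin)

    seeds = _threading_seeds(na, nb, min_overlap=max(16, lmin // 2))
    seeds.append(_abego_seed(abego_string(sa), abego_string(sb)))
    scored = []
    for seed in seeds:
        if len(seed) < 3:
            continue
        scored.append((tm_score(seed, A, B, lmin), seed))
    scored.sort(key=lambda t: -t[0])

    best_tm = -1.0
    best_pairs: list[tuple[int, int]] = []
    for _, seed in scored[:max_refine_seeds]:
        pairs = seed
        seen: set[tuple] = set()
        for _ in range(20):
            tr = _superpose_for_tm(pairs, A, B, d0)
            dmat = np.linalg.norm(tr.apply(A)[:, None, :] - B[None, :, :], axis=2)
            pairs = _dp_align(_tm_terms(dmat, d0), gap=0.0)
            key = tuple(pairs)
            if key in seen:
                break
            seen.add(key)
        tm = tm_score(pairs, A, B, lmin)
        if tm > best_tm:
            best_tm = tm
            best_pairs = pairs

    tr = _superpose_for_tm(best_pairs, A, B, d0)
    return AlignmentResult(
        pairs=best_pairs,
        transform=tr,
        tm_by_A=tm_score(best_pairs, A, B, na),
        tm_by_B=tm_score(best_pairs, A, B, nb),
    )


def _superpose_for_tm(pairs, A, B, d0) -> RigidTransform:
    """The TM-maximizing-style superposition used during refinement."""
    ia = np.fromiter((p[0] for p in pairs), int)
    ib = np.fromiter((p[1] for p in pairs), int)
    a, b = A[ia], B[ib]
    included = np.ones(len(a), bool)
    tr, _ = kabsch(a, b)
    best_tr, best = tr, -1.0
    seen: set[bytes] = set()
    for _ in range(50):
        d = np.linalg.norm(tr.apply(a) - b, axis=1)
        score = float(_tm_terms(d, d0).sum())
        if score > best:
            best, best_tr = score, tr
        cut = d0
        new = d < cut
        while new.sum() < 3:
            cut += 0.5
            new = d < cut
        key = new.tobytes()
        if key in seen:
            break
        seen.add(key)
        included = new
        tr, _ = kabsch(a[included], b[included])
    return best_tr


def greedy_cluster(
    ids: list[str],
    tm_table: dict[tuple[str, str], float],
    threshold: float = 0.5,
) -> list[list[str]]:
    """Single-linkage clusters over edges with TM >= threshold.

    ``tm_table`` holds one symmetric similarity per unordered pair (the
    conservative min-of-both-normalizations by convention). Clusters are
    numbered by smallest member id; members are sorted.
    """
    def lookup(a: str, b: str) -> float:
        for key in ((a, b), (b, a)):
            if key in tm_table:
                return tm_table[key]
        raise KeyError(f"missing TM entry for pair ({a}, {b})")

    graph = nx.Graph()
    graph.add_nodes_from(ids)
    for a, b in itertools.combinations(ids, 2):
        if lookup(a, b) >= threshold:
            graph.add_edge(a, b)
    clusters = [sorted(c) for c in nx.connected_components(graph)]
    clusters.sort(key=lambda c: c[0])
    return clusters


def pick_representative(cluster: list[str], tm_table: dict[tuple[str, str], float]) -> str:
    """The member with the largest mean TM to all other members (ties: smallest id)."""
    if not cluster:
        raise ValueError("empty cluster")
    if len(cluster) == 1:
        return cluster[0]

    def lookup(a: str, b: str) -> float:
        for key in ((a, b), (b, a)):
            if key in tm_table:
                return tm_table[key]
        raise KeyError(f"missing TM entry for pair ({a}, {b})")

    def mean_tm(member: str) -> float:
        return float(np.mean([lookup(member, other) for other in cluster if other != member]))

    best_id, best_mean = None, -np.inf
    for member in sorted(cluster):
        m = mean_tm(member)
        if m > best_mean:  # strict: the first (smallest) id wins ties
            best_id, best_mean = member, m
    return best_id


def all_vs_all_tm(
    structures: list[Structure],
    mode: str = "min",
) -> tuple[list[str], dict[tuple[str, str], float]]:
    """Exact all-vs-all TM table for a modest set of structures."""
    ids = [s.id for s in structures]
    table: dict[tuple[str, str], float] = {}
    for sa, sb in itertools.combinations(structures, 2):
        res = align_pair(sa, sb)
        table[(sa.id, sb.id)] = res.tm(mode)
    return ids, table
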