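"""COI barcode species delimitation.

Colonies are grouped into putative species ("COI species") by percent
identity of their COI sequences: pairs at or above the identity threshold
(default 95%, i.e. less than 5% divergence) are linked, and single-linkage
connected components form the species clusters.  A small Needleman-Wunsch
global aligner is included so unaligned FASTA input can be handled without
external tools; already-aligned input (equal lengths, gaps allowed) bypasses
it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "IdentityMatrix",
    "SpeciesCluster",
    "global_align",
    "pairwise_identity",
    "identity_matrix",
    "cluster_species",
]

_VALID = set("ACGTN")


@dataclass
class IdentityMatrix:
    ids: list[str]
    pi: np.ndarray  # percent identities, symmetric, diagonal 100
    n_compared_columns: np.ndarray
    convention: str = "gap and N columns excluded from numerator and denominator"


@dataclass
class SpeciesCluster:
    cluster_id: str
    member_ids: list[str]
    representative_id: str


def global_align(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -1.0,
) -> tuple[str, str, float]:
    """Optimal global alignment under linear gap scoring.

    Ties during traceback are broken deterministically: substitution first,
    then a gap in the second sequence, then a gap in the first.  An empty
    sequence yields the all-gap alignment (score ``gap * len(other)``).
    """
    a, b = seq_a.upper(), seq_b.upper()
    for s in (a, b):
        bad = set(s) - _VALID
        if bad:
            raise ValueError(f"invalid sequence characters: {sorted(bad)}")
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return "-" * m if n == 0 else a, "-" * n if m == 0 else b, gap * max(n, m)

    # score matrix via numpy row recurrence; pointer matrix for traceback
    score = np.empty((n + 1, m + 1))
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    score[0, :] = gap * np.arange(m + 1)
    score[:, 0] = gap * np.arange(n + 1)
    ptr[0, 1:] = 2
    ptr[1:, 0] = 1
    b_arr = np.frombuffer(b.encode(), dtype=np.uint8)
    a_arr = np.frombuffer(a.encode(), dtype=np.uint8)
    for i in range(1, n + 1):
        sub = np.where(b_arr == a_arr[i - 1], match, mismatch)
        prev, cur = score[i - 1], score[i]
        diag = prev[:-1] + sub
        # linear-gap DP still needs a sequential pass for the left move
        up = prev[1:] + gap
        best = np.where(up > diag, up, diag)
        p = np.where(up > diag, 1, 0).astype(np.int8)
        acc = cur[0]
        for j in range(1, m + 1):
            left = acc + gap
            if left > best[j - 1]:
                acc = left
                ptr[i, j] = 2
            else:
                acc = best[j - 1]
                ptr[i, j] = p[j - 1]
            cur[j] = acc

    out_a, out_b = [], []
    i, j = n, m
    while i > 0 or j > 0:
        move = ptr[i, j]
        if move == 0 and i > 0 and j > 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif move == 1 and i > 0:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(score[n, m])


def pairwise_identity(aligned_a: str, aligned_b: str) -> float:
    """Percent identity over columns where neither sequence has a gap or N."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    a = np.frombuffer(aligned_a.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(aligned_b.upper().encode(), dtype=np.uint8)
    skip = (a == ord("-")) | (b == ord("-")) | (a == ord("N")) | (b == ord("N"))
    usable = ~skip
    n_cols = int(usable.sum())
    if n_cols == 0:
        raise ValueError("no comparable columns between the two sequences")
    matches = int((a[usable] == b[usable]).sum())
    return 100.0 * matches / n_cols


def identity_matrix(
    records: Sequence[tuple[str, str]], aligned: bool | None = None
) -> IdentityMatrix:
    """All-pairs percent identities.

    ``aligned=None`` auto-detects: input containing gaps or sequences of one
    common length is treated as aligned; otherwise each pair is globally
    aligned first.
    """
    ids = [r[0] for r in records]
    seqs = [r[1].upper() for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    k = len(seqs)
    if aligned is None:
        aligned = any("-" in s for s in seqs) or len({len(s) for s in seqs}) == 1
    pi = np.full((k, k), 100.0)
    ncols = np.zeros((k, k), dtype=int)
    for i in range(k):
        ncols[i, i] = len(seqs[i].replace("-", ""))
        for j in range(i + 1, k):
            if aligned:
                sa, sb = seqs[i], seqs[j]
            else:
                sa, sb, _ = global_align(seqs[i], seqs[j])
            p = pairwise_identity(sa, sb)
            usable = sum(
                1
                for x, y in zip(sa, sb)
                if x not in "-N" and y not in "-N"
            )
            pi[i, j] = pi[j, i] = p
            ncols[i, j] = ncols[j, i] = usable
    return IdentityMatrix(ids, pi, ncols)


def cluster_species(
    matrix: IdentityMatrix, threshold: float = 95.0
) -> list[SpeciesCluster]:
    """Single-linkage clusters over pairs with PI >= threshold (inclusive).

    Cluster ids and representatives are the lexicographically smallest member
    id, so the output is invariant to input order.
    """
    ids = matrix.ids
    k = len(ids)
    parent = list(range(k))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(k):
        for j in range(i + 1, k):
            if matrix.pi[i, j] >= threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[str]] = {}
    for i in range(k):
        groups.setdefault(find(i), []).append(ids[i])
    clusters = []
    for members in groups.values():
        members = sorted(members)
        clusters.append(SpeciesCluster(members[0], members, members[0]))
    clusters.sort(key=lambda c: c.cluster_id)
    return clusters
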