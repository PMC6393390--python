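"""Positional consensus, information content and clustering of mined segments.

Given the equal-length, gap-free segments retained by mining, this module
builds the L x 20 positional count matrix, derives the consensus string
(per-position modal residue) and the information content profile
(log2(20) minus positional Shannon entropy — the letter-height scale of
sequence logos), and groups the segments by pairwise p-distance into an
unrooted neighbor-joining tree with average-linkage class assignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"  # alphabetical; argmax ties resolve lexicographically
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
LOG2_20 = math.log2(20.0)


@dataclass
class PositionalCountMatrix:
    """Residue counts per position over n equal-length segments (rows sum to n)."""

    counts: np.ndarray  # shape (L, 20), columns ordered by AA_ORDER
    n_segments: int

    @property
    def length(self) -> int:
        return self.counts.shape[0]


@dataclass
class SegmentTree:
    newick: str
    leaf_ids: list[str]
    class_labels: Optional[dict[str, int]] = None


def build_count_matrix(segments: Sequence[str]) -> PositionalCountMatrix:
    """Exact per-position residue counts over equal-length, gap-free segments."""
    if not segments:
        raise ValueError("no segments given")
    L = len(segments[0])
    counts = np.zeros((L, 20), dtype=int)
    for idx, seg in enumerate(segments):
        if len(seg) != L:
            raise ValueError(
                f"segment {idx} ({seg!r}) has length {len(seg)}, expected {L}"
            )
        for pos, ch in enumerate(seg):
            if ch not in _AA_INDEX:
                raise ValueError(f"segment {idx}: invalid residue {ch!r} at position {pos + 1}")
            counts[pos, _AA_INDEX[ch]] += 1
    return PositionalCountMatrix(counts=counts, n_segments=len(segments))


def consensus_string(matrix: PositionalCountMatrix) -> str:
    """Per-position modal residue; ties broken lexicographically."""
    if matrix.n_segments < 1:
        raise ValueError("empty matrix")
    return "".join(AA_ORDER[j] for j in matrix.counts.argmax(axis=1))


def information_content(matrix: PositionalCountMatrix) -> np.ndarray:
    """Per-position IC in bits: log2(20) - Shannon entropy of the column.

    No small-sample correction is applied (raw observed frequencies).
    """
    freqs = matrix.counts / matrix.n_segments
    ic = np.empty(matrix.length)
    for pos in range(matrix.length):
        p = freqs[pos][freqs[pos] > 0]
        ic[pos] = LOG2_20 + float((p * np.log2(p)).sum())
    return ic


def p_distance_matrix(segments: Sequence[str]) -> np.ndarray:
    """Pairwise mismatch fractions (p-distance) over equal-length segments."""
    n = len(segments)
    L = len(segments[0]) if segments else 0
    for idx, seg in enumerate(segments):
        if len(seg) != L:
            raise ValueError(f"segment {idx} has length {len(seg)}, expected {L}")
    arr = np.frombuffer("".join(segments).encode(), dtype="S1").reshape(n, L)
    dist = np.zeros((n, n))
    for i in range(n):
        mism = (arr[i] != arr).sum(axis=1) / L
        dist[i] = mism
    np.fill_diagonal(dist, 0.0)
    return dist


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def neighbor_joining(dist: np.ndarray, ids: Optional[Sequence[str]] = None) -> SegmentTree:
    """Saitou-Nei neighbor joining on a symmetric distance matrix.

    Q-matrix ties are broken by the smallest index pair; negative branch
    lengths are clamped to 0 with the deficit moved to the sister branch.
    Returns an unrooted tree in newick form (trifurcating root).
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    ids = list(ids) if ids is not None else [f"S{i + 1}" for i in range(n)]
    if len(ids) != n:
        raise ValueError("ids length does not match matrix size")

    labels = list(ids)  # newick subtrees for active nodes
    active = d.copy()
    while len(labels) > 3:
        m = len(labels)
        r = active.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * active[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = active[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = active[i, j] - li
        if li < 0:
            lj, li = lj + li, 0.0
        if lj < 0:
            li, lj = li + lj, 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        new_label = f"({labels[i]}:{_fmt(li)},{labels[j]}:{_fmt(lj)})"
        new_row = np.array(
            [
                max(0.0, (active[i, k] + active[j, k] - active[i, j]) / 2.0)
                for k in range(m)
                if k not in (i, j)
            ]
        )
        keep = [k for k in range(m) if k not in (i, j)]
        active = active[np.ix_(keep, keep)]
        active = np.pad(active, ((0, 1), (0, 1)))
        active[-1, :-1] = new_row
        active[:-1, -1] = new_row
        labels = [labels[k] for k in keep] + [new_label]

    # final unrooted trifurcation: closed-form star branch lengths
    dab, dac, dbc = active[0, 1], active[0, 2], active[1, 2]
    va = max(0.0, (dab + dac - dbc) / 2.0)
    vb = max(0.0, (dab + dbc - dac) / 2.0)
    vc = max(0.0, (dac + dbc - dab) / 2.0)
    newick = (
        f"({labels[0]}:{_fmt(va)},{labels[1]}:{_fmt(vb)},{labels[2]}:{_fmt(vc)});"
    )
    return SegmentTree(newick=newick, leaf_ids=list(ids))


def assign_classes(
    dist: np.ndarray, k: int = 5, ids: Optional[Sequence[str]] = None
) -> dict[str, int]:
    """Average-linkage clustering of the distance matrix cut into k classes.

    Labels are renumbered 1..k in order of first appearance, so the result
    is deterministic given the input order.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of segments ({n})")
    ids = list(ids) if ids is not None else [f"S{i + 1}" for i in range(n)]
    if k == n:
        raw = np.arange(1, n + 1)
    elif k == 1:
        raw = np.ones(n, dtype=int)
    else:
        Z = linkage(squareform(d, checks=False), method="average")
        raw = fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    out: dict[str, int] = {}
    for name, lab in zip(ids, raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        out[name] = relabel[lab]
    return out


def count_matrix_table(matrix: PositionalCountMatrix):
    """Count matrix plus IC as a DataFrame (one row per position)."""
    import pandas as pd

    df = pd.DataFrame(matrix.counts, columns=list(AA_ORDER))
    df.insert(0, "position", np.arange(1, matrix.length + 1))
    df["ic_bits"] = information_content(matrix)
    return df
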