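"""Expanded F-segment mining over a protein database.

Re-expresses the two-round homology search used to collect F-segment
orthologs as explicit local-alignment mining: Smith-Waterman with affine
gaps (BLOSUM62, open 11 / extend 1, the standard protein defaults) aligns
the 18-residue expanded F-segment consensus against each database protein;
hits scoring at least a fraction of the query self-score are extracted
iteratively with masking, so multi-copy proteins yield every copy.  The
e-value gate of a database search is replaced by this self-score-fraction
threshold, which is reproducible without a fixed reference database.

Segments whose optimal alignment to the consensus requires an internal gap
(e.g. two-residue insertions) likely belong to a different family and are
filtered out before consensus profiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

from .motif_scan import MotifDefinition, SegmentMatch, blosum62_score
from .seqio import SequenceRecord

_MASK = "#"  # never matches: score -inf against everything
_NEG = -10**6


def _score_fn(a: str, b: str) -> float:
    if a == _MASK or b == _MASK:
        return _NEG
    return blosum62_score(a, b)


@dataclass
class AlignmentResult:
    """An optimal local alignment; coordinates 1-based inclusive.

    A zero score means no positive-scoring local alignment exists; the
    aligned strings are then empty and coordinates are 0.
    """

    query_id: str
    target_id: str
    score: float
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    aligned_query: str
    aligned_target: str
    identity: float
    gapped: bool


@dataclass
class MiningResult:
    hits: dict[str, list[SegmentMatch]]
    removed_duplicates: int = 0
    removed_gapped: int = 0

    def n_hits(self) -> int:
        return sum(len(v) for v in self.hits.values())


def local_align(
    query: str,
    target: str,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    score: Callable[[str, str], float] = _score_fn,
    query_id: str = "query",
    target_id: str = "target",
) -> AlignmentResult:
    """Smith-Waterman local alignment with affine gaps.

    A gap of length k costs ``gap_open + k * gap_extend``.  Among equal-score
    optima the alignment with the smallest (t_start, q_start) is returned.
    """
    if not query or not target:
        raise ValueError("query and target must be non-empty")
    m, n = len(query), len(target)
    # H: best alignment ending at (t_i, q_j); D consumes target, I consumes query
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    D = [[_NEG * 1.0] * (m + 1) for _ in range(n + 1)]
    I = [[_NEG * 1.0] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            D[i][j] = max(H[i - 1][j] - gap_open - gap_extend, D[i - 1][j] - gap_extend)
            I[i][j] = max(H[i][j - 1] - gap_open - gap_extend, I[i][j - 1] - gap_extend)
            diag = H[i - 1][j - 1] + score(query[j - 1], target[i - 1])
            H[i][j] = max(0.0, diag, D[i][j], I[i][j])
            if H[i][j] > best:
                best = H[i][j]

    if best <= 0:
        return AlignmentResult(query_id, target_id, 0.0, 0, 0, 0, 0, "", "", 0.0, False)

    def _traceback(i: int, j: int) -> tuple[int, int, str, str]:
        aq, at = [], []
        state = "H"
        while i > 0 and j > 0:
            if state == "H":
                if H[i][j] == 0:
                    break
                diag = H[i - 1][j - 1] + score(query[j - 1], target[i - 1])
                if H[i][j] == diag:
                    aq.append(query[j - 1])
                    at.append(target[i - 1])
                    i, j = i - 1, j - 1
                elif H[i][j] == D[i][j]:
                    state = "D"
                else:
                    state = "I"
            elif state == "D":
                aq.append("-")
                at.append(target[i - 1])
                if D[i][j] == H[i - 1][j] - gap_open - gap_extend:
                    state = "H"
                i -= 1
            else:
                aq.append(query[j - 1])
                at.append("-")
                if I[i][j] == H[i][j - 1] - gap_open - gap_extend:
                    state = "H"
                j -= 1
        return i, j, "".join(reversed(aq)), "".join(reversed(at))

    # all optimal end cells, traced back; pick the smallest (t_start, q_start)
    choices = []
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if H[i][j] == best:
                ti, qj, aq, at = _traceback(i, j)
                choices.append(((ti + 1, qj + 1), (qj + 1, ti + 1, j, i, aq, at)))
    choices.sort(key=lambda c: c[0])
    q_start, t_start, q_end, t_end, aq, at = choices[0][1]
    pairs = [(a, b) for a, b in zip(aq, at) if a != "-" and b != "-"]
    identity = sum(a == b for a, b in pairs) / len(aq) if aq else 0.0
    return AlignmentResult(
        query_id, target_id, best, q_start, q_end, t_start, t_end,
        aq, at, identity, "-" in aq or "-" in at,
    )


def alignment_is_gapped(segment: str, consensus: str, **kw) -> bool:
    """Whether the optimal local alignment of segment vs consensus has a gap."""
    return local_align(consensus, segment, **kw).gapped


def mine_database(
    motif: MotifDefinition,
    db: list[SequenceRecord],
    min_score_fraction: float = 0.5,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> MiningResult:
    """Extract every consensus-like segment from each database protein.

    Exact-duplicate entries (same residues under any id) are dropped first.
    Per protein, non-overlapping local alignments scoring at least
    ``min_score_fraction`` x the consensus self-score are pulled out
    iteratively, masking each hit before re-aligning.
    """
    if not db:
        raise ValueError("empty database")
    consensus = motif.consensus
    if not consensus:
        raise ValueError(f"motif {motif.name} has no consensus to mine with")
    cutoff = min_score_fraction * motif.self_score()

    seen: dict[str, str] = {}
    removed_dup = 0
    unique: list[SequenceRecord] = []
    for rec in db:
        if rec.residues in seen:
            removed_dup += 1
            continue
        seen[rec.residues] = rec.id
        unique.append(rec)

    hits: dict[str, list[SegmentMatch]] = {}
    for rec in unique:
        masked = list(rec.residues)
        found: list[SegmentMatch] = []
        while True:
            aln = local_align(
                consensus, "".join(masked),
                gap_open=gap_open, gap_extend=gap_extend,
                query_id=motif.name, target_id=rec.id,
            )
            if aln.score < cutoff or aln.score <= 0:
                break
            if _MASK in "".join(masked[aln.t_start - 1 : aln.t_end]):
                break  # safety: never bridge a previous hit
            found.append(
                SegmentMatch(
                    seq_id=rec.id,
                    motif=motif.name,
                    start=aln.t_start,
                    end=aln.t_end,
                    matched=rec.residues[aln.t_start - 1 : aln.t_end],
                    score=aln.score,
                    identity=aln.identity,
                    gapped=aln.gapped,
                )
            )
            for p in range(aln.t_start - 1, aln.t_end):
                masked[p] = _MASK
        if found:
            found.sort(key=lambda m: m.start)
            hits[rec.id] = found
    return MiningResult(hits=hits, removed_duplicates=removed_dup)


def filter_gapped_segments(result: MiningResult, motif: MotifDefinition) -> MiningResult:
    """Drop hits whose optimal alignment to the consensus contains a gap."""
    kept: dict[str, list[SegmentMatch]] = {}
    removed = result.removed_gapped
    for pid, matches in result.hits.items():
        retained = []
        for m in matches:
            gapped = m.gapped or alignment_is_gapped(m.matched, motif.consensus)
            if gapped:
                removed += 1
            else:
                retained.append(m)
        if retained:
            kept[pid] = retained
    return MiningResult(
        hits=kept, removed_duplicates=result.removed_duplicates, removed_gapped=removed
    )


def copy_number_table(result: MiningResult):
    """Per-protein copy counts as a DataFrame, descending count then id."""
    import pandas as pd

    rows = [
        {"protein_id": pid, "copies": len(ms), "f_class": f"F{len(ms)}"}
        for pid, ms in result.hits.items()
        if ms
    ]
    rows.sort(key=lambda r: (-r["copies"], r["protein_id"]))
    return pd.DataFrame(rows, columns=["protein_id", "copies", "f_class"])
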