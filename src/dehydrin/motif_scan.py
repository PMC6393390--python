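"""Detection of conserved dehydrin segments by fuzzy ungapped matching.

Dehydrins are classified by the segments they carry: the lysine-rich
K-segment (the family-defining amphipathic consensus), the N-terminal
Y-segment, serine tracts (S-segment), histidine-rich stretches, and the
F-segment — an 11-residue core (DRGLFDFLGKK, named for its paired
phenylalanines) embedded in an 18-residue expanded consensus
(ETKDRGLFDFLGKKEEEE).

Three match models are used:

* ``scored_window`` — slide an ungapped window of the consensus length and
  keep windows whose BLOSUM62 score reaches a fraction ``t`` of the
  consensus self-score (greedy non-overlapping selection, best first).
* ``residue_run`` — maximal homopolymer runs (serine tracts).
* ``windowed_count`` — merged regions where a fixed window holds at least a
  minimum count of the target residue (histidine-rich stretches).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.Align import substitution_matrices

from .seqio import SequenceRecord

# BLOSUM62 as a plain dict; X (and any unknown residue) scores 0 against
# everything so NR-style sequences with X never dominate nor break a scan.
_B62 = substitution_matrices.load("BLOSUM62")
BLOSUM62: dict[tuple[str, str], int] = {}
for _a in _B62.alphabet:
    for _b in _B62.alphabet:
        BLOSUM62[(_a, _b)] = int(_B62[_a, _b])


def blosum62_score(a: str, b: str) -> int:
    """BLOSUM62 substitution score; X or unknown residues score 0."""
    if a == "X" or b == "X":
        return 0
    return BLOSUM62.get((a, b), 0)


@dataclass
class MotifDefinition:
    """A named consensus segment plus its match model and parameters."""

    name: str
    match_model: str  # scored_window | residue_run | windowed_count
    consensus: str = ""
    threshold: float = 0.6  # fraction of self-score (scored_window)
    residue: str = ""  # target residue (residue_run / windowed_count)
    min_run: int = 4
    window_len: int = 9
    min_count: int = 5

    def __post_init__(self) -> None:
        if self.match_model == "scored_window":
            if not self.consensus:
                raise ValueError(f"motif {self.name}: scored_window needs a consensus")
            if not (0 < self.threshold <= 1):
                raise ValueError(f"motif {self.name}: threshold must be in (0, 1]")
        elif self.match_model == "residue_run":
            if self.min_run < 2:
                raise ValueError(f"motif {self.name}: min_run must be >= 2")
        elif self.match_model == "windowed_count":
            if self.min_count > self.window_len:
                raise ValueError(f"motif {self.name}: min_count > window_len")
        else:
            raise ValueError(f"motif {self.name}: unknown match model {self.match_model!r}")

    def self_score(self) -> int:
        return sum(blosum62_score(c, c) for c in self.consensus)


@dataclass
class SegmentMatch:
    """A located motif occurrence (1-based inclusive coordinates)."""

    seq_id: str
    motif: str
    start: int
    end: int
    matched: str
    score: float
    identity: float
    gapped: bool = False

    def __len__(self) -> int:
        return self.end - self.start + 1


#: Segment consensus defaults.  The Y/S/K patterns are the literature-standard
#: forms (the K-segment 15-mer is chosen so its composition is K5 E2 D1, the
#: canonical charged-residue census of the motif).
F_EXPANDED = "ETKDRGLFDFLGKKEEEE"
F_CORE = "DRGLFDFLGKK"
K_SEGMENT = "EKKGIMDKIKEKLPG"
Y_SEGMENT = "DEYGNP"
H_SEGMENT_EXAMPLE = "HHQHHHHVE"


def default_motifs() -> dict[str, MotifDefinition]:
    """The default dehydrin segment definitions, keyed by motif name."""
    return {
        "F_expanded": MotifDefinition("F_expanded", "scored_window", F_EXPANDED, threshold=0.6),
        "F_core": MotifDefinition("F_core", "scored_window", F_CORE, threshold=0.6),
        "K": MotifDefinition("K", "scored_window", K_SEGMENT, threshold=0.6),
        "Y": MotifDefinition("Y", "scored_window", Y_SEGMENT, threshold=0.8),
        "S": MotifDefinition("S", "residue_run", residue="S", min_run=4),
        "H": MotifDefinition("H", "windowed_count", residue="H", window_len=9, min_count=5),
    }


def _greedy_nonoverlap(candidates: list[SegmentMatch]) -> list[SegmentMatch]:
    """Pick non-overlapping matches, best score first, leftmost on ties."""
    chosen: list[SegmentMatch] = []
    for cand in sorted(candidates, key=lambda m: (-m.score, m.start)):
        if all(cand.end < c.start or cand.start > c.end for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda m: m.start)
    return chosen


def scan_motif(seq: SequenceRecord, motif: MotifDefinition) -> list[SegmentMatch]:
    """Locate a scored_window motif by ungapped BLOSUM62 window scanning.

    A window qualifies when its score reaches ``threshold`` x the consensus
    self-score; overlapping candidates are resolved greedily (descending
    score, leftmost on ties).  Matches are returned sorted by start.
    """
    if motif.match_model != "scored_window":
        raise ValueError(f"scan_motif requires a scored_window motif, got {motif.match_model}")
    consensus = motif.consensus
    L = len(consensus)
    residues = seq.residues
    if len(residues) < L:
        return []
    cutoff = motif.threshold * motif.self_score()
    candidates = []
    for i in range(len(residues) - L + 1):
        window = residues[i : i + L]
        score = sum(blosum62_score(c, w) for c, w in zip(consensus, window))
        if score >= cutoff:
            ident = sum(c == w for c, w in zip(consensus, window)) / L
            candidates.append(
                SegmentMatch(seq.id, motif.name, i + 1, i + L, window, score, ident)
            )
    return _greedy_nonoverlap(candidates)


def find_residue_run(seq: SequenceRecord, motif: MotifDefinition) -> list[SegmentMatch]:
    """Maximal runs of the target residue with length >= min_run."""
    if motif.match_model != "residue_run":
        raise ValueError("find_residue_run requires a residue_run motif")
    matches = []
    residues = seq.residues
    i = 0
    while i < len(residues):
        if residues[i] == motif.residue:
            j = i
            while j < len(residues) and residues[j] == motif.residue:
                j += 1
            if j - i >= motif.min_run:
                matches.append(
                    SegmentMatch(
                        seq.id, motif.name, i + 1, j, residues[i:j], float(j - i), 1.0
                    )
                )
            i = j
        else:
            i += 1
    return matches


def find_windowed_count(seq: SequenceRecord, motif: MotifDefinition) -> list[SegmentMatch]:
    """Merged regions unionable from windows holding >= min_count target residues.

    Every length-``window_len`` window containing at least ``min_count``
    copies of the target residue contributes its span; overlapping spans are
    merged into maximal regions, each reported as one match.
    """
    if motif.match_model != "windowed_count":
        raise ValueError("find_windowed_count requires a windowed_count motif")
    residues = seq.residues
    w = motif.window_len
    if len(residues) < w:
        return []
    spans = []
    for i in range(len(residues) - w + 1):
        window = residues[i : i + w]
        if window.count(motif.residue) >= motif.min_count:
            spans.append((i + 1, i + w))
    if not spans:
        return []
    merged = [list(spans[0])]
    for s, e in spans[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        region = residues[s - 1 : e]
        n = region.count(motif.residue)
        out.append(
            SegmentMatch(seq.id, motif.name, s, e, region, float(n), n / len(region))
        )
    return out


def scan_all(
    seq: SequenceRecord, motifs: Optional[dict[str, MotifDefinition]] = None
) -> list[SegmentMatch]:
    """Run every motif definition against one record; matches sorted by start."""
    motifs = motifs if motifs is not None else default_motifs()
    matches: list[SegmentMatch] = []
    for motif in motifs.values():
        if motif.match_model == "scored_window":
            matches.extend(scan_motif(seq, motif))
        elif motif.match_model == "residue_run":
            matches.extend(find_residue_run(seq, motif))
        else:
            matches.extend(find_windowed_count(seq, motif))
    matches.sort(key=lambda m: (m.start, m.motif))
    return matches
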