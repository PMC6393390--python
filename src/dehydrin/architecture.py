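"""YSK architecture typing from located segments.

The field's shorthand counts segment copies along the protein: Y-segments,
then the serine tract, then K-segments (e.g. Y3SK2, SK2, K1).  The presence
of at least one K-segment is the dehydrin-defining requirement; the five
structural types are YnSKn, SKn, YnKn, Kn and KnS (the last when the serine
tract lies C-terminal of the final K-segment).  Proteins carrying expanded
F-segments get the count appended ("Y2SK2+F3") and an F-alias in which the
F-block replaces the Y-block ("F3SK2").
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .motif_scan import SegmentMatch

TYPE_YNSKN = "YnSKn"
TYPE_SKN = "SKn"
TYPE_YNKN = "YnKn"
TYPE_KN = "Kn"
TYPE_KNS = "KnS"
TYPE_NONE = "none"


@dataclass
class ArchitectureCall:
    counts: dict[str, int]
    shorthand: str
    f_alias: str
    type_label: str


def _block(letter: str, n: int) -> str:
    if n == 0:
        return ""
    return f"{letter}{n}" if letter != "S" or n > 1 else "S"


def architecture_from_counts(
    counts: dict[str, int], s_after_last_k: bool = False
) -> ArchitectureCall:
    """Build the shorthand, F-alias and type label from segment copy counts.

    ``s_after_last_k`` disambiguates SKn vs KnS when segment order is known;
    with counts alone the SKn reading is assumed.
    """
    y = counts.get("Y", 0)
    s = counts.get("S", 0)
    k = counts.get("K", 0)
    f = counts.get("F", 0)

    shorthand = _block("Y", y) + _block("S", s) + _block("K", k)
    if f > 0:
        shorthand = (shorthand + f"+F{f}") if shorthand else f"F{f}"
    f_alias = _block("F", f) + _block("S", s) + _block("K", k) if f > 0 else ""

    if k == 0:
        label = TYPE_NONE
    elif y > 0 and s > 0:
        label = TYPE_YNSKN
    elif y > 0:
        label = TYPE_YNKN
    elif s > 0:
        label = TYPE_KNS if s_after_last_k else TYPE_SKN
    else:
        label = TYPE_KN

    return ArchitectureCall(
        counts={n: c for n, c in (("Y", y), ("S", s), ("K", k), ("F", f)) if c},
        shorthand=shorthand,
        f_alias=f_alias,
        type_label=label,
    )


def classify_architecture(matches: list[SegmentMatch]) -> ArchitectureCall:
    """Classify one protein's segment matches into its architecture.

    F_core matches nested inside an F_expanded match are counted once (as
    expanded).  The result is independent of the order of ``matches``.
    """
    seq_ids = {m.seq_id for m in matches}
    if len(seq_ids) > 1:
        raise ValueError(f"matches from multiple sequences: {sorted(seq_ids)}")

    expanded = [m for m in matches if m.motif == "F_expanded"]
    cores = [
        m
        for m in matches
        if m.motif == "F_core"
        and not any(e.start <= m.start and m.end <= e.end for e in expanded)
    ]
    counts = {
        "Y": sum(m.motif == "Y" for m in matches),
        "S": sum(m.motif == "S" for m in matches),
        "K": sum(m.motif == "K" for m in matches),
        "F": len(expanded) + len(cores),
    }

    s_after = False
    k_starts = [m.start for m in matches if m.motif == "K"]
    s_starts = [m.start for m in matches if m.motif == "S"]
    if k_starts and s_starts:
        s_after = min(s_starts) > max(k_starts)
    return architecture_from_counts(counts, s_after_last_k=s_after)
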