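"""Synthetic inputs with known ground truth for every analysis stage.

Generators emulate the study designs the analyses expect: dehydrin-like
proteins with planted Y/S/K/F/His segments joined by hydrophilic linkers,
protein databases with known F-segment copy numbers, segment sets sampled
from a positional frequency profile, and Ct tables carrying a known
month-by-month fold trajectory plus Gaussian noise.  Each generator records
the truth it planted, so analyzer round-trips (architecture, copy number,
consensus, fold change) are directly testable.  All randomness flows from
an explicit seed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .motif_scan import F_EXPANDED, H_SEGMENT_EXAMPLE, K_SEGMENT, Y_SEGMENT
from .seqio import SequenceRecord

MOTIF_TEMPLATES = {
    "Y": Y_SEGMENT,
    "S": "SSSSSS",
    "K": K_SEGMENT,
    "F": F_EXPANDED,
    "H": H_SEGMENT_EXAMPLE,
}

#: Linker residue pool: hydrophilic/disorder-promoting residues typical of
#: dehydrin backbones.  Serine and histidine are deliberately excluded so a
#: random linker can never fabricate a serine tract or His-rich segment.
LINKER_POOL = "GTEKPA"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Default 18-position frequency profile of the expanded F-segment ortholog
#: set (208 segments): per position the modal residue and its count.  The
#: final glutamate position is assigned the same count as its neighbour.
F_SEGMENT_PROFILE: list[tuple[str, int]] = [
    ("E", 197), ("T", 67), ("K", 92), ("D", 188), ("R", 207), ("G", 207),
    ("L", 150), ("F", 200), ("D", 198), ("F", 204), ("L", 123), ("G", 167),
    ("K", 142), ("K", 149), ("E", 93), ("E", 114), ("E", 105), ("E", 105),
]
F_SEGMENT_PROFILE_N = 208

MONTHS = ["August", "September", "October", "November", "January", "February"]


@dataclass
class PlantedSegment:
    name: str
    start: int  # 1-based inclusive
    end: int


@dataclass
class SyntheticProtein:
    record: SequenceRecord
    segments: list[PlantedSegment]
    architecture: str
    seed: Optional[int]

    def copies(self, name: str) -> int:
        return sum(s.name == name for s in self.segments)


@dataclass
class SyntheticSegmentDb:
    records: list[SequenceRecord]
    truth: dict[str, list[PlantedSegment]]
    seed: Optional[int]

    def copy_counts(self) -> dict[str, int]:
        return {pid: len(segs) for pid, segs in self.truth.items()}


@dataclass
class SyntheticCtTruth:
    true_folds: dict[str, dict[str, float]]  # gene -> sample -> fold
    ref_gene: str
    baseline: str
    seed: Optional[int]


_SPEC_TOKEN = re.compile(r"([YSKFH])(\d*)")


def parse_architecture_spec(spec: str) -> list[tuple[str, int]]:
    """Parse an architecture string like ``Y2SK2+F3`` into (motif, count) blocks.

    A ``+Fn`` suffix is moved to the front (F-segments sit N-terminal in the
    multi-copy architectures this emulates).
    """
    spec = spec.strip()
    main, plus = (spec.split("+", 1) + [""])[:2] if "+" in spec else (spec, "")
    blocks: list[tuple[str, int]] = []
    for part in (plus, main):
        if not part:
            continue
        pos = 0
        parsed: list[tuple[str, int]] = []
        for m in _SPEC_TOKEN.finditer(part):
            if m.start() != pos:
                raise ValueError(f"unparseable architecture spec {spec!r}")
            parsed.append((m.group(1), int(m.group(2) or 1)))
            pos = m.end()
        if pos != len(part):
            raise ValueError(f"unparseable architecture spec {spec!r}")
        blocks = parsed + blocks if part is plus else blocks + parsed
    if not blocks:
        raise ValueError(f"empty architecture spec {spec!r}")
    return blocks


def _linker(rng: np.random.Generator, linker_len: tuple[int, int]) -> str:
    n = int(rng.integers(linker_len[0], linker_len[1] + 1))
    return "".join(rng.choice(list(LINKER_POOL), size=n))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0:
        return seq
    out = list(seq)
    for i, ch in enumerate(out):
        if rng.random() < rate:
            choices = [a for a in AMINO_ACIDS if a != ch]
            out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def simulate_dehydrin(
    spec: str = "Y2SK2+F3",
    linker_len: tuple[int, int] = (8, 20),
    mutation_rate: float = 0.0,
    seed: Optional[int] = None,
    record_id: str = "synthetic",
) -> SyntheticProtein:
    """Build a dehydrin-like protein from an architecture spec.

    Motif templates are concatenated in spec order (``+Fn`` goes N-terminal)
    with random hydrophilic linkers between and around them, then mutated by
    i.i.d. substitutions at ``mutation_rate``.  Planted coordinates refer to
    the emitted sequence.
    """
    if not 0 <= mutation_rate <= 0.3:
        raise ValueError("mutation_rate must be in [0, 0.3]")
    rng = np.random.default_rng(seed)
    blocks = parse_architecture_spec(spec)
    pieces: list[str] = []
    planted: list[PlantedSegment] = []
    cursor = 0

    def _push(s: str) -> None:
        nonlocal cursor
        pieces.append(s)
        cursor += len(s)

    _push(_linker(rng, linker_len))
    for name, count in blocks:
        for _ in range(count):
            template = MOTIF_TEMPLATES[name]
            planted.append(PlantedSegment(name, cursor + 1, cursor + len(template)))
            _push(template)
            _push(_linker(rng, linker_len))
    sequence = _mutate("".join(pieces), mutation_rate, rng)
    record = SequenceRecord(id=record_id, residues=sequence, moltype="protein")
    return SyntheticProtein(record=record, segments=planted, architecture=spec, seed=seed)


def simulate_segment_db(
    n_proteins: int = 50,
    copy_distribution: Optional[Mapping[int, float]] = None,
    mutation_rate: float = 0.0,
    linker_len: tuple[int, int] = (20, 40),
    seed: Optional[int] = None,
) -> SyntheticSegmentDb:
    """A protein database with a known number of planted F-segment copies each.

    ``copy_distribution`` maps copy number to probability (default
    {0: 0.2, 1: 0.4, 2: 0.2, 3: 0.2}, echoing the observed mix of one-, two-
    and three-copy orthologs plus negatives).
    """
    dist = dict(copy_distribution or {0: 0.2, 1: 0.4, 2: 0.2, 3: 0.2})
    probs = np.array(list(dist.values()), dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("copy_distribution probabilities must sum to 1")
    rng = np.random.default_rng(seed)
    copies = rng.choice(list(dist.keys()), size=n_proteins, p=probs)

    records: list[SequenceRecord] = []
    truth: dict[str, list[PlantedSegment]] = {}
    for i, n_copies in enumerate(copies):
        pid = f"prot{i + 1:03d}"
        pieces: list[str] = []
        planted: list[PlantedSegment] = []
        cursor = 0

        def _push(s: str) -> None:
            nonlocal cursor
            pieces.append(s)
            cursor += len(s)

        _push(_linker(rng, linker_len))
        for _ in range(int(n_copies)):
            planted.append(PlantedSegment("F", cursor + 1, cursor + len(F_EXPANDED)))
            _push(F_EXPANDED)
            _push(_linker(rng, linker_len))
        sequence = _mutate("".join(pieces), mutation_rate, rng)
        records.append(SequenceRecord(id=pid, residues=sequence, moltype="protein"))
        truth[pid] = planted
    return SyntheticSegmentDb(records=records, truth=truth, seed=seed)


def frequency_profile_columns(
    profile: Sequence[tuple[str, int]] = tuple(F_SEGMENT_PROFILE),
    n_total: int = F_SEGMENT_PROFILE_N,
    residual: str = "uniform",
) -> np.ndarray:
    """Per-position residue probabilities from a modal-count profile.

    The profile stores only the modal residue and its count; the residual
    mass (n_total - count) is spread uniformly over the other 19 residues
    (the default; ``residual="modal"`` puts everything on the modal residue,
    useful for deterministic fixtures).
    """
    probs = np.zeros((len(profile), 20))
    for pos, (res, count) in enumerate(profile):
        j = AMINO_ACIDS.index(res)
        if residual == "modal":
            probs[pos, j] = 1.0
            continue
        probs[pos, :] = (n_total - count) / (19.0 * n_total)
        probs[pos, j] = count / n_total
    return probs


def sample_from_frequency_profile(
    profile: Sequence[tuple[str, int]] = tuple(F_SEGMENT_PROFILE),
    n: int = F_SEGMENT_PROFILE_N,
    n_total: int = F_SEGMENT_PROFILE_N,
    seed: Optional[int] = None,
    residual: str = "uniform",
) -> list[str]:
    """Sample n segments by i.i.d. per-position draws from the profile."""
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    probs = frequency_profile_columns(profile, n_total=n_total, residual=residual)
    letters = np.array(list(AMINO_ACIDS))
    cols = [
        rng.choice(letters, size=n, p=probs[pos]) for pos in range(len(profile))
    ]
    return ["".join(col[i] for col in cols) for i in range(n)]


def simulate_ct_table(
    true_folds: Mapping[str, Mapping[str, float]],
    ref_gene: str = "RcUbql",
    baseline: str = "August",
    noise_sd: float = 0.2,
    replicates: int = 3,
    experiments: int = 2,
    base_ct_test: float = 28.0,
    base_ct_ref: float = 20.0,
    seed: Optional[int] = None,
) -> tuple[pd.DataFrame, SyntheticCtTruth]:
    """A replicated Ct table carrying a known fold trajectory.

    Ct(test, sample) = base_ct_test - log2(fold) + N(0, noise_sd);
    Ct(ref, sample) = base_ct_ref + N(0, noise_sd).  ``true_folds`` maps
    gene -> sample -> fold with the baseline fold equal to 1.
    """
    rng = np.random.default_rng(seed)
    rows = []
    samples: list[str] = []
    for gene, folds in true_folds.items():
        if not np.isclose(folds.get(baseline, np.nan), 1.0):
            raise ValueError(f"gene {gene!r}: baseline {baseline!r} fold must be 1")
        if any(f <= 0 for f in folds.values()):
            raise ValueError(f"gene {gene!r}: folds must be positive")
        for sample in folds:
            if sample not in samples:
                samples.append(sample)
        for sample, fold in folds.items():
            for exp in range(1, experiments + 1):
                for rep in range(1, replicates + 1):
                    ct = base_ct_test - np.log2(fold) + rng.normal(0.0, noise_sd)
                    rows.append((sample, gene, rep, exp, ct))
    for sample in samples:
        for exp in range(1, experiments + 1):
            for rep in range(1, replicates + 1):
                ct = base_ct_ref + rng.normal(0.0, noise_sd)
                rows.append((sample, ref_gene, rep, exp, ct))
    table = pd.DataFrame(rows, columns=["sample", "gene", "replicate", "experiment", "ct"])
    truth = SyntheticCtTruth(
        true_folds={g: dict(f) for g, f in true_folds.items()},
        ref_gene=ref_gene,
        baseline=baseline,
        seed=seed,
    )
    return table, truth
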