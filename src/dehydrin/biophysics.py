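"""Charge, hydropathy, isoelectric point and mass of proteins and segments.

Conserved dehydrin segments are strongly hydrophilic and charged; the
expanded F-segment carries K3 E5 D2 R1 for a net formal charge of -3, while
the K-segment consensus carries K5 E2 D1 (net +2).  Net formal charge here
is the segment-level census (+1 per K/R, -1 per D/E, H and termini ignored);
the isoelectric point is the whole-protein statistic, found by bisecting the
Henderson-Hasselbalch titration curve over side chains and termini.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from Bio.SeqUtils import molecular_weight as _bio_mw

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

#: Kyte-Doolittle hydropathy indices (dimensionless, range [-4.5, 4.5]).
KD_SCALE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Side-chain and termini pKa tables.  Bjellqvist is the Expasy-compatible
#: default; EMBOSS is the iep alternative.
PKA_SETS = {
    "Bjellqvist": {
        "n_term": 7.5, "c_term": 3.55,
        "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
        "H": 5.98, "K": 10.0, "R": 12.0,
    },
    "EMBOSS": {
        "n_term": 8.6, "c_term": 3.6,
        "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
        "H": 6.5, "K": 10.8, "R": 12.5,
    },
}


@dataclass
class ChargeProfile:
    composition: dict[str, int]
    net_charge: int
    charged_summary: str


@dataclass
class HydropathyProfile:
    window: int
    values: np.ndarray
    gravy: float


def _check_protein(seq: str, allow_x: bool = True) -> None:
    allowed = VALID_RESIDUES | ({"X"} if allow_x else set())
    for pos, ch in enumerate(seq, start=1):
        if ch not in allowed:
            raise ValueError(f"invalid residue {ch!r} at position {pos}")


def residue_composition(seq: str) -> dict[str, int]:
    """Exact residue counts (errors name the first invalid position)."""
    _check_protein(seq)
    return dict(Counter(seq))


def charged_summary(seq: str) -> str:
    """The charged-residue census in K/E/D/R order, e.g. ``K3E5D2R1``."""
    comp = residue_composition(seq)
    return "".join(f"{r}{comp[r]}" for r in "KEDR" if comp.get(r, 0))


def net_formal_charge(seq: str) -> int:
    """Segment-level formal charge: (#K + #R) - (#D + #E); H counts 0."""
    comp = residue_composition(seq)
    return (comp.get("K", 0) + comp.get("R", 0)) - (comp.get("D", 0) + comp.get("E", 0))


def charge_profile(seq: str) -> ChargeProfile:
    return ChargeProfile(residue_composition(seq), net_formal_charge(seq), charged_summary(seq))


def kd_hydropathy(seq: str, window: int = 1) -> HydropathyProfile:
    """Per-position Kyte-Doolittle hydropathy, centered moving average.

    Edge positions use the residues available (shorter effective window).
    The default window of 1 returns the raw indices — the conserved segments
    analysed here are 6-18-mers, where smoothing would erase structure.
    GRAVY is the unweighted mean of the raw indices.
    """
    _check_protein(seq, allow_x=False)
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and positive, got {window}")
    if window > len(seq):
        raise ValueError(f"window {window} exceeds sequence length {len(seq)}")
    raw = np.array([KD_SCALE[c] for c in seq])
    half = window // 2
    values = np.array(
        [raw[max(0, i - half) : i + half + 1].mean() for i in range(len(seq))]
    )
    return HydropathyProfile(window=window, values=values, gravy=float(raw.mean()))


def gravy(seq: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle index."""
    return kd_hydropathy(seq, window=1).gravy


def _hh_net_charge(comp: Counter, ph: float, pka: dict[str, float]) -> float:
    """Henderson-Hasselbalch net charge at a given pH (termini included)."""
    pos = 1.0 / (1.0 + 10 ** (ph - pka["n_term"]))
    for res in ("K", "R", "H"):
        pos += comp.get(res, 0) / (1.0 + 10 ** (ph - pka[res]))
    neg = 1.0 / (1.0 + 10 ** (pka["c_term"] - ph))
    for res in ("D", "E", "C", "Y"):
        neg += comp.get(res, 0) / (1.0 + 10 ** (pka[res] - ph))
    return pos - neg


def isoelectric_point(
    seq: str, pka_set: str = "Bjellqvist", decimals: int | None = 2
) -> float:
    """pI by bisection on the Henderson-Hasselbalch titration curve.

    Bisection runs until |net charge| < 1e-3; the result is rounded to
    ``decimals`` places for reporting (pass None for the converged value —
    acidic proteins titrate steeply, so rounding can move the nominal charge
    above the convergence tolerance).  X residues contribute no charge.
    """
    if not seq:
        raise ValueError("empty sequence")
    _check_protein(seq)
    pka = PKA_SETS[pka_set]
    comp = Counter(seq)
    lo, hi = 0.0, 14.0
    ph = 7.0
    while True:
        ph = (lo + hi) / 2.0
        q = _hh_net_charge(comp, ph, pka)
        if abs(q) < 1e-3 or hi - lo < 1e-9:
            break
        if q > 0:
            lo = ph
        else:
            hi = ph
    return round(ph, decimals) if decimals is not None else ph


def charge_at_ph(seq: str, ph: float, pka_set: str = "Bjellqvist") -> float:
    """Henderson-Hasselbalch net charge of the whole protein at ``ph``."""
    _check_protein(seq)
    return _hh_net_charge(Counter(seq), ph, PKA_SETS[pka_set])


def molecular_weight(seq: str) -> float:
    """Average-isotopic mass in Da: residue masses plus one water."""
    if not seq:
        raise ValueError("empty sequence")
    _check_protein(seq, allow_x=False)
    return float(_bio_mw(seq, seq_type="protein"))


def profile_table(records):
    """Per-record biophysical report: length, MW, pI, charge, GRAVY, census."""
    import pandas as pd

    rows = []
    for rec in records:
        seq = rec.residues
        has_x = "X" in seq
        rows.append(
            {
                "id": rec.id,
                "length": len(seq),
                "mw_da": np.nan if has_x else round(molecular_weight(seq), 2),
                "pi": isoelectric_point(seq),
                "net_charge": net_formal_charge(seq),
                "gravy": np.nan if has_x else round(gravy(seq), 4),
                "charged_summary": charged_summary(seq),
            }
        )
    return pd.DataFrame(rows)
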