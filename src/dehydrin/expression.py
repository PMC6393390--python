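"""Relative-quantification qPCR analysis (comparative Ct method).

Expression of a test gene is normalised to a reference gene within each
sample (dCt = Ct_test - Ct_ref), referred to a baseline sample
(ddCt = dCt_sample - dCt_baseline), and reported as the fold change
2^-ddCt with the baseline defined as 1.  Replicate Cts (triplicate wells,
repeated experiments) are averaged per (sample, gene) before differencing;
significance against the baseline is a two-tailed Student's t-test on the
per-replicate fold values (* p < 0.05, ** p < 0.01).  Amplification
efficiency comes from a dilution standard curve (Ct vs log10 template),
E = 10^(-1/slope) - 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .seqio import SequenceRecord

CT_COLUMNS = ["sample", "gene", "replicate", "experiment", "ct"]


@dataclass
class FoldChangeResult:
    gene: str
    sample: str
    delta_ct: float
    delta_delta_ct: float
    fold: float
    p_value: float
    flag: str  # "ns", "*", "**"


@dataclass
class EfficiencyResult:
    efficiency: float
    slope: float
    r_squared: float


def read_ct_table(path) -> pd.DataFrame:
    """Read a TSV Ct table with columns sample/gene/replicate/experiment/ct."""
    table = pd.read_csv(path, sep="\t")
    return validate_ct_table(table)


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table is missing columns: {missing}")
    bad = table[(table["ct"] <= 0) | (table["ct"] >= 45)]
    if not bad.empty:
        raise ValueError(
            f"Ct values outside (0, 45) cycles in rows {bad.index.tolist()}"
        )
    return table


def _flag(p: float) -> str:
    if np.isnan(p):
        return "ns"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def fold_changes(
    table: pd.DataFrame,
    test_genes: Sequence[str],
    ref_gene: str,
    baseline_sample: str = "August",
    equal_var: bool = True,
) -> list[FoldChangeResult]:
    """ddCt fold changes of each test gene per sample, relative to baseline.

    Point estimates use replicate-averaged Cts; p-values come from a
    two-sample t-test (Student by default, Welch with ``equal_var=False``)
    of per-replicate folds in a sample versus the baseline sample.
    """
    table = validate_ct_table(table)
    samples = list(dict.fromkeys(table["sample"]))
    if baseline_sample not in samples:
        raise ValueError(f"baseline sample {baseline_sample!r} absent from table")

    ref = table[table["gene"] == ref_gene]
    gaps = []
    for gene in test_genes:
        sub = table[table["gene"] == gene]
        for sample in dict.fromkeys(sub["sample"]):
            if ref[ref["sample"] == sample].empty:
                gaps.append((gene, sample))
    if gaps:
        raise ValueError(f"reference gene {ref_gene!r} has no rows for: {gaps}")

    mean_ct = table.groupby(["gene", "sample"])["ct"].mean()
    results: list[FoldChangeResult] = []
    for gene in test_genes:
        gene_samples = list(dict.fromkeys(table[table["gene"] == gene]["sample"]))
        if baseline_sample not in gene_samples:
            raise ValueError(f"gene {gene!r} has no baseline ({baseline_sample!r}) rows")
        dct = {s: mean_ct[(gene, s)] - mean_ct[(ref_gene, s)] for s in gene_samples}
        base_dct = dct[baseline_sample]

        # per-replicate folds for the t-test, matched on replicate x experiment
        test_sub = table[table["gene"] == gene]
        merged = test_sub.merge(
            ref,
            on=["sample", "replicate", "experiment"],
            suffixes=("", "_ref"),
        )
        merged["fold_rep"] = 2.0 ** -((merged["ct"] - merged["ct_ref"]) - base_dct)
        base_folds = merged.loc[merged["sample"] == baseline_sample, "fold_rep"].to_numpy()

        for sample in gene_samples:
            ddct = dct[sample] - base_dct
            fold = 2.0 ** -ddct
            if sample == baseline_sample:
                results.append(
                    FoldChangeResult(gene, sample, dct[sample], 0.0, 1.0, float("nan"), "ns")
                )
                continue
            folds = merged.loc[merged["sample"] == sample, "fold_rep"].to_numpy()
            if len(folds) >= 2 and len(base_folds) >= 2:
                if np.ptp(folds) == 0 and np.ptp(base_folds) == 0:
                    # degenerate noiseless data: identical means are not
                    # significant, different means trivially are
                    p = 1.0 if np.isclose(folds.mean(), base_folds.mean()) else 0.0
                else:
                    p = float(
                        stats.ttest_ind(folds, base_folds, equal_var=equal_var).pvalue
                    )
            else:
                p = float("nan")
            results.append(FoldChangeResult(gene, sample, dct[sample], ddct, fold, p, _flag(p)))
    return results


def fold_change_table(results: Iterable[FoldChangeResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "sample": r.sample,
                "delta_ct": r.delta_ct,
                "delta_delta_ct": r.delta_delta_ct,
                "fold": r.fold,
                "p_value": r.p_value,
                "flag": r.flag,
            }
            for r in results
        ]
    )


def pcr_efficiency(
    dilution_factors: Sequence[float], cts: Sequence[float]
) -> EfficiencyResult:
    """Amplification efficiency from a dilution standard curve.

    ``dilution_factors`` are relative template amounts (e.g. 1, 0.5, 0.25);
    the least-squares slope of Ct against log10(amount) gives
    E = 10^(-1/slope) - 1 (a perfect doubling series has slope
    -1/log10(2) = -3.3219 and E = 1).
    """
    x = np.asarray(dilution_factors, dtype=float)
    y = np.asarray(cts, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 matched dilution points")
    if np.any(x <= 0):
        raise ValueError("dilution factors must be positive")
    logx = np.log10(x)
    if np.allclose(logx, logx[0]):
        raise ValueError("dilution factors have zero variance")
    fit = stats.linregress(logx, y)
    eff = 10.0 ** (-1.0 / fit.slope) - 1.0
    return EfficiencyResult(efficiency=float(eff), slope=float(fit.slope), r_squared=float(fit.rvalue**2))


def insilico_pcr(
    template: SequenceRecord, fwd: str, rev: str
) -> Optional[list[int]]:
    """Exact-match in-silico PCR; returns sorted product lengths or None.

    The forward primer must match the template strand and the reverse
    primer's reverse complement must occur downstream; the amplicon spans
    the forward primer start through the reverse-binding end, inclusive.
    """
    fwd, rev = fwd.upper(), rev.upper()
    if len(fwd) < 15 or len(rev) < 15:
        raise ValueError("primers must be at least 15 nt")
    seq = template.residues
    rc_rev = str(Seq(rev).reverse_complement())

    def _find_all(needle: str) -> list[int]:
        out, i = [], seq.find(needle)
        while i != -1:
            out.append(i)
            i = seq.find(needle, i + 1)
        return out

    lengths = []
    for f in _find_all(fwd):
        for r in _find_all(rc_rev):
            if r >= f + len(fwd):
                lengths.append(r + len(rc_rev) - f)
    return sorted(lengths) if lengths else None


def densitometry_folds(
    intensities: Mapping[str, float], baseline: str = "NA"
) -> dict[str, float]:
    """Band-intensity fold estimates relative to a baseline lane (== 1)."""
    if baseline not in intensities:
        raise ValueError(f"baseline {baseline!r} absent from intensities")
    base = intensities[baseline]
    if base <= 0:
        raise ValueError("baseline intensity must be positive")
    return {sample: value / base for sample, value in intensities.items()}
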