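# dehydrin

Sequence analysis of plant dehydrins — the group-2 LEA proteins that
accumulate under cold, drought and salinity stress — built around the
conserved segments that define the family: the lysine-rich **K-segment**
(the amphipathic consensus every dehydrin carries), the N-terminal
**Y-segment**, the **S-segment** serine tract, histidine-rich stretches,
and the **F-segment** — an 11-residue core `DRGLFDFLGKK` (named for its
paired phenylalanines) embedded in an 18-residue expanded consensus
`ETKDRGLFDFLGKKEEEE`.

The package is aimed at anyone characterising dehydrin repertoires from
protein or cDNA sequence: it detects the segments, types proteins in the
YSK shorthand (`Y3SK2`, `SK2`, `K1`, `Y2SK2+F3`/`F3SK2`, ...), mines
protein databases for F-segment copies, profiles the mined segments
(consensus, information content, NJ clustering), computes segment
biophysics (net charge, Kyte–Doolittle hydropathy/GRAVY, pI, MW), and
analyses seasonal qPCR expression by the comparative Ct method.

## Methods at a glance

* **Segment detection** — ungapped sliding windows scored with BLOSUM62; a
  window is a hit when `score ≥ t · self_score(consensus)` (default
  t = 0.6, Y-segment 0.8), with greedy non-overlapping selection.  Serine
  tracts are maximal runs (≥ 4 S); His-rich regions are merged 9-residue
  windows holding ≥ 5 H.
* **Architecture typing** — copy counts become the shorthand
  `Y^n S K^n (+F^n)` and one of the five structural types
  YnSKn / SKn / YnKn / Kn / KnS (K-segment presence is the
  dehydrin-defining requirement).
* **F-segment mining** — Smith–Waterman local alignment with affine gaps
  (BLOSUM62, open 11 / extend 1); copies are extracted iteratively by
  masking previous hits; hits scoring `≥ 0.5 · self_score` are kept and
  gap-containing segments are filtered out.
* **Consensus profiling** — L×20 positional count matrix, modal-residue
  consensus, information content `IC_j = log₂20 − H_j` (bits), p-distance,
  Saitou–Nei neighbor joining, average-linkage class assignment.
* **Biophysics** — formal charge `(#K+#R) − (#D+#E)` (H neutral, termini
  ignored), Kyte–Doolittle profiles and GRAVY, Henderson–Hasselbalch pI by
  bisection (Bjellqvist or EMBOSS pKa), average-isotopic MW.
* **Expression** — `ΔCt = Ct_test − Ct_ref`,
  `ΔΔCt = ΔCt_sample − ΔCt_baseline`, fold = `2^−ΔΔCt` with the baseline
  month defined as 1; Student's t-test on per-replicate folds
  (* p < 0.05, ** p < 0.01); standard-curve efficiency
  `E = 10^(−1/slope) − 1`; exact-match in-silico PCR.

Synthetic-data generators (planted-motif proteins, copy-number databases,
frequency-profile segment sets, noisy Ct tables) carry known ground truth,
so every stage is tested by parameter recovery without downloads.

## Worked example

```bash
python examples/04_biophysics.py
```

```
expanded F-segment: ETKDRGLFDFLGKKEEEE
  charged residues : K3E5D2R1
  net formal charge: -3
  GRAVY            : -1.611
  pI               : 4.5
  MW               : 2170.3 Da

K-segment: EKKGIMDKIKEKLPG
  charged residues : K5E2D1
  net formal charge: +2
  GRAVY            : -1.180
  pI               : 9.4
  MW               : 1714.1 Da
```

The expanded F-segment carries K₃E₅D₂R₁ for a net formal charge of −3 —
markedly more acidic than the K-segment's K₅E₂D₁ (+2) — and both are
strongly hydrophilic (negative GRAVY), as expected for intrinsically
disordered stress proteins.  `examples/01_scan_and_classify.py` builds a
synthetic three-F-copy dehydrin and prints every located segment plus the
`Y2SK2+F3` call (alias `F3SK2`); the other examples cover mining,
consensus/tree building, qPCR fold changes and ORF deduction.

A thin CLI wraps the same functions:

```bash
dehydrin simulate --spec Y2SK2+F3 --n 4 --seed 3 --out db.fasta
dehydrin mine --db db.fasta --out hits.tsv --summary summary.json
dehydrin expression --ct ct.tsv --ref RcUbql --baseline August
```

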