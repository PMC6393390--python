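# Methods

## Scope and model

Dehydrins are intrinsically disordered group-2 LEA proteins defined by the
presence of at least one K-segment; their repertoires are conventionally
described by the YSK shorthand counting segment copies.  This package
treats segment detection, architecture typing, F-segment mining, consensus
profiling, biophysical characterisation and qPCR expression analysis as one
pipeline over plain sequence data, with synthetic generators standing in
for field-collected inputs.

## Segment detection

Scored motifs (Y, K, core F, expanded F) are matched by an **ungapped
sliding window** of the consensus length, scored as the sum of BLOSUM62
substitutions between consensus and window.  A window qualifies when its
score reaches a fraction *t* of the consensus self-score; overlapping
candidates are resolved greedily (descending score, leftmost on ties), a
deterministic rule matching the "copy count" semantics of multi-copy
dehydrins.  Defaults:

| motif      | consensus            | rule                   | default |
|------------|----------------------|------------------------|---------|
| F_expanded | ETKDRGLFDFLGKKEEEE   | scored window          | t = 0.6 |
| F_core     | DRGLFDFLGKK          | scored window          | t = 0.6 |
| K          | EKKGIMDKIKEKLPG      | scored window          | t = 0.6 |
| Y          | DEYGNP               | scored window          | t = 0.8 |
| S          | —                    | run of S               | ≥ 4     |
| H          | —                    | ≥ 5 H per 9-window     | merged  |

The K-segment 15-mer was chosen because its charged-residue census is
K₅E₂D₁, the canonical composition of the motif; the His-rich rule (≥ 5 H in
9) is the loosest window rule under which the known instance `HHQHHHHVE` is
a positive.  All consensus strings and thresholds are overridable.  `X`
residues score 0 against everything, so database sequences with ambiguity
codes neither trigger nor break matches.

t = 0.6 is permissive enough for diverged orthologs while keeping the
per-sequence false-positive rate on uniform-random 100-mers below 5%
(property-tested).  Note the trade-off measured by the seeded Monte-Carlo
recovery tests: at 5% per-residue substitution the long motifs (K, expanded
F) remain detectable in > 95% of plants, but the 6-residue Y-segment at
t = 0.8 is lost for roughly half of single substitutions, putting overall
segment recovery near 93%.  Detection of short motifs in mutated sequences
is intrinsically fragile at this stringency; lowering t for Y raises
false positives instead.

## Architecture typing

Copy counts (with F_core hits nested inside F_expanded spans counted once,
as expanded) map to the shorthand `Y^n S K^n` plus an appended `+F^n` and
an F-alias in which the F-block replaces the Y-block (`F3SK2`).  Subscript
1 is written explicitly (`K1`, `Y1K1`).  The five structural types are
assigned from the counts; `KnS` versus `SKn` is disambiguated by segment
order (serine tract after the last K-segment ⇒ KnS), an inference from the
nomenclature since no KnS instance was available.  Informal labels
("blueberry type", "potato type") are free-text annotations only.

## F-segment mining

The database search is explicit **Smith–Waterman with affine gaps**
(BLOSUM62; a gap of length k costs 11 + k, the standard protein defaults).
An e-value gate would depend on the size and version of a reference
database and is irreproducible outside it; it is replaced by a
self-score-fraction threshold (default 0.5) on the local alignment score.
Multi-copy proteins are handled by iterative extraction: after each
accepted hit the matched span is masked with a symbol scoring −∞ and the
alignment repeats until the score falls below threshold, which provably
yields non-overlapping hits.  Exact-duplicate database entries are merged
first (redundant databases list identical sequences under several
accessions).  Tie-breaks: among equal-score optima the alignment with the
smallest (target start, query start) wins; traceback prefers
diagonal > deletion > insertion.

Segments whose optimal alignment to the consensus contains an internal gap
are filtered out before profiling — the observed instances of this
phenomenon are two-residue insertions in segments belonging to another
family, and "any internal gap" is the natural generalisation.

Correctness of the aligner is established against a brute-force suffix
recursion (an independent formulation that enumerates stop/match/gap
decisions) on hundreds of random short pairs, plus symmetry and re-scoring
invariants.

## Consensus profiling and clustering

Equal-length, gap-free segments feed an L×20 count matrix whose rows sum
to n.  The consensus takes the per-position modal residue, ties broken
lexicographically (determinism).  Information content is
`IC_j = log₂20 − H_j` bits from raw observed frequencies; no small-sample
correction is applied by default because the profile sizes used (n ≈ 208)
make the correction (≈ 19/(2·ln2·n) ≈ 0.066 bits) negligible relative to
the signal.

Trees are built by Saitou–Nei **neighbor joining on p-distance**
(mismatch fraction).  Q-matrix ties break on the smallest index pair;
negative branch lengths are clamped to zero with the deficit moved to the
sister branch.  NJ is exact on additive metrics, which the tests exploit
(closed-form 3-taxon star, random 5–8-taxon additive metrics reproduced to
1e-6).  Class assignment cuts an average-linkage dendrogram of the same
distance matrix into k groups (default k = 5); exact class memberships of
any particular published tree are not an acceptance surface, since the
clustering method behind such figures is generally unstated.

## Biophysics

* **Formal charge** (segment statistic): +1 per K/R, −1 per D/E; H counts
  0 and termini are excluded.  This is the only convention under which the
  expanded F-segment's census K₃E₅D₂R₁ gives the reported −3.
* **pI** (whole-protein statistic): bisection on the
  Henderson–Hasselbalch net charge over side chains (D, E, C, Y, H, K, R)
  and both termini, to |charge| < 1e−3.  The reported value is rounded to
  two decimals; acidic proteins titrate steeply near their pI, so the
  converged (unrounded) value is available via `decimals=None` and is the
  one satisfying the charge tolerance.  pKa sets: Bjellqvist
  (Expasy-compatible, default) and EMBOSS — tools rarely state their
  table, so both common ones are provided.
* **Hydropathy**: Kyte–Doolittle indices with a centered moving average;
  edges use truncated windows.  Default window 1, because the conserved
  segments are 6–18-mers where smoothing erases structure; GRAVY is the
  unweighted mean of raw indices.
* **MW**: average-isotopic residue masses plus one water (via Biopython).

## Expression analysis

`ΔCt = Ct_test − Ct_ref` within a sample, `ΔΔCt` against the baseline
month (August), fold = `2^−ΔΔCt`, baseline ≡ 1.  Replicate Cts are averaged
per (gene, sample) for the point estimate; significance is a two-tailed
equal-variance Student's t-test (Welch by flag) on per-replicate folds
pooled across the independent experiments — how published designs pool
triplicates across experiment repeats is typically unstated, so the
pooling is explicit and configurable here.  Flags: * p < 0.05,
** p < 0.01.  Standard-curve efficiency is `E = 10^(−1/slope) − 1` from
the least-squares slope of Ct versus log₁₀ template amount (a perfect
doubling series gives slope −3.3219, E = 1 to 1e−9).  In-silico PCR uses
exact primer matching (primers are designed from the target sequences
themselves, so mismatch tolerance is unnecessary); the amplicon spans the
forward-primer start through the reverse-binding end.

## Synthetic data: what it emulates, and what it does not

* `simulate_dehydrin` concatenates motif templates per an architecture
  spec (`+Fn` placed N-terminal, where multi-copy F-segments are observed)
  with random linkers of hydrophilic, disorder-promoting residues
  (G, T, E, K, P, A) and applies i.i.d. substitutions.  Serine and
  histidine are excluded from the linker pool so a random linker can never
  fabricate an S-tract or His-rich segment — without this exclusion a
  ~1% per-linker chance of a spurious `SSSS` would break exact
  architecture round-trips at mutation 0.
* `simulate_segment_db` plants 0–3 expanded F-segment copies per protein
  with a configurable copy distribution (default 0.2/0.4/0.2/0.2,
  echoing the observed mix of negatives and one-, two- and three-copy
  orthologs).
* `sample_from_frequency_profile` draws segments i.i.d. per position from
  a modal-count profile.  The built-in 18-position profile stores, for
  each position, the modal residue and its count out of 208; the residual
  mass is spread uniformly over the other 19 residues (a Dirichlet-free
  default that affects IC but not consensus recovery).  The final
  glutamate position reuses its neighbour's count, the one position for
  which no census was available.
* `simulate_ct_table` writes `Ct = Ct₀ − log₂(fold) + N(0, σ)` for the
  test gene and constant-mean Cts for the reference gene, triplicate wells
  × two experiments by default, emulating a monthly August→February
  sampling design.

What passing these tests shows: the analyzers invert their generators —
architecture, copy number, consensus and fold trajectory are recovered
under the stated noise.  What it does not show: performance on real
proteomes (domain composition, compositional bias and homologous
non-dehydrin LEA proteins are not modelled), real qPCR error structure
(pipetting correlations, efficiency ≠ 1, inhibitors), or database-search
behaviour against NR-scale redundancy.

## Problem sizes and statistical tolerances

Recovery rates are Monte-Carlo estimates at fixed seeds: consensus
recovery uses 100 replicates of n = 208 segments; fold-change recovery
uses 50 tables of 6 months × 3 replicates × 2 experiments at σ = 0.2
cycles, asserting ≥ 90% of per-sample fold estimates within 25% relative
error and ≥ 90% power for the 15-fold January induction (the per-estimate
relative error at this design is ≈ 11% (1σ), so a per-table all-samples
bound would be a coin flip, while the Monte-Carlo fraction is stable).
The alignment oracle runs 200 random pairs of length ≤ 10, where the
exponential-enumeration oracle is exact and fast.

## Known limitations

* Ungapped window scanning cannot detect segment copies containing
  insertions or deletions; the mining module (gapped Smith–Waterman) is
  the tool for that case.
* ORF finding scans forward frames by default (directionally cloned cDNA);
  a six-frame flag exists but coordinates are then reported on the scanned
  strand.
* The YSK classifier counts only the built-in motif set; exotic segments
  require supplying custom `MotifDefinition`s.
* pI depends on the pKa table; values are comparable within one table
  only, and reported to two decimals.
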