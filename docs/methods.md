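# Methods

`ghmotif` re-implements, as a tested library, a structure-and-sequence
analysis of the lysozyme superfamily of glycoside hydrolases (GH19, GH22c/i,
GH23, GH24v/l, GH46): clustering of structural-similarity scores with
resampling-based node reliability, entropy-based conservation profiling,
extraction and benchmarking of family signature motifs built around the
conserved β-hairpin, and characterization of active-site geometry. This note
records the models, the defaults and why, the numerical conventions, and what
the synthetic generators do and do not emulate.

## Structure clustering

**Similarity → distance.** Input is a labelled symmetric matrix of pairwise
structural-similarity Z-scores S_ij (Dali-style, self-scores S_ii on the
diagonal). The transform to a distance is pluggable; the default is

    D_ij = 100 · (1 − 2·S_ij / (S_ii + S_jj))

It gives D_ii = 0 exactly, D_ij = 100 for unrelated structures (S_ij = 0), a
0–100 scale consistent with published inter-family structural distances for
this superfamily, and is strictly decreasing in S_ij at fixed self-scores.
The exact transform used in the original analysis is not publicly specified,
which is why the transform is a named, substitutable option and why printed
inter-family distances are not asserted anywhere in the test suite. Scores
exceeding a self-score violate the domain assumption and are clamped to
distance 0 with a log message.

**UPGMA.** Agglomerative average-linkage clustering: repeatedly join the
closest pair of clusters; the distance of the merged cluster to any other is
the member-count-weighted arithmetic mean; node height is half the merge
distance, making the tree ultrametric. Ties between equally close pairs are
broken by the lexicographically smallest (minimum-leaf-label) pair, so the
tree is identical across platforms and runs. When the input matrix is itself
ultrametric, the tree's cophenetic matrix reproduces it exactly; this is the
main correctness oracle (checked against generated ultrametric matrices and
against scipy's average linkage as an independent route).

**Jackknife node reliability (Lanyon-style).** Each structure is removed in
turn and the tree rebuilt from the remaining similarities. An internal node
of the full tree is *reliable* only if, in every replicate, its clade
restricted to the surviving taxa appears as a clade of the replicate tree.
Restricted clades of size < 2, or spanning all surviving taxa, are counted
as vacuously present — the original criterion ("found in all possible
trees") does not address them, and a one- or zero-leaf set has no testable
grouping. The report records, per clade, exactly which deletions broke it.

**Family distances.** Within-family mean over unordered member pairs
(singletons rendered "–"); between-family mean over all cross pairs. The
mean (rather than min/max) matches the "mean distance between families"
reading; population conventions are stated where they matter (below).

## Conservation profiling

Per-column conservation follows the AL2CO entropy recipe:

1. **Sequence weights** — position-based Henikoff weights (at each column a
   sequence holding residue *a* gets 1/(r·s_a); sums averaged over columns,
   rescaled to total n). This is a documented stand-in for AL2CO's
   "independent count" estimator: both down-weight near-duplicates; the
   independent-count estimator is not reproduced bit-exactly. A scoring
   matrix (e.g. BLOSUM62) is accepted in family configuration for
   provenance but is irrelevant to the entropy measure and unused.
2. **Weighted frequencies** per column over the 20 amino acids. Gap
   characters `-` and `.` are normalized to `-`; `X` is missing data
   (counts toward neither frequencies nor the gap fraction). Columns with
   weighted gap fraction > 0.5, or with no residue at all, are flagged and
   excluded from all downstream statistics.
3. **Raw index** C = Σ_a f_a ln f_a (nats): 0 for an invariant column,
   −ln 20 at the uniform minimum. Natural log is the AL2CO convention.
4. **Smoothing** — centred moving average, window 3 (odd required); the
   window shrinks at the profile edges and skips flagged columns.
5. **Normalization** — z-scores over unflagged columns with the population
   SD, so the reported profile has mean 0 and SD 1 by construction. A
   zero-variance profile normalizes to all zeros with a warning.

The profile is mapped onto the representative sequence: alignment columns
where the representative row has a gap are unmapped; mapped columns receive
consecutive author residue numbers from a configured start. All residue
labels in outputs are author numbers of the representative structure, never
serial renumbering.

**Signature-motif extraction.** The family signature is the contiguous
column window, with length in [8, 18] (the observed range of published
motif lengths is 9–17), that contains the configured β-hairpin columns and
maximizes the *summed* z-score of the raw conservation index. Summing gives
the window a natural boundary: columns more conserved than average extend
it, less-conserved columns terminate it, so a conserved block is recovered
at its true edges. (A windowed *mean* was considered and rejected: on a
uniformly conserved block it always collapses onto the shortest admissible
sub-window, because a shorter inside-window has mean at least as high.)
Exact ties prefer the shorter, then the leftmost window; a hairpin longer
than the maximum length is returned unchanged with a warning. Flagged
columns score strongly negative so gappy extensions are never selected.

## Signature models and search

**Logo content.** Per position: weighted relative frequencies and
information content IC = log2 20 − H₂(f) in bits, no small-sample
correction; all-gap positions are flagged with IC 0.

**Profile model.** Position-specific emissions with background
pseudocounts, emission(p, a) = (w-count(p, a) + α·bg(a)) / (Σw_p + α),
log-odds ln(emission/bg) in nats. Defaults: α = 1, uniform background
(1/20, overridable by a composition estimated from a negative set),
gap-open 4.0 nats, gap-extend 0.5 nats. With α = 0 unseen residues get
−∞ log-odds, i.e. forbidden matches — permitted and documented.

This is a deliberate simplification of a plan-7 profile HMM: the scientific
claim being tested is the discriminability of the signature, not HMM
internals, and the simplified model admits an exhaustive-enumeration oracle.

**Glocal scoring.** The motif must be accounted for end to end (each
position matched or deleted); the sequence contributes a free local window.
Alignment grammar: optional leading deletion run; gap runs cost
open + (k−1)·extend; insertion runs sit strictly between matches (no
insertion adjacent to a deletion); at least one match; trailing deletion
run allowed. The dynamic program over match/insert/delete states is proven
equivalent to brute-force enumeration of all alignments under this grammar
for all small instances in the test suite. An empty sequence returns a
−∞ sentinel.

**Threshold and evaluation.** The default threshold is the empirical 99th
percentile of best scores over simulated background sequences (target FPR
1%), always reported alongside results. TPR = hits among members / members;
FPR = hits among non-members / non-members; either rate is NA when its
denominator is empty. A curated-database correction is implemented as its
arithmetic only: identifiers on a supplied exclusion list are removed from
the false-positive denominator. Published database-scale TPR/FPR values
depend on a 2010 database release and live curation and are therefore
reproduced only qualitatively, on synthetic benchmarks.

## Structure geometry

**Torsions.** φ(i) = C(i−1)–N–Cα–C, ψ(i) = N–Cα–C–N(i+1),
ω(i) = Cα(i−1)–C(i−1)–N–Cα, IUPAC sign convention, degrees in (−180, 180].
Torsions spanning a peptide bond with C–N > 2.5 Å (a crystallographic chain
break) or involving a missing backbone atom are undefined (NaN, logged).

**Conformation classes.** The Ramachandran half-planes are partitioned into
handed helical/extended boxes. Left-handed requires φ > 20°: *helical* for
ψ ∈ [−45°, 90°), *extended* for ψ (mod 360°) ∈ [90°, 240°). Right-handed
classes are the exact mirror images (φ < −20°); |φ| ≤ 20° and the remaining
ψ sectors are unclassified. The published analysis states only "positive
φ" / "left-handed helical or extended"; these degree bounds are this
package's documented formalization and are deliberately generous around the
canonical αL (≈ 57°, 47°) and left-extended (≈ 75°, 170°) conformations.

**β-turns.** A four-residue window qualifies when Cα(i)–Cα(i+3) < 7 Å and
its central residues are not interior to a continuous α-helix (a run of ≥ 4
right-handed-helical residues — the canonical type I centre dihedrals
themselves fall in the helical box, so the exclusion must use run context,
not per-residue class). Central (φ, ψ) pairs are compared to canonical
values — I: (−60, −30, −90, 0); I′, II, II′ as mirrors/variants — within
±30°, one angle allowed ±45°; windows passing the distance gate but no
named type are type IV.

**Hairpins.** Without donor/acceptor hydrogen-bond assignment (deliberately
out of scope — strand assignment by H-bond energies is known to fail on
some structures of this superfamily), strands are paired Cα-to-Cα by the
best rigid register: antiparallel registers satisfy n1 + n2 = const, and
the register with most pairs under 5.5 Å (ties: smallest mean distance)
wins. If a parallel register (n2 − n1 = const) fits better, the strands
are not antiparallel and an error is raised. The X:Y class reports loop
residues by two brackets: X between the innermost paired residues, Y
between the supplied strand ranges; the canonical conserved hairpin is 4:4.

**Active-site distances.** Role atoms: Glu {OE1, OE2}, Asp {OD1, OD2},
Ser {OG}, Thr {OG1}, Gln {Cβ only}. A role-pair distance is the minimum
over the two atom sets, reported to 0.01 Å. Missing or mutated role
residues yield "/" cells (logged, skipped in family means — whether the
original analysis skipped structures lacking a partially conserved role
residue is unstated, so skip-with-log is the documented choice). Family
summaries report mean and *population* SD (divide by n; the printed-table
convention is not stated in the source analysis), with "–" for singleton
families.

## Synthetic data

All generators are pure functions of (spec, seed) with a single
`numpy.random.default_rng` per call; identical inputs give bitwise-identical
outputs, and every generator returns the ground truth needed to score the
downstream stage.

* **Similarity matrices** — planted partition with Gaussian within-family
  (default 35 ± 2), between-family (5 ± 2) and self (45 ± 1) scores,
  clipped to keep self-scores maximal. The defaults put within/between
  separation in the regime where real Z-scores in this superfamily live
  (roughly 1–47, with clear family structure) while leaving enough noise
  for occasional shallow-node instability.
* **Ultrametric matrices** — recursive random splits with strictly
  decreasing merge heights; used as the exact oracle input for UPGMA.
* **Alignments** — planted motif block (defaults: 40 sequences × 120
  columns, block columns 40–52, consensus emitted with probability 0.95,
  uniform background giving 5% chance column identity, 2% gaps outside the
  block). 40 sequences is a mid-sized family for this superfamily (real
  families span tens to ~1000 sequences).
* **Peptides** — NeRF internal-to-Cartesian construction with fixed
  standard geometry (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å;
  angles N–Cα–C 111.2°, Cα–C–N 116.2°, C–N–Cα 121.7°, Cα–C–O 120.8°).
  Presets: ideal strand (−120°, 130°); a type-I-turn hexapeptide; 4:4 and
  2:2 hairpins whose loop dihedrals were found once by constrained
  geometric optimisation (canonical type I turn fixed at the loop centre,
  loop closure and cross-strand Cα pairing optimised, clash-penalised) and
  frozen as constants. Side-chain pseudo-atoms (OE1, OD1, OG, OG1, CB) are
  placed by explicit coordinates, not rotamer libraries.
* **Sequence databases** — positives embed the motif consensus mutated per
  position at a configurable divergence (default 0.1) inside random flanks
  (10–40 residues); negatives are pure background of comparable length.

What the generators do **not** emulate: phylogenetic correlation between
sequences (no substitution-matrix evolution), alignment errors,
compositional bias, side-chain packing, crystallographic artefacts
(alternate conformations beyond simple cases, disorder), or multi-domain
context around the motif. Passing tests therefore demonstrate algorithmic
correctness and statistical behaviour under the stated model — they do not
certify performance on real database searches, where background
composition and homologous near-misses dominate the false-positive rate.

## Problem sizes and determinism

The default verification suite uses matrices up to n = 12 (100 seeds),
50-seed alignment batches, a 50/500 positive/negative search benchmark,
enumeration-oracle instances up to motif length 4 against sequences up to
length 8, and 500 random 10-residue chains for the torsion round trip —
sizes chosen so each property is measured with comfortable margins while
the whole suite runs in well under a minute per stage. All randomness is
seeded; `scripts/acceptance.py --seed N` derives every generator seed from
N.

## Known limitations

* The similarity→distance transform is a stated default, not a recovered
  constant; absolute distances depend on it (tree topology is invariant
  under any strictly monotone transform of similarities only when
  self-scores are equal).
* Henikoff weighting approximates, not reproduces, the independent-count
  weighting; absolute conservation indices are therefore not comparable
  to AL2CO output, though peak locations are robust.
* The glocal scorer is not a probabilistic HMM: no posterior decoding, no
  E-values; the calibrated-threshold FPR is empirical.
* Hairpin classing without H-bonds can differ from Promotif's class for
  irregular sheets; explicit strand ranges from configuration always
  override detection.
* PDB insertion codes are preserved in residue keys but no structure with
  insertion-coded catalytic residues has been exercised; such residues are
  flagged rather than silently renumbered.
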