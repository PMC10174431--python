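# Methods

This note documents the models, conventions and design choices behind
the package, and what the synthetic benchmarks do and do not show.

## Pairwise alignment and homology statistics

Homology evidence comes from optimal pairwise alignment —
Smith–Waterman (local, the default for searches) and Needleman–Wunsch
(global), both with affine gaps — delegated to Biopython's
`PairwiseAligner` behind the package's own surface. Conventions that
downstream rules depend on:

* **Scoring**: BLOSUM62 by default; gap open 11, extend 1. A gap of
  length L costs `open + (L − 1)·extend` (the textbook/Biopython affine
  convention). Raw scores are used directly; no bit-score conversion.
* **Identity dialect**: identical residue columns divided by the
  alignment length *including internal gap columns*, ×100, reported to
  two decimals. `X` never counts as an identity. Identity values are
  dialect-sensitive, so reported identities are only comparable within
  this convention.
* **E-values**: Karlin–Altschul form `E = K·m·n·exp(−λS)` with the
  published gapped BLOSUM62-11/1 constants λ = 0.267, K = 0.041
  (configurable). For proteome searches n is the summed length of the
  searched sequence set. `E = 0` for an empty search space.
* **Coordinates**: 1-based, inclusive. Coordinate transfer between a
  query and a reference runs through the alignment columns; a reference
  position opposite a gap, or outside a local alignment, is UNMAPPED.
* Local alignment of sequences with an all-non-positive score landscape
  returns the empty alignment with score 0.

Correctness is anchored by an exhaustive-enumeration oracle: for random
pairs up to length 5 the DP score must equal the maximum over every
gapped alignment (local mode: over every substring pair), and the
E-value formula is checked against hand-computed values.

## Ortholog assignment

Each catalog activity is searched with one designated reference protein
(the first with a bundled sequence); all proteome sequences are ranked
by raw score (ties: E-value, then id), and the best-matching sequence is
the representative — multiple alleles therefore resolve to the highest
scorer. Tiers defer judgment rather than discarding weak evidence
(strong E ≤ 1e-10, weak E ≤ 1e-2, else marginal): the real inventory
keeps hits as weak as E ≈ 0.44, so no hard cutoff is applied at search
time.

Presence calls use a permissive rule — best hit with E ≤ 10 and ≥ 25%
of the reference covered — plus an **unambiguous-assignment
verification**: the hit's score into the activity's reference family
must be at least 1.5× its best score into any other family (families
group the references of activities sharing one locus: the two
oxidosqualene cyclases, the two Δ-14/Δ-24(24¹) reductases, the three
methylsterol monooxygenase EC variants). The verification is this
package's offline analogue of the secondary domain check applied to
candidate sequences in the original study design: an E ≤ 10 ceiling by
itself expects ~10 chance alignments per search, and chance hits have
flat score profiles across unrelated references, while even distant
true orthologs dominate their own family. On the synthetic benchmark
this step removed every observed false presence call (21/105 MEP cells
flipped without it over 15 seeds; 0/210 with it over 30 seeds) without
losing any planted ortholog.

## Residue-rule classifiers

Both classifiers align the query to a designated reference locally and
read residues through the coordinate map.

* **Oxidosqualene cyclase specificity**: sites 381/449/453 in the
  human-enzyme numbering; Y/H/I → cycloartenol synthase, T/{C,Q}/V →
  lanosterol synthase. All three sites must match one class; mixed
  signatures are `ambiguous`.
* **Alternative squalene epoxidase**: nine histidine positions in the
  reference frame; verdict `present` only at 9/9 conserved (any single
  substitution gives 8/9 and `absent`). The positions are configuration
  data (`data/altsqe_motif.yaml`), not code: the motif is defined by a
  count and a reference alignment, so the bundled default uses the
  synthetic stand-in reference with nine marked positions.
* **Evidence floor**: local E ≤ 1e-5 and ≥ 40% of the reference
  covered; below it the verdict is `indeterminate`, distinguishing "no
  homolog found" from "homolog lacking the signature".

## Catalog and reaction graph

The activity inventory stores one entry per distinct (symbol, EC) pair:
9 MVA activities, 7 absent MEP activities, and 19 sterol-section
entries from farnesyl pyrophosphate onward (the sterol
methyltransferase appears once with three plant references; the
monooxygenase appears as three EC variants sharing one locus; the two
cyclase activities share the single OSC locus). The alternative
epoxidase is stored as a 20th sterol-section activity flagged
`supplemental` — it enters via a dedicated homology search, not the
primary inventory, and substitutes for the absent conventional
epoxidase in the reaction graph when detected; inventory counts exclude
supplemental entries.

The graph encodes the postulated reaction scheme: the MVA chain from
acetyl-CoA to farnesyl pyrophosphate, squalene synthesis and
epoxidation, both cyclase products, the lanosterol → zymosterol →
cholesterol branch with its two zymosterol sub-routes (via desmosterol,
and via zymostenol/lathosterol), and the cycloartenol →
obtusifoliol → sitosterol → stigmasterol branch. The zymostenol
sub-route uses the standard enzyme assignment (Δ5-desaturation by STE1
followed by Δ7-reduction by DWF5) because the source description of its
final steps is internally inconsistent (it would apply the Δ-24
reductase twice); reachability conclusions were checked to be identical
under either encoding. Absent MEP activities contribute no edges.
Reachability is directed graph search (networkx) from acetyl-CoA over
edges whose catalyzing activity is called present; knockouts recompute
reachability with the knocked symbols treated as absent. A brute-force
single-knockout scan (independent BFS) fixes the blocker sets for the
bundled graph and is asserted in the tests.

## Quantification layer

* **Internal-standard quantification**: mg/g DCW =
  (peak / IS signal) × IS amount (mg) / DCW (g) — the single-point
  reduction of standard-curve calibration; a multi-point linear
  calibration is intentionally out of the default path. Values below
  the limit of detection (default 0.01 mg/g, configurable) are reported
  as `detected = False`, value 0, and excluded from fold denominators
  with an explicit flag.
* **Effects**: fold = mean(treated)/mean(control);
  percent = (fold − 1)×100, asserted on every estimate. "X-fold
  increase over control" is read as ratio = X (4.51-fold ⇒ +351%), and
  "decrease of Y%" as percent = −Y; this convention is stated here
  prominently because fold language is ambiguous in general prose.
* **Paired t-tests**: hand-computed mean difference over its standard
  error, df = n−1, two-sided p from the t distribution; zero-variance
  differences are flagged degenerate (p = 1 when all differences are 0,
  else the 0-limit). The implementation is checked against
  `scipy.stats.ttest_rel` to 1e-9 on random fixtures. No
  multiple-testing correction is applied, matching triplicate-level
  practice in this experimental design; a limitation when many analytes
  are scanned.
* **qPCR**: classic ΔΔCt with amplification efficiency fixed at 2;
  rel_expr = 2^(−ΔΔCt), log2 fold change = −ΔΔCt, contrasted against
  the time-matched untreated control (the pairing key is
  configuration).

## Synthetic data

The generators define the study conditions; they are deterministic
given a seed (single `numpy.random.Generator` stream per call).

* **Reference library**: synthetic stand-in proteins (realistic
  amino-acid background composition, lengths 360–520) for every
  designated reference id, bundled as
  `data/reference_proteins.synthetic.fasta` and reproducible from
  `build_reference_library()`. Activities sharing a locus get
  homologous references (~78% identity family derivation); the cyclase
  numbering anchor carries T/C/V at 381/449/453, the plant cyclase
  reference Y/H/I, and the epoxidase reference histidines at the nine
  motif positions. Only coordinate conventions of the real references
  are emulated, not their sequences.
* **Proteomes**: one diverged ortholog per present catalog locus,
  produced by substitution-only mutation to a target identity (default
  65%, exact to rounding because no indels are introduced), with
  substitutions drawn preferring high off-diagonal BLOSUM62 scores so
  diverged orthologs stay alignable (uniform draws are a fallback
  mode); diagnostic sites and motif histidines are preserved and
  planted per scenario. Decoys (default 10) are per-sequence shuffles
  of references (or fresh random-composition sequences) and carry no
  signatures.
* **Experiments**: triplicate measurement rows per (analyte,
  concentration, time) with treated value = baseline × planted
  multiplier × (1 + CV·N(0,1)), truncated at 0 (multiplicative noise
  matches positive-valued peak signals; CV default 0.05, 0 = exact),
  plus matching qPCR Ct rows built from planted log2 fold changes.
  The five bundled scenarios (growth timecourse; mevinolin,
  fosmidomycin, terbinafine, ketoconazole dose series) plant the
  reported endpoint effects at the reported concentrations; cells
  without a reported value carry plausible monotone fills chosen once
  (commented in the scenario files). Undetectable outcomes
  (stigmasterol under ketoconazole; lanosterol at the highest
  mevinolin/terbinafine doses) are multiplier 0.

**What passing tests show — and don't.** Noise-free recovery
demonstrates that the quantification algebra is exact through the whole
pipeline, not that real chromatogram integration would be. The
proteome benchmark plants point-substitution divergence without indels,
domain shuffling, paralog families beyond the declared locus families,
or compositional bias, so the measured 100% ortholog recovery bounds
only this regime; real proteomes would stress the coverage and
ambiguity rules harder. Growth (DCW) responses and chromatogram/peak
processing are out of scope.

## Problem sizes and numerics

Test and acceptance runs use deliberately compact sizes chosen as
representative: proteomes of ~34 sequences (24 loci + 10 decoys),
alignment oracle pairs up to length 5 (the enumeration space is
complete there), 20–50 seed replicates for recovery rates, and
triplicate measurement tables matching the experimental design.
E-values below the double-precision exponent range underflow to 0,
which is the correct limit for the tier logic. Score ties in best-hit
ranking break by E-value then lexicographic query id, making rankings
deterministic.
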