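# Methods

## Scope and overall design

The package implements the inference layer that sits between a genome
assembly and its evolutionary interpretation: ages of intact LTR
retrotransposons, the collinearity structure of a duplicated genome, and
the timing evidence (Ks, 4dTv) for whole-genome duplications. Every
estimator is paired with a simulator that plants the quantity being
estimated, so correctness is established by recovery of known truth and,
for the discrete algorithms, by brute-force oracles on small instances.

## Mutation model and LTR dating

Sequence evolution in the simulator is site-independent Jukes–Cantor with
no indels: each site changes with probability ¾(1 − e^(−4d/3)) to a
uniformly chosen different base. This is a deliberate trade — indel
realism is sacrificed so that the Jukes–Cantor correction used by the
dating path is *exactly* the right estimator and recovery tests have
closed-form expectations. Each LTR copy evolves d = r·T independently, so
the pair diverges by 2rT (Markov additivity), matching T = K/2r.

Parameters that matter:

* **r** — neutral substitution rate, 7.0×10⁻⁹ substitutions/site/year by
  default; a single global constant per run. Per-lineage rates are out of
  scope.
* **λ filter** — elements with λ ≥ 0.75 are `saturated`: the JC transform
  is undefined there, the boundary is exclusive. Dating additionally
  guards on the *ungapped* divergence of the two equal-length arms,
  because a global aligner will otherwise pull a truly saturated pair
  just under 0.75 by hiding mismatches in gaps.
* **min_sites** — alignments with fewer than 50 usable columns are
  `too_short` (a 50-column λ has a standard error comparable to the
  signal for young elements).
* **alignment scores** — the generic global aligner defaults to match 1 /
  mismatch −1 / gap −2 with deterministic diagonal-first traceback. The
  dating path alone uses gap −4: the two LTRs of one element are
  positionally homologous over their full length, and a cheap gap biases
  ages down by ~2–3% at 10 Myr divergence (measured on simulated truth).
* **edge trim** — 8 alignment columns are dropped from each end before
  counting λ. Structurally detected boundaries are least reliable at
  their termini (maximal-score extension always ends on a match, clipping
  genuine terminal mismatches; failed terminus snaps overshoot into
  flanking sequence). Divergence is site-homogeneous, so the interior
  count is unbiased and the trim costs only 16/300 sites of information.

## Structural detection

Detection is seed-and-extend: exact k-mer pairs (default k = 20) at
separations within [min_sep, max_sep] are clustered by diagonal, extended
ungapped to the maximal-score boundary (match +1 / mismatch −2 — the
asymmetry keeps extension uphill inside a diverged LTR pair but strongly
downhill in non-homologous flank, bounding boundary overshoot), snapped
to TG…CA termini within ±12 bp when both arms carry them, and refined
with a gapped identity check (global edit distance). TSDs are the longest
identical 4–6 bp flank match; their absence demotes the score by 5% but
does not reject, and TG…CA is a flag, not a requirement — standard-tool
tolerance. Overlap conflicts resolve greedily by score (identity ×
length), leftmost on ties, so output order is deterministic. This is a
deliberate simplification of suffix-array intact-element finders; at the
scales tested it gives ≥95% recall on planted elements ≤5 Myr old and
essentially zero calls per Mb of i.i.d. sequence.

Defaults (min_ltr 100, max_ltr 3500, min_sep 1000, max_sep 15000,
min_identity 0.8) are community conventions for "intact" elements, all
configurable; no published threshold set exists for this combination of
criteria.

## Superfamilies, lineages, trees

Superfamily calls use domain *order* only: INT strictly before RT ⇒
Ty1/copia; RT (and RH, when present) strictly before INT ⇒ Ty3/gypsy;
anything else `unknown`, duplicated domains an error. Domain hits are
inputs (the simulator plants fixed 30-bp marker motifs; real pipelines
would supply profile-HMM hits) — profile matching itself is out of scope.

Neighbor joining is the standard Saitou–Nei agglomeration with two
determinism rules: ties in the Q-criterion break by label order, and
negative branch lengths are clamped to zero with the deficit moved to the
sister branch. On additive matrices the tree is exact (checked to 1e-9
against the four-point example and scikit-bio). Lineage assignment builds
the NJ tree from uncorrected p-distances of the query RT plus labelled
exemplars and reports the lineage of the nearest reference leaf by path
length; exact ties give `unknown`, queries under 100 bp are rejected.

## Collinearity and syntenic depth

Chaining works in gene-rank coordinates (order index per chromosome, not
bp; individual gene strand is ignored, block orientation is same/
inverted). Within one chromosome pair and orientation the dynamic program
maximises Σ anchor scores − gap_penalty·Σ skipped ranks, with at most
max_gap (default 25) skipped ranks per genome between consecutive
anchors. Chains are extracted greedily by score with used anchors
removed — each anchor belongs to at most one block, trading global
optimality for determinism — and blocks under min_pairs are discarded.
The block threshold default is min_pairs = 5; "more than 5" in common
usage is ambiguous between ≥5 and ≥6, and 5 follows the cited tool
convention (configurable). In self-comparisons, gene-vs-itself pairs and
unordered duplicates are removed first, so the trivial diagonal and
mirror blocks never appear.

Depth of a reference gene is the number of blocks whose chrom_a rank span
contains it. The ratio test reports the modal nonzero depth and calls
"duplication consistent" when the mode is 2 and fewer than 10% of genes
lie at depth ≥ 3 — the sharp decline past 2× that distinguishes a clean
1:2 ratio from higher ploidy or noise.

## Ks, Ka, 4dTv

Codon alignment translates both CDS, aligns the proteins (match 2 /
mismatch −1 / gap −4) and back-translates gaps as whole-codon triplets;
gapped columns are excluded from every count. The estimator is
Nei–Gojobori (1986): per-position synonymous-site fractions averaged over
the two sequences, multi-difference codons averaged over all minimal
mutational pathways (pathways through stops excluded; if all are blocked,
all are used), and a JC-style correction −¾ln(1 − 4p/3) applied to both
pS and pN. pS ≥ 0.74999 ⇒ `saturated`; fewer than 30 aligned codons ⇒
`too_short`. The estimator was chosen over ML codon models because it is
transparent and oracle-checkable by enumeration; that substitution is a
package decision.

4dTv is reported raw: a column counts only if both sequences share the
first two codon positions *and* that prefix is fourfold-degenerate
(conservative — avoids miscounting at nonsynonymously diverged codons);
the value is transversions at such sites divided by such sites, with no
multiple-hit correction, keeping it exactly countable.

The WGD simulator diverges each duplicate by rejection sampling —
propose a third-position change (transition with probability
1 − transversion_fraction), accept iff the amino acid is unchanged —
until the realized Ks, computed with this package's own estimator against
the undiverged copy, first crosses the target (the closer side of the
crossing is kept, landing well within the ±0.02 calibration band). This
guarantees Ka = 0 in truth and makes transversion_fraction = 0 give
exactly zero 4dTv. The duplicated genome carries the base copy plus one
diverged copy per requested Ks target, so a single round yields uniform
syntenic depth 2 against the reference and two rounds yield depth 3.

## Peak detection

Modes of Ks/4dTv distributions come from a Gaussian KDE with Silverman's
bandwidth (or a fixed one), *reflected at 0 and at the data maximum*:
distances live on a bounded range, and without reflection the density
decays artificially at the edges, handing the global maximum a spurious
~50% prominence even for featureless data. Peaks are strict local maxima
with topographic prominence ≥ 20% of the density maximum, ascending. The
20% floor was calibrated on the null: Silverman-bandwidth KDE wiggles on
uniform samples of a few hundred values reach 5–15% relative prominence,
so a 5% floor flags noise, while genuine bimodal duplication signals
carry ≥50% prominence; at 20% a uniform null is peak-free in ~94% of
seeds and the 0.3/0.7 two-component benchmark is recovered in 100%. Both
bandwidth and prominence are configurable. At least 50 values are
required.

Event calling is declarative: modal depth 2 + a youngest peak ⇒ "recent
WGD at ≈ that distance"; each additional older peak ⇒ "older shared
duplication"; no peaks and modal depth ≤ 1 ⇒ "no duplication signal".
All rule firings and thresholds are echoed into the report.

## Conventions, seeds, problem sizes

All on-disk coordinates are 1-based inclusive (GFF3 convention); internal
arithmetic is 0-based half-open, converted only at the I/O boundary.
Tables are tab-delimited with one header row. One global seed governs all
randomness; per-stage generators derive from (seed, stage-name) by stable
hashing (CRC32), so stages are independently reproducible and pipeline
reruns are byte-identical (manifests echo configuration, including paths,
and are the one file class excluded from checksum comparisons).

Tests and the acceptance script run at desk scale, chosen so recovery
standard errors sit well inside the asserted tolerances: 500 elements per
age on a 10 Mb background for dating recovery (sampling SE of the mean
≈3% at 0.5 Myr, the binding constraint), 2 Mb backgrounds for detection,
200 gene pairs per planted Ks, 200 random instances for each brute-force
oracle.

## What the simulator does not emulate — and what that means

No indels, no nested or solo LTRs, no recombination, no codon-usage bias,
no rate heterogeneity among sites or lineages, fixed marker motifs
instead of real domain profiles, and an undiverged base copy in the WGD
(real homeologs both diverge from their ortholog). Passing recovery tests
therefore demonstrates that the estimators are correct *under their own
model assumptions* and that the implementation is sound; it does not
demonstrate robustness to indel-rich alignments, solo-LTR false
positives, tandem-duplication contamination of anchor sets, or
GC-content-driven rate variation in real genomes. The detection stage's
banded/gapped identity refinement gives some indel tolerance, but recall
under realistic indel loads is uncharacterised.

## Known limitations

Greedy anchor extraction can split one true block in pathological
overlap patterns; the dating path's edge trim assumes arms longer than
~66 bp; lineage assignment trusts the exemplar set (one exemplar per
lineage suffices formally but real use wants several); the event caller
does not attempt absolute dating of WGDs in years.
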