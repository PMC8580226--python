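# Methods

This note documents the models, estimators and numerical conventions the
toolkit implements, the choices made where the design was genuinely
open, and what the synthetic-data tests do and do not demonstrate.

## Similarity and orthology

Pairwise protein similarity is exact Smith–Waterman with BLOSUM62 and
affine gaps.  A gap of length *k* costs `gap_open + k·gap_extend`
(defaults 11/1, so the first gapped residue costs 12) — the BLAST-style
convention.  Scores are normalized by the self-score of the shorter
sequence and clamped to [0, 1]; pairs below `min_norm_score` (default
0.3) are dropped.  The 0.3 default separates random from homologous
pairs on the synthetic families and is configurable; an optional shared
4-mer prefilter skips pairs with no k-mer in common.

Orthogroups are reciprocal best hits: for every ordered genome pair the
best hit per query is marked (score ties broken toward the
lexicographically smaller protein id, for determinism), inter-genome
edges are kept iff reciprocal-best, and an intra-genome pair whose
normalized score exceeds *both* proteins' best inter-genome scores is
merged as in-paralogs.  Connected components of the kept graph are the
groups; every protein belongs to exactly one group (singletons allowed).
This is the simplest operationalization of "common evolutionary origin";
Markov clustering could be swapped in behind the same interface.

The panel tree is neighbor joining on p-distances over the concatenated
alignment of the single-copy core (groups with exactly one member in
every genome).  Columns with a gap in either row are skipped.  NJ is
exact on additive distances, which the test suite verifies on 50 random
10-taxon trees; negative branch lengths arising from non-additive input
are clamped to zero.  The tree orders heatmap rows and carries no other
numeric weight downstream, which is why a full maximum-likelihood
treatment was not warranted.

## Multiple alignment

Families are aligned progressively along a UPGMA guide tree built on
3-mer distances (`1 − shared/min`), with deterministic tie-breaking via
lexicographic pre-sorting.  Merges are global Needleman–Wunsch at the
profile level: the column score is the mean BLOSUM62 score over
residue-bearing row pairs, gaps and X carry no substitution information,
terminal gaps are penalized, and gap columns once introduced are never
removed.  There is no iterative refinement; the stage is deterministic
and order-invariant by construction.  The aligner is not intended to
reproduce any particular external tool column-for-column.

One asymmetry is worth recording: a gap in the first profile may open
directly after a gap in the second, but not vice versa.  With the
default penalties, adjacent opposite gaps are never optimal (aligning
the two residues directly always scores better than paying two gap
opens), so this does not affect the optimum.

## Profile HMMs

Architecture selection flags a column as a match state iff its gap
fraction is strictly below `max_gap_frac` (default 0.5; a column with
exactly half gaps becomes an insert column).  Match emissions are
Laplace-smoothed column frequencies, `(count + 1) / (residues + 20)`;
insert emissions are pinned to the background; transitions are counted
from each row's path through the flagged architecture with a pseudocount
of one per transition type.  The classical architecture has no D↔I
transitions, so insert regions bordered by deletions are counted as if
flanked by match states — a documented simplification that only shifts a
handful of transition counts in gappy families.  Dirichlet mixture
priors, as used by mature HMM builders, are an acknowledged fidelity
gap; Laplace smoothing is the simplest defensible estimator and keeps
every example in the test suite hand-checkable.

The background distribution is estimated from the amino-acid frequencies
of the full reference panel (+1 pseudocount per residue type), falling
back to generic average frequencies for tiny panels.

**Scoring.**  A single score is used everywhere: the full-sequence
log₂-odds *forward* score in a Smith–Waterman-style local architecture —
a path enters any match state (weight 1/M), traverses the trained
match/insert/delete transitions, exits from any match state (weight
1/M), and flanking residues are emitted by the null, contributing zero.
'X' emits the background in both model and null and therefore scores
zero bits.  Natural logs internally, bits at every interface.  The
forward recursion runs in odds space with per-row rescaling (contributions
more than ~300 orders of magnitude below the row maximum underflow
harmlessly); it is verified against exhaustive path enumeration on
hundreds of small random models to 1e-9 bits.  Viterbi (best single
path) is provided as a diagnostic and never exceeds forward.

**Gathering thresholds.**  GA = (lowest-scoring true positive +
highest-scoring true negative)/2, with the model's orthogroup members as
positives and all other panel proteins as negatives.  Because the same
score function is used for calibration and scanning, downstream counts
are internally consistent regardless of which score variant an external
search tool would have reported.  When the score ranges overlap the
model carries a warning flag; with no negatives at all, GA falls back to
min(positives) − 0.5 bits, flagged.  Calibration is monotone in the
stated sense: adding a higher-scoring negative can only raise GA, adding
a lower-scoring positive can only lower it.

Models round-trip through a documented HMMER3-style text dialect
(negative natural-log probabilities, '*' for zero, GA on its own line,
exactly preserved); the format is not bit-compatible with HMMER
binaries, which is out of scope.

## Scanning and normalization

Counting is per model: each model is an independent thresholded search,
so one protein may count toward several models.  Module values are sums
over member models, so a model may belong to exactly one module (the
shipped ten-pathway catalog is disjoint by construction; the urocanic
acid gene hutH is housed under UV-B immune suppression rather than
histidine conversion).  Metagenome quantification weights each
GA-passing catalog gene by its per-sample read count; genes hit by no
model are tallied in an `UNMAPPED` column which is excluded from
relative-abundance denominators by default.

The two normalizations are applied in pipeline order aggregate →
sample-relative → module-max: rows are divided by their totals (undoing
library-size differences), then each module column is divided by its
maximum over the full combined sample set, so within a module all
samples are comparable on [0, 1] and the top sample is exactly 1.  The
two steps only partially commute with aggregation, so the order is fixed
and enforced through the matrix's declared normalization state.

## 16S functional inference

OTUs are mapped to panel genomes by deepest shared taxonomic prefix
(rank-delimited strings, domain→species); a match through the genus rank
is required, ties are averaged with equal weights, and unmapped OTUs are
reported per sample.  Prediction is the linear projection
`abundance × weights × copy-number`, exactly linear in the OTU table —
a deliberate property: it makes the projection auditable and lets the
identity-mapped fixture reproduce abundance-weighted planted copy
numbers exactly.  Raw abundances are projected as-is; callers who want
compositional input can renormalize rows first, and an optional
per-genome 16S copy-number table divides each OTU's contribution.
Sequence-based placement (as in full PICRUSt) and NSTI-style confidence
scores are out of scope.

## Skin-aging statistics

The SA score is the oriented z-score mean of the eight clinical
measurements; each column is standardized (sd with one delta degree of
freedom), multiplied by its orientation (+1 = larger looks older;
default −1 only for skin color evenness) and averaged.  The score is
invariant to affine rescaling of any measurement and is higher for
older-looking skin.  Orientations are fully config-overridable.

RDA with a single constraint (SA score or a 0/1 age-group indicator):
the response is transformed (Hellinger — square root of row proportions
— by default for abundance tables; `none` for pathway scores; `log1p`
available), column-centered, and projected onto the centered constraint.
Variance explained is SS_fitted/SS_total; pseudo-F uses n−2 residual
degrees of freedom; the permutation p-value is
`(1 + #{F_perm ≥ F}) / (1 + n_perm)` with the constraint permuted under
a mandatory seed (default n_perm = 999).  Arrow scores are the
per-variable regression loadings scaled by ‖x‖; only their ranking and
sign are contractual, since axis scaling conventions differ across
ordination software.  Top-arrow defaults follow the workflow's figures:
20 variables for OTU-level runs, 15 for gene-level runs.

Pathway scores are sums of member gene columns; each pathway is related
to the SA score by ordinary least squares (slope, intercept, r²,
two-sided slope p-value), with optional Benjamini–Hochberg q-values
across pathways (off by default, since per-pathway reporting without a
stated correction is the workflow's native form).  Heatmap export
normalizes each pathway row by its maximum and orders subjects by SA
score.

## Synthetic data and what the tests show

`simulate_panel` plants protein families (default 12 families across 10
genomes, 250-residue seeds at panel background composition, 15%
within-family substitution divergence, 1% indel rate, copy numbers
0/1/2 with recent duplicates at 2% divergence, five decoys per genome).
`simulate_community` emulates the two-age-group cheek-swab design (50
samples = 2×25, one OTU per genome, log-normal abundances, a
multiplicative group effect on designated OTUs, multinomial depth
20 000).  `simulate_phenotypes` draws the eight measurements as
`loading × latent age + noise` with a negative evenness loading.  All
generators are bit-reproducible from (config, seed) and emit a truth
registry.

Passing the planted-recovery tests shows the chain is internally
consistent and separates families from background at the stated
divergence — it does not show that real annotation pipelines, real
paralog structure (ancient duplications, domain shuffling) or real
sequencing noise would be handled equally cleanly.  The community
generator has no chimeras, no compositional zero-inflation beyond
multinomial sampling, and taxonomy strings that always match the panel;
real 16S data will have substantial unmapped fractions.

## Numerical conventions and limitations

* Determinism: every stochastic operation takes an explicit seed; all
  clustering and alignment tie-breaks are lexicographic; reruns with the
  same config produce byte-identical outputs.
* Matrix TSVs round-trip to 12 significant digits; model files preserve
  probabilities to ~10 significant digits and GA exactly.
* Degenerate inputs: zero-sum rows stay zero under normalization (with a
  warning); zero-variance phenotype columns are dropped; all-X alignment
  columns fall back to background emissions; unobserved transition rows
  fall back to the path-through move.
* Known limitations: no Dirichlet priors or multi-hit scoring in the
  profile HMMs; no E-value calibration (GA thresholds only); orthology
  is RBH, not tree-aware; the SA score weights all eight measurements
  equally; partial RDA with covariates is not implemented.
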