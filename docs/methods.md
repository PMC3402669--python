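# Methods

This note records the models, conventions and design choices behind
`bovimito`, in the spirit of a methods appendix: what each component
assumes, which knobs matter, and what the synthetic validation does and
does not demonstrate.

## Genomes, coordinates and the D-loop

Mitogenomes are linear strings in record orientation; all serialized
coordinates are 1-based inclusive. Circularity is not modelled — a control
region (D-loop) spanning the replication origin must be annotated as two
regions, as in GenBank flat files. Annotation is read from the record (CDS,
rRNA, tRNA, D-loop features), never recomputed; FASTA inputs can carry a
sidecar region TSV. IUPAC ambiguity codes are kept verbatim at I/O time and
interpreted per operation: distances drop ambiguous columns, the likelihood
engine treats them as partial information, and the variant caller counts a
taxon as a carrier only when its code shares no base with the root's.

D-loop exclusion is defined in the *reference* coordinate frame: a column
is removed when its reference coordinate (or, for insertion columns, its
anchor) lies inside a reference `d_loop` region. Taxa can disagree about
D-loop boundaries; the reference-frame rule is a deliberate convention and
is recorded in run manifests. The operation is idempotent.

## Anchored alignment

Genomes within a tribe differ by a few percent, so full progressive
alignment is unnecessary. Unique shared k-mers (default k=12) are merged
into maximal same-diagonal blocks and chained by dynamic programming
maximizing total matched length. Anchors are trimmed by 8 bp per side so
the alignment path can move freely near block edges, then fixed; the
segments between anchors are solved exactly by affine-gap (Gotoh) global
alignment. Scores default to match +1, mismatch −2, gap open −5, gap
extend −1 (a length-L gap costs −5−L); ties prefer diagonal over up over
left, which makes output platform-independent. When a segment pair's
length difference exceeds the nominal band (default 50) a widening is
logged; the segment solve is exact regardless. With no usable anchors the
whole pair falls back to the full matrix. On 50 random ≤2 kb pairs at ≤5%
divergence with short indels, the anchored score equals the unconstrained
optimum in every case (this is an acceptance check, re-run by
`scripts/acceptance.py`).

Multiple alignment is reference projection: each query is aligned to the
reference pairwise; the MSA has one column per reference base plus the
union of insertion columns keyed by (reference position, offset).
Insertions from different taxa at the same anchor are left-aligned and
stacked, not re-aligned to each other — downstream analysis treats
insertions as events, not as homologous columns. The projection is
invariant to input order.

## Variant catalogue

Events are read off the alignment against a designated root taxon.
Substitutions are per-column, one event per distinct alternate allele, so
carrier sets stay well defined at multi-allelic columns. Maximal gap runs
become single deletion/insertion events; columns where both the root and
the taxon are gapped are transparent, so an insertion interrupted only by
other taxa's insertions still counts once. Indels are left-normalized
(shifted to their leftmost equivalent placement in homopolymer/tandem
context) before coordinates are assigned, which makes coordinates
aligner-independent and is what pushes planted-event coordinate recovery
through re-alignment above 99%.

Micro-reorganization merging collapses runs of ≥3 events with identical
carrier sets and inter-event gaps ≤2 bp into one event (both parameters
configurable). The rationale: a dense same-carrier cluster most plausibly
records a single mutational event that an aligner rendered as several
substitutions. Merged events never re-merge, so the operation is
idempotent. Island detection (two-genome comparisons) uses gaps ≤60 bp and
≥4 events by default; islands are named heuristics, not statistics, and
both knobs are exposed.

Branch mapping is Fitch-style single-origin: a sharing pattern that is a
clade on the fixed rooted topology is assigned to the branch above that
clade's MRCA; non-clade patterns are reported as unresolved rather than
forced. Totals are conserved (branch sums + unresolved + non-focal =
events in).

Coding effects use translation table 2 (vertebrate mitochondrial); minus
strand genes are reverse-complemented before translation, frame offsets
honour `codon_start`. Indels with length not divisible by three are
frameshifts and report the novel residue run up to the next stop (capped
at 60 residues). In-frame coding indels and coding micro-events with no
net frame change are labelled nonsynonymous.

## Distances

The headline "percent divergence" is a substitution-only p-distance with
pairwise deletion of gap/ambiguity columns; complete deletion (drop a
column if *any* taxon is gapped/ambiguous) is available for matrix-wide
consistency, and both modes are reported because era-typical tools differ.
Indels are never counted in distances — they are catalogued separately.

The Tamura–Nei estimator uses pooled empirical base frequencies (exact
symmetry), the two transition proportions P1 (A↔G), P2 (C↔T) and the
transversion proportion Q, with gamma correction
α(w^(−1/α)−1) in place of −ln w; shape defaults to 0.1 to match the
study-era convention and is overridable. As α→∞ the estimator converges to
plain TN93; the implementation agrees with `ape::dist.dna` to 8 decimals
at α ∈ {0.1, 0.5, ∞} on a frozen simulated pair (unit test). Saturation
raises an explicit error, never a silent NaN. Bootstrap SEs resample
columns with replacement to the original length, seeded; >10% inestimable
replicates abort with the failure fraction.

## Likelihood engine

Felsenstein pruning over unique site patterns (per-pattern weights),
partial likelihoods rescaled per internal node to avoid underflow. GTR is
parameterized by six exchangeabilities (GT ≡ 1) and frequencies; the rate
matrix is normalized to mean rate 1 so branch lengths are expected
substitutions/site. P(t) comes from eigendecomposition of the
π-symmetrized matrix; entries within 1e-12 of zero are snapped to zero so
genuinely impossible states are detected and reported by column. Gamma
heterogeneity uses 4 discrete categories with mean-of-quantile-bin rates,
the de facto standard. Base frequencies are empirical counts by default
(as in common PhyML usage); a flag refits exchangeabilities and shape by
bounded quasi-Newton steps (log-rates clamped to ±7) alternating with
branch sweeps.

Branch optimization is cyclic bounded scalar search per branch
(lnL tolerance ~1e-8 per branch; sweeps stop when a full sweep gains
<1e-6, max 100 with a warning). On a rooted tree the two root-child
branches are jointly identified only through their sum under a reversible
model; recovery claims therefore apply to unrooted edges. On 50 kb
simulated data all edge lengths ≥0.01 are recovered within 10% (acceptance
check; observed max error ~3%).

The clock test optimizes free branch lengths, then re-optimizes under an
ultrametric parameterization (root height, per-node fractions of the
parent height) by Nelder–Mead refined with L-BFGS-B, started from the free
tree's mean depths; 2ΔlnL is referred to χ²(n−2). An internal assertion
fires if the constrained optimum exceeds the free one. Calibration: over
200 clocklike replicates (4 taxa, 2 kb) the empirical type-I error at
nominal 5% stays within [2%, 9%], and a 3×-rate terminal branch at 10 kb
is detected essentially always.

aLRT support per internal branch is 2(lnL_best − lnL_best-NNI) under the
½χ²₀+½χ²₁ mixture; each NNI alternative has all branch lengths
re-optimized (trees here are small, so the full re-fit is affordable and
slightly conservative). For a rooted tree whose root has two children,
both child branches name the same unrooted edge and are tested once; an
internal branch whose unrooted counterpart is pendant (e.g. the trio stem
when the outgroup is a single leaf) has no NNI alternative and is reported
as NA.

Relaxed-clock MCMC is out of scope by design; only the harmonic-mean
marginal-likelihood estimator (log-space, via logsumexp) and log Bayes
factors are provided for externally produced traces (one value per line,
`#` comments). The harmonic-mean estimator's notorious variance is the
user's concern; the arithmetic is exact.

## Chronology

A single calibration (taxon set + age). Node depth is the *mean* path
length to descendant tips — the era-typical constant-rate convention; the
max/min alternatives were rejected as they bias toward outlier lineages.
Rate = depth/age; ages = depth/rate, assigned per node. Where rate
heterogeneity makes a child nominally older than its parent the violation
is flagged on the node, never silently fixed. A pairwise-distance variant
(mean cross-split distance / 2 / age) is provided and agrees exactly on
ultrametric trees. No uncertainty propagation on ages: point values only,
matching the upstream workflow.

## Synthetic-data generator

The simulator is first-class, tested code, and defines the package's study
conditions. Sequences evolve on a rooted tree: per branch, substitution
counts are Poisson with mean t·Σ(site weights), where a site's weight is
its gamma multiplier (drawn from the model's discrete categories) times
the leaving rate −q_ii of its current base, and replacement bases follow
the normalized rate-matrix row. Weights are computed once per branch and
hits applied sequentially — exact under Jukes–Cantor, and accurate to
within the acceptance tolerances for the short branches used here.
Indels (events per substitution; geometric lengths) and micro-events
(uniform-length random replacement runs that always change every base) are
planted per branch. A D-loop span evolves at a 5× multiplier to exercise
exclusion logic. Every lineage's genome is a token list with stable column
keys, so the gap-true alignment and exact per-branch truth tables fall out
by construction; per-run randomness is a single seed split per branch by a
stable branch identifier, making output byte-identical for a fixed seed
and independent of traversal order.

Truth pattern counts are computed inside the simulator directly from final
leaf states (per column, per derived allele, with the same indel
run/normalization conventions) — an independent code path from the variant
catalogue, so the "exact pattern-count recovery" check is a dual-route
consistency test that remains exact even when branches hit the same site.

The `wisent_trio` preset emulates the four-taxon study design: 16,338 bp
genomes with a 919 bp terminal D-loop (coding remainder exactly 15,419),
topology (BRS,(wisent,(bison,yak))), transition-heavy GTR (κ≈18), gamma
shape 0.867, and branch lengths chosen so expected whole-molecule unique
counts approximate 342 (wisent) / 158 (bison) / 165 (yak), ~200 bison/yak-
shared and ~342 on the root edge, with node ages 2 My / 1.65 My / 0.706 My
attached as truth. What passing tests show: the catalogue, aligner,
likelihood and dating machinery recover what was planted under the stated
model. What they do not show: robustness to real-data artifacts absent
from the generator — sequencing error, heteroplasmy, circularity effects
at the origin, tandem-repeat length polymorphism in the control region,
and base-composition drift between lineages.

## Problem sizes in the shipped checks

The default test-suite and acceptance-script sizes are chosen as the
smallest that make each check statistically meaningful: 20 preset seeds
for recovery, 50 pairs ≤2 kb for alignment optimality, 50 kb for branch
recovery, 200 × 2 kb replicates for clock calibration, 1,000 bootstrap
replicates at 10 kb. Each knob scales up trivially for heavier validation.

## Known limitations

* Linear-genome assumption; origin-spanning features need two-region
  annotation and events across the join are reported per part.
* The anchored aligner targets ≤~15% divergence; beyond that the chain
  thins and the full-matrix fallback becomes quadratic.
* Parsimony branch mapping ignores recurrent mutation; dense sites can
  leak between patterns (visible as small unresolved bins in the preset).
* The clock LRT's χ² reference is asymptotic; at very short alignments it
  is mildly conservative (observed type-I ~4–7% at 2 kb).
* Harmonic-mean marginal likelihoods are provided for compatibility, not
  endorsed as an estimator.
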