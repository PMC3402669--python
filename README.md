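# bovimito

Comparative mitogenomics of the *Bovini* — wisent (European bison), American
bison, yak and cattle — as a tested, reusable pipeline. The package
re-implements the classic complete-mitogenome comparison workflow: catalogue
every difference against a cattle reference used as an *artificial root*,
merge clustered differences into single micro-reorganization events,
partition mutations onto the branches of a fixed rooted topology, compute
Tamura–Nei/gamma distances with bootstrap errors on the coding (D-loop
excluded) dataset, evaluate and optimize GTR+Γ likelihoods on the fixed
topology, test the molecular clock, and convert substitution distances into
divergence times from a single fossil calibration. A seeded
sequence-evolution simulator with full truth tables makes every step
testable without downloading a single sequence.

## The science in brief

* **Mutation partitioning.** With a root reference *R* (for *Bovini*, the
  bovine reference sequence, GenBank V00654), every aligned column where a
  taxon differs from *R* is an event with a *carrier set*. Under a
  single-origin (parsimony) assumption, a carrier set that is a clade on the
  topology maps to the branch above its most recent common ancestor: unique
  mutations sit on terminal branches, shared ones on internal branches, and
  non-clade patterns (e.g. wisent+yak) are reported as unresolved homoplasy.
* **Distances.** p-distance *p* = differing/compared sites; Tamura–Nei (1993)
  with gamma rate variation,
  *d* = α·[k₁(w₁^(−1/α)−1) + k₂(w₂^(−1/α)−1) + k₃(w₃^(−1/α)−1)],
  with the two transition classes (A↔G, C↔T) separated from transversions
  and empirical base frequencies pooled over the pair. Bootstrap SEs resample
  alignment columns.
* **Likelihood.** Felsenstein pruning over unique site patterns under GTR
  with 4 discrete gamma categories (mean-of-quantile-bin rates); branch
  lengths in expected substitutions/site. The molecular-clock LRT compares
  free branch lengths (2n−3 parameters) against an ultrametric node-height
  parameterization (n−1), with 2ΔlnL ~ χ²(n−2). aLRT branch support compares
  the optimized tree against its best NNI rearrangement per internal branch.
* **Dating.** A fossil-calibrated split of age *t* with node depth *d*
  (mean substitutions/site to descendant tips) gives rate *r = d/t*; every
  internal node is dated as depth/*r*.

## Worked example

`examples/simulate_and_catalog.py` simulates a wisent/bison/yak-style
dataset on the preset topology, catalogues mutations against the BRS root
and maps them onto branches:

```
simulated 4 genomes of ~16338 bp; 1105 raw events, 1056 after micro-merging

branch                mutations  (truth)
  bison                  unique:  150  (150)
  bison+wisent+yak       shared:  284  (284)
  bison+yak              shared:  181  (181)
  wisent                 unique:  303  (303)
  yak                    unique:  158  (158)
  wisent+yak             unresolved: 16
  bison+wisent           unresolved: 13
```

Every clade pattern is recovered exactly against the simulator's truth
table; the wisent branch carries roughly twice the unique mutations of
bison or yak, the asymmetry that motivates the mitochondrial-transfer
question in this clade. `examples/clock_and_dating.py` continues to dating:

```
lnL = -25815.6   gamma shape = 1.167   Ts/Tv = 10.91
clock LRT: 2*dlnL = 3.07, df = 2, p = 0.216  (clock not rejected)

calibration: root split at 2.0 My -> rate = 1.14e-08 subs/site/year
  BRS+bison+wisent+yak             2000 ky
  bison+wisent+yak                 1617 ky
  bison+yak                         803 ky
```

The other examples cover distances with bootstrap SEs, two-genome
comparison with difference islands, and harmonic-mean Bayes factors from
likelihood traces.

## Command line

A thin CLI wraps the pipeline for shell use:

```bash
bovimito simulate --seed 1 --out simulated/
bovimito run-all --config run.json          # full report bundle
bovimito bayes-factor traceA.txt traceB.txt
```

`run-all` writes aligned/coding FASTA, an event table TSV, branch-count
TSV, distance and SE matrices, the optimized newick with aLRT supports, a
clock-test report, a dated chronology TSV and a JSON manifest sufficient to
reproduce the run bit-identically. Real GenBank flat files (e.g. the
published wisent, bison, yak and cattle accessions) are read directly once
fetched locally; the pipeline itself never touches the network.

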