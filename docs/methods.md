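# Methods

This note documents the models, the numerical choices, and the design of
the simulation studies shipped with `stratadate`.

## The scenario scale

All four estimators target the same quantity: the age at which a gene's Z
and W copies stopped recombining, expressed either as an absolute age, a
normalized age (fraction of the root age of a dated reference species
topology), or a discrete *scenario index*.  The index scale is defined by
the focal species' root path: with P internal nodes of ages
h₁ < … < h_P on the path, scenario k covers the half-open interval
(h₍ₖ₋₁₎, hₖ] (h₀ = 0) and corresponds to the gametolog topology with the
W sequence attached on that path segment.  Attachments above the root
(cessation predating the root) are excluded by default; an option
re-enables them.  The S intervals partition (0, 1] on the normalized
scale with S + 1 distinct boundaries.

For the multi-W scale, every w-bearing species that split from the focal
path *after* the cessation contributes its W tip to a clade mirroring the
species topology at the attachment point; a species that split *before*
keeps its W sister to its own Z (recombination continued independently in
that lineage).  Scenario 1 therefore places every W sister to its own Z.
Restricting the multi-W scenario k to the focal W reproduces the single-W
scenario k, which keeps the two index scales interchangeable; this
consistency is property-tested.

### The bundled reference topology

The 13-species tree (six Sylvioidea species nested pectinately around the
great reed warbler, five further Neognaths, emu, green anole) carries
fixture node ages in Myr (4, 6, 7, 17, 22, 30, 39, 52, 65, 90, 110, 312).
These are representative, published-style divergence times assembled for
simulation and testing; they are not inference output.

## Likelihood engine

Reversible nucleotide models (JC69, K80, HKY85, TN93, GTR) with discrete-
gamma rate variation (category means per Yang's quantile method, default
4 categories) and an invariant-sites class.  Conventions:

* rate matrix scaled to one expected substitution per site, so branch
  lengths are substitutions/site; with +I the gamma rates are divided by
  (1 − p_inv) to keep the overall mean rate 1;
* gaps and IUPAC ambiguity codes are missing data (partial likelihood 1
  for every compatible state), not a fifth state;
* site patterns are compressed once per (tree, alignment) pair;
* transition matrices come from the symmetric eigendecomposition of Q,
  cached per model; no partial-likelihood rescaling is performed —
  at the tree sizes and divergences this package targets (≤ ~20 tips,
  per-site likelihoods ≫ 10⁻³⁰⁰) double precision is sufficient, and the
  engine raises on a non-finite site likelihood rather than mask it;
* minimum branch length 10⁻⁹ (avoids log 0).

Branch lengths are optimized by per-branch Brent searches on the log
scale (bounds 10⁻⁹–20, `xatol` 10⁻⁴) using cached post-order ("below")
and pre-order ("outside") partials, swept round-robin until the relative
lnL gain falls under 10⁻⁸.  Because partials are refreshed once per sweep
rather than after every branch, a sweep can stall on flat likelihood
surfaces; the optimizer detects this (lnL flat while branch lengths still
move) and falls back to exact recompute-per-branch coordinate ascent,
which cannot stall.  The returned lnL is never below the starting one.
Model fitting uses empirical base frequencies and coordinate ascent over
exchangeabilities, gamma shape and p_inv, interleaved with branch sweeps.

## ELW

Per-scenario site log-likelihood rows are computed at scenario-specific
ML branch lengths with a single shared substitution model, fitted once on
the scenario-1 topology (whether the reference IQ-TREE-style workflow
refits the model per topology is not documented; sharing is the cheaper
and more comparable choice).  RELL resampling draws multinomial site
counts in fixed-size chunks (4096 replicates) with per-chunk seeds spawned
from the user seed, so results are reproducible and memory stays flat at
the default 100 000 replicates.  The 95% range adds scenarios in
descending weight (ties toward the lower index) until 0.95 is reached and
reports the contiguous index hull of the selected set.

## Bayesian node dating

A deliberately small sampler, not a BEAST reimplementation: the gametolog
topology is fixed (the W tip sits at its hypothesised or simulated
attachment), so the Z–W node age moves between its children's ages and
its parent's age.  Priors: proper calibration densities
(normal/lognormal/uniform) on species nodes resolved by MRCA of their
taxon sets — placing one on the focal Z–W node is an error; 1/rate on the
clock rate within [10⁻⁸, 10]; uncalibrated ages uniform within their
ordering bounds; optionally a hard root-age cap (`max_root_age`), which
makes the root prior proper when outgroup pruning leaves no calibrated
node above the focal one.  The relaxed clock is uncorrelated lognormal:
per-branch multipliers with mean 1 and spread σ ~ Exponential(2).

Moves: bounded-uniform node-age slides (symmetric), scale moves for the
root, rate, σ and branch multipliers (with Hastings terms), and optional
scale moves on substitution parameters (log-uniform prior).  Scale
tunings adapt toward 0.2–0.5 acceptance during the pre-burnin only, so
the post-burnin chain is a fixed-kernel Markov chain.  Likelihood updates
recompute only the transition matrices of the touched branches and the
partials on their path to the root.  Chain bookkeeping follows
floor((chain − pre-burnin)/interval) retained samples; summaries discard
a further 10% of retained samples by default (the reference workflow's
summary burn-in is unstated, so it is exposed as `burnin_frac`).  The
HPD is the shortest window containing ⌈0.95 n⌉ order statistics; ESS is
n/(1 + 2Σρₖ) with autocorrelations summed to the first non-positive lag.
The default chain (2×10⁵ states, sampling every 100) is a desk-scale
setting; production-scale settings (2×10⁸ / 10⁴) are config-reachable.

Outgroup reduction keeps the focal species plus its k *closest* outgroups
along the focal path, prunes the alignment accordingly, and keeps a
calibration only if its node survives (≥ 2 child subtrees retain kept
tips).  The closest-first rule reproduces the qualitative behaviour of
few-outgroup analyses (severe truncation of the age scale with a single
close outgroup).

## dS (NG86)

Per-codon synonymous/nonsynonymous site fractions (changes to stop codons
count as nonsynonymous), difference counts averaged over all orderings of
the differing positions with stop-codon intermediates excluded (if every
ordering is blocked, all orderings are used), Jukes–Cantor correction,
and a saturation flag at p ≥ 3/4 (dS undefined).  Codon columns with a
gap, an ambiguous base or a stop codon in any sequence are dropped at
construction, which also keeps simulated data (whose neutral evolution
can create stops) countable.  Standard genetic code only.

## ML_CT

Replicate trees for bootstrap supports are neighbor-joining trees on
Jukes–Cantor distances of column-resampled alignments — fast, consistent,
and sufficient for the collapse-at-0.7 decision this approach feeds;
the point estimate tree can be NJ or NJ + NNI hill-climbing under the
likelihood engine.  Collapsing is strict (< 0.70 contracted, = 0.70
kept); support scales of [0, 100] are auto-detected.  Compatibility of a
collapsed gene tree with scenario k is defined by split refinement on the
shared taxa (every gene-tree split is a split of scenario k), which
formalizes the otherwise manual position-range assignment; a gene tree
compatible with no scenario (e.g. W nested inside a non-focal clade)
raises an error naming a conflicting split.

## Evaluation statistics

Lloyd K-means (best of 50 seeded starts) clusters coordinate-valued
estimates: dS as scalars, ML_CT ranges as (lo, hi) pairs, ELW as the full
12-component weight vector.  Posterior distributions are compared by the
exact 1-D second-order Wasserstein distance (piecewise-constant quantile
functions integrated on the union grid; for equal sample sizes this is
the RMS difference of sorted samples) and clustered by PAM k-medoids
(BUILD + SWAP), since Euclidean distance is not meaningful between
distributions.  Wilcoxon signed-rank tests use the exact null for n ≤ 25
without ties/zeros and the normal approximation otherwise; Bonferroni
multiplies by the number of pairwise tests, capped at 1.  All-zero paired
differences and constant vectors are flagged as undefined rather than
forced to a number.

## Synthetic data generator

The generator is the package's definition of the study conditions:

* Z genealogy = species tree; no coalescent variation, incomplete lineage
  sorting, gene conversion or indels — the same idealization the
  hypothetical topologies assume, so recovery tests validate estimator
  logic, not robustness to those processes on real data;
* W lineage splits from the focal path at exactly t_RC; in multi-W mode
  the mirror-clade rule above applies, and a w-bearing species that split
  before t_RC gets its own W–Z divergence at half its split age (a value
  below the split age must be chosen; the scenario topology does not
  depend on it);
* clock rate 10⁻³ substitutions/site/Myr (an avian synonymous-scale
  rate; it puts the focal Z–W divergence of ancestral-stratum genes near
  0.3, the magnitude reported for old strata), W-branch multiplier 1.5
  (degeneration-driven acceleration), HKY85 κ = 3 with mildly AT-rich
  frequencies;
* two strata: 22 "old" genes with t_RC ~ U(90, 150) Myr (around/before
  the Neognathae-origin analog, emulating the ancestral sex chromosome)
  and 29 "young" genes with t_RC ~ U(1, 21) Myr (inside the
  Sylvioidea-analog clade, emulating the added part) — the paper-scale
  gene counts with clearly separated strata;
* coding mode redraws root codons until stop-free; downstream evolution
  is nucleotide-wise (no selection), so dS ≈ dN apart from the genetic
  code's structural transition bias.

## Evaluation design (problem sizes)

The shipped acceptance suite runs on one CPU with these sizes, chosen as
the package's own desk-scale evaluation design:

* oracle equivalences: exhaustive-state pruning (5 tips, L = 50),
  loop-based RELL (5 × 30, 25 replicates), codon-pathway enumeration
  (100 random pairs), HPD window scans, LP optimal transport, exhaustive
  clustering partitions (n ≤ 11);
* ELW recovery: 24 genes at L = 2000, two per scenario interval
  (midpoints), argmax accuracy ≥ 80% — the misses concentrate in the
  1–2 Myr-wide intervals, where a handful of expected substitutions must
  separate adjacent scenarios;
* dating coverage: 20 strict-clock replicates on a 4-outgroup fixture
  (L = 400, JC69), 2×10⁵ states each, true age in the 95% HPD in ≥ 18;
* multi-W comparison: 12 added-part genes at L = 1000, median 95%-range
  width multi ≤ single;
* outgroup experiment: 8 added-part genes at L = 600, 3×10⁴-state chains,
  median HPD width smaller with 12 than with 3 outgroups;
* clustering: the full 51-gene two-strata design at L = 801 (coding),
  ELW K-means and dating W2/PAM at adjusted Rand index 1, dS permitted to
  misclassify.

## Known limitations

* No topology sampling in the dating module: uncertainty in the W
  attachment is not propagated into the posterior (the ELW module is the
  tool for that axis).
* No codon substitution models; dS is a counting estimator and inherits
  NG86's known downward bias at high divergence (partly mitigated by the
  saturation flag).
* The simulator's clean-separation defaults make clustering recovery
  easier than in real data, where strata boundaries blur; passing tests
  demonstrate correct estimator machinery, not field performance.
* Likelihood rescaling is not implemented; very large trees or extreme
  divergences would underflow.
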