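# Methods

This note documents the models, parameter choices and numerical conventions
behind `multistat_screen`, and what the synthetic generators do and do not
emulate.

## Screen triage statistics

The cascade operates on docking-engine output only through three per-pose
scores (binding score BS, clash penalty crash ≤ 0, polar contribution ≥ 0)
and a pocket assignment.  BS is treated as a unitless rank score: no
conversion to binding constants is attempted, and all comparisons are
within one engine run.

**Best pose.**  Maximal BS; ties broken by the less negative crash (the
less clash-penalized pose), then by the engine's own rank.  The tie-break
order is a package convention — pose sets from continuous scoring
functions essentially never tie.

**CBAV.**  `CBAV(ref, t) = BS_best(ref) − BS_best(t)`, the difference of
best-pose binding scores for the same compound.  This construction is
antisymmetric and zero exactly at equal affinity, which is the semantics the
selection rule needs: CBAV ≥ 0 against every off-target keeps compounds
that bind the reference at least as well as anything else.  Best-pose
scores (not pose aggregates) enter the difference; aggregating over poses
would mix conformer diversity, which LBPV measures separately, into the
affinity comparison.

**Pocket occupancy and LBPV.**  A pose belongs to exactly one of four
classes: pY+0 only, pY-X only, both, neither.  With precomputed flags the
class is read directly (the canonical input dialect, since the statistic is
defined on pocket assignments, not geometry).  With raw coordinates a
pocket counts as occupied when any heavy atom lies within a configurable
radius (default 5 Å) of the pocket centroid — a minimal reproducible proxy
for visual pose inspection.  LBPV is the fraction of the supplied
top-ranked poses in a class; the denominator is the number of poses
supplied (20 in a full dual-pocket run; fewer triggers a warning rather
than an error).  Aggregate classes "PY0_ANY"/"PYX_ANY" count dual-pocket
poses too, giving the inclusion–exclusion identity
`LBPV(pY0 any) + LBPV(pYX any) − LBPV(both) + LBPV(neither) = 1`.
All four exclusive classes are always reported and never forced to total 1
from a subset, because published single-pocket splits need not exhaust the
pose set.

**Thresholds.**  Every filter threshold is inclusive (≥): similarity 0.5,
molecular weight 300 g/mol, CBAV 0, dual-pocket LBPV 0.8 (the bottom of the
published "low conformer diversity" band).  All are configurable
(`TriageConfig`).

**ΔΔG°.**  `ΔΔG° = ΔG°(mutant) − ΔG°(wild type)` per (target, ligand) pair;
positive values (destabilized mutant complex) are flagged as binding
impairment.  Strictly positive — a mutation with no effect is not impaired.

## Expression pipeline

Processing order: floor(values ≤ 0 → 1) → log2 → background subtraction →
quantile normalization → testing.  Background subtraction defaults to the
per-sample 5th-percentile offset on the log2 scale (clipped at 0), a
control-probe-free proxy; it can be disabled (`method="none"`).

**Quantile normalization** is the classic rank-mean algorithm: sort each
sample, average across samples at each rank, assign back by rank.  Tied
values receive the mean of the rank means their block spans, which also
preserves the grand mean exactly.  After the operation all samples share
one sorted vector (exactly, for tie-free data).  A consequence worth
knowing: when a non-negligible fraction of genes moves in one direction,
the method compresses those effects (it presumes mostly-unchanged
distributions).  Synthetic cohorts here therefore default to array-like
sparsity (3 % of genes induced).

**Testing.**  Fold change is `2**(mean_b − mean_a)` on normalized log2
signals; p comes from a two-sample t-test on the replicate log2 values.
With two replicates per condition — the design this pipeline targets — the
Welch test's effective degrees of freedom collapse toward 1 and it cannot
reliably reach p ≤ 0.05 even for large, clean effects; the pooled-variance
test (df = 2) is therefore the default and Welch is available as
`equal_var=False`.  Degenerate zero-variance genes get p = 1 when the means
agree and p = 0 otherwise.  Induction requires FC ≥ 2 **and** p ≤ 0.05
(both inclusive); the p-value is a differential test, not a detection call.

**Inhibition.**  `ratio = FC(stim)/FC(stim+inhibitor)`, inhibited iff
ratio ≥ 4, evaluated only for genes already passing the induction filter.
Both fold changes share the untreated control as denominator.  Gene
identity everywhere is the (gene id, gene name) pair; one id carrying two
names across lists is an integrity error, not a silent merge.

## Promoter scanning

A PFM with counts `c[i, b]` and pseudocount q (default 1 % of the
per-position total) yields log2 odds against a uniform background,
`w[i, b] = log2(((c[i, b] + q)/(total_i + 4q))/0.25)`.  A window scores the
sum of its letter weights; the **matrix similarity score** rescales by the
minimal/maximal achievable sums so the consensus scores exactly 1 and the
per-position-worst sequence exactly 0.  Ambiguous letters score the column
minimum (conservative).  An all-uniform matrix has no score range and is
rejected as degenerate.

Scanning covers both strands (reverse complement for minus); the best hit
is reported with a leftmost-then-plus-strand tie-break, at the plus-strand
start coordinate relative to the TSS.  The promoter window convention is
[−950, +50) with position 0 = TSS; the window length is an input property,
not enforced beyond `len(seq) ≥ width`.

A site class (ISRE, GAS, NF-κB) is *present* when **any** of its matrices
reaches the class threshold — 0.85 for ISRE/GAS, 0.90 for NF-κB.  The eight
presence/absence categories are reported densely, with percentages over
all genes and over genes carrying at least one site (both denominators are
of interest when the siteless group is excluded from a published census).

The packaged PFMs (`data/pfm/*_synthetic.jaspar`) are hand-built
consensus-based stand-ins constructed from the canonical ISRE
(AGTTTCACTTTC), GAS (TTTCCCGGAAA) and NF-κB (GGGACTTTCC) site structures —
they are synthetic, not database matrices, and carry `synthetic` in their
IDs and filenames.  At the default thresholds their measured chance-hit
rates on motif-free 1 kb backgrounds are roughly 0.05–0.15 per promoter per
class (reported, not asserted, by the acceptance script); that order of
magnitude is realistic for short regulatory motifs and means a cohort's
*measured* category census includes some chance calls on top of planted
sites.

## Assay calculators

ΔΔCt assumes amplification efficiency 2 (exposed as a parameter);
`fold = E**(−ΔΔCt)` with ΔCt = Ct(target) − Ct(reference) per sample.
ChIP percent-of-input uses the standard dilution correction: the input
reaction ran on a chromatin fraction f, so its Ct is first reduced by
log2(1/f), then `percent = 100·2**(Ct_input,adj − Ct_IP)`.  Wound closure is
`100·(1 − mean(gap_t)/mean(gap_t0))`, invariant to measurement order and
length unit, negative when the gap widens.

## Synthetic generators

All generators take one integer seed and are byte-deterministic (identical
seed ⇒ identical files); truth records carry everything needed to score
recovery downstream.

**Pose tables** emulate a dual-pocket re-screen: per compound × target,
20 poses ranked by descending Gaussian BS, occupancy flags drawn from a
per-compound multinomial (p_both, p_pY0, p_pYX, remainder neither).  In the
planted-winner scenario (n_winners > 0) winners pass every stage by
construction (top reference BS ≈ 9.5, similarity 0.65–0.9, MW > 310,
off-target BS below reference, forced dual-pocket occupancy) and each decoy
carries one deterministic disqualifier (low similarity, low MW, negative
CBAV, or low dual-pocket probability), cycling through the four failure
modes; with n_winners = 0 the generator is a plain occupancy/score sampler
for statistical recovery.  No docking geometry or energetics beyond scores
and occupancy labels is simulated.

**Expression matrices** model log2 signals as Gaussian around per-gene
baselines (N(7.5, 1.2), an Illumina-like intensity range), replicate noise
sd 0.25 log2 units, two replicates per condition, five conditions (control,
stim, stim + each of three inhibitors).  3 % of genes are induced with
planted log2 FC ~ N(3, 1) truncated below at a configurable floor (default
log2(2), keeping the FC ≥ 2 planting contract; recovery experiments use
floor 3, i.e. every planted effect ≥ 8-fold).  60 % of induced genes
respond to each inhibitor with a planted FC ratio of 16 applied on the
mean.  The dimmest 0.5 % of raw intensities are reported negative, the way
background subtraction drives near-background probes below zero, which
exercises the flooring rule without corrupting bright probes.  This is not
a bead-level error model: no probe redundancy, no probe-specific biases, no
intensity-dependent variance; passing recovery here shows the pipeline's
criteria act as specified under the stated noise, not that the pipeline
conquers real array artefacts.

**Promoters** are i.i.d. backgrounds at GC 0.45 (length 1000 = 950 bp
upstream + 50 downstream) with per-gene site-combination categories drawn
from a configurable composition (default: most genes carry at least one
site, mirroring an inflammation-responsive cohort).  One motif instance per
planted class is sampled columnwise from a class PFM and accepted only if
its similarity score reaches the class threshold (the high-probability
instance set — planted sites are functional sites); unconditional sampling
is available (`sampler="pfm"`).  Instances are placed non-overlapping at
uniform offsets and strands.  An order-3 Markov resampler
(`markov_resample`) produces motif-free backgrounds with preserved local
composition for false-positive measurement.

## Problem sizes and determinism

The shipped experiments use: 500 compounds × 20 poses for occupancy
recovery (binomial SE ≈ 0.004 on the mean), 20 seeded runs of
2000 genes × 10 samples for expression recovery, 200 promoters for motif
recovery, 100 for false-positive measurement, and a 50-compound planted
library for the cascade — sizes at which every recovery margin is several
standard errors wide while the whole suite runs in seconds.  All
randomness flows through `numpy.random.default_rng(seed)`; reports are
identical across reruns at a fixed seed (manifest timestamps aside).

## Known limitations

- CBAV/LBPV consume engine scores as given; cross-engine or cross-run
  comparability is the caller's responsibility.
- The expression significance test is a two-sample t on n = 2; it has no
  moderation (no empirical-Bayes shrinkage) and the pooled default assumes
  equal variances between conditions.
- Promoter analysis calls motif presence, not occupancy or function, and
  the packaged matrices are synthetic stand-ins — swap in database PFM
  files for real analyses.
- The pipeline does not collapse probes to genes, nor handle missing
  values (inputs must be complete matrices).
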