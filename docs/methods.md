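# Methods

## Observed read depth and filtering

`RD_gs` is the number of distinct reads of sample *s* whose first (5')
base maps within any exon of gene *g* (half-open BED intervals; a read
counts once regardless of length).  Reads flagged as duplicates or with
mapping quality < 20 are discarded before counting; "uniquely mapped" is
operationalized as the mapping-quality cutoff.  When exons of two genes
overlap, a read is assigned to the gene whose covering exon starts first
(ties by gene name) — deterministic and logged; targeted designs rarely
overlap.  Strand is ignored: the placement table carries the 5' position
in reference orientation, and the optional BAM adapter emits the alignment
start for forward reads and the last aligned base for reverse reads.

Genes with median RD (across samples) below 30 are dropped, then samples
with median RD (across retained genes) below 30 — in that order, so the
sample filter sees only usable genes.  Long-read (454-style) data produces
far fewer reads per base; the relaxed thresholds (5, 1) are exposed in
`RunConfig` for that case.  Every filter logs what it removed.  The
ambiguity of filtering per-exon versus per-gene is resolved at the gene
level, after aggregation: calling operates on genes, and an exon-level
pre-filter would discard signal the gene-level aggregate can still use.

## Normalization: uni-linear and tri-linear fits

The diploid expectation is `RD_exp = α_g · MRD_s`.  `α_g` is the
zero-intercept least-squares slope Σ(MRD·RD)/Σ(MRD²).  Fit quality uses
the **centered** r² (SS_tot about the mean of RD): the uncentered
zero-intercept convention reports ≈1 for any positive trend and would
never trip the 0.7 gate, whereas genes with genuinely poor fits land well
below it under the centered form.

Genes failing the gate get the tri-linear fit: minimize over α

```
error_g = Σ_s min[(RD_s − α·MRD_s)², (RD_s − (α/2)·MRD_s)², RD_s²]
```

via bounded 1-D minimization on [0, 2·max(RD/MRD)], then alternating exact
weighted-least-squares re-fits per assignment partition (tolerance 1e-8,
≤100 iterations).  Each sample's arg-min branch assigns CN 2/1/0, and
r²_tri = 1 − error_g / SS_tot.

Acceptance of a tri fit needs more than r²_tri ≥ 0.7.  Because the tri
error is never worse than the single-line SSE (any outlier can be absorbed
by switching branches), high-dispersion genes with no CNV routinely pass a
raw r² gate — on a 106-sample synthetic cohort roughly a fifth of genes
would acquire spurious three-line fits, flooding the callset with direct
CN assignments.  A genuine copy-number mixture requires *resolvable
clusters*: the CN2/CN1 assignment boundary lies sqrt(α·MRD)/4 Poisson
sigmas from either line, so with gene noise odf̂ (robust spread of
assignment-aware z-scores) the boundary sits sqrt(α·MRD)/(4·odf̂) noise
sigmas away.  The fit is kept only when the median separation reaches 1.5σ
(≤ ~7% expected cross-assignment); below that the data cannot distinguish
a common CNV from over-dispersion, and the gene is excluded from calling —
the same conclusion the distribution-inspection approach reaches for such
genes.  Accepted tri genes emit calls directly from the assignment,
flagged with their provenance.

## Over-dispersion and posteriors

Poisson z-scores z = (RD − RD_exp)/√RD_exp have unit spread under ideal
Poisson noise.  The per-sample ODF is the spread of z down its column, the
per-gene ODF the spread along its row, and the per-site ODF their product
divided by the global spread of all z — the product alone double-counts
dispersion shared by rows and columns (a uniformly D-dispersed matrix must
map to D, not D²) — clamped to [1, 20].  All spreads are outlier-trimmed
standard deviations (3σ trim, rescaled by the truncated-normal factor
0.9735 for consistency under normality): genuine CNVs put large outliers
into z, and an untrimmed spread lets strong events inflate their own
gene's ODF and mask themselves; with few samples a single spiked site
would otherwise inflate the gene ODF by ~30%.

Likelihoods are continuous normal approximations to the over-dispersed
Poisson: mean μ_CN = (CN/2)·RD_exp for CN ≥ 1, μ_0 = 0.01·RD_exp (the
homozygous-deletion residual keeps the sd positive and reflects
erroneously mapped reads), sd = ODF·√μ_CN.  This family reproduces the QI
thresholds analytically and is the same model the simulators draw from.  A
negative-binomial alternative (same mean/variance) is available via
`family="nbinom"` but is not the default.  Posteriors are computed in log
space (never a zero vector) over CN 0–9 with the nominal prior table,
renormalized on load.  Sex chromosomes are outside scope: the diploid
baseline is autosomal.

Calling: a site is reported when the most probable non-diploid CN reaches
h = 0.65 (inclusive).  Neighbor rescue builds a per-sample candidate list
of deletions (best of CN 0/1 at posterior ≥ 0.1) and keeps candidates with
at least one *immediately adjacent* sequenced gene — same chromosome, no
analyzed gene between, facing boundaries ≤ 3 Mbp apart — also on the list.
Rescue is restricted to deletions; the multi-gene-event argument motivating
it is only reported for deletions.  The final callset is the union, with
standalone (higher-threshold) provenance winning on overlap.

## Detection power

QI = √RD_exp / ODF.  Theoretical heterozygous-deletion efficiency at
cutoff h integrates the CN=1 observation model Normal(RD_exp/2,
ODF²·RD_exp/2) over the RD interval where the *full* posterior condition
P(CN=1|RD) ≥ h holds (grid scan at 1.5·RD_exp/3000 resolution, flanks
polished by Brent root-finding).  The posterior depends on (RD_exp, ODF)
only through QI in this model, so efficiency curves collapse on QI; the
mapping QI → (RD_exp, ODF) uses a fixed reference ODF of 4.  Thresholds:
qi_zero by bisection on "any RD satisfies the condition" (tolerance 0.01
QI), qi_50/qi_90 by root-finding on the curve.  At h = 0.65 this gives
5.12 / 7.17 / 9.43.  The two-hypothesis (CN1 vs CN2) closed form — maximum
log-likelihood ratio QI²/4 + ln√2, reached as RD → 0 — is kept as a test
oracle only; the shipped curve integrates all ten copy numbers.

The coverage planner scales the MRD level until the mean efficiency over a
joint (affinity, ODF) sample reaches a target, then converts reads to base
coverage as MRD·read_length/gene_target_bases/(1 − duplicate_rate).
Default targeted bases per gene (2278 ≈ 13.4 exons × 170 bp) and duplicate
rate 0 are config inputs, fully overridable.  Note the direction of the
read-length effect: power depends on read *count*, so at a fixed required
read depth, longer reads cost proportionally more base coverage.

FDR is estimated as invalidated / conclusively-validated calls
(inconclusive and unvalidated excluded).  Event projection:
true_total = n_calls·(1−FDR)/sensitivity, divided by samples, scaled by
exome/panel gene counts.  Worked cohort numbers (41 calls, FDR 12.5%,
sensitivity 54.5%, 106 samples, 862 of 21,999 genes) give ≈66 events,
0.62/sample, ≈16 per exome per sample; sensitivity is an explicit argument
because single-gene and neighbor-aware gene-pair spike-in procedures yield
different values and the projection must state which one it corrects by.

## Synthetic cohorts

The generator emulates an Illumina-sequenced capture cohort at the summary
statistics of the reference dataset:

| quantity | model | default |
|---|---|---|
| MRD per sample | lognormal, moment-matched | mean 1710, sd 1073 |
| affinity per gene | lognormal, median/mean-matched | median 1.04, mean 1.40 |
| ODF per gene | lognormal, moment-matched, clamped [1,20] | mean 7.9, sd 8.2 |
| cohort | 862 genes × 106 samples | — |

Lognormals are chosen because only a long right tail reproduces the
mean ≫ median affinity pattern; the ODF lognormal lands quartiles near
3 / 5.5 / 10, matching the observed dispersion spread.  Sites draw
RD ~ round(max(0, Normal(m, (ODF·√m)²))) with m = α·MRD scaled by true CN
(half for CN=1, residual fraction for CN=0).  Genes are laid out on 22
autosomes with 1 Mb gaps (within neighbor-rescue range).  What the
generator does *not* emulate: GC/probe-sequence bias, batch effects,
read-level artifacts, linked multi-gene events, sex chromosomes — so
passing tests demonstrate internal consistency of model and caller, not
performance on any real cohort.

**Spike-in sensitivity.**  Five genes per sample are halved
(round-half-to-even) and truth records CN=1; the full pipeline (filters,
fits, ODF, posteriors) runs on the spiked matrix — re-running estimation
after spiking barely perturbs the fits at 5-of-862 genes per sample — and
sensitivity is the fraction of spiked sites recovered by any deletion
call.  On the default cohort this lands near 0.47 and agrees with the mean
theoretical efficiency over the spiked sites' estimated QI distribution to
within ~1 point; sensitivity is stable from 106 down to ~20 samples once
dispersion is estimated robustly.  Note the procedure halves the noise
along with the signal (a spiked site has sd ODF·√m/2, not ODF·√(m/2)), so
spike-in sensitivity can sit slightly above the theoretical curve in the
transition band.

**Common-deletion frequency sweep.**  One locus (affinity 1.8, ODF 8, 106
samples) segregates a deletion at allele frequency f ∈ {0, 0.1, …, 1}
under Hardy-Weinberg genotypes; heterozygotes halve the affinity,
homozygotes use 0.01·MRD.  Detection re-estimates the affinity from the
simulated data (uni gate → tri fallback) and calls each sample from the
Bayesian posterior at h = 0.65 with the generative dispersion.  The
headline sensitivity is the fraction of **heterozygous** carriers receiving
a deletion call: that is the quantity the QI power framework is defined
for, and it reproduces the published behavior of this simulation — roughly
flat across mid frequencies and declining above 70%, where the shrinking
diploid anchor degrades the affinity estimate.  (Homozygous carriers are
detected near-certainly by the posterior; direct tri-linear assignment
would classify nearly all carriers at these depths.  Both rates are
reported in the sweep table.)  Under the lognormal MRD model the
theoretical ceiling for this quantity is E[eff(√(1.8·MRD)/8)] ≈ 0.34 and
the measured mean over f ∈ [0.1, 0.9] is ≈ 0.31; a less right-skewed MRD
distribution at the same mean and sd yields noticeably higher values, so
this number is sensitive to the MRD distribution shape, of which only the
first two moments are matched.

## Numerical choices and degenerate inputs

Posteriors in log space with log-sum-exp; posterior vectors sum to 1
within 1e-9 and match an extended-precision direct computation to 1e-6
relative.  Constant z-matrices floor all ODF components at odf_min.
Zero-expected-depth sites are excluded from z-scores and forced diploid
(never called), with a log entry.  Tri-fit r² on zero-variance data is 1
for a perfect fit, else 0.  Medians of even-length vectors are the mean of
the central pair.  All randomness flows through a single seeded
`numpy.random.Generator`; fixed seeds give bit-identical datasets.

## Known limitations

Gene-level resolution only (no per-exon breakpoints); no GC correction; no
joint segmentation across genes beyond the immediate-neighbor rescue; the
prior table is population-generic, not frequency-aware; amplification
power is not modeled (the curve covers heterozygous deletions); X/Y
calling is excluded by the autosomal diploid baseline.
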