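# Methods

`transwalker` implements a trans-meQTL analysis chain: pairwise linear
association scans between genotype, DNA methylation and gene expression;
two-cohort replication with inverse-variance meta-analysis; reduction of the
redundant association set to independent sentinel loci; transcription-factor
binding-site (TFBS) enrichment of each sentinel's trans-CpG signature; a
spectral random walk over a protein–protein-interaction (PPI) network to rank
candidate genes at each trans-acting locus; and extraction of candidate
pathways with evidence-tier assignment. A seeded synthetic-data generator with
planted ground truth makes every stage testable without cohort data.

## Association scans and meta-analysis

All scans are per-pair ordinary least squares. Methylation (beta values on
[0, 1]) is first residualised on covariates — age, sex, five white-cell
proportion estimates (CD8T, CD4T, NK, B cell, monocyte) and batch components —
and each SNP–CpG pair is tested as `methylation_residual ~ dosage`. Expression
scans (`expression_residual ~ dosage`, eQTL) and methylation–expression scans
(`expression_residual ~ methylation_residual`, eQTM) follow the same pattern;
the eQTM scan optionally residualises CpG values on the five cell proportions
first, which removes associations that merely track cell composition.
Interaction (iQTL) scans fit `y ~ g + c + g·c (+ covariates)` and report the
interaction coefficient.

Genome-wide significance defaults to p < 1e-14. Single-cohort p-values use the
t reference; the choice of t versus normal matters only at very small n but is
fixed and documented here. Every p-value is carried with its log10 companion,
computed on the log scale from `t.logsf`/`norm.logsf`, so thresholds such as
1e-14 remain exact long after float64 underflow (p < 1e-300) and survive text
serialisation.

Meta-analysis is fixed-effect inverse variance: weights 1/se², combined
se = 1/√(Σw), p from the normal z. Cochran's Q is reported informationally; no
random-effects model is fitted. The replication rule passes a discovery
association when the replication cohort shows the same effect direction,
replication p < 0.05, and combined p < 1e-14. Missing genotypes are handled
pairwise-complete per test; zero-variance predictors are flagged `untestable`
rather than dropped silently.

Distance categories: **cis** = same chromosome and strictly < 1 Mb apart;
**long-range cis** = same chromosome otherwise (so exactly 1,000,000 bp is
long-range cis); **trans** = different chromosomes.

## Sentinel pruning

Stage one is per-CpG forward conditional analysis: repeatedly select the most
strongly associated SNP, re-test all remaining genome-wide-significant
candidates with the selected SNPs as additional regressors, and keep only
those still below threshold; iteration is capped at 50 rounds (error on
non-termination). Ties in p break on lexicographic marker id, making the
selection independent of candidate input order. Candidates collinear with the
selected set are treated as never-significant.

Stage two is greedy clumping, applied to SNPs and to CpGs separately within
each distance category: the lowest-p unassigned marker becomes a locus head
and absorbs unassigned markers with R² > 0.2 and head-to-member distance
< 1 Mb; repeat until all markers are assigned. R² is squared Pearson
correlation of dosages (or methylation values for CpGs) over the combined
samples. The output is a partition by construction. For each (SNP locus,
CpG locus) association the lowest-p pair is the sentinel pair; a trans SNP
locus additionally carries the full set S of its sentinel trans-CpGs. Trans
locus spans are trimmed to at most 1 Mb around the sentinel SNP, and candidate
genes are the genes whose annotation overlaps that span.

## TFBS enrichment

A CpG is "bound" by a DNA-binding protein when a track interval intersects the
closed 100 bp window centred on the CpG (±50 bp); track intervals are 0-based
half-open, so a peak starting one base past the window edge does not bind. The
binding matrix is invariant to interval order and to splitting intervals into
touching pieces.

A CpG set of size k is testable only if its smallest achievable one-sided
Fisher p — attained when all k members are bound,
p_min(k) = Π_{i<k} (K−i)/(N−i) with K bound CpGs in a background of N — beats
an adjusted threshold (default 0.05 Bonferroni-corrected across the screen).
Operationally the screen tests loci with ≥ 5 trans-CpGs. Enrichment itself
uses the two-sided Fisher exact test (a locus signature can be depleted as
well as enriched), sample odds ratio ad/bc with Haldane 0.5 correction on zero
cells (flagged), and Benjamini–Hochberg FDR across all (locus, track) tests at
q < 0.05. The background universe is all CpGs tested in the meQTL scan.

Empirical calibration resamples sets of equal size, matched member-wise on
covariates within tolerance bands, drawn without replacement inside each
draw; the empirical p uses the add-one convention,
p = (1 + #{draws ≥ observed}) / (n_resamples + 1), so it is never zero and is
bounded below by 1/(n+1). The same sampler serves generic matched-background
questions (e.g. matching SNPs on MAF ±2% and gene distance ±10 kb).

## Spectral random walk

For one trans locus, the locus graph G joins the PPI network — restricted to
expressed proteins (median expression above 0.1 on the RPKM-like scale) and
then to its largest connected component — with the locus' trans-CpG set S,
each CpG attached to the proteins whose binding sites cover it. CpGs with no
binder in the network are dropped with a warning; keeping them would
disconnect the graph.

On the adjacency A with degrees d, the symmetric transition matrix is
t_ij = a_ij / √(d(i)·d(j)). Its top eigenpair is λ0 = 1 with ψ0 ∝ √d (the
stationary component of the walk on a connected graph); both facts are
verified numerically at 1e-8/1e-6 on every spectrum. Removing the stationary
component and summing transition probabilities over all walk lengths gives the
aggregated transition matrix

    M = Σ_{t≥0} (T − ψ0ψ0ᵀ)^t − I = Σ_{i≥1} λ_i/(1−λ_i) · ψ_i ψ_iᵀ
      = (I − T + ψ0ψ0ᵀ)⁻¹ − I.

The identity term affects only diagonal entries and never the CpG-to-gene
submatrix (CpGs and genes are distinct nodes), so the λ/(1−λ) spectral form is
used throughout, truncated to the leading `n_eig` = 500 eigenpairs (dense
solver below 500 nodes, iterative sparse solver with a fixed start vector
above). A bipartite-component eigenvalue at −1 contributes the finite
coefficient −1/2; a second eigenvalue at +1 means the graph is disconnected
and is an error. Candidate gene c scores p_c = |S|⁻¹ Σ_{s∈S} M_sc.

Significance comes from B = 100 randomised graphs: each replicate resamples
|S| CpGs matched on methylation mean (width-0.05 bins) and standard deviation
(pool deciles), rebuilds the graph on the same PPI component, and recomputes
all candidate scores. When a member's joint (mean, sd) bin has no pool
candidates the match falls back to the mean bin alone — small pools cannot
always support the joint match; very small pools raise with a bin-occupancy
report. The empirical p of candidate c is the exceedance of its score over the
per-replicate *maximum* candidate score,
P(p_c) = (1 + #{b : max_{c'} p^b_{c'} ≥ p_c}) / (B + 1), and the selected set
is C* = {c : P(p_c) < 0.05}. Note the direction: a candidate is significant
when background maxima rarely reach its score. A literal "count the wins"
reading of the selection statistic would invert the selection semantics of C*;
this package implements the exceedance form, which is the standard empirical
p-value and the only direction consistent with selecting high-scoring
candidates. With B = 100 the smallest achievable p is 1/101 ≈ 0.0099.

## Pathways and evidence tiers

Node weights w_i sum diffusion from S into i and from i into C*
(w_i = Σ_s M_si + Σ_c M_ic, using the symmetry of M), inverted to
w*_i = max(w) − w_i so the best-scoring node costs 0. Any monotone rescaling
before inversion would not change path ordering, so none is applied. For
shortest-path extraction, node weights become edge weights (w*_u + w*_v)/2 —
each endpoint contributes half — which preserves the ordering of path totals
over interior nodes. One minimal-weight path is extracted per (s, c) ∈ S × C*
by Dijkstra on (total weight, hop count) with lexicographically smallest
predecessor on ties, making paths unique and independent of node order; with
all weights equal this degenerates to shortest hop count. Unreachable pairs
are logged and skipped. Path nodes form Q, and the candidate pathway is the
locus subgraph induced by C ∪ Q ∪ S.

The integrated correlation network residualises each expression/methylation
variable on its known cis-QTL SNPs (removing edges driven by shared genetic
control), correlates variable pairs for the pathway's edges plus CpG–cis-gene
pairs within 1 Mb, combines cohorts by fixed-effect meta-analysis on the
Fisher z scale (the natural scale for correlations), and flags edges at BH
q < 0.05 as "bold".

Evidence tiers per candidate, highest applicable wins:
i. TF at the locus, TFBS-enriched in the locus' trans-CpGs, with a cis-eQTL
for the sentinel SNP (nominal p < 0.01); ii. enriched TF without an eQTL;
iii. random-walk selection (C*) with a cis-eQTL; iv. random-walk selection
without; v. a singular cis-eQTL with no other evidence. Tier assignment is a
pure function of the three flags.

## Synthetic scenarios

The generator emulates the study conditions, not any cohort's joint
distribution. Genotypes: two synthetic chromosomes, LD blocks of 6 SNPs; each
block draws a MAF uniformly from (0.2, 0.5], builds a seed haplotype pair per
sample, and copies it to each SNP with per-allele flip probability 0.05
(within-block R² ≈ 0.8; flip 0 gives R² = 1, which the tests exploit).
Methylation: per-CpG baselines uniform on (0.25, 0.75), Gaussian noise on the
beta scale then clipping to [0, 1] (a slight bias at the extremes, accepted),
plus a cell-composition term with N(0, 0.02) loadings on five Dirichlet-drawn
cell proportions. Six blood fractions are drawn jointly and the granulocyte
share is omitted, as with reference-based estimates, so the five kept
proportions are full-rank alongside an intercept.

Planted effects: cis effects of 0.02 methylation change per allele copy with
noise sd 0.04, giving roughly 10% of methylation variance explained per
cis-meQTL — both at the scale reported for blood meQTLs. The trans mechanism
is a chain: sentinel SNP dosage → TF-gene log2 expression (coefficient 1.0,
noise sd 0.5) → methylation at the 10 bound CpGs on the other chromosome
(coefficient 0.08 per log2 unit). The chain is sized so the induced trans
associations clear p < 1e-14 at the default discovery size of 300 samples per
cohort; the realistic 2% *cis* effects intentionally do not reach 1e-14 at
this sample size (they would at cohort scale, n ≈ 3,800), so the reference
fixture's locus table is dominated by the planted trans locus. CpGs are spaced
more than 1 Mb apart so that CpGs correlated through the shared trans
regulator are not merged into one methylation locus by the distance rule —
mirroring real trans signatures, which are scattered across chromosomes.

The PPI graph is scale-free (preferential attachment, m = 2) over all gene
ids, with genes assigned to nodes at random so locus genes are not
systematically hubs. The planted TF's TFBS track places one interval within
±50 bp of every bound CpG; eight decoy tracks for well-connected non-locus
proteins each bind a random 5% of CpGs, which gives the randomised background
graphs realistic attachment points. Interaction effects multiply a cis SNP's
effect by the sample's centred cell proportion.

What the generator does **not** emulate: realistic haplotype/coalescent
structure, array-probe chemistry, probe cross-hybridisation, population
stratification, or cohort-scale dimensions (millions of tests, hundreds of
tracks). Passing tests therefore demonstrate correctness of the machinery and
recoverability of planted mechanisms at desk scale, not cohort-level effect
size estimates.

## Numerical and design choices

- All randomness flows from explicit seeds; the pipeline expands one master
  seed into per-stage child seeds via `SeedSequence` keyed on a stage label,
  so independent stages keep their streams if reordered. Reruns are
  bit-identical (verified by content hashes in the run manifest).
- Eigen-decomposition: `scipy.linalg.eigh` below 500 nodes (full, exact);
  `eigsh(which="LA")` with fixed start vector above. ψ0's sign is aligned to
  +√d.
- Conditional-analysis and clumping tie-breaks are lexicographic on marker id.
- The acceptance checks run at deliberately modest problem sizes — 20 random
  graphs up to 200 nodes for the closed-form equivalence, 25 seeded scenarios
  with B = 100 backgrounds for regulator recovery, 2,000 pairs at n = 200 for
  scan calibration, 50 seeds for sentinel recovery, and Fisher enumeration
  exhaustive for margins ≤ 12 with randomised coverage up to 30 — chosen as
  the package's own reference workload.

## Known limitations

- Fixed-effect meta-analysis only; heterogeneity is reported (Q), not
  modelled.
- The conditional analysis runs on combined samples rather than per ancestry
  with meta-analysis of conditional estimates; with a single synthetic
  population the two coincide.
- Clumping measures distance head-to-member, so a locus can span up to ~2 Mb
  before the trans-locus trim to 1 Mb around the sentinel.
- Gaussian-then-clip methylation noise is mildly biased for baselines near 0
  or 1.
- The matched-CpG fallback (mean bin only) weakens sd matching in small
  pools; with array-scale pools the joint match always applies.
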