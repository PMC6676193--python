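# Methods

## Study design being modelled

Four subjects are sampled on twelve days spanning a long intervention
(−45, −15, +2, +30, +60, +75, +90, +105, +120, +150, +175, +210). The two
pre-intervention days (−45, −15) are treated as technical replicates of a
single biological baseline. Methylation is measured as 450k-style beta
values (methylated fraction, in [0, 1]); 223-parameter biochemical panels
at full scale, 60 at the desk scale used throughout the tests. Methylation
and parameter series share seven in-mission days (+2, +30, +60, +90,
+120, +150, +175), which are the only days used for correlation.

## Probe filtering

Five QC filters run in a fixed order, each recorded with its removal
count: (1) detection p > 0.01 in any sample; (2) bead count < 3 in ≥ 5% of
samples; (3) SNP-overlapping probes; (4) multi-mapping probes; (5) X/Y
probes. Filters 3–5 commute; the order only affects how removals are
attributed, not the final set.

The variability screen computes per subject `sd_personal` (sample sd of
beta across all sampled days, n−1 denominator, pairwise-complete; probes
with fewer than two observations are flagged missing, never zero) and
`err_personal` (absolute beta difference between the two baseline
replicates; zero is attainable). Probes are kept when, in **every**
subject, `sd_personal > err_personal` and `sd_personal > 0.03`. The
"every subject" scope is configurable (`sd_scope='any'`) because the
alternative reading cannot be excluded; all-subjects is the default as
the stricter, more reproducible choice. `err_personal` is read as the
difference between the single pair of replicate samples, consistent with
an attainable minimum of exactly zero.

## Correlation stage

Spearman rank correlation (average ranks for ties — checked cell-by-cell
against a rank-then-Pearson oracle) between every retained probe and
every parameter over the seven shared days; pairwise-complete with a
default minimum of 5 usable points, zero-variance series give missing
cells rather than zeros. With seven points the attainable values lie on
the lattice 1 − Σd²/56, and the null sd is 1/√6 ≈ 0.41 — a key constant
for everything downstream: any single 7-point correlation is extremely
noisy, which is why the pipeline aggregates over blocks rather than
testing cells.

Matrices are column-standardized (mean 0, sd 1 per parameter, n−1
denominator, matching the conventional column-default of statistical
environments); missing cells are imputed to the column mean and constant
columns zeroed with a log entry. Parameters sampled off the shared grid
(e.g. urine panels) can be aligned by nearest day within ±5 days
(`correlation.align_days`); the alignment rule is configurable because
the original design leaves it open.

## Sparse factor-analysis biclustering

Model: X = Σᵢ λᵢ zᵢᵀ + γ with diagonal per-row noise Ψ. Laplace priors on
both factors and loadings give simultaneous row/column sparsity, so each
factor is interpretable as one bicluster.

Fitting (variational EM):

* **E-step.** The Laplace factor prior is handled by the standard
  Gaussian scale bound: a variational scale ξᵢⱼ per factor × column acts
  as a Gaussian prior variance, updated to √E[z²] each sweep. Posterior
  per column j: covariance (diag(1/ξⱼ) + ΛᵀΨ⁻¹Λ)⁻¹, mean the matching
  ridge regression.
* **M-step.** Λ solves the moment equation, then a soft threshold
  `sparseness · √ψ_r` is applied per row — the published sparseness
  factor (default 0.1) scaled by the row noise level, so noiseless
  structure is recovered exactly (the threshold vanishes with ψ) while
  noisy rows are pruned. Ψ is the residual diagonal, floored at 10⁻⁶.
  Factors are rescaled to unit second moment each sweep, absorbing scale
  into Λ.
* **Initialization and rotation.** Λ starts from the top-K SVD of X plus
  a small seeded perturbation. A correlation matrix over seven time
  points has rank ≤ 6, so the signal subspace is rotationally degenerate
  and equal-strength biclusters produce near-equal singular values; a
  varimax rotation — the orthogonal rotation maximizing loading
  sparsity, i.e. the direction the Laplace loading prior prefers — is
  applied at initialization and again after EM to resolve the
  degeneracy. Everything is deterministic given the seed.

**Information content.** Factor i is ranked by
IC_i = ½ Σⱼ [ln ξᵢⱼ − ln (Σⱼ)ᵢᵢ] nats — the Gaussian mutual information
between factor i and the data columns under the fitted variational
approximation. It is exactly 0 for a zero loading vector, strictly
increasing in ‖λᵢ‖, and matches the joint-covariance-determinant mutual
information in the Gaussian-prior case (tested against that oracle).
Factors with IC below `ic_eps` (default 1.0 nats — no canonical value
exists, so the cutoff is configurable and the planted-signal tests show
the retained count is stable across a decade of choices) are superfluous.

**Membership extraction.** Because K typically exceeds the matrix rank,
per-factor loadings from the joint M-step regression are collinear and
unstable; membership therefore uses *marginal* scores — each row
regressed on the unit-scaled factor alone, each column projected on the
unit loading direction. Member scores form a plateau (the correlation
lattice quantizes them) over a continuum of background scores, so the
threshold is a margin times the median of the top scores holding half the
squared mass: 0.8 for rows, 0.95 for columns (the column plateau is
tighter, background closer). `thresZ = 0.5` remains the absolute floor on
the standardized column score. Overlapping membership across biclusters
is permitted.

## Associations and consensus

Within a bicluster, every annotated gene of every member probe is paired
with every member parameter; multi-symbol annotations are split on ";"
and contribute all symbols, unannotated probes are skipped at gene level
(not mapped to a pseudo-gene). A pair supported by several biclusters of
one subject counts once; consensus keeps pairs present in ≥ 3 subjects
(configurable), recording support, subjects and contributing biclusters.
Venn-region counts over the subject pair sets are emitted for audit; the
regions sum to the union by construction.

## Validation and enrichment statistics

All enrichment tests are exact hypergeometric upper tails P(X ≥ k),
summed in log space (verified against exhaustive enumeration for all
N ≤ 12 instances at 10⁻¹²). Raw p-values with a 0.05 cut are the default;
Benjamini–Hochberg q-values are opt-in. The permutation null redraws the
association set as uniform distinct pairs from the observed gene ×
parameter universe (1,000 draws by default) and uses the add-one
empirical p, (1 + #{null ≥ obs})/(n_perm + 1), which cannot reach zero.
Parameter–disease associations test each parameter's partner-gene set
against every disease gene set over the union-of-annotation-sets
universe. Coverage counts distinct (subject, bicluster) units per
parameter or per significantly enriched term.

## Synthetic-study generator

What it emulates, and the choices behind it:

* **Latent courses.** Each planted bicluster follows one latent
  physiological program per subject: a cosine of distinct frequency over
  the mission timeline (monotone drift, mid-mission dip, oscillation)
  with random sign and smooth jitter. Programs are Gram–Schmidt
  orthogonalized on the seven correlation days — independent smooth
  random walks were rejected because their spurious mutual 7-point
  correlations make distinct planted biclusters statistically
  inseparable in principle — and monotonically respaced so their levels
  on those days are equispaced, keeping member rank patterns resolvable
  against biological noise while preserving serial structure.
* **Probes.** Member probes: logit-scale beta = base + sign · effect_sd ·
  course + N(0, bio_sd), squashed by the inverse logit (logit-normal
  noise keeps beta in [0, 1]). Defaults: effect_sd 0.35 on the logit
  scale (planted probes emulate the *selected most-variable* probes,
  beta-sd ≈ 0.075 — upper-quartile-to-max territory for blood 450k
  variability), bio_sd 0.065 (background beta-sd ≈ 0.013, the typical
  median). A fraction `bg_variable_frac = 0.10` of background probes
  carries its own independent random-walk course — biologically variable
  but linked to no parameter — so the variability filter retains
  realistic signal-free rows for the biclustering to reject. Member and
  variable probes draw mid-range baselines (beta 0.3–0.7); flat
  background spans 0.05–0.95.
* **Replicates and QC.** The two baseline days share their biology and
  differ only by technical noise of sd `tech_sd` (default 0.007, giving
  mean replicate errors ≈ 0.008) added per sample on the beta scale. QC
  tables are mostly clean with ~1% planted failures per filter;
  SNP/multimap/sex flags are probe properties shared across subjects,
  detection p and bead counts vary per sample. QC failures avoid planted
  probes so ground-truth recovery stays interpretable.
* **Parameters.** Member parameters: gain (±0.8–1.2) × course +
  N(0, 0.15) — assay noise ~15% of the dynamic range, in line with
  clinical-chemistry CVs; background parameters are independent
  unit-normal series.
* **Annotation, reference, term sets.** Genes receive
  1 + Poisson(mean − 1) probes each (mean 2.0), probes carry 0–2 symbols;
  the reference-interaction set includes truth pairs at `ref_recall`
  (0.8) and non-truth pairs at `ref_background` (0.0169, the background
  validation rate of curated chemical–gene resources); annotation sets
  are random gene sets plus the planted biclusters' gene sets as planted
  terms.
* **Scale.** Tests run 4 × 2,000 × 60 (and 500 × 60 single-subject for
  the recovery property, planted as 3 × 130-probe blocks — the matrix
  stands for the post-variability-filter probe set, which is mostly
  signal-carrying); the full 20,158 × 223 geometry is reachable through
  the same configuration but is not exercised by the default suite.

What the generator does **not** model — and what passing tests therefore
do not show about real data: cell-composition shifts and batch effects
(the emulated design is single-batch), age/sex covariates, genome-scale
annotation structure (CpG islands, co-methylation blocks), non-Gaussian
parameter distributions, missing-at-random structure in the panels, or
latent programs that real physiology would not keep orthogonal.
Planted-recovery results demonstrate algorithmic correctness under the
generator's assumptions, not field performance.

## Numerical choices and degenerate inputs

Noise variances floored at 10⁻⁶; variational scales at 10⁻⁶; ridge 10⁻⁹
in the M-step solve. Zero-variance series → missing correlations;
constant columns → zeroed after standardization (logged); all-superfluous
factor sets → empty bicluster list with a warning, not an error. Ties in
ranks use average ranks throughout. The per-stage seed scheme is
`(global_seed · 31 + stage_index) mod 2³¹`, so any stage can be rerun in
isolation bit-identically.

## Known limitations

Seven time points bound what any method can do here: the null sd of a
single correlation is 0.41 and background probes genuinely correlated
with a latent course are indistinguishable from members at the matrix
level — recovery targets are met with planted blocks large enough for
plateau detection, and single-cell-level membership claims should not be
over-read. The EM monitors reconstruction error, not the full variational
bound; monotonicity is asserted only over the converged tail. Runtime is
dominated by the per-column K × K inversions; the full published-scale
fit (K = 50, 15,000 iterations, 20,158 × 223 × 4 subjects) is supported
but takes orders of magnitude longer than the desk-scale defaults
(K = 10, 500 iterations), which the planted-signal tests show are
sufficient at test scale.
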