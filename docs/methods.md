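# Methods

`genosubtype` discovers genetically defined subgroups of hypertensive
patients from case/control genotype data in two phases: supervised
selection of disease-informative variants, and unsupervised clustering of
the patients on those variants. This note records the statistical model,
the tunable parameters, the numerical conventions, and what the synthetic
cohort generator does and does not emulate.

## 1. Variant selection

**Per-variant logistic filter.** For each variant p, disease status y_i is
regressed on the additive genotype count G_ip ∈ {0,1,2} with age, sex and
BMI as covariates:

    logit P(y_i = 1) = α_0p + α_p' X_i + β_p G_ip.

Fits use Newton-Raphson maximum likelihood (statsmodels `Logit`).
Variants with a two-sided Wald p-value below the cutoff (default 0.05;
0.1 as a sensitivity setting) **and β_p > 0** are retained: protective
variants (β < 0) are discarded because the goal is to subdivide patients
by risk-conferring genetic load, and a burden over variants of mixed sign
would cancel. Monomorphic variants, non-convergent fits and
quasi-separated fits (Wald SE above 100, i.e. a diverging estimate) are
flagged `converged=False` and excluded rather than penalized — a
conservative and easily auditable convention. Covariates enter on their
raw scales; constant covariate columns are dropped (they are collinear
with the intercept), which also permits covariate-free fits.

**Rare-variant filter.** A variant is *rare* when its reference-panel
minor-allele frequency is strictly below 1%. The panel frequency is
folded, min(f, 1−f), so the rule is invariant to which allele the panel
happens to report; the threshold is strict (`<`) to match the "less than
1%" convention.

**Deleterious filter.** A variant is *deleterious* when at least one of
the three gene-model annotation sources labels it nonsynonymous, stopgain
or stoploss (union rule). Any class string outside the closed vocabulary
{nonsynonymous, stopgain, stoploss, synonymous, unknown} is a validation
error, not a silent miss.

**F-statistic ranking.** For two status classes with allele frequencies
p₁ (hypertensive) and p₂ (normotensive),

    F = Var(p) / (p̄ q̄),   p̄ = (p₁+p₂)/2,  q̄ = 1−p̄,
    Var(p) = ((p₁−p̄)² + (p₂−p̄)²)/2.

F ∈ [0,1] for two classes (Var(p) = ((p₁−p₂)/2)² ≤ p̄q̄), is 0 iff
p₁ = p₂, and is symmetric under allele relabelling p → 1−p. Monomorphic
variants (p̄ ∈ {0,1}) are assigned F = 0: the 0/0 limit carries no
classification information and must never outrank a polymorphic variant.
Ranking is computed over the full candidate pool (rare variants when the
rare filter is active, otherwise all variants), the top ⌈fraction·N⌉ are
cut (ceiling, so a small fraction is never empty; ties broken by variant
id), and the cut is then intersected with the positive-effect logistic
selection. The default top fraction is 2%.

**Stage order and monotonicity.** The pipeline applies: imputation →
logistic/positive filter → rare filter → deleterious filter → F cut →
feature-matrix construction. Every stage only removes candidates, so the
selection at cutoff 0.05 is nested inside the selection at 0.1; each
stage logs input/output counts.

**Missing genotypes** are imputed before any statistic with the
per-variant rounded mean (nearest integer in {0,1,2}), keeping the matrix
count-valued for the Poisson-likelihood factorization. The generator's
missingness is completely at random; upstream QC of systematically
missing data is out of scope.

## 2. Burden aggregation

With the gene-aggregation option, selected variants in the same gene
region are summed per patient into a single burden count. Because every
retained variant has a positive effect, the burden is directionally
coherent. The grand total of allele counts is conserved by construction.
Each variant belongs to exactly one gene region (the annotation's
assignment). All-zero feature rows and all-zero patient columns are
dropped before factorization — the KL objective is degenerate on them —
and the drops are recorded on the result object.

## 3. NMF consensus subtyping

The feature-by-patient count matrix A (N×M, hypertensive patients only)
is factorized as A ≈ WH, W ≥ 0 (N×K), H ≥ 0 (K×M), by minimizing the
generalized Kullback–Leibler divergence

    D(A‖WH) = Σ_ij [ A_ij log(A_ij/(WH)_ij) − A_ij + (WH)_ij ],

the objective implied by a Poisson likelihood on counts, with the classic
multiplicative updates

    H_kj ← H_kj · (Σ_i W_ik A_ij/(WH)_ij) / Σ_i W_ik
    W_ik ← W_ik · (Σ_j H_kj A_ij/(WH)_ij) / Σ_j H_kj.

Numerical conventions: W, H initialized uniform in (0,1] from the run
seed; an epsilon guard of 1e-12 inside divisions and logs (multiplicative
updates on sparse count matrices hit exact zeros); 0·log 0 = 0 in the
objective. Convergence is connectivity-based, as in the original metagene
protocol: every 10 iterations the patient partition (argmax over rows of
H per column) is recomputed, and the run stops when it has been unchanged
for 40 consecutive checks, or at 2000 iterations. The divergence trace is
non-increasing up to a 1e-8 relative tolerance (verified property).

**Assignment and margin.** Patient j joins cluster argmax_k H_kj (ties to
the smallest k). The ambiguity margin is (largest − second largest)
H entry divided by the column sum; patients near 0 sit between two
meta-features. The raw-argmax rule follows the highest-meta-feature-level
convention; it is invariant under a global rescaling of H but not under
independent per-row rescalings, so H is reported as produced by the
update rules without renormalization.

**Consensus and rank selection.** For each candidate rank K (default
{2,3,4,5}) the factorization is restarted n_runs times (default 30,
seeds base..base+n_runs−1). Each run contributes a binary connectivity
matrix (1 where two patients share a cluster); their average is the
consensus matrix, whose entries are co-clustering frequencies. The
cophenetic correlation coefficient (CCC) is the Pearson correlation
between the distances 1−consensus and the cophenetic distances of their
average-linkage dendrogram (scipy hierarchy). Conventions: an exactly
0/1 consensus with transitive block structure returns CCC = 1 (the
perfect-reproducibility case, detected before any correlation); a
consensus with zero distance variance returns 0 — it carries no cluster
structure and must never win rank selection. The selected rank maximizes
CCC, ties broken toward smaller K (parsimony). The run with the lowest
final divergence at the selected rank provides the H used for the final
assignment.

## 4. Evaluation

**Kruskal–Wallis tests.** Each echocardiographic outcome variable
(lateral/septal e′ and s′ velocities, global circumferential/longitudinal/
radial strain, atrial/early-diastolic/systolic strain rates) is compared
across the subtype groups with the tie-corrected Kruskal–Wallis H and the
chi-square approximation on (groups−1) degrees of freedom
(scipy `kruskal`). All-identical values give H = 0, p = 1 by convention;
variables that are entirely missing, or vacuous because all patients fall
in one cluster, are reported untestable. The default significance level
is α = 0.1, configurable. No multiplicity correction is applied across
the nine variables. The chi-square approximation was checked against a
10,000-permutation null: in the decision-relevant tail (p ≲ 0.1) the two
agree within Monte-Carlo error; the approximation is loose only deep in
the right tail (p ≈ 0.95), far from any threshold.

**Allocation stability.** Two configurations' assignments are compared
after matching their arbitrary cluster labels by maximum-overlap
(exhaustive over label permutations, K ≤ 5). Reported: the number of
patients whose matched label is unchanged, and the mean assignment margin
of changed vs unchanged patients — switching patients are expected to be
the low-margin, ambiguous ones.

## 5. Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes,
with defaults chosen as a realistic desk-scale case/control study:

| parameter | default | meaning |
|---|---|---|
| n_cases / n_controls | 200 / 200 | cohort size |
| n_variants | 300 | variant panel |
| n_subtypes | 2 | planted subgroups among cases |
| n_risk_variants | 30 | variants driving disease risk |
| n_subtype_variants | 30 per subtype | subtype-marker variants |
| base_maf_range | (0.05, 0.4) | common-variant frequency range |
| rare_fraction | 0.10 | background variants drawn with f < 1% |
| subtype_freq_shift | 0.25 | allele-frequency delta in the marker block |
| risk_beta | 0.5 | log-odds per risk allele |
| covariate_effects | (0.02, 0.3, 0.03) | age (per year), sex, BMI (per kg/m²) log-odds |
| phenotype_shift | 1.0 SD | mean outcome difference between subtypes |
| missing_rate | 0 | MCAR genotype missingness |

Mechanics: genotypes are Binomial(2, f) under Hardy–Weinberg; disease
status follows the logistic model above with the intercept calibrated by
bisection so the expected case fraction matches the requested one, then
exact case/control counts are drawn from an oversampled pool. Planted
subtype labels are balanced among the cases; the subtype-marker block of
each subtype is re-drawn at f + shift for that subtype's cases only, so
subtype structure exists among cases and not controls (the clustering
operates on cases only). Marker and risk blocks are disjoint, and rare
variants are drawn only among background variants so the shift keeps
frequencies inside (0,1). Outcomes are standard normal noise; six of the
nine variables receive the subtype mean shift (rank-based testing makes
the noise family uncritical). Covariates are independent draws
(age ~ N(55,10), sex ~ Bernoulli(0.5), BMI ~ N(30,5)) — no claim of
joint-distribution fidelity to any real cohort. The annotation generator
assigns each variant one gene region, makes a configurable fraction
deleterious in ≥1 of the three sources, and reports the generating
frequency under small multiplicative noise as the reference-panel
frequency.

**What the generator does not emulate:** linkage disequilibrium,
family/pedigree relatedness, imputation dosages, systematic missingness,
population stratification, realistic covariate correlation. Passing the
planted-recovery tests therefore shows the machinery is correct under the
assumed generative structure, not that real cohorts will cluster as
cleanly.

## 6. Problem sizes used in tests

The test suite and the acceptance script run the full workflow at the
default cohort scale (400 subjects × 300 variants, feature matrices of
roughly 20–90 features × 200 patients). Consensus scans use 30 restarts
for rank selection and 5 restarts per seed in the repeated-seed power
checks; these sizes give stable medians while keeping a full run of the
suite under a minute on one CPU.

## 7. Known limitations

- The positive-effect rule assumes the alternate allele is coded
  consistently; flipped coding reverses the sign of β.
- Rank selection compares CCC across K without a null calibration; on
  data with no structure all CCCs are low and the selected K is
  arbitrary (the no-signal contrast test documents this regime).
- Quasi-separated variants are dropped, which can discard genuinely
  strong rare effects in small cohorts; penalized likelihood would retain
  them at the cost of a different inferential convention.
- Only bi-allelic variants are supported; multi-allelic VCF records must
  be split upstream.
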