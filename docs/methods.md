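# Methods

## Model

The unit of analysis is the gene. For each gene g and mutation type
t ∈ {missense, nonsense, frameshift}, the observed somatic mutation count
y_tg across a cohort of tumor samples is modeled as

    E[y_tg] = β_t0 + Σ_j β_tj x_gj

where x_g is the vector of gene characteristics, fitted by ordinary least
squares on the raw count scale. The characteristics are:

* **cds_length** — coding-region length N in nucleotides (largest
  transcript per gene; exact ties broken by lexicographically smallest
  record id).
* **n_potential_{missense,nonsense,silent}** — of the 3N possible
  single-nucleotide substitutions (SNSs) of the CDS, the number whose
  outcome under the standard nuclear genetic code (NCBI table 1) is of the
  given class. Stop-loss substitutions form a fourth class that completes
  the 3N partition but is not used as a predictor. The terminal stop codon
  is enumerated like any other codon; the counts are deterministic in the
  sequence.
* **pct_a/c/g/t, pct_cpg, nd** — base fractions; CpG-dinucleotide count
  divided by N; nucleotide diversity ND = 1 − Σ p_b², the probability that
  two randomly drawn bases differ (0 for a homopolymer, maximum 0.75 at
  equal composition).
* **conservation_index** — ⌊n_orthologs/2⌋ + 1 over a 20-species reference
  panel (0–1 orthologs → 1, 2–3 → 2, ...).
* **snp_density** — unique germline SNPs in the CDS divided by N.
* **mean_expression / log_mean_expression** — arithmetic mean across cell
  lines; log₁₀(mean + pseudocount), pseudocount 0 by default so a gene with
  zero mean expression is dropped as incomplete rather than imputed.
* **replication_time** — signed relative replication time (negative early,
  positive late), per gene the mean of track probes inside the gene
  interval, or the value of the nearest probe when the gene contains none
  (distance to the closer interval edge; exact ties go to the lower
  coordinate). Intervals are 0-based half-open internally; 1-based closed
  input is converted on read.
* **chromatin_accessibility** — mean accessibility signal.
* **n_silent_observed** — the gene's observed silent-mutation count, used
  as an empirical mutability surrogate (silent mutations are assumed
  selectively neutral). Configurable to enter as a density instead.
* **mutsig_expr / mutsig_hic / mutsig_reptime** — passthrough covariates on
  the scale of an external driver-detection tool; never recomputed here.

Only whole-genome-screen mutation records enter the counts (uniform
interrogation across genes), records flagged as germline SNPs are excluded,
and duplicate reports of the same allele count as distinct occurrences.
Frameshift = insertion- or deletion-type records explicitly marked as
coding frameshifts; in-frame indels and unrecognized descriptions are
ignored. Only genes with complete data for every predictor are modeled;
genes on exclusion lists (e.g. olfactory receptors, or extreme known
drivers) can be withheld from fitting while still being scored.

## Stepwise selection

Because the characteristics are strongly inter-correlated, each model uses
forward selection with backward elimination on OLS partial p-values:
the most significant remaining candidate enters while p < p_enter (default
0.05; ties broken by smaller p, then alphabetically), and any included
predictor whose p-value rises above p_remove (default 0.10) is removed,
worst first, until stable. The procedure is deterministic given the input.
An exhaustive best-subset mode (BIC-minimizing, ≤15 candidates) is provided
as a sensitivity check. Default candidate sets differ by mutation type,
reflecting which characteristics show a usable univariate association with
each outcome; they are configurable.

Reported per predictor: raw coefficient, t, two-sided p, and standardized
β = coef · sd(x)/sd(y). The model's residual scale is the root-mean-square
residual on the fitting set. The pan-mutation model fits the per-gene sum
of missense + nonsense + frameshift counts. When the pan model is scored
against a single type's counts the scales differ, so its per-type accuracy
is the squared Pearson correlation between the pan prediction and the
observed type counts (identical to 1 − SS_res/SS_tot on the fitting set
when scales agree).

## Outlier calling

Residual Z-scores Z_tg = (y_tg − ŷ_tg)/residual_sd_t are computed per type
over all scored genes (predictions are not clipped at zero, so residuals
stay centered). Each gene is tested three times and n genes are tested, so
the per-type significance threshold is Φ⁻¹((1 − α/n)^(1/3)) — Bonferroni
over genes combined with a max-of-three correction, assuming independence
of the three scores. Flags use strict one-sided Z > cutoff (configurable to
two-sided); genes with Z < −cutoff (mutation deficits) are reported
separately. An optional average-leverage studentization (divide by
√(1 − p/n)) is available; plain standardization is the default since the
method treats standardized residuals as N(0,1).

Moving-average curves (predictor vs outcome means over a window of 100
genes ranked by the predictor, sliding one gene at a time) are exported for
visualization. A window in *genes*, not nucleotides, is used: the window
slides over ranked genes, which is the only reading under which a window
size of 100 is meaningful for all predictors.

## Synthetic cohorts

The generator emulates the statistical structure of a pan-cancer cohort of
~15,000 genes, not any real genome:

* CDS lengths are log-normal (ln-scale mean 7.2 ≈ 1340 nt median, sd 0.55,
  minimum 40 codons); per-gene base composition is Dirichlet around
  (A, C, G, T) = (0.25, 0.26, 0.27, 0.22) with concentration 60; sequences
  are ATG + base-wise-sampled codons with in-frame stop codons rejected +
  one uniform stop codon.
* Non-sequence covariates and a latent per-gene mutability factor h come
  from a Gaussian copula correlated with log CDS length (defaults: larger
  genes slightly more conserved and SNP-poor; expressed genes replicate
  earlier in more open chromatin; h tracks late replication and low
  expression), then mapped to marginal scales (log-normal expression and
  chromatin, Poisson SNP counts, binomial ortholog counts).
* Counts are Poisson with mean λ_t = max(0, a_t + b_t·u_t), where u_t is a
  standardized linear combination of characteristics (optionally including
  h) and b_t = √(a_t·R²/(1−R²)) calibrates the achievable OLS R² to a
  target: Poisson residual variance ≈ the mean count a_t. Mean counts per
  gene default to 143 (missense), 10.5 (nonsense), 5.5 (frameshift) and 55
  (silent) — the first three follow a large pan-cancer cohort's totals over
  ~15,610 genes; the silent mean is set at a typical silent:missense ratio
  for coding substitutions. Default R² targets are 0.88/0.40/0.23/0.80.
  Raw-scale generating coefficients are recorded as ground truth.
* Driver genes multiply λ by (1 + δ) for their designated types: TS-like
  drivers in all three types (δ = 2.0/2.5/3.0), OG-like drivers in missense
  only (δ = 2.0) — sized so every injected excess exceeds six residual
  standard deviations. Silent counts are always generated driver-free.
* Two named scenarios: `SimulationConfig.default()` includes the latent
  factor, which makes observed silent counts an informative predictor of
  the other types (as in real data, where silent density proxies
  mutability); `SimulationConfig.feature_only()` puts all structured
  variance on observed characteristics with no drivers, so generating
  coefficients are exactly recoverable by regression.
* One integer seed determines everything; stage-level generators are
  spawned from a `numpy.random.SeedSequence` so each stage is independently
  reproducible. Exports round-trip exactly: the in-memory feature matrix
  equals the matrix rebuilt from the exported FASTA/TSV/BED files, because
  both paths run the same assembly code.

What the generator does **not** emulate: trinucleotide mutational
signatures, sample-level heterogeneity (hypermutators), positional
clustering of mutations within genes (hotspots), realistic ortholog
phylogenetics, and olfactory-receptor-like composition outliers. Passing
tests on synthetic cohorts therefore demonstrate correctness of the
machinery and its statistical calibration under the stated model, not
performance on real tumor data.

## Numerical choices and known limitations

* **OLS on Poisson counts.** The linear-regression framing is kept
  deliberately (no Poisson/negative-binomial likelihood). Under Poisson
  noise OLS point estimates remain unbiased for a linear mean, but
  homoskedastic standard errors are approximate; parameter-recovery checks
  therefore use heteroskedasticity-robust (sandwich) standard errors.
* **False-flag rate at low mean counts.** The Z cutoff assumes Gaussian
  residuals. For types with small per-gene means (nonsense ~10, frameshift
  ~5), the Poisson right tail is heavier than Gaussian, so a 15,000-gene
  cohort typically shows ~2–3 barely-over-cutoff null flags concentrated in
  those types — above the nominal ≈α family-wise rate that holds exactly
  for Gaussian residuals (and is verified by Monte-Carlo). Interpreting
  marginal frameshift/nonsense outliers therefore warrants extra caution;
  injected-driver excesses (≥6 residual sd) are flagged with essentially
  full sensitivity regardless.
* **Collinear predictor twins.** Gene size and the potential-site counts
  are nearly proportional (r > 0.99), so subset selection between them is
  not identifiable: stepwise keeps whichever twin enters first, which is a
  property of the data, not an error. Parameter-recovery tests use
  candidate sets without near-duplicates of the generating predictors.
* **Stepwise thresholds.** p_enter = 0.05 / p_remove = 0.10 are
  conventional defaults; the selection events themselves are deterministic
  and tie-broken (smaller p, then alphabetical) for reproducibility.
* **Cutoff boundary.** Strictly greater-than; a gene exactly at the cutoff
  is not flagged.
* **Degenerate inputs.** Ambiguity codes in sequences, non-positive
  residual scales, constant outcomes, empty source intersections and
  missing mapped columns are hard errors; constant predictors are skipped
  with a warning; intercept-only models are returned (with R² = 0) when no
  candidate enters.
* **Problem sizes.** Statistical acceptance checks run on 15,000-gene
  cohorts (three replicates for coefficient recovery), 1,000 Monte-Carlo
  null cohorts for cutoff calibration, and 100 random CDSs against the
  brute-force enumeration oracle; unit tests use smaller cohorts (120–3,000
  genes) chosen so each check's statistical power, not runtime, dictates
  the size.
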