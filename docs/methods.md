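# Methods

This note documents the statistical model behind `allelic`, the choices
made where the design was genuinely open, and what the bundled simulator
does and does not emulate.

## The allelic-imbalance test

A biallelic reporter library carries two oligos per SNP (one per allele,
in both orientations relative to reporter transcription).  Because the two
alleles share a construct backbone, promoter and transfection batch, any
*trans* effect cancels and the quantity of interest is the within-SNP
allelic ratio of reporter transcripts relative to the allelic ratio of the
plasmid DNA input.

For SNP *i* in replicate *j*, let `R` and `A` be deduplicated reference and
alternate RNA molecule counts, `N = R + A`, and let `p0` be the reference
proportion of the pooled plasmid DNA with sampling variance `var0`.  The
effect is the log-odds difference

    beta = logit(p_hat) - logit(p0),    p_hat = (R + 1/2) / (N + 1),

with delta-method variance

    Var(beta) = (1 + (N - 1) rho) / (N p_hat (1 - p_hat))
              + var0 / (p0 (1 - p0))^2.

The `1 + (N - 1) rho` factor is the beta-binomial variance inflation: the
per-replicate reference proportion is modelled as a Beta draw with mean
`expit(logit(p0) + beta)` and correlation parameter `rho`, and molecule
counts as binomial given that draw.  `z = beta/se` is the per-replicate
statistic; the normal approximation on the logit scale (rather than exact
beta-binomial tail sums) was chosen because z-scores are the currency of
the downstream meta-analysis, with an exact beta-binomial tail fallback
available for small `N` (`exact_below`).

Numerical choices: the 1/2 pseudocount (Haldane–Anscombe) keeps `p_hat`
off the boundary and is symmetric under allele relabelling; `p0` uses the
same pseudocount via `(Dref + 1/2)/(D + 1)`.  Whether the DNA-proportion
uncertainty is propagated into the SE is a toggle
(`include_dna_variance`, default on); with seven pooled DNA replicates the
term is small, but switching it off reproduces the commonly used
"plug-in" variant.

## Overdispersion estimation

Two estimators are provided.

* `estimate_overdispersion` (per library): method of moments on the
  squared deviations from `N p0`,

      rho = [ sum (R - N p0)^2 - N p0 q0 - N^2 var0 ] /
            [ sum N (N - 1) p0 q0 ],

  clamped to [0, 0.49].  The `N^2 var0` subtraction removes the DNA-
  estimation error so it is not double-counted against the propagated
  term.  This marginal estimator charges genuinely imbalanced SNPs to the
  dispersion, so on signal-bearing data it is biased upward by roughly
  `pi_functional * E[beta^2] * p q` — a conservative direction for the
  test.  It is the default in `run_ase` (one rho per replicate, since each
  sequencing library has its own dispersion).

* `estimate_overdispersion_pooled` (across replicates): the true allelic
  effect is a property of the sequence and is shared by all replicates,
  while the overdispersion draw is independent per replicate.  Within-SNP
  deviations of per-replicate reference fractions from their across-
  replicate mean therefore identify rho free of signal contamination:

      E[ sum_j (y_ij - ybar_i)^2 ] =
          (1 - 1/k_i) pi_i q_i sum_j [ 1/N_ij + rho (N_ij - 1)/N_ij ].

  This estimator needs no DNA reference and is the recommended way to
  *measure* the dispersion parameter itself.

A trimmed variant of the marginal estimator (excluding outlying SNPs with
a chi-square truncation correction) was evaluated and rejected: the
correction assumes chi-square-distributed standardized deviations, and the
beta-binomial is platykurtic enough at realistic depths to bias the
corrected estimate, while moderate true effects evade any trim threshold.

## Meta-analysis, FDR, inflation

Replicates are combined by inverse-variance fixed effects
(`beta_meta = sum(w beta)/sum(w)`, `w = 1/se^2`); z-score sets are combined
by unweighted Stouffer (`Z = sum(z)/sqrt(k)`) — unweighted because the
replicates are balanced by design; a weighted option exists.  All tests are
two-sided (allelic direction is not pre-specified).  FDR control is
Benjamini–Hochberg (the standard referent where only an FDR level is
stated); Bonferroni is used where a small fixed family is tested (the
per-factor direction analysis).  Genomic inflation is
`lambda_GC = median(Qchisq(1 - p, 1)) / 0.4549`, the median chi-square(1)
being 0.4549 to four figures.

## Differential allele-specific binding

Allelic imbalance measured in the bound fraction alone confounds binding
effects with plasmid library imbalance.  Both fractions are therefore
tested against the same reference proportion (estimated from the pooled
bound + unbound counts) and contrasted:

    delta_beta = beta_bound - beta_unbound,
    se^2 = se_bound^2 + se_unbound^2.

Any shared imbalance cancels in the difference, which is what keeps the
null calibrated under an arbitrarily skewed library — the test's reason to
exist.  Replicates are Stouffer-combined within each factor concentration,
the concentration-level Zs are Stouffer-combined again for the overall
call (concentrations treated as exchangeable), BH is applied within each
level, and the per-concentration union is reported alongside the
combined-Z call since the two "total ASB" conventions differ.

## Region-level bound/unbound test

Constructs overrepresented in the bound library are called with a
deliberately simple negative-binomial Wald test: median-of-ratios size
factors; a method-of-moments dispersion per region pooled across ten
quantile bins of normalized mean (floored at 1e-8); normalized condition
means `q = (sum k + 1/2)/sum s` with

    Var(ln q) = 1/(q sum s) + alpha sum(s^2)/(sum s)^2;

`log2fc = (ln q_b - ln q_u)/ln 2` and a Wald z against zero.  A region is
called bound only at the joint gate `log2fc > 1 AND FDR < 1%` — the
fold-change threshold is a hard gate on the estimate, not a test against
1.  There is no dispersion shrinkage, no outlier refitting and no
independent filtering; the scientific content exercised is the joint gate,
not a particular production implementation's refinements, and results
will differ from such tools in the tails accordingly.

## Enrichment

Annotation enrichment is the two-sided Fisher exact test on a 2x2 table
over an explicit universe.  Odds ratios are the conditional maximum-
likelihood estimate with its exact 95% CI (the exact-test convention);
the sample cross-product ratio is reported alongside.  The universe
matters: the ASE x ASB overlap is computed over SNPs testable in *both*
assays, and restricting the universe changes the OR — which is why overlap
ORs quoted against different universes legitimately differ.

Motif-direction analysis: each SNP-oligo pair is labelled *match* when the
motif strand equals the strand transcribed by the reporter (strand `+`
with a forward oligo, or `-` with a reverse oligo):

    reporter --->  [motif + strand]   forward oligo  => match
    reporter --->  [motif - strand]   forward oligo  => opposite

Per factor, a 2x2 of configuration x ASE-significance is tested and
Bonferroni-corrected over the factors tested; factors with fewer than two
pairs in either configuration are skipped.

## The simulator

`SimConfig` defaults encode the assay's replicate structure: nine
biological RNA replicates, seven DNA library replicates, binding
triplicates at three factor concentrations; 100 expected molecules per SNP
per replicate with negative-binomial depth variation (size 10); a
symmetric Beta(20, 20) plasmid imbalance (reference-proportion SD ≈ 0.08);
20% of SNPs functional with effects `N(0, 0.5^2)` on the log-odds scale;
overdispersion rho = 0.02.  Oligo design constants (230 bp insert = 15 bp
adapter + 200 bp regulatory sequence with the SNP centered) are recorded
as design metadata; an optional FASTA writer emits placeholder sequence.

Choices worth knowing:

* **Overdispersion injection.** One Beta draw per (SNP, replicate),
  shared by the two oligo orientations — interpreted as transfection-
  sampling drift of the plasmid pool, which affects both constructs of a
  SNP jointly.  This makes pooled counts exactly beta-binomial at pooled
  depth and per-orientation counts exactly beta-binomial at their own
  depth, so calibration is exact under the matched model at every
  aggregation level.  When orientation-specific effects are enabled the
  draws are independent per orientation.
* **PCR duplication.** Each molecule receives a UMI uniform over
  `4^umi_length` (collisions allowed — they exercise the dedup contract)
  and is emitted `1 + Poisson(mu_dup * A)` times.  The amplification
  propensity `A ~ Lognormal(-sd^2/2, sd)` (default sd 0.3) is attached to
  the (SNP, allele) fragment and shared across replicates, reflecting that
  amplification efficiency is sequence-determined.  This matters: i.i.d.
  duplication would be absorbed by re-estimated overdispersion, whereas
  the replicate-correlated component survives meta-analysis and is what
  makes retained duplicates inflate the combined statistics — the
  behaviour the dedup step exists to remove.
* **Concentration scaling.** The effective binding effect is
  `gamma * scale_c` with default scales (0.7, 1.0, 1.1): the lowest
  concentration does not capture all binding, and occupancy (hence power)
  grows mildly at the highest, giving the low < mid <= high discovery
  ordering characteristic of such titrations.
* **Annotations.** The CentiSNP label is assigned at a configurable odds
  ratio (default 2.5) with functional status; negative controls are drawn
  only from SNPs with zero ASE and binding effects; footprint regions get
  a higher mean log2 bound/unbound occupancy (default 2 vs 0, SD 0.25).
  A Gaussian copula (`corr_functional`) couples ASE- and ASB-functional
  status for overlap studies.
* **Region totals** are simulated independently of the allele-level
  binding counts; the two never share a data path in the analysis either.

What the simulator does **not** emulate: sequence-level realism (motif
content, GC bias), read-level errors, reference-mapping bias, UMI
sequencing errors (hence exact-match collapse suffices by construction),
position-in-window covariates, and cell-state effects.  Passing tests
therefore demonstrate the statistical machinery is correct under its
stated model, not that real libraries satisfy that model.

## Problem sizes in the test suite

The bundled checks run at sizes chosen to make their statistical bands
tight while staying desk-scale: 10,000 SNPs for calibration/inflation
properties, 5,000 for ΔAST and effect recovery, 20,000 for enrichment
recovery, 20 simulated libraries of 300 SNPs for the region gate, and all
135,750 2x2 tables with total ≤ 40 for the Fisher enumeration check.

## Known limitations

* The normal approximation on the logit scale degrades below ~10
  molecules; the exact fallback covers this but is not the default.
* The marginal dispersion estimator is conservative on signal-dense data
  (documented above); the pooled estimator requires replicates.
* The region test's binned MOM dispersion is crude for very low counts;
  regions with all-zero counts are flagged untestable rather than tested.
* Exact-match UMI collapse does not merge sequencing-error UMI variants;
  on real reads it slightly overcounts molecules.
* The conditional-MLE odds ratio is reported as +/-inf on zero margins,
  with the corresponding one-sided CI bound.
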