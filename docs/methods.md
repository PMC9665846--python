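# Methods

`kinface` studies a question from primate behavioural ecology: in a
society where one alpha male sires most of a birth cohort, can mothers
exploit facial resemblance among infants — a cue of shared paternity —
to steer their offspring's social life towards paternal half-siblings,
and can such maternal behaviour be favoured by selection even though the
mother is unrelated to the infants she recruits? The package implements
the full analysis chain on synthetic data with known ground truth: a
demographic generator, the face-verification distance, the dyadic mixed
models, and a one-generation evolutionary model of "second-order kin
selection".

## Synthetic study system

The generator (`kinface.simulate`) produces a matrilineal population
observed over breeding seasons. Its defaults are the study conditions
and were fixed once, before any calibration experiments:

| parameter | default | meaning / rationale |
| --- | --- | --- |
| `p_alpha` | 0.65 | probability an infant is sired by the current alpha; the field estimate is that alphas monopolize 60–70 % of conceptions |
| `n_breeding_females`, `n_seasons` | 29, 10 | ~290 infants, the scale of the observed cohorts |
| `alpha_tenure_seasons` | 2 | alpha turnover, so cohorts split into same-alpha / different-alpha classes |
| `p_disputed` | 0.10 | fraction of conceptions under a disputed alpha position; these infants are excluded from the facial-distance model, as in the field protocol |
| `p_father_known` | 0.40 | genotyped-paternity fraction (32 of 80 infants in the field data) |
| `min/max_pictures` | 1–10 | portrait pictures per infant |
| `embedding_dim` | 128 | synthetic face-feature dimension (stands in for the 4,096-d network activations; distances only need the relative kin structure) |
| `w_pat`, `w_mat`, `w_ind`, `w_pic` | 1.0, 0.3, 1.0, 0.3 | loadings of paternal, maternal, individual and picture components on features; `w_pat > w_mat` encodes the empirical finding that paternal half-sibs look most alike |
| `age_drift` | 0.003 /day | shared drift direction with age, so picture pairs taken at similar ages are more similar (the age-difference effect) |
| `scans_per_individual`, `scan_shape` | 85, 2.5 | gamma-Poisson scan effort per individual; a dyad's offset is the sum of its members' efforts, reproducing the observed ~169 ± 77 scans per pair |
| `sigma_a`, `nb_shape` | 0.5, 2.5 | additive individual effect SD and negative-binomial shape of the count model (observed dispersions run 1.3–2.6) |
| `p_infant_initiates_*` | 0.976 / 0.894 | infant-initiated fraction of follow / approach bouts, with Poisson bout counts of mean 17.2 / 28.9 per dyad |

Mothers are daughters of founder grandmothers (two per matriline), sired
with the same paternity skew by founder males; this yields mother–mother
relatedness varying over 0–0.5 and matriline structure, as the
association models require. Pedigree relatedness is twice the kinship
coefficient from the standard recursive traversal, with founders
unrelated and non-inbred and missing parents treated as founders.

Per-picture features are `w_pat·g(father) + w_mat·g(mother) +
w_ind·ε_individual + age_drift·age·v + w_pic·ε_picture`, clipped
elementwise at zero and shifted by 10⁻³. The clip mimics the sparsity of
post-ReLU network activations while keeping χ² distances defined; the
shift avoids all-zero vectors.

What the generator does **not** emulate: image content and photographic
nuisance structure (pose, lighting, occlusion), uncertainty in birth
dates, demographic turnover (death, dispersal), rank dynamics (mothers
are simply assigned to three equal rank classes), and any dependence of
scan effort on the social structure itself. Passing tests therefore show
that the estimators recover the assumed generative structure at field
sample sizes — not that the field data satisfy that structure.

## Face verification distance

Features of each picture are L1-normalized to unit sum (the standard
companion to χ² histogram distances). For a picture pair, the
per-feature components are `(x_i − y_i)² / (x_i + y_i)` with `0/0 → 0`
(the limit of the formula). A linear max-margin classifier
(`LinearSVC`, primal, squared hinge, `C = 1`, standardized inputs) is
trained on balanced same-/different-individual pairs with the χ²
components as predictors; its coefficients, mapped back to the raw
component scale, sign-flipped so that larger components indicate
different individuals, and clipped at zero, become the feature weights
of a weighted χ² dissimilarity. Negative-weight clipping keeps the
distance a valid nonnegative dissimilarity; a k-fold accuracy
(`kfold_verification_accuracy`) is exposed alongside the held-in
training accuracy. Dyadic facial distance is the unweighted mean of the
weighted χ² distance over all cross picture pairs of two individuals,
with the matching mean absolute age difference.

## Dyadic mixed models

**Facial-distance LMM.** Dyads are not independent: two dyads sharing an
individual are correlated. The dyad random effect has the "diallel"
covariance `σ_u² (I + ρ A)`, where `A` indicates pairs of dyads sharing
exactly one individual and `ρ` is fitted; `ρ = 0.5` is exactly the case
of two additive individual effects (general combining ability), and
deviations capture pair-specific effects. Residuals are heteroscedastic
with prior weights equal to the number of picture pairs behind each
dyad mean (`σ_e²/w_d`). Because `A` is a line-graph adjacency, its
eigenvalues are the squared singular values of the dyad–individual
incidence matrix minus two (padded with −2 when dyads outnumber
individuals); the admissible `ρ` interval is computed per dataset from
that spectrum, and the optimizer works on an unconstrained transform of
it. The marginal likelihood uses the Woodbury identity on
`V = diag(d) + σ_u²ρ ZZ'`, so each evaluation costs O(n) assembly plus
an m×m determinant; β is profiled out by GLS and the three variance
parameters are maximized by Nelder-Mead. Both ML (used for LRTs) and
REML (reported) solutions are returned. With the random effect switched
off the fit reduces to the weighted-least-squares closed form, which is
the oracle-equivalence test.

**Residualization.** Facial distance is regressed on standardized mean
age distance under the same random structure, and the *marginal*
residuals `y − Xβ̂` are carried forward as the association-model
predictor. Conditional residuals (subtracting the dyad BLUPs) would
absorb the dyad-level resemblance signal itself into the random effect
and leave the predictor empty of meaning; marginal residuals remove only
the age artefact.

**Association GLMMs.** Scan counts are negative binomial with log link,
variance `μ + μ²/shape`, and an offset (log total scans of the dyad)
with fixed coefficient 1. Random structure is either symmetric additive
individual effects over the union of both members (infant–infant,
mother–mother; the multi-membership "general combining ability" form) or
two crossed individual effects with separate variances (mother–infant).
Fitting maximizes the Laplace-approximated marginal likelihood: an inner
Newton solve finds the joint (β, a) penalized mode, and an outer
Nelder-Mead (with one restart to guard against premature simplex
collapse) maximizes the Laplace objective over log variance(s) and log
shape. Profiling β at the joint mode rather than re-maximizing the
Laplace objective in β is numerically indistinguishable here (checked
against full optimization; LRT statistics agree to 0.01) and was
validated externally: on the same data, the crossed-effects fit matches
`glmmTMB` in log-likelihood (−838.13 vs −838.11), slopes, standard
errors, variances and shape. Wald standard errors come from the Schur
complement of the joint information (the standard conditional GLMM SEs);
per-term Wald χ² and LRT χ² are both reported, since published per-term
statistics may be either.

**Likelihood-ratio tests** compare nested ML fits on identical data with
the same random structure; χ² is `2Δll` clipped at zero with df the
fixed-effect difference. Null calibration holds at the study's model
scale (~80 random-effect levels, ~400 dyads: null mean χ² 1.01,
rejection 3–5 % at α = 0.05). At substantially smaller sizes (e.g. 40
levels, 200 dyads) the mixed-model LRT is visibly anti-conservative —
a finite-sample property of the statistic, not of this implementation —
so the calibration suite runs at study scale. No multiple-testing
correction is applied anywhere.

**Eligibility filters** mirror the field protocol: ≥ 5 scans per dyad
for association models, ≥ 30 minutes joint observation for grooming,
same birth cohort, infants ≤ 1 year.

## Second-order kin selection

Paired infants play an iterated prisoner's dilemma (payoffs T > R > P >
S, iteration probability w) under tit-for-tat, so a pair either
cooperates every round or, after any defection, defects forever. The
closed-form expected payoffs are `R/(1−w)` and `P/(1−w)` for identical
pairs and `S + wP/(1−w)`, `T + wP/(1−w)` for mixed pairs. Writing the
focal payoff as `β0 + β_z z + β_zp z_p + β_zzp z z_p` over the four
(z, z_p) combinations gives `β_zzp = W11 + W00 − W10 − W01` — twice the
difference between the unweighted mean payoffs of identical and
non-identical dyads — and `(1−w) β_zzp → R − P` as w → 1: long
interactions reward pairing identically-behaved partners in proportion
to R − P.

The simulator runs one generation: mothers carry an assortment allele
(haploid, maternally transmitted, female-limited expression) raising by
δ the probability that their infant is paired with an available paternal
half-sib; every infant is paired exactly once (random visiting order,
residents pair at random); infants inherit one cooperation allele from
each parent and initiate cooperation with probability `(Cm + Cf)/2`
(genic map; a dominant map is available); survival is `clip(s0 + s1·W,
0, 1)` with defaults keeping clipping rare, and an optional fixed cost
of choosing is available (default 0). Under paternity skew, forced
half-sib pairings raise `E[Cf·Cf_p]` — identity disequilibrium — for
mutant-mothers' infants, while the maternal and cross products stay at
zero absent maternal relatedness and assortative mating. The reported
analytic prediction is `q(1−q)·s1·β_zzp·ΔE(z z_p)/W̄` with `ΔE(z z_p)`
mapped from the measured allele products (¼ of their sum under the genic
map); under the haploid bookkeeping the realized Δq is compared against
it in sign and proportionality, with Monte-Carlo standard errors over
replicates throughout.

For the response-proportionality experiment the game grid holds
`S + T = 2P` (e.g. P = 1, S = −3, T = 5) so that `β_zzp = (R−P)/(1−w)`
exactly; the selection response is then proportional to R − P with no
additive offset, which is what the through-origin regression checks.

## Numerical choices and limitations

* All randomness flows from a single integer seed through named,
  independent generator streams (one per operation/stage), so disabling
  one stage never perturbs another's draws; re-running a stage from its
  cached inputs is byte-identical.
* NB counts are drawn as gamma-Poisson mixtures (exact and stable at
  extreme shapes, covering the Poisson limit `shape → ∞`).
* Inner Newton solves use step halving and converge on the penalized
  objective to 1e−9; outer optimizers are derivative-free with modest
  tolerances because warm starts make objectives very slightly
  history-dependent.
* Degenerate inputs fail loudly: all-zero feature vectors, single-class
  verification sets, zero-variance predictors, single-level categorical
  predictors, non-integer counts, non-nested LRT pairs, unknown pedigree
  ids. Perfect collinearity in the VIF is reported as infinity, not an
  error. If a categorical reference level is absent from a (small)
  fitted table, the most frequent level is substituted with a warning.
* Problem sizes in the test suite (e.g. 200 coverage replicates at 500
  dyads, 500 LRT null replicates at 400 dyads, 100 end-to-end replicates
  at 580/282/325 dyads, 200 simulator replicates of 10⁴ mothers per
  grid point) are the package's chosen desk-scale study designs and run
  on a single CPU.
* The ground-truth facial-distance coefficient of the association models
  defaults to −0.5 SD for the mother–infant and infant–infant models and
  0 for the mother–mother models. The field analyses fix only the signs
  of these truths; the magnitude was chosen a priori so that the
  significant/significant/non-significant pattern is the design
  condition at the study's dyad counts, rather than a coin flip of
  marginal power.
* Known limitations: the verification classifier on clean synthetic
  embeddings is often perfectly separable (accuracy 1.0), unlike real
  images; the diallel LMM assumes a single shared ρ; the evolutionary
  model tracks one generation only and measures (rather than models)
  linkage disequilibria; the pairing process is the simplest one that
  realizes ΔE(Cf·Cf_p) > 0. The generator also draws infant–infant and
  mother–infant counts independently given their shared covariates, so
  the pipeline's infant-infant vs mean mother-infant association
  correlation reflects covariate sharing only (r ≈ 0.3 at the defaults)
  rather than the mechanical coupling through the mother's position that
  field data exhibit; `association_correlation` is the measurement tool,
  not a calibrated target.
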