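# kinface

Tools for studying **facial-resemblance-guided kin assortment** in
primate societies with high paternity skew, together with the
evolutionary theory that explains it. The package is aimed at
behavioural ecologists and quantitative geneticists who want to test,
on data with known ground truth, the full analysis chain behind the
claim that mothers bring their infants close to infants that look like
their own — who are disproportionately paternal half-siblings — and
that such maternal behaviour can be selected for.

It provides four pieces, each usable on its own:

* **`kinface.simulate`** — a synthetic study system: a matrilineal
  population in which the alpha male sires ~60–70 % of each season's
  conceptions, pedigree relatedness (twice the recursive kinship
  coefficient), nonnegative per-picture face embeddings in which
  paternal half-sibs resemble each other most, dyadic scan counts from
  a negative-binomial log-link model with offset and additive individual
  effects, and mother–infant follow/approach bouts with strong
  infant-initiated directionality.
* **`kinface.faces`** — the face-verification distance: L1
  normalization, per-feature χ² components
  `(x_i−y_i)²/(x_i+y_i)`, feature weights learned by a linear
  max-margin classifier on same-/different-individual picture pairs, the
  weighted χ² distance, and per-dyad averaging over all cross picture
  pairs.
* **`kinface.dyadic`** — dyadic mixed models: a Gaussian LMM for facial
  distance with the "diallel" dyad random effect (covariance
  `σ_u²(I + ρA)`, where `A` links dyads sharing one individual and
  `ρ = 0.5` is the additive general-combining-ability case) and
  heteroscedastic picture-pair weights; residualization of distance on
  age difference; negative-binomial GLMMs with log link, offset and
  symmetric-additive or crossed individual random effects, fitted by
  Laplace approximation; likelihood-ratio tests; VIF; association and
  directionality summaries.
* **`kinface.theory`** — second-order kin selection: iterated
  prisoner's dilemma payoffs under tit-for-tat
  (`R/(1−w)`, `P/(1−w)`, `S+wP/(1−w)`, `T+wP/(1−w)`), the payoff
  regression `W = β0 + β_z z + β_zp z_p + β_zzp z z_p` (so
  `β_zzp = W11+W00−W10−W01`, with `(1−w)β_zzp → R−P` for long games),
  identity disequilibrium `ΔE(Cf·Cf_p)`, and a one-generation
  Monte-Carlo simulator of selection on a maternal assortment allele,
  reported with its analytic prediction.

A thin CLI (`kinface simulate | distances | fit | theory | run-all |
report`) orchestrates the stages into a run directory with seeds,
configs and CSV outputs sufficient for bit-reproduction.

## Worked example

```python
import numpy as np
import kinface as kf

cfg = kf.SimConfig(seed=1, embedding_dim=64)
pop = kf.simulate_population(cfg)
inf = pop.infants[0]
print("infants:", len(pop.infants))
print("mother-offspring relatedness:",
      kf.pedigree_relatedness(pop, inf.id, inf.mother_id))

emb = kf.simulate_embeddings(pop, cfg)
rng = np.random.default_rng(1)
same, diff = kf.sample_verification_pairs(emb, 2000, rng)
model = kf.learn_verification_weights(same, diff)
print(f"verification accuracy: {model.training_accuracy:.3f}")

dist = kf.dyad_facial_distances(emb, model)
meta = {i.id: i for i in pop.infants}
pat = [r.mean_distance for r in dist.itertuples()
       if meta[r.id_a].father_id == meta[r.id_b].father_id]
non = [r.mean_distance for r in dist.itertuples()
       if meta[r.id_a].father_id != meta[r.id_b].father_id
       and meta[r.id_a].mother_id != meta[r.id_b].mother_id]
print(f"mean distance, paternal half-sibs: {np.mean(pat):.2f}; "
      f"non-kin: {np.mean(non):.2f}")

from kinface.theory import (EvoConfig, PdGame, beta_decomposition,
                            iterated_payoffs,
                            simulate_second_order_selection)
game = PdGame(R=3, S=0, T=5, P=1, w=0.9)
tab = iterated_payoffs(game)
print("iterated payoffs:", (tab.W11, tab.W00, tab.W10, tab.W01))
print("beta_zzp:", beta_decomposition(tab).beta_zzp)
res = simulate_second_order_selection(
    EvoConfig(n_mothers=10_000, replicates=100, delta=0.9, seed=1), game)
print(f"delta q = {res.delta_freq:.2e} +- {res.delta_freq_se:.1e}  "
      f"(analytic {res.analytic_prediction:.2e})")
print(f"identity disequilibrium = {res.identity_disequilibrium:.4f} "
      f"+- {res.identity_disequilibrium_se:.4f}")
```

prints

```
infants: 290
mother-offspring relatedness: 0.5
verification accuracy: 1.000
mean distance, paternal half-sibs: 4.33; non-kin: 6.33
iterated payoffs: (30.000000000000007, 10.000000000000002, 9.000000000000002, 14.000000000000002)
beta_zzp: 17.000000000000007
delta q = 1.08e-03 +- 5.4e-04  (analytic 1.61e-03)
identity disequilibrium = 0.0307 +- 0.0017
```

Reading the numbers: the generator produced a 290-infant cohort with
the configured paternity skew; infants sharing a father sit clearly
closer in the weighted χ² face space (4.33) than non-kin (6.33), which
is the cue the maternal behaviour could exploit. In the canonical
iterated game the interaction coefficient `β_zzp = 17` quantifies the
payoff advantage of identically-behaved pairs; with mothers steering
infants towards paternal half-sibs (δ = 0.9) the assortment allele gains
frequency (Δq ≈ 1.1 × 10⁻³ per generation, same sign and order as the
analytic prediction) because forced half-sib pairings build positive
identity disequilibrium between the paired infants' paternal
cooperation alleles.

A full pipeline run, writing population, distances, the Table-style
model summaries and the theory outputs into `runs/demo`:

```sh
kinface run-all --out runs/demo --seed 7
kinface report --out runs/demo
```

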