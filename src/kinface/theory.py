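"""Second-order kin selection: iterated prisoner's dilemma payoffs,
payoff regression algebra, and a one-generation evolutionary simulator.

Mothers carry an "assortment" allele that raises, by ``delta``, the
probability that their infant is paired with one of its paternal
half-sibs. Paired infants play an iterated prisoner's dilemma under
tit-for-tat (any defection triggers mutual defection forever), payoffs
affect infant survival, and the mother's fitness is the survival of her
offspring. Because paternity is skewed towards the alpha male, forcing
half-sib pairings raises the expected product of paternally inherited
cooperation alleles across pair members ("identity disequilibrium"), and
selection on the maternal assortment allele is proportional to the
interaction payoff coefficient — itself proportional to R - P — times
that disequilibrium. The simulator measures the realized one-generation
allele-frequency change and reports it next to the analytic prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "PdGame",
    "PayoffTable",
    "BetaDecomposition",
    "EvoConfig",
    "SelectionResult",
    "iterated_payoffs",
    "average_payoffs",
    "beta_decomposition",
    "selection_differential",
    "identity_disequilibrium",
    "cov_selection",
    "simulate_second_order_selection",
]


@dataclass(frozen=True)
class PdGame:
    """Prisoner's dilemma payoffs (R rewards, S sucker, T temptation,
    P punishment) with iteration probability w.

    The canonical ordering ``T > R > P > S`` and mutual benefit
    ``2R > T + S`` are enforced unless ``validate=False`` (degenerate
    games such as R = P are occasionally useful to isolate the R - P
    dependence of selection).
    """

    R: float
    S: float
    T: float
    P: float
    w: float
    validate: bool = True

    def __post_init__(self):
        if not 0.0 <= self.w < 1.0:
            raise ValueError(f"iteration probability w must be in [0, 1), got {self.w}")
        if self.validate:
            if not (self.T > self.R > self.P > self.S):
                raise ValueError("payoffs must satisfy T > R > P > S")
            if not (2 * self.R > self.T + self.S):
                raise ValueError("cooperation must be mutually beneficial: 2R > T + S")


@dataclass(frozen=True)
class PayoffTable:
    """Expected iterated payoffs of the focal infant by (z, zp), where z
    indicates that the focal initiates cooperation and zp the same for
    its partner: W11 = R/(1-w), W00 = P/(1-w), W10 = S + wP/(1-w),
    W01 = T + wP/(1-w)."""

    W11: float
    W00: float
    W10: float
    W01: float

    def payoff(self, z: int, zp: int) -> float:
        return {(1, 1): self.W11, (0, 0): self.W00,
                (1, 0): self.W10, (0, 1): self.W01}[(z, zp)]


@dataclass(frozen=True)
class BetaDecomposition:
    """Coefficients of W = beta0 + beta_z z + beta_zp zp + beta_zzp z zp,
    reconstructing the payoff table exactly over (z, zp) in {0,1}^2."""

    beta0: float
    beta_z: float
    beta_zp: float
    beta_zzp: float

    def payoff(self, z: int, zp: int) -> float:
        return (self.beta0 + self.beta_z * z + self.beta_zp * zp
                + self.beta_zzp * z * zp)


def iterated_payoffs(game: PdGame) -> PayoffTable:
    """Closed-form expected payoffs of the iterated game under
    tit-for-tat: cooperator pairs earn R every round, defector pairs P,
    and a mixed pair defects mutually after the first round, so the
    one-shot S (or T) is followed by the P continuation wP/(1-w)."""
    if game.w >= 1.0:
        raise ValueError("iteration probability w must be < 1")
    cont = game.w * game.P / (1.0 - game.w)
    return PayoffTable(
        W11=game.R / (1.0 - game.w),
        W00=game.P / (1.0 - game.w),
        W10=game.S + cont,
        W01=game.T + cont,
    )


def average_payoffs(game: PdGame, p_coop: float = 0.5) -> tuple[float, float]:
    """Average payoffs of identical and non-identical dyads.

    At ``p_coop = 0.5`` these are ``(R+P)/(2(1-w))`` and
    ``((1-w)(S+T) + 2Pw)/(2(1-w))``; for general cooperator frequency the
    identical-dyad average weights R and P by the relative frequencies of
    cooperator-cooperator and defector-defector pairs. The non-identical
    average is the per-capita mean of the two mixed-pair payoffs.
    """
    if not 0.0 <= p_coop <= 1.0:
        raise ValueError("p_coop must be in [0, 1]")
    t = iterated_payoffs(game)
    wcc = p_coop**2
    wdd = (1.0 - p_coop) ** 2
    tot = wcc + wdd
    if tot == 0:
        identical = 0.5 * (t.W11 + t.W00)
    else:
        identical = (wcc * t.W11 + wdd * t.W00) / tot
    nonidentical = 0.5 * (t.W10 + t.W01)
    return identical, nonidentical


def beta_decomposition(payoffs: PayoffTable) -> BetaDecomposition:
    """Solve the four-equation system for the payoff regression: beta0 =
    W00, beta_z = W10 - W00, beta_zp = W01 - W00, beta_zzp =
    W11 + W00 - W10 - W01 (twice the identical-vs-non-identical mean
    payoff difference)."""
    return BetaDecomposition(
        beta0=payoffs.W00,
        beta_z=payoffs.W10 - payoffs.W00,
        beta_zp=payoffs.W01 - payoffs.W00,
        beta_zzp=payoffs.W11 + payoffs.W00 - payoffs.W10 - payoffs.W01,
    )


def selection_differential(
    betas: BetaDecomposition, dE_z: float, dE_zp: float, dE_zzp: float
) -> float:
    """Mutant-vs-resident expected payoff difference
    ``beta_z dE(z) + beta_zp dE(zp) + beta_zzp dE(z zp)``; the total
    mutant fitness effect is proportional to delta times this."""
    for v in (dE_z, dE_zp, dE_zzp):
        if not np.isfinite(v):
            raise ValueError("expectation differences must be finite")
    return betas.beta_z * dE_z + betas.beta_zp * dE_zp + betas.beta_zzp * dE_zzp


def cov_selection(zf_values, fitness_values) -> float:
    """Sample covariance between the maternal allele indicator and
    maternal fitness (the one-generation selection measure)."""
    z = np.asarray(zf_values, dtype=float)
    w = np.asarray(fitness_values, dtype=float)
    if z.shape != w.shape:
        raise ValueError("zf and fitness must have equal length")
    if z.size < 2:
        raise ValueError("need at least two paired observations")
    return float(np.cov(z, w, ddof=1)[0, 1])


def identity_disequilibrium(
    partner: np.ndarray,
    Cm: np.ndarray,
    Cf: np.ndarray,
    mother_mutant: np.ndarray,
) -> dict[str, float]:
    """Mutant-minus-resident differences of allele-product expectations.

    ``partner[i]`` is the index of infant i's pair partner; ``Cm``/``Cf``
    the maternally/paternally inherited cooperation-allele indicators;
    ``mother_mutant`` flags infants whose mother carries the assortment
    allele. Returns ``dE_CfCfp`` (the identity disequilibrium the
    maternal behaviour creates) together with the three cross products,
    which stay near zero without maternal relatedness or assortative
    mating.
    """
    pr = np.asarray(partner, int)
    ok = pr >= 0  # unpaired infants (odd leftover) are ignored
    mut = np.asarray(mother_mutant, bool) & ok
    res = ~np.asarray(mother_mutant, bool) & ok
    if not mut.any() or not res.any():
        raise ValueError("need both mutant- and resident-mother infants")
    out = {}
    for name, a, b in (
        ("dE_CfCfp", Cf, Cf),
        ("dE_CmCmp", Cm, Cm),
        ("dE_CmCfp", Cm, Cf),
        ("dE_CfCmp", Cf, Cm),
    ):
        prod = a * np.where(ok, b[pr], 0)
        out[name] = float(prod[mut].mean() - prod[res].mean())
    return out


@dataclass
class EvoConfig:
    """One-generation life-cycle parameters.

    ``delta`` raises a mutant mother's probability (over ``base_assort``)
    of pairing her infant with an available paternal half-sib; ``s0`` and
    ``s1`` map the infant's iterated payoff to survival
    ``clip(s0 + s1 W, 0, 1)``; ``cost`` is an optional fixed survival
    cost of the choice process paid by mutant mothers' offspring. The
    assortment locus is treated as a maternally transmitted haploid
    marker (expression is female-limited), so the reported frequency
    change is among mothers' surviving offspring.
    """

    n_mothers: int = 10_000
    n_males: int = 20
    p_alpha: float = 0.65
    q_assort: float = 0.5
    p_coop: float = 0.5
    delta: float = 0.9
    base_assort: float = 0.0
    s0: float = 0.1
    s1: float = 0.02
    cost: float = 0.0
    replicates: int = 200
    batch_size: int = 20
    genotype_map: str = "genic"  # or "dominant"
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_alpha", "q_assort", "p_coop", "base_assort"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        if self.delta < 0:
            raise ValueError("delta must be nonnegative")
        if self.n_mothers < 2 or self.n_males < 2 or self.replicates < 1:
            raise ValueError("population sizes and replicates must be >= 2 / >= 1")
        if self.genotype_map not in ("genic", "dominant"):
            raise ValueError("genotype_map must be 'genic' or 'dominant'")


@dataclass
class SelectionResult:
    delta_freq: float
    delta_freq_se: float
    cov_zf_W: float
    cov_zf_W_se: float
    identity_disequilibrium: float
    identity_disequilibrium_se: float
    cross_products: dict[str, float]
    cross_products_se: dict[str, float]
    analytic_prediction: float
    replicates: int
    per_replicate: pd.DataFrame
    batch_sign_agreement: float
    clipped_survival_fraction: float


def _pair_infants(
    rng: np.random.Generator,
    father: np.ndarray,
    mutant: np.ndarray,
    p_assort_mut: float,
    p_assort_res: float,
) -> np.ndarray:
    """Pair every infant exactly once. Infants are visited in random
    order; an unpaired infant whose mother seeks assortment (with the
    class-specific probability) takes a random still-unpaired paternal
    half-sib if one exists, otherwise a random unpaired infant."""
    n = len(father)
    partner = np.full(n, -1, dtype=int)
    order = rng.permutation(n)
    # per-father pools with lazy deletion
    pools: dict[int, list[int]] = {}
    for i in order:
        pools.setdefault(int(father[i]), []).append(int(i))
    free_stack = list(order[::-1])
    u_assort = rng.random(n)
    for i in order:
        if partner[i] >= 0:
            continue
        p_assort = p_assort_mut if mutant[i] else p_assort_res
        j = -1
        if u_assort[i] < p_assort:
            pool = pools.get(int(father[i]))
            if pool:
                # reservoir of available half-sibs; pop random candidates
                while pool:
                    k = pool.pop(rng.integers(len(pool)) if len(pool) > 1 else 0)
                    if partner[k] < 0 and k != i:
                        j = k
                        break
        if j < 0:
            while free_stack:
                k = free_stack.pop()
                if partner[k] < 0 and k != i:
                    j = k
                    break
        if j < 0:
            break  # odd leftover infant stays unpaired
        partner[i] = j
        partner[j] = i
    return partner


def simulate_second_order_selection(
    evo_config: EvoConfig,
    game: PdGame,
    rng: Optional[np.random.Generator] = None,
) -> SelectionResult:
    """Monte-Carlo one-generation selection on the maternal assortment
    allele, with the analytic prediction computed alongside.

    Life cycle per replicate: mothers (mutant with frequency
    ``q_assort``) conceive under alpha paternity skew; each infant
    inherits one cooperation allele from each parent; mutant mothers
    preferentially pair their infant with a paternal half-sib; pairs play
    the iterated game (an infant initiates cooperation with probability
    ``(Cm+Cf)/2`` under the genic map, or 1 if it carries any cooperation
    allele under the dominant map); survival is an affine, clipped
    function of payoff. Reported: the realized frequency change of the
    assortment allele among surviving offspring, ``cov(z_f, W)`` across
    mothers, the identity disequilibrium, and the analytic prediction
    ``q(1-q) s1 beta_zzp dE(z zp) / Wbar`` with ``dE(z zp)`` mapped from
    the measured ``dE(Cf Cfp)``, all with Monte-Carlo standard errors.
    """
    evo_config.validate()
    cfg = evo_config
    rng = np.random.default_rng([cfg.seed, 97]) if rng is None else rng
    betas = beta_decomposition(iterated_payoffs(game))
    tab = iterated_payoffs(game)
    N = cfg.n_mothers
    rows = []
    clipped = 0
    total_draws = 0
    p_mut = min(1.0, cfg.base_assort + cfg.delta)
    for _rep in range(cfg.replicates):
        zf = (rng.random(N) < cfg.q_assort).astype(int)
        if zf.sum() in (0, N):
            rows.append(dict(delta_freq=0.0, cov_zf_W=0.0, dE_CfCfp=0.0,
                             dE_CmCmp=0.0, dE_CmCfp=0.0, dE_CfCmp=0.0,
                             pred=0.0))
            continue
        father = np.where(
            rng.random(N) < cfg.p_alpha, 0, 1 + rng.integers(cfg.n_males - 1, size=N)
        )
        # diploid cooperation locus in parents; one allele drops to the infant
        Cm = (rng.random(N) < cfg.p_coop).astype(int)
        father_alleles = (rng.random((cfg.n_males, 2)) < cfg.p_coop).astype(int)
        which = rng.integers(2, size=N)
        Cf = father_alleles[father, which]
        mutant = zf.astype(bool)
        partner = _pair_infants(rng, father, mutant, p_mut, cfg.base_assort)
        paired = partner >= 0
        if cfg.genotype_map == "genic":
            pz = (Cm + Cf) / 2.0
            z = (rng.random(N) < pz).astype(int)
        else:
            z = ((Cm + Cf) >= 1).astype(int)
        zp = np.where(paired, z[partner], 0)
        W = np.where(
            z & zp, tab.W11,
            np.where(~z.astype(bool) & ~zp.astype(bool), tab.W00,
                     np.where(z.astype(bool), tab.W10, tab.W01)),
        )
        s_raw = cfg.s0 + cfg.s1 * W - cfg.cost * mutant
        s = np.clip(s_raw, 0.0, 1.0)
        clipped += int(np.sum((s_raw < 0) | (s_raw > 1)))
        total_draws += N
        surv = (rng.random(N) < s).astype(int)
        surv = np.where(paired, surv, 0)
        if surv.sum() == 0:
            dq = 0.0
        else:
            dq = float(zf[surv == 1].mean() - zf.mean())
        cov = float(np.cov(zf, surv.astype(float), ddof=1)[0, 1])
        if paired.sum() > 3 and 0 < mutant[paired].sum() < paired.sum():
            ids = identity_disequilibrium(partner, Cm, Cf, mutant)
        else:
            ids = {"dE_CfCfp": 0.0, "dE_CmCmp": 0.0,
                   "dE_CmCfp": 0.0, "dE_CfCmp": 0.0}
        wbar = float(surv.mean()) or 1.0
        if cfg.genotype_map == "genic":
            dE_zzp = 0.25 * sum(ids.values())
        else:
            dE_zzp = ids["dE_CfCfp"]  # dominant map: same sign, no exact scale
        q = float(zf.mean())
        pred = q * (1 - q) * cfg.s1 * betas.beta_zzp * dE_zzp / wbar
        rows.append(dict(delta_freq=dq, cov_zf_W=cov, pred=pred, **ids))
    rep = pd.DataFrame(rows)
    R = len(rep)

    def mse(col):
        return float(rep[col].std(ddof=1) / np.sqrt(R)) if R > 1 else np.nan

    # sign agreement between batch-mean delta_freq and the analytic prediction
    nb = max(1, R // cfg.batch_size)
    batches = np.array_split(rep["delta_freq"].to_numpy(), nb)
    pred_mean = float(rep["pred"].mean())
    if pred_mean == 0.0:
        agree = float(np.mean([abs(np.mean(b)) <= 3 * (np.std(b) / np.sqrt(len(b)) + 1e-12)
                               for b in batches]))
    else:
        agree = float(np.mean([np.sign(np.mean(b)) == np.sign(pred_mean)
                               for b in batches]))
    frac_clip = clipped / max(total_draws, 1)
    if frac_clip > 0.01:
        import logging
        logging.getLogger(__name__).warning(
            "survival mapping clipped %.1f%% of draws", 100 * frac_clip
        )
    return SelectionResult(
        delta_freq=float(rep["delta_freq"].mean()),
        delta_freq_se=mse("delta_freq"),
        cov_zf_W=float(rep["cov_zf_W"].mean()),
        cov_zf_W_se=mse("cov_zf_W"),
        identity_disequilibrium=float(rep["dE_CfCfp"].mean()),
        identity_disequilibrium_se=mse("dE_CfCfp"),
        cross_products={k: float(rep[k].mean())
                        for k in ("dE_CmCmp", "dE_CmCfp", "dE_CfCmp")},
        cross_products_se={k: mse(k)
                           for k in ("dE_CmCmp", "dE_CmCfp", "dE_CfCmp")},
        analytic_prediction=pred_mean,
        replicates=R,
        per_replicate=rep,
        batch_sign_agreement=agree,
        clipped_survival_fraction=float(frac_clip),
    )
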