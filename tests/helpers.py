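"""Independent oracles used by the test suite.

These deliberately avoid the package's own computational paths: gene
dropping for pedigree relatedness, brute-force summation for the
weighted chi-square distance, normal equations for weighted least
squares, and a hand-rolled IRLS Poisson fitter.
"""

from __future__ import annotations

import numpy as np

from kinface.simulate import Population


def gene_drop_relatedness(
    population: Population,
    id1: str,
    id2: str,
    n_drops: int = 100_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Monte-Carlo relatedness (2 x kinship) by gene dropping.

    Founders get unique allele pairs; every drop transmits one random
    allele per parent down the pedigree. The kinship estimate is the
    probability that one random allele from each individual is identical
    by descent; returns (estimate, standard error) on the relatedness
    scale.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    counter = 0

    def fresh_pair():
        nonlocal counter
        counter += 2
        return counter - 2, counter - 1

    # insertion order has parents before offspring
    alleles: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for ind in population.individuals.values():
        gametes = []
        for parent in (ind.mother_id, ind.father_id):
            if parent is None:
                a, b = fresh_pair()
                pa = np.full(n_drops, a)
                pb = np.full(n_drops, b)
            else:
                pa, pb = alleles[parent]
            pick = rng.integers(2, size=n_drops).astype(bool)
            gametes.append(np.where(pick, pa, pb))
        alleles[ind.id] = (gametes[0], gametes[1])

    a1, b1 = alleles[id1]
    a2, b2 = alleles[id2]
    ibd = 0.25 * (
        (a1 == a2).astype(float) + (a1 == b2) + (b1 == a2) + (b1 == b2)
    )
    r = 2.0 * ibd
    return float(r.mean()), float(r.std(ddof=1) / np.sqrt(n_drops))


def brute_force_weighted_chi2(x, y, w) -> float:
    total = 0.0
    for xi, yi, wi in zip(x, y, w):
        if xi + yi > 0:
            total += wi * (xi - yi) ** 2 / (xi + yi)
    return total


def wls_normal_equations(y, X, w):
    """Closed-form weighted least squares via the normal equations."""
    XtW = X.T * w
    return np.linalg.solve(XtW @ X, XtW @ y)


def irls_poisson(y, X, offset, n_iter=50, tol=1e-12):
    """Hand-rolled iteratively reweighted least squares for a log-link
    Poisson regression (the score equations X'(y - mu) = 0)."""
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        eta = offset + X @ beta
        mu = np.exp(eta)
        W = mu
        z = eta - offset + (y - mu) / mu
        XtW = X.T * W
        new = np.linalg.solve(XtW @ X, XtW @ z)
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    return beta


def random_pedigree(rng: np.random.Generator, n_founders=10, n_offspring=20):
    """Random multi-generation pedigree of <= 30 individuals."""
    from kinface.simulate import Individual

    inds = []
    for k in range(n_founders):
        inds.append(
            Individual(
                id=f"P{k}", sex="F" if k % 2 == 0 else "M", birth_day=0
            )
        )
    for k in range(n_offspring):
        day = (k + 1) * 10
        females = [i for i in inds if i.sex == "F" and i.birth_day < day]
        males = [i for i in inds if i.sex == "M" and i.birth_day < day]
        inds.append(
            Individual(
                id=f"O{k}",
                sex="F" if rng.random() < 0.5 else "M",
                birth_day=day,
                mother_id=females[rng.integers(len(females))].id,
                father_id=males[rng.integers(len(males))].id,
            )
        )
    return Population(inds)
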