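"""End-to-end orchestration: simulate -> distances -> models -> theory.

Each stage writes plain CSV/JSON into the run directory and reads its
inputs back from there, so any single stage can be re-run from the
cached outputs of the previous ones and reproduces its results exactly.
A single global seed fans out into independent per-stage generator
streams, so disabling one stage does not perturb another's draws.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .dyadic import (
    ModelSpec,
    association_correlation,
    build_design,
    directionality_summary,
    filter_dyads,
    fit_association_glmm,
    fit_facial_distance_lmm,
    lrt,
    residual_facial_distance,
    vif,
)
from .faces import (
    EmbeddingSet,
    dyad_facial_distances,
    learn_verification_weights,
    sample_verification_pairs,
)
from .simulate import (
    DISPUTED,
    Population,
    SimConfig,
    simulate_embeddings,
    simulate_follow_approach,
    simulate_population,
    simulate_scans,
)
from .theory import EvoConfig, PdGame, simulate_second_order_selection

logger = logging.getLogger(__name__)

STAGES = ("simulate", "distances", "fit", "theory")

# stream tags for per-stage generators
_STAGE_STREAM = {"distances": 211, "fit": 223, "theory": 227, "grooming": 229}

# Ground-truth coefficients (SD scale for continuous terms) of the three
# association models and the grooming model. Signs follow the fitted
# association analyses (closer kin and similar-looking infants associate
# more: negative facial-distance and rank/age-difference effects); the
# facial-distance effect is null for the mother-mother models.
DEFAULT_BETA_TRUTH: dict[str, dict[str, float]] = {
    "mother_infant": {
        "intercept": -2.2, "facial_std": -0.5, "matriline_same": 0.7,
        "relatedness_std": 0.27, "rank_std": -0.37, "age_std": -0.23,
        "sex_FF": -0.20, "sex_FM": -0.18,
    },
    "infant_infant": {
        "intercept": -2.2, "facial_std": -0.5, "matriline_same": 0.61,
        "relatedness_std": 0.32, "rank_std": -0.28, "age_std": -0.27,
        "sex_FF": -0.21, "sex_FM": -0.11,
    },
    "mother_mother": {
        "intercept": -2.2, "facial_std": 0.0, "matriline_same": 0.44,
        "relatedness_std": 0.31, "rank_std": -0.44, "age_std": -0.20,
        "sex_FF": -0.72, "sex_FM": -0.50,
    },
    "grooming": {
        "intercept": -5.0, "facial_std": 0.0, "matriline_same": 0.44,
        "relatedness_std": 0.31, "rank_std": -0.44, "age_std": -0.20,
        "sex_FF": -0.72, "sex_FM": -0.50,
    },
}

ASSOCIATION_SPEC = ModelSpec(
    response="count",
    continuous=("facial_distance_residual", "mother_relatedness",
                "rank_difference", "age_difference"),
    categorical={"same_matriline": "different", "sex_class": "MM"},
    offset="total_scans",
)


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "kinface_run"
    sim: SimConfig = field(default_factory=SimConfig)
    evo: EvoConfig = field(default_factory=EvoConfig)
    game: Mapping[str, float] = field(
        default_factory=lambda: {"R": 3.0, "S": 0.0, "T": 5.0, "P": 1.0, "w": 0.9}
    )
    stages: Sequence[str] = STAGES
    models: Sequence[str] = (
        "facial_lmm", "mother_infant", "infant_infant", "mother_mother", "grooming"
    )
    beta_truth: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_BETA_TRUTH.items()}
    )
    n_verification_pairs: int = 2000

    def __post_init__(self):
        self.sim.seed = self.seed
        self.evo.seed = self.seed
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "out_dir": str(self.out_dir),
            "sim": self.sim.to_dict(),
            "evo": dataclasses.asdict(self.evo),
            "game": dict(self.game),
            "stages": list(self.stages),
            "models": list(self.models),
            "beta_truth": {k: dict(v) for k, v in self.beta_truth.items()},
            "n_verification_pairs": self.n_verification_pairs,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = SimConfig.from_dict(d["sim"])
        if "evo" in d:
            d["evo"] = EvoConfig(**dict(d["evo"]))
        return cls(**d)


class StageError(RuntimeError):
    def __init__(self, stage: str, log_path: Path, cause: Exception):
        super().__init__(
            f"stage {stage!r} failed ({cause}); see {log_path}"
        )
        self.stage = stage
        self.log_path = log_path


def _stage_rng(cfg: RunConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), _STAGE_STREAM[stage]])


# ---------------------------------------------------------------------------
# dyad-table construction
# ---------------------------------------------------------------------------

def infant_metadata(population: Population) -> pd.DataFrame:
    rows = []
    for inf in population.infants:
        mother = population[inf.mother_id]
        rows.append(
            {
                "id": inf.id, "sex": inf.sex, "birth_day": inf.birth_day,
                "season": inf.season, "mother_id": inf.mother_id,
                "father_id": inf.father_id, "father_known": inf.father_known,
                "alpha": inf.alpha_id_at_conception,
                "matriline_id": inf.matriline_id,
                "mother_rank": mother.rank_class,
            }
        )
    return pd.DataFrame(rows).set_index("id")


def _sex_class(s1: str, s2: str) -> str:
    return "".join(sorted((s1, s2)))


def _paternity_class(a, b) -> str:
    if a.father_known and b.father_known:
        return "same_father" if a.father_id == b.father_id else "different_father"
    return "same_alpha" if a.alpha == b.alpha else "different_alpha"


def make_facial_lmm_table(
    population: Population, distances: pd.DataFrame
) -> pd.DataFrame:
    """All-infant dyad table for the facial-distance LMM: paternity
    class, same mother, sex class, mean age distance, with picture-pair
    counts as prior weights. Dyads involving an infant conceived under a
    disputed alpha position are excluded."""
    meta = infant_metadata(population)
    rows = []
    for r in distances.itertuples():
        a, b = meta.loc[r.id_a], meta.loc[r.id_b]
        if a.alpha == DISPUTED or b.alpha == DISPUTED:
            continue
        rows.append(
            {
                "id_a": r.id_a, "id_b": r.id_b,
                "mean_distance": r.mean_distance,
                "n_picture_pairs": r.n_picture_pairs,
                "mean_age_distance": r.mean_age_distance,
                "paternity_class": _paternity_class(a, b),
                "same_mother": "same" if a.mother_id == b.mother_id else "different",
                "sex_class": _sex_class(a.sex, b.sex),
            }
        )
    return pd.DataFrame(rows)


def make_association_tables(
    population: Population, residuals: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Dyad covariate tables for the three association models.

    Infant-infant dyads pair infants of the same birth cohort; each one
    yields two mother-infant dyads (each mother with the other's infant,
    mother stored in ``id_a``); mother-mother dyads pair co-mothers of a
    cohort (first co-occurrence kept). All carry the infant dyad's
    facial-distance residual, matriline/relatedness/rank covariates of
    the mothers, and the infants' age difference and sex class.
    """
    meta = infant_metadata(population)
    resid = residuals.set_index(["id_a", "id_b"])["facial_distance_residual"]
    ii_rows, mi_rows = [], []
    mm_seen: dict[tuple[str, str], dict] = {}
    infants = meta.sort_index()
    for season, grp in infants.groupby("season"):
        ids = list(grp.index)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                ia, ib = sorted((ids[i], ids[j]))
                a, b = meta.loc[ia], meta.loc[ib]
                if a.mother_id == b.mother_id:
                    continue
                key = (ia, ib)
                if key not in resid.index:
                    continue
                cov = {
                    "facial_distance_residual": float(resid.loc[key]),
                    "same_matriline": (
                        "same" if a.matriline_id == b.matriline_id else "different"
                    ),
                    "mother_relatedness": population.relatedness(
                        a.mother_id, b.mother_id
                    ),
                    "rank_difference": abs(a.mother_rank - b.mother_rank),
                    "age_difference": abs(a.birth_day - b.birth_day),
                    "sex_class": _sex_class(a.sex, b.sex),
                }
                ii_rows.append({"id_a": ia, "id_b": ib, **cov})
                mi_rows.append({"id_a": a.mother_id, "id_b": ib, **cov})
                mi_rows.append({"id_a": b.mother_id, "id_b": ia, **cov})
                mkey = tuple(sorted((a.mother_id, b.mother_id)))
                if mkey not in mm_seen:
                    mm_seen[mkey] = {"id_a": mkey[0], "id_b": mkey[1], **cov}
    return {
        "infant_infant": pd.DataFrame(ii_rows),
        "mother_infant": pd.DataFrame(mi_rows),
        "mother_mother": pd.DataFrame(list(mm_seen.values())),
    }


def add_standardized_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Append the z-scored / dummy-coded columns the ground-truth count
    model uses (``facial_std``, ``relatedness_std``, ``rank_std``,
    ``age_std``, ``matriline_same``, ``sex_FF``, ``sex_FM``)."""
    out = table.copy()

    def _z(col):
        v = out[col].to_numpy(float)
        s = v.std()
        return (v - v.mean()) / s if s > 0 else np.zeros_like(v)

    out["facial_std"] = _z("facial_distance_residual")
    out["relatedness_std"] = _z("mother_relatedness")
    out["rank_std"] = _z("rank_difference")
    out["age_std"] = _z("age_difference")
    out["matriline_same"] = (out["same_matriline"] == "same").astype(float)
    out["sex_FF"] = (out["sex_class"] == "FF").astype(float)
    out["sex_FM"] = (out["sex_class"] == "FM").astype(float)
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, out: Path) -> None:
    population = simulate_population(cfg.sim)
    population.to_csv(out / "population.csv")
    emb = simulate_embeddings(population, cfg.sim)
    emb.to_csv(out / "embeddings.csv")
    events = simulate_follow_approach(population, cfg.sim)
    events.to_csv(out / "events.csv", index=False)
    directionality_summary(events).to_csv(out / "directionality.csv", index=False)


def stage_distances(cfg: RunConfig, out: Path) -> None:
    emb = EmbeddingSet.read_csv(out / "embeddings.csv")
    rng = _stage_rng(cfg, "distances")
    same, diff = sample_verification_pairs(emb, cfg.n_verification_pairs, rng)
    model = learn_verification_weights(same, diff)
    model.to_csv(out / "verification_weights.csv")
    with open(out / "verification.json", "w") as fh:
        json.dump({"training_accuracy": model.training_accuracy}, fh, indent=1)
    dist = dyad_facial_distances(emb, model)
    dist.to_csv(out / "dyad_distances.csv", index=False)
    resid = residual_facial_distance(dist)
    resid.to_csv(out / "dyad_distance_residuals.csv", index=False)


def stage_fit(cfg: RunConfig, out: Path) -> dict:
    population = Population.read_csv(out / "population.csv")
    distances = pd.read_csv(out / "dyad_distances.csv")
    residuals = pd.read_csv(out / "dyad_distance_residuals.csv")
    rng = _stage_rng(cfg, "fit")
    converged = True
    results: dict[str, object] = {}

    if "facial_lmm" in cfg.models:
        ftab = make_facial_lmm_table(population, distances)
        spec = ModelSpec(
            response="mean_distance",
            continuous=("mean_age_distance",),
            categorical={
                "paternity_class": "different_alpha",
                "same_mother": "different",
                "sex_class": "MM",
            },
            weights="n_picture_pairs",
        )
        fit = fit_facial_distance_lmm(ftab, build_design(ftab, spec))
        converged &= fit.converged
        summ = fit.summary()
        summ.to_csv(out / "fit_facial_lmm.csv", index=False)
        results["facial_lmm"] = fit
        with open(out / "fit_facial_lmm_varcomp.json", "w") as fh:
            json.dump(
                {"sigma_u2": fit.sigma_u2, "rho": fit.rho,
                 "sigma_e2": fit.sigma_e2, "loglik_ml": fit.loglik,
                 "loglik_reml": fit.loglik_reml, "n": fit.n,
                 "converged": fit.converged},
                fh, indent=1,
            )

    tables = make_association_tables(population, residuals)
    for name in ("mother_infant", "infant_infant", "mother_mother"):
        if name not in cfg.models:
            continue
        tab = add_standardized_columns(tables[name])
        tab = simulate_scans(
            population, tab, cfg.sim, beta_truth=cfg.beta_truth[name], rng=rng
        )
        tab = filter_dyads(tab, min_total_scans=5)
        tab.to_csv(out / f"dyads_{name}.csv", index=False)
        design = build_design(tab, ASSOCIATION_SPEC)
        fit = fit_association_glmm(
            tab, design,
            random_spec="crossed" if name == "mother_infant" else "gca",
        )
        converged &= fit.converged
        summ = fit.summary()
        summ.to_csv(out / f"fit_{name}.csv", index=False)
        results[name] = fit
        cont_cols = [n for n in design.names
                     if n in ASSOCIATION_SPEC.continuous]
        with open(out / f"fit_{name}_varcomp.json", "w") as fh:
            json.dump(
                {"sigma_a2": list(fit.sigma_a2), "nb_shape": fit.nb_shape,
                 "loglik": fit.loglik, "n": fit.n, "converged": fit.converged,
                 "vif": {k: v for k, v in vif(design).items() if k in cont_cols}},
                fh, indent=1,
            )

    if "infant_infant" in cfg.models and "mother_infant" in cfg.models:
        # how much of infant-infant association is carried by the
        # corresponding mother-infant associations
        mother_of = {i.id: i.mother_id for i in population.infants}
        ii = pd.read_csv(out / "dyads_infant_infant.csv")
        mi = pd.read_csv(out / "dyads_mother_infant.csv")
        try:
            r, r2 = association_correlation(ii, mi, mother_of)
            with open(out / "association_correlation.json", "w") as fh:
                json.dump({"pearson_r": r, "variance_explained": r2}, fh,
                          indent=1)
        except ValueError as exc:
            logger.warning("association correlation skipped: %s", exc)

    if "grooming" in cfg.models:
        rng_g = _stage_rng(cfg, "grooming")
        tab = add_standardized_columns(tables["mother_mother"])
        # grooming exposure: observation minutes instead of scans
        minutes = np.maximum(
            rng_g.gamma(2.0, 540.0 / 2.0, size=len(tab)), 1.0
        ).round(1)
        tab["total_scans"] = minutes
        tab = simulate_scans(
            population, tab, cfg.sim, beta_truth=cfg.beta_truth["grooming"],
            rng=rng_g,
        )
        tab = filter_dyads(tab, min_offset=30.0)
        tab.to_csv(out / "dyads_grooming.csv", index=False)
        design = build_design(tab, ASSOCIATION_SPEC)
        full = fit_association_glmm(tab, design, random_spec="gca")
        reduced_spec = ModelSpec(
            response="count",
            continuous=("mother_relatedness", "rank_difference", "age_difference"),
            categorical={"same_matriline": "different", "sex_class": "MM"},
            offset="total_scans",
        )
        reduced = fit_association_glmm(
            tab, build_design(tab, reduced_spec), random_spec="gca"
        )
        test = lrt(full, reduced)
        converged &= full.converged and reduced.converged
        full.summary().to_csv(out / "fit_grooming.csv", index=False)
        with open(out / "fit_grooming_lrt.json", "w") as fh:
            json.dump(
                {"term": "facial_distance_residual", "chi2": test.chi2,
                 "df": test.df, "p": test.p_value}, fh, indent=1,
            )
        results["grooming"] = full
    results["converged"] = converged
    with open(out / "fit_status.json", "w") as fh:
        json.dump({"converged": converged}, fh, indent=1)
    return results


def stage_theory(cfg: RunConfig, out: Path) -> None:
    game = PdGame(**dict(cfg.game))
    res = simulate_second_order_selection(
        cfg.evo, game, rng=_stage_rng(cfg, "theory")
    )
    res.per_replicate.to_csv(out / "theory_replicates.csv", index=False)
    with open(out / "theory_summary.json", "w") as fh:
        json.dump(
            {
                "delta_freq": res.delta_freq,
                "delta_freq_se": res.delta_freq_se,
                "cov_zf_W": res.cov_zf_W,
                "cov_zf_W_se": res.cov_zf_W_se,
                "identity_disequilibrium": res.identity_disequilibrium,
                "identity_disequilibrium_se": res.identity_disequilibrium_se,
                "cross_products": res.cross_products,
                "cross_products_se": res.cross_products_se,
                "analytic_prediction": res.analytic_prediction,
                "replicates": res.replicates,
                "batch_sign_agreement": res.batch_sign_agreement,
            },
            fh, indent=1,
        )


_STAGE_FN = {
    "simulate": stage_simulate,
    "distances": stage_distances,
    "fit": stage_fit,
    "theory": stage_theory,
}

_STAGE_OUTPUTS = {
    "simulate": ("population.csv", "embeddings.csv", "events.csv"),
    "distances": ("dyad_distances.csv", "dyad_distance_residuals.csv"),
    "fit": ("fit_status.json",),
    "theory": ("theory_summary.json",),
}


def run_pipeline(
    run_config: RunConfig,
    stages: Optional[Sequence[str]] = None,
    force: bool = True,
) -> Path:
    """Execute the pipeline stages in order into the run directory.

    With ``force=False`` a stage whose outputs already exist is skipped
    (resume semantics). Any stage failure raises :class:`StageError`
    naming the stage and its log. Returns the run directory; the file
    ``fit_status.json`` records whether all fits converged.
    """
    out = Path(run_config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.json", "w") as fh:
        json.dump(run_config.to_dict(), fh, indent=1, sort_keys=True)
    with open(out / "metadata.json", "w") as fh:
        import scipy
        import sklearn

        json.dump(
            {
                "seed": run_config.seed,
                "kinface": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "scipy": scipy.__version__,
                "sklearn": sklearn.__version__,
            },
            fh, indent=1, sort_keys=True,
        )
    todo = [s for s in STAGES
            if s in run_config.stages and (stages is None or s in stages)]
    log_path = out / "pipeline.log"
    for stage in todo:
        if not force and all((out / f).exists() for f in _STAGE_OUTPUTS[stage]):
            logger.info("stage %s: outputs exist, skipped", stage)
            continue
        logger.info("stage %s: running", stage)
        try:
            _STAGE_FN[stage](run_config, out)
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
            with open(log_path, "a") as fh:
                fh.write(f"stage {stage} failed: {exc!r}\n")
            raise StageError(stage, log_path, exc) from exc
    return out


def report(out_dir) -> str:
    """Plain-text report of the fitted models in the published table
    layout (chi2 | p | Estimate | Standard error)."""
    out = Path(out_dir)
    lines = []
    for name in ("facial_lmm", "mother_infant", "infant_infant",
                 "mother_mother", "grooming"):
        path = out / f"fit_{name}.csv"
        if not path.exists():
            continue
        df = pd.read_csv(path)
        lines.append(f"== {name}")
        header = f"{'predictor':<38}{'chi2':>9}{'p':>9}{'Estimate':>10}{'Standard error':>16}"
        lines.append(header)
        for r in df.itertuples():
            lines.append(
                f"{r.predictor:<38}{r.wald_chi2:>9.2f}{r.p:>9.3g}"
                f"{r.estimate:>10.3f}{r.se:>16.3f}"
            )
        lines.append("")
    theory = out / "theory_summary.json"
    if theory.exists():
        with open(theory) as fh:
            t = json.load(fh)
        lines.append("== second-order selection")
        lines.append(
            f"delta_freq = {t['delta_freq']:.3g} +- {t['delta_freq_se']:.2g}"
            f" (analytic prediction {t['analytic_prediction']:.3g})"
        )
        lines.append(
            f"identity disequilibrium dE(CfCfp) = "
            f"{t['identity_disequilibrium']:.4f} +- "
            f"{t['identity_disequilibrium_se']:.2g}"
        )
        lines.append("")
    text = "\n".join(lines)
    with open(out / "report.txt", "w") as fh:
        fh.write(text)
    return text
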