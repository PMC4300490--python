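"""End-to-end orchestration with one config, derived seeds, and a manifest.

``run_pipeline`` chains: synthetic data generation -> preprocessing ->
effect classification -> specificity -> profile clustering -> peptide
filtering and network construction (incl. MIDAS export and the model
ensemble) -> logic-ODE fitting -> AIC comparison. Every stochastic stage
derives its seed deterministically from the global seed and the stage name,
and every output file is listed in a manifest with a content hash, so a
rerun with the same config reproduces the run bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .core import StimulationDesign
from .effects import classify_effects, hier_cluster
from .network import (
    ModelingFilterConfig,
    ap_merge,
    build_pepnet,
    cv_filter,
    enumerate_ensemble,
    load_ensemble_scheme,
    load_prior_network,
    missingness_filter,
)
from .ode import (
    OptimizerConfig,
    compare_models,
    fit,
    hill_normalize,
    select_training_conditions,
    to_logic_ode,
)
from .preprocess import average_replicates, impute_spline, tic_normalize
from .specificity import default_epsilon, specificity_matrix, specificity_vector
from .synthetic import NoiseModel, add_noise, effect_panel, generate_truth, modeling_panel

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

log = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (zlib.crc32(f"{global_seed}:{stage}".encode()) + global_seed) % (2**31 - 1)


@dataclass
class PipelineConfig:
    out_dir: str = "costim_run"
    seed: int = 0
    # synthetic data
    n_effect_ppeps: int = 60
    noise_cv: float = 0.05
    noise_tic_spread: float = 0.05
    noise_missing_rate: float = 0.0
    # classification
    k_nacl: int = 6
    k_phe: int = 8
    score_threshold: float = 0.7
    score_mode: str = "per_curve"
    kmeans_restarts: int = 50
    hier_k: int = 7
    hier_p: float = 2.0
    # specificity
    spec_window: int = 4
    spec_r_min: float = 0.8
    # modeling
    filter_config: ModelingFilterConfig = field(default_factory=ModelingFilterConfig)
    hill_coefficient: float = 4.0
    fit_models: tuple[str, ...] = ("both_mechanisms",)
    fit_restarts: int = 1
    fit_eval_budget: int = 300
    aic_formula: str = "n_ln_mse"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "filter_config" in raw:
            raw["filter_config"] = ModelingFilterConfig(**raw["filter_config"])
        if "fit_models" in raw:
            raw["fit_models"] = tuple(raw["fit_models"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fit_models"] = list(self.fit_models)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the run directory containing the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = StimulationDesign()
    outputs: list[Path] = []

    def save(name: str, writer) -> Path:
        path = out / name
        writer(path)
        outputs.append(path)
        return path

    # --- simulate ---------------------------------------------------------
    stage = "simulate"
    log.info("stage %s", stage)
    panel = effect_panel(config.n_effect_ppeps, seed=stage_seed(config.seed, stage))
    truth = generate_truth(design, panel)
    effects_ds = add_noise(
        truth,
        NoiseModel(
            cv_multiplicative=config.noise_cv,
            tic_spread=config.noise_tic_spread,
            missing_rate=config.noise_missing_rate,
            seed=stage_seed(config.seed, stage + ".noise"),
        ),
    )
    save("effects_data.csv", lambda p: cio.write_long_csv(effects_ds, p))
    labels = pd.DataFrame(
        [(pp, lab["NaCl"].value, lab["Phe"].value) for pp, lab in truth.labels.items()],
        columns=["ppep_id", "planted_nacl", "planted_phe"],
    )
    save("planted_labels.csv", lambda p: labels.to_csv(p, index=False))
    modeling_ds, modeling_info = modeling_panel(seed=stage_seed(config.seed, stage + ".modeling"))
    save("modeling_data.csv", lambda p: cio.write_long_csv(modeling_ds, p))

    # --- preprocess -------------------------------------------------------
    log.info("stage preprocess")
    surface = impute_spline(average_replicates(tic_normalize(effects_ds)))
    wide = pd.DataFrame(
        {pp: surface.grid(pp).ravel() for pp in surface.ppeps},
        index=[f"t{tn}_p{tp}" for tn, tp in design.conditions],
    ).T
    save("surface_wide.csv", lambda p: wide.to_csv(p, index_label="ppep_id"))

    # --- classify ---------------------------------------------------------
    log.info("stage classify")
    calls = classify_effects(
        surface,
        k_nacl=config.k_nacl,
        k_phe=config.k_phe,
        score_threshold=config.score_threshold,
        seed=stage_seed(config.seed, "classify"),
        restarts=config.kmeans_restarts,
        score_mode=config.score_mode,
    )
    calls_out = calls.copy()
    calls_out["call"] = calls_out["call"].map(lambda c: c.value)
    save("effect_calls.csv", lambda p: calls_out.to_csv(p, index=False))

    # --- specificity ------------------------------------------------------
    log.info("stage specificity")
    eps = default_epsilon(surface)
    vec_rows = {}
    for modulating in ("NaCl", "Phe"):
        for pp in surface.ppeps:
            vec = specificity_vector(specificity_matrix(surface, pp, modulating, eps))
            vec_rows[(pp, modulating)] = vec
    vectors = pd.DataFrame(vec_rows).T
    vectors.index.names = ["ppep_id", "modulating_stimulus"]
    save("specificity_vectors.csv", lambda p: vectors.to_csv(p))

    # --- cluster ----------------------------------------------------------
    log.info("stage cluster")
    clusters = hier_cluster(surface, p=config.hier_p, k=config.hier_k)
    save("profile_clusters.csv", lambda p: clusters.to_csv(p, header=True))

    # --- build (filters, network, ensemble, MIDAS) ------------------------
    log.info("stage build")
    modeling_norm = tic_normalize(modeling_ds)
    cv_ok = cv_filter(modeling_norm, config.filter_config.cv_threshold,
                      config.filter_config.cv_aggregation)
    modeling_surface = average_replicates(modeling_norm)
    training = select_training_conditions(design)
    miss_ok = missingness_filter(modeling_surface, training,
                                 config.filter_config.max_missing_fraction)
    survivors = sorted(cv_ok & miss_ok)
    trajs = {
        pp: np.array([modeling_surface.df.loc[(pp, *c), "mean"] for c in training])
        for pp in survivors
    }
    reps, cluster_map = ap_merge(
        trajs,
        modeling_info["protein_of"],
        modeling_info["known_function"],
        config.filter_config,
        seed=stage_seed(config.seed, "build"),
    )
    pd.Series(cluster_map, name="representative").rename_axis("ppep_id").pipe(
        lambda s: save("peptide_clusters.csv", lambda p: s.to_csv(p))
    )
    prior = load_prior_network()
    assignment: dict[str, list[str]] = {}
    for pp in reps:
        assignment.setdefault(modeling_info["protein_of"][pp], []).append(pp)
    base_model = build_pepnet(prior, assignment)
    save("base_model.sif", lambda p: cio.write_sif(base_model, p))
    ensemble = enumerate_ensemble(base_model, load_ensemble_scheme())
    summary = pd.DataFrame(
        [(name, m.n_nodes, m.n_interactions) for name, _spec, m in ensemble],
        columns=["model_id", "n_nodes", "n_interactions"],
    )
    save("ensemble_summary.csv", lambda p: summary.to_csv(p, index=False))

    # MIDAS export of the hill-normalized training data
    norm = {}
    for pp in reps:
        raw = np.array([modeling_surface.df.loc[(pp, *c), "mean"] for c in training])
        norm[pp] = hill_normalize(raw, n=config.hill_coefficient)
    cond_rows = pd.DataFrame(
        [
            {"TR:NaCl": int(tn > 0), "TR:Phe": int(tp > 0), "time": max(tn, tp)}
            for tn, tp in training
        ]
    )
    measurements = pd.DataFrame(norm)
    midas_path = save(
        "training_data_midas.csv", lambda p: cio.write_midas(cond_rows, measurements, p)
    )

    # --- fit + compare ----------------------------------------------------
    fits = {}
    models = {name: model for name, _spec, model in ensemble}
    common_nodes: list[str] | None = None
    for name in config.fit_models:
        if name not in models:
            raise ValueError(f"fit stage: unknown ensemble model {name!r}")
    if config.fit_models:
        measured_sets = [
            {n for n in measurements.columns if n in models[name].nodes}
            for name in config.fit_models
        ]
        common_nodes = sorted(set.intersection(*measured_sets))
    for name in config.fit_models:
        log.info("stage fit: %s", name)
        system = to_logic_ode(models[name])
        conds, meas = cio.read_midas(midas_path)
        basal = meas.iloc[
            ((conds["TR:NaCl"] == 0) & (conds["TR:Phe"] == 0) & (conds["time"] == 0)).idxmax()
        ]
        y0 = {n: float(v) for n, v in basal.items() if np.isfinite(v) and n in system.species}
        fits[name] = fit(
            system,
            conds,
            meas,
            OptimizerConfig(
                n_restarts=config.fit_restarts,
                eval_budget=config.fit_eval_budget,
                seed=stage_seed(config.seed, f"fit.{name}"),
            ),
            node_subset=[n for n in common_nodes if n in system.species],
            y0=y0,
            aic_formula=config.aic_formula,
        )
    if fits:
        rows = [
            dataclasses.asdict(res) | {"model_id": name}
            for name, res in fits.items()
        ]
        for row in rows:
            row["params"] = {
                "tau": row["params"]["tau"],
                "hill_n": {f"{s}|{sg}|{t}": v for (s, sg, t), v in row["params"]["hill_n"].items()},
                "hill_k": {f"{s}|{sg}|{t}": v for (s, sg, t), v in row["params"]["hill_k"].items()},
            }
        save(
            "fit_results.jsonl",
            lambda p: p.write_text("\n".join(json.dumps(r) for r in rows) + "\n"),
        )
        table = compare_models(fits, common_nodes)
        save("model_ranking.csv", lambda p: table.to_csv(p, index=False))

    # --- manifest ---------------------------------------------------------
    manifest = {
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "stage_seeds": {
            s: stage_seed(config.seed, s)
            for s in ("simulate", "simulate.noise", "simulate.modeling", "classify", "build")
        },
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
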