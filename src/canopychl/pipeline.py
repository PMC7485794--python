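"""End-to-end orchestration: synthetic scene -> calibrated, smoothed spectra
-> screening -> SPA band selection -> (optional) orthogonal-array tuning ->
PSO-ELM inversion -> validation metrics.

All randomness flows from one master seed through named substreams (data
generation, sensor noise, splitting, band refinement, swarm, tuning), so a
run is bit-reproducible and each stage is independently replayable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .calibration import calibrate_reflectance, crop_interval, drop_boundary_bands
from .chemistry import split_dataset, summarize_chl
from .exceptions import ConfigurationError, StageError
from .inversion import PsoConfig, elm_fit, elm_predict, pso_elm_fit
from .io import write_spectra_table
from .metrics import r2_score, rmse
from .preprocessing import SmoothingConfig, savgol_smooth
from .screening import screen_bands
from .spa import mlr_refine, spa_select
from .synthetic import SyntheticConfig, generate_dataset, simulate_dn_scene
from .tuning import DEFAULT_LEVELS, build_l25_design, marginal_analysis, run_orthogonal_experiment

__all__ = ["PipelineConfig", "EvaluationReport", "run_pipeline", "load_config", "save_config"]

logger = logging.getLogger("canopychl")

_SUBSTREAMS = {"data": 11, "sensor": 23, "split": 37, "refine": 53, "pso": 71,
               "tune": 89, "elm": 97}


def _substream(master_seed: int, name: str) -> int:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(_SUBSTREAMS[name],))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Every stage's settings plus the master seed and stage toggles.

    Defaults run the full workflow on synthetic data with the tuned swarm
    settings (pop=50, w 0.9->0.3, c1=1.65, c2=2.8, m=0.2, 100 iterations).
    """

    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    simulate_dn: bool = True
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    boundary_bands: int = 1
    crop_lo: float = 400.0
    crop_hi: float = 800.0
    frac_model: float = 0.84
    do_screening: bool = True
    spa_n_candidates: int = 10
    hidden_count: int = 20
    pso: PsoConfig = field(default_factory=PsoConfig)
    do_tuning: bool = False
    tuning_iterations: int = 20
    fit_baseline_elm: bool = True


@dataclass
class EvaluationReport:
    r2: float
    rmse: float
    n: int
    predictions: list[dict]
    refined_bands: list[float]
    spa_candidates: list[float]
    baseline_elm_r2: float | None = None
    baseline_elm_rmse: float | None = None
    training_r2: float | None = None
    screening_peaks: dict | None = None
    tuned_parameters: dict | None = None
    modeling_stats: dict | None = None
    validation_stats: dict | None = None


def _standardize(train: np.ndarray, *others):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return tuple((arr - mu) / sd for arr in (train, *others))


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> EvaluationReport:
    """Execute the full inversion workflow; optionally persist artifacts."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        save_config(cfg, out / "config.yaml")

    # --- synthetic scene -------------------------------------------------
    try:
        syn_cfg = dataclasses.replace(cfg.synthetic, seed=_substream(cfg.seed, "data"))
        ds = generate_dataset(syn_cfg)
    except ConfigurationError as exc:
        raise StageError("simulate", "bad-config", str(exc)) from exc
    spectra = ds.spectra
    logger.info("generated %d synthetic spectra on %d bands", spectra.n_samples, spectra.n_bands)

    # --- DN round trip through the sensor model + black-white correction --
    if cfg.simulate_dn:
        dn, cal = simulate_dn_scene(ds, seed=_substream(cfg.seed, "sensor"))
        spectra = calibrate_reflectance(dn, cal)
        logger.info("calibrated DN scene back to reflectance")

    # --- grid cleanup and smoothing --------------------------------------
    try:
        spectra = drop_boundary_bands(spectra, cfg.boundary_bands)
        spectra = crop_interval(spectra, cfg.crop_lo, cfg.crop_hi)
        spectra = savgol_smooth(spectra, cfg.smoothing)
    except ConfigurationError as exc:
        raise StageError("preprocess", "bad-config", str(exc)) from exc
    if out is not None:
        write_spectra_table(spectra, out / "spectra_preprocessed.csv")

    # --- screening (reporting only; SPA does the selection) ---------------
    screening_peaks = None
    if cfg.do_screening:
        result = screen_bands(spectra)
        screening_peaks = {m: result.peak_band(m) for m in ("pearson", "dcor", "mic")}
        logger.info("screening peaks: %s", screening_peaks)
        if out is not None:
            result.to_frame().to_csv(out / "screening.csv", index=False)

    # --- modeling / validation split --------------------------------------
    model_set, val_set = split_dataset(spectra, cfg.frac_model, seed=_substream(cfg.seed, "split"))
    logger.info("split: %d modeling / %d validation", model_set.n_samples, val_set.n_samples)

    # --- SPA band selection on the modeling set ---------------------------
    try:
        candidates = spa_select(model_set.values, cfg.spa_n_candidates)
        spa_result = mlr_refine(model_set, model_set.chl, candidates,
                                seed=_substream(cfg.seed, "refine"))
    except ConfigurationError as exc:
        raise StageError("select-bands", "spa-failed", str(exc)) from exc
    bands = spa_result.refined_indices
    logger.info("SPA candidates %s -> refined %s", spa_result.selected_wavelengths,
                spa_result.refined_subset)

    X_model = model_set.values[:, bands]
    X_val = val_set.values[:, bands]
    y_model, y_val = model_set.chl, val_set.chl
    X_model, X_val = _standardize(X_model, X_val)

    # --- optional orthogonal-array tuning of the swarm --------------------
    pso_cfg = dataclasses.replace(cfg.pso, seed=_substream(cfg.seed, "pso"))
    tuned = None
    if cfg.do_tuning:
        design = build_l25_design(DEFAULT_LEVELS)
        r2_runs = run_orthogonal_experiment(
            X_model, y_model, X_val, y_val, design,
            hidden_count=cfg.hidden_count, iterations=cfg.tuning_iterations,
            seed=_substream(cfg.seed, "tune"),
        )
        table = marginal_analysis(design, r2_runs)
        tuned = {f: table.best_values[f] for f in design.factors}
        pso_cfg = dataclasses.replace(
            pso_cfg, pop=int(tuned["pop"]), w_schedule=tuned["w"],
            c1=float(tuned["c1"]), c2=float(tuned["c2"]), m=float(tuned["m"]),
        )
        logger.info("tuned swarm parameters: %s", tuned)
        if out is not None:
            np.savetxt(out / "tuning_run_r2.csv", r2_runs, header="run_r2")
            np.savetxt(out / "tuning_marginal_W.csv", table.W, delimiter=",")

    # --- PSO-ELM inversion -------------------------------------------------
    model, trace = pso_elm_fit(X_model, y_model, X_val, y_val, cfg.hidden_count, pso_cfg)
    y_pred = elm_predict(model, X_val)
    report = EvaluationReport(
        r2=r2_score(y_val, y_pred),
        rmse=rmse(y_val, y_pred),
        n=val_set.n_samples,
        predictions=[
            {"sample_id": sid, "true": float(t), "predicted": float(p)}
            for sid, t, p in zip(val_set.sample_ids, y_val, y_pred)
        ],
        refined_bands=spa_result.refined_subset,
        spa_candidates=spa_result.selected_wavelengths,
        training_r2=r2_score(y_model, elm_predict(model, X_model)),
        screening_peaks=screening_peaks,
        tuned_parameters=tuned,
        modeling_stats=dataclasses.asdict(summarize_chl(y_model)),
        validation_stats=dataclasses.asdict(summarize_chl(y_val)),
    )

    # --- untuned-ELM baseline for comparison ------------------------------
    if cfg.fit_baseline_elm:
        baseline = elm_fit(X_model, y_model, cfg.hidden_count, seed=_substream(cfg.seed, "elm"))
        yb = elm_predict(baseline, X_val)
        report.baseline_elm_r2 = r2_score(y_val, yb)
        report.baseline_elm_rmse = rmse(y_val, yb)

    logger.info("validation R2=%.3f RMSE=%.3f mg/L", report.r2, report.rmse)
    if out is not None:
        (out / "report.json").write_text(json.dumps(dataclasses.asdict(report), indent=2))
    return report


# --- configuration round trip --------------------------------------------

def _cfg_to_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["synthetic"]["grid"] = {
        "start": float(cfg.synthetic.grid.centers[0] - cfg.synthetic.grid.step / 2),
        "end": float(cfg.synthetic.grid.centers[-1] + cfg.synthetic.grid.step / 2),
        "step": cfg.synthetic.grid.step,
    }
    return d


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_cfg_to_dict(cfg), sort_keys=False))


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from YAML; unknown keys are rejected."""
    from .calibration import make_grid

    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(raw)
    if "synthetic" in kwargs:
        syn = dict(kwargs["synthetic"])
        syn_known = {f.name for f in dataclasses.fields(SyntheticConfig)}
        syn_unknown = set(syn) - syn_known
        if syn_unknown:
            raise ConfigurationError(f"unknown synthetic config keys: {sorted(syn_unknown)}")
        if "grid" in syn:
            g = syn.pop("grid")
            syn["grid"] = make_grid(g["start"], g["end"], g["step"])
        for key in ("absorption_centers", "absorption_widths", "absorption_gains"):
            if key in syn:
                syn[key] = tuple(syn[key])
        kwargs["synthetic"] = SyntheticConfig(**syn)
    if "smoothing" in kwargs:
        kwargs["smoothing"] = SmoothingConfig(**kwargs["smoothing"])
    if "pso" in kwargs:
        pso = dict(kwargs["pso"])
        if isinstance(pso.get("w_schedule"), list):
            pso["w_schedule"] = tuple(pso["w_schedule"])
        if isinstance(pso.get("bounds"), list):
            pso["bounds"] = tuple(pso["bounds"])
        kwargs["pso"] = PsoConfig(**pso)
    return PipelineConfig(**kwargs)
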