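"""Metrics, model comparison and the end-to-end calibration pipeline.

The figures of merit are the ones used throughout quantitative
spectrophotometry: RMSEP on an external test set, per-sample recovery
(100 · predicted/nominal) with its mean and n−1 SD, RPD (the ratio of the
test-set reference SD to RMSEP) and R².  ``run_pipeline`` executes the whole
study on one configuration: simulate (or load) spectra for the packaged
43-sample design, fit every requested analyte × model combination on the
25 calibration samples with its own bands, preprocessing chain and optional
score compression, evaluate on the 12 test mixtures and check replicate
precision on the 6 stability runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from . import adapters, boost, design as design_mod, latent, preprocess, simulate


@dataclass
class MetricRecord:
    """Accuracy/precision summary for one analyte × model on one sample set."""

    rmsep: float
    recoveries: np.ndarray
    mean_recovery: float
    sd_recovery: float
    rpd: float
    r2: float

    def as_dict(self) -> dict:
        return {
            "rmsep": self.rmsep,
            "mean_recovery": self.mean_recovery,
            "sd_recovery": self.sd_recovery,
            "rpd": self.rpd,
            "r2": self.r2,
            "recoveries": self.recoveries.tolist(),
        }


def metrics(predicted, nominal) -> MetricRecord:
    """RMSEP, recovery statistics, RPD and R² for paired predictions.

    Recovery is 100·ŷ/y per sample, undefined if any nominal value is zero;
    SD uses the n−1 denominator; RPD = sd(nominal)/RMSEP, so
    RPD · RMSEP = sd(nominal) identically.
    """
    yhat = np.asarray(predicted, dtype=float).ravel()
    y = np.asarray(nominal, dtype=float).ravel()
    if yhat.size != y.size:
        raise ValueError("predicted and nominal lengths differ")
    if y.size < 2:
        raise ValueError("metrics need at least 2 samples")
    if np.any(y == 0):
        raise ValueError("recovery undefined: nominal concentration of 0")
    resid = yhat - y
    rmsep = float(np.sqrt(np.mean(resid**2)))
    rec = 100.0 * yhat / y
    sd_y = float(np.std(y, ddof=1))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    rpd = sd_y / rmsep if rmsep > 0 else np.inf
    return MetricRecord(
        rmsep=rmsep,
        recoveries=rec,
        mean_recovery=float(rec.mean()),
        sd_recovery=float(np.std(rec, ddof=1)),
        rpd=float(rpd),
        r2=r2,
    )


def recovery_summary(recoveries: Sequence[float]) -> tuple[float, float]:
    """Mean and n−1 SD of a list of recovery percentages."""
    r = np.asarray(recoveries, dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 recoveries")
    return float(r.mean()), float(np.std(r, ddof=1))


def compare_models(reports: dict[str, MetricRecord]) -> pd.DataFrame:
    """Rank models for one analyte by RMSEP ascending, ties by recovery SD.

    ``reports`` maps model name → MetricRecord, all computed on the same
    evaluation samples (equal recovery counts are enforced).
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to compare")
    sizes = {rec.recoveries.size for rec in reports.values()}
    if len(sizes) != 1:
        raise ValueError("reports evaluate different sample sets")
    rows = [
        {"model": name, "rmsep": rec.rmsep, "sd_recovery": rec.sd_recovery,
         "mean_recovery": rec.mean_recovery, "rpd": rec.rpd, "r2": rec.r2}
        for name, rec in reports.items()
    ]
    df = pd.DataFrame(rows).sort_values(
        ["rmsep", "sd_recovery", "model"], kind="stable"
    ).reset_index(drop=True)
    df.index = df.index + 1
    df.index.name = "rank"
    return df


# ------------------------------ pipeline --------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """One analyte × model cell of the pipeline configuration."""

    model: str                      # PLS | XGB | SVR | ANN
    preprocessing: tuple[str, ...] = ("MC",)
    compression: tuple[str, int] | None = None  # (method, k)
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce one full calibration study.

    ``specs`` maps (analyte, model name) → ModelSpec.  ``distortion``
    configures the synthetic spectra; ``seed`` drives every random draw.
    """

    specs: dict
    distortion: simulate.DistortionConfig = simulate.DistortionConfig()
    components: tuple = simulate.DEFAULT_LIBRARY
    seed: int = 0
    osc_components: int = 1

    def hash(self) -> str:
        payload = {
            "specs": {f"{a}:{m}": asdict(s) for (a, m), s in sorted(self.specs.items())},
            "distortion": asdict(self.distortion),
            "components": [[c.name, list(map(list, c.bands))] for c in self.components],
            "seed": self.seed,
            "osc_components": self.osc_components,
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def preset_study_config(
    distortion: simulate.DistortionConfig | None = None,
    seed: int = 0,
    models: Sequence[str] = ("PLS", "ANN", "SVR", "XGB"),
    analytes: Sequence[str] = ("PIO", "ALG", "GLM"),
) -> PipelineConfig:
    """The shipped preset registry as a ready-to-run configuration."""
    registry = adapters.load_presets()
    specs = {}
    for model in models:
        for analyte in analytes:
            entry = registry[model][analyte]
            comp = entry["compression"]
            specs[(analyte, model)] = ModelSpec(
                model=model,
                preprocessing=tuple(entry["preprocessing"]),
                compression=None if comp is None else (comp["method"], int(comp["k"])),
                params=dict(entry["params"]),
            )
    if distortion is None:
        distortion = simulate.DistortionConfig(noise_sd=0.002, seed=seed)
    return PipelineConfig(specs=specs, distortion=distortion, seed=seed)


def _fit_model(spec: ModelSpec, X_train, y_train, seed: int):
    """Dispatch one model spec; returns (predict_fn over SpectraSet/array, model).

    Compression (if configured) is fitted on the training block and folded
    into the returned predictor, so callers hand it preprocessed spectra.
    """
    if spec.compression is not None:
        method, k = spec.compression
        sm = latent.compress(X_train, y=y_train, k=k, method=method)
        feats_train = sm.scores
        featurise = sm.project
    else:
        feats_train = latent._as_matrix(X_train)
        featurise = latent._as_matrix
    params = dict(spec.params)
    if spec.model == "PLS":
        model = latent.fit_with_cv(feats_train, y_train, **params)
        return (lambda X: latent.pls_predict(model, featurise(X))), model
    if spec.model == "XGB":
        cfg = boost.GBTConfig(**{**params, "seed": seed})
        model = boost.gbt_fit(feats_train, y_train, cfg)
        return (lambda X: boost.gbt_predict(model, featurise(X))), model
    if spec.model == "SVR":
        model = adapters.svr_fit(feats_train, y_train, adapters.SVRConfig(**params))
        return (lambda X: model.predict(featurise(X))), model
    if spec.model == "ANN":
        cfg = adapters.ANNConfig(**{**params, "seed": seed})
        # hold out every 5th calibration sample as the early-stop monitor
        mon = np.arange(feats_train.shape[0]) % 5 == 4
        model = adapters.ann_fit(
            feats_train[~mon], np.asarray(y_train)[~mon], cfg,
            monitor=(feats_train[mon], np.asarray(y_train)[mon]),
        )
        return (lambda X: model.predict(featurise(X))), model
    raise ValueError(f"unknown model {spec.model!r}")


def run_pipeline(cfg: PipelineConfig,
                 data: tuple | None = None) -> dict:
    """Execute the full study; returns a JSON-serialisable report bundle.

    Stages: simulate (or accept pre-loaded) spectra for the packaged design →
    split M/St/T → per analyte × model: band selection → preprocessing fitted
    on M only → optional compression → fit → predict T (and St) → metrics.
    Any stage failure is re-raised with the analyte/model it belongs to.
    """
    table = design_mod.load_table1_fixture()
    if data is None:
        spectra, conc = simulate.simulate_dataset(
            table, cfg.components, cfg.distortion
        )
    else:
        spectra, conc = data
    sets = table.sets
    ids_m = list(sets.index[sets == "M"])
    ids_t = list(sets.index[sets == "T"])
    ids_st = list(sets.index[sets == "St"])
    report: dict = {
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "results": {},
    }
    for (analyte, model_name), spec in sorted(cfg.specs.items()):
        try:
            bands = preprocess.ANALYTE_BANDS[analyte]
            banded = preprocess.select_bands(spectra, bands)
            train = banded.subset(ids_m)
            y_train = conc.loc[ids_m, analyte].to_numpy()
            states, train_pp = preprocess.fit_chain(
                train, spec.preprocessing, y=y_train,
                osc_components=cfg.osc_components,
            )
            test_pp = preprocess.apply_chain(states, banded.subset(ids_t))
            st_pp = preprocess.apply_chain(states, banded.subset(ids_st))
            predict, model = _fit_model(spec, train_pp, y_train, cfg.seed)
            pred_t = predict(test_pp)
            pred_st = predict(st_pp)
            y_t = conc.loc[ids_t, analyte].to_numpy()
            rec = metrics(pred_t, y_t)
            entry = rec.as_dict()
            entry["preprocessing"] = list(spec.preprocessing)
            entry["compression"] = (
                None if spec.compression is None else list(spec.compression)
            )
            entry["st_prediction_sd"] = float(np.std(pred_st, ddof=1))
            if spec.model == "PLS":
                entry["n_lv"] = int(model.n_lv)
                entry["rmsecv"] = float(model.rmsecv[model.n_lv - 1])
            report["results"][f"{analyte}:{model_name}"] = entry
        except Exception as exc:  # annotate the failing stage
            raise RuntimeError(f"pipeline failed at {analyte}:{model_name}") from exc
    return report


# ----------------------- model-ordering experiments ---------------------


def _pls_gbt_single(analyte: str, distortion: simulate.DistortionConfig,
                    registry: dict) -> tuple[float, float]:
    """Test-set RMSEP of the preset PLS and preset GBT for one replicate."""
    table = design_mod.load_table1_fixture()
    spectra, conc = simulate.simulate_dataset(table, cfg=distortion)
    sets = table.sets
    ids_m = list(sets.index[sets == "M"])
    ids_t = list(sets.index[sets == "T"])
    banded = preprocess.select_bands(spectra, preprocess.ANALYTE_BANDS[analyte])
    y_m = conc.loc[ids_m, analyte].to_numpy()
    y_t = conc.loc[ids_t, analyte].to_numpy()
    out = []
    for model_name in ("PLS", "XGB"):
        entry = registry[model_name][analyte]
        comp = entry["compression"]
        spec = ModelSpec(
            model=model_name,
            preprocessing=tuple(entry["preprocessing"]),
            compression=None if comp is None else (comp["method"], int(comp["k"])),
            params=dict(entry["params"]),
        )
        states, train_pp = preprocess.fit_chain(
            banded.subset(ids_m), spec.preprocessing, y=y_m
        )
        test_pp = preprocess.apply_chain(states, banded.subset(ids_t))
        predict, _ = _fit_model(spec, train_pp, y_m, distortion.seed)
        out.append(float(np.sqrt(np.mean((predict(test_pp) - y_t) ** 2))))
    return out[0], out[1]


def saturation_sweep(
    analyte: str = "ALG",
    saturation_grid: Sequence[float] = (0.0, 0.1, 0.3, 0.6, 1.0, 2.0),
    noise_sd: float = 0.002,
    seed: int = 0,
) -> pd.DataFrame:
    """Preset-PLS test RMSEP as saturation strength grows.

    Returns one row per saturation value; the headline statistic is the
    Spearman correlation between saturation_k and RMSEP (linear calibration
    degrades monotonically as the spectra leave the Beer-Lambert regime).
    """
    registry = adapters.load_presets()
    rows = []
    for k in saturation_grid:
        cfg = simulate.DistortionConfig(saturation_k=k, noise_sd=noise_sd, seed=seed)
        rm_pls, rm_gbt = _pls_gbt_single(analyte, cfg, registry)
        rows.append({"saturation_k": k, "pls_rmsep": rm_pls, "gbt_rmsep": rm_gbt})
    return pd.DataFrame(rows)


def pls_gbt_ordering(
    analyte: str = "GLM",
    n_replicates: int = 25,
    base_seed: int = 0,
    distortion_for_seed=simulate.severe_distortion,
) -> pd.DataFrame:
    """Replicated preset-PLS vs preset-GBT comparison on severe non-linear data.

    One row per seeded replicate with both test RMSEPs; the summary of
    interest is the fraction of replicates where the boosted trees beat PLS.
    """
    registry = adapters.load_presets()
    rows = []
    for r in range(n_replicates):
        cfg = distortion_for_seed(base_seed + r)
        rm_pls, rm_gbt = _pls_gbt_single(analyte, cfg, registry)
        rows.append({"seed": base_seed + r, "pls_rmsep": rm_pls,
                     "gbt_rmsep": rm_gbt, "gbt_wins": rm_gbt < rm_pls})
    return pd.DataFrame(rows)


def _round_sig(x, sig=6):
    if isinstance(x, float):
        return float(f"{x:.{sig}g}")
    if isinstance(x, dict):
        return {k: _round_sig(v, sig) for k, v in x.items()}
    if isinstance(x, list):
        return [_round_sig(v, sig) for v in x]
    return x


def report_to_json(report: dict) -> str:
    """Byte-stable serialisation: sorted keys, floats at 6 significant digits."""
    return json.dumps(_round_sig(report), sort_keys=True, indent=1)


def report_to_frame(report: dict) -> pd.DataFrame:
    """Flat per-analyte × model table of the headline metrics."""
    rows = []
    for key, entry in report["results"].items():
        analyte, model = key.split(":")
        rows.append({
            "analyte": analyte, "model": model,
            "rmsep": entry["rmsep"], "mean_recovery": entry["mean_recovery"],
            "sd_recovery": entry["sd_recovery"], "rpd": entry["rpd"],
            "r2": entry["r2"],
        })
    return pd.DataFrame(rows).sort_values(["analyte", "rmsep"]).reset_index(drop=True)
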