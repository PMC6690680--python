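"""End-to-end study orchestration.

A full run chains: control-population calibration -> per-model cable
simulations at each severity (and optionally several ischemic-region
sizes) -> pseudo-ECG synthesis and biomarker extraction into a feature
table -> neural-network training/evaluation -> summary tables and
figures.  Every stage writes its artifact to the output directory and the
manifest records configuration, seeds and provenance, so a run is
reproducible from its RunConfig alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from . import ml
from .biomarkers import (
    PECG_FEATURES,
    BlockError,
    DelineationError,
    PropagationError,
    activation_time,
    ap_biomarkers,
    conduction_velocity,
    delineate_pecg,
    ratio_of_change,
)
from .cell_model import IschemiaSpec, PacingProtocol, ParameterSet, steady_state
from .pecg import ProbeConfig, compute_pecg
from .population import Population, build_control_epom
from .tissue import CableGeometry, region_profile, simulate_cable, uniform_profile

log = logging.getLogger("epom")

SEVERITIES = ("control", "mild", "severe")
CLASS_TO_INT = {"control": 0, "mild": 1, "severe": 2}

#: study learning rates: the severity grader trains fastest, the detector
#: at half... the multi-class network at a twentieth of the grader's rate
LEARNING_RATES = {"ann1": 0.005, "ann21": 0.01, "ann22": 0.1}


@dataclass
class RunConfig:
    """Fully serializable configuration of a study run."""

    n_samples: int = 10000
    seed: int = 1
    max_models: int | None = None  # cap on accepted models carried forward
    zone_sizes: tuple = (2.0,)  # cm, ischemic-region sizes for the sweep
    ml_zone: float = 2.0  # cm, the zone used for the classifier dataset
    # pacing / solver
    cell_beats: int = 200
    cable_beats: int = 30
    warm_start: bool = False  # seed cables from single-cell steady states
    warm_cell_beats: int = 100  # ischemic single-cell pre-pacing when warm
    cable_dt: float = 0.02  # ms
    cell_dt_prepace: float = 0.1  # ms
    convention: str = "repol90"  # APD90 convention
    # ML protocol
    ann_grid: str = "best"  # "best" (the three known optima) or "full"
    ann_epochs: int = 5000
    ann_seed: int = 0
    out_dir: str = "epom_run"
    make_figures: bool = False

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("zone_sizes",):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


# ---------------------------------------------------------------------------
# cable features
# ---------------------------------------------------------------------------

def _mid_cell_ap(sol, convention):
    """AP biomarkers of the mid-cable cell of a saved beat."""
    from .cell_model import APTrace

    mid = sol.v.shape[1] // 2
    return ap_biomarkers(APTrace(t=sol.t, v=sol.v[:, mid], cl=sol.cl),
                         convention=convention)


def cable_biomarkers(params: ParameterSet, spec: IschemiaSpec, zone_size: float,
                     config: RunConfig, control_state=None,
                     geometry: CableGeometry = CableGeometry()):
    """Simulate one cable and extract (pECG biomarkers, CV, solution).

    When ``config.warm_start`` is set the cable starts from the single-cell
    steady state of the matching severity (pre-paced from the control
    state), which shortens the number of cable beats needed; otherwise the
    published cold-start protocol (30 beats from resting conditions) runs.
    """
    protocol = PacingProtocol(cl=600.0, n_beats=config.cable_beats)
    if zone_size >= geometry.length or spec.label == "control":
        profile = uniform_profile(spec, geometry)
        if spec.label != "control":
            profile["zone_size"] = float(zone_size)
    else:
        profile = region_profile(spec, zone_size, geometry)
    initial = None
    if config.warm_start:
        if spec.label == "control" and control_state is not None:
            initial = control_state
        elif control_state is not None:
            initial = steady_state(
                params, spec,
                PacingProtocol(cl=600.0, n_beats=config.warm_cell_beats),
                dt=config.cell_dt_prepace, initial=control_state,
            )
    sol = simulate_cable(params, profile, geometry, protocol,
                         dt=config.cable_dt, initial=initial)
    probe = ProbeConfig()
    pecg = compute_pecg(sol, probe)
    # the QRS complex ends shortly after the last windowed cell activates,
    # so the search window adapts to the (possibly very slow) conduction
    at_last = activation_time(sol.t, sol.v[:, probe.window[1]])
    marks = delineate_pecg(pecg, qrs_window=at_last + 20.0)
    cv = conduction_velocity(sol)
    return marks, cv, sol


def model_feature_rows(params: ParameterSet, config: RunConfig,
                       control_state=None, zone_sizes=None) -> list:
    """Feature-table rows for one model: control plus each severity/zone.

    The severe cable is simulated first: if the model blocks under severe
    ischemia (the usual failure) nothing else is spent on it.
    """
    zones = zone_sizes if zone_sizes is not None else config.zone_sizes
    sims = {}
    for label in ("severe", "control", "mild"):
        if label == "control":
            sims[("control", 0.0)] = cable_biomarkers(
                params, IschemiaSpec.control(), 0.0, config, control_state
            )
            continue
        spec = IschemiaSpec.preset(label)
        for zone in zones:
            sims[(label, zone)] = cable_biomarkers(
                params, spec, zone, config, control_state
            )

    ctrl_marks = sims[("control", 0.0)][0]
    rows = []
    for (label, zone), (marks, cv, sol) in sorted(
        sims.items(), key=lambda kv: (CLASS_TO_INT[kv[0][0]], kv[0][1])
    ):
        ap = _mid_cell_ap(sol, config.convention)
        ratios = ratio_of_change(ctrl_marks, marks)
        row = {"model_id": params.id, "severity": label, "zone_size": zone,
               "label": CLASS_TO_INT[label], "cv": cv.cv,
               "apd90_cable": ap.apd90, "apa_cable": ap.apa,
               "rmp_cable": ap.rmp}
        row.update(marks.as_dict())
        row.update({f"r_{k}": ratios[k] for k in PECG_FEATURES})
        rows.append(row)
    return rows


def build_feature_table(population: Population, config: RunConfig) -> pd.DataFrame:
    """Cable + pECG features for every accepted model in the population."""
    rows = []
    n_done = 0
    target = config.max_models or len(population.accepted)
    for rec in population.accepted:
        if n_done >= target:
            break
        state = rec.final_states.get(600.0) if config.warm_start else None
        try:
            rows.extend(model_feature_rows(rec.params, config, state))
            n_done += 1
        except (DelineationError, PropagationError, BlockError) as exc:
            # conduction block or an undelineatable trace under severe
            # ischemia: replace the model with the next accepted one so
            # every class keeps a full complement
            log.warning("model %s dropped from feature table: %s",
                        rec.params.id, exc)
    return pd.DataFrame(rows)


def region_size_sweep(params: ParameterSet, config: RunConfig,
                      zones=(0.5, 1.0, 1.5, 2.0), control_state=None) -> pd.DataFrame:
    """Biomarkers of one model as a function of the ischemic-region size."""
    rows = model_feature_rows(params, config, control_state, zone_sizes=zones)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# classifier stage
# ---------------------------------------------------------------------------

def _best_architectures(n_inputs, name, epochs, seed):
    """The known-best architectures (HL/HU): multi-class 5/7, detector 5/8,
    severity grader 4/4."""
    hl, hu = {"ann1": (5, 7), "ann21": (5, 8), "ann22": (4, 4)}[name]
    return [ml.MLPSpec(
        n_inputs=n_inputs, hidden_layers=hl, hidden_units=hu,
        n_outputs=3 if name == "ann1" else 1,
        learning_rate=LEARNING_RATES[name], epochs=epochs, seed=seed,
    )]


def _grid_for(name, n_inputs, config: RunConfig):
    if config.ann_grid == "best":
        return _best_architectures(n_inputs, name, config.ann_epochs, config.ann_seed)
    return ml.default_grid(
        n_inputs, 3 if name == "ann1" else 1, LEARNING_RATES[name],
        epochs=config.ann_epochs, seed=config.ann_seed,
    )


def train_networks(features: pd.DataFrame, config: RunConfig) -> dict:
    """Train the multi-class network and the cascade on one feature table.

    Uses the rows of the configured ML zone (plus all control rows).  The
    detector and the multi-class network share the magnitude features and
    the same master train/evaluation split; the severity grader trains on
    the ratio features of the ischemic training rows only, so no
    evaluation example of any network leaks into training.
    """
    df = features[
        (features["severity"] == "control")
        | (features["zone_size"] == config.ml_zone)
    ].reset_index(drop=True)
    mag_cols = list(PECG_FEATURES)
    ratio_cols = [f"r_{k}" for k in PECG_FEATURES]

    x_mag = df[mag_cols].to_numpy(float)
    x_ratio = df[ratio_cols].to_numpy(float)
    y3 = df["label"].to_numpy(int)

    ds1 = ml.make_dataset(x_mag, y3, feature_names=mag_cols,
                          class_names=SEVERITIES, seed=config.ann_seed)
    # detector: same rows, split and normalization; binary labels
    ds21 = ml.Dataset(
        x=x_mag, y=(y3 > 0).astype(int), feature_names=tuple(mag_cols),
        class_names=("control", "ischemic"), train_idx=ds1.train_idx,
        eval_idx=ds1.eval_idx, folds=ds1.folds, mean=ds1.mean, std=ds1.std,
    )
    # severity grader: ischemic rows only, ratio features; split inherited
    # from the master split so its evaluation rows are the master's
    tr22 = np.array([i for i in ds1.train_idx if y3[i] > 0])
    ev22 = np.array([i for i in ds1.eval_idx if y3[i] > 0])
    mean22 = x_ratio[tr22].mean(axis=0)
    std22 = np.where(x_ratio[tr22].std(axis=0) < 1e-12, 1.0,
                     x_ratio[tr22].std(axis=0))
    folds22 = ml.stratified_folds(tr22, (y3[tr22] == 2).astype(int), 10)
    ds22 = ml.Dataset(
        x=x_ratio, y=(y3 == 2).astype(int), feature_names=tuple(ratio_cols),
        class_names=("mild", "severe"), train_idx=tr22, eval_idx=ev22,
        folds=folds22, mean=mean22, std=std22,
    )

    results = {}
    for name, ds in (("ann1", ds1), ("ann21", ds21), ("ann22", ds22)):
        grid = _grid_for(name, ds.x.shape[1], config)
        sel = ml.cross_validate_and_select(ds, grid)
        sel["importance"] = ml.garson_importance(sel["model"])
        sel["dataset"] = ds
        results[name] = sel
        log.info("%s: HL=%d HU=%d Se=%.2f PPV=%.2f F1=%.2f", name,
                 sel["selected_spec"].hidden_layers,
                 sel["selected_spec"].hidden_units,
                 sel["metrics"].se, sel["metrics"].ppv, sel["metrics"].f1)

    # cascade evaluation on the master evaluation split
    ev = ds1.eval_idx
    xm = (x_mag[ev] - ds1.mean) / ds1.std
    xr = (x_ratio[ev] - ds22.mean) / ds22.std
    y_hat = ml.cascade_predict(results["ann21"]["model"],
                               results["ann22"]["model"], xm, xr)
    results["cascade"] = {
        "metrics": ml.evaluate_predictions(y3[ev], y_hat, 3),
        "predictions": y_hat,
        "truth": y3[ev],
    }

    # logistic-regression baseline on the detection task, with its
    # per-severity detection rates (it should catch severe far more
    # readily than mild)
    lr = ml.logistic_baseline(ds21, seed=config.ann_seed)
    sev_eval = y3[ds21.eval_idx]
    det = {}
    for cls in ("mild", "severe"):
        m = sev_eval == CLASS_TO_INT[cls]
        det[cls] = float(np.mean(lr["predictions"][m] == 1)) if m.any() else np.nan
    lr["detection_rate"] = det
    ann_det = {}
    ann_pred = ml.predict_labels(
        results["ann21"]["model"],
        (x_mag[ds21.eval_idx] - ds21.mean) / ds21.std,
    )
    for cls in ("mild", "severe"):
        m = sev_eval == CLASS_TO_INT[cls]
        ann_det[cls] = float(np.mean(ann_pred[m] == 1)) if m.any() else np.nan
    results["ann21"]["detection_rate"] = ann_det
    results["logistic"] = lr
    return results


# ---------------------------------------------------------------------------
# tables and figures
# ---------------------------------------------------------------------------

def population_table(population: Population) -> pd.DataFrame:
    """Mean and SD of the single-cell biomarkers at CL 600 (accepted models)."""
    s = population.summary()
    rows = [
        {"biomarker": "APD90 (ms)", "mean": s["apd90_mean"], "sd": s["apd90_sd"]},
        {"biomarker": "APA (mV)", "mean": s["apa_mean"], "sd": s["apa_sd"]},
        {"biomarker": "RMP (mV)", "mean": s["rmp_mean"], "sd": s["rmp_sd"]},
    ]
    return pd.DataFrame(rows)


def control_biomarker_table(population: Population, features: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD of AP and pECG biomarkers of the control population."""
    tab = population_table(population)
    ctrl = features[features["severity"] == "control"]
    extra = [
        ("CV (cm/s)", "cv"),
        ("QT interval (ms)", "qt_interval"),
        ("QRS duration (ms)", "qrs_duration"),
        ("T wave duration (ms)", "t_duration"),
    ]
    rows = [{"biomarker": label, "mean": ctrl[col].mean(), "sd": ctrl[col].std()}
            for label, col in extra]
    return pd.concat([tab, pd.DataFrame(rows)], ignore_index=True)


def network_table(results: dict) -> pd.DataFrame:
    """Best-network summary: architecture and evaluation metrics."""
    rows = []
    for name in ("ann1", "ann21", "ann22"):
        sel = results[name]
        rows.append({
            "network": name, "hl": sel["selected_spec"].hidden_layers,
            "hu": sel["selected_spec"].hidden_units,
            "se": sel["metrics"].se, "ppv": sel["metrics"].ppv,
            "f1": sel["metrics"].f1,
        })
    return pd.DataFrame(rows)


def importance_table(results: dict) -> pd.DataFrame:
    """Garson relative feature importance per network (columns sum to 1)."""
    out = {"feature": list(PECG_FEATURES)}
    for name in ("ann1", "ann21", "ann22"):
        out[name] = results[name]["importance"]
    return pd.DataFrame(out)


def make_tables(population, features, results, out_dir) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("control_biomarkers", control_biomarker_table(population, features)),
        ("best_networks", network_table(results)),
        ("feature_importance", importance_table(results)),
    ):
        p = out_dir / f"table_{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = str(p)
    return paths


def make_figures(features: pd.DataFrame, sweep: pd.DataFrame | None, out_dir) -> list:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    made = []

    fig, axes = plt.subplots(2, 3, figsize=(12, 7))
    for ax, col in zip(axes.ravel(), PECG_FEATURES):
        data = [features.loc[features["severity"] == s, col].dropna()
                for s in SEVERITIES]
        ax.boxplot(data, tick_labels=SEVERITIES)
        ax.set_title(col)
    fig.suptitle("pseudo-ECG biomarkers by ischemic severity")
    fig.tight_layout()
    p = out_dir / "fig_pecg_biomarkers.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    made.append(str(p))

    if sweep is not None and not sweep.empty:
        fig, axes = plt.subplots(2, 3, figsize=(12, 7))
        for ax, col in zip(axes.ravel(), PECG_FEATURES):
            for s in ("mild", "severe"):
                sub = sweep[sweep["severity"] == s].sort_values("zone_size")
                ax.plot(sub["zone_size"], sub[col], marker="o", label=s)
            ax.set_title(col)
            ax.set_xlabel("ischemic region size (cm)")
        axes[0, 0].legend()
        fig.suptitle("biomarkers vs ischemic-region size")
        fig.tight_layout()
        p = out_dir / "fig_region_size.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        made.append(str(p))
    return made


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

def run_full_study(config: RunConfig) -> dict:
    """Execute every stage and persist artifacts; returns the bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    bundle = {"config": config}
    manifest = {"config_digest": config.digest(), "stages": {}}

    log.info("stage 1/4: control population (n=%d)", config.n_samples)
    population = build_control_epom(
        config.n_samples, seed=config.seed, n_beats=config.cell_beats,
        convention=config.convention, dt_prepace=config.cell_dt_prepace,
    )
    eio.save_population(out / "population.h5", population)
    population.write_index(out / "population_index.csv")
    bundle["population"] = population
    manifest["stages"]["population"] = {
        "n_accepted": len(population.accepted),
        "acceptance_fraction": population.acceptance_fraction,
        "artifact": "population.h5",
    }

    log.info("stage 2/4: cables + features (%d models)",
             len(population.accepted[:config.max_models]))
    features = build_feature_table(population, config)
    features.to_csv(out / "features.csv", index=False)
    bundle["features"] = features
    manifest["stages"]["features"] = {"rows": len(features), "artifact": "features.csv"}

    sweep = None
    if len(config.zone_sizes) > 1 and len(population.accepted) > 0:
        rec = population.accepted[0]
        sweep = region_size_sweep(
            rec.params, config, zones=config.zone_sizes,
            control_state=rec.final_states.get(600.0) if config.warm_start else None,
        )
        sweep.to_csv(out / "region_sweep.csv", index=False)
        bundle["sweep"] = sweep

    log.info("stage 3/4: classifiers")
    results = train_networks(features, config)
    bundle["results"] = results
    for name in ("ann1", "ann21", "ann22"):
        eio.save_model_json(out / f"model_{name}.json", results[name]["model"],
                            results[name]["dataset"].mean,
                            results[name]["dataset"].std)
    manifest["stages"]["ml"] = {
        name: results[name]["metrics"].as_dict() for name in ("ann1", "ann21", "ann22")
    }
    manifest["stages"]["ml"]["cascade"] = results["cascade"]["metrics"].as_dict()

    log.info("stage 4/4: tables%s", " + figures" if config.make_figures else "")
    manifest["tables"] = make_tables(population, features, results, out)
    if config.make_figures:
        manifest["figures"] = make_figures(features, sweep, out)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    bundle["manifest"] = manifest
    return bundle
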