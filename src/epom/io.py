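"""Persistence: HDF5 containers for populations and cables, JSON for
trained networks, CSV for feature tables and reports."""

from __future__ import annotations

import json

import h5py
import numpy as np

from ._tp06 import PARAM_NAMES
from .cell_model import ParameterSet
from .ml import MLPSpec, TrainedModel


def save_population(path, population) -> None:
    """One HDF5 group per sampled model: parameters, flags, biomarkers."""
    with h5py.File(path, "w") as f:
        f.attrs["seed"] = population.seed
        f.attrs["n_samples"] = population.n_samples
        for rec in population.records:
            g = f.create_group(rec.params.id)
            g.create_dataset("scales", data=rec.params.scales)
            g.attrs["accepted"] = rec.accepted
            g.attrs["reason"] = rec.reason or ""
            for cl, b in rec.biomarkers.items():
                gb = g.create_group(f"cl{int(cl)}")
                for name in ("apd90", "apa", "rmp", "upstroke_time"):
                    gb.attrs[name] = getattr(b, name)
            for cl, state in rec.final_states.items():
                g.create_dataset(f"state_cl{int(cl)}", data=state)
            for cl, tr in rec.traces.items():
                gt = g.create_group(f"trace_cl{int(cl)}")
                gt.create_dataset("t", data=tr.t)
                gt.create_dataset("v", data=tr.v)


def load_accepted_parameters(path) -> list:
    """ParameterSets of the accepted models in a stored population."""
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            g = f[name]
            if g.attrs["accepted"]:
                out.append(ParameterSet(scales=np.array(g["scales"]), id=name))
    return out


def save_cable(path_or_group, solution) -> None:
    def _write(g):
        g.create_dataset("t", data=solution.t)
        g.create_dataset("v", data=solution.v)
        g.create_dataset("positions", data=solution.positions)
        for key in ("ko", "f_katp", "f_inhib"):
            g.create_dataset(key, data=np.asarray(solution.profile[key]))
        for key, val in solution.meta.items():
            g.attrs[key] = val
        g.attrs["cl"] = solution.cl
        g.attrs["n_beats"] = solution.n_beats

    if isinstance(path_or_group, (str, bytes)) or hasattr(path_or_group, "__fspath__"):
        with h5py.File(path_or_group, "w") as f:
            _write(f)
    else:
        _write(path_or_group)


def save_pecg_csv(path, trace) -> None:
    np.savetxt(path, np.column_stack([trace.t, trace.phi]),
               delimiter=",", header="time_ms,phi_e", comments="")


def save_model_json(path, model: TrainedModel, norm_mean=None, norm_std=None) -> None:
    spec = model.spec
    payload = {
        "spec": {
            "n_inputs": spec.n_inputs, "hidden_layers": spec.hidden_layers,
            "hidden_units": spec.hidden_units, "n_outputs": spec.n_outputs,
            "learning_rate": spec.learning_rate, "weight_decay": spec.weight_decay,
            "epochs": spec.epochs, "seed": spec.seed,
        },
        "weights": [w.tolist() for w in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "fold": model.fold,
    }
    if norm_mean is not None:
        payload["norm_mean"] = np.asarray(norm_mean).tolist()
        payload["norm_std"] = np.asarray(norm_std).tolist()
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model_json(path) -> TrainedModel:
    with open(path) as fh:
        payload = json.load(fh)
    spec = MLPSpec(**payload["spec"])
    return TrainedModel(
        weights=[np.array(w) for w in payload["weights"]],
        biases=[np.array(b) for b in payload["biases"]],
        spec=spec, fold=payload.get("fold"),
    )


def parameter_set_json(params: ParameterSet) -> str:
    return json.dumps(params.to_dict())


def parameter_set_from_json(s: str) -> ParameterSet:
    return ParameterSet.from_dict(json.loads(s))


__all__ = [
    "PARAM_NAMES", "save_population", "load_accepted_parameters", "save_cable",
    "save_pecg_csv", "save_model_json", "load_model_json",
    "parameter_set_json", "parameter_set_from_json",
]
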