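"""Persistent trial-ensemble container (HDF5) and config round-tripping.

The container stores the verbatim config snapshot, seeds, population layout,
ragged per-trial spike data, per-trial labels and the common stimulus terms,
so that every analysis product is reproducible from the file alone and the
simulation can be re-run bit-identically from the snapshot.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import yaml

from .config import (NetworkConfig, StimulusConfig, NeuronParams, _to_dict,
                     _from_dict, NETWORK_NESTED)
from .protocol import TrialEnsemble, TrialResult

__all__ = ["write_ensemble", "read_ensemble", "add_product", "read_products",
           "SCHEMA"]

SCHEMA = "cpnet-ensemble-1"


def write_ensemble(ensemble: TrialEnsemble, path) -> None:
    """Lossless write of an ensemble (spike times at native resolution)."""
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = SCHEMA
        f.attrs["mode"] = ensemble.mode
        f.attrs["master_seed"] = ensemble.master_seed
        f.attrs["config_yaml"] = yaml.safe_dump(
            {"network": _to_dict(ensemble.network_config),
             "stimulus": _to_dict(ensemble.stimulus_config)})
        f.create_dataset("offsets", data=np.asarray(ensemble.offsets, np.int64))
        if ensemble.group_labels is not None:
            f.create_dataset("group_labels", data=ensemble.group_labels)
        g = f.create_group("trials")
        L = ensemble.n_trials
        if L:
            nrn = np.concatenate([t.spike_neurons for t in ensemble.trials])
            tms = np.concatenate([t.spike_times for t in ensemble.trials])
            counts = [len(t.spike_times) for t in ensemble.trials]
            g.create_dataset("spike_neurons", data=nrn.astype(np.int32))
            g.create_dataset("spike_times", data=tms)
            g.create_dataset("trial_offsets",
                             data=np.concatenate([[0], np.cumsum(counts)]))
            g.create_dataset("choice", data=ensemble.choices.astype(np.int8))
            g.create_dataset("coherence", data=ensemble.coherences)
            g.create_dataset("stimulus_id",
                             data=ensemble.stimulus_ids.astype(np.int64))
            g.create_dataset("stimulus_seed", data=np.array(
                [t.stimulus_seed for t in ensemble.trials], np.int64))
            g.create_dataset("trial_seed", data=np.array(
                [t.trial_seed for t in ensemble.trials], np.int64))
            g.create_dataset("s_e1", data=np.stack(
                [t.s_e1 for t in ensemble.trials]).astype(np.float32))
            g.create_dataset("s_e2", data=np.stack(
                [t.s_e2 for t in ensemble.trials]).astype(np.float32))
            g.attrs["pre"] = ensemble.trials[0].pre
            g.attrs["stim_duration"] = ensemble.trials[0].stim_duration
            g.attrs["stim_dt"] = ensemble.trials[0].stim_dt
        else:
            g.create_dataset("trial_offsets", data=np.zeros(1, np.int64))
            g.attrs["pre"] = 0.0
            g.attrs["stim_duration"] = 0.0
            g.attrs["stim_dt"] = 1.0


def read_ensemble(path) -> TrialEnsemble:
    with h5py.File(path, "r") as f:
        schema = f.attrs.get("schema", "")
        if schema != SCHEMA:
            raise ValueError(f"unsupported container schema {schema!r}; "
                             f"expected {SCHEMA}")
        doc = yaml.safe_load(f.attrs["config_yaml"])
        net = _from_dict(NetworkConfig, doc["network"], nested=NETWORK_NESTED)
        stim = _from_dict(StimulusConfig, doc["stimulus"])
        offsets = f["offsets"][:]
        group_labels = f["group_labels"][:] if "group_labels" in f else None
        g = f["trials"]
        toff = g["trial_offsets"][:]
        trials = []
        L = len(toff) - 1
        if L and "choice" in g:
            nrn = g["spike_neurons"][:]
            tms = g["spike_times"][:]
            choice = g["choice"][:]
            coh = g["coherence"][:]
            sid = g["stimulus_id"][:]
            sseed = g["stimulus_seed"][:]
            tseed = g["trial_seed"][:]
            s1 = g["s_e1"][:]
            s2 = g["s_e2"][:]
            pre = float(g.attrs["pre"])
            dur = float(g.attrs["stim_duration"])
            sdt = float(g.attrs["stim_dt"])
            for j in range(L):
                a, b = toff[j], toff[j + 1]
                trials.append(TrialResult(
                    spike_neurons=nrn[a:b], spike_times=tms[a:b],
                    choice=int(choice[j]), coherence=float(coh[j]),
                    stimulus_id=int(sid[j]), stimulus_seed=int(sseed[j]),
                    pre=pre, stim_duration=dur,
                    s_e1=s1[j].astype(np.float64),
                    s_e2=s2[j].astype(np.float64), stim_dt=sdt,
                    trial_seed=int(tseed[j])))
        return TrialEnsemble(trials=trials, mode=str(f.attrs["mode"]),
                             network_config=net, stimulus_config=stim,
                             offsets=offsets, group_labels=group_labels,
                             master_seed=int(f.attrs["master_seed"]))


def add_product(path, name: str, arrays: dict, operation: str,
                parameters: dict) -> None:
    """Attach an analysis product (named arrays) with provenance."""
    with h5py.File(path, "a") as f:
        g = f.require_group("products")
        if name in g:
            del g[name]
        p = g.create_group(name)
        p.attrs["operation"] = operation
        p.attrs["parameters"] = json.dumps(parameters, default=float)
        from . import __version__
        p.attrs["code_version"] = __version__
        for key, arr in arrays.items():
            p.create_dataset(key, data=np.asarray(arr))


def read_products(path) -> dict:
    out = {}
    with h5py.File(path, "r") as f:
        if "products" not in f:
            return out
        for name, p in f["products"].items():
            out[name] = {
                "operation": p.attrs["operation"],
                "parameters": json.loads(p.attrs["parameters"]),
                "arrays": {k: p[k][:] for k in p},
            }
    return out
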