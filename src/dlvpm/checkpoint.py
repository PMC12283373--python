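"""Model checkpointing: a single ``.npz`` archive of named arrays plus a
JSON metadata record.

The archive stores, per view: the feature standardization statistics, all
network parameters (in deterministic traversal order), the moving
batch-statistics, and every covariance tracker (value, momentum, full
sample size).  Restored models transform new data exactly as the original
(the training views themselves are not stored).
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from .covariance import CovarianceTracker, InvalidArgumentError
from .measurement import MeasurementModel, MeasurementModelSpec
from .model import DLVPM, DLVPMResults
from .path import PathSpec
from .twins import AugmentationSpec, DLVPMTwins, TwinsResults

__all__ = ["save_checkpoint", "load_checkpoint"]

_FORMAT = 1


def _pack_measurement(mm: MeasurementModel, prefix: str, arrays: dict) -> dict:
    meta = {"spec": dataclasses.asdict(mm.spec), "view_name": mm.view_name,
            "rho": mm.rho}
    for j, p in enumerate(mm.params()):
        arrays[f"{prefix}_param{j}"] = p.data
    st = mm.bn.stats
    meta["bn_initialized"] = st.initialized
    if st.initialized:
        arrays[f"{prefix}_bn_mean"] = st.mean
        arrays[f"{prefix}_bn_std"] = st.std
    for name in ("sigma_yf", "sigma_yy", "scale"):
        tr = getattr(mm, name)
        if tr is not None:
            arrays[f"{prefix}_{name}"] = tr.value
            meta[f"{name}_n_total"] = tr.n_total
    if mm.conf is not None and mm.conf.initialized:
        arrays[f"{prefix}_conf_cc"] = mm.conf.cc.value
        arrays[f"{prefix}_conf_cf"] = mm.conf.cf.value
        meta["conf_n_total"] = mm.conf.cc.n_total
    return meta


def _unpack_measurement(meta: dict, prefix: str, arrays) -> MeasurementModel:
    spec = MeasurementModelSpec(**meta["spec"])
    rng = np.random.default_rng(0)
    mm = MeasurementModel(spec, meta["rho"], rng, meta["view_name"])
    for j, p in enumerate(mm.params()):
        p.data = np.array(arrays[f"{prefix}_param{j}"])
    if meta["bn_initialized"]:
        mm.bn.stats.mean = np.array(arrays[f"{prefix}_bn_mean"])
        mm.bn.stats.std = np.array(arrays[f"{prefix}_bn_std"])
        mm.bn.stats.initialized = True
    for name in ("sigma_yf", "sigma_yy", "scale"):
        key = f"{prefix}_{name}"
        if key in arrays:
            setattr(mm, name, CovarianceTracker(
                value=np.array(arrays[key]), rho=meta["rho"],
                n_total=int(meta[f"{name}_n_total"])))
    if mm.conf is not None and f"{prefix}_conf_cc" in arrays:
        n_total = int(meta["conf_n_total"])
        mm.conf.cc = CovarianceTracker(np.array(arrays[f"{prefix}_conf_cc"]),
                                       meta["rho"], n_total)
        mm.conf.cf = CovarianceTracker(np.array(arrays[f"{prefix}_conf_cf"]),
                                       meta["rho"], n_total)
    return mm


def save_checkpoint(results, path) -> None:
    """Serialize a fitted :class:`DLVPMResults` or :class:`TwinsResults`."""
    arrays: dict = {}
    if isinstance(results, DLVPMResults):
        model = results.model
        if model.measurement_models is None:
            raise InvalidArgumentError("cannot checkpoint an unfitted model")
        meta = {
            "format": _FORMAT, "kind": "dlvpm",
            "variant": model.variant, "n_dims": model.n_dims,
            "rho": model.rho, "whiten_method": model.whiten_method,
            "view_names": model.path.view_names,
            "confound_names": (model.confounds.names
                               if model.confounds is not None else None),
            "views": [],
        }
        arrays["adjacency"] = model.path.adjacency
        for i, mm in enumerate(model.measurement_models):
            meta["views"].append(_pack_measurement(mm, f"view{i}", arrays))
            arrays[f"view{i}_mu"] = model._mu[i]
            arrays[f"view{i}_sd"] = model._sd[i]
            arrays[f"view{i}_signs"] = results._signs[i]
            arrays[f"view{i}_rot"] = results._rotations[i]
        arrays["history"] = results.history.to_numpy()
        meta["history_columns"] = list(results.history.columns)
    elif isinstance(results, TwinsResults):
        model = results.model
        meta = {
            "format": _FORMAT, "kind": "twins",
            "variant": model.variant, "n_dims": model.n_dims,
            "rho": model.rho, "whiten_method": model.whiten_method,
            "augmentation": dataclasses.asdict(model.augmentation),
            "view": _pack_measurement(model.measurement_model, "view0",
                                      arrays),
        }
        arrays["view0_mu"] = model._mu
        arrays["view0_sd"] = model._sd
        arrays["history"] = results.history.to_numpy()
        meta["history_columns"] = list(results.history.columns)
    else:
        raise InvalidArgumentError(f"cannot checkpoint {type(results)!r}")
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Restore a results object able to ``transform`` new data."""
    with np.load(path) as arrays:
        meta = json.loads(bytes(arrays["meta_json"].tobytes()).decode())
        if meta.get("format") != _FORMAT:
            raise InvalidArgumentError("unrecognized checkpoint format")
        if meta["kind"] == "dlvpm":
            model = DLVPM.__new__(DLVPM)
            model.path = PathSpec(np.array(arrays["adjacency"]),
                                  meta["view_names"])
            model.variant = meta["variant"]
            model.n_dims = meta["n_dims"]
            model.rho = meta["rho"]
            model.whiten_method = meta["whiten_method"]
            model.confounds = None
            model.sample_ids = []
            model.views = []
            model._mu, model._sd = [], []
            model.measurement_models = []
            signs, rots = [], []
            for i, vm in enumerate(meta["views"]):
                model.measurement_models.append(
                    _unpack_measurement(vm, f"view{i}", arrays))
                model._mu.append(np.array(arrays[f"view{i}_mu"]))
                model._sd.append(np.array(arrays[f"view{i}_sd"]))
                signs.append(np.array(arrays[f"view{i}_signs"]))
                rots.append(np.array(arrays[f"view{i}_rot"]))
            model.measurement_specs = [mm.spec
                                       for mm in model.measurement_models]
            hist = pd.DataFrame(np.array(arrays["history"]),
                                columns=meta["history_columns"])
            results = DLVPMResults(model, hist)
            results._signs = signs
            results._rotations = rots
            return results
        if meta["kind"] == "twins":
            model = DLVPMTwins.__new__(DLVPMTwins)
            model.variant = meta["variant"]
            model.n_dims = meta["n_dims"]
            model.rho = meta["rho"]
            model.whiten_method = meta["whiten_method"]
            model.augmentation = AugmentationSpec(**meta["augmentation"])
            model.measurement_model = _unpack_measurement(
                meta["view"], "view0", arrays)
            model.measurement_spec = model.measurement_model.spec
            model._mu = np.array(arrays["view0_mu"])
            model._sd = np.array(arrays["view0_sd"])
            model.view = None
            hist = pd.DataFrame(np.array(arrays["history"]),
                                columns=meta["history_columns"])
            return TwinsResults(model, hist)
        raise InvalidArgumentError(f"unknown checkpoint kind {meta['kind']!r}")
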