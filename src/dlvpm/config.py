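"""Run configuration: YAML/JSON parsing and the reproducibility manifest.

A run configuration names the view files, the adjacency (full matrix or an
edge list over view names), optional confounds, the orthogonalization
variant, the number of latent dimensions, and the training settings.  All
randomness in a run flows from the single top-level seed, expanded into
named substreams.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .covariance import InvalidArgumentError
from .measurement import MeasurementModelSpec
from .model import TrainConfig
from .path import PathSpec, validate_path_spec

__all__ = ["RunConfig", "load_config", "seed_streams", "write_manifest"]

_STREAMS = ("init", "shuffle", "permutation", "bootstrap", "augmentation",
            "simulate")


def seed_streams(seed: int) -> dict:
    """Expand one seed into named integer substream seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_STREAMS))
    return {name: int(c.generate_state(1)[0] % (2**31))
            for name, c in zip(_STREAMS, children)}


@dataclass
class RunConfig:
    """Validated configuration of one command-line run."""

    views: list                       # (name, path, MeasurementModelSpec)
    path_spec: PathSpec
    confounds_path: str | None
    variant: str
    n_dims: int
    train: TrainConfig
    out_dir: str
    seed: int
    twins: dict | None = None
    raw: dict = field(default_factory=dict)


def _spec_from_dict(d: dict, n_dims: int) -> MeasurementModelSpec:
    d = dict(d or {})
    d.setdefault("kind", "linear")
    d["n_dims"] = n_dims
    return MeasurementModelSpec(**d)


def load_config(path) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration file."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise InvalidArgumentError(f"config {path} is not a mapping")
    views_cfg = cfg.get("views")
    if not views_cfg:
        raise InvalidArgumentError("config must list views")
    n_dims = int(cfg.get("n_dims", 5))
    names, view_entries = [], []
    for v in views_cfg:
        name = v["name"]
        vpath = v["path"]
        if name in names:
            raise InvalidArgumentError(f"duplicate view name {name!r}")
        if not Path(vpath).exists():
            raise InvalidArgumentError(f"view file not found: {vpath}")
        names.append(name)
        spec = v.get("model", {})
        view_entries.append((name, vpath, spec, n_dims))
    if "adjacency" in cfg:
        path_spec = validate_path_spec(np.asarray(cfg["adjacency"]), names)
    elif "edges" in cfg:
        A = np.zeros((len(names), len(names)))
        for a, b in cfg["edges"]:
            ia, ib = names.index(a), names.index(b)
            A[ia, ib] = A[ib, ia] = 1
        path_spec = validate_path_spec(A, names)
    elif cfg.get("twins") is not None:
        path_spec = None            # single-view Siamese run: no path model
    else:
        raise InvalidArgumentError("config needs 'adjacency' or 'edges'")
    conf_path = cfg.get("confounds")
    if conf_path is not None and not Path(conf_path).exists():
        raise InvalidArgumentError(f"confound file not found: {conf_path}")
    use_conf = conf_path is not None
    views = []
    for name, vpath, spec, nd in view_entries:
        spec = dict(spec)
        spec.setdefault("use_confound_layer", use_conf)
        views.append((name, vpath, spec))
    train = TrainConfig(**{**dict(cfg.get("train", {})),
                           "seed": int(cfg.get("seed", 0))})
    return RunConfig(
        views=views, path_spec=path_spec, confounds_path=conf_path,
        variant=cfg.get("variant", "iterative"), n_dims=n_dims,
        train=train, out_dir=cfg.get("out", "."),
        seed=int(cfg.get("seed", 0)), twins=cfg.get("twins"), raw=cfg)


def build_specs(run: RunConfig, input_dims: list) -> list:
    """Instantiate per-view measurement specs with known input sizes."""
    specs = []
    for (name, _, spec_dict), p in zip(run.views, input_dims):
        d = dict(spec_dict)
        d["input_dim"] = p
        specs.append(_spec_from_dict(d, run.n_dims))
    return specs


def write_manifest(out_dir, config_path=None, seed: int | None = None,
                   extra: dict | None = None) -> Path:
    """Write a manifest sufficient to reproduce the run."""
    import dlvpm

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": dlvpm.__version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": seed,
        "seed_streams": seed_streams(seed) if seed is not None else None,
    }
    if config_path is not None:
        text = Path(config_path).read_bytes()
        manifest["config_path"] = str(config_path)
        manifest["config_sha256"] = hashlib.sha256(text).hexdigest()
    if extra:
        manifest.update(extra)
    p = out_dir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2))
    return p
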