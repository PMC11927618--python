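"""Model specs, run configuration, and artifact persistence.

Model specs are YAML mappings ``{type: powerlaw|bidiffusive|viscoelastic|rouse|table,
...params}``; tabulated MSDs are two-column CSV (t, psi).  Every artifact
written by the CLI carries the verbatim config echo, the package version and
the seeds, so a run can be reproduced from its own output.  JSON is the
default container; ``.h5`` paths switch to HDF5.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from memfp import __version__
from memfp.msd_models import (
    MsdModel,
    make_bidiffusive,
    make_powerlaw,
    make_rouse_monomer_msd,
    make_tabulated,
    make_viscoelastic,
)

__all__ = ["load_model_spec", "model_from_dict", "save_artifact", "load_artifact"]


def model_from_dict(spec: dict) -> MsdModel:
    """Build an MsdModel from a spec mapping (see module docstring)."""
    spec = dict(spec)
    kind = spec.pop("type", None)
    if kind == "powerlaw":
        return make_powerlaw(float(spec["kappa"]), float(spec["H"]))
    if kind == "bidiffusive":
        return make_bidiffusive(float(spec["B"]))
    if kind == "viscoelastic":
        return make_viscoelastic(float(spec["amplitude"]), float(spec["tau0"]),
                                 float(spec["alpha"]))
    if kind == "rouse":
        return make_rouse_monomer_msd(int(spec["N"]))
    if kind == "table":
        df = pd.read_csv(spec["path"], comment="#")
        cols = list(df.columns[:2])
        return make_tabulated(df[cols[0]].to_numpy(), df[cols[1]].to_numpy(),
                              kappa=spec.get("kappa"), H=spec.get("H"))
    raise ValueError(f"unknown model type {kind!r} "
                     "(expected powerlaw|bidiffusive|viscoelastic|rouse|table)")


def load_model_spec(path) -> MsdModel:
    """Load a model spec from a YAML file."""
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    if not isinstance(spec, dict):
        raise ValueError(f"model spec {path} must be a YAML mapping")
    return model_from_dict(spec)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def save_artifact(results: dict, path, config: dict | None = None,
                  seed: int | None = None) -> None:
    """Persist results with config echo, version and seed (JSON or HDF5 by suffix)."""
    path = Path(path)
    payload = {
        "version": __version__,
        "seed": seed,
        "config": _jsonify(config or {}),
        "results": _jsonify(results),
    }
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        def write(group, obj):
            for k, v in obj.items():
                if isinstance(v, dict):
                    write(group.create_group(str(k)), v)
                elif isinstance(v, (list, tuple, np.ndarray)):
                    arr = np.asarray(v)
                    if arr.dtype == object:
                        group.attrs[str(k)] = json.dumps(_jsonify(v))
                    else:
                        group.create_dataset(str(k), data=arr)
                elif v is None:
                    group.attrs[str(k)] = "null"
                else:
                    group.attrs[str(k)] = v
        with h5py.File(path, "w") as fh:
            write(fh, payload)
    else:
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def load_artifact(path) -> dict:
    """Load a JSON artifact written by :func:`save_artifact`."""
    with open(path) as fh:
        return json.load(fh)
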