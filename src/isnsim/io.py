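"""Readers and writers for all on-disk artifacts.

Formats: SWC morphologies (plain text, de facto standard type codes:
1 soma, 2 axon, 3 dendrite), a documented JSON network schema with
explicit connection lists (so downstream analysis never depends on RNG
implementation details), two-column text and HDF5 spike files, CSV and
HDF5 voltage traces with unit metadata, and YAML experiment configs.
Every file the package writes is re-readable by its own readers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .errors import SchemaError
from .engine import SpikeData, TraceData
from .model_core import CableModel, ExpIFParams, HHPointParams
from .network import BackgroundInput, NetworkModel, Population, Projection

__all__ = [
    "SWCMorphology",
    "read_swc",
    "write_swc",
    "cable_to_swc",
    "swc_to_cable",
    "write_network_json",
    "read_network_json",
    "write_spikes_text",
    "read_spikes_text",
    "write_spikes_h5",
    "read_spikes_h5",
    "write_traces_h5",
    "read_traces_h5",
    "write_traces_csv",
    "load_yaml_config",
]


# ---------------------------------------------------------------------------
# SWC
# ---------------------------------------------------------------------------

@dataclass
class SWCMorphology:
    """Raw SWC records plus preserved comment lines."""

    ids: np.ndarray
    type_codes: np.ndarray
    xyz: np.ndarray            # (n, 3) um
    radius: np.ndarray         # um
    parent: np.ndarray         # sample ids, -1 for root
    comments: list = field(default_factory=list)

    @property
    def n_points(self) -> int:
        return len(self.ids)


def read_swc(path) -> SWCMorphology:
    """Parse an SWC file, validating ids, parent links and radii."""
    ids, types, xyz, radius, parent, comments = [], [], [], [], [], []
    seen = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                comments.append(line)
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SchemaError(f"{path}:{lineno}: expected 7 fields, got {len(parts)}")
            sid, ty = int(parts[0]), int(parts[1])
            x, y, z, r = (float(v) for v in parts[2:6])
            par = int(parts[6])
            if sid in seen:
                raise SchemaError(f"{path}:{lineno}: duplicate sample id {sid}")
            if r <= 0:
                raise SchemaError(f"{path}:{lineno}: non-positive radius {r}")
            if par != -1 and par not in seen:
                raise SchemaError(
                    f"{path}:{lineno}: parent id {par} does not precede sample {sid}"
                )
            seen.add(sid)
            ids.append(sid); types.append(ty); xyz.append((x, y, z))
            radius.append(r); parent.append(par)
    if not ids:
        raise SchemaError(f"{path}: no SWC records found")
    return SWCMorphology(
        np.asarray(ids), np.asarray(types), np.asarray(xyz, dtype=float),
        np.asarray(radius, dtype=float), np.asarray(parent), comments,
    )


def write_swc(morph: SWCMorphology, path) -> None:
    with open(path, "w") as fh:
        for c in morph.comments:
            fh.write(c if c.startswith("#") else f"# {c}")
            fh.write("\n")
        for i in range(morph.n_points):
            x, y, z = morph.xyz[i]
            fh.write(
                f"{int(morph.ids[i])} {int(morph.type_codes[i])} "
                f"{x:.6g} {y:.6g} {z:.6g} {morph.radius[i]:.6g} {int(morph.parent[i])}\n"
            )


def cable_to_swc(model: CableModel) -> SWCMorphology:
    """Represent a cable model as SWC sample points.

    The root becomes a single soma point; each further compartment is a
    point at its distal end, laid out along +x from its parent (the
    synthetic morphologies carry no real 3D shape, only path lengths
    and radii, which is what the cable equations use).
    """
    n = model.n_comp
    ids = np.arange(1, n + 1)
    xyz = np.zeros((n, 3))
    x_end = np.zeros(n)
    for i in range(1, n):
        x_end[i] = x_end[model.parent[i]] + model.length[i]
        xyz[i, 0] = x_end[i]
    return SWCMorphology(
        ids,
        model.comp_type.copy(),
        xyz,
        model.diam / 2.0,
        np.where(model.parent < 0, -1, model.parent + 1),
        comments=[f"# {model.name}", f"# Ra={model.Ra} cm={model.cm} "
                  f"g_pas={model.g_pas} e_pas={model.e_pas}"],
    )


def swc_to_cable(morph: SWCMorphology, **cable_kw) -> CableModel:
    """Rebuild a cable model from SWC points (root point = spherical soma).

    Compartment lengths are the Euclidean distances to the parent
    point; the root's length is its diameter.
    """
    id_to_idx = {int(s): i for i, s in enumerate(morph.ids)}
    n = morph.n_points
    length = np.empty(n)
    parent = np.empty(n, dtype=int)
    for i in range(n):
        p = int(morph.parent[i])
        if p == -1:
            parent[i] = -1
            length[i] = 2.0 * morph.radius[i]
        else:
            j = id_to_idx[p]
            parent[i] = j
            length[i] = float(np.linalg.norm(morph.xyz[i] - morph.xyz[j]))
    return CableModel(length, 2.0 * morph.radius, parent,
                      comp_type=morph.type_codes.copy(), **cable_kw)


# ---------------------------------------------------------------------------
# network JSON schema
# ---------------------------------------------------------------------------

_PARAM_TYPES = {"ExpIFParams": ExpIFParams, "HHPointParams": HHPointParams}


def _params_to_dict(params) -> dict:
    if isinstance(params, (ExpIFParams, HHPointParams)):
        fields = {
            k: getattr(params, k)
            for k in type(params).__dataclass_fields__
        }
        return {"type": type(params).__name__, **fields}
    if isinstance(params, CableModel):
        return {"type": "CableModel", **_cable_to_dict(params)}
    raise SchemaError(f"cannot serialize parameters of type {type(params).__name__}")


def _cable_to_dict(model: CableModel) -> dict:
    return {
        "length": model.length.tolist(),
        "diam": model.diam.tolist(),
        "parent": model.parent.tolist(),
        "comp_type": model.comp_type.tolist(),
        "Ra": model.Ra, "cm": model.cm, "g_pas": model.g_pas,
        "e_pas": model.e_pas, "spherical_root": model.spherical_root,
        "name": model.name,
    }


def _params_from_dict(d: dict):
    d = dict(d)
    t = d.pop("type")
    if t == "CableModel":
        return CableModel(
            np.asarray(d["length"]), np.asarray(d["diam"]),
            np.asarray(d["parent"], dtype=int),
            Ra=d["Ra"], cm=d["cm"], g_pas=d["g_pas"], e_pas=d["e_pas"],
            spherical_root=d["spherical_root"], name=d.get("name", "cable"),
            comp_type=np.asarray(d["comp_type"], dtype=int),
        )
    if t not in _PARAM_TYPES:
        raise SchemaError(f"unknown parameter type {t!r}")
    return _PARAM_TYPES[t](**d)


def write_network_json(net: NetworkModel, path) -> None:
    doc = {
        "schema": "isnsim-network-v1",
        "seed": net.seed,
        "meta": net.meta,
        "populations": [
            {
                "name": p.name, "size": p.size, "model": p.model, "role": p.role,
                "params": _params_to_dict(p.params),
                "positions": None if p.positions is None else p.positions.tolist(),
                "detailed": {str(k): _cable_to_dict(v) for k, v in p.detailed.items()},
            }
            for p in net.populations
        ],
        "projections": [
            {
                "pre": pr.pre, "post": pr.post, "p": pr.p, "weight": pr.weight,
                "e_syn": pr.e_syn, "tau_syn": pr.tau_syn, "delay": pr.delay,
                "connections": pr.connections.tolist(),
                "post_compartments": None if pr.post_compartments is None
                else np.asarray(pr.post_compartments).tolist(),
            }
            for pr in net.projections
        ],
        "backgrounds": [
            {"target": b.target, "rate": b.rate, "weight": b.weight,
             "e_syn": b.e_syn, "tau_syn": b.tau_syn}
            for b in net.backgrounds
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_network_json(path) -> NetworkModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema") != "isnsim-network-v1":
        raise SchemaError(f"{path}: not an isnsim network document")
    pops = []
    for p in doc["populations"]:
        pops.append(Population(
            p["name"], p["size"], p["model"], _params_from_dict(p["params"]),
            role=p["role"],
            positions=None if p["positions"] is None else np.asarray(p["positions"]),
            detailed={int(k): _params_from_dict({"type": "CableModel", **v})
                      for k, v in p.get("detailed", {}).items()},
        ))
    projs = []
    for pr in doc["projections"]:
        projs.append(Projection(
            pr["pre"], pr["post"], pr["p"], pr["weight"], pr["e_syn"],
            pr["tau_syn"], pr["delay"],
            np.asarray(pr["connections"], dtype=int).reshape(-1, 2),
            None if pr.get("post_compartments") is None
            else np.asarray(pr["post_compartments"], dtype=int),
        ))
    bgs = [BackgroundInput(**b) for b in doc["backgrounds"]]
    return NetworkModel(pops, projs, bgs, seed=doc.get("seed", 0),
                        meta=doc.get("meta", {}))


# ---------------------------------------------------------------------------
# spikes and traces
# ---------------------------------------------------------------------------

def write_spikes_text(spikes: SpikeData, path) -> None:
    """Two columns: time (ms), global cell id."""
    with open(path, "w") as fh:
        fh.write(f"# duration_ms {spikes.duration}\n")
        fh.write(f"# populations {json.dumps(spikes.pop_slices)}\n")
        for t, i in zip(spikes.times, spikes.ids):
            fh.write(f"{t:.6f} {int(i)}\n")


def read_spikes_text(path) -> SpikeData:
    duration, pop_slices = 0.0, {}
    times, ids = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("# duration_ms"):
                duration = float(line.split()[-1])
            elif line.startswith("# populations"):
                pop_slices = {k: tuple(v) for k, v in
                              json.loads(line.split(None, 2)[2]).items()}
            elif line and not line.startswith("#"):
                a, b = line.split()
                times.append(float(a)); ids.append(int(b))
    return SpikeData(np.asarray(times), np.asarray(ids, dtype=int), duration, pop_slices)


def write_spikes_h5(spikes: SpikeData, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("times", data=spikes.times)
        fh.create_dataset("ids", data=spikes.ids)
        fh.attrs["duration_ms"] = spikes.duration
        fh.attrs["pop_slices"] = json.dumps(spikes.pop_slices)


def read_spikes_h5(path) -> SpikeData:
    with h5py.File(path, "r") as fh:
        return SpikeData(
            fh["times"][:], fh["ids"][:], float(fh.attrs["duration_ms"]),
            {k: tuple(v) for k, v in json.loads(fh.attrs["pop_slices"]).items()},
        )


def write_traces_h5(trace: TraceData, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("times", data=trace.times)
        fh.create_dataset("values", data=trace.values)
        fh.attrs["name"] = trace.name
        fh.attrs["unit"] = trace.unit
        fh.attrs["targets"] = json.dumps([list(t) for t in trace.targets])


def read_traces_h5(path) -> TraceData:
    with h5py.File(path, "r") as fh:
        return TraceData(
            str(fh.attrs["name"]), str(fh.attrs["unit"]),
            fh["times"][:], fh["values"][:],
            [tuple(t) for t in json.loads(fh.attrs["targets"])],
        )


def write_traces_csv(trace: TraceData, path) -> None:
    import pandas as pd

    cols = {"time_ms": trace.times}
    for i, tgt in enumerate(trace.targets):
        cols[f"{tgt[0]}_{tgt[1]}_{tgt[2]}_{trace.unit}"] = trace.values[:, i]
    pd.DataFrame(cols).to_csv(path, index=False)


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: config must be a YAML mapping")
    return doc
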