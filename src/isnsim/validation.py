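"""Declarative model validation.

Expected emergent properties of a model (spike times, resting membrane
potential, spike count, total membrane area) are written down in small
YAML documents together with per-observable tolerances; a runner
executes the model, measures the observables and reports pass/fail per
observable. The schema is this package's own YAML dialect (documented
below); it is inspired by, but not byte-compatible with, the
expected-properties / test-spec file pairs used for continuous model
validation on public model-sharing platforms.

Expected-properties document::

    observables:
      resting_potential: {value: -70.0, unit: mV}
      spike_count:       {value: 4}
      spike_times:       {value: [105.2, 180.0], unit: ms}
      membrane_area:     {value: 4398.2, unit: um^2}

Validation spec document::

    expected: path/to/expected.yaml     # or an inline mapping
    model:                              # what to run / measure
      kind: expif_zero_input            # | ball_and_stick | hh_step
      ...model parameters...
    tolerances:
      resting_potential: 0.5
      spike_times: 1.0
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import CapabilityError, SchemaError
from .engine import SimulationConfig, SpikeData, run
from .model_core import CableModel, ExpIFParams, HHPointParams
from .network import NetworkModel, Population
from .synthetic import StimulusProtocol, make_ball_and_stick, simulate_hh_sweeps

__all__ = [
    "ExpectedProperties",
    "ValidationSpec",
    "ValidationReport",
    "extract_observables",
    "run_validation",
]

KNOWN_OBSERVABLES = ("resting_potential", "spike_times", "spike_count", "membrane_area")


@dataclass
class ExpectedProperties:
    """Named expected observables with values and unit metadata."""

    observables: dict                  # name -> {"value": ..., "unit": ...}

    def __post_init__(self) -> None:
        if not self.observables:
            raise SchemaError("at least one observable is required")
        for name, entry in self.observables.items():
            if not isinstance(entry, dict) or "value" not in entry:
                raise SchemaError(f"observable {name!r} must carry a 'value' field")

    @classmethod
    def from_yaml(cls, source) -> "ExpectedProperties":
        if isinstance(source, (str, Path)):
            with open(source) as fh:
                doc = yaml.safe_load(fh)
        else:
            doc = source
        if not isinstance(doc, dict) or "observables" not in doc:
            raise SchemaError("expected-properties document needs an 'observables' map")
        return cls(doc["observables"])

    def to_yaml(self, path) -> None:
        def _plain(v):
            if isinstance(v, np.ndarray):
                return [float(x) for x in v]
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v
        doc = {
            "observables": {
                k: {kk: _plain(vv) for kk, vv in e.items()}
                for k, e in self.observables.items()
            }
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class ValidationSpec:
    """A pointer to expected properties plus the model under test."""

    expected: ExpectedProperties
    model: dict
    tolerances: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, tol in self.tolerances.items():
            if tol < 0:
                raise SchemaError(f"tolerance for {name!r} must be >= 0")

    @classmethod
    def from_yaml(cls, source, base_dir=None) -> "ValidationSpec":
        if isinstance(source, (str, Path)):
            base_dir = Path(source).parent
            with open(source) as fh:
                doc = yaml.safe_load(fh)
        else:
            doc = source
        if not isinstance(doc, dict):
            raise SchemaError("validation spec must be a mapping")
        for key in ("expected", "model"):
            if key not in doc:
                raise SchemaError(f"validation spec lacks required field {key!r}")
        exp = doc["expected"]
        if isinstance(exp, str):
            path = Path(exp)
            if base_dir is not None and not path.is_absolute():
                path = Path(base_dir) / path
            expected = ExpectedProperties.from_yaml(path)
        else:
            expected = ExpectedProperties.from_yaml(exp)
        return cls(expected, doc["model"], doc.get("tolerances", {}))


def _zero_input_rest_trace(params: ExpIFParams, duration: float = 500.0, dt: float = 0.1):
    pop = Population("cell", 1, "expif", params)
    net = NetworkModel([pop], [], [], seed=0)
    sim = SimulationConfig(dt=dt, duration=duration, seed=0, init_jitter=0.0,
                           record_traces=[("cell", 0)])
    return run(net, sim)


def _model_outputs(model: dict) -> dict:
    """Execute the small model vocabulary of the validation spec."""
    kind = model.get("kind")
    if kind == "expif_zero_input":
        params = ExpIFParams(**model.get("params", {}))
        res = _zero_input_rest_trace(params, duration=float(model.get("duration", 500.0)))
        return {"trace": res.traces, "spikes": res.spikes}
    if kind == "ball_and_stick":
        geo = {k: model[k] for k in ("soma_diam", "dend_len", "dend_diam", "n_comp")
               if k in model}
        return {"cable": make_ball_and_stick(**geo)}
    if kind == "hh_step":
        params = HHPointParams(**model.get("params", {}))
        prot = StimulusProtocol(
            amplitudes=(float(model.get("amplitude", 200.0)),),
            onset=float(model.get("onset", 100.0)),
            duration=float(model.get("duration", 1000.0)),
            total=float(model.get("total", 1300.0)),
        )
        times, traces = simulate_hh_sweeps(params, prot, dt=float(model.get("dt", 0.05)))
        from .tuning import extract_features

        feats = extract_features(times, traces, prot)
        return {"features": feats}
    raise SchemaError(f"unknown model kind {kind!r} in validation spec")


def extract_observables(outputs: dict, names) -> dict:
    """Measure the requested observables from simulation outputs.

    ``outputs`` may contain a zero-input voltage ``trace`` (TraceData),
    ``spikes`` (SpikeData), a ``cable`` (CableModel) and/or tuning
    ``features``. Resting potential is the mean voltage over the final
    20% of the zero-input trace; membrane area is the cable's analytic
    compartment-area sum.
    """
    out = {}
    for name in names:
        if name == "resting_potential":
            trace = outputs.get("trace")
            if trace is None:
                raise CapabilityError("resting_potential requires a recorded voltage trace")
            n = trace.values.shape[0]
            out[name] = float(trace.values[int(0.8 * n):, 0].mean())
        elif name == "spike_times":
            if "features" in outputs:
                out[name] = np.concatenate(outputs["features"].spike_times)
            elif isinstance(outputs.get("spikes"), SpikeData):
                out[name] = outputs["spikes"].times
            else:
                raise CapabilityError("spike_times requires spike recording")
        elif name == "spike_count":
            if "features" in outputs:
                out[name] = int(outputs["features"].spike_counts.sum())
            elif isinstance(outputs.get("spikes"), SpikeData):
                out[name] = int(outputs["spikes"].n_spikes)
            else:
                raise CapabilityError("spike_count requires spike recording")
        elif name == "membrane_area":
            cable = outputs.get("cable")
            if not isinstance(cable, CableModel):
                raise CapabilityError("membrane_area requires a cable model")
            out[name] = cable.total_area_um2()
        else:
            raise CapabilityError(f"unknown observable {name!r}")
    return out


@dataclass
class ObservableResult:
    name: str
    expected: object
    measured: object
    tolerance: float
    passed: bool
    detail: str = ""


@dataclass
class ValidationReport:
    results: list
    passed: bool

    def failing(self):
        return [r for r in self.results if not r.passed]


def _compare(name, expected, measured, tol) -> ObservableResult:
    if isinstance(expected, (list, tuple, np.ndarray)):
        e = np.asarray(expected, dtype=float)
        m = np.asarray(measured, dtype=float)
        if len(e) != len(m):
            return ObservableResult(name, e, m, tol, False,
                                    f"count mismatch: expected {len(e)}, got {len(m)}")
        dev = float(np.max(np.abs(e - m))) if len(e) else 0.0
        return ObservableResult(name, e, m, tol, dev <= tol,
                                f"max abs deviation {dev:.6g}")
    dev = abs(float(expected) - float(measured))
    return ObservableResult(name, expected, measured, tol, dev <= tol,
                            f"abs deviation {dev:.6g}")


def run_validation(spec: ValidationSpec, outputs: dict | None = None) -> ValidationReport:
    """Compare measured observables against expectations.

    A scalar passes iff |measured - expected| <= tolerance; a spike-time
    list passes iff the counts agree and the maximum absolute time
    difference is within tolerance. The report is a pure function of
    (outputs, spec); if ``outputs`` is omitted they are produced by
    running ``spec.model``.
    """
    if outputs is None:
        outputs = _model_outputs(spec.model)
    names = list(spec.expected.observables)
    measured = extract_observables(outputs, names)
    results = [
        _compare(name, spec.expected.observables[name]["value"], measured[name],
                 float(spec.tolerances.get(name, 0.0)))
        for name in names
    ]
    return ValidationReport(results, passed=all(r.passed for r in results))
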