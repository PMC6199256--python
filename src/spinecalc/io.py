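"""Configuration files, result writers and the run manifest.

Config files are TOML or JSON with up to four sections — ``[geometry]``,
``[model]``, ``[solver]``, ``[scenario]`` — whose keys mirror the
corresponding dataclass fields (SpineParams, ModelConfig, SolverConfig,
ScenarioConfig) in the units those fields document (µm, µM, s, mol s⁻¹,
µm s⁻¹ …). Unspecified fields take the published defaults; unknown keys are
hard errors so typos cannot silently revert a parameter to its default.

Outputs are plain text with fixed float formatting, so identical inputs
produce byte-identical files; the manifest records a checksum per file and
the fully resolved configuration needed to re-run bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from pathlib import Path

from .config import MembraneComposition, ModelConfig
from .params import SpineParams, validate_params
from .scenarios import DetectionCriterion, ScenarioConfig, ScenarioResult
from .solver import SolverConfig

FLOAT_FMT = "%.10g"
_SECTIONS = ("geometry", "model", "solver", "scenario")


class ConfigError(ValueError):
    pass


def _build(cls, section: dict, name: str, extra: dict | None = None):
    known = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in section.items():
        if key not in known:
            raise ConfigError(f"unknown key {key!r} in [{name}]")
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    if extra:
        kwargs.update(extra)
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid [{name}] section: {exc}") from exc


def load_config(path):
    """Parse a TOML/JSON config into the four configuration objects."""
    path = Path(path)
    raw = path.read_bytes()
    if path.suffix.lower() == ".json":
        data = json.loads(raw or b"{}")
    else:
        data = tomllib.loads(raw.decode())
    if not isinstance(data, dict):
        raise ConfigError("config root must be a table/object")
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown section(s): {sorted(unknown)}")

    geometry = _build(SpineParams, data.get("geometry", {}), "geometry")
    validate_params(geometry)

    msec = dict(data.get("model", {}))
    comp = None
    if "composition" in msec:
        comp = _build(MembraneComposition, msec.pop("composition"),
                      "model.composition")
    model = _build(ModelConfig, msec, "model",
                   extra={"composition": comp} if comp else None)
    solver = _build(SolverConfig, data.get("solver", {}), "solver")

    ssec = dict(data.get("scenario", {}))
    det = None
    if "detection" in ssec:
        det = _build(DetectionCriterion, ssec.pop("detection"),
                     "scenario.detection")
    scenario = _build(ScenarioConfig, ssec, "scenario",
                      extra={"detection": det} if det else None)
    return geometry, model, solver, scenario


def config_snapshot(geometry, model, solver, scenario) -> dict:
    """Fully resolved configuration; sufficient to re-run bit-identically."""
    def as_dict(obj):
        d = dataclasses.asdict(obj)
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in d.items()}

    return {
        "geometry": as_dict(geometry),
        "model": model.to_dict(),
        "solver": as_dict(solver),
        "scenario": as_dict(scenario),
    }


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _fmt(x) -> str:
    return FLOAT_FMT % float(x)


def write_trace_csv(result, path):
    """ROI traces of one simulation as CSV."""
    tr = result.traces
    cols = ["time_s", "head_uM", "neck_uM", "dendrite_uM"]
    data = [result.times, tr["head"], tr["neck"], tr["dendrite_roi"]]
    if "er_spine" in tr:
        cols.append("er_spine_uM")
        data.append(tr["er_spine"])
    cols.append("ip3_head_uM")
    data.append(tr["ip3_head"])
    with open(path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        for row in zip(*data):
            fh.write(",".join(_fmt(x) for x in row) + "\n")


def write_ledger_csv(result, path):
    names = sorted(result.ledger)
    with open(path, "w") as fh:
        fh.write("time_s," + ",".join(f"{n}_mol" for n in names)
                 + ",total_ca_mol\n")
        for i, t in enumerate(result.times):
            fh.write(_fmt(t) + ","
                     + ",".join(_fmt(result.ledger[n][i]) for n in names)
                     + "," + _fmt(result.total_ca[i]) + "\n")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_outputs(result: ScenarioResult, outdir, snapshot: dict | None = None,
                  version: str = "unknown") -> dict:
    """Write traces, ledgers and metrics of a scenario; return the manifest.

    The manifest lists every written file with its sha256 checksum and the
    configuration snapshot.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for run in result.runs:
        tag = ("L%.3f" % run.spine_er_length).replace(".", "p")
        tp = outdir / f"trace_{tag}.csv"
        write_trace_csv(run.result, tp)
        lp = outdir / f"ledger_{tag}.csv"
        write_ledger_csv(run.result, lp)
        files += [tp, lp]

    metrics = {
        "transition_length_um": result.transition_length,
        "runs": [
            {
                "spine_er_length_um": r.spine_er_length,
                "peaks_uM": r.peaks,
                "peak_times_s": r.peak_times,
                "dendritic_signal": r.detected,
                "onset_s": r.onset,
                "released_mol": r.result.released,
            }
            for r in result.runs
        ],
    }
    metrics.update(result.metrics)
    mp = outdir / "metrics.json"
    mp.write_text(json.dumps(metrics, indent=1, sort_keys=True))
    files.append(mp)

    manifest = {
        "software": {"name": "spinecalc", "version": version},
        "config": snapshot or {},
        "files": {f.name: _checksum(f) for f in files},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
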