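"""Configuration files, run manifests, and trace serialization.

Config files are YAML or TOML with up to four sections::

    model:                      # synaptic models
      N: 50000
      n: 5                      # default 1 (homogeneous)
      q1: 0.5
      qn: 0.01                  # default q1
      F: 1.0                    # optional coding-level factor
    run:
      T: 500                    # horizon (memories)
      n_real: 500               # Monte-Carlo realizations (simulate only)
    protocol:                   # neuronal transfer protocol (optional)
      f: 0.1
      theta_low: -28.5
      theta_high: 28.5
      M: 10
      q: 1.0
    neuronal:                   # neuronal chain geometry (optional)
      n_stages: 3
      N_neurons: 200

``model: {N, q}`` is accepted as homogeneous shorthand. Unknown keys are
rejected. Traces are written as CSV with the fixed column order
``time, stage, signal_mean, signal_sd, snr, snr_combined`` plus a JSON
manifest (config snapshot, master seed, version, file inventory) that
suffices to reproduce the run exactly.
"""

from __future__ import annotations

import datetime as _dt
import json
import tomllib
from dataclasses import dataclass, field as _field
from pathlib import Path

import yaml

from .config import ConfigError, ModelConfig
from .neuronal import TransferProtocol

__all__ = ["ConfigFileError", "load_config", "RunManifest", "write_outputs", "version"]

CSV_COLUMNS = ["time", "stage", "signal_mean", "signal_sd", "snr", "snr_combined"]

_SECTIONS = {"model", "run", "protocol", "neuronal"}
_MODEL_KEYS = {"N", "n", "q", "q1", "qn", "F"}
_RUN_KEYS = {"T", "n_real", "points_per_decade", "t_max"}
_PROTOCOL_KEYS = {"f", "theta_low", "theta_high", "M", "q"}
_NEURONAL_KEYS = {"n_stages", "N_neurons", "q1"}


class ConfigFileError(ValueError):
    """The file could not be parsed as a config document."""


def version() -> str:
    try:
        from importlib.metadata import version as _v

        return _v("memsim")
    except Exception:
        return "unknown"


def _reject_unknown(section: str, data: dict, allowed: set) -> None:
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section '{section}' "
            f"(allowed: {sorted(allowed)})"
        )


def load_config(path: str | Path) -> dict:
    """Parse and validate a config file into a bundle dict.

    Returns ``{"model": ModelConfig | None, "run": dict,
    "protocol": TransferProtocol | None, "neuronal": dict | None}``.
    Raises ``FileNotFoundError`` (missing file), :class:`ConfigFileError`
    (unparseable) or :class:`memsim.config.ConfigError` (bad values) —
    three distinct, messaged failure modes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    try:
        if path.suffix == ".toml":
            raw = tomllib.loads(text)
        else:
            raw = yaml.safe_load(text)
    except (yaml.YAMLError, tomllib.TOMLDecodeError) as e:
        raise ConfigFileError(f"could not parse {path}: {e}") from e
    if not isinstance(raw, dict):
        raise ConfigFileError(f"{path} does not contain a mapping at top level")
    _reject_unknown("(top level)", raw, _SECTIONS)

    bundle: dict = {"model": None, "run": {}, "protocol": None, "neuronal": None}
    if "model" in raw:
        m = dict(raw["model"])
        _reject_unknown("model", m, _MODEL_KEYS)
        if "q" in m:  # homogeneous shorthand
            if "q1" in m or "qn" in m:
                raise ConfigError("give either 'q' (homogeneous) or 'q1'/'qn', not both")
            m["q1"] = m["qn"] = m.pop("q")
        m.setdefault("n", 1)
        m.setdefault("qn", m.get("q1"))
        if m.get("q1") is None or m.get("N") is None:
            raise ConfigError("model section needs at least N and q (or q1/qn)")
        bundle["model"] = ModelConfig(N=int(m["N"]), n=int(m["n"]),
                                      q1=float(m["q1"]), qn=float(m["qn"]),
                                      F=float(m.get("F", 1.0)))
    if "run" in raw:
        r = dict(raw["run"])
        _reject_unknown("run", r, _RUN_KEYS)
        bundle["run"] = r
    if "protocol" in raw:
        p = dict(raw["protocol"])
        _reject_unknown("protocol", p, _PROTOCOL_KEYS)
        bundle["protocol"] = TransferProtocol(
            f=float(p["f"]), theta_low=float(p["theta_low"]),
            theta_high=float(p["theta_high"]), M=int(p["M"]),
            q=float(p.get("q", 1.0)),
        )
    if "neuronal" in raw:
        nsec = dict(raw["neuronal"])
        _reject_unknown("neuronal", nsec, _NEURONAL_KEYS)
        bundle["neuronal"] = {k: (float(v) if k == "q1" else int(v))
                              for k, v in nsec.items()}
    return bundle


def bundle_to_dict(bundle: dict) -> dict:
    """Normalized JSON-serializable snapshot of a config bundle."""
    out: dict = {}
    if bundle.get("model") is not None:
        out["model"] = bundle["model"].to_dict()
    if bundle.get("run"):
        out["run"] = dict(bundle["run"])
    if bundle.get("protocol") is not None:
        p = bundle["protocol"]
        out["protocol"] = {"f": p.f, "theta_low": p.theta_low,
                           "theta_high": p.theta_high, "M": p.M, "q": p.q}
    if bundle.get("neuronal"):
        out["neuronal"] = dict(bundle["neuronal"])
    return out


@dataclass
class RunManifest:
    """Everything needed to reproduce a run: config snapshot + master seed."""

    config: dict
    seed: int | None
    command: str = ""
    tool_version: str = _field(default_factory=version)
    timestamp: str = _field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )
    files: list = _field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "seed": self.seed,
            "command": self.command,
            "tool_version": self.tool_version,
            "timestamp": self.timestamp,
            "files": self.files,
        }


def write_outputs(trace, manifest: RunManifest, out_dir: str | Path,
                  force: bool = False) -> list[dict]:
    """Write ``trace.csv`` + ``manifest.json`` to ``out_dir``.

    ``trace`` is any object with ``to_dataframe()`` producing the shared
    schema (or ``None`` for a header-only CSV). Existing files are only
    overwritten with ``force=True``. Returns the file inventory
    ``[{"path", "bytes"}, ...]`` (also recorded in the manifest).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / "trace.csv"
    json_path = out / "manifest.json"
    for p in (csv_path, json_path):
        if p.exists() and not force:
            raise FileExistsError(f"{p} exists; pass force=True (--force) to overwrite")
    if trace is None:
        csv_path.write_text(",".join(CSV_COLUMNS) + "\n")
    else:
        df = trace.to_dataframe()[CSV_COLUMNS]
        df.to_csv(csv_path, index=False, float_format="%.10g")
    # the manifest lists the data files it describes; its own size is
    # reported in the returned inventory only (it cannot contain itself)
    manifest.files = [{"path": csv_path.name, "bytes": csv_path.stat().st_size}]
    json_path.write_text(json.dumps(manifest.to_dict(), indent=2) + "\n")
    return manifest.files + [{"path": json_path.name,
                              "bytes": json_path.stat().st_size}]
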