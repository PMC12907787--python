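"""Array container I/O, configuration files, and run reports.

Arrays are stored as ``.npy`` (a documented shape/dtype header + raw data)
with a JSON sidecar (``<name>.json``) carrying provenance: label, geometry,
seed, config hash, and artifact version. Configurations are INI files with
one section per module.
"""

from __future__ import annotations

import configparser
import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np

ARTIFACT_VERSION = "0.1.0"

log = logging.getLogger("dectbench")


def setup_logging(out_dir: Path | None = None, verbosity: int = 1) -> None:
    level = {0: logging.WARNING, 1: logging.INFO}.get(verbosity, logging.DEBUG)
    handlers = [logging.StreamHandler()]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(out_dir / "run.log"))
    logging.basicConfig(level=level, handlers=handlers, force=True,
                        format="%(asctime)s %(levelname)s %(name)s: %(message)s")


def _jsonable(value):
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, dict):
        return {k: _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    return value


def save_array(path, array: np.ndarray, **meta) -> Path:
    """Write ``<path>.npy`` plus a ``<path>.json`` provenance sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(path.with_suffix(".npy"), np.asarray(array))
    meta = dict(meta)
    meta.setdefault("artifact_version", ARTIFACT_VERSION)
    meta["shape"] = list(np.asarray(array).shape)
    meta["dtype"] = str(np.asarray(array).dtype)
    path.with_suffix(".json").write_text(json.dumps(_jsonable(meta), indent=1))
    return path.with_suffix(".npy")


def load_array(path):
    """Read an array container; returns (array, sidecar dict)."""
    path = Path(path)
    arr = np.load(path.with_suffix(".npy"))
    sidecar = {}
    if path.with_suffix(".json").exists():
        sidecar = json.loads(path.with_suffix(".json").read_text())
    return arr, sidecar


def write_json(path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(payload), indent=1, sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# Config files (INI, one section per module)
# ---------------------------------------------------------------------------

def config_to_ini(config, path) -> Path:
    """Serialize a dataclass config; fields map to sections via its
    ``SECTIONS`` attribute ({section: [field, ...]})."""
    cp = configparser.ConfigParser()
    values = dataclasses.asdict(config)
    for section, names in config.SECTIONS.items():
        cp[section] = {}
        for name in names:
            v = values[name]
            if isinstance(v, (tuple, list)):
                v = " ".join(str(x) for x in v)
            cp[section][name] = str(v)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        cp.write(fh)
    return path


def config_from_ini(cls, path):
    """Parse an INI file back into the dataclass ``cls``; missing keys keep
    defaults, unknown keys raise."""
    cp = configparser.ConfigParser()
    read = cp.read(path)
    if not read:
        raise FileNotFoundError(path)
    fields = {f.name: f for f in dataclasses.fields(cls)}
    known = {n for names in cls.SECTIONS.values() for n in names}
    kwargs = {}
    for section in cp.sections():
        for key, raw in cp[section].items():
            if key not in known or key not in fields:
                raise KeyError(f"unknown config key {key!r} in [{section}]")
            kwargs[key] = _coerce(raw, fields[key].type, getattr(cls, key, None))
    return cls(**kwargs)


def _coerce(raw: str, annotation, default):
    raw = raw.strip()
    if raw.lower() in ("none", ""):
        return None
    ref = default
    if isinstance(ref, bool) or annotation == "bool":
        return raw.lower() in ("1", "true", "yes", "on")
    if isinstance(ref, (tuple, list)):
        parts = raw.replace(",", " ").split()
        return tuple(float(p) for p in parts)
    if isinstance(ref, int) and not isinstance(ref, bool):
        return int(float(raw))
    if isinstance(ref, float):
        return float(raw)
    if ref is None:
        for cast in (int, float):
            try:
                return cast(raw)
            except ValueError:
                pass
    return raw


def config_hash(config) -> str:
    payload = json.dumps(_jsonable(dataclasses.asdict(config)), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
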