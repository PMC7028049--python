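"""Configuration files, result serialisation and run manifests.

Configs are YAML with a fixed schema; unknown keys are rejected so typos
cannot silently fall back to defaults.  Exactly one of the two parameter
sections (dimensional / nondimensional) must be present.  Results are
written as plain CSV and columnar text so that runs diff cleanly and
re-running a config with the same seed reproduces identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import ClimateRamp, ConstantRainfall, DimParams, NondimParams, nondimensionalize
from .patterns import PulseConfiguration, random_pattern, regular_pattern, DEFAULT_TARGET_GAP
from .pde import FieldState, resolve_dx
from .scenarios import RemovalPolicy

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "write_result",
    "write_field",
    "read_field",
    "write_trajectory",
]


class ConfigError(ValueError):
    pass


_SCHEMA = {
    "params": {"nondimensional": {"a", "m", "D", "s"},
               "dimensional": {"A", "L", "R", "J", "M", "S", "D_W", "D_V"}},
    "geometry": {"domain_length", "target_gap", "bc", "dx"},
    "pattern": {"kind", "n", "min_gap", "seed", "positions"},
    "ramp": {"a_start", "a_end", "T", "constant", "t_end"},
    "engine": None,
    "policy": {"kind", "trigger", "value", "k", "index"},
    "output": None,
    "seed": None,
    "profile": None,
}


@dataclass
class RunConfig:
    """Validated, fully defaulted run configuration."""

    params: NondimParams
    dim_params: DimParams | None
    cfg: PulseConfiguration
    ramp: ClimateRamp | ConstantRainfall
    t_end: float
    engine: str
    policy: RemovalPolicy
    dx: float
    seed: int
    profile: str
    raw: dict = dc_field(default_factory=dict)


def _check_keys(section: str, data: dict, allowed) -> None:
    unknown = set(data) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section {section!r}")


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    _check_keys("<top level>", raw, _SCHEMA)

    pblock = raw.get("params", {})
    _check_keys("params", pblock, {"nondimensional", "dimensional"})
    if ("nondimensional" in pblock) == ("dimensional" in pblock):
        raise ConfigError("exactly one of params.nondimensional / params.dimensional is required")
    dim = None
    if "dimensional" in pblock:
        _check_keys("params.dimensional", pblock["dimensional"], _SCHEMA["params"]["dimensional"])
        dim = DimParams(**pblock["dimensional"])
        params, _scales = nondimensionalize(dim)
    else:
        _check_keys("params.nondimensional", pblock["nondimensional"], _SCHEMA["params"]["nondimensional"])
        params = NondimParams(**pblock["nondimensional"])

    geo = raw.get("geometry", {})
    _check_keys("geometry", geo, _SCHEMA["geometry"])
    pat = raw.get("pattern", {})
    _check_keys("pattern", pat, _SCHEMA["pattern"])
    n = int(pat.get("n", 8))
    bc = geo.get("bc", "periodic")
    domain_length = geo.get("domain_length")
    if domain_length is None:
        domain_length = n * float(geo.get("target_gap", DEFAULT_TARGET_GAP))

    profile = raw.get("profile", "smoke")
    if profile not in ("smoke", "paper"):
        raise ConfigError(f"profile must be smoke or paper, got {profile!r}")
    dx = geo.get("dx")
    if dx is None:
        dx = resolve_dx(params, None) * (2.5 if profile == "smoke" else 1.0)

    seed = raw.get("seed")
    kind = pat.get("kind", "regular")
    if kind == "regular":
        cfg = regular_pattern(n, domain_length, bc=bc)
    elif kind == "random":
        if seed is None:
            raise ConfigError("a top-level seed is mandatory for random patterns")
        cfg = random_pattern(n, domain_length, min_gap=pat.get("min_gap"), seed=int(seed), bc=bc)
    elif kind == "explicit":
        cfg = PulseConfiguration(domain_length=domain_length,
                                 positions=np.asarray(pat["positions"], dtype=float), bc=bc)
    else:
        raise ConfigError(f"unknown pattern kind {kind!r}")

    rblock = raw.get("ramp", {})
    _check_keys("ramp", rblock, _SCHEMA["ramp"])
    if "constant" in rblock:
        ramp = ConstantRainfall(float(rblock["constant"]))
        t_end = float(rblock.get("t_end", 100.0))
    else:
        ramp = ClimateRamp(
            a_start=float(rblock.get("a_start", params.a)),
            a_end=float(rblock.get("a_end", 0.0)),
            T=float(rblock.get("T", 1e5)),
        )
        t_end = float(rblock.get("t_end", ramp.T))

    pol = raw.get("policy", {})
    _check_keys("policy", pol, _SCHEMA["policy"])
    trigger = None
    if "trigger" in pol:
        trigger = (pol["trigger"], float(pol.get("value", 0.02)))
    policy = RemovalPolicy(kind=pol.get("kind", "none"), trigger=trigger,
                           index=pol.get("index"), k=int(pol.get("k", 3)))

    return RunConfig(
        params=params, dim_params=dim, cfg=cfg, ramp=ramp, t_end=t_end,
        engine=raw.get("engine", "hybrid"), policy=policy, dx=float(dx),
        seed=int(seed if seed is not None else 0), profile=profile, raw=raw,
    )


# ---------------------------------------------------------------------------
# result writing

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_field(f: FieldState, path) -> None:
    """Columnar text snapshot (x, w, v) with full precision."""
    header = f"drypatch field t={f.t!r} a={f.a_now!r} bc={f.bc} l={f.domain_length!r}"
    np.savetxt(path, np.column_stack([f.x, f.w, f.v]), header=header, fmt="%.17g")


def read_field(path) -> FieldState:
    with open(path) as fh:
        header = fh.readline().lstrip("# ").split()
    fields = dict(tok.split("=", 1) for tok in header[2:])
    data = np.loadtxt(path)
    return FieldState(
        x=data[:, 0], w=data[:, 1], v=data[:, 2],
        t=float(fields["t"]), a_now=float(fields["a"]),
        bc=fields["bc"], domain_length=float(fields["l"]),
    )


def write_trajectory(traj, path) -> None:
    """Pulse trajectory as CSV: t, a, p_1..p_N."""
    n = traj.positions.shape[1]
    df = pd.DataFrame(traj.positions, columns=[f"p_{j + 1}" for j in range(n)])
    df.insert(0, "a", traj.a_values)
    df.insert(0, "t", traj.ts)
    df.to_csv(path, index=False, float_format="%.12g")


def write_result(result, out_dir, config: dict | None = None, seed: int | None = None) -> dict:
    """Write a scenario/simulation result and return its manifest.

    Emits series.csv, events.csv, a final-state artifact, and
    manifest.json listing every file with a content hash plus the full
    configuration and seed needed to reproduce the run byte-for-byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    series = getattr(result, "series", None)
    if series is not None and len(series):
        path = out / "series.csv"
        series.to_csv(path, index=False, float_format="%.12g")
        artifacts["series.csv"] = _sha256(path)

    events = getattr(result, "events", None)
    if events is not None:
        path = out / "events.csv"
        rows = [
            {
                "t_event": e.t_event, "a_event": e.a_event, "n_before": e.n_before,
                "n_after": e.n_after, "lost_indices": ";".join(map(str, e.lost_indices)),
                "type": e.type, "manual": e.manual,
            }
            for e in events
        ]
        pd.DataFrame(rows, columns=["t_event", "a_event", "n_before", "n_after",
                                    "lost_indices", "type", "manual"]).to_csv(
            path, index=False, float_format="%.12g")
        artifacts["events.csv"] = _sha256(path)

    final_field = getattr(result, "final_field", None) or getattr(result, "final", None)
    if isinstance(final_field, FieldState):
        path = out / "final_state.txt"
        write_field(final_field, path)
        artifacts["final_state.txt"] = _sha256(path)

    manifest = {
        "artifacts": artifacts,
        "seed": seed,
        "config": config,
        "engine": getattr(result, "engine", None),
        "version": _version(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=_jsonable))
    return manifest


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        return asdict(obj)
    return str(obj)


def _version() -> str:
    from . import __version__

    return __version__
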