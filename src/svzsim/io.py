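"""Configuration files and result archives.

Run configuration is a TOML (or JSON) file with ``domain``,
``parameters``, ``numerics``, ``campaign`` and ``output`` sections;
unknown keys are a hard error so typos cannot silently fall back to
defaults.  Gridded results go to HDF5 (every saved frame, readouts,
solver statistics and the fully resolved configuration for provenance);
time series and campaign tables go to CSV.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .geometry import Box, DomainSpec, build_grid
from .model import PARAM_NAMES, ModelParameters, reference_parameters
from .numerics import NumericsConfig
from .simulation import SimulationResult, TimeSeries

ARCHIVE_VERSION = 1


class ConfigError(ValueError):
    pass


class ArchiveError(ValueError):
    pass


_DOMAIN_KEYS = {"ob_box", "rms_box", "svz_box", "ob_centre",
                "centre_square_side", "grid_spacing", "length_unit_mm"}
_NUMERICS_KEYS = {"tolerance", "t_final", "save_every", "max_nfev",
                  "limiter", "blowup_factor", "method"}
_CAMPAIGN_KEYS = {"kind", "n", "fraction", "distribution", "low", "high",
                  "seed", "rounds", "samples_per_round", "verification_n"}
_TOP_KEYS = {"domain", "parameters", "numerics", "campaign", "output", "seed"}


@dataclass
class RunConfig:
    domain: DomainSpec
    parameters: ModelParameters
    numerics: NumericsConfig
    campaign: dict = field(default_factory=dict)
    output: dict = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        d = self.domain
        return {
            "domain": {
                "ob_box": [d.ob_box.x0, d.ob_box.x1, d.ob_box.y0, d.ob_box.y1],
                "rms_box": [d.rms_box.x0, d.rms_box.x1,
                            d.rms_box.y0, d.rms_box.y1],
                "svz_box": [d.svz_box.x0, d.svz_box.x1,
                            d.svz_box.y0, d.svz_box.y1],
                "ob_centre": list(d.ob_centre),
                "centre_square_side": d.centre_square_side,
                "grid_spacing": d.grid_spacing,
                "length_unit_mm": d.length_unit_mm,
            },
            "parameters": self.parameters.to_dict(),
            "numerics": {
                "tolerance": self.numerics.tolerance,
                "t_final": self.numerics.t_final,
                "save_every": self.numerics.save_every,
                "max_nfev": self.numerics.max_nfev,
                "limiter": self.numerics.limiter,
                "blowup_factor": self.numerics.blowup_factor,
                "method": self.numerics.method,
            },
            "campaign": self.campaign,
            "output": self.output,
            "seed": self.seed,
        }


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")


def _domain_from_dict(d: dict) -> DomainSpec:
    _check_keys(d, _DOMAIN_KEYS, "domain")
    kw = {}
    for name in ("ob_box", "rms_box", "svz_box"):
        if name in d:
            kw[name] = Box(*map(float, d[name]))
    if "ob_centre" in d:
        kw["ob_centre"] = tuple(map(float, d["ob_centre"]))
    for name in ("centre_square_side", "grid_spacing", "length_unit_mm"):
        if name in d:
            kw[name] = float(d[name])
    return DomainSpec(**kw)


def load_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    if path.suffix == ".json":
        raw = json.loads(path.read_text())
    else:
        raw = tomllib.loads(path.read_text())
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    _check_keys(raw, _TOP_KEYS, "config")
    domain = _domain_from_dict(raw.get("domain", {}))
    pd = raw.get("parameters", {})
    if isinstance(pd, str):
        params = load_parameters(pd)
    else:
        _check_keys(pd, set(PARAM_NAMES), "parameters")
        if pd:
            base = reference_parameters().to_dict()
            base.update({k: float(v) for k, v in pd.items()})
            params = ModelParameters(**base)
        else:
            params = reference_parameters()
    nd = dict(raw.get("numerics", {}))
    _check_keys(nd, _NUMERICS_KEYS, "numerics")
    numerics = NumericsConfig(**nd)
    camp = raw.get("campaign", {})
    _check_keys(camp, _CAMPAIGN_KEYS, "campaign")
    return RunConfig(domain=domain, parameters=params, numerics=numerics,
                     campaign=dict(camp), output=dict(raw.get("output", {})),
                     seed=int(raw.get("seed", 0)))


def load_parameters(path) -> ModelParameters:
    path = Path(path)
    if path.suffix == ".json":
        raw = json.loads(path.read_text())
    else:
        raw = tomllib.loads(path.read_text())
    table = raw.get("parameters", raw)
    _check_keys(table, set(PARAM_NAMES), str(path))
    missing = set(PARAM_NAMES) - set(table)
    if missing:
        raise ConfigError(f"missing parameters in {path}: {sorted(missing)}")
    return ModelParameters(**{k: float(v) for k, v in table.items()})


def write_config(cfg: RunConfig, path) -> None:
    path = Path(path)
    d = cfg.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
        return
    lines = [f"seed = {d['seed']}", ""]
    for section in ("domain", "parameters", "numerics", "campaign", "output"):
        body = d[section]
        if not body:
            continue
        lines.append(f"[{section}]")
        for k, v in body.items():
            if isinstance(v, str):
                lines.append(f'{k} = "{v}"')
            elif isinstance(v, (list, tuple)):
                lines.append(f"{k} = {list(v)}")
            elif isinstance(v, bool):
                lines.append(f"{k} = {str(v).lower()}")
            else:
                lines.append(f"{k} = {v}")
        lines.append("")
    path.write_text("\n".join(lines))


# -- result archives ----------------------------------------------------

def write_result(result: SimulationResult, path, seed: int = 0) -> None:
    """Lossless HDF5 archive of a run: frames, readouts, solver stats and
    the resolved configuration."""
    path = Path(path)
    cfg = RunConfig(domain=result.grid.spec, parameters=result.params_used,
                    numerics=result.config, seed=seed)
    with h5py.File(path, "w") as f:
        f.attrs["version"] = ARCHIVE_VERSION
        f.attrs["config_json"] = json.dumps(cfg.to_dict())
        f.attrs["failure_flag"] = bool(result.failure_flag)
        f.attrs["solver_stats"] = json.dumps(
            {k: (v if not isinstance(v, np.generic) else v.item())
             for k, v in result.solver_stats.items()})
        f.create_dataset("times", data=result.times)
        grp = f.create_group("fields")
        for k, name in enumerate(("n_B", "n_C", "n_A", "n_N", "f_A")):
            grp.create_dataset(name, data=result.states[:, k, :])
        ro = f.create_group("readouts")
        for name, ts in result.readouts.items():
            g = ro.create_group(name)
            g.create_dataset("times", data=ts.times)
            g.create_dataset("values", data=ts.values)


def read_result(path) -> SimulationResult:
    path = Path(path)
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("version", -1))
        if version != ARCHIVE_VERSION:
            raise ArchiveError(
                f"archive version {version} not supported "
                f"(expected {ARCHIVE_VERSION}); no migration path")
        cfg = config_from_dict(json.loads(f.attrs["config_json"]))
        times = f["times"][...]
        frames = []
        for name in ("n_B", "n_C", "n_A", "n_N", "f_A"):
            if name not in f["fields"]:
                raise ArchiveError(f"archive missing field group '{name}'")
            frames.append(f["fields"][name][...])
        states = np.stack(frames, axis=1)
        readouts = {}
        for name in f["readouts"]:
            g = f["readouts"][name]
            readouts[name] = TimeSeries(g["times"][...], g["values"][...],
                                        name)
        stats = json.loads(f.attrs["solver_stats"])
        failed = bool(f.attrs["failure_flag"])
    grid = build_grid(cfg.domain)
    from .model import check_constraints

    return SimulationResult(
        times=times, states=states, readouts=readouts, solver_stats=stats,
        failure_flag=failed, params_used=cfg.parameters, grid=grid,
        config=cfg.numerics, constraints=check_constraints(cfg.parameters))


def write_sloppiness(path, surface, report) -> None:
    """HDF5 archive of a sloppiness analysis: training theta matrix and
    zeta^2 vector, the Hessian, and its eigen-decomposition."""
    with h5py.File(path, "w") as f:
        f.attrs["version"] = ARCHIVE_VERSION
        f.attrs["method"] = surface.method
        if surface.holdout_m is not None:
            f.attrs["holdout_m"] = surface.holdout_m
            f.attrs["holdout_n"] = surface.holdout_n
        f.create_dataset("theta_train", data=surface.thetas)
        f.create_dataset("zeta2_train", data=surface.values)
        f.create_dataset("hessian", data=report.hessian)
        f.create_dataset("eigenvalues", data=report.eigenvalues)
        f.create_dataset("eigenvectors", data=report.eigenvectors)
        f.create_dataset("normalized_spectrum",
                         data=report.normalized_spectrum)
        f.attrs["span_orders"] = report.span_orders
        f.attrs["axis_ratio"] = report.axis_ratio
        f.attrs["sloppy"] = bool(report.sloppy)


def readouts_to_csv(result: SimulationResult, path) -> None:
    import pandas as pd

    data = {"time": result.times}
    for name, ts in result.readouts.items():
        data[name] = ts.values
    pd.DataFrame(data).to_csv(path, index=False)
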