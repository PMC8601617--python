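"""Run configuration, deterministic seeding, and tabular persistence.

A run is fully described by a :class:`RunConfig`: the model parameters
(supply, dilution, cost scale, cost-fluctuation scale, community size), the
structural grids (competition/facilitation factors, leakage levels, optional
guild factors), the assembly controls, and the protocol sizes.  Configs
round-trip losslessly through YAML or JSON, every field is validated against
its admissible range, and all randomness flows from one master seed through
spawned child seeds so any individual community or protocol run can be
replayed in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assembly import AssemblyControls

logger = logging.getLogger("commcoal")


@dataclass
class RunConfig:
    # model parameters
    g: float = 1.0
    chi0: float = 0.1
    kappa: float = 2.0
    tau: float = 0.25
    s: int = 60
    m: int = 60
    eps_sigma: float = 0.1
    n_pref_mean: float = 5.0
    leakage_dependent_cost: bool = True
    # structural grids
    leakage_grid: tuple = (0.1, 0.5, 0.9)
    k_grid: tuple = (0.0, 0.5, 0.9)
    n_guilds: int | None = None
    K_c: float | None = None
    K_f: float | None = None
    # assembly controls
    extinction_threshold: float = 1e-9
    conv_tol: float = 1e-8
    chunk: float = 1e3
    max_time: float = 1e7
    rtol: float = 1e-7
    atol: float = 1e-10
    # protocol sizes
    n_replicates_assembly: int = 100
    n_pairs: int = 20000
    n_replicates_recursive: int = 25
    n_replicates_serial: int = 20
    n_events: int = 30
    n_bins: int = 20
    l_B_grid: tuple = (0.1, 0.3, 0.5, 0.7, 0.9)
    # bookkeeping
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        checks = [
            (self.g > 0, "growth factor g must be positive"),
            (self.chi0 >= 0, "chi0 must be nonnegative"),
            (self.kappa >= 0, "supply rate kappa must be nonnegative"),
            (self.tau > 0, "dilution timescale tau must be positive"),
            (self.s >= 1 and self.m >= 1, "s and m must be positive"),
            (self.eps_sigma >= 0, "cost fluctuation scale must be nonnegative"),
            (self.n_pref_mean >= 1, "mean preference count must be at least 1"),
            (
                all(0.0 <= l < 1.0 for l in self.leakage_grid),
                "leakage values must lie in [0, 1)",
            ),
            (
                all(0.0 <= k < 1.0 for k in self.k_grid),
                "competition/facilitation factors k must lie in [0, 1)",
            ),
            (
                all(0.0 < l < 1.0 for l in np.diff(self.l_B_grid)) or len(self.l_B_grid) < 2,
                "l_B grid must be strictly increasing",
            ),
            (self.extinction_threshold > 0, "extinction threshold must be positive"),
            (self.conv_tol > 0 and self.rtol > 0 and self.atol > 0, "tolerances must be positive"),
            (self.chunk > 0 and self.max_time > 0, "time controls must be positive"),
            (self.n_bins >= 1, "need at least one bin"),
        ]
        if self.K_c is not None:
            checks.append((0.1 < self.K_c < 0.9, "K_c must lie in (0.1, 0.9)"))
        if self.K_f is not None:
            checks.append((0.1 < self.K_f < 0.9, "K_f must lie in (0.1, 0.9)"))
        for ok, message in checks:
            if not ok:
                raise ValueError(f"invalid configuration: {message}")
        self.leakage_grid = tuple(float(x) for x in self.leakage_grid)
        self.k_grid = tuple(float(x) for x in self.k_grid)
        self.l_B_grid = tuple(float(x) for x in self.l_B_grid)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        data = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=True))

    def assembly_controls(self) -> AssemblyControls:
        return AssemblyControls(
            extinction_threshold=self.extinction_threshold,
            conv_tol=self.conv_tol,
            chunk=self.chunk,
            max_time=self.max_time,
            rtol=self.rtol,
            atol=self.atol,
        )

    def child_seeds(self, n: int) -> list[int]:
        """Independent per-run seeds spawned from the master seed."""
        ss = np.random.SeedSequence(self.seed)
        return [int(child.generate_state(1)[0] % (2**31 - 1)) for child in ss.spawn(n)]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON/TOML config; omitted fields default."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text) if text.strip() else {}
    elif path.suffix == ".toml":
        import tomllib

        data = tomllib.loads(text)
    else:
        data = yaml.safe_load(text) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    data = {k: (tuple(v) if isinstance(v, list) else v) for k, v in data.items()}
    return RunConfig(**data)


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    """Persist a record table as TSV with a deterministic column order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, sep="\t", index=False)
    logger.info("wrote %d records to %s", len(records), path)


def read_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_manifest(config: RunConfig, path: str | Path, extra: dict | None = None) -> None:
    """JSON run manifest: full config plus any extra provenance."""
    payload = {"config": config.to_dict()}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
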