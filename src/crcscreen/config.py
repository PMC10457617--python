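"""Run-configuration loading/validation and result serialization.

A run configuration is a small YAML/JSON document naming the natural-history
parameter file, the strategies to simulate, the cohort size and the master
seed.  Results are written as RFC-4180 CSV plus a JSON metadata sidecar
(seed, n, parameter-file hash, package version) from which any results file
can be regenerated exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .params import ConfigurationError, NaturalHistoryParams, load_params
from .scenarios import load_test_specs
from .screening import AdherenceModel, Strategy, TestSpec

__all__ = ["RunConfig", "load_config", "write_results", "file_sha256"]

log = logging.getLogger("crcscreen")

_TOP_KEYS = {"params_file", "tests_file", "strategies", "n", "master_seed", "output_dir", "log_level"}
_STRATEGY_KEYS = {"test", "adherence", "start_age", "stop_age"}


@dataclass
class RunConfig:
    params_file: Path | None
    n: int
    master_seed: int
    strategies: list[Strategy]
    output_dir: Path
    log_level: str = "INFO"
    tests_file: Path | None = None

    def load_params(self) -> NaturalHistoryParams:
        from .params import default_params

        return load_params(self.params_file) if self.params_file else default_params()


def _resolve(base: Path, p: str | None) -> Path | None:
    if p is None:
        return None
    path = Path(p)
    return path if path.is_absolute() else base / path


def load_config(path: str | Path) -> RunConfig:
    """Load and fully validate a run configuration; unknown keys rejected."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    n = int(raw.get("n", 1000))
    if n < 1:
        raise ConfigurationError("n: must be >= 1")
    master_seed = int(raw.get("master_seed", 0))
    params_file = _resolve(path.parent, raw.get("params_file"))
    tests_file = _resolve(path.parent, raw.get("tests_file"))
    for f in (params_file, tests_file):
        if f is not None and not f.exists():
            raise ConfigurationError(f"referenced file does not exist: {f}")
    known_tests = load_test_specs(tests_file)
    strategies = []
    for i, s in enumerate(raw.get("strategies", [])):
        unknown = set(s) - _STRATEGY_KEYS
        if unknown:
            raise ConfigurationError(f"strategies[{i}]: unknown keys {sorted(unknown)}")
        test = s["test"]
        if isinstance(test, str):
            if test not in known_tests:
                raise ConfigurationError(f"strategies[{i}].test: unknown test {test!r}")
            spec = known_tests[test]
        else:
            spec = TestSpec(**test)
            spec.validate()
        rate = float(s.get("adherence", 1.0))
        strategy = Strategy(test=spec, adherence=AdherenceModel.per_round(rate),
                            start_age=float(s.get("start_age", 45.0)),
                            stop_age=float(s.get("stop_age", 75.0)))
        strategy.validate()
        strategies.append(strategy)
    cfg = RunConfig(
        params_file=params_file,
        n=n,
        master_seed=master_seed,
        strategies=strategies,
        output_dir=_resolve(path.parent, raw.get("output_dir", "results")) or Path("results"),
        log_level=str(raw.get("log_level", "INFO")),
        tests_file=tests_file,
    )
    cfg.load_params()  # surfaces parameter-file schema errors at load time
    return cfg


def file_sha256(path: str | Path | None) -> str | None:
    if path is None:
        return None
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_results(table: pd.DataFrame, metadata: dict, output_dir: str | Path,
                  stem: str = "results") -> dict[str, Path]:
    """Write ``<stem>.csv`` and ``<stem>_metadata.json``; re-reading the CSV
    reproduces the table values exactly (full float precision)."""
    output_dir = Path(output_dir)
    try:
        output_dir.mkdir(parents=True, exist_ok=True)
        csv_path = output_dir / f"{stem}.csv"
        meta_path = output_dir / f"{stem}_metadata.json"
        table.to_csv(csv_path, index=False, float_format="%.17g", lineterminator="\r\n")
        meta = {"package_version": __version__, **metadata}
        meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write results under {output_dir}: {exc}") from exc
    log.info("wrote %s and %s", csv_path, meta_path)
    return {"csv": csv_path, "metadata": meta_path}
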