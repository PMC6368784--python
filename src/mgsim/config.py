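"""Run configuration: INI schema, validation, defaults.

A run is described by an INI file with sections ``[general]``,
``[community]``, ``[samples]``, ``[reads]`` and ``[output]``. Unknown
sections or keys are rejected, and validation reports every violation at
once rather than stopping at the first.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field, fields
from pathlib import Path

from mgsim.taxonomy import DEFAULT_R_MAX, RANKS

COMMUNITY_MODES = ("profile", "denovo")
SAMPLE_MODES = ("single", "differential", "replicates", "timeseries")
TIMESERIES_MODES = ("gaussian", "lognormal")

_SCHEMA: dict[str, set[str]] = {
    "general": {"seed"},
    "community": {
        "mode", "profile", "taxonomy_nodes", "taxonomy_names", "metadata",
        "mapping", "g_real", "g_tot", "max_strains", "r_max", "quality",
        "allow_reuse", "ani_min", "ani_max",
    },
    "samples": {
        "mode", "count", "log_mu", "log_sigma", "noise_sd",
        "timeseries_mode", "log_space",
    },
    "reads": {
        "total_bases", "read_length", "insert_mean", "insert_sd",
        "error_rate", "base_quality",
    },
    "output": {"dir", "compress", "anonymize"},
}


@dataclass
class RunConfig:
    # general
    seed: int = 42
    # community design
    mode: str = "profile"
    profile: str | None = None
    taxonomy_nodes: str | None = None
    taxonomy_names: str | None = None
    metadata: str | None = None
    mapping: str | None = None
    g_real: int = 0
    g_tot: int = 0
    max_strains: int = 10
    r_max: str = DEFAULT_R_MAX
    quality: tuple[str, ...] = ("complete",)
    allow_reuse: bool = False
    ani_min: float = 0.95
    ani_max: float = 0.999
    # samples
    sample_mode: str = "single"
    n_samples: int = 1
    log_mu: float = 1.0
    log_sigma: float = 2.0
    noise_sd: float = 1.0
    timeseries_mode: str = "gaussian"
    log_space: bool = False
    # reads
    total_bases: int = 1_000_000
    read_length: int = 150
    insert_mean: int | None = None
    insert_sd: float | None = None
    error_rate: float = 0.0
    base_quality: int = 40
    # output
    output_dir: str = "out"
    compress: bool = True
    anonymize: bool = True
    # bookkeeping
    base_dir: Path = field(default_factory=Path)

    def resolve(self, key: str) -> Path:
        """A path-valued key resolved against the config file's directory."""
        val = getattr(self, key)
        if val is None:
            raise ValueError(f"config key {key!r} is not set")
        p = Path(val)
        return p if p.is_absolute() else self.base_dir / p

    def validate(self) -> None:
        problems: list[str] = []
        if self.mode not in COMMUNITY_MODES:
            problems.append(f"community mode {self.mode!r} not in {COMMUNITY_MODES}")
        if self.sample_mode not in SAMPLE_MODES:
            problems.append(f"sample mode {self.sample_mode!r} not in {SAMPLE_MODES}")
        if self.timeseries_mode not in TIMESERIES_MODES:
            problems.append(
                f"timeseries mode {self.timeseries_mode!r} not in {TIMESERIES_MODES}"
            )
        if self.r_max not in RANKS:
            problems.append(f"r_max {self.r_max!r} not in {RANKS}")
        if self.n_samples < 1:
            problems.append(f"samples count must be >= 1, got {self.n_samples}")
        if self.sample_mode in ("differential", "timeseries") and self.n_samples < 2:
            problems.append(f"{self.sample_mode} mode needs at least 2 samples")
        if self.sample_mode == "single" and self.n_samples != 1:
            problems.append("single sample mode requires count = 1")
        if self.total_bases < self.read_length:
            problems.append("total_bases must be at least one read length")
        if self.read_length < 1:
            problems.append("read_length must be positive")
        if not 0 <= self.error_rate < 1:
            problems.append(f"error_rate must be in [0, 1), got {self.error_rate}")
        if self.log_sigma < 0:
            problems.append("log_sigma must be >= 0")
        if self.max_strains < 1:
            problems.append("max_strains must be >= 1")
        if not set(self.quality) <= {"complete", "scaffold", "contig"}:
            problems.append(f"quality tags {self.quality} invalid")
        if not (0 < self.ani_min <= self.ani_max <= 1):
            problems.append("need 0 < ani_min <= ani_max <= 1")
        if self.mode == "profile":
            for key in ("profile", "taxonomy_nodes", "taxonomy_names", "metadata"):
                if getattr(self, key) is None:
                    problems.append(f"profile mode requires community key {key!r}")
                elif not self.resolve(key).exists():
                    problems.append(f"{key} path does not exist: {self.resolve(key)}")
        else:
            for key in ("metadata", "mapping"):
                if getattr(self, key) is None:
                    problems.append(f"denovo mode requires community key {key!r}")
                elif not self.resolve(key).exists():
                    problems.append(f"{key} path does not exist: {self.resolve(key)}")
            if self.g_real < 1:
                problems.append("denovo mode requires g_real >= 1")
            if self.g_tot < self.g_real:
                problems.append("g_tot must be >= g_real")
        if problems:
            raise ValueError("invalid configuration:\n  - " + "\n  - ".join(problems))


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load and validate a run configuration from an INI file.

    ``overrides`` (CLI flags) replace file values; defaults fill the rest.
    """
    path = Path(path)
    parser = configparser.ConfigParser()
    if not parser.read(path):
        raise ValueError(f"cannot read config file {path}")
    problems: list[str] = []
    for section in parser.sections():
        if section not in _SCHEMA:
            problems.append(f"unknown section [{section}]")
            continue
        for key in parser[section]:
            if key not in _SCHEMA[section]:
                problems.append(
                    f"unknown key {key!r} in [{section}] "
                    f"(valid: {sorted(_SCHEMA[section])})"
                )
    if problems:
        raise ValueError("invalid configuration:\n  - " + "\n  - ".join(problems))

    cfg = RunConfig(base_dir=path.parent.resolve())

    def get(section, key, conv, attr=None):
        if parser.has_option(section, key):
            raw = parser.get(section, key)
            try:
                setattr(cfg, attr or key, conv(raw))
            except ValueError:
                problems.append(f"[{section}] {key}: cannot parse {raw!r}")

    as_bool = lambda s: s.strip().lower() in ("1", "true", "yes", "on")
    get("general", "seed", int)
    get("community", "mode", str)
    for key in ("profile", "taxonomy_nodes", "taxonomy_names", "metadata", "mapping"):
        get("community", key, str)
    get("community", "g_real", int)
    get("community", "g_tot", int)
    get("community", "max_strains", int)
    get("community", "r_max", str)
    get("community", "quality", lambda s: tuple(t.strip() for t in s.split(",")))
    get("community", "allow_reuse", as_bool)
    get("community", "ani_min", float)
    get("community", "ani_max", float)
    get("samples", "mode", str, attr="sample_mode")
    get("samples", "count", int, attr="n_samples")
    get("samples", "log_mu", float)
    get("samples", "log_sigma", float)
    get("samples", "noise_sd", float)
    get("samples", "timeseries_mode", str)
    get("samples", "log_space", as_bool)
    get("reads", "total_bases", int)
    get("reads", "read_length", int)
    get("reads", "insert_mean", int)
    get("reads", "insert_sd", float)
    get("reads", "error_rate", float)
    get("reads", "base_quality", int)
    get("output", "dir", str, attr="output_dir")
    get("output", "compress", as_bool)
    get("output", "anonymize", as_bool)
    if problems:
        raise ValueError("invalid configuration:\n  - " + "\n  - ".join(problems))
    valid_attrs = {f.name for f in fields(RunConfig)}
    for attr, val in overrides.items():
        if val is None:
            continue
        if attr not in valid_attrs:
            raise ValueError(f"unknown config override {attr!r}")
        setattr(cfg, attr, val)
    cfg.validate()
    return cfg


def write_resolved(cfg: RunConfig, path: str | Path) -> None:
    """Write the fully resolved configuration back out (audit copy)."""
    parser = configparser.ConfigParser()
    parser["general"] = {"seed": str(cfg.seed)}
    parser["community"] = {
        "mode": cfg.mode,
        "max_strains": str(cfg.max_strains),
        "r_max": cfg.r_max,
        "quality": ",".join(cfg.quality),
        "allow_reuse": str(cfg.allow_reuse).lower(),
        "ani_min": str(cfg.ani_min),
        "ani_max": str(cfg.ani_max),
    }
    for key in ("profile", "taxonomy_nodes", "taxonomy_names", "metadata", "mapping"):
        if getattr(cfg, key) is not None:
            parser["community"][key] = str(cfg.resolve(key))
    if cfg.mode == "denovo":
        parser["community"]["g_real"] = str(cfg.g_real)
        parser["community"]["g_tot"] = str(cfg.g_tot)
    parser["samples"] = {
        "mode": cfg.sample_mode,
        "count": str(cfg.n_samples),
        "log_mu": str(cfg.log_mu),
        "log_sigma": str(cfg.log_sigma),
        "noise_sd": str(cfg.noise_sd),
        "timeseries_mode": cfg.timeseries_mode,
        "log_space": str(cfg.log_space).lower(),
    }
    parser["reads"] = {
        "total_bases": str(cfg.total_bases),
        "read_length": str(cfg.read_length),
        "error_rate": str(cfg.error_rate),
        "base_quality": str(cfg.base_quality),
    }
    if cfg.insert_mean is not None:
        parser["reads"]["insert_mean"] = str(cfg.insert_mean)
    if cfg.insert_sd is not None:
        parser["reads"]["insert_sd"] = str(cfg.insert_sd)
    parser["output"] = {
        "dir": str(cfg.output_dir),
        "compress": str(cfg.compress).lower(),
        "anonymize": str(cfg.anonymize).lower(),
    }
    with open(path, "w") as fh:
        parser.write(fh)
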