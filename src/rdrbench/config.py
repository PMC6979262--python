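"""YAML configuration loading with strict key validation and full defaults."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .evaluate import TOP_FRACTIONS
from .sim import ParamPrior, SimConfig


class ConfigError(ValueError):
    """A configuration key is unknown or violates its constraint."""


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Validated configuration for the simulate/benchmark subcommands.

    An empty file yields the standard study conditions: 10,000 isoforms,
    80 cells per group, 5% DE at |lfc| 1, 50 replicates, alpha 0.05,
    top fractions 5/10/20/100%, stratum rule CPM > 1 in > 25% of cells.
    """

    n_isoforms: int = 10_000
    n_cells_per_group: int = 80
    de_fraction: float = 0.05
    lfc: float = 1.0
    library_size_min: float = 1e6
    library_size_max: float = 3e6
    seed: int = 0
    methods: tuple = tuple(("ttest", "wilcoxon", "limmatrend", "nbwald",
                            "zinb", "hurdle", "bp4"))
    scenario: str = "alternative"
    n_replicates: int = 50
    n_per_set_per_group: int = 40
    alpha: float = 0.05
    top_fractions: tuple = TOP_FRACTIONS
    stratum_threshold: float = 1.0
    stratum_cell_fraction: float = 0.25
    prior_alpha_shape: float = 2.0
    prior_alpha_scale: float = 1.0
    prior_beta_shape: float = 2.0
    prior_beta_scale: float = 2.0
    prior_log_lambda1_mean: float = 3.0
    prior_log_lambda1_sd: float = 1.5
    prior_lambda2: float = 1.0

    def sim_config(self) -> SimConfig:
        return SimConfig(
            n_isoforms=self.n_isoforms,
            n_cells_per_group=self.n_cells_per_group,
            de_fraction=self.de_fraction,
            lfc=self.lfc,
            library_size_range=(self.library_size_min, self.library_size_max),
            seed=self.seed,
            prior=ParamPrior(
                alpha_shape=self.prior_alpha_shape,
                alpha_scale=self.prior_alpha_scale,
                beta_shape=self.prior_beta_shape,
                beta_scale=self.prior_beta_scale,
                log_lambda1_mean=self.prior_log_lambda1_mean,
                log_lambda1_sd=self.prior_log_lambda1_sd,
                lambda2=self.prior_lambda2,
            ),
        )


_RANGES = {
    "n_isoforms": (1, None),
    "n_cells_per_group": (1, None),
    "de_fraction": (0.0, 1.0),
    "lfc": (0.0, None),
    "library_size_min": (1e-9, None),
    "library_size_max": (1e-9, None),
    "n_replicates": (1, None),
    "n_per_set_per_group": (1, None),
    "alpha": (1e-12, 1.0),
    "stratum_threshold": (0.0, None),
    "stratum_cell_fraction": (0.0, 1.0),
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML config; unknown keys and range violations raise.

    ``path=None`` or an empty file yields the full default configuration.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a key/value mapping")
        raw.update(loaded)
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})

    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")

    for key, (lo, hi) in _RANGES.items():
        if key in raw:
            try:
                val = float(raw[key])
            except (TypeError, ValueError):
                raise ConfigError(f"config key {key!r} must be numeric")
            if (lo is not None and val < lo) or (hi is not None and val > hi):
                raise ConfigError(
                    f"config key {key!r}={raw[key]} outside allowed range "
                    f"[{lo}, {hi if hi is not None else 'inf'}]"
                )
    for key in ("methods", "top_fractions"):
        if key in raw:
            raw[key] = tuple(raw[key]) if isinstance(raw[key], (list, tuple)) else (raw[key],)
    for key in ("n_isoforms", "n_cells_per_group", "n_replicates",
                "n_per_set_per_group", "seed"):
        if key in raw:
            raw[key] = int(raw[key])
    cfg = RunConfig(**raw)
    if cfg.library_size_min > cfg.library_size_max:
        raise ConfigError("library_size_min must not exceed library_size_max")
    if cfg.scenario not in ("null", "alternative"):
        raise ConfigError("scenario must be 'null' or 'alternative'")
    from .de_tests import METHODS

    bad = [mth for mth in cfg.methods if mth not in METHODS]
    if bad:
        raise ConfigError(f"unknown method(s): {bad}; choose from {sorted(METHODS)}")
    return cfg
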