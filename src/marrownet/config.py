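"""Run configuration for the analysis pipeline.

A run is controlled by a small flat set of knobs (significance cutoffs,
profile-set size, correlation threshold, hub degree cutoff, RNG seed).
They can be read from a plain ``key = value`` text file so that a whole
analysis is reproducible from one config + one seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path


@dataclass
class RunConfig:
    """Pipeline-wide parameters.

    alpha_de
        Per-timepoint t-test cutoff; a gene is differential when p < alpha_de
        at one or more post-baseline timepoints.
    alpha_profile
        Significance level for model temporal profiles, applied after
        Bonferroni correction over the profile set.
    alpha_enrich
        Raw Fisher p cutoff for calling a gene-set term significant.
    n_model_profiles
        Number of model temporal profiles kept by the max-min selection.
    max_unit_change
        Largest per-step change c of a model profile (steps move in
        {-c, ..., +c} between consecutive timepoints).
    correlation_threshold
        Minimum |Pearson r| for a co-expression edge.
    correlation_p_threshold
        Correlation-test p gate for an edge; set >= 1 to disable.
    hub_min_degree
        Minimum within-subnetwork degree for a PPI hub (11 means "degree
        above 10").
    seed
        Seed for every stochastic step.
    """

    alpha_de: float = 0.05
    alpha_profile: float = 0.001
    alpha_enrich: float = 0.05
    n_model_profiles: int = 50
    max_unit_change: int = 2
    correlation_threshold: float = 0.8
    correlation_p_threshold: float = 0.05
    hub_min_degree: int = 11
    seed: int = 0

    def __post_init__(self) -> None:
        # alphas may be set to the degenerate 1.0 to disable a filter
        for name in ("alpha_de", "alpha_profile", "alpha_enrich"):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {value}")
        if self.n_model_profiles < 1:
            raise ValueError("n_model_profiles must be positive")
        if self.max_unit_change < 1:
            raise ValueError("max_unit_change must be positive")
        if not 0.0 <= self.correlation_threshold <= 1.0:
            raise ValueError("correlation_threshold must be in [0, 1]")
        if self.hub_min_degree < 1:
            raise ValueError("hub_min_degree must be positive")


_INT_FIELDS = {"n_model_profiles", "max_unit_change", "hub_min_degree", "seed"}


def read_config(path: str | Path) -> RunConfig:
    """Parse a flat ``key = value`` config file; unset keys take defaults."""
    known = {f.name for f in dataclasses.fields(RunConfig)}
    values: dict[str, float | int] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in known:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        text = value.strip()
        values[key] = int(text) if key in _INT_FIELDS else float(text)
    return RunConfig(**values)


def write_config(config: RunConfig, path: str | Path) -> None:
    lines = [
        f"{f.name} = {getattr(config, f.name)}" for f in dataclasses.fields(RunConfig)
    ]
    Path(path).write_text("\n".join(lines) + "\n")
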