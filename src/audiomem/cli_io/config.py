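"""Pipeline configuration: a YAML document that determines every output.

Schema (all keys optional, defaults shown)::

    cohort:
      n_per_group: 12
      master_seed: 0
      age_range: [12.0, 54.0]
      conditions: [four_pair, twelve_pair]
      safety_cap: 10000
      groups:
        sighted_like:
          p_encode_mean: 0.8
          p_encode_sd: 0.05
          p_forget_mean: 0.55
          p_forget_sd: 0.05
          anchor_mean: 0.1
          anchor_sd: 0.05
          policy: uniform_random
        blind_like:
          ...
    board:
      # optional explicit aperture coordinates per condition
      four_pair: [[0, 0], [0, 1], ...]
    stats:
      n_perm: 5000
      seed: 0
      scheme: raw            # raw | residual
      strata: false          # restrict multivariate permutations within subject
      distance: euclidean_standardized
      alpha: 0.05
    output:
      directory: ./audiomem_out
      verbosity: 1
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from ..agents import DEFAULT_GROUP_PARAMS, CohortSpec, GroupParams


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass(frozen=True)
class StatsConfig:
    n_perm: int = 5000
    seed: int = 0
    scheme: str = "raw"
    strata: bool = False
    distance: str = "euclidean_standardized"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if self.scheme not in ("raw", "residual"):
            raise ConfigError(f"unknown scheme {self.scheme!r}")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    stats: StatsConfig = field(default_factory=StatsConfig)
    output_dir: Path = Path("audiomem_out")
    verbosity: int = 1


def _group_params(doc: dict) -> GroupParams:
    allowed = {
        "p_encode_mean", "p_encode_sd", "p_forget_mean", "p_forget_sd",
        "anchor_mean", "anchor_sd", "policy",
    }
    unknown = set(doc) - allowed
    if unknown:
        raise ConfigError(f"unknown group parameter keys: {sorted(unknown)}")
    try:
        return GroupParams(**doc)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from None


def load_config(path: Optional[Union[str, Path]] = None) -> PipelineConfig:
    """Load a YAML config file; with no path, return the defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")

    cohort_doc = dict(doc.get("cohort") or {})
    groups_doc = cohort_doc.pop("groups", None)
    if groups_doc is None:
        group_params = dict(DEFAULT_GROUP_PARAMS)
    else:
        group_params = {
            name: _group_params(gp or {}) for name, gp in groups_doc.items()
        }
    board_doc = doc.get("board") or None
    aperture_specs = None
    if board_doc:
        aperture_specs = {
            cond: [tuple(int(v) for v in pos) for pos in positions]
            for cond, positions in board_doc.items()
        }
    try:
        cohort = CohortSpec(
            n_per_group=int(cohort_doc.get("n_per_group", 12)),
            group_params=group_params,
            age_range=tuple(cohort_doc.get("age_range", (12.0, 54.0))),
            conditions=tuple(
                cohort_doc.get("conditions", ("four_pair", "twelve_pair"))
            ),
            master_seed=int(cohort_doc.get("master_seed", 0)),
            safety_cap=int(cohort_doc.get("safety_cap", 10_000)),
            aperture_specs=aperture_specs,
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from None

    stats_doc = doc.get("stats") or {}
    stats = StatsConfig(
        n_perm=int(stats_doc.get("n_perm", 5000)),
        seed=int(stats_doc.get("seed", 0)),
        scheme=str(stats_doc.get("scheme", "raw")),
        strata=bool(stats_doc.get("strata", False)),
        distance=str(stats_doc.get("distance", "euclidean_standardized")),
        alpha=float(stats_doc.get("alpha", 0.05)),
    )
    out_doc = doc.get("output") or {}
    return PipelineConfig(
        cohort=cohort,
        stats=stats,
        output_dir=Path(out_doc.get("directory", "audiomem_out")),
        verbosity=int(out_doc.get("verbosity", 1)),
    )
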