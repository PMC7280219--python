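"""Single-file pipeline configuration (JSON or YAML).

A configuration file holds three optional sections — ``cohort`` (the
simulation settings, including per-group generative parameters),
``analysis`` (feature-extraction and scoring settings) and
``n_per_group`` — plus a ``config_version``.  Every omitted key falls
back to the package defaults, so an empty file reproduces the canonical
pipeline settings (binning n = 4, annuli 14/24 and 24/36 px, entropy
radius 2 px).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .exceptions import ConfigurationError
from .pipeline import AnalysisConfig
from .simulate import CohortConfig, GroupParams, default_group_params

__all__ = ["PipelineConfig", "load_config", "save_config"]

CONFIG_VERSION = 1


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortConfig
    analysis: AnalysisConfig
    n_per_group: dict[str, int]
    config_version: int = CONFIG_VERSION

    @classmethod
    def default(cls) -> "PipelineConfig":
        return cls(
            cohort=CohortConfig(),
            analysis=AnalysisConfig(),
            n_per_group={"control": 18, "psoriasis": 33, "eczema": 7},
        )

    @classmethod
    def reduced(cls) -> "PipelineConfig":
        """Resolution-reduced configuration for desk-scale simulation runs.

        128 px frames, 64 time bins, only the SG and SB sections
        materialised, and an 8-pixel fit stride.  Because the spatial
        binning window already spans 9 pixels, the strided fit grid loses
        almost no frame-level information, and the statistical structure
        of every feature is unchanged — only sampling noise grows
        slightly.  Group sizes keep 33 psoriasis subjects and give the
        control and eczema arms 20 subjects each.
        """
        return cls(
            cohort=CohortConfig(
                frame_size=128, n_time_bins=64, layers_only=True
            ),
            analysis=AnalysisConfig(fit_stride=8),
            n_per_group={"control": 20, "psoriasis": 33, "eczema": 20},
        )


def _build(section: dict, cls, name: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ConfigurationError(
            f"unknown keys in {name!r} section: {sorted(unknown)}"
        )
    return cls(**section)


def load_config(path=None) -> PipelineConfig:
    """Load a pipeline configuration file; ``None`` gives the defaults."""
    if path is None:
        return PipelineConfig.default()
    text = Path(path).read_text()
    data = (
        json.loads(text)
        if str(path).endswith(".json")
        else yaml.safe_load(text)
    ) or {}
    version = data.get("config_version", CONFIG_VERSION)
    if version != CONFIG_VERSION:
        raise ConfigurationError(
            f"unsupported config_version {version}; expected {CONFIG_VERSION}"
        )
    cohort_section = dict(data.get("cohort", {}))
    group_section = cohort_section.pop("group_params", None)
    if group_section is not None:
        params = default_group_params()
        for g, overrides in group_section.items():
            base = dataclasses.asdict(params[g])
            base.update(overrides)
            params[g] = GroupParams(**base)
        cohort_section["group_params"] = params
    analysis_section = dict(data.get("analysis", {}))
    for key in ("medium_annulus", "high_annulus"):
        if key in analysis_section:
            analysis_section[key] = tuple(analysis_section[key])
    defaults = PipelineConfig.default()
    return PipelineConfig(
        cohort=_build(cohort_section, CohortConfig, "cohort"),
        analysis=_build(analysis_section, AnalysisConfig, "analysis"),
        n_per_group=dict(data.get("n_per_group", defaults.n_per_group)),
        config_version=version,
    )


def save_config(config: PipelineConfig, path) -> None:
    data = {
        "config_version": config.config_version,
        "cohort": dataclasses.asdict(config.cohort),
        "analysis": dataclasses.asdict(config.analysis),
        "n_per_group": config.n_per_group,
    }
    data["analysis"]["medium_annulus"] = list(
        data["analysis"]["medium_annulus"]
    )
    data["analysis"]["high_annulus"] = list(data["analysis"]["high_annulus"])
    text = (
        json.dumps(data, indent=2, sort_keys=True)
        if str(path).endswith(".json")
        else yaml.safe_dump(data, sort_keys=True)
    )
    Path(path).write_text(text)
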