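"""Layer selection and per-subject feature assembly.

Every imaging site is a depth stack of decay frames.  Two living epidermal
layers carry the analysis: the stratum granulosum (SG, superficial) and
the stratum basale (SB, deep); their axial separation measures epidermal
thickness, a classical psoriasis biomarker.  Frames are selected by depth
metadata (no content-based detection), mirroring a workflow where stage
depths are recorded during acquisition.

Two named feature vectors are assembled per site/subject:

* the 8-feature *condition* vector used to separate control,
  pseudo-control, psoriasis and eczema skin, and
* the 5-feature *PASI* vector computed per psoriasis subject from the
  lesional ("inflamed") site and its contralateral pseudo-control site,
  three of whose entries are inflamed / pseudo-control ratios.

Feature order and naming are fixed (schema version
:data:`FEATURE_SCHEMA_VERSION`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decay import FrameStats
from .exceptions import (
    DegenerateRatioError,
    IncompleteSubjectError,
    InconsistentLayersError,
    ValidationError,
)

__all__ = [
    "LayerSelection",
    "ProcessedSite",
    "select_layers",
    "depth_features",
    "condition_feature_vector",
    "pasi_feature_vector",
    "CONDITION_FEATURES",
    "PASI_FEATURES",
    "FEATURE_SCHEMA_VERSION",
]

FEATURE_SCHEMA_VERSION = 1

#: The 8 condition features, in fixed order: Fourier parameter at the SB,
#: mean tau1 at the SB, mean tau2 at the SB, std of tau1 at the SB, std of
#: tau2 at the SG, imaging depth of the SG, SG->SB distance, entropy at
#: the SG.
CONDITION_FEATURES = (
    "fourier_SB",
    "tau1_mean_SB",
    "tau2_mean_SB",
    "tau1_std_SB",
    "tau2_std_SG",
    "depth_SG_um",
    "dist_SG_SB_um",
    "entropy_SG",
)

#: The 5 PASI-analysis features, in fixed order: SG->SB distance at the
#: inflamed site, inflamed/pseudo-control ratio of that distance,
#: inflamed/pseudo-control ratio of the SG tau2-component percentage,
#: inflamed/pseudo-control ratio of the SB Fourier parameter, and the SB
#: tau1-component percentage at the inflamed site.
PASI_FEATURES = (
    "dist_SG_SB_inflamed_um",
    "dist_ratio_inflamed_over_pseudo",
    "p2_SG_ratio_inflamed_over_pseudo",
    "fourier_SB_ratio_inflamed_over_pseudo",
    "p1_SB_inflamed_percent",
)


@dataclass(frozen=True)
class LayerSelection:
    """Indices and depths of the SG and SB frames within one stack."""

    sg_index: int
    sb_index: int
    sg_depth_um: float
    sb_depth_um: float

    def __post_init__(self) -> None:
        if not self.sg_depth_um < self.sb_depth_um:
            raise InconsistentLayersError(
                f"SG depth {self.sg_depth_um} um must be shallower than "
                f"SB depth {self.sb_depth_um} um"
            )


@dataclass
class ProcessedSite:
    """All per-layer measurements for one imaging site.

    Produced by the pipeline (decay fitting + texture features at the SG
    and SB layers); consumed by the feature-vector assemblers below.
    """

    subject_id: str
    site_label: str
    group_label: str
    selection: LayerSelection
    sg_stats: FrameStats
    sb_stats: FrameStats
    fourier_sb: float
    entropy_sg: float


def select_layers(
    depths_um: np.ndarray,
    sg_target_um: float | None = None,
    sb_target_um: float | None = None,
    sg_index: int | None = None,
    sb_index: int | None = None,
) -> LayerSelection:
    """Select the SG and SB frames of a stack.

    Either explicit frame indices or target depths must be given for both
    layers; with targets, the frame whose depth metadata is nearest each
    target is chosen (ties to the shallower frame).  Raises
    ``InconsistentLayersError`` if the selected SG frame is not strictly
    shallower than the SB frame.
    """
    depths = np.asarray(depths_um, dtype=float)
    if depths.ndim != 1 or depths.size == 0:
        raise ValidationError("stack depth metadata must be non-empty 1-D")

    def _resolve(index: int | None, target: float | None, name: str) -> int:
        if index is not None:
            if not 0 <= index < depths.size:
                raise ValidationError(
                    f"{name} index {index} outside stack of {depths.size}"
                )
            return index
        if target is None:
            raise ValidationError(f"must give either an index or a depth for {name}")
        return int(np.argmin(np.abs(depths - target)))

    sg_i = _resolve(sg_index, sg_target_um, "SG")
    sb_i = _resolve(sb_index, sb_target_um, "SB")
    return LayerSelection(
        sg_index=sg_i,
        sb_index=sb_i,
        sg_depth_um=float(depths[sg_i]),
        sb_depth_um=float(depths[sb_i]),
    )


def depth_features(sel: LayerSelection) -> tuple[float, float]:
    """(SG imaging depth, SG->SB optical distance), both in micrometres.

    The distance is the raw difference of recorded stage depths; no
    refractive-index correction is applied.
    """
    return sel.sg_depth_um, sel.sb_depth_um - sel.sg_depth_um


def _require_finite(values: dict[str, float], context: str) -> None:
    bad = [k for k, v in values.items() if not np.isfinite(v)]
    if bad:
        raise IncompleteSubjectError(
            f"{context}: non-finite features {bad}; subject excluded"
        )


def condition_feature_vector(site: ProcessedSite) -> pd.Series:
    """Assemble the 8-feature condition vector for one site.

    Order and names follow :data:`CONDITION_FEATURES`.  Any non-finite
    constituent raises ``IncompleteSubjectError`` (the site is excluded
    rather than imputed).
    """
    depth_sg, dist = depth_features(site.selection)
    values = {
        "fourier_SB": site.fourier_sb,
        "tau1_mean_SB": site.sb_stats.tau1_mean_ns,
        "tau2_mean_SB": site.sb_stats.tau2_mean_ns,
        "tau1_std_SB": site.sb_stats.tau1_std_ns,
        "tau2_std_SG": site.sg_stats.tau2_std_ns,
        "depth_SG_um": depth_sg,
        "dist_SG_SB_um": dist,
        "entropy_SG": site.entropy_sg,
    }
    _require_finite(values, f"{site.subject_id}/{site.site_label}")
    return pd.Series(
        [values[k] for k in CONDITION_FEATURES],
        index=list(CONDITION_FEATURES),
        name=f"{site.subject_id}/{site.site_label}",
    )


def pasi_feature_vector(
    inflamed: ProcessedSite, pseudo_control: ProcessedSite
) -> pd.Series:
    """Assemble the 5-feature PASI vector from a subject's two sites.

    All three ratio features are inflamed / pseudo-control.  Raises
    ``IncompleteSubjectError`` on non-finite constituents and
    ``DegenerateRatioError`` on a zero denominator.
    """
    if inflamed.subject_id != pseudo_control.subject_id:
        raise ValidationError(
            "inflamed and pseudo-control sites must belong to one subject"
        )
    _, dist_inf = depth_features(inflamed.selection)
    _, dist_pseudo = depth_features(pseudo_control.selection)
    denominators = {
        "dist_ratio_inflamed_over_pseudo": dist_pseudo,
        "p2_SG_ratio_inflamed_over_pseudo": pseudo_control.sg_stats.p2_mean_percent,
        "fourier_SB_ratio_inflamed_over_pseudo": pseudo_control.fourier_sb,
    }
    for name, denom in denominators.items():
        if denom == 0:
            raise DegenerateRatioError(
                f"{inflamed.subject_id}: zero denominator for {name}"
            )
    values = {
        "dist_SG_SB_inflamed_um": dist_inf,
        "dist_ratio_inflamed_over_pseudo": dist_inf / dist_pseudo,
        "p2_SG_ratio_inflamed_over_pseudo": (
            inflamed.sg_stats.p2_mean_percent
            / pseudo_control.sg_stats.p2_mean_percent
        ),
        "fourier_SB_ratio_inflamed_over_pseudo": (
            inflamed.fourier_sb / pseudo_control.fourier_sb
        ),
        "p1_SB_inflamed_percent": inflamed.sb_stats.p1_mean_percent,
    }
    _require_finite(values, inflamed.subject_id)
    return pd.Series(
        [values[k] for k in PASI_FEATURES],
        index=list(PASI_FEATURES),
        name=inflamed.subject_id,
    )
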