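"""End-to-end analysis pipeline: stacks -> features -> severity scores.

Ties together layer selection, lifetime fitting, texture features and the
severity model.  The same functions back the command-line interface and
the in-memory study runner used for simulation experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import decay as _decay
from . import texture as _texture
from .exceptions import DermaflimError, IncompleteSubjectError, ValidationError
from .severity import SeverityModel, SeverityResults
from .simulate import CohortConfig, SiteStack, SyntheticSubject, generate_cohort
from .stack import (
    CONDITION_FEATURES,
    PASI_FEATURES,
    ProcessedSite,
    condition_feature_vector,
    pasi_feature_vector,
    select_layers,
)

__all__ = [
    "AnalysisConfig",
    "process_site",
    "cohort_condition_table",
    "cohort_pasi_table",
    "StudyResult",
    "run_study",
]

log = logging.getLogger("dermaflim")


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings of the feature-extraction and scoring stages.

    The defaults reproduce the analysis pipeline the package implements:
    spatial binning factor ``n = 4`` (a 9x9 moving window), Fourier annuli
    at 14-24 px (medium) and 24-36 px (high) for a 512 px frame, and a
    2 px circular structuring element for the local entropy.

    ``fit_stride`` fits every stride-th pixel of the binned frame; frame
    statistics are estimated from the sampled grid.  Because binning
    already correlates neighbouring traces over a 9-pixel window, moderate
    strides lose almost no information while cutting compute.
    """

    binning_n: int = 4
    min_photons: int = 100
    fit_stride: int = 1
    medium_annulus: tuple[float, float] = _texture.MEDIUM_ANNULUS_PX
    high_annulus: tuple[float, float] = _texture.HIGH_ANNULUS_PX
    entropy_radius: int = 2
    entropy_levels: int = 256
    n_components: int = 2
    invert_fourier: bool = False


def process_site(
    stack: SiteStack,
    config: AnalysisConfig | None = None,
    subject_id: str = "",
) -> ProcessedSite:
    """Measure one imaging site: select layers, fit decays, texture.

    Raises ``IncompleteSubjectError`` if either layer frame is unusable
    (e.g. all pixels masked).
    """
    cfg = config or AnalysisConfig()
    sel = select_layers(
        stack.depths_um,
        sg_target_um=stack.sg_depth_um,
        sb_target_um=stack.sb_depth_um,
    )
    sg_cube = stack.frames[sel.sg_index]
    sb_cube = stack.frames[sel.sb_index]
    try:
        sg_map = _decay.fit_frame(
            sg_cube, n=cfg.binning_n, min_photons=cfg.min_photons,
            stride=cfg.fit_stride,
        )
        sb_map = _decay.fit_frame(
            sb_cube, n=cfg.binning_n, min_photons=cfg.min_photons,
            stride=cfg.fit_stride,
        )
        sg_stats = _decay.frame_lifetime_stats(sg_map)
        sb_stats = _decay.frame_lifetime_stats(sb_map)
        fourier_sb = _texture.fourier_parameter(
            sb_cube.intensity().astype(float),
            medium=cfg.medium_annulus,
            high=cfg.high_annulus,
            invert=cfg.invert_fourier,
        )
        entropy_sg = _texture.local_entropy_mean(
            sg_cube.intensity().astype(float),
            radius=cfg.entropy_radius,
            levels=cfg.entropy_levels,
        )
    except DermaflimError as err:
        raise IncompleteSubjectError(
            f"{subject_id}/{stack.site_label}: {err}"
        ) from err
    return ProcessedSite(
        subject_id=subject_id,
        site_label=stack.site_label,
        group_label=stack.group_label,
        selection=sel,
        sg_stats=sg_stats,
        sb_stats=sb_stats,
        fourier_sb=fourier_sb,
        entropy_sg=entropy_sg,
    )


def _process_subjects(
    subjects: list[SyntheticSubject],
    config: AnalysisConfig,
) -> tuple[dict[tuple[str, str], ProcessedSite], list[dict]]:
    processed: dict[tuple[str, str], ProcessedSite] = {}
    exclusions: list[dict] = []
    for subj in subjects:
        for site_label, stack in subj.sites.items():
            try:
                processed[(subj.subject_id, site_label)] = process_site(
                    stack, config, subject_id=subj.subject_id
                )
            except IncompleteSubjectError as err:
                exclusions.append(
                    {
                        "subject_id": subj.subject_id,
                        "site": site_label,
                        "reason": str(err),
                    }
                )
                log.warning("excluded %s/%s: %s", subj.subject_id, site_label, err)
    return processed, exclusions


def cohort_condition_table(
    subjects: list[SyntheticSubject],
    config: AnalysisConfig | None = None,
    _processed: dict | None = None,
    _exclusions: list[dict] | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """One condition-feature row per usable imaging site.

    Rows carry the 8 condition features plus ``group`` (the tissue group
    of the site: a psoriasis subject contributes a ``psoriasis`` row for
    its lesional site and a ``pseudo_control`` row for the contralateral
    one), ``subject_id`` and ``site``.  Returns the table and the
    exclusion log.
    """
    cfg = config or AnalysisConfig()
    if _processed is None:
        processed, exclusions = _process_subjects(subjects, cfg)
    else:
        processed, exclusions = _processed, list(_exclusions or [])
    rows = []
    for (subject_id, site_label), site in processed.items():
        try:
            vec = condition_feature_vector(site)
        except DermaflimError as err:
            exclusions.append(
                {"subject_id": subject_id, "site": site_label, "reason": str(err)}
            )
            continue
        row = vec.to_dict()
        row.update(
            subject_id=subject_id, site=site_label, group=site.group_label
        )
        rows.append(row)
    table = pd.DataFrame(
        rows, columns=[*CONDITION_FEATURES, "subject_id", "site", "group"]
    )
    return table, exclusions


def cohort_pasi_table(
    subjects: list[SyntheticSubject],
    config: AnalysisConfig | None = None,
    _processed: dict | None = None,
    _exclusions: list[dict] | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """One PASI-feature row per psoriasis subject with both sites usable.

    Rows carry the 5 PASI features plus ``pasi`` and ``lis``.  Subjects
    missing a site, a PASI score, or any constituent feature are excluded
    and logged.
    """
    cfg = config or AnalysisConfig()
    pso = [s for s in subjects if s.group_label == "psoriasis"]
    if _processed is None:
        processed, exclusions = _process_subjects(pso, cfg)
    else:
        processed, exclusions = _processed, list(_exclusions or [])
    rows = []
    for subj in pso:
        inflamed = processed.get((subj.subject_id, "lesional"))
        pseudo = processed.get((subj.subject_id, "pseudo_control"))
        if inflamed is None or pseudo is None:
            continue  # already in the exclusion log
        if subj.pasi is None:
            exclusions.append(
                {
                    "subject_id": subj.subject_id,
                    "site": "both",
                    "reason": "no PASI score recorded",
                }
            )
            continue
        try:
            vec = pasi_feature_vector(inflamed, pseudo)
        except DermaflimError as err:
            exclusions.append(
                {"subject_id": subj.subject_id, "site": "both", "reason": str(err)}
            )
            continue
        row = vec.to_dict()
        row.update(subject_id=subj.subject_id, pasi=subj.pasi, lis=subj.lis)
        rows.append(row)
    table = pd.DataFrame(
        rows, columns=[*PASI_FEATURES, "subject_id", "pasi", "lis"]
    )
    return table, exclusions


@dataclass
class StudyResult:
    """Everything one simulated study run produces."""

    condition_table: pd.DataFrame
    pasi_table: pd.DataFrame
    condition_results: SeverityResults | None
    pasi_results: SeverityResults | None
    exclusions: list[dict] = field(default_factory=list)
    truth_table: pd.DataFrame | None = None

    def pc1_group_means(self) -> pd.Series:
        scores = self.condition_results.severity_scores()
        return scores.groupby(self.condition_results.model.groups).mean()


def run_study(
    n_per_group: dict[str, int],
    cohort_config: CohortConfig | None = None,
    analysis_config: AnalysisConfig | None = None,
    seed: int = 0,
) -> StudyResult:
    """Simulate a cohort and run the full analysis on it.

    Fits the condition model (one row per site, 8 features, PC1 oriented
    by group severity) and, when at least three psoriasis subjects have
    PASI scores, the PASI model (one row per subject, 5 features, PC1
    oriented so the inflamed SG->SB distance loads positively).
    """
    cohort_cfg = cohort_config or CohortConfig()
    cfg = analysis_config or AnalysisConfig()
    subjects, truth = generate_cohort(n_per_group, cohort_cfg, seed=seed)
    if not subjects:
        raise ValidationError("empty cohort")

    processed, excl = _process_subjects(subjects, cfg)
    cond_table, cond_excl = cohort_condition_table(
        subjects, cfg, _processed=processed, _exclusions=excl
    )
    cond_results = None
    if len(cond_table) >= 3 and cond_table["group"].nunique() >= 1:
        cond_results = SeverityModel(
            cond_table[list(CONDITION_FEATURES)],
            groups=cond_table["group"],
            n_components=cfg.n_components,
            orient="groups",
        ).fit()

    pasi_table, pasi_excl = cohort_pasi_table(
        subjects, cfg, _processed=processed, _exclusions=[]
    )
    pasi_results = None
    if len(pasi_table) >= 3:
        pasi_results = SeverityModel(
            pasi_table[list(PASI_FEATURES)],
            pasi=pasi_table["pasi"],
            lis=pasi_table["lis"],
            n_components=cfg.n_components,
            orient=("feature", "dist_SG_SB_inflamed_um"),
        ).fit()

    return StudyResult(
        condition_table=cond_table,
        pasi_table=pasi_table,
        condition_results=cond_results,
        pasi_results=pasi_results,
        exclusions=cond_excl + pasi_excl,
        truth_table=truth,
    )
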