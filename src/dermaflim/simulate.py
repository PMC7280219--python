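"""Synthetic FLIM cohorts with a ground-truthed generative model.

The study design this package analyses images four kinds of skin: healthy
skin of control subjects, lesional and contralateral non-lesional
("pseudo-control") skin of psoriasis subjects, and lesional skin of eczema
subjects.  Because no raw image data is publicly deposited, this module
generates volumetric decay cubes whose statistical structure carries the
effects the analysis is designed to detect:

* a longer second lifetime component and a larger long-component amplitude
  fraction in inflamed skin (altered NAD(P)H metabolic state),
* a deeper stratum basale, i.e. a thicker epidermis (SG -> SB distance),
* more bright sub-cellular puncta (perinuclear mitochondrial clustering),
  which raises the high-spatial-frequency content of the intensity image.

Each pixel's decay follows

    E[counts(t)] proportional to  A(x, y) * [(1 - q) exp(-t/tau1) + q exp(-t/tau2)]

with the amplitude field ``A`` modulated by a cellular texture (smooth
blobs, bright cytoplasm rings, dark nuclei, plus small bright puncta), the
long-component fraction ``q`` weakly modulated by the same texture, and
photon counts drawn per time bin from a Poisson law.  All generators are
pure functions of ``(params, seed)``.

Severity coupling: each psoriasis subject draws a latent severity ``z``
(standard normal) that shifts the inflamed-site parameters along the
disease direction and, through ``pasi_coupling_r``, generates a PASI score
correlated with ``z`` at a configurable strength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .decay import DecayCube
from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "GroupParams",
    "CohortConfig",
    "SiteStack",
    "SyntheticSubject",
    "generate_decay_frame",
    "generate_subject",
    "generate_cohort",
    "default_group_params",
]

GROUPS = ("control", "pseudo_control", "psoriasis", "eczema")
#: Ordinal severity encoding used to orient the PC1 axis.
GROUP_ORDER = {"control": 0, "pseudo_control": 1, "eczema": 2, "psoriasis": 3}


@dataclass(frozen=True)
class GroupParams:
    """Generative parameters for one study group (or imaging-site kind).

    Lifetimes are in nanoseconds, depths in micrometres.  ``a2_fraction``
    is the amplitude fraction of the long (tau2) component at t = 0;
    ``puncta_density`` is the expected count of bright 1-2 px puncta per
    frame; ``photons_per_pixel`` the mean total photon count per pixel.
    ``pasi_mean/sd`` and ``lis_mean/sd`` parameterise the clinical-score
    generator (only used for psoriasis subjects).
    """

    group_label: str
    tau1_ns: float = 0.30
    tau2_ns: float = 2.0
    a2_fraction: float = 0.30
    sg_depth_um: float = 25.0
    sb_depth_um: float = 55.0
    puncta_density: float = 30.0
    photons_per_pixel: float = 200.0
    texture_amplitude: float = 0.5
    pasi_mean: float = 12.0
    pasi_sd: float = 6.0
    lis_mean: float = 5.0
    lis_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.group_label not in GROUPS:
            raise ValidationError(f"unknown group label {self.group_label!r}")
        if not 0 < self.tau1_ns < self.tau2_ns:
            raise ValidationError("require 0 < tau1_ns < tau2_ns")
        if not 0 <= self.a2_fraction <= 1:
            raise ValidationError("a2_fraction must lie in [0, 1]")
        if not self.sg_depth_um < self.sb_depth_um:
            raise ValidationError("require sg_depth_um < sb_depth_um")
        if self.puncta_density < 0:
            raise ValidationError("puncta_density must be >= 0")
        if self.photons_per_pixel <= 0:
            raise ValidationError("photons_per_pixel must be > 0")


def default_group_params() -> dict[str, GroupParams]:
    """Simulation defaults for the four study groups.

    Effect directions follow the study's qualitative findings (longer
    lifetime, thicker epidermis, more puncta, larger long-component
    fraction in inflamed skin); magnitudes are simulation choices, with
    eczema placed between pseudo-control and psoriasis.
    """
    return {
        "control": GroupParams(
            group_label="control",
            tau1_ns=0.30, tau2_ns=2.0, a2_fraction=0.30,
            sg_depth_um=25.0, sb_depth_um=55.0, puncta_density=30.0,
        ),
        "pseudo_control": GroupParams(
            group_label="pseudo_control",
            tau1_ns=0.32, tau2_ns=2.2, a2_fraction=0.34,
            sg_depth_um=25.0, sb_depth_um=60.0, puncta_density=45.0,
        ),
        "eczema": GroupParams(
            group_label="eczema",
            tau1_ns=0.33, tau2_ns=2.3, a2_fraction=0.37,
            sg_depth_um=27.5, sb_depth_um=70.0, puncta_density=52.0,
        ),
        "psoriasis": GroupParams(
            group_label="psoriasis",
            tau1_ns=0.35, tau2_ns=2.4, a2_fraction=0.40,
            sg_depth_um=30.0, sb_depth_um=90.0, puncta_density=60.0,
        ),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level acquisition and coupling settings.

    The acquisition geometry defaults mirror the imaging protocol the
    analysis was designed around: a 200 um x 200 um field of view recorded
    as 40 optical sections in 5 um steps down to 200 um, with per-pixel
    TCSPC histograms of 256 bins over 12.5 ns (an 80 MHz repetition rate).
    ``frame_size`` and ``n_time_bins`` are configurable because analyses at
    reduced resolution are statistically equivalent and much cheaper.

    ``layers_only=True`` materialises only the two optical sections the
    feature extraction consumes (SG and SB); the depth metadata still
    reflects their true axial positions.

    ``pasi_coupling_r`` is the target correlation between the latent
    severity of a psoriasis subject and its generated PASI score;
    ``severity_scale`` multiplies the per-subject severity shifts of the
    inflamed-site parameters.
    """

    group_params: dict[str, GroupParams] = field(
        default_factory=default_group_params
    )
    frame_size: int = 512
    n_time_bins: int = 256
    time_range_ns: float = 12.5
    depth_step_um: float = 5.0
    n_sections: int = 40
    layers_only: bool = False
    pasi_coupling_r: float = 0.5
    severity_scale: float = 1.0
    subject_tau2_sd_ns: float = 0.05
    subject_depth_sd_um: float = 2.5
    subject_puncta_sd: float = 5.0
    subject_a2_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.frame_size < 64:
            raise ConfigurationError("frame_size must be >= 64")
        if self.n_time_bins < 32:
            raise ConfigurationError("n_time_bins must be >= 32")
        if self.time_range_ns <= 0:
            raise ConfigurationError("time_range_ns must be positive")
        if self.n_sections < 2 or self.depth_step_um <= 0:
            raise ConfigurationError("need >= 2 sections at a positive step")
        if not -1 < self.pasi_coupling_r < 1:
            raise ConfigurationError("pasi_coupling_r must lie in (-1, 1)")

    @property
    def time_bin_ns(self) -> float:
        return self.time_range_ns / self.n_time_bins

    def depths_um(self) -> np.ndarray:
        return np.arange(self.n_sections) * self.depth_step_um


@dataclass
class SiteStack:
    """One imaging site: a stack of decay frames with depth metadata."""

    site_label: str  # "lesional", "pseudo_control" or "primary"
    group_label: str  # group the site's tissue belongs to
    frames: list[DecayCube]
    sg_depth_um: float
    sb_depth_um: float

    @property
    def depths_um(self) -> np.ndarray:
        return np.array([f.depth_um for f in self.frames])


@dataclass
class SyntheticSubject:
    subject_id: str
    group_label: str
    sites: dict[str, SiteStack]
    pasi: int | None
    lis: int | None
    truth: dict[str, GroupParams]

    def __post_init__(self) -> None:
        n_sites = len(self.sites)
        if self.group_label == "psoriasis" and n_sites != 2:
            raise ValidationError("psoriasis subjects must have 2 sites")
        if self.group_label in ("control", "eczema") and n_sites != 1:
            raise ValidationError(
                f"{self.group_label} subjects must have exactly 1 site"
            )


def _cellular_texture(
    rng: np.random.Generator, size: int, amplitude: float
) -> np.ndarray:
    """Multiplicative amplitude texture: blobs, cytoplasm rings, nuclei.

    Feature sizes are in pixels so the spectral content scales with the
    frame the way the annulus radii of the Fourier parameter do.  Returns a
    positive field normalised to mean 1.
    """
    if amplitude == 0:
        return np.ones((size, size))
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    # Smooth background field from low-frequency cosines (cheap, seedable).
    field_ = np.zeros((size, size))
    n_modes = 8
    freqs = rng.uniform(1.0, 4.0, size=n_modes)
    angles = rng.uniform(0, np.pi, size=n_modes)
    phases = rng.uniform(0, 2 * np.pi, size=n_modes)
    amps = rng.uniform(0.3, 1.0, size=n_modes)
    for fq, an, ph, am in zip(freqs, angles, phases, amps):
        k = 2 * np.pi * fq / size
        field_ += am * np.cos(
            k * (xx * np.cos(an) + yy * np.sin(an)) + ph
        )
    field_ /= max(np.abs(field_).max(), 1e-9)

    # Cells: bright cytoplasm ring around a dark nucleus.  The spacing is
    # a fixed fraction of the frame so the cell-scale spectral power lands
    # in the medium-frequency annulus at any frame size.
    cell_spacing = max(size / 18.0, 6.0)
    n_cells = rng.poisson((size / cell_spacing) ** 2)
    ring_r = cell_spacing * 0.38
    ring_w = cell_spacing * 0.12
    nucleus_r = cell_spacing * 0.2
    cells = np.zeros((size, size))
    half = int(np.ceil(ring_r + 3 * ring_w))
    for _ in range(n_cells):
        cy, cx = rng.uniform(0, size, size=2)
        iy, ix = int(round(cy)), int(round(cx))
        y0, y1 = max(iy - half, 0), min(iy + half + 1, size)
        x0, x1 = max(ix - half, 0), min(ix + half + 1, size)
        if y0 >= y1 or x0 >= x1:
            continue
        d2 = (yy[y0:y1, x0:x1] - cy) ** 2 + (xx[y0:y1, x0:x1] - cx) ** 2
        d = np.sqrt(d2)
        cells[y0:y1, x0:x1] += 0.8 * np.exp(
            -((d - ring_r) ** 2) / (2 * ring_w**2)
        ) - 0.7 * np.exp(-d2 / (2 * nucleus_r**2))
    texture = 1.0 + amplitude * (0.6 * field_ + cells)
    texture = np.clip(texture, 0.05, None)
    return texture / texture.mean()


def _add_puncta(
    rng: np.random.Generator,
    texture: np.ndarray,
    density: float,
    brightness: float = 3.0,
) -> np.ndarray:
    """Stamp bright sub-cellular puncta (Gaussian spots, sigma 0.6-1.2 px)."""
    n = rng.poisson(density)
    if n == 0:
        return texture
    size = texture.shape[0]
    out = texture.copy()
    half = 4
    for _ in range(n):
        cy, cx = rng.uniform(half, size - half - 1, size=2)
        sigma = rng.uniform(0.6, 1.2)
        iy, ix = int(round(cy)), int(round(cx))
        yy, xx = np.mgrid[iy - half : iy + half + 1, ix - half : ix + half + 1]
        spot = brightness * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)
        )
        out[iy - half : iy + half + 1, ix - half : ix + half + 1] += spot
    return out / out.mean()


def generate_decay_frame(
    params: GroupParams,
    depth_um: float,
    frame_size: int = 512,
    n_time_bins: int = 256,
    time_range_ns: float = 12.5,
    seed: int | np.random.SeedSequence = 0,
) -> DecayCube:
    """Generate one synthetic optical section as a decay cube.

    The per-pixel expected decay is
    ``A(x,y) * [(1-q(x,y)) exp(-t/tau1) + q(x,y) exp(-t/tau2)]`` normalised
    so that the expected total photon count per pixel is
    ``photons_per_pixel * A(x,y)`` with ``mean(A) = 1``; counts are Poisson.
    Identical ``(params, seed)`` give bit-identical cubes.
    """
    if frame_size < 64:
        raise ConfigurationError("frame_size must be >= 64")
    if n_time_bins < 32:
        raise ConfigurationError("n_time_bins must be >= 32")
    if time_range_ns <= 0:
        raise ConfigurationError("time_range_ns must be positive")
    rng = np.random.default_rng(seed)
    texture = _cellular_texture(rng, frame_size, params.texture_amplitude)
    texture = _add_puncta(rng, texture, params.puncta_density)

    # Long-component fraction weakly tracks the texture (metabolically
    # active structures carry more bound-NAD(P)H-like signal).
    if params.texture_amplitude > 0:
        q = np.clip(
            params.a2_fraction * (1.0 + 0.15 * (texture - 1.0)), 0.0, 0.99
        )
    else:
        q = np.full((frame_size, frame_size), params.a2_fraction)

    dt = time_range_ns / n_time_bins
    t = (np.arange(n_time_bins) + 0.5) * dt
    e1 = np.exp(-t / params.tau1_ns)
    e2 = np.exp(-t / params.tau2_ns)
    # shape (y, x, t); normalise each pixel's profile to unit sum so the
    # expected total equals photons_per_pixel * texture.
    profile = (1.0 - q)[:, :, None] * e1[None, None, :] + q[:, :, None] * e2[
        None, None, :
    ]
    profile /= profile.sum(axis=2, keepdims=True)
    lam = (params.photons_per_pixel * texture)[:, :, None] * profile
    counts = rng.poisson(lam).astype(np.uint16)
    return DecayCube(counts, time_bin_ns=dt, depth_um=float(depth_um))


def _snap(value: float, step: float) -> float:
    return round(value / step) * step


def _perturbed_site_params(
    base: GroupParams,
    cfg: CohortConfig,
    rng: np.random.Generator,
    severity_z: float = 0.0,
) -> GroupParams:
    """Subject-level jitter plus the latent-severity shift (inflamed sites)."""
    s = cfg.severity_scale * severity_z
    tau2 = base.tau2_ns + rng.normal(0, cfg.subject_tau2_sd_ns) + 0.08 * s
    a2 = base.a2_fraction + rng.normal(0, cfg.subject_a2_sd) + 0.03 * s
    sg = base.sg_depth_um + _snap(
        rng.normal(0, cfg.subject_depth_sd_um), cfg.depth_step_um
    )
    sb = base.sb_depth_um + _snap(
        rng.normal(0, cfg.subject_depth_sd_um) + 8.0 * s, cfg.depth_step_um
    )
    puncta = base.puncta_density + rng.normal(0, cfg.subject_puncta_sd) + 10.0 * s
    sg = max(_snap(sg, cfg.depth_step_um), cfg.depth_step_um)
    sb = max(_snap(sb, cfg.depth_step_um), sg + cfg.depth_step_um)
    max_depth = (cfg.n_sections - 1) * cfg.depth_step_um
    sb = min(sb, max_depth)
    sg = min(sg, sb - cfg.depth_step_um)
    return replace(
        base,
        tau2_ns=float(np.clip(tau2, base.tau1_ns * 2, 9.0)),
        a2_fraction=float(np.clip(a2, 0.02, 0.98)),
        sg_depth_um=float(sg),
        sb_depth_um=float(sb),
        puncta_density=float(max(puncta, 0.0)),
    )


def _build_site(
    label: str,
    params: GroupParams,
    cfg: CohortConfig,
    seed_seq: np.random.SeedSequence,
) -> SiteStack:
    if cfg.layers_only:
        depths = [params.sg_depth_um, params.sb_depth_um]
    else:
        depths = list(cfg.depths_um())
    child_seeds = seed_seq.spawn(len(depths))
    frames = [
        generate_decay_frame(
            params,
            depth_um=d,
            frame_size=cfg.frame_size,
            n_time_bins=cfg.n_time_bins,
            time_range_ns=cfg.time_range_ns,
            seed=cs,
        )
        for d, cs in zip(depths, child_seeds)
    ]
    return SiteStack(
        site_label=label,
        group_label=params.group_label,
        frames=frames,
        sg_depth_um=params.sg_depth_um,
        sb_depth_um=params.sb_depth_um,
    )


def generate_subject(
    group: str,
    config: CohortConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    subject_id: str | None = None,
) -> SyntheticSubject:
    """Generate one subject with its imaging site(s) and clinical scores.

    Psoriasis subjects get a lesional and a pseudo-control site plus PASI
    and LIS scores; control and eczema subjects a single site and no
    scores.  ``pseudo_control`` is not a valid subject group (it only
    exists as a site of a psoriasis subject).
    """
    cfg = config or CohortConfig()
    if group not in ("control", "psoriasis", "eczema"):
        raise ValidationError(
            f"unknown subject group {group!r}; "
            "expected control, psoriasis or eczema"
        )
    seed_seq = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    param_seq, site_seq = seed_seq.spawn(2)
    rng = np.random.default_rng(param_seq)
    subject_id = subject_id or f"{group}-{seed_seq.entropy}-{seed_seq.spawn_key}"

    sites: dict[str, SiteStack] = {}
    truth: dict[str, GroupParams] = {}
    pasi = lis = None
    if group == "psoriasis":
        z = rng.standard_normal()
        lesional = _perturbed_site_params(
            cfg.group_params["psoriasis"], cfg, rng, severity_z=z
        )
        pseudo = _perturbed_site_params(
            cfg.group_params["pseudo_control"], cfg, rng
        )
        les_seq, pseudo_seq = site_seq.spawn(2)
        sites["lesional"] = _build_site("lesional", lesional, cfg, les_seq)
        sites["pseudo_control"] = _build_site(
            "pseudo_control", pseudo, cfg, pseudo_seq
        )
        truth = {"lesional": lesional, "pseudo_control": pseudo}
        r = cfg.pasi_coupling_r
        gp = cfg.group_params["psoriasis"]
        pasi_latent = r * z + math.sqrt(1 - r * r) * rng.standard_normal()
        pasi = int(np.clip(round(gp.pasi_mean + gp.pasi_sd * pasi_latent), 1, 29))
        lis_latent = 0.5 * z + math.sqrt(0.75) * rng.standard_normal()
        lis = int(np.clip(round(gp.lis_mean + gp.lis_sd * lis_latent), 1, 10))
    else:
        params = _perturbed_site_params(cfg.group_params[group], cfg, rng)
        (only_seq,) = site_seq.spawn(1)
        sites["primary"] = _build_site("primary", params, cfg, only_seq)
        truth = {"primary": params}
    return SyntheticSubject(
        subject_id=subject_id,
        group_label=group,
        sites=sites,
        pasi=pasi,
        lis=lis,
        truth=truth,
    )


def generate_cohort(
    n_per_group: dict[str, int],
    config: CohortConfig | None = None,
    seed: int = 0,
) -> tuple[list[SyntheticSubject], "pandas.DataFrame"]:
    """Generate a cohort; returns the subjects and a truth table.

    ``n_per_group`` maps subject groups (control/psoriasis/eczema) to
    counts; a study-sized cohort is ``{"control": 18, "psoriasis": 33,
    "eczema": 7}``.  Deterministic for a fixed seed.
    """
    import pandas as pd

    cfg = config or CohortConfig()
    for g, n in n_per_group.items():
        if g not in ("control", "psoriasis", "eczema"):
            raise ValidationError(f"unknown subject group {g!r}")
        if n < 0:
            raise ValidationError("n_per_group values must be >= 0")
    root = np.random.SeedSequence(seed)
    subjects: list[SyntheticSubject] = []
    rows = []
    idx = 0
    for group in ("control", "psoriasis", "eczema"):
        n = n_per_group.get(group, 0)
        if n == 0:
            continue
        for j, child in enumerate(root.spawn(n)):
            subj = generate_subject(
                group, cfg, seed=child, subject_id=f"{group}-{j:03d}"
            )
            subjects.append(subj)
            for site_label, params in subj.truth.items():
                rows.append(
                    {
                        "subject_id": subj.subject_id,
                        "group": subj.group_label,
                        "site": site_label,
                        "site_group": params.group_label,
                        "tau1_ns": params.tau1_ns,
                        "tau2_ns": params.tau2_ns,
                        "a2_fraction": params.a2_fraction,
                        "sg_depth_um": params.sg_depth_um,
                        "sb_depth_um": params.sb_depth_um,
                        "puncta_density": params.puncta_density,
                        "pasi": subj.pasi,
                        "lis": subj.lis,
                    }
                )
            idx += 1
    truth_table = pd.DataFrame(rows)
    return subjects, truth_table
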