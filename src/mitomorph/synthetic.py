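"""Synthetic microscopy fields and label-free quant tables with known truth.

The image simulator emulates confocal fields of fibroblast mitochondria:
a *filamentous* network state is drawn as cubic-spline-smoothed bounded-
curvature random walks (optionally with one side branch per filament),
a *fragmented* state as filled ellipses; the fraction of fragmented
objects is the dial that mitochondrial depolarization (CCCP) turns up.
Objects are rendered into a binary truth mask, optionally distributed
over z-slices with Gaussian z-weighting, blurred with a Gaussian PSF and
corrupted with Poisson shot noise on (background + photon_scale·signal).
A second channel carries a marker enriched multiplicatively inside the
mitochondrial truth mask.

The study design mirrors the source experiment: two groups (CTRL and a
mutant line) × two treatments (DMSO vehicle, CCCP) with five subjects per
group and five fields of view per sample by default.

The proteomics simulator emits a PLGS-style table of per-replicate
log2(patient/control) ratios for three technical replicates, with a
planted fraction of changed proteins, per-replicate missingness,
condition-unique proteins (all ratios missing), and isoform groups that
share a root accession with "-n" suffixes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.interpolate import splev, splprep
from skimage.draw import ellipse as draw_ellipse
from skimage.morphology import disk as disk_footprint

from .core import CalibratedImage

__all__ = [
    "ImageSimConfig",
    "StudyDesign",
    "ProteomeSimConfig",
    "ImageStudySet",
    "simulate_mito_image",
    "simulate_population",
    "simulate_proteome_table",
]


# ------------------------------------------------------------------ configs


@dataclass(frozen=True)
class ImageSimConfig:
    image_shape: tuple[int, int] = (256, 256)
    n_slices: int = 3
    pixel_size_um: float = 0.1
    n_filaments: int = 15
    filament_length_um: tuple[float, float] = (4.0, 1.5)  # mean, sd
    filament_width_um: float = 0.4
    branching_prob: float = 0.3
    fragment_fraction: float = 0.2
    fragment_axes_um: tuple[float, float] = (0.8, 0.5)  # major, minor means
    psf_sigma_um: float = 0.15
    background_level: float = 50.0
    photon_scale: float = 150.0
    marker_enrichment: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.image_shape) or self.n_slices <= 0:
            raise ValueError("image dimensions must be positive")
        if not 0.0 <= self.fragment_fraction <= 1.0:
            raise ValueError("fragment_fraction must lie in [0, 1]")
        if not 0.0 <= self.branching_prob <= 1.0:
            raise ValueError("branching_prob must lie in [0, 1]")
        for name in ("pixel_size_um", "filament_width_um", "psf_sigma_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.background_level < 0 or self.photon_scale < 0:
            raise ValueError("noise levels must be non-negative")


@dataclass(frozen=True)
class StudyDesign:
    groups: tuple[str, str] = ("CTRL", "MUT")
    treatments: tuple[str, str] = ("DMSO", "CCCP")
    n_subjects_per_group: int = 5
    n_fov_per_sample: int = 5
    base_config: ImageSimConfig = field(default_factory=ImageSimConfig)
    # per-cell overrides: {(group, treatment): {field: value}}
    overrides: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1 or self.n_fov_per_sample < 1:
            raise ValueError("design requires at least one subject and one field of view")


@dataclass(frozen=True)
class ProteomeSimConfig:
    n_proteins: int = 1000
    frac_changed: float = 0.2
    effect_size_log2: float = 1.0
    replicate_cv: float = 0.1
    n_replicates: int = 3
    missing_prob: float = 0.05
    frac_unique: float = 0.05
    n_isoform_groups: int = 0
    isoforms_per_group: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_changed", "missing_prob", "frac_unique"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.frac_changed + self.frac_unique > 1.0:
            raise ValueError("frac_changed + frac_unique must not exceed 1")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be at least 2")


# ------------------------------------------------------------ image renderer


def _render_filament(rng: np.random.Generator, cfg: ImageSimConfig, canvas: np.ndarray) -> int:
    """Rasterize one spline-smoothed bounded-curvature walk; return px drawn."""
    h, w = cfg.image_shape
    length_um = max(rng.normal(*cfg.filament_length_um), cfg.filament_width_um)
    length_px = length_um / cfg.pixel_size_um
    coarse_step = max(length_px / 12.0, 2.0)
    n_steps = max(int(round(length_px / coarse_step)), 2)

    margin = 4
    pos = np.array(
        [rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)], dtype=float
    )
    heading = rng.uniform(0, 2 * np.pi)
    pts = [pos.copy()]
    for _ in range(n_steps):
        heading += np.clip(rng.normal(0.0, 0.45), -0.8, 0.8)  # bounded curvature
        pos = pos + coarse_step * np.array([np.sin(heading), np.cos(heading)])
        pos = np.clip(pos, margin, [h - margin, w - margin])
        pts.append(pos.copy())
    way = np.array(pts)

    drawn = _draw_path(way, cfg, canvas)
    if rng.random() < cfg.branching_prob and len(way) >= 3:
        i = rng.integers(1, len(way) - 1)
        bh = heading + rng.choice([-1.0, 1.0]) * rng.uniform(0.7, 1.5)
        bl = length_px * rng.uniform(0.3, 0.6)
        bn = max(int(round(bl / coarse_step)), 2)
        bpos = way[i].copy()
        bpts = [bpos.copy()]
        for _ in range(bn):
            bh += np.clip(rng.normal(0.0, 0.45), -0.8, 0.8)
            bpos = bpos + coarse_step * np.array([np.sin(bh), np.cos(bh)])
            bpos = np.clip(bpos, margin, [h - margin, w - margin])
            bpts.append(bpos.copy())
        drawn += _draw_path(np.array(bpts), cfg, canvas)
    return drawn


def _draw_path(way: np.ndarray, cfg: ImageSimConfig, canvas: np.ndarray) -> int:
    """Spline-smooth waypoints, sample densely, stamp width via dilation."""
    h, w = cfg.image_shape
    try:
        tck, _ = splprep([way[:, 0], way[:, 1]], s=len(way), k=min(3, len(way) - 1))
        u = np.linspace(0, 1, max(int(4 * len(way) * 3), 16))
        yy, xx = splev(u, tck)
    except Exception:  # nearly coincident waypoints: fall back to linear chain
        yy, xx = way[:, 0], way[:, 1]
    yy = np.clip(np.round(yy).astype(int), 0, h - 1)
    xx = np.clip(np.round(xx).astype(int), 0, w - 1)
    line = np.zeros_like(canvas)
    line[yy, xx] = True
    r = max(int(round(cfg.filament_width_um / cfg.pixel_size_um / 2)), 1)
    obj = ndi.binary_dilation(line, structure=disk_footprint(r))
    new = obj & ~canvas
    canvas |= obj
    return int(new.sum())


def _render_fragment(rng: np.random.Generator, cfg: ImageSimConfig, canvas: np.ndarray) -> int:
    h, w = cfg.image_shape
    maj = max(rng.normal(cfg.fragment_axes_um[0], cfg.fragment_axes_um[0] * 0.25), cfg.pixel_size_um)
    mino = max(rng.normal(cfg.fragment_axes_um[1], cfg.fragment_axes_um[1] * 0.25), cfg.pixel_size_um)
    cy = rng.uniform(4, h - 4)
    cx = rng.uniform(4, w - 4)
    theta = rng.uniform(0, np.pi)
    rr, cc = draw_ellipse(
        cy,
        cx,
        max(maj / cfg.pixel_size_um / 2, 1.0),
        max(mino / cfg.pixel_size_um / 2, 1.0),
        shape=(h, w),
        rotation=theta,
    )
    obj = np.zeros_like(canvas)
    obj[rr, cc] = True
    new = obj & ~canvas
    canvas |= obj
    return int(new.sum())


def simulate_mito_image(config: ImageSimConfig):
    """Render one synthetic field of view.

    Returns ``(mito, marker, truth_mask, truth_table)``: two
    :class:`CalibratedImage` channels (z-stacks when ``n_slices > 1``),
    the pre-blur 2-D binary truth mask, and a table with one row per
    rendered object (type, nominal size, pixels newly covered).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_shape
    canvas = np.zeros((h, w), dtype=bool)

    n_frag = int(round(cfg.fragment_fraction * cfg.n_filaments))
    kinds = ["fragment"] * n_frag + ["filament"] * (cfg.n_filaments - n_frag)
    rows = []
    for i, kind in enumerate(kinds):
        if kind == "filament":
            n_px = _render_filament(rng, cfg, canvas)
        else:
            n_px = _render_fragment(rng, cfg, canvas)
        rows.append(dict(object_id=i, type=kind, n_new_pixels=n_px))
    truth_table = pd.DataFrame(rows)
    signal2d = canvas.astype(np.float64)

    # distribute over z with Gaussian weights around a per-image focal plane
    if cfg.n_slices > 1:
        z = np.arange(cfg.n_slices, dtype=np.float64)
        zc = (cfg.n_slices - 1) / 2.0
        weights = np.exp(-0.5 * ((z - zc) / max(cfg.n_slices / 3.0, 1.0)) ** 2)
        signal = signal2d[None, :, :] * weights[:, None, None]
    else:
        signal = signal2d[None, :, :]

    sigma_px = cfg.psf_sigma_um / cfg.pixel_size_um
    blurred = np.stack([ndi.gaussian_filter(s, sigma_px, mode="reflect") for s in signal])
    marker_sig = np.stack(
        [ndi.gaussian_filter(s * cfg.marker_enrichment, sigma_px, mode="reflect") for s in signal]
    )

    mito_px = rng.poisson(cfg.background_level + cfg.photon_scale * blurred).astype(np.float64)
    marker_px = rng.poisson(cfg.background_level + cfg.photon_scale * marker_sig).astype(np.float64)
    if cfg.n_slices == 1:
        mito_px, marker_px = mito_px[0], marker_px[0]

    mito = CalibratedImage(mito_px, cfg.pixel_size_um, channel="mito")
    marker = CalibratedImage(marker_px, cfg.pixel_size_um, channel="marker")
    return mito, marker, canvas, truth_table


# --------------------------------------------------------------- population


@dataclass
class ImageStudySet:
    images: list  # records: dict(subject, group, treatment, fov, mito, marker, truth_mask, truth_table)
    metadata: pd.DataFrame


def simulate_population(design: StudyDesign) -> ImageStudySet:
    """Simulate the full balanced 2×2 study.

    Per-cell configuration overrides (e.g. a higher ``fragment_fraction``
    for CCCP-treated cells) are applied via ``design.overrides`` keyed by
    ``(group, treatment)``.  Every image gets an independent child seed
    derived deterministically from ``design.seed``.
    """
    ss = np.random.SeedSequence(design.seed)
    images, meta = [], []
    n_images = (
        len(design.groups) * len(design.treatments)
        * design.n_subjects_per_group * design.n_fov_per_sample
    )
    children = ss.spawn(n_images)
    i = 0
    for group in design.groups:
        for s in range(design.n_subjects_per_group):
            subject = f"{group}{s + 1}"
            for treatment in design.treatments:
                cfg_cell = design.base_config
                ov = design.overrides.get((group, treatment))
                if ov:
                    cfg_cell = replace(cfg_cell, **ov)
                for fov in range(design.n_fov_per_sample):
                    seed = int(children[i].generate_state(1)[0] % (2 ** 31))
                    i += 1
                    cfg = replace(cfg_cell, seed=seed)
                    mito, marker, mask, table = simulate_mito_image(cfg)
                    images.append(
                        dict(
                            subject=subject,
                            group=group,
                            treatment=treatment,
                            fov=fov,
                            mito=mito,
                            marker=marker,
                            truth_mask=mask,
                            truth_table=table,
                        )
                    )
                    meta.append(
                        dict(subject=subject, group=group, treatment=treatment, fov=fov, seed=seed)
                    )
    return ImageStudySet(images=images, metadata=pd.DataFrame(meta))


# ---------------------------------------------------------------- proteomics


def simulate_proteome_table(config: ProteomeSimConfig) -> pd.DataFrame:
    """PLGS-style replicate-level log2(P/C) table with planted truth.

    Columns: ``accession``, ``replicate_1..n`` (log2 ratio, NaN when the
    replicate missed the protein), ``n_detected``, ``uniqueness``
    (none | patient_only | control_only), ``truth_label``
    (changed | unchanged | unique) and ``truth_log2``.  The first
    ``n_isoform_groups`` proteins are emitted as ``isoforms_per_group``
    rows sharing a root accession with ``-k`` suffixes and the same truth.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_proteins
    n_changed = int(round(cfg.frac_changed * n))
    n_unique = int(round(cfg.frac_unique * n))
    labels = np.array(
        ["changed"] * n_changed + ["unique"] * n_unique + ["unchanged"] * (n - n_changed - n_unique)
    )
    rng.shuffle(labels)

    sigma = np.log2(1.0 + cfg.replicate_cv)
    truth = np.zeros(n)
    changed_idx = labels == "changed"
    truth[changed_idx] = rng.choice([-1.0, 1.0], changed_idx.sum()) * cfg.effect_size_log2

    rows = []
    for i in range(n):
        root = f"P{i + 1:05d}"
        n_iso = cfg.isoforms_per_group if i < cfg.n_isoform_groups else 1
        for k in range(n_iso):
            acc = root if k == 0 else f"{root}-{k + 1}"
            if labels[i] == "unique":
                reps = [np.nan] * cfg.n_replicates
                n_det = int(rng.binomial(cfg.n_replicates, 1.0 - cfg.missing_prob))
                uniq = rng.choice(["patient_only", "control_only"])
            else:
                detected = rng.random(cfg.n_replicates) >= cfg.missing_prob
                vals = truth[i] + rng.normal(0.0, sigma, cfg.n_replicates)
                reps = [v if d else np.nan for v, d in zip(vals, detected)]
                n_det = int(detected.sum())
                uniq = "none"
            rows.append(
                dict(
                    accession=acc,
                    **{f"replicate_{j + 1}": reps[j] for j in range(cfg.n_replicates)},
                    n_detected=n_det,
                    uniqueness=uniq,
                    truth_label=labels[i],
                    truth_log2=truth[i],
                )
            )
    return pd.DataFrame(rows)
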