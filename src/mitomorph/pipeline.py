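"""End-to-end pipelines: images → morphology statistics, tables → differential results.

Two entry levels are provided.  In-memory functions (:func:`analyze_study`,
:func:`run_proteomics`) operate on simulated study sets or data frames and
are what the test-bench and repeated-study simulations call.  File-level
wrappers (:func:`run_morphology_pipeline`, :func:`run_proteomics_pipeline`)
read a manifest/CSV, write every output table plus a provenance JSON
recording all parameters, and are what the command line drives.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import BinaryMask, CalibratedImage
from .morphometrics import PARAMETER_NAMES, measure_particles, particle_table
from .morphostats import sample_distance_table, two_way_anova
from .proteodiff import (
    FC_LOG2,
    collapse_isoforms,
    filter_differential,
    preranked_enrichment,
    ranked_list,
    read_gmt,
    summarize_replicates,
    volcano_table,
)
from .segmentation import binarize_and_clean, max_project, threshold_image, unsharp_mask
from .skeleton import analyze_skeleton, skeletonize
from .synthetic import ImageStudySet, StudyDesign, simulate_population

__all__ = [
    "MorphologyParams",
    "MorphologyResults",
    "segment_mito",
    "analyze_study",
    "study_anova_pvalues",
    "factor_rejection_rates",
    "run_proteomics",
    "run_morphology_pipeline",
    "run_proteomics_pipeline",
    "save_study",
    "load_image_set",
    "blind_study",
    "unblind_table",
]


@dataclass(frozen=True)
class MorphologyParams:
    unsharp_sigma_px: float = 1.0
    unsharp_weight: float = 0.6
    threshold_method: str = "huang"
    per_slice_threshold: bool = True
    min_area_px: int = 5
    clear_border: bool = False
    parameters: tuple = PARAMETER_NAMES
    distance_unit: str = "fov"
    leave_one_out: bool = True
    reference_group: str = "CTRL"
    reference_treatment: str = "DMSO"
    with_skeleton: bool = True


@dataclass
class MorphologyResults:
    particles: pd.DataFrame
    skeletons: pd.DataFrame
    distances: dict
    anova: dict


def segment_mito(img: CalibratedImage, params: MorphologyParams) -> BinaryMask:
    """Unsharp mask → automatic threshold → binarize and clean."""
    sharp = unsharp_mask(img, params.unsharp_sigma_px, params.unsharp_weight)
    thr = threshold_image(sharp, method=params.threshold_method, per_slice=params.per_slice_threshold)
    return binarize_and_clean(
        sharp, thr if img.is_stack else thr[0], params.min_area_px, params.clear_border
    )


def analyze_study(study: ImageStudySet, params: MorphologyParams = MorphologyParams()) -> MorphologyResults:
    """Segment and measure every field of view, then distance + ANOVA stats.

    Fields of view whose segmentation is empty are excluded with a warning;
    the distance/ANOVA stage then sees whatever remains.
    """
    all_particles = []
    skeleton_rows = []
    for rec in study.images:
        mask = segment_mito(rec["mito"], params)
        parts = measure_particles(
            mask,
            subject=rec["subject"],
            group=rec["group"],
            treatment=rec["treatment"],
            fov=rec["fov"],
        )
        if not parts:
            warnings.warn(
                f"empty segmentation for {rec['subject']}/{rec['treatment']}/fov{rec['fov']}; excluded"
            )
            continue
        all_particles.extend(parts)
        if params.with_skeleton:
            mask2d = BinaryMask(
                mask.pixels.max(axis=0) if mask.is_stack else mask.pixels,
                mask.pixel_size_um,
                provenance=mask.provenance,
            )
            summ = analyze_skeleton(skeletonize(mask2d), footprint_um2=mask2d.area_um2)
            skeleton_rows.append(
                dict(
                    subject=rec["subject"],
                    group=rec["group"],
                    treatment=rec["treatment"],
                    fov=rec["fov"],
                    n_branches=summ.n_branches,
                    n_junctions=summ.n_junctions,
                    n_individuals=summ.n_individuals,
                    n_networks=summ.n_networks,
                    mean_branch_length_um=summ.mean_branch_length_um,
                    mean_network_size=summ.mean_network_size,
                    footprint_um2=summ.footprint_um2,
                )
            )

    particles = particle_table(all_particles)
    distances, anova = {}, {}
    for param in params.parameters:
        dist = sample_distance_table(
            particles,
            param,
            unit=params.distance_unit,
            leave_one_out=params.leave_one_out,
            reference_group=params.reference_group,
            reference_treatment=params.reference_treatment,
        )
        distances[param] = dist
        anova[param] = two_way_anova(dist, "D", "group", "treatment")
    return MorphologyResults(
        particles=particles,
        skeletons=pd.DataFrame(skeleton_rows),
        distances=distances,
        anova=anova,
    )


# ---------------------------------------------------------------- blinding


def blind_study(study: ImageStudySet, seed: int = 0) -> tuple[ImageStudySet, pd.DataFrame]:
    """Scramble sample identities so image analysis cannot see the groups.

    Mirrors the blinded-analysis safeguard of manual scoring: every
    (subject, treatment) sample gets an anonymous code in shuffled order;
    the returned key table maps codes back for the statistics stage (see
    :func:`unblind_table`).  The image measurements themselves never read
    the labels, so blinded and unblinded runs must produce identical
    numbers — a property the test suite asserts.
    """
    samples = sorted({(r["subject"], r["group"], r["treatment"]) for r in study.images})
    order = np.random.default_rng(seed).permutation(len(samples))
    codes = {s: f"S{order[i] + 1:03d}" for i, s in enumerate(samples)}
    key = pd.DataFrame(
        [dict(code=c, subject=s[0], group=s[1], treatment=s[2]) for s, c in codes.items()]
    )
    blinded_images = []
    for rec in study.images:
        r = dict(rec)
        r["subject"] = codes[(rec["subject"], rec["group"], rec["treatment"])]
        r["group"] = "BLINDED"
        r["treatment"] = "BLINDED"
        blinded_images.append(r)
    meta = pd.DataFrame(
        [dict(subject=r["subject"], group=r["group"], treatment=r["treatment"], fov=r["fov"])
         for r in blinded_images]
    )
    return ImageStudySet(images=blinded_images, metadata=meta), key


def unblind_table(table: pd.DataFrame, key: pd.DataFrame) -> pd.DataFrame:
    """Restore subject/group/treatment columns from the blinding key."""
    out = table.drop(columns=[c for c in ("group", "treatment") if c in table.columns])
    out = out.rename(columns={"subject": "code"})
    return out.merge(key, on="code", how="left").drop(columns=["code"])


# ----------------------------------------------- repeated-study simulations


def study_anova_pvalues(design: StudyDesign, params: MorphologyParams) -> dict:
    """One simulated study → {parameter: {factor: p}}."""
    res = analyze_study(simulate_population(design), params)
    return {
        param: {f: res.anova[param].p(f) for f in ("mutation", "treatment", "interaction")}
        for param in params.parameters
    }


def factor_rejection_rates(
    n_studies: int,
    design: StudyDesign,
    params: MorphologyParams,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Fraction of simulated studies rejecting each factor at ``alpha``.

    Each study re-runs the full pipeline (simulation → segmentation →
    morphometrics → KS distances → ANOVA) with an independent child seed.
    Returns {parameter: {factor: rejection rate}}.
    """
    children = np.random.SeedSequence(seed).spawn(n_studies)
    counts = {p: {f: 0 for f in ("mutation", "treatment", "interaction")} for p in params.parameters}
    for ch in children:
        d = replace(design, seed=int(ch.generate_state(1)[0] % (2 ** 31)))
        pvals = study_anova_pvalues(d, params)
        for param, fs in pvals.items():
            for f, p in fs.items():
                if p < alpha:
                    counts[param][f] += 1
    return {p: {f: c / n_studies for f, c in fs.items()} for p, fs in counts.items()}


# ------------------------------------------------------------- proteomics


def run_proteomics(
    table: pd.DataFrame,
    min_detected: int = 2,
    fc_log2: float = FC_LOG2,
    alpha: float = 0.05,
    gene_sets: dict | None = None,
    n_perm: int = 10000,
    seed: int = 0,
):
    """Summarize → collapse isoforms → filter → volcano → ranked list (→ GSEA).

    Returns a dict with keys ``diff`` (:class:`DiffTable`), ``volcano``,
    ``ranked`` and, when gene sets are given, ``enrichment``.
    """
    if table.empty:
        raise ValueError("empty input table")
    summarized = summarize_replicates(table)
    collapsed = collapse_isoforms(summarized)
    diff = filter_differential(collapsed, min_detected=min_detected, fc_log2=fc_log2, alpha=alpha)
    out = {
        "collapsed": collapsed,
        "diff": diff,
        "volcano": volcano_table(collapsed, fc_log2=fc_log2, alpha=alpha),
        "ranked": ranked_list(collapsed),
    }
    if gene_sets:
        out["enrichment"] = preranked_enrichment(out["ranked"], gene_sets, n_perm=n_perm, seed=seed)
    return out


# --------------------------------------------------------------- file level


def save_study(study: ImageStudySet, outdir) -> pd.DataFrame:
    """Write per-fov multi-page TIFFs plus metadata and truth CSVs."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    truth_rows = []
    for rec in study.images:
        stem = f"{rec['subject']}_{rec['treatment']}_fov{rec['fov']}"
        p_mito = outdir / f"{stem}_mito.tif"
        p_marker = outdir / f"{stem}_marker.tif"
        for path, img in ((p_mito, rec["mito"]), (p_marker, rec["marker"])):
            data = img.pixels if img.is_stack else img.pixels[None]
            tifffile.imwrite(path, data.astype(np.float32))
        rows.append(
            dict(
                subject=rec["subject"],
                group=rec["group"],
                treatment=rec["treatment"],
                fov=rec["fov"],
                pixel_size_um=rec["mito"].pixel_size_um,
                path_mito=str(p_mito),
                path_marker=str(p_marker),
            )
        )
        t = rec["truth_table"].copy()
        t.insert(0, "subject", rec["subject"])
        t.insert(1, "treatment", rec["treatment"])
        t.insert(2, "fov", rec["fov"])
        truth_rows.append(t)
    meta = pd.DataFrame(rows)
    meta.to_csv(outdir / "metadata.csv", index=False)
    pd.concat(truth_rows, ignore_index=True).to_csv(outdir / "truth.csv", index=False)
    return meta


def load_image_set(row: pd.Series) -> dict:
    """Re-load one manifest row written by :func:`save_study`."""
    import tifffile

    mito = tifffile.imread(row["path_mito"])
    marker = tifffile.imread(row["path_marker"])
    cal = float(row["pixel_size_um"])
    return dict(
        subject=row["subject"],
        group=row["group"],
        treatment=row["treatment"],
        fov=int(row["fov"]),
        mito=CalibratedImage(mito if mito.ndim == 3 else mito, cal, channel="mito"),
        marker=CalibratedImage(marker if marker.ndim == 3 else marker, cal, channel="marker"),
        truth_mask=None,
        truth_table=None,
    )


def _write_provenance(outdir: Path, payload: dict) -> None:
    payload = dict(payload)
    payload["mitomorph_version"] = __version__
    (outdir / "provenance.json").write_text(json.dumps(payload, indent=2, default=str))


def run_morphology_pipeline(
    manifest_csv,
    outdir,
    params: MorphologyParams = MorphologyParams(),
) -> MorphologyResults:
    """Morphology pipeline over a manifest of TIFF image sets.

    Writes particles.csv, skeleton.csv, distances.csv, anova.csv and
    provenance.json to ``outdir``.
    """
    manifest = pd.read_csv(manifest_csv)
    required = {"subject", "group", "treatment", "fov", "pixel_size_um", "path_mito"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    images = [load_image_set(row) for _, row in manifest.iterrows()]
    study = ImageStudySet(images=images, metadata=manifest)
    results = analyze_study(study, params)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results.particles.to_csv(outdir / "particles.csv", index=False)
    results.skeletons.to_csv(outdir / "skeleton.csv", index=False)
    pd.concat(results.distances.values(), ignore_index=True).to_csv(
        outdir / "distances.csv", index=False
    )
    anova_rows = []
    for param, res in results.anova.items():
        t = res.table.reset_index(names="factor")
        t.insert(0, "parameter", param)
        anova_rows.append(t)
    pd.concat(anova_rows, ignore_index=True).to_csv(outdir / "anova.csv", index=False)
    _write_provenance(outdir, dict(pipeline="morphology", params=asdict(params), manifest=str(manifest_csv)))
    return results


def run_proteomics_pipeline(
    table_csv,
    outdir,
    min_detected: int = 2,
    fc_log2: float = FC_LOG2,
    alpha: float = 0.05,
    gmt_path=None,
    n_perm: int = 10000,
    seed: int = 0,
):
    """Proteomics pipeline over a replicate-level quant CSV.

    Writes filtered.csv, counts.json, volcano.csv, ranked.rnk and,
    with a GMT file, enrichment.csv — plus provenance.json.
    """
    table = pd.read_csv(table_csv)
    gene_sets = read_gmt(gmt_path) if gmt_path else None
    res = run_proteomics(
        table, min_detected=min_detected, fc_log2=fc_log2, alpha=alpha,
        gene_sets=gene_sets, n_perm=n_perm, seed=seed,
    )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res["diff"].table.to_csv(outdir / "filtered.csv", index=False)
    (outdir / "counts.json").write_text(json.dumps(res["diff"].counts, indent=2))
    res["volcano"].to_csv(outdir / "volcano.csv", index=False)
    res["ranked"].to_csv(outdir / "ranked.rnk", sep="\t", header=False, index=False)
    if "enrichment" in res:
        res["enrichment"].to_csv(outdir / "enrichment.csv", index=False)
    _write_provenance(
        outdir,
        dict(
            pipeline="proteomics",
            input=str(table_csv),
            min_detected=min_detected,
            fc_log2=fc_log2,
            alpha=alpha,
            n_perm=n_perm,
            seed=seed,
        ),
    )
    return res
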