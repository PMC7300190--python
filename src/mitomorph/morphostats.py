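"""Distributional statistics for mitochondrial morphology parameters.

The central statistic: for each sample unit (field of view by default,
subject optionally) the two-sample Kolmogorov–Smirnov distance D between
that unit's particle-parameter values and a *reference pool* made of all
particles from control subjects under vehicle (CTRL/DMSO).  The per-unit
distances are then decomposed by a balanced fixed-effects two-way ANOVA
(mutation × treatment, with interaction) to ask whether genotype or
mitochondrial depolarization shifts the morphology distribution.

When a unit is itself part of the reference pool, its own particles are
excluded from the pool for its comparison (leave-one-out, default on):
otherwise reference units would be compared partly against themselves and
their distances biased toward zero, inflating apparent group effects.

D is computed on raw values — the KS statistic is invariant under any
strictly increasing transform, so the log transform applied to
circularity for density plots changes the densities but never D.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DensityEstimate",
    "KSDistanceRecord",
    "AnovaResult",
    "density_estimate",
    "ks_distance",
    "sample_distance_table",
    "two_way_anova",
    "wilcoxon_rank_sum",
]


# ---------------------------------------------------------------- densities


@dataclass
class DensityEstimate:
    parameter: str
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    transform: str = "identity"


def density_estimate(
    values: Sequence[float],
    transform: Literal["identity", "log"] = "identity",
    parameter: str = "",
    n_grid: int = 512,
) -> DensityEstimate:
    """Gaussian kernel density on a 512-point grid spanning data ± 3 bandwidths.

    Bandwidth by the Silverman-type rule 0.9·min(sd, IQR/1.34)·n^(−1/5);
    the returned density is renormalized to unit trapezoidal integral.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("density_estimate requires at least 2 distinct values")
    if transform == "log":
        if np.any(x <= 0):
            raise ValueError("log transform requires positive values")
        x = np.log(x)
    elif transform != "identity":
        raise ValueError(f"unknown transform {transform!r}")
    sd = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    bw = 0.9 * spread * x.size ** (-0.2)
    grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, n_grid)
    z = (grid[:, None] - x[None, :]) / bw
    dens = np.exp(-0.5 * z ** 2).sum(axis=1) / (x.size * bw * np.sqrt(2 * np.pi))
    dens /= np.trapezoid(dens, grid)
    return DensityEstimate(parameter, grid, dens, bw, transform)


# ------------------------------------------------------------- KS distances


@dataclass
class KSDistanceRecord:
    sample_id: str
    parameter: str
    D: float
    n_sample: int
    n_reference: int
    reference: str
    p_value: Optional[float] = None
    subject: str = ""
    group: str = ""
    treatment: str = ""
    fov: int = -1


def ks_distance(sample: Sequence[float], reference: Sequence[float], compute_p: bool = False):
    """Two-sample Kolmogorov–Smirnov distance D = sup |ECDF₁ − ECDF₂|.

    Returns D, or (D, asymptotic p) when ``compute_p``.
    """
    x = np.asarray(sample, dtype=np.float64)
    y = np.asarray(reference, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("ks_distance requires nonempty inputs")
    res = stats.ks_2samp(x, y, method="asymp")
    return (float(res.statistic), float(res.pvalue)) if compute_p else float(res.statistic)


def sample_distance_table(
    particles: pd.DataFrame,
    parameter: str,
    unit: Literal["fov", "subject"] = "fov",
    leave_one_out: bool = True,
    reference_group: str = "CTRL",
    reference_treatment: str = "DMSO",
    compute_p: bool = True,
) -> pd.DataFrame:
    """Per-unit KS distances to the pooled CTRL/DMSO particle reference."""
    if parameter not in particles.columns:
        raise KeyError(f"unknown parameter {parameter!r}")
    ref_rows = (particles["group"] == reference_group) & (
        particles["treatment"] == reference_treatment
    )
    if not ref_rows.any():
        raise ValueError(
            f"empty reference: no particles with group={reference_group!r}, "
            f"treatment={reference_treatment!r}"
        )
    unit_cols = ["subject", "group", "treatment"] + (["fov"] if unit == "fov" else [])
    ref_values = particles.loc[ref_rows, parameter].to_numpy()
    ref_desc = f"pooled {reference_group}/{reference_treatment}"

    records = []
    for key, sub in particles.groupby(unit_cols, sort=True):
        vals = sub[parameter].to_numpy()
        in_pool = key[1] == reference_group and key[2] == reference_treatment
        if in_pool and leave_one_out:
            reference = particles.loc[ref_rows & ~particles.index.isin(sub.index), parameter].to_numpy()
            if reference.size == 0:
                raise ValueError("leave-one-out emptied the reference pool")
        else:
            reference = ref_values
        D, p = ks_distance(vals, reference, compute_p=True)
        records.append(
            KSDistanceRecord(
                sample_id="/".join(str(k) for k in key),
                parameter=parameter,
                D=D,
                n_sample=len(vals),
                n_reference=len(reference),
                reference=ref_desc + (" (leave-one-out)" if in_pool and leave_one_out else ""),
                p_value=p if compute_p else None,
                subject=key[0],
                group=key[1],
                treatment=key[2],
                fov=key[3] if unit == "fov" else -1,
            )
        )
    return pd.DataFrame([r.__dict__ for r in records])


# ------------------------------------------------------------------- ANOVA


@dataclass
class AnovaResult:
    table: pd.DataFrame  # rows: mutation, treatment, interaction, error
    balanced: bool
    degenerate: bool = False

    def p(self, factor: str) -> float:
        return float(self.table.loc[factor, "p"])

    def F(self, factor: str) -> float:
        return float(self.table.loc[factor, "F"])


def two_way_anova(
    data: pd.DataFrame,
    response: str,
    factor_a: str = "group",
    factor_b: str = "treatment",
) -> AnovaResult:
    """Balanced fixed-effects two-way ANOVA with interaction (closed form).

    SS terms from cell/marginal means; F = MS_factor / MS_error; p from the
    F distribution.  Requires ≥ 2 levels per factor and a balanced design
    with at least one replicate per cell.
    """
    df = data[[response, factor_a, factor_b]].dropna()
    a_levels = sorted(df[factor_a].unique())
    b_levels = sorted(df[factor_b].unique())
    if len(a_levels) < 2 or len(b_levels) < 2:
        raise ValueError("two_way_anova requires at least 2 levels per factor")
    counts = df.groupby([factor_a, factor_b], sort=True)[response].count()
    for a in a_levels:
        for b in b_levels:
            if (a, b) not in counts.index or counts[(a, b)] == 0:
                raise ValueError(f"empty cell ({a!r}, {b!r})")
    n_per_cell = counts.iloc[0]
    balanced = bool((counts == n_per_cell).all())
    if not balanced:
        raise ValueError("unbalanced design: the closed-form path requires equal cell sizes")

    y = df[response].to_numpy(dtype=np.float64)
    grand = y.mean()
    N = y.size
    a_n, b_n, n = len(a_levels), len(b_levels), int(n_per_cell)

    mean_a = df.groupby(factor_a, sort=True)[response].mean()
    mean_b = df.groupby(factor_b, sort=True)[response].mean()
    mean_ab = df.groupby([factor_a, factor_b], sort=True)[response].mean()

    ss_a = b_n * n * float(((mean_a - grand) ** 2).sum())
    ss_b = a_n * n * float(((mean_b - grand) ** 2).sum())
    ss_cells = n * float(((mean_ab - grand) ** 2).sum())
    ss_int = ss_cells - ss_a - ss_b
    ss_tot = float(((y - grand) ** 2).sum())
    ss_err = ss_tot - ss_cells

    df_a, df_b = a_n - 1, b_n - 1
    df_int = df_a * df_b
    df_err = N - a_n * b_n

    degenerate = ss_err <= 0 or df_err == 0
    rows = {}
    ms_err = ss_err / df_err if df_err > 0 else np.nan
    for name, ss, d in (
        ("mutation", ss_a, df_a),
        ("treatment", ss_b, df_b),
        ("interaction", ss_int, df_int),
    ):
        ms = ss / d
        if degenerate or not np.isfinite(ms_err) or ms_err == 0:
            F = np.nan
            p = np.nan
        else:
            F = ms / ms_err
            p = float(stats.f.sf(F, d, df_err))
        rows[name] = dict(SS=ss, df=d, MS=ms, F=F, p=p)
    rows["error"] = dict(SS=ss_err, df=df_err, MS=ms_err, F=np.nan, p=np.nan)
    table = pd.DataFrame(rows).T
    return AnovaResult(table=table, balanced=balanced, degenerate=degenerate)


# ----------------------------------------------------------------- ranksum


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) test.

    Exact p by enumeration when n + m ≤ 12 with no ties; otherwise the
    normal approximation with continuity and tie correction.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("wilcoxon_rank_sum requires nonempty inputs")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)
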