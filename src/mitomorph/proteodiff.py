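"""Label-free differential-abundance workflow and ranked-list enrichment.

Post-acquisition steps of a PLGS-style label-free experiment comparing
patient (P) and control (C) pools over technical replicates:

1. summarize per-replicate log2(P/C) ratios (median) and their variance;
2. collapse protein isoforms (``ACC-2`` style suffixes) to the root
   accession, taking medians of ratio and variance;
3. a summary-statistics one-sample t test of the log2 ratio against 0
   (t = ratio / sqrt(variance/n), df = n−1) — the canonical test computable
   from "variance, ratio and sample size" alone;
4. the differential filter chain: detected in ≥ 2 of 3 replicates, then
   |log2 ratio| ≥ 0.38 (a 30% change: the threshold is stored exactly as
   |log2 1.30| = 0.3785… and displayed as 0.38, inclusive comparison),
   then p ≤ alpha.  Condition-unique proteins carry no ratio; they bypass
   the ratio/p filters but must meet the detection rule, and are counted
   among the retained ("altered") proteins;
5. volcano table and a ranked list (log2 ratio descending, uniques
   excluded) feeding a pre-ranked permutation gene-set enrichment with a
   weighted running-sum statistic and Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FC_LOG2",
    "DiffTable",
    "summarize_replicates",
    "collapse_isoforms",
    "summary_pvalue",
    "filter_differential",
    "volcano_table",
    "ranked_list",
    "preranked_enrichment",
    "read_gmt",
]

#: exact fold-change threshold: a 30% change in linear scale
FC_LOG2 = abs(math.log2(1.30))


# ----------------------------------------------------------- summarization


def summarize_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Per-protein summary from replicate columns ``replicate_1..n``.

    Adds/overwrites ``log2_ratio`` (median of detected replicates),
    ``variance`` (unbiased across detected replicates) and ``n_detected``
    (count of non-missing replicates unless the table already provides it,
    as it must for condition-unique proteins whose ratios are all missing).
    """
    rep_cols = [c for c in table.columns if c.startswith("replicate_")]
    if not rep_cols:
        raise ValueError("no replicate_* columns found")
    out = table.copy()
    reps = out[rep_cols].to_numpy(dtype=np.float64)
    detected = (~np.isnan(reps)).sum(axis=1)
    med = np.full(len(out), np.nan)
    var = np.full(len(out), np.nan)
    any_det = detected > 0
    med[any_det] = np.nanmedian(reps[any_det], axis=1)
    two_det = detected >= 2
    var[two_det] = np.nanvar(reps[two_det], axis=1, ddof=1)
    out["log2_ratio"] = med
    out["variance"] = var
    if "n_detected" not in out.columns:
        out["n_detected"] = detected
    else:
        out["n_detected"] = np.where(detected > 0, detected, out["n_detected"])
    if "uniqueness" not in out.columns:
        out["uniqueness"] = "none"
    return out


def collapse_isoforms(table: pd.DataFrame) -> pd.DataFrame:
    """One row per root Uniprot accession.

    ``log2_ratio`` and ``variance`` become medians across isoforms,
    ``n_detected`` the maximum.  A table without ``-n`` suffixes is
    returned unchanged (the operation is idempotent).
    """
    out = table.copy()
    root = out["accession"].astype(str).str.split("-", n=1).str[0]
    if (root == out["accession"]).all():
        return out
    out["accession"] = root

    def _uniq(s):
        vals = s.unique()
        return vals[0] if len(vals) == 1 else "none"

    agg = {"log2_ratio": "median", "variance": "median", "n_detected": "max"}
    extra = {}
    for col in out.columns:
        if col in ("accession", *agg):
            continue
        if col == "uniqueness":
            extra[col] = _uniq
        else:
            extra[col] = "first"
    collapsed = out.groupby("accession", sort=True, as_index=False).agg({**agg, **extra})
    return collapsed[[c for c in out.columns if c in collapsed.columns]]


# ------------------------------------------------------------------ p-value


def summary_pvalue(log2_ratio, variance, n):
    """Two-sided one-sample t p-value of a log2 ratio against 0.

    Computed from summary statistics only: t = ratio / sqrt(variance / n),
    df = n − 1.  variance = 0 gives p = 0 (ratio ≠ 0) or 1 (ratio = 0).
    Accepts scalars or arrays.
    """
    r = np.asarray(log2_ratio, dtype=np.float64)
    v = np.asarray(variance, dtype=np.float64)
    nn = np.asarray(n, dtype=np.float64)
    if np.any(nn < 2):
        raise ValueError("summary_pvalue requires n >= 2")
    if np.any(v < 0):
        raise ValueError("variance must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r / np.sqrt(v / nn)
        p = 2.0 * stats.t.sf(np.abs(t), nn - 1)
    p = np.where(v == 0, np.where(r == 0, 1.0, 0.0), p)
    p = np.where(np.isnan(r), np.nan, p)
    return float(p) if p.ndim == 0 else p


# ------------------------------------------------------------------ filters


@dataclass
class DiffTable:
    table: pd.DataFrame = field(repr=False)
    counts: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)


def filter_differential(
    table: pd.DataFrame,
    min_detected: int = 2,
    fc_log2: float = FC_LOG2,
    alpha: float = 0.05,
) -> DiffTable:
    """Differential filter chain on a collapsed per-protein table.

    Retains rows with ``n_detected ≥ min_detected`` AND |log2_ratio| ≥
    fc_log2 (inclusive) AND p ≤ alpha; condition-unique proteins bypass the
    ratio and p filters.  Stage counts are recorded and are monotone
    non-increasing.
    """
    if fc_log2 < 0:
        raise ValueError("fc_log2 must be non-negative")
    df = table.copy()
    if "p_value" not in df.columns:
        p = np.full(len(df), np.nan)
        ok = (df["n_detected"] >= 2) & df["variance"].notna()
        p[ok.to_numpy()] = summary_pvalue(
            df.loc[ok, "log2_ratio"], df.loc[ok, "variance"], df.loc[ok, "n_detected"]
        )
        df["p_value"] = p
    unique = df["uniqueness"].ne("none")

    s1 = df[df["n_detected"] >= min_detected]
    s2 = s1[(s1["log2_ratio"].abs() >= fc_log2) | unique.reindex(s1.index, fill_value=False)]
    s3 = s2[(s2["p_value"] <= alpha) | unique.reindex(s2.index, fill_value=False)]
    counts = dict(
        n_input=len(df),
        n_after_replicate_filter=len(s1),
        n_after_fc_filter=len(s2),
        n_after_p_filter=len(s3),
        n_unique_included=int(unique.reindex(s3.index, fill_value=False).sum()),
    )
    return DiffTable(
        table=s3.reset_index(drop=True),
        counts=counts,
        thresholds=dict(min_detected=min_detected, fc_log2=fc_log2, alpha=alpha),
    )


def volcano_table(
    table: pd.DataFrame, fc_log2: float = FC_LOG2, alpha: float = 0.05
) -> pd.DataFrame:
    """(accession, log2_ratio, −log10 p, status) rows; uniques excluded."""
    df = table[table["uniqueness"].eq("none") & table["log2_ratio"].notna()].copy()
    if "p_value" not in df.columns:
        p = np.full(len(df), np.nan)
        ok = ((df["n_detected"] >= 2) & df["variance"].notna()).to_numpy()
        p[ok] = summary_pvalue(
            df.loc[ok, "log2_ratio"], df.loc[ok, "variance"], df.loc[ok, "n_detected"]
        )
        df["p_value"] = p
    passing = (df["log2_ratio"].abs() >= fc_log2) & (df["p_value"] <= alpha)
    status = np.where(~passing, "ns", np.where(df["log2_ratio"] > 0, "up", "down"))
    with np.errstate(divide="ignore"):
        neg_log10_p = -np.log10(df["p_value"].to_numpy())
    return pd.DataFrame(
        dict(
            accession=df["accession"].to_numpy(),
            log2_ratio=df["log2_ratio"].to_numpy(),
            neg_log10_p=neg_log10_p,
            status=status,
        )
    )


def ranked_list(table: pd.DataFrame) -> pd.DataFrame:
    """Genes ranked by log2(P/C), descending; uniques excluded.

    Ties broken by accession (ascending) for determinism.
    """
    df = table[table["uniqueness"].eq("none") & table["log2_ratio"].notna()]
    if df.empty:
        raise ValueError("ranked_list: no ranked entries (empty table or all unique)")
    df = df.sort_values(
        ["log2_ratio", "accession"], ascending=[False, True], kind="mergesort"
    )
    return df[["accession", "log2_ratio"]].reset_index(drop=True)


# --------------------------------------------------------------- enrichment


def _es_from_positions(pos: np.ndarray, absm: np.ndarray, d: float) -> np.ndarray:
    """Signed enrichment score(s) from sorted hit positions.

    ``pos``: (n_rows, k) sorted 0-based hit positions; ``absm``: |metric|
    over the ranked universe; ``d``: miss decrement 1/(N−k).  The running
    sum is piecewise linear, so its extrema lie at the values just before
    and just after each hit.
    """
    w = absm[pos]
    wsum = w.sum(axis=1, keepdims=True)
    # all-zero weights (null metric inside the set): fall back to equal weights
    eq = (wsum == 0).ravel()
    if eq.any():
        w[eq] = 1.0
        wsum = w.sum(axis=1, keepdims=True)
    cumw = np.cumsum(w, axis=1) / wsum
    k = pos.shape[1]
    misses_before = pos - np.arange(k)[None, :]
    v_after = cumw - d * misses_before
    v_before = v_after - w / wsum
    cand = np.concatenate([v_before, v_after], axis=1)
    idx = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(cand.shape[0]), idx]


def preranked_enrichment(
    ranked: pd.DataFrame,
    gene_sets: dict[str, set],
    n_perm: int = 10000,
    seed: int = 0,
    alpha_report: float = 0.5,
) -> pd.DataFrame:
    """Pre-ranked gene-set enrichment with a gene-label permutation null.

    The running sum increments by |metric| / Σ_hits |metric| at set members
    and decrements by 1/(N − N_hit) elsewhere; ES is the maximum absolute
    deviation (signed).  The null permutes gene labels ``n_perm`` times;
    two-sided p = (1 + #{|ES_null| ≥ |ES|}) / (n_perm + 1), adjusted across
    sets by Benjamini–Hochberg.  Sets with < 2 mapped members are skipped.
    """
    universe = ranked["accession"].to_numpy()
    metric = ranked["log2_ratio"].to_numpy(dtype=np.float64)
    N = len(universe)
    index = {g: i for i, g in enumerate(universe)}
    absm = np.abs(metric)
    rng = np.random.default_rng(seed)

    rows = []
    for name in sorted(gene_sets):
        members = sorted({g for g in gene_sets[name] if g in index})
        k = len(members)
        if k < 2:
            continue
        if k >= N:
            raise ValueError(f"gene set {name!r} covers the whole ranked universe")
        d = 1.0 / (N - k)
        pos = np.sort(np.array([index[g] for g in members]))[None, :]
        es = float(_es_from_positions(pos, absm, d)[0])

        null = np.empty(n_perm)
        chunk = max(1, min(n_perm, int(2e6 // max(k, 1))))
        done = 0
        while done < n_perm:
            m = min(chunk, n_perm - done)
            keys = rng.random((m, N))
            perm_pos = np.sort(np.argpartition(keys, k, axis=1)[:, :k], axis=1)
            null[done : done + m] = _es_from_positions(perm_pos, absm, d)
            done += m
        p = (1.0 + np.sum(np.abs(null) >= abs(es))) / (n_perm + 1.0)
        rows.append(dict(gene_set=name, size=k, ES=es, p_value=p))

    if not rows:
        return pd.DataFrame(columns=["gene_set", "size", "ES", "p_value", "p_adjusted"])
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def read_gmt(path) -> dict[str, set]:
    """Gene sets from a GMT file (name, description, members...)."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(p for p in parts[2:] if p)
    return sets
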