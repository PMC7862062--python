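"""Pooled CRISPR screen count analysis.

Normalisation to counts-per-million, per-gRNA log2 fold changes against the
day-0 baseline (which represents the full library), replicate concordance,
and target-level selection calls. Targets are aggregated with a transparent
scheme — the median gRNA LFC, pooled as the mean of replicate medians, with
a permutation null built from size-matched gRNA sets resampled from the
whole library — rather than any published screen-analysis model, so the
resulting FDRs are this package's own, not e.g. MAGeCK-equivalent ones.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from psiforge import io
from psiforge._rng import child_rng

NONTARGETING = "nontargeting"
PSEUDOCOUNT = 0.5

_SAMPLE_RE = re.compile(r"^d(\d+)_r(\d+)$")


def sample_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if _SAMPLE_RE.match(c)]


def read_count_table(path: str | os.PathLike) -> pd.DataFrame:
    table = io.read_tsv(path)
    validate_count_table(table)
    return table


def validate_count_table(table: pd.DataFrame) -> None:
    for col in ("grna", "target"):
        if col not in table.columns:
            raise ValueError(f"count table missing column {col!r}")
    if table["target"].isna().any() or (table["target"] == "").any():
        raise ValueError("every gRNA must map to a target or to 'nontargeting'")
    cols = sample_columns(table)
    if not cols:
        raise ValueError("no sample columns of the form d<day>_r<rep>")
    if not any(_SAMPLE_RE.match(c).group(1) == "0" for c in cols):
        raise ValueError("day-0 baseline column required")
    if (table[cols] < 0).to_numpy().any():
        raise ValueError("negative counts")


def normalize_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million per sample (sums to 1e6 before any pseudocount)."""
    validate_count_table(table)
    out = table.copy()
    for col in sample_columns(table):
        total = table[col].sum()
        if total == 0:
            raise ValueError(f"sample {col!r} has all-zero counts")
        out[col] = table[col] / total * 1e6
    return out


def grna_lfc(normalized: pd.DataFrame, day: int, replicate: int) -> pd.Series:
    """Per-gRNA log2(CPM_day / CPM_day0) within one replicate, pseudocounted."""
    col = f"d{day}_r{replicate}"
    base = f"d0_r{replicate}"
    for c in (col, base):
        if c not in normalized.columns:
            raise ValueError(f"missing sample column {c!r}")
    lfc = np.log2((normalized[col] + PSEUDOCOUNT) / (normalized[base] + PSEUDOCOUNT))
    lfc.index = pd.Index(normalized["grna"], name="grna")
    return lfc.rename(col)


@dataclass
class ReplicateCorrelation:
    r: float
    slope: float
    intercept: float
    n: int
    defined: bool = True


def replicate_correlation(lfc_a: pd.Series, lfc_b: pd.Series) -> ReplicateCorrelation:
    """Pearson correlation and least-squares line between replicate LFCs."""
    shared = lfc_a.index.intersection(lfc_b.index)
    if len(shared) < 10:
        raise ValueError("need >= 10 shared gRNAs")
    x = lfc_a[shared].to_numpy(dtype=float)
    y = lfc_b[shared].to_numpy(dtype=float)
    if np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
        return ReplicateCorrelation(np.nan, np.nan, np.nan, len(shared), defined=False)
    fit = stats.linregress(x, y)
    return ReplicateCorrelation(float(fit.rvalue), float(fit.slope),
                                float(fit.intercept), len(shared))


def aggregate_targets(
    lfc_by_replicate: pd.DataFrame,
    target_map: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
    fdr_threshold: float = 0.8,
) -> pd.DataFrame:
    """Target-level selection calls from per-gRNA LFCs.

    Parameters
    ----------
    lfc_by_replicate
        gRNAs × replicate columns of LFCs (one timepoint, or a
        caller-chosen pooling over timepoints).
    target_map
        gRNA → target id.
    n_perm
        Permutation draws per gRNA-set size (≥ 1000).
    fdr_threshold
        BH FDR at which a selection direction is called; screens often use
        a permissive 0.8 to rank candidates for follow-up.

    A target's statistic is the mean over replicates of the median gRNA LFC
    within the replicate. The null resamples size-matched gRNA sets from
    the full library (all replicate columns kept together, preserving
    between-replicate correlation). One-sided permutation p-values are
    reported for each direction with the add-one estimator, so the smallest
    attainable p is ``1/(n_perm+1)``; targets with a single gRNA are
    untested.
    """
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    rng = child_rng(seed, "target-permutations")
    mat = lfc_by_replicate.to_numpy(dtype=float)
    targets = target_map.reindex(lfc_by_replicate.index)
    if targets.isna().any():
        raise ValueError("every gRNA needs a target id")
    groups = {t: np.flatnonzero((targets == t).to_numpy()) for t in pd.unique(targets)}
    sizes = sorted({len(ix) for ix in groups.values() if len(ix) >= 2})
    null_by_size: dict[int, np.ndarray] = {}
    for k in sizes:
        draws = np.empty(n_perm)
        for j in range(n_perm):
            pick = rng.choice(mat.shape[0], size=k, replace=False)
            draws[j] = np.median(mat[pick], axis=0).mean()
        null_by_size[k] = draws
    rows = []
    for target, ix in groups.items():
        k = len(ix)
        row: dict[str, object] = {"target": target, "n_grnas": k}
        for j, col in enumerate(lfc_by_replicate.columns):
            row[f"median_lfc_{col}"] = float(np.median(mat[ix, j]))
        if k < 2:
            row.update({"median_lfc_pooled": np.nan, "p_depletion": np.nan,
                        "p_enrichment": np.nan, "tested": False})
        else:
            obs = float(np.median(mat[ix], axis=0).mean())
            null = null_by_size[k]
            row["median_lfc_pooled"] = obs
            row["p_depletion"] = (1 + int((null <= obs).sum())) / (n_perm + 1)
            row["p_enrichment"] = (1 + int((null >= obs).sum())) / (n_perm + 1)
            row["tested"] = True
        rows.append(row)
    out = pd.DataFrame(rows).set_index("target")
    p_two = (2 * out[["p_depletion", "p_enrichment"]].min(axis=1)).clip(upper=1.0)
    out["p_two_sided"] = p_two
    ok = out["tested"].astype(bool) & p_two.notna()
    out["fdr"] = np.nan
    if ok.any():
        out.loc[ok, "fdr"] = stats.false_discovery_control(p_two[ok].to_numpy(), method="bh")
    out["direction"] = "none"
    called = ok & (out["fdr"] <= fdr_threshold)
    neg = called & (out["p_depletion"] < out["p_enrichment"])
    pos = called & (out["p_enrichment"] < out["p_depletion"])
    out.loc[neg, "direction"] = "negative"
    out.loc[pos, "direction"] = "positive"
    return out.sort_values("median_lfc_pooled")
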