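"""Paired differential pseudouridylation.

Three granularities, mirroring how paired tumour/normal (or KO/control)
Ψ-ratio data is usually interrogated:

* per-site paired tests (default paired t, Wilcoxon available) with raw p,
  BH q, and a significance flag at raw p < 0.05;
* hotspot tests: paired t on per-sample *sums* of Ψ-ratios over a region of
  adjacent sites;
* a global shift test: Wilcoxon signed-rank across sites on per-condition
  mean ratios, optionally restricted to a site subset (e.g. sites guided by
  H/ACA-box snoRNAs).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from psiforge import io
from psiforge.psi_quant import PsiRatioMatrix, region_sum

LFC_PSEUDOCOUNT = 1e-3  # guards log2 of zero ratios

DESIGN_COLUMNS = ["unit", "sample_a", "sample_b"]


def validate_design(design: pd.DataFrame, samples: Sequence[str] | None = None) -> pd.DataFrame:
    """Validate a paired design table (columns ``unit, sample_a, sample_b``)."""
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design table missing columns: {missing}")
    if design["unit"].duplicated().any():
        raise ValueError("each unit must appear exactly once per condition")
    flat = pd.concat([design["sample_a"], design["sample_b"]])
    if flat.duplicated().any():
        raise ValueError("a sample id may belong to only one (unit, condition)")
    if samples is not None:
        unknown = sorted(set(flat) - set(samples))
        if unknown:
            raise ValueError(f"design references unknown samples: {unknown}")
    return design


def read_design(path: str | os.PathLike) -> pd.DataFrame:
    return validate_design(io.read_tsv(path, dtype=str))


def _paired_t(diff: np.ndarray) -> tuple[float, float, bool]:
    """Two-sided paired t on the differences; degenerate variance → p = 1."""
    if np.allclose(diff.std(ddof=1), 0.0):
        return 0.0, 1.0, True
    res = stats.ttest_rel(diff, np.zeros_like(diff))
    return float(res.statistic), float(res.pvalue), False


def signed_rank_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank with the classical conventions.

    Zero differences are dropped (Wilcoxon's treatment); the exact null
    distribution is used for n ≤ 25 informative pairs, the normal
    approximation with continuity correction above. All differences zero
    → p = 1.
    """
    diff = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    diff = diff[diff != 0]
    if diff.size == 0:
        return 0.0, 1.0
    method = "exact" if diff.size <= 25 else "approx"
    try:
        res = stats.wilcoxon(diff, zero_method="wilcox", correction=True, method=method)
    except ValueError:
        # ties make the exact distribution unavailable; fall back
        res = stats.wilcoxon(diff, zero_method="wilcox", correction=True, method="approx")
    return float(res.statistic), float(res.pvalue)


def _bh(p: pd.Series) -> pd.Series:
    q = pd.Series(np.nan, index=p.index, dtype=float)
    ok = p.notna()
    if ok.any():
        q[ok] = stats.false_discovery_control(p[ok].to_numpy(), method="bh")
    return q


def site_tests(
    matrix: PsiRatioMatrix,
    design: pd.DataFrame,
    test: str = "t",
    p_threshold: float = 0.05,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Per-site paired differential test between conditions A and B.

    Pairs with a missing ratio in either member are dropped per site; sites
    with fewer than ``min_pairs`` complete pairs are reported untested. Log2
    fold change uses a small pseudocount on the mean ratios. The
    ``significant`` flag uses the raw p-value (BH q is reported alongside).
    """
    design = validate_design(design, matrix.samples)
    a = matrix.values[design["sample_a"].tolist()].to_numpy(dtype=float)
    b = matrix.values[design["sample_b"].tolist()].to_numpy(dtype=float)
    rows = []
    for i, site_id in enumerate(matrix.values.index):
        ok = ~np.isnan(a[i]) & ~np.isnan(b[i])
        n = int(ok.sum())
        row = {"site_id": site_id, "n_pairs": n, "tested": n >= min_pairs,
               "mean_a": np.nan, "mean_b": np.nan, "delta": np.nan, "log2fc": np.nan,
               "statistic": np.nan, "p_value": np.nan, "degenerate": False}
        if n >= min_pairs:
            av, bv = a[i, ok], b[i, ok]
            row["mean_a"], row["mean_b"] = float(av.mean()), float(bv.mean())
            row["delta"] = float((av - bv).mean())
            row["log2fc"] = float(
                np.log2((av.mean() + LFC_PSEUDOCOUNT) / (bv.mean() + LFC_PSEUDOCOUNT))
            )
            if test == "t":
                stat, p, degen = _paired_t(av - bv)
            elif test == "wilcoxon":
                stat, p = signed_rank_test(av, bv)
                degen = bool(np.all(av == bv))
            else:
                raise ValueError(f"unknown test {test!r}")
            row["statistic"], row["p_value"], row["degenerate"] = stat, p, degen
        rows.append(row)
    out = pd.DataFrame(rows).set_index("site_id")
    out["q_value"] = _bh(out["p_value"])
    out["significant"] = out["p_value"] < p_threshold
    return out


@dataclass
class ShiftTestResult:
    statistic: float
    p_value: float
    n_sites: int
    median_a: float
    median_b: float


def global_shift_test(
    matrix: PsiRatioMatrix,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    site_subset: Sequence[str] | None = None,
    min_sites: int = 6,
) -> ShiftTestResult:
    """Wilcoxon signed-rank across sites for a global condition shift.

    Each site contributes one pair: its mean ratio over the condition-A
    samples vs over the condition-B samples (means taken over non-missing
    values; sites missing an entire condition are dropped). ``site_subset``
    restricts the test, e.g. to H/ACA-guided sites.
    """
    values = matrix.values
    if site_subset is not None:
        unknown = sorted(set(site_subset) - set(values.index))
        if unknown:
            raise ValueError(f"unknown sites in subset: {unknown}")
        values = values.loc[list(site_subset)]
    mean_a = values[list(samples_a)].mean(axis=1)
    mean_b = values[list(samples_b)].mean(axis=1)
    ok = mean_a.notna() & mean_b.notna()
    if int(ok.sum()) < min_sites:
        raise ValueError(
            f"global shift test needs >= {min_sites} paired sites, got {int(ok.sum())}"
        )
    stat, p = signed_rank_test(mean_a[ok].to_numpy(), mean_b[ok].to_numpy())
    return ShiftTestResult(
        statistic=stat, p_value=p, n_sites=int(ok.sum()),
        median_a=float(mean_a[ok].median()), median_b=float(mean_b[ok].median()),
    )


@dataclass
class HotspotTestResult:
    molecule: str
    positions: tuple[int, ...]
    n_pairs: int
    mean_sum_a: float
    mean_sum_b: float
    statistic: float
    p_value: float
    tested: bool


def hotspot_test(
    matrix: PsiRatioMatrix,
    design: pd.DataFrame,
    molecule: str,
    positions: Sequence[int],
    min_pairs: int = 3,
) -> HotspotTestResult:
    """Paired t-test on per-sample summed Ψ-ratios over a hotspot region.

    Samples flagged incomplete by :func:`psiforge.psi_quant.region_sum`
    drop the whole pair. Fewer than ``min_pairs`` complete pairs → untested.
    """
    design = validate_design(design, matrix.samples)
    sums, _complete = region_sum(matrix, molecule, positions)
    a = sums[design["sample_a"].tolist()].to_numpy(dtype=float)
    b = sums[design["sample_b"].tolist()].to_numpy(dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    n = int(ok.sum())
    if n < min_pairs:
        return HotspotTestResult(molecule, tuple(positions), n, np.nan, np.nan,
                                 np.nan, np.nan, tested=False)
    stat, p, _degen = _paired_t(a[ok] - b[ok])
    return HotspotTestResult(
        molecule, tuple(positions), n, float(a[ok].mean()), float(b[ok].mean()),
        stat, p, tested=True,
    )
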