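"""snoRNA → rRNA-target integration.

Joins snoRNA-level differential-expression results to site-level
differential-pseudouridylation results through the guide→target annotation
(one row per (snoRNA, target site)), then asks whether sites guided by
up-regulated snoRNAs are enriched for tumour-hyper-pseudouridylation —
either with Fisher's exact test on the 2×2 site table or by permuting the
guide→site map (preserving each snoRNA's number of targets and every
site's multiplicity, so both margins are conserved).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from psiforge import io
from psiforge._rng import child_rng

MAP_COLUMNS = ["snorna", "site_id"]


def read_guide_map(path: str | os.PathLike) -> pd.DataFrame:
    """Read a guide map TSV: columns ``snorna`` and ``site_id`` (molecule:position)."""
    df = io.read_tsv(path, dtype=str)
    missing = [c for c in MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"guide map missing columns: {missing}")
    return df


def join_results(
    volcano: pd.DataFrame,
    site_results: pd.DataFrame,
    guide_map: pd.DataFrame,
) -> pd.DataFrame:
    """One row per (snoRNA, target site) carrying both result sets.

    ``volcano`` is indexed by snoRNA (from :func:`psiforge.snorna_expr.paired_de`),
    ``site_results`` by site_id (from :func:`psiforge.diff_psi.site_tests`).
    Map entries pointing at sites absent from ``site_results`` are an error;
    snoRNAs or sites absent from the map are appended flagged unmapped.
    """
    unknown_sites = sorted(set(guide_map["site_id"]) - set(site_results.index))
    if unknown_sites:
        raise ValueError(f"guide map references unknown sites: {unknown_sites}")
    unknown_snornas = sorted(set(guide_map["snorna"]) - set(volcano.index))
    if unknown_snornas:
        raise ValueError(f"guide map references unknown snoRNAs: {unknown_snornas}")
    linked = guide_map.copy()
    linked["linked"] = True
    sno_cols = volcano.add_prefix("sno_")
    site_cols = site_results.add_prefix("site_")
    out = linked.merge(sno_cols, left_on="snorna", right_index=True, how="left")
    out = out.merge(site_cols, left_on="site_id", right_index=True, how="left")
    orphan_snornas = volcano.index.difference(guide_map["snorna"])
    orphan_sites = site_results.index.difference(guide_map["site_id"])
    extra = []
    for s in orphan_snornas:
        extra.append({"snorna": s, "site_id": "", "linked": False,
                      **sno_cols.loc[s].to_dict()})
    for s in orphan_sites:
        extra.append({"snorna": "", "site_id": s, "linked": False,
                      **site_cols.loc[s].to_dict()})
    if extra:
        out = pd.concat([out, pd.DataFrame(extra)], ignore_index=True)
    return out


@lru_cache(maxsize=4096)
def _hypergeom_numerators(n: int, r1: int, c1: int) -> tuple[int, ...]:
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    return tuple(math.comb(r1, k) * math.comb(n - r1, c1 - k) for k in range(lo, hi + 1))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on the table [[a, b], [c, d]].

    Conditions on both margins; the p-value sums the hypergeometric
    probabilities of all tables as or less probable than the observed one,
    with ties decided by exact integer comparison. Returns
    ``(sample_odds_ratio, p)``.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table entries must be non-negative integers")
    n, r1, c1 = a + b + c + d, a + b, a + c
    if n == 0:
        return np.nan, 1.0
    nums = _hypergeom_numerators(n, r1, c1)
    lo = max(0, r1 + c1 - n)
    obs = nums[a - lo]
    p = sum(m for m in nums if m <= obs) / math.comb(n, c1)
    odds = (a * d) / (b * c) if b * c > 0 else (np.inf if a * d > 0 else np.nan)
    return odds, min(1.0, float(p))


@dataclass
class ConcordanceResult:
    table: tuple[int, int, int, int]  # a: linked&hyper, b: linked&not, c: unlinked&hyper, d: rest
    odds_ratio: float
    p_value: float
    mode: str
    n_sites: int
    degenerate: bool = False


def _site_flags(
    linked: pd.DataFrame,
    p_threshold: float = 0.05,
    use_q: bool = False,
) -> pd.DataFrame:
    rows = linked[linked["linked"] & (linked["site_id"] != "")]
    p_col = "site_q_value" if use_q else "site_p_value"
    per_site = rows.groupby("site_id").agg(
        p=(p_col, "first"), delta=("site_delta", "first"),
        any_enriched=("sno_status", lambda s: bool((s == "enriched").any())),
    )
    per_site["hyper"] = (per_site["p"] < p_threshold) & (per_site["delta"] > 0)
    return per_site


def concordance_test(
    linked: pd.DataFrame,
    mode: str = "fisher",
    n_perm: int = 1000,
    seed: int = 0,
    p_threshold: float = 0.05,
    use_q: bool = False,
) -> ConcordanceResult:
    """Test whether up-regulated guides concentrate on hyper-Ψ sites.

    A site is *hyper* when its differential-Ψ raw p < ``p_threshold`` (BH q
    with ``use_q=True``) with positive delta, and *linked* when ANY of its
    guides is called enriched; multi-guide sites count once. ``fisher``
    runs the exact 2×2 test; ``permutation`` reapplies random bijections of
    the site universe to the guide map, preserving both margins, and scores
    the count of linked-and-hyper sites.
    """
    flags = _site_flags(linked, p_threshold=p_threshold, use_q=use_q)
    if len(flags) < 10:
        raise ValueError("need >= 10 linked sites for the concordance test")
    hyper = flags["hyper"].to_numpy(dtype=bool)
    up = flags["any_enriched"].to_numpy(dtype=bool)
    a = int((up & hyper).sum())
    b = int((up & ~hyper).sum())
    c = int((~up & hyper).sum())
    d = int((~up & ~hyper).sum())
    odds, _ = fisher_exact_2x2(a, b, c, d)
    if hyper.all() or not hyper.any() or up.all() or not up.any():
        return ConcordanceResult((a, b, c, d), odds, 1.0, mode, len(flags), degenerate=True)
    if mode == "fisher":
        odds, p = fisher_exact_2x2(a, b, c, d)
        return ConcordanceResult((a, b, c, d), odds, p, mode, len(flags))
    if mode == "permutation":
        rng = child_rng(seed, "concordance-permutation")
        rows = linked[linked["linked"] & (linked["site_id"] != "")]
        site_ids = flags.index.to_numpy()
        hyper_by_site = dict(zip(flags.index, flags["hyper"]))
        enriched_guides = set(
            rows.loc[rows["sno_status"] == "enriched", "snorna"]
        )
        linked_sites = rows.loc[rows["snorna"].isin(enriched_guides), "site_id"].unique()
        n_extreme = 0
        for _ in range(n_perm):
            perm = dict(zip(site_ids, rng.permutation(site_ids)))
            a_perm = sum(1 for s in {perm[s] for s in linked_sites} if hyper_by_site[s])
            if a_perm >= a:
                n_extreme += 1
        p = (1 + n_extreme) / (n_perm + 1)
        return ConcordanceResult((a, b, c, d), odds, p, mode, len(flags))
    raise ValueError(f"unknown mode {mode!r}")
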