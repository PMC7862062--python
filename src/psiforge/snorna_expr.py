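"""snoRNA quantification and paired differential expression.

Counting assigns a read to a snoRNA when at least ``min_overlap_frac`` of
its aligned length overlaps the annotated interval on the same strand;
reads hitting several snoRNAs go to the larger overlap, exact ties are
discarded (and logged). Differential expression works on log2 CPM
(counts-per-million of *total mapped reads*, pseudocount 0.5) with a paired
Wilcoxon signed-rank test per snoRNA and the volcano-style joint flag
log2FC > threshold AND p < threshold.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import pysam

from psiforge import io
from psiforge.diff_psi import _bh, _paired_t, signed_rank_test, validate_design

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand", "sno_class", "host_gene", "target_sites",
]
CLASSES = {"CD_box", "HACA_box", "other"}


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS[:7] if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    if (ann["end"] <= ann["start"]).any():
        bad = ann.loc[ann["end"] <= ann["start"], "name"].tolist()
        raise ValueError(f"annotation intervals with end <= start: {bad}")
    unknown = set(ann["sno_class"]) - CLASSES
    if unknown:
        raise ValueError(f"unknown snoRNA classes: {sorted(unknown)}")
    out = ann.copy()
    for col in ("host_gene", "target_sites"):
        if col not in out.columns:
            out[col] = ""
        out[col] = out[col].fillna("")
    return out


def read_annotation(path: str | os.PathLike) -> pd.DataFrame:
    """Read a BED6+3 snoRNA annotation (class, host gene, target sites)."""
    df = io.read_tsv(path)
    if list(df.columns[:4]) != ANNOTATION_COLUMNS[:4]:
        df.columns = ANNOTATION_COLUMNS[: len(df.columns)]
    return validate_annotation(df)


@dataclass
class CountingStats:
    total: int = 0
    assigned: int = 0
    unassigned: int = 0
    ties_discarded: int = 0
    reverse_discarded: int = 0


def count_snornas(
    alignments: str | os.PathLike,
    annotation: pd.DataFrame,
    min_overlap_frac: float = 0.5,
) -> tuple[pd.Series, CountingStats]:
    """Count reads per snoRNA from a sorted SAM/BAM.

    Returns ``(counts, stats)``; ``stats.total`` is the number of mapped
    reads seen, so total mapped reads per sample (the CPM denominator) comes
    straight from this call. Conservation holds:
    ``assigned + unassigned + ties_discarded + reverse_discarded == total``.
    """
    annotation = validate_annotation(annotation)
    by_chrom: dict[str, pd.DataFrame] = {
        str(chrom): grp.sort_values("start").reset_index(drop=True)
        for chrom, grp in annotation.groupby("chrom")
    }
    counts = pd.Series(0, index=pd.Index(annotation["name"], name="snorna"), dtype=int)
    stats = CountingStats()
    with pysam.AlignmentFile(str(alignments), check_sq=False) as af:
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            stats.total += 1
            strand = "-" if rec.is_reverse else "+"
            chrom = rec.reference_name
            cand = by_chrom.get(chrom)
            aligned_len = rec.reference_end - rec.reference_start
            best: list[str] = []
            best_ov = 0
            if cand is not None:
                sel = cand[
                    (cand["start"] < rec.reference_end)
                    & (cand["end"] > rec.reference_start)
                    & (cand["strand"] == strand)
                ]
                for row in sel.itertuples(index=False):
                    ov = min(row.end, rec.reference_end) - max(row.start, rec.reference_start)
                    if ov > best_ov:
                        best, best_ov = [row.name], ov
                    elif ov == best_ov and ov > 0:
                        best.append(row.name)
            if best_ov >= min_overlap_frac * aligned_len and len(best) == 1:
                counts[best[0]] += 1
                stats.assigned += 1
            elif best_ov >= min_overlap_frac * aligned_len and len(best) > 1:
                stats.ties_discarded += 1
            else:
                stats.unassigned += 1
    if stats.total and stats.ties_discarded > 0.01 * stats.total:
        logger.warning(
            "%.1f%% of reads discarded as overlap ties; annotations may overlap heavily",
            100 * stats.ties_discarded / stats.total,
        )
    return counts, stats


def class_fractions(
    counts: pd.DataFrame,
    classes: pd.Series,
    total_mapped: pd.Series,
    min_count_detected: int = 1,
) -> pd.DataFrame:
    """Per-class share of total mapped reads, per sample and pooled.

    Returns one row per class (plus ``other_rna`` for reads outside the
    snoRNA annotation) with the fraction of total mapped reads and the
    number of detected members; fractions per sample sum to 1.
    """
    if (total_mapped <= 0).any():
        raise ValueError("total mapped reads must be positive for every sample")
    classes = classes.reindex(counts.index)
    if classes.isna().any():
        raise ValueError("every snoRNA needs a class label")
    rows = []
    class_totals = counts.groupby(classes).sum()
    for cls in class_totals.index:
        row = {"sno_class": cls, "n_members": int((classes == cls).sum())}
        for sample in counts.columns:
            row[sample] = class_totals.loc[cls, sample] / total_mapped[sample]
        row["pooled_fraction"] = class_totals.loc[cls].sum() / total_mapped[counts.columns].sum()
        row["n_detected_pooled"] = int(
            (counts.loc[(classes == cls).to_numpy()].sum(axis=1) >= min_count_detected).sum()
        )
        rows.append(row)
    other = {"sno_class": "other_rna", "n_members": 0, "n_detected_pooled": 0}
    for sample in counts.columns:
        other[sample] = 1.0 - counts[sample].sum() / total_mapped[sample]
    other["pooled_fraction"] = 1.0 - counts.sum().sum() / total_mapped[counts.columns].sum()
    rows.append(other)
    return pd.DataFrame(rows)


def cpm(counts: pd.DataFrame, total_mapped: pd.Series, pseudocount: float = 0.5) -> pd.DataFrame:
    """Counts-per-million of total mapped reads, pseudocounted for logs."""
    return (counts + pseudocount).div(total_mapped[counts.columns], axis=1) * 1e6


def paired_de(
    counts: pd.DataFrame,
    total_mapped: pd.Series,
    design: pd.DataFrame,
    lfc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    test: str = "wilcoxon",
) -> pd.DataFrame:
    """Paired differential snoRNA expression with volcano-style calls.

    Per snoRNA: mean over pairs of log2 CPM(T)/CPM(N), a paired Wilcoxon
    signed-rank p (paired t by ``test="t"``), BH q, and a status of
    ``enriched`` (log2FC > threshold AND p < threshold), ``depleted``
    (symmetric) or ``ns``. snoRNAs with zero counts in all samples are
    excluded and logged.
    """
    design = validate_design(design, list(counts.columns))
    all_zero = (counts == 0).all(axis=1)
    if all_zero.any():
        logger.info("excluding %d snoRNAs with zero counts everywhere", int(all_zero.sum()))
    counts = counts[~all_zero]
    log_cpm = np.log2(cpm(counts, total_mapped))
    a = log_cpm[design["sample_a"].tolist()].to_numpy()
    b = log_cpm[design["sample_b"].tolist()].to_numpy()
    rows = []
    for i, name in enumerate(counts.index):
        lfc = float((a[i] - b[i]).mean())
        if test == "wilcoxon":
            stat, p = signed_rank_test(a[i], b[i])
        elif test == "t":
            stat, p, _ = _paired_t(a[i] - b[i])
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append({"snorna": name, "n_pairs": len(design), "log2fc": lfc,
                     "statistic": stat, "p_value": p})
    out = pd.DataFrame(rows).set_index("snorna")
    out["q_value"] = _bh(out["p_value"])
    out["status"] = "ns"
    out.loc[(out["log2fc"] > lfc_threshold) & (out["p_value"] < p_threshold), "status"] = "enriched"
    out.loc[(out["log2fc"] < -lfc_threshold) & (out["p_value"] < p_threshold), "status"] = "depleted"
    return out
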