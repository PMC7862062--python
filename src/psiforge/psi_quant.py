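"""Per-position termination profiles and the per-site Ψ-ratio.

The Ψ-ratio at an annotated site is the number of reads *beginning* at the
position (reverse-transcriptase termination events) divided by the number
of reads *overlapping* it. Reads that begin at a site overlap it, so the
ratio is a proper termination fraction in [0, 1]: 1 means every molecule
covering the site produced a stop there.

Coordinates are 1-based inclusive throughout (site labels like ``18S:105``);
SAM input is handled by pysam, which exposes 0-based positions internally.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from psiforge import io

logger = logging.getLogger(__name__)

SITE_COLUMNS = ["site_id", "molecule", "position", "guides"]

# CIGAR ops that consume the reference; of those, N (skip) does not count as
# covered while D (deletion) does.
_REF_CONSUMING = {0, 2, 3, 7, 8}  # M, D, N, =, X
_COVERED = {0, 2, 7, 8}


def validate_site_table(sites: pd.DataFrame) -> pd.DataFrame:
    """Validate a Ψ-site table (columns ``site_id, molecule, position, guides``)."""
    missing = [c for c in SITE_COLUMNS[:3] if c not in sites.columns]
    if missing:
        raise ValueError(f"site table missing columns: {missing}")
    if (sites["position"] < 1).any():
        bad = sites.loc[sites["position"] < 1, "site_id"].tolist()
        raise ValueError(f"site positions must be >= 1: {bad}")
    dup = sites.duplicated(subset=["molecule", "position"])
    if dup.any():
        raise ValueError(
            "duplicate (molecule, position) entries: "
            + ", ".join(sites.loc[dup, "site_id"].astype(str))
        )
    out = sites.copy()
    if "guides" not in out.columns:
        out["guides"] = ""
    out["guides"] = out["guides"].fillna("")
    return out


def read_site_table(path: str | os.PathLike) -> pd.DataFrame:
    return validate_site_table(io.read_tsv(path, dtype={"guides": str}))


@dataclass
class TerminationProfile:
    """Per-molecule 5′-start and overlap coverage counts for one sample.

    ``starts[molecule][p-1]`` counts reads whose reference 5′-most aligned
    base is position ``p``; ``overlap[molecule][p-1]`` counts reads whose
    alignment covers ``p`` (the start base included, deletions covered,
    insertions/clips/skips not).
    """

    sample_id: str
    starts: dict[str, np.ndarray] = field(default_factory=dict)
    overlap: dict[str, np.ndarray] = field(default_factory=dict)
    total_mapped: int = 0
    n_reverse_discarded: int = 0

    def check(self) -> None:
        """Assert internal conservation invariants."""
        total = 0
        for mol, st in self.starts.items():
            ov = self.overlap[mol]
            if (st < 0).any() or (ov < 0).any():
                raise AssertionError("negative counts in profile")
            if (st > ov).any():
                raise AssertionError("a starting read must also overlap its start base")
            total += int(st.sum())
        if total != self.total_mapped:
            raise AssertionError("sum of starts != number of mapped reads")


def build_profile(
    alignments: str | os.PathLike | pysam.AlignmentFile,
    reference_lengths: Mapping[str, int] | None = None,
    sample_id: str | None = None,
) -> TerminationProfile:
    """Build a :class:`TerminationProfile` from mapped single-end alignments.

    Parameters
    ----------
    alignments
        SAM/BAM path or an open :class:`pysam.AlignmentFile`.
    reference_lengths
        Expected reference names and lengths; a mapped read on a reference
        not listed here is a hard error. Defaults to the file header.

    Reverse-strand alignments are discarded (rRNA references are
    single-stranded) and counted in ``n_reverse_discarded``.
    """
    own = not isinstance(alignments, pysam.AlignmentFile)
    af = pysam.AlignmentFile(str(alignments), check_sq=False) if own else alignments
    try:
        header_lengths = dict(zip(af.references, af.lengths))
        if reference_lengths is None:
            reference_lengths = header_lengths
        profile = TerminationProfile(sample_id=sample_id or os.path.basename(str(alignments)))
        starts_idx: dict[str, list[int]] = {m: [] for m in reference_lengths}
        cover_diff = {m: np.zeros(int(L) + 1, dtype=np.int64) for m, L in reference_lengths.items()}
        n_mapped = 0
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            mol = rec.reference_name
            if mol not in reference_lengths:
                raise ValueError(
                    f"read {rec.query_name!r} mapped to unknown reference {mol!r}; "
                    f"expected one of {sorted(reference_lengths)}"
                )
            if rec.is_reverse:
                profile.n_reverse_discarded += 1
                continue
            n_mapped += 1
            starts_idx[mol].append(rec.reference_start)  # 0-based 5'-most aligned base
            pos = rec.reference_start
            diff = cover_diff[mol]
            for op, length in rec.cigartuples or []:
                if op in _REF_CONSUMING:
                    if op in _COVERED:
                        diff[pos] += 1
                        diff[pos + length] -= 1
                    pos += length
        for mol, length in reference_lengths.items():
            st = np.bincount(np.array(starts_idx[mol], dtype=np.int64), minlength=int(length)) \
                if starts_idx[mol] else np.zeros(int(length), dtype=np.int64)
            profile.starts[mol] = st[: int(length)].astype(np.int64)
            profile.overlap[mol] = np.cumsum(cover_diff[mol][:-1])
        profile.total_mapped = n_mapped
        if n_mapped == 0:
            warnings.warn(f"no mapped forward reads in {profile.sample_id}; profile is empty")
        return profile
    finally:
        if own:
            af.close()


def psi_ratio_column(
    profile: TerminationProfile,
    sites: pd.DataFrame,
    offset: int = 0,
    min_coverage: int = 20,
) -> pd.DataFrame:
    """Compute the per-site Ψ-ratio for one sample.

    For a site at 1-based position ``p`` the ratio is
    ``starts[p+offset] / overlap[p+offset]`` with ``overlap`` counting every
    read covering the base (starting reads included). Sites whose
    denominator is below ``min_coverage`` are reported missing (NaN).

    Returns a DataFrame indexed by ``site_id`` with columns
    ``ratio, n_start, n_overlap``.
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    sites = validate_site_table(sites)
    rows = []
    for row in sites.itertuples(index=False):
        mol = row.molecule
        if mol not in profile.starts:
            raise ValueError(f"site {row.site_id}: molecule {mol!r} absent from profile")
        p = int(row.position) + offset
        length = len(profile.starts[mol])
        if not 1 <= p <= length:
            warnings.warn(f"site {row.site_id}: offset {offset} pushes position outside molecule")
            rows.append({"site_id": row.site_id, "ratio": np.nan, "n_start": 0, "n_overlap": 0})
            continue
        n_start = int(profile.starts[mol][p - 1])
        n_overlap = int(profile.overlap[mol][p - 1])
        ratio = n_start / n_overlap if n_overlap >= min_coverage else np.nan
        rows.append(
            {"site_id": row.site_id, "ratio": ratio, "n_start": n_start, "n_overlap": n_overlap}
        )
    return pd.DataFrame(rows).set_index("site_id")


@dataclass
class PsiRatioMatrix:
    """Sites × samples Ψ-ratios with per-cell overlap coverage."""

    values: pd.DataFrame  # sites × samples, NaN = missing (coverage below threshold)
    coverage: pd.DataFrame  # denominator used per cell
    sites: pd.DataFrame  # the site table (site_id, molecule, position, guides)
    offset: int = 0
    min_coverage: int = 20

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=0.0) > 1:
                raise ValueError("Ψ-ratios must lie in [0, 1]")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def build_ratio_matrix(
    profiles: Iterable[TerminationProfile],
    sites: pd.DataFrame,
    offset: int = 0,
    min_coverage: int = 20,
) -> PsiRatioMatrix:
    """Assemble Ψ-ratio columns from several samples into one matrix."""
    sites = validate_site_table(sites)
    cols, covs = {}, {}
    for profile in profiles:
        col = psi_ratio_column(profile, sites, offset=offset, min_coverage=min_coverage)
        cols[profile.sample_id] = col["ratio"]
        covs[profile.sample_id] = col["n_overlap"]
    values = pd.DataFrame(cols)
    coverage = pd.DataFrame(covs)
    return PsiRatioMatrix(values=values, coverage=coverage, sites=sites,
                          offset=offset, min_coverage=min_coverage)


def region_sum(
    matrix: PsiRatioMatrix, molecule: str, positions: Sequence[int]
) -> tuple[pd.Series, pd.Series]:
    """Per-sample sum of Ψ-ratios over a region (e.g. a hotspot).

    Returns ``(sums, complete)``: samples missing any listed site get a NaN
    sum and ``complete=False`` (they are excluded from downstream paired
    tests). Raises on an empty region or on sites absent from the matrix.
    """
    if len(positions) == 0:
        raise ValueError("empty region")
    ids = [f"{molecule}:{p}" for p in positions]
    missing = [s for s in ids if s not in matrix.values.index]
    if missing:
        raise ValueError(f"region sites absent from matrix: {missing}")
    block = matrix.values.loc[ids]
    complete = block.notna().all(axis=0)
    sums = block.sum(axis=0, skipna=False)
    if (~complete).any():
        logger.warning(
            "region %s:%s: %d sample(s) flagged incomplete", molecule, list(positions),
            int((~complete).sum()),
        )
    return sums, complete


def write_ratio_matrix(matrix: PsiRatioMatrix, path: str | os.PathLike,
                       meta: Mapping[str, object] | None = None) -> None:
    meta = dict(meta or {})
    meta.setdefault("offset", matrix.offset)
    meta.setdefault("min_coverage", matrix.min_coverage)
    io.write_tsv(matrix.values.reset_index(), path, meta=meta)
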