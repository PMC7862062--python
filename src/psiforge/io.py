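"""Shared I/O: headered TSV tables, FASTA, and SAM writing.

TSV is the interchange format between pipeline stages: a mandatory header
row, optional ``#`` comment lines carrying provenance (tool version, config
hash, seed) above it.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def provenance_lines(meta: Mapping[str, object] | None) -> list[str]:
    import psiforge

    lines = [f"# psiforge {psiforge.__version__}"]
    for key, val in (meta or {}).items():
        lines.append(f"# {key}={val}")
    return lines


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, meta: Mapping[str, object] | None = None,
              index: bool = False) -> None:
    """Write a DataFrame as TSV with ``#`` provenance comment lines on top."""
    with open(path, "w") as fh:
        for line in provenance_lines(meta):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def sam_header(reference_lengths: Mapping[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": name, "LN": int(length)} for name, length in reference_lengths.items()],
        }
    )


def write_sam(path: str | os.PathLike, reference_lengths: Mapping[str, int],
              reads: Iterable[tuple[str, int, int, str]],
              sequences: Mapping[str, str] | None = None) -> int:
    """Write mapped single-end reads as coordinate-sorted SAM.

    ``reads`` yields ``(molecule, start_1based, end_1based, qname)`` with the
    read spanning ``start..end`` inclusive on the forward strand; caller is
    responsible for sort order. Returns the number of records written.
    """
    header = sam_header(reference_lengths)
    ref_ids = {name: i for i, name in enumerate(reference_lengths)}
    n = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for molecule, start, end, qname in reads:
            length = end - start + 1
            rec = pysam.AlignedSegment(header)
            rec.query_name = qname
            rec.reference_id = ref_ids[molecule]
            rec.reference_start = start - 1  # SAM POS is 1-based; pysam takes 0-based
            rec.mapping_quality = 60
            rec.cigartuples = [(0, length)]
            if sequences is not None:
                rec.query_sequence = sequences[molecule][start - 1 : end]
                rec.query_qualities = pysam.qualitystring_to_array("I" * length)
            rec.flag = 0
            out.write(rec)
            n += 1
    return n


def sort_reads(reads: Sequence[tuple[str, int, int, str]]) -> list[tuple[str, int, int, str]]:
    return sorted(reads, key=lambda r: (r[0], r[1], r[2], r[3]))
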