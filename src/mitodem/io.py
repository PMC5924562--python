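"""FASTA / metadata I/O for temporal alignments.

The on-disk form is a plain FASTA plus a tab-separated metadata table with
columns ``sample_id``, ``layer``, ``age_generations``.  The join between
the two is strict: every FASTA record must appear in the metadata and vice
versa.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sumstats import TemporalAlignment

__all__ = ["read_alignment", "write_alignment", "read_metadata", "write_metadata"]

META_COLUMNS = ["sample_id", "layer", "age_generations"]


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"metadata file not found: {path}")
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "layer": str})
    missing = set(META_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata {path} lacks column(s): {sorted(missing)}")
    return meta


def read_alignment(fasta_path: str | os.PathLike, meta_path: str | os.PathLike) -> TemporalAlignment:
    """Load a FASTA alignment and its metadata table (strict id join)."""
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise FileNotFoundError(f"FASTA file not found: {fasta_path}")
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {fasta_path}")
    meta = read_metadata(meta_path).set_index("sample_id")

    fasta_ids = [r.id for r in records]
    extra = set(fasta_ids) - set(meta.index)
    absent = set(meta.index) - set(fasta_ids)
    if extra or absent:
        raise ValueError(
            f"FASTA/metadata mismatch: {sorted(extra)} only in FASTA, {sorted(absent)} only in metadata"
        )

    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    matrix = np.array([list(str(r.seq).upper()) for r in records], dtype="S1")
    layers = [str(meta.loc[i, "layer"]) for i in fasta_ids]
    ages = {
        str(row.layer): float(row.age_generations)
        for row in meta.itertuples()
    }
    return TemporalAlignment(matrix=matrix, ids=fasta_ids, layers=layers, ages=ages)


def write_alignment(
    alignment: TemporalAlignment,
    fasta_path: str | os.PathLike,
    meta_path: str | os.PathLike | None = None,
) -> None:
    records = [
        SeqRecord(Seq(bytes(row).decode()), id=sid, description="")
        for sid, row in zip(alignment.ids, alignment.matrix)
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    if meta_path is not None:
        write_metadata(alignment, meta_path)


def write_metadata(alignment: TemporalAlignment, meta_path: str | os.PathLike) -> None:
    meta = pd.DataFrame(
        {
            "sample_id": alignment.ids,
            "layer": alignment.layers,
            "age_generations": [alignment.ages[l] for l in alignment.layers],
        }
    )
    meta.to_csv(meta_path, sep="\t", index=False)
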