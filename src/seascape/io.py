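"""Reading and writing the pipeline's on-disk artifacts.

Reads are stored as gzipped FASTQ (one file per sample, constant quality),
stations and environment tables as TSV, dissimilarity/travel-time matrices
as square TSV (see :mod:`seascape.matrices`), velocity fields as netCDF
(see :mod:`seascape.field`), and generator truth as JSON.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synth import ReadSet

__all__ = [
    "write_fastq",
    "read_fastq",
    "write_stations",
    "read_stations",
    "write_truth",
    "read_truth",
]


def write_fastq(reads: ReadSet, path) -> None:
    """Write a read set as (optionally gzipped) FASTQ with constant quality."""
    path = Path(path)
    records = (
        SeqRecord(
            Seq(r),
            id=f"{reads.sample_id}.{i}",
            description="",
            letter_annotations={"phred_quality": [40] * len(r)},
        )
        for i, r in enumerate(reads.reads)
    )
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        SeqIO.write(records, fh, "fastq")


def read_fastq(path, sample_id: str | None = None) -> ReadSet:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        reads = [str(rec.seq) for rec in SeqIO.parse(fh, "fastq")]
    if sample_id is None:
        sample_id = path.name.split(".")[0]
    length = max((len(r) for r in reads), default=0)
    return ReadSet(sample_id=sample_id, reads=reads, read_length=length)


def write_stations(stations: pd.DataFrame, path) -> None:
    stations.to_csv(path, sep="\t", index=False)


def read_stations(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth(path, **payload) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
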