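"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA goes through Biopython; BED, chrom.sizes, bedGraph and the various
TSV tables are thin pandas wrappers.  Coordinates are 0-based half-open
(BED dialect) throughout.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file as ``[(id, sequence), ...]`` with IDs verbatim."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records, path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED_COLUMNS[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def write_bedgraph(track, path) -> None:
    """Write a binned per-chromosome track (CoverageTrack-like) as bedGraph."""
    bw = track.bin_width
    with open(path, "w") as fh:
        for chrom, values in track.per_chrom().items():
            for i, v in enumerate(values):
                if v != 0:
                    fh.write(f"{chrom}\t{i * bw}\t{(i + 1) * bw}\t{v:g}\n")


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
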