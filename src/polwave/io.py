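"""Readers and writers for the plain-text genomics formats the pipeline uses.

All genomic coordinates are 0-based half-open (BED convention); strand is
always carried explicitly.  BED6 and bedGraph round-trip losslessly
(field order preserved, floats normalized to %.6g), which is what makes the
pipeline's output hashes reproducible.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from . import FormatError
from .coverage import CoverageTrack

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed6(path) -> pd.DataFrame:
    """Read a BED6 file into a DataFrame with columns chrom..strand."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{i}: expected >=6 BED fields, got {len(parts)}")
            try:
                rows.append(
                    (parts[0], int(parts[1]), int(parts[2]), parts[3], parts[4], parts[5])
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{i}: {exc}") from exc
    return pd.DataFrame(rows, columns=BED6_COLUMNS)


def write_bed6(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in df[BED6_COLUMNS].itertuples(index=False):
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}:{i}: expected 'name size'")
            try:
                sizes[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{i}: {exc}") from exc
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def read_bedgraph(path) -> CoverageTrack:
    return CoverageTrack.from_bedgraph(path)


def write_bedgraph(track: CoverageTrack, path) -> None:
    track.to_bedgraph(path)


def read_gtf_genes(path) -> pd.DataFrame:
    """Reduce GTF ``gene`` records to a gene table (chrom/start/end/name/strand).

    Coordinates are converted from GTF 1-based closed to 0-based half-open.
    Emits a warning (and returns an empty table) when no gene feature exists.
    """
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}:{i}: expected 9 GTF fields")
            if parts[2] != "gene":
                continue
            try:
                start, end = int(parts[3]) - 1, int(parts[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{i}: {exc}") from exc
            attrs = {}
            for item in parts[8].strip().split(";"):
                item = item.strip()
                if not item:
                    continue
                key, _, val = item.partition(" ")
                attrs[key] = val.strip().strip('"')
            gene_id = attrs.get("gene_id", f"gene_{i}")
            rows.append((parts[0], start, end, gene_id, "0", parts[6]))
    if not rows:
        warnings.warn(f"{path}: no gene features found", stacklevel=2)
    return pd.DataFrame(rows, columns=BED6_COLUMNS)


def write_gtf_genes(genes: pd.DataFrame, path, source: str = "polwave") -> None:
    with open(path, "w") as fh:
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{source}\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f'{row.strand}\t.\tgene_id "{row.name}";\n'
            )


def read_fastq(path):
    """Iterate Biopython SeqRecords from a FASTQ file."""
    from Bio import SeqIO

    return SeqIO.parse(str(path), "fastq")


def write_fastq(records, path) -> int:
    from Bio import SeqIO

    return SeqIO.write(records, str(path), "fastq")


def write_tsv(df: pd.DataFrame, path, comments: list[str] | None = None) -> None:
    """Write a TSV table with optional '#' header comments (units etc.)."""
    path = Path(path)
    with open(path, "w") as fh:
        for c in comments or []:
            fh.write(f"# {c}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
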