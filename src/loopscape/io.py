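"""Readers and writers for the tabular formats the pipeline touches.

Supported dialects:

* ``bed3``      chrom, start, end
* ``bed6``      + name, score, strand
* ``state_bed`` chrom, start, end, state-label
* ``motif_bed`` bed6 where name is the TF and strand is required (+/-)
* ``bedpe``     10 columns: chromA startA endA chromB startB endB name score
  strandA strandB

Matrices are TSV with a header row and the row id (loop/gene/exon) in
column 1.  The sample sheet is a TSV with named columns.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import VALID_STRANDS, FeatureTrack, ParseError

_DIALECT_NCOLS = {"bed3": 3, "bed6": 6, "state_bed": 4, "motif_bed": 6, "bedpe": 10}

BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2",
]


def _check_interval(chrom, start, end, strand, lineno):
    if start < 0 or end <= start:
        raise ParseError(f"line {lineno}: invalid interval {chrom}:{start}-{end}")
    if strand not in VALID_STRANDS:
        raise ParseError(f"line {lineno}: invalid strand {strand!r}")


def read_intervals(path, dialect: str):
    """Parse an interval file into a FeatureTrack (or a BEDPE DataFrame).

    Coordinates are taken as 0-based half-open.  Malformed lines raise
    :class:`ParseError` naming the offending line number.
    """
    if dialect not in _DIALECT_NCOLS:
        raise ValueError(f"unknown dialect {dialect!r}")
    ncols = _DIALECT_NCOLS[dialect]
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < ncols:
                raise ParseError(
                    f"line {lineno}: expected {ncols} fields for {dialect}, got {len(fields)}"
                )
            try:
                if dialect == "bedpe":
                    c1, s1, e1, c2, s2, e2, name, score, st1, st2 = fields[:10]
                    s1, e1, s2, e2 = int(s1), int(e1), int(s2), int(e2)
                    _check_interval(c1, s1, e1, st1, lineno)
                    _check_interval(c2, s2, e2, st2, lineno)
                    rows.append((c1, s1, e1, c2, s2, e2, name, float(score), st1, st2))
                else:
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    if dialect == "bed3":
                        label, score, strand = "", 0.0, "."
                    elif dialect == "state_bed":
                        label, score, strand = fields[3], 0.0, "."
                    else:  # bed6 / motif_bed
                        label, score, strand = fields[3], float(fields[4]), fields[5]
                        if dialect == "motif_bed" and strand not in ("+", "-"):
                            raise ParseError(f"line {lineno}: motif strand must be + or -")
                    _check_interval(chrom, start, end, strand, lineno)
                    rows.append((chrom, start, end, strand, label, score))
            except ParseError:
                raise
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    if dialect == "bedpe":
        return pd.DataFrame(rows, columns=BEDPE_COLUMNS)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "label", "score"])
    return FeatureTrack(df)


def write_intervals(track: FeatureTrack, path, dialect: str = "bed6") -> None:
    df = track.df
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for row in df.itertuples(index=False):
            if dialect == "bed3":
                w.writerow([row.chrom, row.start, row.end])
            elif dialect == "state_bed":
                w.writerow([row.chrom, row.start, row.end, row.label])
            else:
                w.writerow([row.chrom, row.start, row.end, row.label,
                            _fmt_score(row.score), row.strand])


def _fmt_score(x: float):
    return int(x) if float(x).is_integer() else x


def write_bedpe(df: pd.DataFrame, path) -> None:
    out = df[BEDPE_COLUMNS].copy()
    out["score"] = out["score"].map(_fmt_score)
    out.to_csv(path, sep="\t", header=False, index=False)


def write_matrix(matrix: pd.DataFrame, path, index_label: str = "id") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


@dataclass
class SampleSheet:
    """Sample metadata: cell type, replicate, group, batch, library depth."""

    df: pd.DataFrame

    REQUIRED = ("sample_id", "cell_type", "replicate", "group", "batch", "depth")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        df = self.df
        dup = df.duplicated(subset=["cell_type", "replicate"])
        if dup.any():
            raise ValueError("duplicate (cell_type, replicate) rows in sample sheet")
        groups_per_cell = df.groupby("cell_type")["group"].nunique()
        if (groups_per_cell > 1).any():
            bad = groups_per_cell[groups_per_cell > 1].index.tolist()
            raise ValueError(f"cell type(s) mapped to multiple groups: {bad}")
        self.df = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list:
        return self.df["sample_id"].tolist()

    def cell_type_of(self) -> dict:
        return dict(zip(self.df["sample_id"], self.df["cell_type"]))

    def group_of(self) -> dict:
        return dict(zip(self.df["sample_id"], self.df["group"]))

    def samples_of_cell(self, cell_type: str) -> list:
        return self.df.loc[self.df["cell_type"] == cell_type, "sample_id"].tolist()

    def samples_of_group(self, group: str) -> list:
        return self.df.loc[self.df["group"] == group, "sample_id"].tolist()

    @property
    def cell_types(self) -> list:
        return sorted(self.df["cell_type"].unique())

    @property
    def groups(self) -> list:
        return sorted(self.df["group"].unique())

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t"))


GENE_TABLE_COLUMNS = [
    "gene_id", "chrom", "strand", "start", "end", "exon_start", "exon_end", "biotype",
]


def read_gene_table(path) -> pd.DataFrame:
    """Read the reduced gene/exon annotation (one row per exon)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"gene table missing columns: {missing}")
    return df


def write_gene_table(df: pd.DataFrame, path) -> None:
    df[GENE_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


SNP_TABLE_COLUMNS = [
    "study_id", "snp_id", "chrom", "pos", "p_value", "ld_cluster", "r2_to_lead",
]


def read_snp_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SNP_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"SNP table missing columns: {missing}")
    if ((df["p_value"] <= 0) | (df["p_value"] > 1)).any():
        raise ParseError("SNP p-values must lie in (0, 1]")
    return df


def write_snp_table(df: pd.DataFrame, path) -> None:
    df[SNP_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)
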