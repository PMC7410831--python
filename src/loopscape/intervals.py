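"""Genomic interval primitives.

All coordinates are 0-based half-open (BED convention); conversion, if any,
happens at I/O boundaries only.  Chromosome names are compared by exact
string match.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_STRANDS = ("+", "-", ".")

TRACK_COLUMNS = ["chrom", "start", "end", "strand", "label", "score"]


class ParseError(ValueError):
    """Raised for malformed interval records; message names the line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""
    score: float = 0.0

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


class FeatureTrack:
    """An ordered collection of labelled genomic intervals.

    Backed by a pandas DataFrame with columns chrom/start/end/strand/label/
    score, sorted by (chrom, start, end) on construction.
    """

    def __init__(self, df: pd.DataFrame, name: str = ""):
        df = df.copy()
        for col, default in (("strand", "."), ("label", ""), ("score", 0.0)):
            if col not in df.columns:
                df[col] = default
        df = df[TRACK_COLUMNS]
        if len(df):
            if (df["start"] < 0).any():
                raise ValueError("negative start coordinate")
            if (df["end"] <= df["start"]).any():
                raise ValueError("interval with end <= start")
            bad = ~df["strand"].isin(VALID_STRANDS)
            if bad.any():
                raise ValueError(f"invalid strand value(s): {df.loc[bad, 'strand'].unique()}")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        self.df = df
        self.name = name

    @classmethod
    def from_intervals(cls, intervals, name: str = "") -> "FeatureTrack":
        rows = [
            (iv.chrom, iv.start, iv.end, iv.strand, iv.label, iv.score) for iv in intervals
        ]
        df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
        return cls(df, name=name)

    def __len__(self) -> int:
        return len(self.df)

    def __getitem__(self, i: int) -> GenomicInterval:
        r = self.df.iloc[i]
        return GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand, r.label, float(r.score))

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, FeatureTrack):
            return NotImplemented
        return self.df.equals(other.df)

    @property
    def chroms(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def starts(self) -> np.ndarray:
        return self.df["start"].to_numpy()

    @property
    def ends(self) -> np.ndarray:
        return self.df["end"].to_numpy()

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) // 2


@dataclass(frozen=True)
class LoopRecord:
    """A chromatin loop: an ordered pair of anchors on one chromosome."""

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    loop_id: int = -1

    def __post_init__(self):
        if self.anchor_a.chrom != self.anchor_b.chrom:
            raise ValueError("loop anchors must share a chromosome")
        if self.anchor_a.midpoint >= self.anchor_b.midpoint:
            raise ValueError("anchor_a must precede anchor_b in genome order")

    @property
    def span(self) -> int:
        return self.anchor_b.midpoint - self.anchor_a.midpoint


def merge_intervals(track: FeatureTrack, gap: int = 0) -> FeatureTrack:
    """Merge intervals closer than or equal to ``gap`` bp into single spans.

    With the default ``gap=0`` only touching or overlapping intervals merge.
    Output intervals are disjoint and cover the same bases (plus closed gaps).
    """
    if len(track) == 0:
        return FeatureTrack(track.df.copy(), name=track.name)
    out = []
    df = track.df
    for chrom, sub in df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e + gap:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return FeatureTrack(pd.DataFrame(out, columns=["chrom", "start", "end"]), name=track.name)


def overlap_join(query: FeatureTrack, subject: FeatureTrack, min_overlap: int = 1):
    """All (query_index, subject_index) pairs sharing >= min_overlap bases.

    Indices refer to row order in the sorted tracks.  Equivalent to the
    quadratic all-pairs scan; implemented as a per-chromosome sweep.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    qi_out, si_out = [], []
    qdf, sdf = query.df, subject.df
    s_groups = {c: g for c, g in sdf.groupby("chrom", sort=False)}
    for chrom, qsub in qdf.groupby("chrom", sort=False):
        ssub = s_groups.get(chrom)
        if ssub is None:
            continue
        s_idx = ssub.index.to_numpy()
        s_starts = ssub["start"].to_numpy()
        s_ends = ssub["end"].to_numpy()
        for qi, qs, qe in zip(qsub.index.to_numpy(), qsub["start"].to_numpy(), qsub["end"].to_numpy()):
            # subjects starting too late cannot reach min_overlap
            hi = np.searchsorted(s_starts, qe - min_overlap, side="right")
            if hi == 0:
                continue
            ov = np.minimum(qe, s_ends[:hi]) - np.maximum(qs, s_starts[:hi])
            hit = np.nonzero(ov >= min_overlap)[0]
            qi_out.extend([qi] * len(hit))
            si_out.extend(s_idx[hit])
    return np.asarray(qi_out, dtype=np.int64), np.asarray(si_out, dtype=np.int64)


def overlaps_any(query: FeatureTrack, subject: FeatureTrack, min_overlap: int = 1) -> np.ndarray:
    """Boolean per query interval: does it overlap any subject interval?"""
    flags = np.zeros(len(query), dtype=bool)
    qi, _ = overlap_join(query, subject, min_overlap=min_overlap)
    flags[np.unique(qi)] = True
    return flags


def assign_points_to_disjoint(
    point_chroms: np.ndarray,
    point_pos: np.ndarray,
    track: FeatureTrack,
) -> np.ndarray:
    """Index of the disjoint track interval containing each point, else -1.

    The track must hold disjoint intervals (e.g. merged anchors); containment
    uses the half-open convention.
    """
    out = np.full(len(point_pos), -1, dtype=np.int64)
    df = track.df
    for chrom, sub in df.groupby("chrom", sort=False):
        mask = point_chroms == chrom
        if not mask.any():
            continue
        pos = point_pos[mask]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        ok[ok] &= pos[ok] < ends[idx[ok]]
        res = np.where(ok, sub.index.to_numpy()[np.clip(idx, 0, None)], -1)
        out[mask] = res
    return out
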