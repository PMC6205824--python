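"""Core in-memory containers shared across pipeline stages.

Coordinates are 0-based half-open throughout; BED/bedGraph on disk use the
same convention.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SAMPLE_META_ROWS = ("condition", "timepoint", "replicate")


@dataclass
class PileupTrack:
    """Per-base read depth over one region for one replicate."""

    region_id: str
    start: int
    end: int
    depth: np.ndarray  # int, length end - start

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if len(self.depth) != self.end - self.start:
            raise ValueError(
                f"depth length {len(self.depth)} != end-start "
                f"{self.end - self.start} for {self.region_id}"
            )
        if np.any(self.depth < 0):
            raise ValueError("negative depth")

    def to_bedgraph(self, handle: io.TextIOBase) -> None:
        """Write run-length-encoded 4-column bedGraph lines for this track."""
        d = self.depth
        if len(d) == 0:
            return
        change = np.flatnonzero(np.diff(d)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(d)]))
        for s, e in zip(starts, ends):
            v = d[s]
            if v != 0:
                handle.write(
                    f"{self.region_id}\t{self.start + s}\t{self.start + e}\t{v}\n"
                )


def read_bedgraph(path: str | Path, region_lengths: dict[str, int]) -> list[PileupTrack]:
    """Read a bedGraph into one dense :class:`PileupTrack` per region.

    ``region_lengths`` fixes the span of each region so zero-depth tails are
    preserved.
    """
    depths = {rid: np.zeros(n, dtype=int) for rid, n in region_lengths.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            rid, s, e, v = line.split("\t")
            s, e = int(s), int(e)
            if rid not in depths:
                raise ValueError(f"unknown region {rid!r} in {path}")
            if e > region_lengths[rid] or s < 0 or s >= e:
                raise ValueError(f"interval {rid}:{s}-{e} out of range")
            depths[rid][s:e] = int(float(v))
    return [
        PileupTrack(rid, 0, region_lengths[rid], d) for rid, d in depths.items()
    ]


@dataclass
class BindingSite:
    """Contiguous pileup interval emitted by the recursive summit splitter."""

    region_id: str
    start: int
    end: int
    summit_pos: int
    summit_height: float
    parent_id: str = ""
    depth_sum: float = 0.0

    def overlaps(self, other: "BindingSite") -> bool:
        return (
            self.region_id == other.region_id
            and self.start < other.end
            and other.start < self.end
        )


def sites_to_bed(sites: Sequence[BindingSite], path: str | Path) -> None:
    """Write sites as BED6 with the summit height in the score column."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.region_id}\t{s.start}\t{s.end}\t{s.parent_id or '.'}\t"
                f"{s.summit_height:g}\t+\n"
            )


def sites_from_bed(path: str | Path) -> list[BindingSite]:
    out = []
    for line in open(path):
        if not line.strip():
            continue
        rid, s, e, name, score, _ = line.rstrip("\n").split("\t")
        s, e = int(s), int(e)
        out.append(
            BindingSite(rid, s, e, summit_pos=s, summit_height=float(score),
                        parent_id="" if name == "." else name)
        )
    return out


class ExpressionMatrix:
    """Genes x samples matrix with condition/timepoint/replicate metadata.

    ``values`` is a pandas DataFrame indexed by gene id; ``samples`` is a
    DataFrame indexed by sample id with columns ``condition`` (str),
    ``timepoint`` (int) and ``replicate`` (int).
    """

    def __init__(self, values: pd.DataFrame, samples: pd.DataFrame) -> None:
        if not values.columns.equals(samples.index):
            raise ValueError("sample metadata does not match matrix columns")
        missing = set(SAMPLE_META_ROWS) - set(samples.columns)
        if missing:
            raise ValueError(f"sample metadata missing {sorted(missing)}")
        if values.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        values = values.rename_axis(index="gene_id")
        self.values = values
        self.samples = samples

    # -- selection ----------------------------------------------------------
    def subset(self, condition: str | None = None,
               timepoint: int | None = None) -> "ExpressionMatrix":
        mask = pd.Series(True, index=self.samples.index)
        if condition is not None:
            mask &= self.samples["condition"] == condition
        if timepoint is not None:
            mask &= self.samples["timepoint"] == int(timepoint)
        cols = self.samples.index[mask]
        return ExpressionMatrix(self.values[cols], self.samples.loc[cols])

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def conditions(self) -> list[str]:
        return sorted(self.samples["condition"].unique())

    @property
    def timepoints(self) -> list[int]:
        return sorted(self.samples["timepoint"].unique())

    def day_means(self, condition: str) -> pd.DataFrame:
        """Per-gene mean across replicates for each timepoint of one condition."""
        sub = self.subset(condition=condition)
        tp = sub.samples["timepoint"]
        return sub.values.T.groupby(tp.values).mean().T

    # -- disk round trip ----------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """TSV with a 3-row sample-metadata header above the gene rows."""
        with open(path, "w") as fh:
            for row in SAMPLE_META_ROWS:
                vals = "\t".join(str(v) for v in self.samples[row])
                fh.write(f"#{row}\t{vals}\n")
            self.values.to_csv(fh, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        meta: dict[str, list[str]] = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, *vals = line[1:].rstrip("\n").split("\t")
                meta[key] = vals
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            values = pd.read_csv(fh, sep="\t", index_col=0)
        values.index.name = "gene_id"
        samples = pd.DataFrame(
            {
                "condition": meta["condition"],
                "timepoint": [int(t) for t in meta["timepoint"]],
                "replicate": [int(r) for r in meta["replicate"]],
            },
            index=values.columns,
        )
        return cls(values, samples)


def annotation_to_bed(ann: pd.DataFrame, path: str | Path) -> None:
    """Write an interval annotation table as BED6+gene_id.

    Columns required: region_id, start, end, gene_id, feature.
    """
    cols = ["region_id", "start", "end", "feature", "gene_id"]
    with open(path, "w") as fh:
        for _, r in ann[cols].iterrows():
            fh.write(
                f"{r.region_id}\t{r.start}\t{r.end}\t{r.feature}\t0\t+\t{r.gene_id}\n"
            )


def annotation_from_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    for line in open(path):
        if not line.strip():
            continue
        rid, s, e, feat, _score, _strand, gid = line.rstrip("\n").split("\t")
        rows.append((rid, int(s), int(e), feat, gid))
    return pd.DataFrame(rows, columns=["region_id", "start", "end", "feature", "gene_id"])
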