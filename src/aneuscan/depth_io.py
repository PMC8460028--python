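"""Binned read-depth profiles: the container plus bedGraph/TSV I/O and rebinning.

Coordinates are 0-based half-open throughout (UCSC bedGraph convention).
Depth is stored as a real number so pooled or averaged tracks remain
representable.
"""

from __future__ import annotations

import gzip
import io
from typing import Iterable

import numpy as np
import pandas as pd

from .genome import GenomeModel

COLUMNS = ["chrom", "start", "end", "depth"]


class DepthProfileError(ValueError):
    """A depth profile violated its format or coordinate contract."""


class DepthProfile:
    """Non-overlapping, sorted (chrom, start, end, depth) records over a genome.

    ``data`` is a DataFrame with columns chrom/start/end/depth; records are
    sorted by genome chromosome order then start, and validated on
    construction.
    """

    def __init__(self, data: pd.DataFrame, genome: GenomeModel):
        df = data.loc[:, COLUMNS].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["depth"] = df["depth"].astype(np.float64)

        known = set(genome.names)
        bad = sorted(set(df["chrom"]) - known)
        if bad:
            raise DepthProfileError(f"unknown chromosome(s) {bad} not in genome")

        order = {name: i for i, name in enumerate(genome.names)}
        df = df.sort_values(
            ["chrom", "start"], key=lambda s: s.map(order) if s.name == "chrom" else s
        ).reset_index(drop=True)

        if (df["end"] <= df["start"]).any():
            row = df[df["end"] <= df["start"]].iloc[0]
            raise DepthProfileError(
                f"empty or inverted interval {row.chrom}:{row.start}-{row.end}"
            )
        if (df["depth"] < 0).any() or not np.isfinite(df["depth"]).all():
            raise DepthProfileError("depth values must be finite and non-negative")
        for chrom, sub in df.groupby("chrom", sort=False):
            if (sub["start"].values[1:] < sub["end"].values[:-1]).any():
                raise DepthProfileError(f"overlapping intervals on {chrom}")
            if (sub["end"] > genome.length(str(chrom))).any():
                raise DepthProfileError(
                    f"interval extends past end of {chrom} "
                    f"(length {genome.length(str(chrom))})"
                )

        self.data = df
        self.genome = genome

    # -- accessors -----------------------------------------------------------

    @property
    def chromosomes(self) -> list[str]:
        present = set(self.data["chrom"])
        return [c for c in self.genome.names if c in present]

    def chrom_table(self, chrom: str) -> pd.DataFrame:
        return self.data[self.data["chrom"] == chrom]

    def chrom_depths(self, chrom: str) -> np.ndarray:
        return self.chrom_table(chrom)["depth"].to_numpy()

    @property
    def depths(self) -> np.ndarray:
        return self.data["depth"].to_numpy()

    def total_mass(self) -> float:
        """Sum of depth x interval length over all records."""
        lengths = (self.data["end"] - self.data["start"]).to_numpy()
        return float(np.sum(self.depths * lengths))

    def scaled(self, k: float) -> "DepthProfile":
        df = self.data.copy()
        df["depth"] *= k
        return DepthProfile(df, self.genome)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DepthProfile):
            return NotImplemented
        return self.data.equals(other.data) and self.genome == other.genome

    def __len__(self) -> int:
        return len(self.data)

    # -- output --------------------------------------------------------------

    def write_bedgraph(self, path, header_comments: Iterable[str] = ()) -> None:
        with _open_write(path) as fh:
            for line in header_comments:
                fh.write(f"# {line}\n")
            self.data.to_csv(fh, sep="\t", header=False, index=False)

    def write_tsv(self, path, header_comments: Iterable[str] = ()) -> None:
        with _open_write(path) as fh:
            for line in header_comments:
                fh.write(f"# {line}\n")
            self.data.to_csv(fh, sep="\t", header=True, index=False)


def _open_write(path) -> io.TextIOBase:
    if str(path).endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def _open_read(path) -> io.TextIOBase:
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "r")


def read_depth(path, genome: GenomeModel) -> DepthProfile:
    """Parse a bedGraph or headered 4-column TSV into a validated profile.

    track/browser/# lines are skipped; a non-numeric first data line is
    treated as a column header. Errors report the offending line number.
    """
    records = []
    with _open_read(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise DepthProfileError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            chrom, start_s, end_s, depth_s = fields[:4]
            try:
                start, end, depth = int(start_s), int(end_s), float(depth_s)
            except ValueError:
                if not records and lineno <= 10:
                    continue  # header row
                raise DepthProfileError(f"{path}:{lineno}: non-numeric coordinates/depth") from None
            if chrom not in genome.lengths:
                raise DepthProfileError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if depth < 0:
                raise DepthProfileError(f"{path}:{lineno}: negative depth {depth}")
            records.append((chrom, start, end, depth))
    if not records:
        raise DepthProfileError(f"{path}: no depth records found")
    df = pd.DataFrame(records, columns=COLUMNS)
    try:
        return DepthProfile(df, genome)
    except DepthProfileError as exc:
        raise DepthProfileError(f"{path}: {exc}") from None


def rebin(profile: DepthProfile, bin_size: int) -> DepthProfile:
    """Re-grid a profile onto fixed bins anchored at 0.

    The depth of an output bin is the length-weighted mean of the input
    depths overlapping it; a trailing partial bin is kept. Total
    depth x length mass is conserved for contiguous profiles.
    """
    if bin_size < 1:
        raise ValueError(f"bin_size must be >= 1, got {bin_size}")
    out_rows = []
    for chrom in profile.chromosomes:
        sub = profile.chrom_table(chrom)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        depths = sub["depth"].to_numpy()
        span_lo, span_hi = int(starts.min()), int(ends.max())
        n_out = -(-span_hi // bin_size)
        mass = np.zeros(n_out)
        cover = np.zeros(n_out)
        for s, e, d in zip(starts, ends, depths):
            first, last = s // bin_size, (e - 1) // bin_size
            for b in range(first, last + 1):
                lo = max(s, b * bin_size)
                hi = min(e, (b + 1) * bin_size)
                mass[b] += d * (hi - lo)
                cover[b] += hi - lo
        for b in np.nonzero(cover)[0]:
            lo = max(span_lo, int(b) * bin_size)
            hi = min(span_hi, (int(b) + 1) * bin_size)
            out_rows.append((chrom, lo, hi, mass[b] / cover[b]))
    return DepthProfile(pd.DataFrame(out_rows, columns=COLUMNS), profile.genome)
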