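"""Genome model: an ordered set of chromosomes with lengths and a bin size.

The default model is a 16-chromosome budding-yeast genome at rounded S288C
chromosome lengths (chr1 shortest, chr4 longest, ~12.1 Mb total), binned at
1 kb. Any genome can be supplied instead, from YAML or programmatically.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd
import yaml

DEFAULT_BIN_SIZE = 1_000


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosomes (name, length in bp) plus a binning resolution.

    Invariants: at least one chromosome; unique names; every length at least
    twice the bin size (so every chromosome has >= 2 bins).
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int = DEFAULT_BIN_SIZE

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome must contain at least one chromosome")
        if self.bin_size < 1:
            raise ValueError(f"bin_size must be >= 1, got {self.bin_size}")
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length < 2 * self.bin_size:
                raise ValueError(
                    f"chromosome {name} length {length} is shorter than "
                    f"2 x bin_size ({2 * self.bin_size})"
                )

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def n_bins(self, chrom: str) -> int:
        length = self.length(chrom)
        return -(-length // self.bin_size)  # ceil division, trailing partial bin kept

    def bin_edges(self, chrom: str) -> tuple[list[int], list[int]]:
        """Half-open [start, end) bin boundaries for one chromosome."""
        length = self.length(chrom)
        starts = list(range(0, length, self.bin_size))
        ends = [min(s + self.bin_size, length) for s in starts]
        return starts, ends

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.names)

    def to_yaml(self, path) -> None:
        doc = {
            "bin_size": self.bin_size,
            "chromosomes": [{"name": n, "length": l} for n, l in self.chromosomes],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GenomeModel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        chroms = tuple((c["name"], int(c["length"])) for c in doc["chromosomes"])
        return cls(chromosomes=chroms, bin_size=int(doc.get("bin_size", DEFAULT_BIN_SIZE)))


def default_genome(bin_size: int = DEFAULT_BIN_SIZE) -> GenomeModel:
    """The packaged 16-chromosome yeast genome at rounded S288C lengths."""
    ref = importlib.resources.files("aneuscan.data") / "s288c_chromosomes.tsv"
    with importlib.resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t")
    chroms = tuple(zip(table["chrom"], table["length"].astype(int)))
    return GenomeModel(chromosomes=chroms, bin_size=bin_size)
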