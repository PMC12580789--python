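"""Reference genome coordinate model: chromosomes, lengths, centromeres, arms.

Coordinates are 0-based half-open throughout the package. A chromosome arm
``p`` covers ``[0, centromere)`` and ``q`` covers ``[centromere, length)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosomes with lengths and centromere positions (bp)."""

    chromosomes: tuple[str, ...]
    lengths: dict[str, int] = field(repr=False)
    centromeres: dict[str, int] = field(repr=False)

    def __post_init__(self) -> None:
        for chrom in self.chromosomes:
            length = self.lengths[chrom]
            centro = self.centromeres[chrom]
            if length <= 0:
                raise ValueError(f"{chrom}: length must be positive, got {length}")
            if not 0 < centro < length:
                raise ValueError(
                    f"{chrom}: centromere {centro} not strictly inside (0, {length})"
                )

    @property
    def arms(self) -> list[tuple[str, str, int, int]]:
        """All arms as (chrom, arm, start, end) with p=[0,centromere), q=[centromere,len)."""
        out = []
        for chrom in self.chromosomes:
            out.append((chrom, "p", 0, self.centromeres[chrom]))
            out.append((chrom, "q", self.centromeres[chrom], self.lengths[chrom]))
        return out

    def total_length(self) -> int:
        return sum(self.lengths[c] for c in self.chromosomes)

    @classmethod
    def from_table(cls, path: str | Path) -> "GenomeModel":
        """Load a 3-column TSV (chrom, length, centromere)."""
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        required = {"chrom", "length", "centromere"}
        if not required.issubset(df.columns):
            raise ValueError(f"genome table needs columns {sorted(required)}")
        return cls(
            chromosomes=tuple(df["chrom"]),
            lengths=dict(zip(df["chrom"], df["length"].astype(int))),
            centromeres=dict(zip(df["chrom"], df["centromere"].astype(int))),
        )

    @classmethod
    def grch38(cls) -> "GenomeModel":
        """The bundled GRCh38 autosome + X model."""
        with resources.as_file(resources.files("cinsig.data") / "grch38.tsv") as p:
            return cls.from_table(p)

    @classmethod
    def toy(cls, n_chrom: int = 3, length: int = 100_000_000) -> "GenomeModel":
        """Small uniform genome for tests and simulations at reduced scale."""
        chroms = tuple(f"chr{i + 1}" for i in range(n_chrom))
        return cls(
            chromosomes=chroms,
            lengths={c: length for c in chroms},
            centromeres={c: length // 2 for c in chroms},
        )
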