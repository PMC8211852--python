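"""Genome coordinate model shared by every stage of the pipeline.

Coordinates are 0-based half-open internally; text formats convert at the
boundary (pairs files are 1-based, BED is 0-based half-open).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenomeModel"]


@dataclass
class GenomeModel:
    """Chromosome sizes plus the gene and CTCF-motif catalogs.

    Parameters
    ----------
    chromosomes
        Ordered mapping of chromosome name to length in bp.
    binsize
        Native bin size in bp used by the simulator; analysis operations
        may re-bin to coarser resolutions.
    genes
        DataFrame with columns ``name, chrom, start, end, strand``
        (0-based half-open), or None.
    motifs
        DataFrame with columns ``chrom, start, end, name, score, strand``
        (BED6 convention), or None.
    """

    chromosomes: dict[str, int]
    binsize: int = 40_000
    genes: pd.DataFrame | None = None
    motifs: pd.DataFrame | None = None
    _order: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.binsize <= 0:
            raise ValueError("binsize must be positive")
        for name, length in self.chromosomes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        self._order = {c: i for i, c in enumerate(self.chromosomes)}
        for df, what in ((self.genes, "gene"), (self.motifs, "motif")):
            if df is None or len(df) == 0:
                continue
            for _, row in df.iterrows():
                if row["chrom"] not in self.chromosomes:
                    raise ValueError(f"{what} on unknown chromosome {row['chrom']!r}")
                if not (0 <= row["start"] < row["end"] <= self.chromosomes[row["chrom"]]):
                    raise ValueError(f"{what} outside chromosome bounds: {dict(row)}")

    # -- bin arithmetic -------------------------------------------------
    def n_bins(self, chrom: str, binsize: int | None = None) -> int:
        bs = binsize or self.binsize
        return -(-self.chromosomes[chrom] // bs)  # ceil; last bin may be partial

    def chrom_order(self, chrom: str) -> int:
        try:
            return self._order[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def canonical_pair(self, c1: str, c2: str) -> tuple[str, str, bool]:
        """Return (first, second, swapped) with chromosomes in genome order."""
        if self.chrom_order(c1) <= self.chrom_order(c2):
            return c1, c2, False
        return c2, c1, True

    def bin_of(self, chrom: str, pos_1based: int, binsize: int | None = None) -> int:
        """Bin index of a 1-based genomic position."""
        bs = binsize or self.binsize
        if not (1 <= pos_1based <= self.chromosomes[chrom]):
            raise ValueError(f"position {pos_1based} outside {chrom} (len {self.chromosomes[chrom]})")
        return (pos_1based - 1) // bs

    def bin_mid(self, chrom: str, bin_index: int, binsize: int | None = None) -> int:
        """1-based midpoint position of a bin, clipped to the chromosome."""
        bs = binsize or self.binsize
        mid = bin_index * bs + bs // 2
        return int(min(mid, self.chromosomes[chrom]))

    # -- catalogs -------------------------------------------------------
    def gene_density(self, chrom: str, binsize: int) -> np.ndarray:
        """Genes-per-bin track, the activity proxy used to orient compartments."""
        n = self.n_bins(chrom, binsize)
        dens = np.zeros(n)
        if self.genes is not None:
            sub = self.genes[self.genes["chrom"] == chrom]
            for _, g in sub.iterrows():
                b0, b1 = int(g["start"]) // binsize, (int(g["end"]) - 1) // binsize
                dens[b0 : b1 + 1] += 1.0
        return dens
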