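"""Genome coordinate frame shared by the simulator and the analysis modules.

A :class:`GenomeModel` carries the chromosomes (physical length in bp,
genetic length in cM) and the marker loci, each with a physical (bp) and a
genetic (cM) position.  Physical and genetic coordinates are related by
piecewise-linear interpolation between anchor points; the default anchors
are the chromosome ends, i.e. a uniform recombination landscape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Chromosome", "GenomeModel"]


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_bp: int
    length_cm: float

    def __post_init__(self) -> None:
        if self.length_bp <= 0 or self.length_cm < 0:
            raise ValueError(f"invalid chromosome {self.name}: "
                             f"length_bp={self.length_bp}, length_cm={self.length_cm}")


@dataclass
class GenomeModel:
    """Chromosomes plus ordered marker loci in bp and cM coordinates.

    Parameters
    ----------
    chromosomes:
        Chromosome definitions, in karyotype order.
    markers:
        DataFrame with columns ``marker``, ``chromosome``, ``bp`` and
        optionally ``cm``.  Missing cM positions are interpolated from the
        anchor map.  Within a chromosome both coordinates must be strictly
        increasing.
    anchors:
        Optional ``{chromosome: (bp_array, cm_array)}`` interpolation anchors.
        Defaults to the chromosome ends (linear bp-to-cM map).
    """

    chromosomes: list[Chromosome]
    markers: pd.DataFrame
    anchors: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("a genome needs at least one chromosome")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        required = {"marker", "chromosome", "bp"}
        if not required.issubset(self.markers.columns):
            raise ValueError(f"marker table needs columns {sorted(required)}")
        if self.markers["marker"].duplicated().any():
            raise ValueError("duplicate marker ids in genome")
        unknown = set(self.markers["chromosome"]) - set(names)
        if unknown:
            raise ValueError(f"markers on unknown chromosomes: {sorted(unknown)}")
        for c in self.chromosomes:
            self.anchors.setdefault(
                c.name,
                (np.array([0.0, float(c.length_bp)]), np.array([0.0, c.length_cm])),
            )
        df = self.markers.copy()
        if "cm" not in df.columns:
            df["cm"] = np.nan
        # keep the caller's chromosome ordering, sort by position within each
        order = {n: i for i, n in enumerate(names)}
        df = df.sort_values(["chromosome", "bp"],
                            key=lambda s: s.map(order) if s.name == "chromosome" else s,
                            kind="stable").reset_index(drop=True)
        fill = df["cm"].isna()
        if fill.any():
            df.loc[fill, "cm"] = [
                self.bp_to_cm(row.chromosome, row.bp)
                for row in df.loc[fill].itertuples()
            ]
        self.markers = df
        by_chrom = {c.name: c for c in self.chromosomes}
        for name, sub in df.groupby("chromosome", sort=False):
            bp = sub["bp"].to_numpy(float)
            cm = sub["cm"].to_numpy(float)
            # bp strictly increasing; cM may tie (zero genetic distance, e.g.
            # pericentromeric recombination suppression)
            if np.any(np.diff(bp) <= 0) or np.any(np.diff(cm) < 0):
                raise ValueError(f"marker positions not increasing on {name}")
            c = by_chrom[name]
            if bp[0] < 1 or bp[-1] > c.length_bp:
                raise ValueError(f"marker bp outside {name}")
            if cm[0] < 0 or cm[-1] > c.length_cm + 1e-9:
                raise ValueError(f"marker cM outside [0, {c.length_cm}] on {name}")

    # -- coordinate helpers -------------------------------------------------

    def bp_to_cm(self, chromosome: str, bp: float) -> float:
        xs, ys = self.anchors[chromosome]
        return float(np.interp(bp, xs, ys))

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.markers["marker"].to_numpy()

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous marker index ranges per chromosome, in marker order."""
        out: dict[str, slice] = {}
        chroms = self.markers["chromosome"].to_numpy()
        start = 0
        for name, sub in self.markers.groupby("chromosome", sort=False):
            idx = sub.index.to_numpy()
            out[name] = slice(int(idx[0]), int(idx[-1]) + 1)
            start += len(sub)
        assert start == len(chroms)
        return out

    def placement_table(self) -> pd.DataFrame:
        """Marker physical placements as a (marker, chromosome, position) table."""
        return pd.DataFrame({
            "marker": self.markers["marker"],
            "chromosome": self.markers["chromosome"],
            "position": self.markers["bp"].astype(int),
        })

    # -- constructors -------------------------------------------------------

    @classmethod
    def regular(cls,
                n_chromosomes: int = 14,
                chrom_length_bp: int = 600_000_000,
                chrom_length_cm: float = 150.0,
                markers_per_chromosome: int = 860,
                name_prefix: str = "chr") -> "GenomeModel":
        """Evenly spaced markers on equal chromosomes.

        Defaults mirror a tetraploid wheat-like array: 14 chromosomes and
        ~12 000 markers genome-wide.
        """
        chroms = [Chromosome(f"{name_prefix}{i + 1}", chrom_length_bp, chrom_length_cm)
                  for i in range(n_chromosomes)]
        rows = []
        step = chrom_length_bp / (markers_per_chromosome + 1)
        for c in chroms:
            for j in range(markers_per_chromosome):
                rows.append((f"{c.name}_m{j + 1:04d}", c.name, int(round((j + 1) * step))))
        markers = pd.DataFrame(rows, columns=["marker", "chromosome", "bp"])
        return cls(chroms, markers)
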