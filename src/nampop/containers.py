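"""Core data containers: the genotype call matrix and the marker physical map.

Calls are stored as int8 codes: 0 = AA, 1 = AB, 2 = BB, -1 = missing.  The
code doubles as the dosage of the B allele, which is what every numeric
routine (MAF, LD, kinship, PCA) consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "PhysicalMap", "MISSING", "CALL_CODES"]

MISSING = -1
CALL_CODES = {"AA": 0, "AB": 1, "BB": 2}
_CODE_TO_CALL = {0: "AA", 1: "AB", 2: "BB", MISSING: "NA"}


@dataclass
class GenotypeMatrix:
    """Samples x markers call table with family labels.

    Attributes
    ----------
    calls:
        int8 array (n_samples, n_markers) of call codes.
    sample_ids, marker_ids:
        Unique identifiers along each axis.
    families:
        Family label per sample (non-empty strings).
    is_founder:
        Boolean flag per sample; founder rows are excluded from family
        polymorphism statistics and used only where founder calls are needed.
    """

    calls: np.ndarray
    sample_ids: np.ndarray
    marker_ids: np.ndarray
    families: np.ndarray
    is_founder: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.families = np.asarray(self.families, dtype=object)
        if self.is_founder is None:
            self.is_founder = np.zeros(len(self.sample_ids), dtype=bool)
        self.is_founder = np.asarray(self.is_founder, dtype=bool)
        n, m = self.calls.shape
        if len(self.sample_ids) != n or len(self.families) != n or len(self.is_founder) != n:
            raise ValueError("sample annotation length mismatch")
        if len(self.marker_ids) != m:
            raise ValueError("marker id length mismatch")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.marker_ids)) != m:
            raise ValueError("duplicate marker ids")
        if any(f == "" or f is None for f in self.families):
            raise ValueError("empty family labels")
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("calls must be coded 0/1/2/-1")

    # -- basic views --------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def dosage(self) -> np.ndarray:
        """Float B-allele dosage with NaN for missing calls."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        return d

    def ril_mask(self) -> np.ndarray:
        return ~self.is_founder

    def family_of(self) -> pd.Series:
        return pd.Series(self.families, index=self.sample_ids)

    # -- subsetting ---------------------------------------------------------

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(self.calls[index], self.sample_ids[index],
                              self.marker_ids, self.families[index],
                              self.is_founder[index])

    def take_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(self.calls[:, index], self.sample_ids,
                              self.marker_ids[index], self.families,
                              self.is_founder)

    def select_family(self, family: str, include_founders: bool = False) -> "GenotypeMatrix":
        keep = self.families == family
        if not include_founders:
            keep &= ~self.is_founder
        return self.take_samples(keep)

    def marker_index(self, ids) -> np.ndarray:
        lookup = {m: i for i, m in enumerate(self.marker_ids)}
        return np.array([lookup[m] for m in ids], dtype=int)

    # -- text round-trip ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        body = pd.DataFrame(
            np.vectorize(_CODE_TO_CALL.get)(self.calls),
            index=pd.Index(self.sample_ids, name="sample"),
            columns=self.marker_ids,
        )
        body.insert(0, "family", self.families)
        body.insert(1, "is_founder", self.is_founder.astype(int))
        return body

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        meta_cols = ["family", "is_founder"]
        markers = [c for c in df.columns if c not in meta_cols]
        raw = df[markers].to_numpy(dtype=object)
        codes = np.full(raw.shape, MISSING, dtype=np.int8)
        for call, code in CALL_CODES.items():
            codes[raw == call] = code
        return cls(codes, df.index.to_numpy(object), np.asarray(markers, object),
                   df["family"].to_numpy(object),
                   df["is_founder"].to_numpy() if "is_founder" in df else None)

    @classmethod
    def read_tsv(cls, path) -> "GenotypeMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col="sample",
                                          keep_default_na=False, na_values=[]))


class PhysicalMap:
    """Marker -> (chromosome, 1-based bp position) assignments.

    Thin wrapper around a DataFrame indexed by marker id, with columns
    ``chromosome``, ``position`` and optional provenance (``strand``,
    ``mapq``).
    """

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        if table.index.name != "marker":
            if "marker" not in table.columns:
                raise ValueError("placement table needs a 'marker' column")
            table = table.set_index("marker")
        for col in ("chromosome", "position"):
            if col not in table.columns:
                raise ValueError(f"placement table needs a '{col}' column")
        if table.index.duplicated().any():
            dups = sorted(set(table.index[table.index.duplicated()]))
            raise ValueError(f"duplicate marker ids in placement: {dups}")
        pos = pd.to_numeric(table["position"], errors="raise")
        if (pos < 1).any():
            raise ValueError("positions must be >= 1 (1-based)")
        table["position"] = pos.astype(int)
        if len(table) == 0:
            warnings.warn("empty physical map", stacklevel=2)
        self.table = table

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, marker) -> bool:
        return marker in self.table.index

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table.index.to_numpy(object)

    def chromosomes(self) -> list[str]:
        return list(pd.unique(self.table["chromosome"]))

    def subset(self, markers) -> "PhysicalMap":
        present = [m for m in markers if m in self.table.index]
        return PhysicalMap(self.table.loc[present])

    def positions(self, markers) -> pd.DataFrame:
        return self.table.loc[list(markers), ["chromosome", "position"]]

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "PhysicalMap":
        return cls(pd.read_csv(path, sep="\t"))
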