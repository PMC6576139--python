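"""Physical placement of array markers from alignments of their flanking
sequences.

The module consumes SAM records (read name = marker id, one read per marker)
and applies the standard placement filters: a marker is kept iff its primary
alignment is mapped with MAPQ >= 10 (strict: MAPQ 10 is kept), is not
secondary or supplementary, and shows no alternative-hit evidence (XA/SA tag,
or more than one non-secondary record for the same read name).  Positions are
1-based leftmost mapping coordinates, as in the SAM format.
"""

from __future__ import annotations

import warnings
from collections import defaultdict

import pandas as pd

from .containers import PhysicalMap

__all__ = ["place_from_sam", "merge_placement_table"]


def place_from_sam(sam_path, min_mapq: int = 10) -> tuple[PhysicalMap, pd.DataFrame]:
    """Derive a :class:`PhysicalMap` from a SAM/BAM file of marker flanking
    reads, returning the map and a rejection log (marker, reason)."""
    import pysam

    by_name: dict[str, list] = defaultdict(list)
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as f:
        for rec in f:
            by_name[rec.query_name].append(
                dict(
                    chromosome=rec.reference_name,
                    pos0=rec.reference_start,
                    mapq=rec.mapping_quality,
                    unmapped=rec.is_unmapped,
                    secondary=rec.is_secondary,
                    supplementary=rec.is_supplementary,
                    reverse=rec.is_reverse,
                    has_alt=rec.has_tag("XA") or rec.has_tag("SA"),
                )
            )

    placed, rejected = [], []
    for name in sorted(by_name):
        recs = by_name[name]
        primaries = [r for r in recs if not r["secondary"] and not r["supplementary"]]
        if len(primaries) == 0:
            rejected.append((name, "no_primary_alignment"))
            continue
        if len(primaries) > 1:
            rejected.append((name, "multiple_hits"))
            continue
        p = primaries[0]
        if p["unmapped"]:
            rejected.append((name, "unmapped"))
        elif p["mapq"] < min_mapq:
            rejected.append((name, "low_mapq"))
        elif len(recs) > 1 or p["has_alt"]:
            # secondary records present, or XA/SA alternative-hit tags
            rejected.append((name, "multiple_hits"))
        else:
            placed.append((name, p["chromosome"], p["pos0"] + 1,
                           "-" if p["reverse"] else "+", p["mapq"]))

    pmap = PhysicalMap(pd.DataFrame(placed, columns=["marker", "chromosome",
                                                     "position", "strand", "mapq"]))
    rej = pd.DataFrame(rejected, columns=["marker", "reason"])
    return pmap, rej


def merge_placement_table(path, sep: str = "\t") -> PhysicalMap:
    """Load a precomputed delimited placement table (marker, chromosome,
    position[, ...]) into a typed :class:`PhysicalMap`."""
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        warnings.warn(f"empty placement table: {path}", stacklevel=2)
        return PhysicalMap(pd.DataFrame(columns=["marker", "chromosome", "position"]))
    missing = {"marker", "chromosome", "position"} - set(df.columns)
    if missing:
        raise ValueError(f"placement table lacks columns: {sorted(missing)}")
    return PhysicalMap(df)
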