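"""Forward simulator of NAM RIL populations and alpha-lattice trials.

Generative model
----------------
A NAM population is a star of biparental crosses: one recurrent founder (RF)
crossed to each of several alternative founders.  Each F1 is advanced by
single-seed descent (SSD): one offspring per line per generation, obtained by
selfing, for ``generations_of_selfing`` generations (the default 5 turns the
F1 into F6 lines with expected residual heterozygosity (1/2)^5 per locus).
Meiosis follows the Haldane model: crossover counts per chromosome are
Poisson(genetic length / 100), breakpoints uniform on the genetic map, no
interference.  Optional viability selection rejects offspring of a targeted
genotype class with probability ``s`` each generation, producing localized
segregation distortion; drift and residual heterozygosity are emergent from
the literal one-seed bottleneck, not imposed.

Array-like measurement artifacts (missing calls, spurious heterozygotes,
ascertainment masking of farmer-variety-private markers) are injected as a
separate, logged step so every downstream filter can be tested against known
truth.

Field-trial phenotypes follow the row-column alpha-lattice model
``Y = mu + G + L + GxL + rep + col(rep) + row(rep) + e`` with independent
normal draws for every random term.

All randomness flows from a single master seed through named substreams, so a
fixed seed gives byte-identical output regardless of call order elsewhere.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix
from .genome import GenomeModel

__all__ = [
    "FounderPanel", "SelectionSpec", "SimConfig", "SimulationError",
    "simulate_founders", "meiosis", "simulate_family", "simulate_nam",
    "FamilySim", "inject_array_artifacts", "ArtifactLog",
    "write_synthetic_sam", "simulate_trial", "substream",
]


class SimulationError(RuntimeError):
    pass


def substream(seed: int, *keys) -> np.random.Generator:
    """Named, reproducible child stream of a master seed."""
    words = [int(seed) & 0xFFFFFFFF]
    for k in keys:
        if isinstance(k, (int, np.integer)):
            words.append(int(k) & 0xFFFFFFFF)
        else:
            words.append(zlib.crc32(str(k).encode()))
    return np.random.default_rng(np.random.SeedSequence(words))


# ---------------------------------------------------------------------------
# founders


@dataclass
class FounderPanel:
    """Fully homozygous founder lines over the genome's marker loci.

    ``haplotypes`` holds one haplotype per founder (uint8, allele 0 = A,
    1 = B); homozygosity makes a single haplotype sufficient.
    """

    founder_ids: list[str]
    haplotypes: np.ndarray  # (n_founders, n_markers) in {0, 1}
    rf_id: str

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.rf_id not in self.founder_ids:
            raise ValueError(f"recurrent founder {self.rf_id!r} not in panel")
        if self.haplotypes.shape[0] != len(self.founder_ids):
            raise ValueError("one haplotype row per founder required")
        if not np.isin(self.haplotypes, [0, 1]).all():
            raise ValueError("alleles must be coded 0/1")

    def haplotype(self, founder_id: str) -> np.ndarray:
        return self.haplotypes[self.founder_ids.index(founder_id)]

    @property
    def rf_haplotype(self) -> np.ndarray:
        return self.haplotype(self.rf_id)

    def alt_ids(self) -> list[str]:
        return [f for f in self.founder_ids if f != self.rf_id]

    def polymorphic_in_cross(self, alt_id: str) -> np.ndarray:
        return self.rf_haplotype != self.haplotype(alt_id)

    def fv_private_markers(self) -> np.ndarray:
        """Markers where the RF carries the panel-majority allele.

        These emulate variation contributed only by the exotic (farmer
        variety) side of the panel — the markers an internationally
        ascertained array is most likely to miss.
        """
        poly = self.haplotypes.min(axis=0) != self.haplotypes.max(axis=0)
        freq_b = self.haplotypes.mean(axis=0)
        rf = self.rf_haplotype
        rf_major = np.where(rf == 1, freq_b >= 0.5, freq_b <= 0.5)
        return poly & rf_major


def simulate_founders(genome: GenomeModel, n_founders: int, divergence,
                      seed: int = 0, rf_index: int = 0) -> FounderPanel:
    """Draw a homozygous founder panel.

    ``divergence`` is the per-marker probability that a non-RF founder
    carries the allele opposite to the RF's (scalar or length-n_markers
    array).  divergence 0 makes the panel monomorphic; divergence 1 makes
    every marker polymorphic in every cross.
    """
    if genome.n_markers == 0:
        raise ValueError("degenerate genome: no markers")
    if n_founders < 2:
        raise ValueError("need at least two founders")
    div = np.broadcast_to(np.asarray(divergence, dtype=float), (genome.n_markers,))
    if ((div < 0) | (div > 1)).any():
        raise ValueError("divergence must be in [0, 1]")
    rng = substream(seed, "founders")
    rf_hap = rng.integers(0, 2, size=genome.n_markers, dtype=np.uint8)
    haps = np.tile(rf_hap, (n_founders, 1))
    for i in range(n_founders):
        if i == rf_index:
            continue
        flip = rng.random(genome.n_markers) < div
        haps[i, flip] = 1 - haps[i, flip]
    ids = [f"founder{i:02d}" for i in range(n_founders)]
    ids[rf_index] = "RF"
    return FounderPanel(ids, haps, "RF")


# ---------------------------------------------------------------------------
# meiosis


def _batch_gametes(h0: np.ndarray, h1: np.ndarray, genome: GenomeModel,
                   rng: np.random.Generator) -> np.ndarray:
    """One gamete per row of the (n, M) haplotype pair arrays (Haldane model)."""
    n, m = h0.shape
    cm = genome.markers["cm"].to_numpy(float)
    gamete = np.empty((n, m), dtype=np.uint8)
    for name, sl in genome.chrom_slices().items():
        length_cm = next(c.length_cm for c in genome.chromosomes if c.name == name)
        loc_cm = cm[sl]
        start = rng.integers(0, 2, size=n)
        k = rng.poisson(length_cm / 100.0, size=n)
        phase = np.broadcast_to(start[:, None], (n, sl.stop - sl.start)).copy()
        for i in np.flatnonzero(k):
            bp = np.sort(rng.uniform(0.0, length_cm, size=k[i]))
            phase[i] = (start[i] + np.searchsorted(bp, loc_cm)) % 2
        block = np.where(phase == 0, h0[:, sl], h1[:, sl])
        gamete[:, sl] = block
    return gamete


def meiosis(parent_haplotype_pair, genome: GenomeModel, seed=0) -> np.ndarray:
    """Single gamete from a phased haplotype pair.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    h0, h1 = parent_haplotype_pair
    h0 = np.asarray(h0, dtype=np.uint8)
    h1 = np.asarray(h1, dtype=np.uint8)
    if h0.shape != (genome.n_markers,) or h1.shape != (genome.n_markers,):
        raise ValueError("haplotypes must match the genome's marker count")
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "meiosis")
    return _batch_gametes(h0[None, :], h1[None, :], genome, rng)[0]


# ---------------------------------------------------------------------------
# single-seed descent


@dataclass
class SelectionSpec:
    """Viability selection against one genotype class at one locus.

    ``mode`` names the targeted class relative to founder origin:
    ``against_alt_hom`` (homozygous for the alternative founder's allele),
    ``against_rf_hom``, or ``against_het``.  ``s`` in [0, 1] is the
    probability that a targeted offspring fails to survive (1 = lethal).
    """

    locus: tuple[str, int]
    s: float
    mode: str = "against_alt_hom"

    _MODES = ("against_alt_hom", "against_rf_hom", "against_het")

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 1.0:
            raise ValueError("selection coefficient s must be in [0, 1]")
        if self.mode not in self._MODES:
            raise ValueError(f"mode must be one of {self._MODES}")

    def marker_index(self, genome: GenomeModel) -> int:
        chrom, bp = self.locus
        sub = genome.markers[genome.markers["chromosome"] == chrom]
        if sub.empty:
            raise ValueError(f"no markers on chromosome {chrom}")
        pos = sub["bp"].to_numpy()
        return int(sub.index[np.argmin(np.abs(pos - bp))])


@dataclass
class SimConfig:
    """Scale and measurement parameters of a simulated NAM.

    Defaults emulate the study conditions the package targets: ~12 families
    of ~100 F6 RILs (5 selfing generations after the F1) genotyped on an
    array with mild missingness and heterozygote error and with a share of
    FV-private markers lost to ascertainment.
    """

    n_families: int = 12
    rils_per_family: int = 100
    generations_of_selfing: int = 5
    missing_rate: float = 0.01
    het_error_rate: float = 0.002
    ascertainment_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missing_rate", "het_error_rate", "ascertainment_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.generations_of_selfing < 1:
            raise ValueError("generations_of_selfing must be >= 1")


@dataclass
class FamilySim:
    """One simulated biparental RIL family with its ground truth."""

    family_id: str
    genotypes: GenotypeMatrix          # clean calls (no artifacts)
    truth: np.ndarray                  # (n_rils, n_markers) dosage of allele B
    rf_allele: np.ndarray              # RF allele per marker (0/1)
    alt_allele: np.ndarray
    lines_lost: int = 0


def _targeted(mode: str, a0: np.ndarray, a1: np.ndarray,
              rf: np.ndarray, idx: int) -> np.ndarray:
    """Boolean mask of individuals whose genotype at marker idx is targeted."""
    g0, g1 = a0[:, idx], a1[:, idx]
    rf_allele = rf[idx]
    n_rf = (g0 == rf_allele).astype(int) + (g1 == rf_allele).astype(int)
    if mode == "against_alt_hom":
        return n_rf == 0
    if mode == "against_rf_hom":
        return n_rf == 2
    return n_rf == 1


def simulate_family(founders: FounderPanel, alt_id: str, genome: GenomeModel,
                    sim: SimConfig, selection: list[SelectionSpec] = (),
                    family_id: str | None = None,
                    retry_cap: int = 100, line_retry_cap: int = 20) -> FamilySim:
    """Advance ``rils_per_family`` lines from RF x alt by single-seed descent.

    Viability selection is applied by rejection: a rejected offspring is
    replaced by a sibling seed (a fresh selfing draw) up to ``retry_cap``
    times, after which the line dies and is restarted from the F1 (up to
    ``line_retry_cap`` restarts, counted in ``lines_lost``).
    """
    family_id = family_id or alt_id
    rf_hap = founders.rf_haplotype
    alt_hap = founders.haplotype(alt_id)
    sel = [(spec, spec.marker_index(genome)) for spec in selection]
    rng = substream(sim.seed, "family", family_id)
    n = sim.rils_per_family

    # haplotype pair per active line; every line starts as the F1
    a0 = np.tile(rf_hap, (n, 1))
    a1 = np.tile(alt_hap, (n, 1))
    lines_lost = 0
    for restart in range(line_retry_cap + 1):
        dead = np.zeros(n, dtype=bool)
        for gen in range(sim.generations_of_selfing):
            pending = ~dead
            tries = 0
            new0 = np.empty_like(a0)
            new1 = np.empty_like(a1)
            while pending.any():
                idx = np.flatnonzero(pending)
                g0 = _batch_gametes(a0[idx], a1[idx], genome, rng)
                g1 = _batch_gametes(a0[idx], a1[idx], genome, rng)
                reject = np.zeros(len(idx), dtype=bool)
                for spec, mi in sel:
                    if spec.s == 0:
                        continue
                    hit = _targeted(spec.mode, g0, g1, rf_hap, mi)
                    reject |= hit & (rng.random(len(idx)) < spec.s)
                ok = idx[~reject]
                new0[ok] = g0[~reject]
                new1[ok] = g1[~reject]
                pending[ok] = False
                tries += 1
                if tries > retry_cap:
                    dead |= pending
                    break
            a0[~dead] = new0[~dead]
            a1[~dead] = new1[~dead]
        if not dead.any():
            break
        lines_lost += int(dead.sum())
        # restart dead lines from the F1
        a0[dead] = rf_hap
        a1[dead] = alt_hap
        if restart == line_retry_cap:
            locus = sel[0][0].locus if sel else None
            raise SimulationError(
                f"selection at {locus} too strong: lines keep dying in family {family_id}")

    truth = (a0 + a1).astype(np.int8)  # dosage of allele B
    sample_ids = np.array([f"{family_id}_r{i + 1:03d}" for i in range(n)], dtype=object)
    gm = GenotypeMatrix(truth, sample_ids, genome.marker_ids.copy(),
                        np.full(n, family_id, dtype=object))
    return FamilySim(family_id, gm, truth.copy(), rf_hap.copy(), alt_hap.copy(),
                     lines_lost=lines_lost)


def simulate_nam(founders: FounderPanel, genome: GenomeModel, sim: SimConfig,
                 selection: dict[str, list[SelectionSpec]] | None = None,
                 include_founders: bool = False,
                 ) -> tuple[GenotypeMatrix, dict[str, FamilySim]]:
    """Simulate families for the first ``n_families`` non-RF founders.

    Returns the stacked RIL genotype matrix (optionally with founder rows
    flagged) and the per-family simulations with ground truth.
    """
    alts = founders.alt_ids()[: sim.n_families]
    if len(alts) < sim.n_families:
        raise ValueError("founder panel too small for n_families")
    fams: dict[str, FamilySim] = {}
    blocks, ids, labels, flags = [], [], [], []
    for i, alt in enumerate(alts):
        fam_id = f"fam{i + 1:02d}"
        fs = simulate_family(founders, alt, genome, sim,
                             (selection or {}).get(fam_id, ()), family_id=fam_id)
        fams[fam_id] = fs
        blocks.append(fs.genotypes.calls)
        ids.extend(fs.genotypes.sample_ids)
        labels.extend(fs.genotypes.families)
        flags.extend([False] * fs.genotypes.n_samples)
        if include_founders:
            blocks.append((2 * founders.haplotype(alt)).astype(np.int8)[None, :])
            ids.append(f"{fam_id}_founder_{alt}")
            labels.append(fam_id)
            flags.append(True)
    if include_founders:
        blocks.append((2 * founders.rf_haplotype).astype(np.int8)[None, :])
        ids.append("RF")
        labels.append("RF")
        flags.append(True)
    gm = GenotypeMatrix(np.vstack(blocks), np.array(ids, object),
                        genome.marker_ids.copy(), np.array(labels, object),
                        np.array(flags))
    return gm, fams


# ---------------------------------------------------------------------------
# array artifacts


@dataclass
class ArtifactLog:
    n_set_missing: int
    n_het_errors: int
    masked_markers: list[str]
    missing_mask: np.ndarray
    het_error_mask: np.ndarray


def inject_array_artifacts(G: GenotypeMatrix, sim: SimConfig,
                           founders: FounderPanel | None = None,
                           fv_private: np.ndarray | None = None,
                           seed: int | None = None,
                           ) -> tuple[GenotypeMatrix, ArtifactLog]:
    """Overlay array measurement artifacts on clean simulated calls.

    Heterozygote errors flip true homozygotes to AB at ``het_error_rate``;
    calls go missing at ``missing_rate``; a fraction
    ``ascertainment_fraction`` of FV-private polymorphic markers (from
    ``founders`` or an explicit boolean ``fv_private`` mask over markers) is
    masked to the RF-homozygote call, emulating probes blind to exotic
    alleles.  All changes are logged.
    """
    rng = substream(sim.seed if seed is None else seed, "artifacts")
    calls = G.calls.copy()

    hom = (calls == 0) | (calls == 2)
    het_err = hom & (rng.random(calls.shape) < sim.het_error_rate)
    calls[het_err] = 1

    miss = rng.random(calls.shape) < sim.missing_rate
    calls[miss] = MISSING

    masked: list[str] = []
    if sim.ascertainment_fraction > 0:
        if fv_private is None:
            if founders is None:
                raise ValueError("ascertainment masking needs founders or fv_private mask")
            fv_private = founders.fv_private_markers()
        cand = np.flatnonzero(np.asarray(fv_private, bool))
        k = int(round(sim.ascertainment_fraction * len(cand)))
        if sim.ascertainment_fraction >= 1.0:
            k = len(cand)
        chosen = np.sort(rng.choice(cand, size=k, replace=False))
        if founders is not None:
            rf_call = (2 * founders.rf_haplotype).astype(np.int8)
        else:  # fall back to the modal homozygote in the data
            rf_call = np.where(np.nanmean(np.where(G.calls < 0, np.nan, G.calls), axis=0) >= 1,
                               2, 0).astype(np.int8)
        for j in chosen:
            calls[:, j] = rf_call[j]
        masked = [str(m) for m in G.marker_ids[chosen]]

    out = GenotypeMatrix(calls, G.sample_ids, G.marker_ids, G.families, G.is_founder)
    return out, ArtifactLog(int(miss.sum()), int(het_err.sum()), masked, miss, het_err)


# ---------------------------------------------------------------------------
# synthetic SAM records for the placement module


def write_synthetic_sam(genome: GenomeModel, path, *,
                        low_mapq: list[str] = (), secondary: list[str] = (),
                        alt_hits: list[str] = (), unmapped: list[str] = (),
                        read_length: int = 100, mapq: int = 60) -> None:
    """Write one alignment per marker at its true position, plus deliberately
    rejectable records for the named markers (known-truth fixture for the
    SAM placement filters)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c.name, "LN": int(c.length_bp) + read_length}
               for c in genome.chromosomes],
    }
    refs = {c.name: i for i, c in enumerate(genome.chromosomes)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for row in genome.markers.itertuples():
            a = pysam.AlignedSegment()
            a.query_name = row.marker
            a.query_sequence = "A" * read_length
            a.query_qualities = pysam.qualitystring_to_array("I" * read_length)
            a.cigarstring = f"{read_length}M"
            a.reference_id = refs[row.chromosome]
            a.reference_start = int(row.bp) - 1  # SAM text is 1-based; pysam takes 0-based
            a.mapping_quality = 5 if row.marker in low_mapq else mapq
            if row.marker in unmapped:
                a.is_unmapped = True
                a.reference_id = -1
                a.reference_start = -1
                a.mapping_quality = 0
            if row.marker in alt_hits:
                a.set_tag("XA", f"{genome.chromosomes[0].name},+1000,{read_length}M,1;")
            out.write(a)
            if row.marker in secondary:
                b = pysam.AlignedSegment()
                b.query_name = row.marker
                b.query_sequence = None
                b.cigarstring = f"{read_length}M"
                b.reference_id = refs[row.chromosome]
                b.reference_start = int(row.bp) + 500
                b.mapping_quality = 0
                b.is_secondary = True
                out.write(b)


# ---------------------------------------------------------------------------
# field trials


def simulate_trial(genotype_effects: pd.Series,
                   design: dict,
                   varcomps: dict,
                   seed: int = 0,
                   trait: str = "trait",
                   mu: float = 0.0,
                   location_effects: pd.Series | None = None) -> pd.DataFrame:
    """Draw plot records from the row-column alpha-lattice model.

    Parameters
    ----------
    genotype_effects:
        True genotypic value per genotype id (the G term).
    design:
        ``{"locations": int | list, "reps": int, "rows": int, "cols": int}``;
        rows x cols must cover the genotypes, and rows/columns are nested in
        replication (each location-rep has its own randomization and its own
        row/column effect draws).
    varcomps:
        Variances for the random terms: ``gl``, ``rep``, ``col``, ``row``,
        ``resid`` (missing keys default to 0).
    location_effects:
        Fixed location effects; default all zero.
    """
    for k, v in varcomps.items():
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"variance {k!r} must be finite and >= 0")
    rng = substream(seed, "trial", trait)
    genos = genotype_effects.index.to_numpy(object)
    n_g = len(genos)
    locs = design["locations"]
    if isinstance(locs, int):
        locs = [f"loc{i + 1}" for i in range(locs)]
    reps = design["reps"]
    n_rows, n_cols = design["rows"], design["cols"]
    if n_rows * n_cols < n_g:
        raise ValueError("rows x cols too small for the genotype set")

    v = {k: float(varcomps.get(k, 0.0)) for k in ("gl", "rep", "col", "row", "resid")}
    if location_effects is None:
        location_effects = pd.Series(0.0, index=locs)
    gl = {(g, l): rng.normal(0.0, np.sqrt(v["gl"])) if v["gl"] > 0 else 0.0
          for l in locs for g in genos}

    records = []
    for l in locs:
        for r in range(1, reps + 1):
            b = rng.normal(0.0, np.sqrt(v["rep"])) if v["rep"] > 0 else 0.0
            col_eff = rng.normal(0.0, np.sqrt(v["col"]), n_cols) if v["col"] > 0 else np.zeros(n_cols)
            row_eff = rng.normal(0.0, np.sqrt(v["row"]), n_rows) if v["row"] > 0 else np.zeros(n_rows)
            order = rng.permutation(n_g)
            for plot, gi in enumerate(order):
                rr, cc = divmod(plot, n_cols)
                eps = rng.normal(0.0, np.sqrt(v["resid"])) if v["resid"] > 0 else 0.0
                y = (mu + genotype_effects.iloc[gi] + location_effects[l]
                     + gl[(genos[gi], l)] + b + col_eff[cc] + row_eff[rr] + eps)
                records.append((genos[gi], l, r, rr + 1, cc + 1, trait, y))
    return pd.DataFrame(records, columns=["genotype", "location", "replication",
                                          "row", "column", "trait", "value"])
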