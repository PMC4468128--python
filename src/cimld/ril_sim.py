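"""Recombinant-inbred-line (RIL) genome simulation and trait architectures.

A RIL derived by repeated selfing of a biparental cross is essentially
homozygous, so its genotype at any locus is a binary indicator of parental
origin (coded 0/1 here).  Along a chromosome the parental origin follows a
two-state Markov chain whose switch probability between adjacent loci is the
map-expanded recombination fraction for selfed RILs,

    R = 2r / (1 + 2r),    r = (1 - exp(-2d/100)) / 2   (Haldane),

with ``d`` the map distance in centimorgans.  The first-order Markov
approximation along a dense locus grid is exact for any pair of loci on the
grid, which is what linkage-based QTL scans consume.

The module also builds quantitative-trait architectures: a small set of
major QTLs with fixed positions/effects plus a polygenic background of many
small-effect loci, and evaluates per-line genotypic values as the dot
product of the 0/1 genotype with the effect vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: integer code for a missing genotype
NA = -1

#: kind tags for loci on a scan grid
KIND_MARKER = "marker"
KIND_PSEUDO = "pseudo"
KIND_TRAIT = "trait"

_KIND_PRIORITY = {KIND_MARKER: 0, KIND_TRAIT: 1, KIND_PSEUDO: 2}

#: position-merge tolerance in cM
POSITION_TOL = 1e-9


def haldane_r(d):
    """Map distance (cM) -> recombination fraction, Haldane map function.

    Accepts scalars or arrays; vectorised.  r = (1 - exp(-2 d / 100)) / 2.
    """
    arr = np.asarray(d, dtype=float)
    if np.any(arr < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * arr / 100.0))
    return float(r) if arr.ndim == 0 else r


def ril_adjust(r):
    """Single-meiosis recombination fraction -> RIL-scale fraction.

    For selfed RILs the accumulated recombination between two loci is
    R = 2r / (1 + 2r); R(0) = 0 and R(0.5) = 0.5.
    """
    arr = np.asarray(r, dtype=float)
    if np.any((arr < 0) | (arr > 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5]")
    R = 2.0 * arr / (1.0 + 2.0 * arr)
    return float(R) if arr.ndim == 0 else R


@dataclass(frozen=True)
class Chromosome:
    """One linkage group: ordered markers with cM positions."""

    id: str
    marker_names: tuple
    positions: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "marker_names", tuple(self.marker_names))
        if len(self.marker_names) != len(pos):
            raise ValueError("marker_names and positions length mismatch")
        if len(pos) < 2:
            raise ValueError(f"chromosome {self.id!r} needs >= 2 markers")
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"chromosome {self.id!r} positions must be nondecreasing")
        if pos[0] < 0:
            raise ValueError("marker positions must be non-negative")

    @property
    def length(self) -> float:
        return float(self.positions[-1])


@dataclass(frozen=True)
class GeneticMap:
    """Ordered collection of chromosomes; marker names unique genome-wide."""

    chromosomes: tuple

    def __post_init__(self):
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        names = [n for c in self.chromosomes for n in c.marker_names]
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique genome-wide")
        ids = [c.id for c in self.chromosomes]
        if len(set(ids)) != len(ids):
            raise ValueError("chromosome ids must be unique")

    @property
    def chrom_ids(self) -> tuple:
        return tuple(c.id for c in self.chromosomes)

    def chromosome(self, cid) -> Chromosome:
        for c in self.chromosomes:
            if c.id == cid:
                return c
        raise KeyError(cid)

    @property
    def n_markers(self) -> int:
        return sum(len(c.marker_names) for c in self.chromosomes)


def uniform_map(
    n_chromosomes: int = 5,
    length: float = 150.0,
    markers_per_chromosome: int = 16,
    prefix: str = "C",
) -> GeneticMap:
    """Genome of equal-length chromosomes with evenly spaced markers.

    The default is five 150 cM chromosomes carrying 16 markers each
    (10 cM spacing, positions 0, 10, ..., 150).
    """
    chroms = []
    for i in range(n_chromosomes):
        cid = f"{prefix}{i + 1}"
        pos = np.linspace(0.0, length, markers_per_chromosome)
        names = tuple(f"{cid}M{j + 1:02d}" for j in range(markers_per_chromosome))
        chroms.append(Chromosome(cid, names, pos))
    return GeneticMap(tuple(chroms))


@dataclass(frozen=True)
class LocusGrid:
    """Merged, per-chromosome locus lists used for simulation and scanning.

    Each chromosome carries a sorted, deduplicated position vector and a
    parallel ``kinds`` vector tagging each locus ``marker``/``pseudo``/
    ``trait``.  Loci closer than 1e-9 cM are merged; a marker tag wins over
    a trait tag, which wins over a pseudo tag.
    """

    chrom_ids: tuple
    positions: tuple  # tuple of 1-d float arrays, one per chromosome
    kinds: tuple  # tuple of 1-d str arrays parallel to positions

    def __post_init__(self):
        object.__setattr__(self, "chrom_ids", tuple(self.chrom_ids))
        object.__setattr__(
            self, "positions", tuple(np.asarray(p, dtype=float) for p in self.positions)
        )
        object.__setattr__(self, "kinds", tuple(np.asarray(k) for k in self.kinds))
        for p in self.positions:
            if len(p) and np.any(np.diff(p) <= 0):
                raise ValueError("grid positions must be strictly increasing")

    @property
    def n_loci(self) -> int:
        return sum(len(p) for p in self.positions)

    @property
    def offsets(self) -> np.ndarray:
        """Column offset of each chromosome's first locus."""
        return np.concatenate([[0], np.cumsum([len(p) for p in self.positions])])

    def flat_chrom(self) -> np.ndarray:
        """Chromosome id of every grid column, flattened in grid order."""
        return np.concatenate(
            [np.repeat(cid, len(p)) for cid, p in zip(self.chrom_ids, self.positions)]
        )

    def flat_pos(self) -> np.ndarray:
        return np.concatenate(self.positions)

    def flat_kinds(self) -> np.ndarray:
        return np.concatenate(self.kinds)

    def column_of(self, chrom, pos: float, tol: float = 1e-6) -> int:
        """Global column index of the locus at ``pos`` on ``chrom``."""
        for i, cid in enumerate(self.chrom_ids):
            if cid == chrom:
                j = np.searchsorted(self.positions[i], pos)
                off = int(self.offsets[i])
                for cand in (j - 1, j):
                    if 0 <= cand < len(self.positions[i]) and abs(
                        self.positions[i][cand] - pos
                    ) <= tol:
                        return off + cand
                raise KeyError(f"no locus at {pos} cM on {chrom}")
        raise KeyError(chrom)


def build_grid(
    gmap: GeneticMap,
    step: float | None = None,
    extra: Sequence[tuple] = (),
) -> LocusGrid:
    """Merge map markers, optional pseudo-markers and extra (trait) loci.

    ``step`` adds pseudo-markers every ``step`` cM from 0 to the chromosome
    end; ``extra`` is an iterable of (chrom_id, position) pairs tagged as
    trait loci.  Every map marker is always present.
    """
    extra_by_chrom: dict = {}
    for cid, pos in extra:
        extra_by_chrom.setdefault(cid, []).append(float(pos))
    positions, kinds = [], []
    for chrom in gmap.chromosomes:
        entries = [(float(p), KIND_MARKER) for p in chrom.positions]
        if step is not None:
            if step <= 0:
                raise ValueError("step must be positive")
            grid = np.arange(0.0, chrom.length + POSITION_TOL, step)
            entries += [(float(p), KIND_PSEUDO) for p in grid]
        for p in extra_by_chrom.get(chrom.id, []):
            if not (0.0 <= p <= chrom.length + POSITION_TOL):
                raise ValueError(
                    f"trait locus at {p} cM outside chromosome {chrom.id}"
                )
            entries.append((p, KIND_TRAIT))
        entries.sort(key=lambda e: (e[0], _KIND_PRIORITY[e[1]]))
        keep_pos, keep_kind = [], []
        for p, kind in entries:
            if keep_pos and p - keep_pos[-1] <= POSITION_TOL:
                continue  # duplicate within tolerance; higher-priority tag kept
            keep_pos.append(p)
            keep_kind.append(kind)
        positions.append(np.array(keep_pos))
        kinds.append(np.array(keep_kind))
    return LocusGrid(gmap.chrom_ids, tuple(positions), tuple(kinds))


@dataclass
class RilGenotypes:
    """Lines x loci matrix of 0/1 parental-origin indicators.

    Missing genotypes (real data only) are coded -1; simulated data are
    complete.  Column order follows ``grid``.
    """

    matrix: np.ndarray
    grid: LocusGrid
    line_ids: tuple = ()

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise ValueError("genotype matrix must be 2-d")
        if self.matrix.shape[1] != self.grid.n_loci:
            raise ValueError("genotype columns do not match grid")
        bad = ~np.isin(self.matrix, (0, 1, NA))
        if bad.any():
            raise ValueError("genotype entries must be 0, 1 or NA(-1)")
        if not self.line_ids:
            self.line_ids = tuple(f"L{i + 1:03d}" for i in range(self.matrix.shape[0]))
        if len(self.line_ids) != self.matrix.shape[0]:
            raise ValueError("line_ids length mismatch")

    @property
    def n_lines(self) -> int:
        return self.matrix.shape[0]

    def marker_matrix(self) -> np.ndarray:
        """Genotypes restricted to map-marker columns, in grid order."""
        return self.matrix[:, self.grid.flat_kinds() == KIND_MARKER]


def simulate_ril_genotypes(grid: LocusGrid, n_lines: int, rng=None) -> RilGenotypes:
    """Simulate complete RIL genotypes on every grid locus.

    Each chromosome is an independent two-state Markov chain per line: the
    first locus is Bernoulli(1/2) and the switch probability between
    adjacent loci is ``ril_adjust(haldane_r(delta_d))``.
    """
    if n_lines < 2:
        raise ValueError("need at least 2 lines")
    if grid.n_loci == 0:
        raise ValueError("empty locus grid")
    rng = np.random.default_rng(rng)
    blocks = []
    for pos in grid.positions:
        L = len(pos)
        first = rng.random(n_lines) < 0.5
        if L > 1:
            R = ril_adjust(haldane_r(np.diff(pos)))
            switches = rng.random((n_lines, L - 1)) < R
            steps = np.concatenate([first[:, None], switches], axis=1)
            states = np.logical_xor.accumulate(steps, axis=1)
        else:
            states = first[:, None]
        blocks.append(states.astype(np.int8))
    return RilGenotypes(np.concatenate(blocks, axis=1), grid)


@dataclass(frozen=True)
class TraitLocus:
    """A trait-affecting locus; ``chrom`` is None for loci segregating
    independently of the mapped genome (unmapped background)."""

    chrom: str | None
    position: float
    effect: float

    @property
    def mapped(self) -> bool:
        return self.chrom is not None


@dataclass(frozen=True)
class TraitArchitecture:
    """Major QTLs plus a polygenic background, effects in trait units."""

    qtls: tuple
    polygenes: tuple

    @property
    def loci(self) -> tuple:
        return self.qtls + self.polygenes

    @property
    def mapped_loci(self) -> tuple:
        return tuple(l for l in self.loci if l.mapped)

    @property
    def unmapped_loci(self) -> tuple:
        return tuple(l for l in self.loci if not l.mapped)

    def positions(self) -> list:
        """(chrom, position) pairs of the mapped trait loci."""
        return [(q.chrom, q.position) for q in self.mapped_loci]


# The classic 10-QTL architecture used throughout the simulation study:
# three QTLs on each of the first three chromosomes, one on the fourth,
# none on the fifth (positions in cM, effects in trait units).
ZENG_QTLS = (
    ("C1", 16.0, 0.42),
    ("C1", 48.0, 0.75),
    ("C1", 108.0, 0.58),
    ("C2", 3.0, 1.02),
    ("C2", 43.0, -1.23),
    ("C2", 77.0, -1.26),
    ("C3", 33.0, -0.46),
    ("C3", 68.0, 1.61),
    ("C3", 129.0, 0.88),
    ("C4", 26.0, 0.74),
)


def zeng_architecture(
    rng=None,
    gmap: GeneticMap | None = None,
    n_polygenes: int = 100,
    polygene_effect_max: float = 0.1,
    polygene_placement: str = "background",
) -> TraitArchitecture:
    """Ten major QTLs (Zeng's layout) plus U(0, max)-effect polygenes.

    With ``polygene_placement="background"`` (default) the polygenes
    segregate independently of the mapped genome, as loci on the many
    unmapped chromosomes of a real genome would: they make the trait
    polygenic without imprinting a directional effect gradient on the
    mapped chromosomes (all polygene effects are positive, so placing 100
    of them on 5 mapped chromosomes would turn each chromosome into one
    large diffuse pseudo-QTL).  ``polygene_placement="genome"`` instead
    scatters them uniformly over the mapped chromosomes (length-weighted),
    for studying exactly that contamination.  All draws are seeded.
    """
    rng = np.random.default_rng(rng)
    if gmap is None:
        gmap = uniform_map()
    qtls = tuple(TraitLocus(c, p, e) for c, p, e in ZENG_QTLS)
    effects = rng.uniform(0.0, polygene_effect_max, size=n_polygenes)
    if polygene_placement == "background":
        poly = tuple(TraitLocus(None, float("nan"), float(e)) for e in effects)
    elif polygene_placement == "genome":
        lengths = np.array([c.length for c in gmap.chromosomes])
        chrom_idx = rng.choice(len(lengths), size=n_polygenes, p=lengths / lengths.sum())
        positions = rng.uniform(0.0, lengths[chrom_idx])
        poly = tuple(
            TraitLocus(gmap.chromosomes[ci].id, float(p), float(e))
            for ci, p, e in zip(chrom_idx, positions, effects)
        )
    else:
        raise ValueError("polygene_placement must be 'background' or 'genome'")
    return TraitArchitecture(qtls, poly)


def simulate_background_genotypes(arch: TraitArchitecture, n_lines: int, rng=None) -> np.ndarray:
    """Bernoulli(1/2) genotypes at the unmapped background loci.

    Background loci are mutually unlinked and unlinked to the mapped
    genome, so each is an independent coin per line.
    """
    rng = np.random.default_rng(rng)
    m = len(arch.unmapped_loci)
    return (rng.random((n_lines, m)) < 0.5).astype(np.int8)


def genotypic_values(
    geno: RilGenotypes, arch: TraitArchitecture, background: np.ndarray | None = None
) -> np.ndarray:
    """Per-line genetic value g_k = sum of effects carried at trait loci.

    Every mapped trait locus of ``arch`` must be present as a column of
    the genotype grid and fully observed; ``background`` supplies the
    genotypes of unmapped loci (lines x loci, same order as
    ``arch.unmapped_loci``).
    """
    mapped = arch.mapped_loci
    cols = [geno.grid.column_of(l.chrom, l.position) for l in mapped]
    effects = np.array([l.effect for l in mapped])
    sub = geno.matrix[:, cols]
    if np.any(sub == NA):
        raise ValueError("missing genotypes at trait loci")
    g = sub.astype(float) @ effects
    unmapped = arch.unmapped_loci
    if unmapped:
        if background is None:
            raise ValueError("background genotypes required for unmapped trait loci")
        background = np.asarray(background)
        if background.shape != (geno.n_lines, len(unmapped)):
            raise ValueError("background genotype shape mismatch")
        g = g + background.astype(float) @ np.array([l.effect for l in unmapped])
    return g
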