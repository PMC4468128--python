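"""Multiple imputation of pseudo-marker genotypes for RIL scans.

A genome scan tests positions between markers where the genotype is not
observed.  Instead of the classical normal-mixture likelihood, the scan
here consumes D complete imputations of every line's genotype along the
scan grid, drawn from the two-state hidden Markov chain of parental origin
conditional on all observed markers (forward filtering, backward sampling).
Each imputation is a complete 0/1 matrix, so any downstream model is an
ordinary regression; the D per-position LOD scores are averaged by the
scan.  With fully observed markers the draws reproduce the observed
genotypes at marker columns exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ril_sim import (
    NA,
    KIND_MARKER,
    GeneticMap,
    LocusGrid,
    RilGenotypes,
    build_grid,
    haldane_r,
    ril_adjust,
)


def conditional_probability(
    left: int, right: int, d_left: float, d_right: float
) -> float:
    """P(genotype = 1) at a locus given its two flanking marker genotypes.

    Distances are in cM on either side; ``left``/``right`` are 0, 1 or NA.
    A missing flank contributes no information (RIL prior 1/2 per state),
    so with both flanks missing the probability is 1/2.  With both flanks
    observed this is the classic two-interval formula, e.g.
    P(1|1,1) = (1-RL)(1-RR) / [(1-RL)(1-RR) + RL RR].
    """
    RL = ril_adjust(haldane_r(d_left))
    RR = ril_adjust(haldane_r(d_right))

    def flank(g, R, state):
        if g == NA or g is None:
            return 1.0
        if g not in (0, 1):
            raise ValueError("flanking genotype must be 0, 1 or NA")
        return 1.0 - R if g == state else R

    w1 = flank(left, RL, 1) * flank(right, RR, 1)
    w0 = flank(left, RL, 0) * flank(right, RR, 0)
    return w1 / (w1 + w0)


@dataclass
class ImputationDraws:
    """D complete genotype imputations on a scan grid.

    ``geno`` has shape (D, n_lines, n_grid_loci) with binary entries; at
    observed marker columns every draw equals the data.
    """

    geno: np.ndarray
    grid: LocusGrid

    def __post_init__(self):
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.geno.ndim != 3:
            raise ValueError("draws must be (D, lines, loci)")
        if self.geno.shape[2] != self.grid.n_loci:
            raise ValueError("draw columns do not match grid")

    @property
    def n_draws(self) -> int:
        return self.geno.shape[0]

    @property
    def n_lines(self) -> int:
        return self.geno.shape[1]

    def line_major(self) -> np.ndarray:
        """View reshaped to (n_lines, n_loci, D) for scan consumption."""
        return np.moveaxis(self.geno, 0, -1)

    def expected(self) -> np.ndarray:
        """Mean genotype across draws, (n_lines, n_loci)."""
        return self.geno.mean(axis=0)


def impute_draws(
    geno,
    gmap: GeneticMap,
    step: float = 2.0,
    n_draws: int = 16,
    rng=None,
) -> ImputationDraws:
    """Sample D complete chains on the marker + pseudo-marker grid.

    ``geno`` is a RilGenotypes (its marker columns are used) or a plain
    (lines x markers) matrix in map order; entries may be NA.  Sampling is
    exact forward-backward conditioning on all observed markers of the
    chromosome, so draws are independent given the data and marginally
    consistent with the analytic conditional probabilities.
    """
    if n_draws < 1:
        raise ValueError("need at least one draw")
    rng = np.random.default_rng(rng)
    if isinstance(geno, RilGenotypes):
        obs_markers = geno.marker_matrix()
    else:
        obs_markers = np.asarray(geno, dtype=np.int8)
    if obs_markers.shape[1] != gmap.n_markers:
        raise ValueError("marker matrix does not match map")
    grid = build_grid(gmap, step=step)
    n_lines = obs_markers.shape[0]
    out = np.empty((n_draws, n_lines, grid.n_loci), dtype=np.int8)
    mcol = 0
    for ci, chrom in enumerate(gmap.chromosomes):
        nm = len(chrom.positions)
        chrom_obs = obs_markers[:, mcol : mcol + nm]
        if np.all(chrom_obs == NA):
            raise ValueError(f"chromosome {chrom.id} has no observed markers")
        mcol += nm
        pos = grid.positions[ci]
        # observation vector along the grid: NA everywhere except markers
        obs = np.full((n_lines, len(pos)), NA, dtype=np.int8)
        gidx = np.searchsorted(pos, chrom.positions)
        obs[:, gidx] = chrom_obs
        draws = _sample_chain(obs, pos, n_draws, rng)
        off = int(grid.offsets[ci])
        out[:, :, off : off + len(pos)] = draws
    return ImputationDraws(out, grid)


def _sample_chain(obs: np.ndarray, pos: np.ndarray, n_draws: int, rng) -> np.ndarray:
    """Forward filter / backward sample the 2-state chain for all lines.

    obs: (n_lines, L) in {0,1,NA}; returns (n_draws, n_lines, L).
    """
    n_lines, L = obs.shape
    R = ril_adjust(haldane_r(np.diff(pos))) if L > 1 else np.empty(0)
    # forward filtered P(state | obs[..t]); shape (L, n_lines, 2)
    f = np.empty((L, n_lines, 2))
    cur = np.full((n_lines, 2), 0.5)
    for t in range(L):
        if t > 0:
            r = R[t - 1]
            prev = f[t - 1]
            cur = np.empty_like(prev)
            cur[:, 0] = prev[:, 0] * (1 - r) + prev[:, 1] * r
            cur[:, 1] = prev[:, 0] * r + prev[:, 1] * (1 - r)
        o = obs[:, t]
        e = np.ones((n_lines, 2))
        e[o == 0, 1] = 0.0
        e[o == 1, 0] = 0.0
        cur = cur * e
        norm = cur.sum(axis=1, keepdims=True)
        if np.any(norm == 0):
            raise ValueError("inconsistent observations in chain")
        f[t] = cur / norm
    # backward sampling, vectorised over lines x draws
    z = np.empty((n_draws, n_lines, L), dtype=np.int8)
    p1 = f[L - 1][:, 1]
    z[:, :, L - 1] = rng.random((n_draws, n_lines)) < p1
    for t in range(L - 2, -1, -1):
        r = R[t]
        nxt = z[:, :, t + 1].astype(float)
        f1 = f[t][:, 1]
        f0 = f[t][:, 0]
        # P(z_t=1 | z_{t+1}) prop. to f_t(1) * T(1 -> z_{t+1})
        w1 = f1 * np.where(nxt == 1, 1 - r, r)
        w0 = f0 * np.where(nxt == 1, r, 1 - r)
        p = w1 / (w1 + w0)
        z[:, :, t] = rng.random((n_draws, n_lines)) < p
    return z
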