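"""Composite interval mapping engines for lattice-design trials.

Three response strategies are implemented behind one scan core:

``rcbd``
    Standard CIM on per-line arithmetic means.  Block effects are ignored,
    which is equivalent to analysing the trial as a randomized complete
    block design.
``amld``
    Standard CIM on lattice-adjusted line means (GLS line estimates).
``cimld``
    CIM on the raw plot-level data.  The plot model contains replication
    effects and a random block-within-replication effect, giving residual
    covariance sigma^2 (I + delta ZZ').  Pre-multiplying response and every
    design column by the block-diagonal Sigma^(-1/2) (closed form, see
    ``sigma_inv_sqrt_block``) makes the errors spherical, after which the
    position-by-position QTL test is ordinary least squares.

At each grid position the alternative model adds the (imputed) test-locus
genotype to an intercept (+ replication dummies for the plot model) and the
background covariate markers, dropping covariates within ``window`` cM of
the test position from both null and alternative so the LOD contrast
isolates the tested locus:

    LOD = n/2 * log10(RSS_null / RSS_alt),

computed per imputation draw and averaged across draws.  Covariate markers
are chosen once per method by forward stepwise regression on that method's
own response representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np

from ._whiten import block_whiten, inv_sqrt_coeff, sigma_inv_sqrt_block  # noqa: F401
from .imputation import ImputationDraws
from .lattice import LatticeLayout, LineMeans, PhenotypeRecords, _check_complete
from .ril_sim import KIND_MARKER

METHODS = ("rcbd", "amld", "cimld")

_RSS_FLOOR = 1e-12


@dataclass
class WhitenedData:
    """Plot-level response and base design after Sigma^(-1/2) whitening.

    Rows are in canonical block order; ``plot_line`` maps each row to its
    line so line-level genotype columns can be expanded to plots.  The
    ``apply`` helper whitens further plot-level columns (genotypes) with
    the same transform.
    """

    y: np.ndarray
    X_base: np.ndarray  # whitened [intercept, replication dummies]
    plot_line: np.ndarray
    n_blocks: int
    k: int
    delta: float
    raw_y: np.ndarray | None = None  # unwhitened response, canonical order

    @property
    def n(self) -> int:
        return len(self.y)

    def apply(self, cols: np.ndarray) -> np.ndarray:
        """Whiten plot-level columns (rows in canonical block order)."""
        return block_whiten(cols, self.n_blocks, self.k, self.delta)

    def expand(self, line_cols: np.ndarray) -> np.ndarray:
        """Line-level columns -> plot-level columns (no whitening)."""
        return np.asarray(line_cols, dtype=float)[self.plot_line]

    def expand_whiten(self, line_cols: np.ndarray) -> np.ndarray:
        return self.apply(self.expand(line_cols))


def whiten(records: PhenotypeRecords, layout: LatticeLayout, delta: float) -> WhitenedData:
    """Whiten a complete lattice trial with the given block-variance ratio.

    ``delta`` normally comes from ``lattice_anova``; delta = 0 leaves the
    data untransformed.
    """
    if delta is None:
        raise ValueError("delta is required (estimate it with lattice_anova)")
    if delta < 0:
        raise ValueError("delta must be non-negative")
    _check_complete(records, layout)
    k = layout.k
    n_blocks = layout.n_blocks
    y = block_whiten(records.value, n_blocks, k, delta)
    X = np.ones((records.n, layout.r))
    for i in range(1, layout.r):
        X[:, i] = (records.rep == i).astype(float)
    Xw = block_whiten(X, n_blocks, k, delta)
    return WhitenedData(
        y=y, X_base=Xw, plot_line=records.line.copy(), n_blocks=n_blocks, k=k,
        delta=delta, raw_y=records.value.copy(),
    )


def lod(rss0, rss1, n: int):
    """LOD = n/2 * log10(rss0 / rss1), clamped at zero.

    ``rss1`` above ``rss0`` (possible only through numerical noise in a
    nested comparison) yields 0 rather than a negative score.
    """
    rss0 = np.asarray(rss0, dtype=float)
    rss1 = np.asarray(rss1, dtype=float)
    if np.any(rss0 <= 0) or np.any(rss1 <= 0):
        raise ValueError("residual sums of squares must be positive")
    out = np.maximum(0.5 * n * np.log10(rss0 / rss1), 0.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CovariateSet:
    """Background covariate markers selected for a scan."""

    grid_columns: tuple  # global grid column indices
    chrom: tuple
    pos: tuple

    def __len__(self):
        return len(self.grid_columns)


@dataclass
class ScanProfile:
    """Averaged-LOD genome scan profile for one method."""

    chrom: np.ndarray
    pos: np.ndarray
    lod: np.ndarray
    effect: np.ndarray
    method: str
    covariates: CovariateSet | None = None
    lod_g: np.ndarray | None = None
    lod_ge: np.ndarray | None = None
    lod_join: np.ndarray | None = None
    effect_ae: np.ndarray | None = None

    def max_lod(self) -> float:
        return float(self.lod.max())


def _forward_select(y: np.ndarray, X0: np.ndarray, C: np.ndarray, p: int) -> list:
    """Greedy stepwise selection of p columns of C minimizing RSS.

    Ties break to the lowest column index (genome order).  Columns that
    become numerically collinear with the current model score zero.
    """
    n, m = C.shape
    if p > m:
        raise ValueError("cannot select more covariates than markers")
    Q, _ = np.linalg.qr(X0)
    yr = y - Q @ (Q.T @ y)
    Cr = C - Q @ (Q.T @ C)
    chosen: list = []
    mask = np.zeros(m, dtype=bool)
    for _ in range(p):
        ss = np.einsum("ij,ij->j", Cr, Cr)
        good = (ss > 1e-10) & ~mask
        if not good.any():
            break
        score = np.where(good, (Cr.T @ yr) ** 2 / np.where(ss > 1e-10, ss, 1.0), -1.0)
        j = int(np.argmax(score))
        chosen.append(j)
        mask[j] = True
        q = Cr[:, j] / np.sqrt(ss[j])
        yr = yr - q * (q @ yr)
        Cr = Cr - np.outer(q, q @ Cr)
    return chosen


def select_covariates(
    response: np.ndarray,
    marker_geno: np.ndarray,
    p: int,
    *,
    X_base: np.ndarray | None = None,
    chrom=None,
    pos=None,
    grid_columns=None,
    seed=None,
) -> CovariateSet:
    """Forward stepwise selection of ``p`` covariate markers.

    ``response`` and ``marker_geno`` must live on the same level (line
    means with line genotypes, or whitened plots with whitened expanded
    genotypes).  ``X_base`` defaults to an intercept.  The procedure is
    deterministic; ``seed`` is accepted for interface uniformity.
    """
    if p < 0:
        raise ValueError("p must be non-negative")
    y = np.asarray(response, dtype=float)
    C = np.asarray(marker_geno, dtype=float)
    if X_base is None:
        X_base = np.ones((len(y), 1))
    idx = _forward_select(y, X_base, C, p) if p else []
    m = C.shape[1]
    chrom = np.asarray(chrom) if chrom is not None else np.array([""] * m)
    pos = np.asarray(pos, dtype=float) if pos is not None else np.full(m, np.nan)
    cols = np.asarray(grid_columns) if grid_columns is not None else np.arange(m)
    return CovariateSet(
        grid_columns=tuple(int(cols[j]) for j in idx),
        chrom=tuple(chrom[j] for j in idx),
        pos=tuple(float(pos[j]) for j in idx),
    )


def _scan_core(y, X_base, cov_cols, cov_chrom, cov_pos, G, chrom, pos, window, n_lod):
    """Shared per-position single-column regression scan.

    G is (rows, positions, draws).  Positions are grouped by their set of
    window-excluded covariates so each null model is factorized only once.
    """
    n_rows, P, D = G.shape
    n_cov = len(cov_pos)
    excl = np.zeros((P, n_cov), dtype=bool)
    for c in range(n_cov):
        excl[:, c] = (chrom == cov_chrom[c]) & (np.abs(pos - cov_pos[c]) < window)
    lod_out = np.empty(P)
    eff_out = np.empty(P)
    groups: dict = {}
    for j in range(P):
        groups.setdefault(excl[j].tobytes(), []).append(j)
    for key, idx in groups.items():
        keep = ~np.frombuffer(key, dtype=bool)
        X0 = np.concatenate([X_base, cov_cols[:, keep]], axis=1) if n_cov else X_base
        Q, _ = np.linalg.qr(X0)
        yr = y - Q @ (Q.T @ y)
        rss0 = float(yr @ yr)
        T = G[:, idx, :].reshape(n_rows, -1)
        Tr = T - Q @ (Q.T @ T)
        ss = np.einsum("ij,ij->j", Tr, Tr)
        xy = Tr.T @ yr
        good = ss > 1e-10
        red = np.where(good, xy**2 / np.where(good, ss, 1.0), 0.0)
        rss1 = np.maximum(rss0 - red, rss0 * _RSS_FLOOR)
        lods = (0.5 * n_lod * np.log10(rss0 / rss1)).reshape(len(idx), D)
        betas = np.where(good, xy / np.where(good, ss, 1.0), 0.0).reshape(len(idx), D)
        lod_out[idx] = lods.mean(axis=1)
        eff_out[idx] = betas.mean(axis=1)
    return np.maximum(lod_out, 0.0), eff_out


def _marker_info(draws: ImputationDraws):
    kinds = draws.grid.flat_kinds()
    mcols = np.where(kinds == KIND_MARKER)[0]
    chrom = draws.grid.flat_chrom()
    pos = draws.grid.flat_pos()
    return mcols, chrom, pos


def run_method_scan(
    method: str,
    *,
    draws: ImputationDraws,
    p: int = 3,
    window: float = 10.0,
    means: LineMeans | None = None,
    whitened: WhitenedData | None = None,
    covariates: CovariateSet | None = None,
    perm: np.ndarray | None = None,
    cache: dict | None = None,
) -> ScanProfile:
    """Covariate selection plus genome scan for one response strategy.

    ``perm`` permutes the genotype-row-to-line assignment (used by the
    permutation test); phenotypes and field structure stay fixed.  Passing
    ``covariates`` skips the selection step.  ``cache`` (a plain dict) can
    be shared across calls with identical draws/whitening to reuse the
    expanded genotype design, e.g. across phenotype permutations.
    """
    method = method.lower()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    mcols, chrom, pos = _marker_info(draws)
    cacheable = perm is None and cache is not None
    if cacheable and "G" in cache:
        G, C_all = cache["G"], cache["C"]
        if method in ("rcbd", "amld"):
            y = means.values
            X_base = np.ones((len(y), 1))
            n_lod = len(y)
        else:
            y = whitened.y
            X_base = whitened.X_base
            n_lod = whitened.n
    else:
        GL = draws.line_major().astype(float)  # (t, P, D)
        if perm is not None:
            GL = GL[np.asarray(perm)]
        M_line = GL[:, mcols, :].mean(axis=2)  # expected genotype at markers

        if method in ("rcbd", "amld"):
            if means is None:
                raise ValueError(f"{method} requires line means")
            y = means.values
            X_base = np.ones((len(y), 1))
            C_all = M_line
            G = GL
            n_lod = len(y)
        else:
            if whitened is None:
                raise ValueError("cimld requires whitened plot data")
            y = whitened.y
            X_base = whitened.X_base
            C_all = whitened.expand_whiten(M_line)
            n = whitened.n
            t, P, D = GL.shape
            G = whitened.expand_whiten(GL.reshape(t, P * D)).reshape(n, P, D)
            n_lod = n
        if cacheable:
            cache["G"], cache["C"] = G, C_all

    if covariates is None:
        covariates = select_covariates(
            y,
            C_all,
            p,
            X_base=X_base,
            chrom=chrom[mcols],
            pos=pos[mcols],
            grid_columns=mcols,
        )
    sel = [int(np.where(mcols == c)[0][0]) for c in covariates.grid_columns]
    cov_cols = C_all[:, sel]
    lods, effs = _scan_core(
        y,
        X_base,
        cov_cols,
        np.asarray(covariates.chrom),
        np.asarray(covariates.pos, dtype=float),
        G,
        chrom,
        pos,
        window,
        n_lod,
    )
    return ScanProfile(
        chrom=chrom, pos=pos, lod=lods, effect=effs, method=method, covariates=covariates
    )


def cim_scan(
    method: str,
    *,
    draws: ImputationDraws,
    covariates: CovariateSet | None = None,
    window: float = 10.0,
    p: int = 3,
    means: LineMeans | None = None,
    whitened: WhitenedData | None = None,
) -> ScanProfile:
    """Genome scan with a pre-selected (or freshly selected) covariate set.

    Thin alias of ``run_method_scan`` mirroring the method contracts:
    ``rcbd`` scans arithmetic line means, ``amld`` adjusted line means and
    ``cimld`` the whitened plot-level data.
    """
    return run_method_scan(
        method,
        draws=draws,
        p=p,
        window=window,
        means=means,
        whitened=whitened,
        covariates=covariates,
    )


def covariates_at(draws: ImputationDraws, peaks) -> CovariateSet:
    """Covariate set at the markers nearest a list of (chrom, pos) peaks.

    Used by the two-pass refinement: after a first scan, the called peaks
    themselves become the background covariates of a second scan, which
    re-localizes each peak conditional on all the others.
    """
    kinds = draws.grid.flat_kinds()
    chrom = draws.grid.flat_chrom()
    pos = draws.grid.flat_pos()
    mcols = np.where(kinds == KIND_MARKER)[0]
    cols: list = []
    for cc, cp in peaks:
        cand = mcols[chrom[mcols] == cc]
        if len(cand) == 0:
            continue
        j = int(cand[np.argmin(np.abs(pos[cand] - cp))])
        if j not in cols:
            cols.append(j)
    return CovariateSet(
        grid_columns=tuple(cols),
        chrom=tuple(str(c) for c in chrom[cols]),
        pos=tuple(float(p) for p in pos[cols]),
    )


@dataclass
class MultiEnvData:
    """Whitened stacked plot data over s >= 2 environments.

    ``X_base`` holds intercept, environment dummies and replication-within-
    environment dummies, all whitened per environment-block with that
    environment's delta.
    """

    y: np.ndarray
    X_base: np.ndarray
    plot_line: np.ndarray
    env_idx: np.ndarray
    block_sizes: tuple  # (n_blocks, k, delta) per environment, row-ordered
    n_envs: int

    @property
    def n(self) -> int:
        return len(self.y)

    def apply(self, cols: np.ndarray) -> np.ndarray:
        out = np.asarray(cols, dtype=float).copy()
        flat = out.ndim == 1
        if flat:
            out = out[:, None]
        row = 0
        for n_blocks, k, delta in self.block_sizes:
            n_env = n_blocks * k
            out[row : row + n_env] = block_whiten(out[row : row + n_env], n_blocks, k, delta)
            row += n_env
        return out[:, 0] if flat else out

    def expand(self, line_cols: np.ndarray) -> np.ndarray:
        return np.asarray(line_cols, dtype=float)[self.plot_line]

    def expand_whiten(self, line_cols: np.ndarray) -> np.ndarray:
        return self.apply(self.expand(line_cols))


def whiten_multi(records_by_env: dict, layouts: dict, deltas: dict) -> MultiEnvData:
    """Stack and whiten per-environment lattice trials for a joint scan."""
    envs = sorted(records_by_env)
    if len(envs) < 2:
        raise ValueError("need >= 2 environments; use cim_scan for one")
    ys, lines, env_idx, sizes, bases = [], [], [], [], []
    for e_i, env in enumerate(envs):
        rec, lay = records_by_env[env], layouts[env]
        _check_complete(rec, lay)
        delta = deltas[env]
        ys.append(rec.value)
        lines.append(rec.line)
        env_idx.append(np.full(rec.n, e_i))
        sizes.append((lay.n_blocks, lay.k, float(delta)))
        X = np.ones((rec.n, 1 + (len(envs) - 1) + (lay.r - 1)))
        for j in range(1, len(envs)):
            X[:, j] = 1.0 if e_i == j else 0.0
        for i in range(1, lay.r):
            X[:, len(envs) + i - 1] = (rec.rep == i).astype(float)
        bases.append(X)
    me = MultiEnvData(
        y=np.concatenate(ys),
        X_base=np.concatenate(bases, axis=0),
        plot_line=np.concatenate(lines),
        env_idx=np.concatenate(env_idx),
        block_sizes=tuple(sizes),
        n_envs=len(envs),
    )
    me.y = me.apply(me.y)
    me.X_base = me.apply(me.X_base)
    return me


def multi_env_scan(
    me: MultiEnvData,
    *,
    draws: ImputationDraws,
    p: int = 3,
    window: float = 10.0,
    covariates: CovariateSet | None = None,
    perm: np.ndarray | None = None,
) -> ScanProfile:
    """Joint QTL / QTL-by-environment scan over whitened environments.

    Per position the full model adds the test-locus genotype (additive
    effect a) and its interaction with the environment dummies (effect ae).
    Three LODs are reported against the full model: ``lod_join`` drops
    both, ``lod_g`` drops the additive term only and ``lod_ge`` drops the
    interaction only; nested RSS ordering guarantees
    lod_join >= max(lod_g, lod_ge) - numerical noise.
    """
    mcols, chrom, pos = _marker_info(draws)
    GL = draws.line_major().astype(float)
    if perm is not None:
        GL = GL[np.asarray(perm)]
    t, P, D = GL.shape
    M_line = GL[:, mcols, :].mean(axis=2)
    C_all = me.expand_whiten(M_line)
    if covariates is None:
        covariates = select_covariates(
            me.y, C_all, p, X_base=me.X_base,
            chrom=chrom[mcols], pos=pos[mcols], grid_columns=mcols,
        )
    sel = [int(np.where(mcols == c)[0][0]) for c in covariates.grid_columns]
    cov_cols = C_all[:, sel]
    n = me.n
    # raw expanded genotype, interaction built before whitening
    Graw = np.asarray(GL.reshape(t, P * D))[me.plot_line]
    env_dummy = (me.env_idx >= 1).astype(float)  # s=2 interaction contrast
    if me.n_envs != 2:
        raise NotImplementedError("interaction scan implemented for 2 environments")
    U = me.apply(Graw)
    W = me.apply(Graw * env_dummy[:, None])
    n_cov = len(covariates)
    excl = np.zeros((P, n_cov), dtype=bool)
    cchr = np.asarray(covariates.chrom)
    cpos = np.asarray(covariates.pos, dtype=float)
    for c in range(n_cov):
        excl[:, c] = (chrom == cchr[c]) & (np.abs(pos - cpos[c]) < window)
    groups: dict = {}
    for j in range(P):
        groups.setdefault(excl[j].tobytes(), []).append(j)
    lod_join = np.empty(P)
    lod_g = np.empty(P)
    lod_ge = np.empty(P)
    eff_a = np.empty(P)
    eff_ae = np.empty(P)
    for key, idx in groups.items():
        keep = ~np.frombuffer(key, dtype=bool)
        X0 = np.concatenate([me.X_base, cov_cols[:, keep]], axis=1) if n_cov else me.X_base
        Q, _ = np.linalg.qr(X0)
        yr = me.y - Q @ (Q.T @ me.y)
        rss0 = float(yr @ yr)
        cols = np.array(idx)[:, None] * D + np.arange(D)[None, :]
        cols = cols.ravel()
        Ur = U[:, cols] - Q @ (Q.T @ U[:, cols])
        Wr = W[:, cols] - Q @ (Q.T @ W[:, cols])
        a = np.einsum("ij,ij->j", Ur, Ur)
        b = np.einsum("ij,ij->j", Ur, Wr)
        c2 = np.einsum("ij,ij->j", Wr, Wr)
        gu = Ur.T @ yr
        gw = Wr.T @ yr
        det = a * c2 - b * b
        ok = det > 1e-10
        red_both = np.where(
            ok, (c2 * gu**2 - 2 * b * gu * gw + a * gw**2) / np.where(ok, det, 1.0), 0.0
        )
        red_u = np.where(a > 1e-10, gu**2 / np.where(a > 1e-10, a, 1.0), 0.0)
        red_w = np.where(c2 > 1e-10, gw**2 / np.where(c2 > 1e-10, c2, 1.0), 0.0)
        red_both = np.maximum(red_both, np.maximum(red_u, red_w))
        rss_full = np.maximum(rss0 - red_both, rss0 * _RSS_FLOOR)
        rss_nq = np.maximum(rss0 - red_w, rss0 * _RSS_FLOOR)  # drops additive term
        rss_nqe = np.maximum(rss0 - red_u, rss0 * _RSS_FLOOR)  # drops interaction
        lj = 0.5 * n * np.log10(rss0 / rss_full)
        lg = 0.5 * n * np.log10(rss_nq / rss_full)
        lge = 0.5 * n * np.log10(rss_nqe / rss_full)
        beta_a = np.where(ok, (c2 * gu - b * gw) / np.where(ok, det, 1.0), 0.0)
        beta_ae = np.where(ok, (a * gw - b * gu) / np.where(ok, det, 1.0), 0.0)
        sh = (len(idx), D)
        lod_join[idx] = np.maximum(lj.reshape(sh).mean(axis=1), 0.0)
        lod_g[idx] = np.maximum(lg.reshape(sh).mean(axis=1), 0.0)
        lod_ge[idx] = np.maximum(lge.reshape(sh).mean(axis=1), 0.0)
        eff_a[idx] = beta_a.reshape(sh).mean(axis=1)
        eff_ae[idx] = beta_ae.reshape(sh).mean(axis=1)
    return ScanProfile(
        chrom=chrom,
        pos=pos,
        lod=lod_join,
        effect=eff_a,
        method="cimld-multienv",
        covariates=covariates,
        lod_g=lod_g,
        lod_ge=lod_ge,
        lod_join=lod_join,
        effect_ae=eff_ae,
    )
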