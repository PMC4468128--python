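"""Simple-lattice field designs: layout, phenotype simulation, ANOVA, means.

A simple lattice accommodates t = k^2 lines in incomplete blocks of size k
with two replications whose blockings are mutually orthogonal (rows versus
columns of a k x k square), so any two lines meet in a block at most once.
The observational model for plot (replication i, block j, line k) is

    y_ijk = mu + alpha_i + gamma_j(i) + g_k + eps_ijk,

with fixed replication and line effects, random block-within-replication
effects gamma ~ N(0, sigma_b^2) and residuals eps ~ N(0, sigma^2).  The
ratio delta = sigma_b^2 / sigma^2 measures how much field heterogeneity the
incomplete blocks absorb; it is estimated here by equating the
treatment-adjusted block mean square to its expectation (method of
moments), and drives both the lattice-adjusted line means and the
whitening used by the plot-level QTL scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._whiten import block_whiten


@dataclass(frozen=True)
class LatticeLayout:
    """Plot -> (replication, block-within-replication, line) assignment."""

    k: int
    r: int
    plots: np.ndarray  # (n, 3) int columns: rep, block, line

    def __post_init__(self):
        object.__setattr__(self, "plots", np.asarray(self.plots, dtype=int))
        if self.plots.ndim != 2 or self.plots.shape[1] != 3:
            raise ValueError("plots must be an (n, 3) array")
        t = self.k * self.k
        rep, block, line = self.plots.T
        if self.plots.shape[0] != t * self.r:
            raise ValueError("plot count must be k^2 * r")
        for i in range(self.r):
            lines_i = np.sort(line[rep == i])
            if not np.array_equal(lines_i, np.arange(t)):
                raise ValueError(f"replication {i}: every line must appear exactly once")
            for j in range(self.k):
                if np.sum((rep == i) & (block == j)) != self.k:
                    raise ValueError(f"block ({i},{j}) must contain exactly k plots")

    @property
    def n_lines(self) -> int:
        return self.k * self.k

    @property
    def n_plots(self) -> int:
        return self.plots.shape[0]

    @property
    def n_blocks(self) -> int:
        return self.r * self.k


def concurrence_matrix(layout: LatticeLayout) -> np.ndarray:
    """Number of blocks in which each pair of lines co-occurs."""
    t = layout.n_lines
    conc = np.zeros((t, t), dtype=int)
    rep, block, line = layout.plots.T
    for i in range(layout.r):
        for j in range(layout.k):
            members = line[(rep == i) & (block == j)]
            conc[np.ix_(members, members)] += 1
    np.fill_diagonal(conc, 0)
    return conc


def make_simple_lattice(k: int, rng=None, randomize: bool = True) -> LatticeLayout:
    """Simple lattice for t = k^2 lines, r = 2 replications.

    Lines are arranged (optionally at random) in a k x k square; the blocks
    of replication 1 are its rows and those of replication 2 its columns,
    which guarantees the simple-lattice concurrence property.  Block order
    within each replication is randomised too when ``randomize`` is set.
    """
    if k < 2:
        raise ValueError("block size k must be >= 2")
    rng = np.random.default_rng(rng)
    t = k * k
    square = rng.permutation(t).reshape(k, k) if randomize else np.arange(t).reshape(k, k)
    row_order = rng.permutation(k) if randomize else np.arange(k)
    col_order = rng.permutation(k) if randomize else np.arange(k)
    plots = []
    for j, row in enumerate(row_order):
        for line in square[row, :]:
            plots.append((0, j, int(line)))
    for j, col in enumerate(col_order):
        for line in square[:, col]:
            plots.append((1, j, int(line)))
    return LatticeLayout(k, 2, np.array(plots))


@dataclass
class PhenotypeRecords:
    """Plot-level observations with their design labels.

    Rows are kept in canonical order (env, rep, block); ``env`` is None for
    single-environment trials.
    """

    rep: np.ndarray
    block: np.ndarray
    line: np.ndarray
    value: np.ndarray
    env: np.ndarray | None = None

    def __post_init__(self):
        self.rep = np.asarray(self.rep, dtype=int)
        self.block = np.asarray(self.block, dtype=int)
        self.line = np.asarray(self.line, dtype=int)
        self.value = np.asarray(self.value, dtype=float)
        n = len(self.value)
        if not (len(self.rep) == len(self.block) == len(self.line) == n):
            raise ValueError("column length mismatch")
        if self.env is not None:
            self.env = np.asarray(self.env)
            if len(self.env) != n:
                raise ValueError("env column length mismatch")
        self._sort_canonical()

    def _sort_canonical(self):
        if self.env is None:
            order = np.lexsort((self.block, self.rep))
        else:
            order = np.lexsort((self.block, self.rep, self.env))
        for name in ("rep", "block", "line", "value"):
            setattr(self, name, getattr(self, name)[order])
        if self.env is not None:
            self.env = self.env[order]

    @property
    def n(self) -> int:
        return len(self.value)

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        if self.env is not None:
            cols["env"] = self.env
        cols.update(rep=self.rep, block=self.block, line=self.line, value=self.value)
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PhenotypeRecords":
        env = frame["env"].to_numpy() if "env" in frame.columns else None
        return cls(
            rep=frame["rep"].to_numpy(),
            block=frame["block"].to_numpy(),
            line=frame["line"].to_numpy(),
            value=frame["value"].to_numpy(),
            env=env,
        )


def simulate_phenotypes(
    g: np.ndarray,
    layout: LatticeLayout,
    h2: float,
    delta: float,
    rep_effect: float = 2.0,
    rng=None,
) -> PhenotypeRecords:
    """Plot phenotypes y = alpha_i + gamma_j(i) + g_k + eps on a lattice.

    The residual variance is calibrated from the realized sample variance
    of the genetic values, sigma^2 = Var(g) * (1/h2 - 1), so ``h2`` is the
    plot-level heritability; block effects have variance sigma^2 * delta.
    Replication effects are 0, rep_effect, 2*rep_effect, ...
    """
    g = np.asarray(g, dtype=float)
    if len(g) != layout.n_lines:
        raise ValueError("genetic values do not match layout lines")
    if not (0.0 < h2 <= 1.0):
        raise ValueError("h2 must lie in (0, 1]")
    if delta < 0:
        raise ValueError("delta must be non-negative")
    rng = np.random.default_rng(rng)
    sigma2 = float(np.var(g, ddof=1)) * (1.0 / h2 - 1.0)
    rep, block, line = layout.plots.T
    alpha = rep_effect * rep
    gamma = rng.normal(0.0, np.sqrt(sigma2 * delta), size=layout.n_blocks)
    eps = rng.normal(0.0, np.sqrt(sigma2), size=layout.n_plots)
    y = alpha + gamma[rep * layout.k + block] + g[line] + eps
    return PhenotypeRecords(rep=rep, block=block, line=line, value=y)


@dataclass
class VarianceComponents:
    """ANOVA estimates: residual sigma^2, block sigma_b^2, their ratio."""

    sigma2: float
    sigma_b2: float
    delta: float
    anova_table: pd.DataFrame


def _design_matrices(records: PhenotypeRecords, layout: LatticeLayout):
    t, r, k = layout.n_lines, layout.r, layout.k
    n = records.n
    rep, block, line = records.rep, records.block, records.line
    X = np.zeros((n, 1 + (r - 1) + (t - 1)))
    X[:, 0] = 1.0
    for i in range(1, r):
        X[rep == i, i] = 1.0
    for l in range(1, t):
        X[line == l, r - 1 + l] = 1.0
    Z = np.zeros((n, r * k))
    Z[np.arange(n), rep * k + block] = 1.0
    return X, Z


def lattice_anova(records: PhenotypeRecords, layout: LatticeLayout) -> VarianceComponents:
    """Intra-block ANOVA of a complete lattice trial.

    Fits fixed replications and lines with blocks-within-replications; the
    residual mean square estimates sigma^2, and sigma_b^2 comes from
    equating the treatment-adjusted block mean square to its expectation
    sigma^2 + c * sigma_b^2 with c = tr(Z'(P_full - P_X)Z), truncating
    negative moment estimates at zero.
    """
    if records.env is not None and len(np.unique(records.env)) > 1:
        raise ValueError("lattice_anova handles a single environment; split by env first")
    _check_complete(records, layout)
    y = records.value
    n = records.n
    X, Z = _design_matrices(records, layout)
    Qx, _ = np.linalg.qr(X)
    rss_x = float(y @ y - (Qx.T @ y) @ (Qx.T @ y))
    XZ = np.concatenate([X, Z], axis=1)
    beta, _, rank, _ = np.linalg.lstsq(XZ, y, rcond=None)
    resid = y - XZ @ beta
    rss_full = float(resid @ resid)
    df_resid = n - rank
    df_block = rank - X.shape[1]
    if df_resid <= 0 or df_block <= 0:
        raise ValueError(
            "degenerate lattice design: no residual or block degrees of freedom "
            f"(rank={rank}, n={n})"
        )
    QxZ = Qx.T @ Z
    c = float(n - np.sum(QxZ * QxZ))
    if c <= 1e-8:
        raise ValueError("blocks are confounded with replications/lines")
    sigma2 = rss_full / df_resid
    ss_block_adj = max(rss_x - rss_full, 0.0)
    sigma_b2 = max((ss_block_adj - df_block * sigma2) / c, 0.0)

    # classical table: replications, lines (unadjusted), blocks within
    # replications (adjusted for lines), intra-block error
    ones = np.ones((n, 1)) / np.sqrt(n)
    Qr, _ = np.linalg.qr(np.concatenate([ones, _rep_dummies(records, layout)], axis=1))
    ss_mean = float(y.sum()) ** 2 / n
    ss_total = float(y @ y) - ss_mean
    ss_rep = float((Qr.T @ y) @ (Qr.T @ y)) - ss_mean
    ss_lines = float((Qx.T @ y) @ (Qx.T @ y)) - ss_rep - ss_mean
    rows = [
        ("replications", layout.r - 1, ss_rep),
        ("lines (unadj.)", layout.n_lines - 1, ss_lines),
        ("blocks within reps (adj.)", df_block, ss_block_adj),
        ("intra-block error", df_resid, rss_full),
        ("total", n - 1, ss_total),
    ]
    table = pd.DataFrame(rows, columns=["source", "df", "SS"])
    table["MS"] = table["SS"] / table["df"]
    return VarianceComponents(
        sigma2=sigma2, sigma_b2=sigma_b2, delta=sigma_b2 / sigma2, anova_table=table
    )


def _rep_dummies(records: PhenotypeRecords, layout: LatticeLayout) -> np.ndarray:
    d = np.zeros((records.n, layout.r - 1))
    for i in range(1, layout.r):
        d[records.rep == i, i - 1] = 1.0
    return d


def _check_complete(records: PhenotypeRecords, layout: LatticeLayout):
    if records.n != layout.n_plots:
        raise ValueError("records do not cover the layout (missing plots unsupported)")
    key_rec = np.lexsort((records.line, records.block, records.rep))
    key_lay = np.lexsort((layout.plots[:, 2], layout.plots[:, 1], layout.plots[:, 0]))
    rec = np.stack([records.rep, records.block, records.line], axis=1)[key_rec]
    if not np.array_equal(rec, layout.plots[key_lay]):
        raise ValueError("records do not match the layout plot set")


@dataclass
class LineMeans:
    """Per-line response values on the line (not plot) level."""

    values: np.ndarray
    kind: str  # "arithmetic" | "adjusted"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


def arithmetic_means(records: PhenotypeRecords) -> LineMeans:
    """Raw per-line average over all its plots (all environments pooled)."""
    t = int(records.line.max()) + 1
    sums = np.bincount(records.line, weights=records.value, minlength=t)
    counts = np.bincount(records.line, minlength=t)
    if np.any(counts == 0):
        raise ValueError("every line must be observed at least once")
    return LineMeans(sums / counts, "arithmetic")


def adjusted_means(
    records: PhenotypeRecords, layout: LatticeLayout, vc: VarianceComponents
) -> LineMeans:
    """Lattice-adjusted line means: GLS estimates under random blocks.

    Solves the fixed replication + line model by OLS on data whitened with
    the ANOVA-estimated delta (equivalently GLS with covariance
    sigma^2 (I + delta ZZ')), recovering inter-block information.  The
    reported mean for line k is the average replication effect plus the
    line effect, which for delta = 0 reduces to the arithmetic mean.
    """
    _check_complete(records, layout)
    t, r, k = layout.n_lines, layout.r, layout.k
    y = block_whiten(records.value, layout.n_blocks, k, vc.delta)
    X = np.zeros((records.n, r + t))
    X[np.arange(records.n), records.rep] = 1.0
    X[np.arange(records.n), r + records.line] = 1.0
    Xw = block_whiten(X, layout.n_blocks, k, vc.delta)
    beta, _, rank, _ = np.linalg.lstsq(Xw, y, rcond=None)
    if rank < r + t - 1:
        raise ValueError("singular adjusted-means system")
    return LineMeans(beta[:r].mean() + beta[r:], "adjusted")


def estimate_heritability(
    sigma_g2: float, sigma_ge2: float, sigma2: float, s: int, r: int
) -> float:
    """Entry-mean heritability h2 = sg2 / (sg2 + sge2/s + s2/(s r))."""
    if min(sigma_g2, sigma_ge2, sigma2) < 0:
        raise ValueError("variance components must be non-negative")
    if s < 1 or r < 1:
        raise ValueError("s and r must be >= 1")
    denom = sigma_g2 + sigma_ge2 / s + sigma2 / (s * r)
    if denom <= 0:
        raise ValueError("all variance components are zero")
    return sigma_g2 / denom


def multi_env_variance_components(records: PhenotypeRecords) -> dict:
    """Method-of-moments genotype / GxE / error components over environments.

    Balanced two-way expected mean squares with lines random:
    E[MS_line] = s2 + r*sge2 + r*s*sg2, E[MS_LxE] = s2 + r*sge2,
    E[MS_err] = s2.  Block effects, if present, inflate the error term;
    use per-environment ``lattice_anova`` for the block structure itself.
    """
    if records.env is None:
        raise ValueError("records carry no environment labels")
    envs = np.unique(records.env)
    s = len(envs)
    if s < 2:
        raise ValueError("need >= 2 environments")
    t = int(records.line.max()) + 1
    reps = np.unique(records.rep)
    r = len(reps)
    n = records.n
    if n != s * r * t:
        raise ValueError("unbalanced layout across environments")
    y = records.value
    env_idx = np.searchsorted(envs, records.env)
    cell = env_idx * t + records.line
    cell_mean = np.bincount(cell, weights=y, minlength=s * t) / r
    line_mean = cell_mean.reshape(s, t).mean(axis=0)
    env_mean = cell_mean.reshape(s, t).mean(axis=1)
    grand = y.mean()
    ss_line = s * r * np.sum((line_mean - grand) ** 2)
    ss_cell = r * np.sum((cell_mean - grand) ** 2)
    ss_env = r * t * np.sum((env_mean - grand) ** 2)
    ss_ge = ss_cell - ss_line - ss_env
    ss_within = np.sum((y - cell_mean[cell]) ** 2)
    ms_line = ss_line / (t - 1)
    ms_ge = ss_ge / ((t - 1) * (s - 1))
    ms_err = ss_within / (s * t * (r - 1))
    sigma2 = ms_err
    sigma_ge2 = max((ms_ge - ms_err) / r, 0.0)
    sigma_g2 = max((ms_line - ms_ge) / (r * s), 0.0)
    return {"sigma_g2": sigma_g2, "sigma_ge2": sigma_ge2, "sigma2": sigma2, "s": s, "r": r}
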