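"""Significance thresholds, QTL calling and power/FDR evaluation.

Genome-wide LOD thresholds come from a Churchill-Doerge permutation test:
phenotypes are shuffled against genotypes, the full scan (including
covariate re-selection) is repeated, and the threshold is the empirical
(1 - alpha) quantile of the genome-wide maximum averaged LOD.  For the
mean-response methods the shuffle acts on lines (equivalently, genotype
rows).  For the plot-level scan the default exchanges raw plot
phenotypes over all plots — the classical complete-null permutation —
with line-label shuffling available as a stricter alternative that keeps
line-level phenotype structure in the null.  The block-variance ratio is
not re-estimated per permutation.

QTL calls are extracted greedily from a profile: take the global maximum
above the threshold, mask ``min_sep`` cM around it on that chromosome and
repeat.  A call's support interval is the contiguous region where the LOD
stays within 1.5 units of the peak.  Detection power and the false
discovery rate compare calls with the true simulated QTL using a 10 cM
matching radius around each position.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import ceil

import numpy as np

from .imputation import ImputationDraws
from .scan import ScanProfile, run_method_scan


@dataclass
class QtlCall:
    chrom: str
    pos: float
    lod: float
    effect: float
    support: tuple  # (lo, hi) in cM
    effect_ae: float | None = None
    h2: float | None = None


@dataclass
class EvalMetrics:
    """Detection power (percent) and pooled FDR against a known truth."""

    per_qtl_power: np.ndarray  # percent, one entry per true QTL
    overall_power: float  # percent, mean over true QTLs
    fdr: float  # pooled false positives / pooled calls, fraction
    n_replicates: int
    total_calls: int
    false_positives: int


def permutation_threshold(
    method: str,
    *,
    draws: ImputationDraws,
    n_perm: int = 1000,
    alpha: float = 0.05,
    rng=None,
    p: int = 3,
    window: float = 10.0,
    means=None,
    whitened=None,
    unit: str = "plot",
) -> float:
    """Genome-wide LOD threshold from permutations of the data.

    For the mean-response methods the permutation shuffles the
    genotype-row-to-line assignment, which is equivalent to shuffling the
    response vector over lines.  For the plot-level scan ``unit`` selects
    the exchangeable unit: ``"plot"`` (default) shuffles the raw plot
    phenotypes over all plots before re-whitening — the classical
    complete-null permutation — while ``"line"`` shuffles genotype rows
    over line labels, preserving any line-level structure of the
    phenotypes in the null distribution.

    Returns the k-th smallest of the ``n_perm`` permutation maxima with
    k = ceil((1 - alpha) * (n_perm + 1)); for alpha = 0.05 and 19
    permutations this is their maximum.
    """
    if n_perm < 19:
        raise ValueError("need at least 19 permutations")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if (n_perm + 1) * alpha < 1.0:
        raise ValueError("(n_perm + 1) * alpha must be >= 1 to reach the quantile")
    if unit not in ("plot", "line"):
        raise ValueError("unit must be 'plot' or 'line'")
    rng = np.random.default_rng(rng)
    t = draws.n_lines
    plot_unit = method == "cimld" and unit == "plot"
    if plot_unit and (whitened is None or whitened.raw_y is None):
        raise ValueError("plot-unit permutation requires whitened data with raw_y")
    maxima = np.empty(n_perm)
    cache: dict = {}
    for i in range(n_perm):
        if plot_unit:
            perm = rng.permutation(whitened.n)
            wh_perm = replace(whitened, y=whitened.apply(whitened.raw_y[perm]))
            prof = run_method_scan(
                method, draws=draws, p=p, window=window, whitened=wh_perm,
                cache=cache,
            )
        elif method in ("rcbd", "amld"):
            # shuffling genotype rows over line labels is equivalent to
            # shuffling the line-level response; the latter reuses the
            # cached genotype design
            perm = rng.permutation(t)
            means_perm = replace(means, values=means.values[perm])
            prof = run_method_scan(
                method, draws=draws, p=p, window=window, means=means_perm,
                cache=cache,
            )
        else:
            perm = rng.permutation(t)
            prof = run_method_scan(
                method, draws=draws, p=p, window=window, means=means,
                whitened=whitened, perm=perm,
            )
        maxima[i] = prof.max_lod()
    k = min(ceil((1.0 - alpha) * (n_perm + 1)), n_perm)
    return float(np.sort(maxima)[k - 1])


def call_qtls(
    profile: ScanProfile,
    threshold: float,
    min_sep: float = 10.0,
    draws: ImputationDraws | None = None,
    response_variance: float | None = None,
) -> list:
    """Greedy peak extraction above ``threshold``.

    When ``draws`` and ``response_variance`` are given, each call gets a
    heritability estimate Var(a * x_peak) / response_variance, where
    x_peak is the per-line expected genotype at the peak.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if len(profile.lod) == 0:
        raise ValueError("empty scan profile")
    lod = profile.lod
    chrom = profile.chrom
    pos = profile.pos
    # a candidate peak must be the maximum of the raw profile within its
    # own +-min_sep neighbourhood on its chromosome, so monotone shoulders
    # of a taller peak are never reported as separate QTLs
    local_max = np.ones(len(lod), dtype=bool)
    for j in range(len(lod)):
        near = (chrom == chrom[j]) & (np.abs(pos - pos[j]) <= min_sep)
        local_max[j] = lod[j] >= lod[near].max()
    available = (lod > threshold) & local_max
    calls: list = []
    expected = draws.expected() if draws is not None else None
    while available.any():
        j = int(np.argmax(np.where(available, lod, -np.inf)))
        peak_lod = float(lod[j])
        same = chrom == chrom[j]
        # support interval: contiguous run around the peak with
        # LOD >= peak - 1.5 on the peak's chromosome
        lo = hi = j
        while lo - 1 >= 0 and same[lo - 1] and lod[lo - 1] >= peak_lod - 1.5:
            lo -= 1
        while hi + 1 < len(lod) and same[hi + 1] and lod[hi + 1] >= peak_lod - 1.5:
            hi += 1
        h2 = None
        if expected is not None and response_variance:
            x = expected[:, j]
            h2 = float(np.var(profile.effect[j] * x, ddof=1) / response_variance)
        calls.append(
            QtlCall(
                chrom=str(chrom[j]),
                pos=float(pos[j]),
                lod=peak_lod,
                effect=float(profile.effect[j]),
                support=(float(pos[lo]), float(pos[hi])),
                effect_ae=(
                    float(profile.effect_ae[j]) if profile.effect_ae is not None else None
                ),
                h2=h2,
            )
        )
        available &= ~(same & (np.abs(pos - pos[j]) <= min_sep))
    return calls


def evaluate(calls_per_replicate, truth, window: float = 10.0) -> EvalMetrics:
    """Power and pooled FDR of replicate call lists against true QTLs.

    ``truth`` is a sequence of objects with ``chrom``/``position`` (or
    (chrom, pos) pairs).  ``window`` is the matching radius in cM: a call
    is a false positive iff no true QTL lies within ``window`` cM of it on
    its chromosome, and a true QTL is detected in a replicate iff at least
    one call lies within ``window`` cM of it.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    half = window
    tlist = []
    for q in truth:
        if hasattr(q, "chrom"):
            tlist.append((str(q.chrom), float(q.position)))
        else:
            tlist.append((str(q[0]), float(q[1])))
    n_rep = len(calls_per_replicate)
    n_truth = len(tlist)
    detected = np.zeros((n_rep, n_truth), dtype=bool)
    total_calls = 0
    fp = 0
    for rep, calls in enumerate(calls_per_replicate):
        for call in calls:
            total_calls += 1
            hit = False
            for qi, (tc, tp) in enumerate(tlist):
                if call.chrom == tc and abs(call.pos - tp) <= half:
                    detected[rep, qi] = True
                    hit = True
            if not hit:
                fp += 1
    per_qtl = detected.mean(axis=0) * 100.0 if n_rep else np.zeros(n_truth)
    overall = float(per_qtl.mean()) if n_truth else 0.0
    fdr = fp / total_calls if total_calls else 0.0
    return EvalMetrics(
        per_qtl_power=per_qtl,
        overall_power=overall,
        fdr=fdr,
        n_replicates=n_rep,
        total_calls=total_calls,
        false_positives=fp,
    )


def pointwise_power(profiles, thresholds) -> np.ndarray:
    """Fraction of replicates whose LOD exceeds their threshold, per position."""
    if len(profiles) != len(thresholds):
        raise ValueError("one threshold per profile required")
    ref = profiles[0]
    for prof in profiles[1:]:
        if not (
            np.array_equal(prof.pos, ref.pos) and np.array_equal(prof.chrom, ref.chrom)
        ):
            raise ValueError("profiles are not on a common scan grid")
    lods = np.stack([prof.lod for prof in profiles])
    thr = np.asarray(thresholds, dtype=float)[:, None]
    return (lods > thr).mean(axis=0)
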