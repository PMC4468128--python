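"""Permutation thresholds, QTL calling, evaluation metrics."""

import numpy as np
import pytest

from cimld.imputation import impute_draws
from cimld.inference import (
    call_qtls,
    evaluate,
    permutation_threshold,
    pointwise_power,
)
from cimld.lattice import LineMeans
from cimld.ril_sim import build_grid, simulate_ril_genotypes, uniform_map
from cimld.scan import ScanProfile


def _profile(chrom, pos, lod, effect=None):
    chrom = np.asarray(chrom)
    pos = np.asarray(pos, dtype=float)
    lod = np.asarray(lod, dtype=float)
    if effect is None:
        effect = np.zeros_like(lod)
    return ScanProfile(chrom=chrom, pos=pos, lod=lod, effect=effect, method="test")


# --------------------------------------------------------------- thresholds

@pytest.fixture(scope="module")
def null_scan_inputs():
    gmap = uniform_map(n_chromosomes=1, length=40.0, markers_per_chromosome=5)
    rng = np.random.default_rng(0)
    geno = simulate_ril_genotypes(build_grid(gmap), 30, rng)
    y = rng.normal(size=30)
    draws = impute_draws(geno.matrix, gmap, step=10.0, n_draws=3, rng=rng)
    return draws, LineMeans(y, "arithmetic")


def test_threshold_monotone_in_alpha(null_scan_inputs):
    draws, means = null_scan_inputs
    thr5 = permutation_threshold("rcbd", draws=draws, means=means, n_perm=120,
                                 alpha=0.05, rng=1, p=1)
    thr1 = permutation_threshold("rcbd", draws=draws, means=means, n_perm=120,
                                 alpha=0.01, rng=1, p=1)
    assert thr1 >= thr5


def test_threshold_edge_case_19_perms(null_scan_inputs):
    """With alpha=0.05 and 19 permutations the threshold is the max."""
    draws, means = null_scan_inputs
    thr = permutation_threshold("rcbd", draws=draws, means=means, n_perm=19,
                                alpha=0.05, rng=2, p=1)
    thr_loose = permutation_threshold("rcbd", draws=draws, means=means, n_perm=19,
                                      alpha=0.051, rng=2, p=1)
    assert thr == thr_loose  # both are the 19th order statistic (the max)


def test_threshold_input_validation(null_scan_inputs):
    draws, means = null_scan_inputs
    with pytest.raises(ValueError):
        permutation_threshold("rcbd", draws=draws, means=means, n_perm=10,
                              alpha=0.05, rng=0)
    with pytest.raises(ValueError):
        permutation_threshold("rcbd", draws=draws, means=means, n_perm=19,
                              alpha=0.01, rng=0)


def test_permutation_type_one_error_calibrated():
    """Under the null, the genome-wide test rejects at ~alpha."""
    gmap = uniform_map(n_chromosomes=1, length=60.0, markers_per_chromosome=7)
    grid = build_grid(gmap)
    n_sims, n_perm, alpha = 120, 60, 0.05
    rejections = 0
    for s in range(n_sims):
        rng = np.random.default_rng(9000 + s)
        geno = simulate_ril_genotypes(grid, 25, rng)
        y = rng.normal(size=25)
        draws = impute_draws(geno.matrix, gmap, step=10.0, n_draws=3, rng=rng)
        means = LineMeans(y, "arithmetic")
        from cimld.scan import run_method_scan

        prof = run_method_scan("rcbd", draws=draws, p=1, means=means)
        thr = permutation_threshold("rcbd", draws=draws, means=means,
                                    n_perm=n_perm, alpha=alpha, rng=rng, p=1)
        if prof.max_lod() > thr:
            rejections += 1
    rate = rejections / n_sims
    assert abs(rate - alpha) < 3 * np.sqrt(alpha * (1 - alpha) / n_sims) + 1e-9


# ------------------------------------------------------------------ calling

def test_flat_profile_no_calls():
    pos = np.arange(0.0, 100.0, 2.0)
    prof = _profile(["C1"] * len(pos), pos, np.full(len(pos), 1.0))
    assert call_qtls(prof, 2.5) == []


def test_triangular_peak_support_interval():
    pos = np.arange(0.0, 82.0, 2.0)
    lod = np.maximum(0.0, 5.0 - 0.15 * np.abs(pos - 40.0))
    prof = _profile(["C1"] * len(pos), pos, lod)
    calls = call_qtls(prof, 2.5)
    assert len(calls) == 1
    assert calls[0].pos == 40.0
    assert calls[0].support == (30.0, 50.0)


def test_two_close_peaks_single_call():
    pos = np.arange(0.0, 62.0, 2.0)
    lod = np.zeros(len(pos))
    lod[pos == 30.0] = 5.0
    lod[pos == 38.0] = 4.0
    prof = _profile(["C1"] * len(pos), pos, lod)
    calls = call_qtls(prof, 3.0, min_sep=10.0)
    assert len(calls) == 1 and calls[0].pos == 30.0


def test_distant_peaks_both_called_and_separated():
    pos = np.arange(0.0, 102.0, 2.0)
    lod = np.zeros(len(pos))
    lod[pos == 20.0] = 6.0
    lod[pos == 70.0] = 4.0
    prof = _profile(["C1"] * len(pos), pos, lod)
    calls = call_qtls(prof, 2.5, min_sep=10.0)
    assert sorted(c.pos for c in calls) == [20.0, 70.0]
    # greedy calling never returns two calls within min_sep
    for a in calls:
        for b in calls:
            if a is not b:
                assert abs(a.pos - b.pos) > 10.0


def test_call_errors():
    prof = _profile([], [], [])
    with pytest.raises(ValueError):
        call_qtls(prof, 2.5)
    prof2 = _profile(["C1"], [0.0], [3.0])
    with pytest.raises(ValueError):
        call_qtls(prof2, 0.0)


# --------------------------------------------------------------- evaluation

class _Call:
    def __init__(self, chrom, pos):
        self.chrom, self.pos = chrom, pos


def test_evaluate_perfect_calls():
    truth = [("C1", 10.0), ("C1", 50.0), ("C2", 30.0)]
    calls = [[_Call(c, p) for c, p in truth]] * 4
    m = evaluate(calls, truth, window=10.0)
    assert m.overall_power == 100.0
    assert m.fdr == 0.0


def test_evaluate_no_calls():
    truth = [("C1", 10.0)]
    m = evaluate([[], [], []], truth)
    assert m.overall_power == 0.0
    assert m.fdr == 0.0


def test_evaluate_matches_bruteforce_oracle():
    rng = np.random.default_rng(31)
    truth = [("C1", 20.0), ("C1", 70.0), ("C2", 40.0)]
    radius = 10.0
    for _ in range(20):
        calls_per_rep = []
        for _ in range(5):
            n = rng.integers(0, 6)
            calls_per_rep.append(
                [_Call(rng.choice(["C1", "C2", "C3"]), float(rng.uniform(0, 100)))
                 for _ in range(n)]
            )
        m = evaluate(calls_per_rep, truth, window=radius)
        # independent oracle
        fp = 0
        total = 0
        det = np.zeros((5, len(truth)))
        for i, calls in enumerate(calls_per_rep):
            for c in calls:
                total += 1
                near = [q for q in truth if q[0] == c.chrom and abs(q[1] - c.pos) <= radius]
                if not near:
                    fp += 1
                for j, q in enumerate(truth):
                    if q[0] == c.chrom and abs(q[1] - c.pos) <= radius:
                        det[i, j] = 1
        assert m.false_positives == fp
        assert m.total_calls == total
        assert m.overall_power == pytest.approx(det.mean() * 100.0)
        assert m.fdr == pytest.approx(fp / total if total else 0.0)


# ----------------------------------------------------------- pointwise power

def test_pointwise_power_tally():
    pos = np.arange(0.0, 20.0, 2.0)
    base = _profile(["C1"] * len(pos), pos, np.zeros(len(pos)))
    high = _profile(["C1"] * len(pos), pos, np.full(len(pos), 5.0))
    assert np.all(pointwise_power([base, base], [2.5, 2.5]) == 0.0)
    assert np.all(pointwise_power([base, high], [2.5, 2.5]) == 0.5)
    rng = np.random.default_rng(2)
    profs = [_profile(["C1"] * len(pos), pos, rng.uniform(0, 5, len(pos)))
             for _ in range(7)]
    thrs = rng.uniform(1, 4, 7)
    curve = pointwise_power(profs, thrs)
    oracle = np.mean([p.lod > t for p, t in zip(profs, thrs)], axis=0)
    assert np.allclose(curve, oracle)


def test_pointwise_power_grid_mismatch():
    pos = np.arange(0.0, 20.0, 2.0)
    a = _profile(["C1"] * len(pos), pos, np.zeros(len(pos)))
    b = _profile(["C1"] * (len(pos) - 1), pos[:-1], np.zeros(len(pos) - 1))
    with pytest.raises(ValueError):
        pointwise_power([a, b], [2.5, 2.5])
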