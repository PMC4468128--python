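"""Orchestration of the full power/FDR simulation study.

One study crosses three response strategies (rcbd / amld / cimld), a grid
of block-variance ratios delta, and two threshold rules (a fixed LOD of
2.5 and a per-replicate permutation threshold), each cell replicated many
times.  A replicate simulates a fresh RIL population and lattice trial,
estimates the variance components by ANOVA, builds the three responses,
draws one shared set of genotype imputations, scans with each method,
derives thresholds and calls QTLs.  All randomness derives from the master
seed through a documented counter scheme: replicate ``rep`` of cell
``cell`` uses ``SeedSequence([seed, cell, rep])``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import inference, lattice, ril_sim, scan
from .imputation import ImputationDraws, impute_draws

RULES = ("fixed", "permutation")


@dataclass
class StudyConfig:
    """Knobs of the simulation experiment (trait units arbitrary, cM maps)."""

    deltas: tuple = (0.5, 1.0, 5.0, 10.0)
    h2: float = 0.7
    k: int = 14
    r: int = 2
    rep_effect: float = 2.0
    n_chromosomes: int = 5
    chrom_length: float = 150.0
    markers_per_chromosome: int = 16
    n_polygenes: int = 100
    polygene_effect_max: float = 0.1
    n_replicates: int = 100
    n_perm: int = 1000
    fixed_threshold: float = 2.5
    alpha: float = 0.05
    step: float = 2.0
    n_draws: int = 16
    n_covariates: int = 3
    window: float = 10.0
    min_sep: float = 10.0
    eval_window: float = 10.0
    seed: int = 0
    methods: tuple = ("rcbd", "amld", "cimld")
    rules: tuple = ("fixed", "permutation")
    perm_unit: str = "plot"

    def __post_init__(self):
        if self.k < 2 or self.r < 1:
            raise ValueError("invalid lattice dimensions")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if any(d < 0 for d in self.deltas):
            raise ValueError("deltas must be non-negative")

    @property
    def n_lines(self) -> int:
        return self.k * self.k

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("deltas", "methods", "rules"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path):
        data = dataclasses.asdict(self)
        for key in ("deltas", "methods", "rules"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class ReplicateResult:
    profiles: dict  # method -> ScanProfile
    thresholds: dict  # (method, rule) -> float
    calls: dict  # (method, rule) -> list[QtlCall]
    truth: tuple  # the ten major QTLs
    delta_hat: float
    sigma2_hat: float


def replicate_seed(master: int, cell: int, rep: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master), int(cell), int(rep)])


def run_replicate(
    cfg: StudyConfig,
    delta: float,
    seed_seq,
    methods=None,
    permutation: bool | None = None,
) -> ReplicateResult:
    """One end-to-end simulation replicate at block-variance ratio delta."""
    methods = tuple(methods or cfg.methods)
    if permutation is None:
        permutation = "permutation" in cfg.rules
    rng = np.random.default_rng(seed_seq)
    gmap = ril_sim.uniform_map(
        cfg.n_chromosomes, cfg.chrom_length, cfg.markers_per_chromosome
    )
    arch = ril_sim.zeng_architecture(
        rng, gmap=gmap, n_polygenes=cfg.n_polygenes,
        polygene_effect_max=cfg.polygene_effect_max,
    )
    sim_grid = ril_sim.build_grid(gmap, step=None, extra=arch.positions())
    geno = ril_sim.simulate_ril_genotypes(sim_grid, cfg.n_lines, rng)
    background = ril_sim.simulate_background_genotypes(arch, cfg.n_lines, rng)
    g = ril_sim.genotypic_values(geno, arch, background)
    layout = lattice.make_simple_lattice(cfg.k, rng)
    records = lattice.simulate_phenotypes(
        g, layout, cfg.h2, delta, cfg.rep_effect, rng
    )
    vc = lattice.lattice_anova(records, layout)
    means_ar = lattice.arithmetic_means(records)
    means_ad = lattice.adjusted_means(records, layout, vc)
    wh = scan.whiten(records, layout, vc.delta)
    draws = impute_draws(
        geno.marker_matrix(), gmap, step=cfg.step, n_draws=cfg.n_draws, rng=rng
    )
    resp_var = {
        "rcbd": float(np.var(means_ar.values, ddof=1)),
        "amld": float(np.var(means_ad.values, ddof=1)),
        "cimld": float(np.var(means_ar.values, ddof=1)),
    }
    method_kwargs = {
        "rcbd": dict(means=means_ar),
        "amld": dict(means=means_ad),
        "cimld": dict(whitened=wh),
    }
    profiles, thresholds, calls = {}, {}, {}
    for method in methods:
        kw = method_kwargs[method]
        prof = scan.run_method_scan(
            method, draws=draws, p=cfg.n_covariates, window=cfg.window, **kw
        )
        profiles[method] = prof
        # two-pass refinement: re-scan with the first-pass peaks as the
        # background covariates, then call from the refined profile
        candidates = inference.call_qtls(
            prof, cfg.fixed_threshold, min_sep=cfg.min_sep
        )
        final_prof = prof
        if candidates:
            cov = scan.covariates_at(draws, [(c.chrom, c.pos) for c in candidates])
            final_prof = scan.run_method_scan(
                method, draws=draws, window=cfg.window, covariates=cov, **kw
            )
        rule_thr = {}
        if "fixed" in cfg.rules:
            rule_thr["fixed"] = cfg.fixed_threshold
        if permutation and "permutation" in cfg.rules:
            rule_thr["permutation"] = inference.permutation_threshold(
                method, draws=draws, n_perm=cfg.n_perm, alpha=cfg.alpha,
                rng=rng, p=cfg.n_covariates, window=cfg.window,
                unit=cfg.perm_unit, **kw,
            )
        for rule, thr in rule_thr.items():
            thresholds[(method, rule)] = thr
            calls[(method, rule)] = inference.call_qtls(
                final_prof, thr, min_sep=cfg.min_sep, draws=draws,
                response_variance=resp_var[method],
            )
    return ReplicateResult(
        profiles=profiles, thresholds=thresholds, calls=calls,
        truth=arch.qtls, delta_hat=vc.delta, sigma2_hat=vc.sigma2,
    )


def evaluate_cell(
    cfg: StudyConfig,
    method: str,
    delta: float,
    rule: str,
    n_replicates: int,
    cell_index: int,
):
    """Power/FDR of one (method, delta, threshold-rule) cell.

    Runs ``n_replicates`` independent replicates (seeded from
    ``cfg.seed`` and ``cell_index`` by the study's counter scheme) for a
    single method and returns the ``EvalMetrics`` against the ten true
    QTLs.  Convenience driver shared by the reproduction scripts.
    """
    permutation = rule == "permutation"
    calls = []
    truth = None
    for rep in range(n_replicates):
        res = run_replicate(
            cfg, delta, replicate_seed(cfg.seed, cell_index, rep),
            methods=(method,), permutation=permutation,
        )
        truth = res.truth
        calls.append(res.calls[(method, rule)])
    return inference.evaluate(calls, truth, window=cfg.eval_window)


@dataclass
class StudyResult:
    config: StudyConfig
    power: dict  # (method, rule, delta) -> overall power %
    per_qtl_power: dict  # (method, rule, delta) -> np.ndarray %
    fdr: dict  # (method, rule, delta) -> fraction
    metrics: dict  # (method, rule, delta) -> EvalMetrics
    avg_lod: dict  # (method, delta) -> np.ndarray
    pointwise: dict  # (method, rule, delta) -> np.ndarray
    grid_chrom: np.ndarray
    grid_pos: np.ndarray

    def power_table(self) -> pd.DataFrame:
        rows = []
        for delta in self.config.deltas:
            row = {"delta": delta}
            for rule in self.config.rules:
                for method in self.config.methods:
                    key = (method, rule, delta)
                    if key in self.power:
                        row[f"{method}_{rule}"] = self.power[key]
            rows.append(row)
        return pd.DataFrame(rows)

    def fdr_table(self) -> pd.DataFrame:
        rows = []
        for delta in self.config.deltas:
            row = {"delta": delta}
            for rule in self.config.rules:
                for method in self.config.methods:
                    key = (method, rule, delta)
                    if key in self.fdr:
                        row[f"{method}_{rule}"] = self.fdr[key]
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.power_table().to_csv(outdir / "power_table.tsv", sep="\t", index=False)
        self.fdr_table().to_csv(outdir / "fdr_table.tsv", sep="\t", index=False)
        for (method, delta), prof in self.avg_lod.items():
            pd.DataFrame(
                {"chr": self.grid_chrom, "pos_cM": self.grid_pos, "lod": prof}
            ).to_csv(
                outdir / f"avg_lod_{method}_{_fmt(delta)}.tsv", sep="\t", index=False
            )
        for (method, rule, delta), curve in self.pointwise.items():
            pd.DataFrame(
                {"chr": self.grid_chrom, "pos_cM": self.grid_pos, "power": curve}
            ).to_csv(
                outdir / f"pointwise_power_{method}_{_fmt(delta)}_{rule}.tsv",
                sep="\t",
                index=False,
            )


def _fmt(delta: float) -> str:
    return str(delta).replace(".", "p")


def run_study(cfg: StudyConfig, progress: bool = False) -> StudyResult:
    """Run all (delta x replicate) cells and aggregate power/FDR tables."""
    permutation = "permutation" in cfg.rules
    all_calls: dict = {}
    profiles_acc: dict = {}
    thresholds_acc: dict = {}
    truth = None
    grid_chrom = grid_pos = None
    for cell, delta in enumerate(cfg.deltas):
        for rep in range(cfg.n_replicates):
            res = run_replicate(
                cfg, delta, replicate_seed(cfg.seed, cell, rep),
                permutation=permutation,
            )
            truth = res.truth
            for method in cfg.methods:
                prof = res.profiles[method]
                if grid_pos is None:
                    grid_chrom, grid_pos = prof.chrom, prof.pos
                profiles_acc.setdefault((method, delta), []).append(prof)
                for rule in cfg.rules:
                    key = (method, rule, delta)
                    all_calls.setdefault(key, []).append(res.calls[(method, rule)])
                    thresholds_acc.setdefault(key, []).append(
                        res.thresholds[(method, rule)]
                    )
            if progress:
                print(
                    f"delta={delta} rep={rep + 1}/{cfg.n_replicates} "
                    f"delta_hat={res.delta_hat:.2f}",
                    flush=True,
                )
    power, per_qtl, fdr, metrics, avg_lod, pointwise = {}, {}, {}, {}, {}, {}
    for (method, delta), profs in profiles_acc.items():
        avg_lod[(method, delta)] = np.mean([p.lod for p in profs], axis=0)
    for key, calls in all_calls.items():
        m = inference.evaluate(calls, truth, window=cfg.eval_window)
        metrics[key] = m
        power[key] = m.overall_power
        per_qtl[key] = m.per_qtl_power
        method, rule, delta = key
        pointwise[key] = inference.pointwise_power(
            profiles_acc[(method, delta)], thresholds_acc[key]
        )
        fdr[key] = m.fdr
    return StudyResult(
        config=cfg,
        power=power,
        per_qtl_power=per_qtl,
        fdr=fdr,
        metrics=metrics,
        avg_lod=avg_lod,
        pointwise=pointwise,
        grid_chrom=grid_chrom,
        grid_pos=grid_pos,
    )
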