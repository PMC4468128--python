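"""Plain-text readers and writers for the package's file formats.

Genotype + map files use a rotated CSV dialect: one row per marker with
columns ``marker, chromosome, position`` followed by one genotype code per
line ("A" = 0, "B" = 1, "-" = missing); the header row carries the line
ids.  Positions are written with ``repr`` so a write/read cycle is
bit-exact.  Phenotype and layout tables are TSV.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .lattice import LatticeLayout, PhenotypeRecords
from .ril_sim import (
    NA,
    Chromosome,
    GeneticMap,
    KIND_MARKER,
    LocusGrid,
    RilGenotypes,
    build_grid,
)

_CODE = {0: "A", 1: "B", NA: "-"}
_DECODE = {"A": 0, "B": 1, "-": NA}


def write_genotypes(path, geno: RilGenotypes, gmap: GeneticMap):
    """Write marker genotypes and the map in the rotated CSV dialect."""
    markers = geno.marker_matrix()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["marker", "chromosome", "position", *geno.line_ids])
        col = 0
        for chrom in gmap.chromosomes:
            for name, pos in zip(chrom.marker_names, chrom.positions):
                codes = [_CODE[int(v)] for v in markers[:, col]]
                w.writerow([name, chrom.id, repr(float(pos)), *codes])
                col += 1


def read_genotypes(path) -> tuple:
    """Read a rotated-CSV genotype file -> (RilGenotypes, GeneticMap)."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    header = rows[0]
    line_ids = tuple(header[3:])
    chrom_order: list = []
    by_chrom: dict = {}
    geno_cols = []
    for row in rows[1:]:
        name, cid, pos = row[0], row[1], float(row[2])
        if cid not in by_chrom:
            by_chrom[cid] = ([], [])
            chrom_order.append(cid)
        by_chrom[cid][0].append(name)
        by_chrom[cid][1].append(pos)
        geno_cols.append([_DECODE[c] for c in row[3:]])
    chroms = tuple(
        Chromosome(cid, tuple(by_chrom[cid][0]), np.array(by_chrom[cid][1]))
        for cid in chrom_order
    )
    gmap = GeneticMap(chroms)
    grid = build_grid(gmap)
    matrix = np.array(geno_cols, dtype=np.int8).T
    return RilGenotypes(matrix, grid, line_ids), gmap


def write_phenotypes(path, records: PhenotypeRecords):
    records.to_frame().to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> PhenotypeRecords:
    return PhenotypeRecords.from_frame(pd.read_csv(path, sep="\t"))


def write_layout(path, layout: LatticeLayout):
    pd.DataFrame(layout.plots, columns=["rep", "block", "line"]).to_csv(
        path, sep="\t", index=False
    )


def read_layout(path) -> LatticeLayout:
    frame = pd.read_csv(path, sep="\t")
    plots = frame[["rep", "block", "line"]].to_numpy()
    k = int(np.sum((plots[:, 0] == plots[0, 0]) & (plots[:, 1] == plots[0, 1])))
    r = int(plots[:, 0].max()) + 1
    return LatticeLayout(k, r, plots)


def write_scan(path, profile):
    cols = {"chr": profile.chrom, "pos_cM": profile.pos, "lod": profile.lod,
            "effect": profile.effect}
    if profile.lod_g is not None:
        cols.update(
            lod_g=profile.lod_g, lod_ge=profile.lod_ge, lod_join=profile.lod_join,
            effect_a=profile.effect, effect_ae=profile.effect_ae,
        )
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_scan(path):
    from .scan import ScanProfile

    frame = pd.read_csv(path, sep="\t")
    kw = {}
    if "lod_g" in frame.columns:
        kw = dict(
            lod_g=frame["lod_g"].to_numpy(),
            lod_ge=frame["lod_ge"].to_numpy(),
            lod_join=frame["lod_join"].to_numpy(),
            effect_ae=frame["effect_ae"].to_numpy(),
        )
    return ScanProfile(
        chrom=frame["chr"].to_numpy(),
        pos=frame["pos_cM"].to_numpy(dtype=float),
        lod=frame["lod"].to_numpy(dtype=float),
        effect=frame["effect"].to_numpy(dtype=float),
        method="file",
        **kw,
    )


def write_qtl_table(path, calls):
    rows = []
    for c in calls:
        rows.append(
            {
                "chr": c.chrom,
                "pos_cM": c.pos,
                "lod": c.lod,
                "effect_a": c.effect,
                "effect_ae": c.effect_ae if c.effect_ae is not None else "",
                "support_lo": c.support[0],
                "support_hi": c.support[1],
                "h2": c.h2 if c.h2 is not None else "",
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "chr", "pos_cM", "lod", "effect_a", "effect_ae",
            "support_lo", "support_hi", "h2",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_truth(path, arch):
    rows = [
        {"chr": q.chrom, "pos_cM": q.position, "effect": q.effect, "kind": kind}
        for kind, group in (("qtl", arch.qtls), ("polygene", arch.polygenes))
        for q in group
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
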