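"""Readers and writers for the package's external formats.

Counts come in as Matrix Market (MTX with gene/barcode TSV sidecars) or dense
CSV; marker gene lists as one-symbol-per-line text; model parameters as JSON.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .kinetics import KineticParams, TurningPoints
from .pipeline import CountMatrix

__all__ = [
    "read_counts_mtx",
    "write_counts_mtx",
    "read_counts_csv",
    "write_counts_csv",
    "read_gene_list",
    "default_gene_sets",
    "load_params",
    "save_params",
    "read_turning_points",
    "write_turning_points",
]


def read_counts_mtx(mtx: str | Path, genes: str | Path, barcodes: str | Path) -> CountMatrix:
    """Read a genes x cells Matrix Market matrix with TSV sidecars."""
    values = scipy.io.mmread(str(mtx)).tocsr()
    gene_ids = pd.read_csv(genes, sep="\t", header=None)[0].to_numpy(dtype=object)
    cell_ids = pd.read_csv(barcodes, sep="\t", header=None)[0].to_numpy(dtype=object)
    return CountMatrix(values, gene_ids, cell_ids)


def write_counts_mtx(counts: CountMatrix, outdir: str | Path, prefix: str = "matrix") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vals = counts.values if sp.issparse(counts.values) else sp.csr_matrix(counts.values)
    scipy.io.mmwrite(str(outdir / f"{prefix}.mtx"), vals)
    pd.Series(counts.gene_ids).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(counts.cell_ids).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)


def read_counts_csv(path: str | Path) -> CountMatrix:
    """Dense CSV: first column gene ids, header row cell ids."""
    df = pd.read_csv(path, index_col=0)
    return CountMatrix(
        df.to_numpy(), df.index.to_numpy(dtype=object), df.columns.to_numpy(dtype=object)
    )


def write_counts_csv(counts: CountMatrix, path: str | Path) -> None:
    pd.DataFrame(
        counts.dense(), index=counts.gene_ids.astype(str), columns=counts.cell_ids.astype(str)
    ).to_csv(path)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def default_gene_sets() -> dict[str, list[str]]:
    """Packaged S-phase and G2/M marker lists (the standard scoring sets)."""
    sets = {}
    for name, fname in (("S", "s_genes.txt"), ("G2M", "g2m_genes.txt")):
        text = resources.files("cct.data").joinpath(fname).read_text()
        sets[name] = [l.strip() for l in text.splitlines() if l.strip() and not l.startswith("#")]
    return sets


def load_params(path: str | Path) -> KineticParams:
    return KineticParams.from_dict(json.loads(Path(path).read_text()))


def save_params(params: KineticParams, path: str | Path) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=2))


def read_turning_points(path: str | Path) -> TurningPoints:
    """CSV with columns s,m (log coordinates), five rows ordered along the cycle."""
    df = pd.read_csv(path)
    return TurningPoints(df[["s", "m"]].to_numpy())


def write_turning_points(tp: TurningPoints, path: str | Path) -> None:
    pd.DataFrame(tp.points, columns=["s", "m"]).to_csv(path, index=False)
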