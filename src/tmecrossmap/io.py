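"""Reading and writing the pipeline's tabular formats.

Expression tables travel as TSV (genes as rows, header = sample ids) or
MatrixMarket MTX with row/column name sidecar files; frequency, signature,
match and survival tables as TSV; configs as YAML.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from tmecrossmap.matching import GeneSignature

__all__ = [
    "read_expression",
    "write_expression",
    "read_frequency_table",
    "write_signatures",
    "read_signatures",
    "read_survival_table",
    "read_yaml",
    "write_yaml",
]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample expression table (TSV, or MTX with sidecars).

    For ``x.mtx``, gene ids are read from ``x.genes.tsv`` and sample ids from
    ``x.samples.tsv`` alongside it.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        mat = spio.mmread(path)
        genes = pd.read_csv(path.with_suffix(".genes.tsv"), header=None)[0].tolist()
        samples = pd.read_csv(path.with_suffix(".samples.tsv"), header=None)[0].tolist()
        dense = mat.toarray() if sparse.issparse(mat) else mat
        return pd.DataFrame(dense, index=genes, columns=samples)
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(table: pd.DataFrame, path: str | Path, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt == "mtx":
        spio.mmwrite(path, sparse.csr_matrix(table.values))
        pd.Series(table.index).to_csv(path.with_suffix(".genes.tsv"), index=False, header=False)
        pd.Series(table.columns).to_csv(path.with_suffix(".samples.tsv"), index=False, header=False)
    else:
        table.to_csv(path, sep="\t")


def read_frequency_table(
    path: str | Path, sample_col: str = "sample", meta_cols: tuple[str, ...] = ("species", "group")
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a frequency TSV; returns (feature table, metadata table)."""
    df = pd.read_csv(path, sep="\t").set_index(sample_col)
    meta = df[[c for c in meta_cols if c in df.columns]]
    feats = df.drop(columns=meta.columns)
    return feats, meta


def write_signatures(signatures: list[GeneSignature], path: str | Path) -> None:
    rows = [
        {"program": s.program, "rank": i + 1, "gene": g}
        for s in signatures
        for i, g in enumerate(s.genes)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_signatures(path: str | Path, universe_size: int = 0) -> list[GeneSignature]:
    df = pd.read_csv(path, sep="\t")
    sigs = []
    for prog, sub in df.groupby("program", sort=False):
        genes = sub.sort_values("rank")["gene"].tolist()
        sigs.append(GeneSignature(program=str(prog), genes=genes, n=len(genes), universe_size=universe_size))
    return sigs


def read_survival_table(path: str | Path) -> pd.DataFrame:
    """Read a survival TSV with columns id, time, event (+ score columns)."""
    return pd.read_csv(path, sep="\t").set_index("id")


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
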