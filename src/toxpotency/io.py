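"""Readers and writers for the plain-text interchange formats.

Matrices and metadata travel as TSV, gene sets as GMT (with an optional
``gene:+1`` / ``gene:-1`` direction suffix used by the activation
z-score), simulation truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .datatypes import ExpressionMatrix, GeneSetCollection


def write_matrix(em: ExpressionMatrix, matrix_path, meta_path) -> None:
    em.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
    em.samples.to_csv(meta_path, sep="\t", index_label="sample_id")


def read_matrix(matrix_path, meta_path) -> ExpressionMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col="gene_id")
    samples = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    return ExpressionMatrix(values, samples)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            dirs = collection.directions.get(name)
            if dirs:
                fields = [f"{g}:{dirs[g]:+d}" if g in dirs else g for g in genes]
            else:
                fields = list(genes)
            fh.write("\t".join([name, collection.description or "na", *fields]) + "\n")


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    directions: dict[str, dict[str, int]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        name, _desc, *fields = line.rstrip("\n").split("\t")
        genes, dirs = [], {}
        for f in fields:
            if ":" in f:
                g, d = f.rsplit(":", 1)
                genes.append(g)
                dirs[g] = int(d)
            else:
                genes.append(f)
        sets[name] = genes
        if dirs:
            directions[name] = dirs
    return GeneSetCollection(sets, directions)


def write_truth(truth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True))


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_compendium(path) -> tuple[pd.DataFrame, pd.Series]:
    """Reference compendium TSV: condition, label, one column per signature gene.

    Returns (fold-change matrix indexed by condition, label Series).
    """
    df = pd.read_csv(path, sep="\t", index_col="condition")
    labels = df.pop("label")
    return df, labels


def write_compendium(fc: pd.DataFrame, labels: pd.Series, path) -> None:
    out = fc.copy()
    out.insert(0, "label", labels)
    out.to_csv(path, sep="\t", index_label="condition")
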