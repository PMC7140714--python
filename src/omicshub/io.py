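"""Readers and writers for the pipeline's tab-separated interchange files."""

from __future__ import annotations

import json

import pandas as pd

from .deg import ExpressionStudy

__all__ = [
    "write_expression_study",
    "read_expression_study",
    "write_truth",
    "read_truth",
    "write_id_set",
    "read_id_set",
]


def write_expression_study(study: ExpressionStudy, matrix_path, samples_path) -> None:
    study.matrix.to_csv(matrix_path, sep="\t", index_label="gene_id")
    study.samples.to_csv(samples_path, sep="\t", index_label="sample_id")


def read_expression_study(
    matrix_path, samples_path, condition_levels: tuple[str, str] | None = None
) -> ExpressionStudy:
    matrix = pd.read_csv(matrix_path, sep="\t", index_col="gene_id")
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
    return ExpressionStudy(matrix=matrix, samples=samples,
                           condition_levels=condition_levels)


def write_truth(truth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_id_set(ids, path) -> None:
    with open(path, "w") as fh:
        for i in sorted(ids):
            fh.write(f"{i}\n")


def read_id_set(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
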