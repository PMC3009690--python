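"""Tab-separated text formats shared by the CLI and the library.

Expression matrices travel as TSV with gene identifiers in the first column
and a header row of sample labels (genes x samples on disk; the
factorization works on the transposed experiments x genes orientation).
Replicates are declared either through sample labels of the form
``condition.replicate`` or an explicit two-column design file.  All numeric
output uses 10 significant digits so reruns are byte-identical.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "write_matrix_tsv",
    "read_design_tsv",
    "conditions_from_labels",
]

FLOAT_FMT = "%.10g"


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Genes x samples expression matrix (first column = gene identifier)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers in {path}: {dups[:5]}")
    return df.astype(float)


def write_expression_tsv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="gene")


def write_matrix_tsv(
    path: str | Path,
    M: np.ndarray,
    row_labels: Sequence[str],
    col_labels: Sequence[str],
    index_label: str = "id",
) -> None:
    pd.DataFrame(np.asarray(M), index=list(row_labels), columns=list(col_labels)) \
        .to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label=index_label)


def read_design_tsv(path: str | Path) -> dict[str, str]:
    """Two-column sample -> condition map (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] != 2:
        raise ValueError("design file must have exactly two columns")
    return dict(zip(df[0], df[1]))


def conditions_from_labels(labels: Iterable[str]) -> list[str]:
    """Condition part of ``condition.replicate`` sample labels.

    Labels without a dot are their own condition (single replicate).
    """
    return [lab.rsplit(".", 1)[0] for lab in labels]
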