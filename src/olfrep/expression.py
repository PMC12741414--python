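"""TPM-matrix transformation and organ-specificity calls.

Expression matrices are genes × organs tables of TPM values, one library
per organ (nine organs in the reference design: olfactory organ, brain,
pituitary gland, gill, intestine, kidney, liver, testis, ovary). Two
operations reproduce the repertoire-level expression summary: a log10
transform with a 0.001 pseudocount (for display on heatmaps), and the
specificity call — "expressed" when focal-organ TPM strictly exceeds 1,
"highest" when the focal organ strictly tops every other organ (a tie is
not highest).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ORGANS",
    "SpecificityCall",
    "log_transform",
    "classify_specificity",
    "read_tpm_matrix",
    "write_calls",
]

ORGANS = (
    "olfactory organ",
    "brain",
    "pituitary gland",
    "gill",
    "intestine",
    "kidney",
    "liver",
    "testis",
    "ovary",
)


@dataclass(frozen=True)
class SpecificityCall:
    gene_id: str
    expressed_in_focal: bool
    highest_in_focal: bool
    focal_tpm: float
    max_other_tpm: float


def _validate(matrix: pd.DataFrame) -> None:
    if matrix.columns.duplicated().any():
        raise ValueError("duplicate organ names")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("negative TPM values")


def log_transform(matrix: pd.DataFrame, pseudocount: float = 0.001) -> pd.DataFrame:
    """log10(TPM + pseudocount), element-wise."""
    _validate(matrix)
    return np.log10(matrix + pseudocount)


def classify_specificity(
    matrix: pd.DataFrame,
    focal_organ: str = "olfactory organ",
    expressed_threshold: float = 1.0,
) -> tuple[list[SpecificityCall], dict]:
    """Per-gene expression calls relative to a focal organ, plus summary.

    ``expressed_in_focal``: focal TPM > threshold (strict).
    ``highest_in_focal``: focal TPM strictly exceeds every other organ.
    The summary counts {n_expressed, n_highest, n_total}. Note a gene can
    be highest in the focal organ while below the expressed threshold.
    """
    _validate(matrix)
    if focal_organ not in matrix.columns:
        raise ValueError(f"unknown organ {focal_organ!r}")
    others = [c for c in matrix.columns if c != focal_organ]
    calls = []
    for gene, row in matrix.iterrows():
        focal = float(row[focal_organ])
        max_other = float(row[others].max()) if others else float("-inf")
        calls.append(
            SpecificityCall(
                gene_id=str(gene),
                expressed_in_focal=focal > expressed_threshold,
                highest_in_focal=focal > max_other,
                focal_tpm=focal,
                max_other_tpm=max_other,
            )
        )
    summary = {
        "n_expressed": sum(c.expressed_in_focal for c in calls),
        "n_highest": sum(c.highest_in_focal for c in calls),
        "n_total": len(calls),
    }
    return calls, summary


def read_tpm_matrix(path) -> pd.DataFrame:
    """Read a TPM TSV: rows genes, columns organs, header required."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    _validate(df)
    return df


def write_calls(calls: Sequence[SpecificityCall], path) -> None:
    pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "expressed_in_focal": [c.expressed_in_focal for c in calls],
            "highest_in_focal": [c.highest_in_focal for c in calls],
            "focal_tpm": [c.focal_tpm for c in calls],
            "max_other_tpm": [c.max_other_tpm for c in calls],
        }
    ).to_csv(path, sep="\t", index=False)


def plot_heatmap(matrix: pd.DataFrame, path, leaf_order: Sequence[str] | None = None,
                 pseudocount: float = 0.001) -> None:
    """Log-scale expression heatmap, rows optionally in tree-leaf order."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = log_transform(matrix, pseudocount)
    if leaf_order is not None:
        order = [g for g in leaf_order if g in data.index]
        data = data.loc[order]
    fig, ax = plt.subplots(figsize=(6, max(2, 0.15 * len(data))))
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(data.columns)))
    ax.set_xticklabels(data.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(data)))
    ax.set_yticklabels(data.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="log10(TPM + pc)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
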