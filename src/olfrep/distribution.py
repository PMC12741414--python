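"""Phylogenetic-vs-genomic distance tables and proximity statistics.

For a repertoire of n genes with scaffold coordinates, a clade assignment
and a tree, this module builds the full C(n,2) table of unordered gene
pairs — phylogenetic (cophenetic) distance against genomic distance — and
summarises, per clade class, the fraction of pairs lying within a genomic
proximity threshold (10 Mbp by default). Pairs on different scaffolds have
undefined genomic distance and can never fall inside the threshold, but
they stay in the denominators, matching how the published pair fractions
are computed. Genes labelled ``Else`` count as interclade in every pair
they join, including Else-Else pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phylo import ELSE_LABEL, SupportTree, cophenetic_distances
from .screen import CandidateGene

__all__ = [
    "GenePairRecord",
    "ProximitySummary",
    "genomic_distance",
    "build_pair_table",
    "proximity_summary",
    "scaffold_occupancy",
    "write_pair_table",
]

INTRACLADE = "intraclade"
INTERCLADE = "interclade"


@dataclass(frozen=True)
class GenePairRecord:
    """One unordered gene pair (gene_a < gene_b lexicographically)."""

    gene_a: str
    gene_b: str
    phylo_dist: float
    genomic_dist: float | None  # None: different scaffolds
    clade_class: str  # intraclade | interclade
    scaffold_class: str  # intrascaffold | interscaffold


@dataclass(frozen=True)
class ProximitySummary:
    """Per-class counts of pairs within the genomic proximity threshold."""

    threshold_bp: int
    intraclade_near: int
    intraclade_total: int
    interclade_near: int
    interclade_total: int

    @property
    def intraclade_fraction(self) -> float:
        return self.intraclade_near / self.intraclade_total if self.intraclade_total else math.nan

    @property
    def interclade_fraction(self) -> float:
        return self.interclade_near / self.interclade_total if self.interclade_total else math.nan

    def as_dict(self) -> dict:
        return {
            "threshold_bp": self.threshold_bp,
            "intraclade_near": self.intraclade_near,
            "intraclade_total": self.intraclade_total,
            "intraclade_fraction": round(self.intraclade_fraction, 3)
            if self.intraclade_total else None,
            "interclade_near": self.interclade_near,
            "interclade_total": self.interclade_total,
            "interclade_fraction": round(self.interclade_fraction, 3)
            if self.interclade_total else None,
        }


def genomic_distance(a: CandidateGene, b: CandidateGene) -> int | None:
    """Midpoint-to-midpoint distance in bp; None across scaffolds."""
    if a.scaffold != b.scaffold:
        return None
    return round(abs(a.midpoint - b.midpoint))


def build_pair_table(
    genes: Sequence[CandidateGene],
    clades: Mapping[str, str],
    tree: SupportTree,
) -> list[GenePairRecord]:
    """All C(n,2) unordered gene pairs with both distances and class labels.

    Raises if any gene is missing from the tree or the clade assignment,
    and asserts the exact pair count — any upstream duplication or loss
    surfaces here rather than as a silently wrong fraction.
    """
    leaf_set = set(tree.leaf_labels)
    missing_tree = [g.gene_id for g in genes if g.gene_id not in leaf_set]
    if missing_tree:
        raise ValueError(f"genes missing from tree: {missing_tree}")
    missing_clade = [g.gene_id for g in genes if g.gene_id not in clades]
    if missing_clade:
        raise ValueError(f"genes missing from clade assignment: {missing_clade}")

    dmat = cophenetic_distances(tree)
    ordered = sorted(genes, key=lambda g: g.gene_id)
    records: list[GenePairRecord] = []
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            a, b = ordered[i], ordered[j]
            ca, cb = clades[a.gene_id], clades[b.gene_id]
            intra = ca == cb and ca != ELSE_LABEL
            gdist = genomic_distance(a, b)
            records.append(
                GenePairRecord(
                    gene_a=a.gene_id,
                    gene_b=b.gene_id,
                    phylo_dist=float(dmat.loc[a.gene_id, b.gene_id]),
                    genomic_dist=gdist,
                    clade_class=INTRACLADE if intra else INTERCLADE,
                    scaffold_class="intrascaffold" if gdist is not None else "interscaffold",
                )
            )
    n = len(genes)
    expected = n * (n - 1) // 2
    if len(records) != expected:
        raise AssertionError(
            f"pair table has {len(records)} records, expected C({n},2)={expected}"
        )
    return records


def proximity_summary(
    pairs: Sequence[GenePairRecord], threshold_bp: int = 10_000_000
) -> ProximitySummary:
    """Fraction of intra-/interclade pairs with genomic distance < threshold."""
    if not pairs:
        raise ValueError("empty pair list")
    near = {INTRACLADE: 0, INTERCLADE: 0}
    total = {INTRACLADE: 0, INTERCLADE: 0}
    for p in pairs:
        total[p.clade_class] += 1
        if p.genomic_dist is not None and p.genomic_dist < threshold_bp:
            near[p.clade_class] += 1
    return ProximitySummary(
        threshold_bp=threshold_bp,
        intraclade_near=near[INTRACLADE],
        intraclade_total=total[INTRACLADE],
        interclade_near=near[INTERCLADE],
        interclade_total=total[INTERCLADE],
    )


def scaffold_occupancy(
    genes: Sequence[CandidateGene],
    scaffold_lengths: Mapping[str, int],
    min_scaffold_len: int = 100_000,
) -> pd.DataFrame:
    """Gene counts per scaffold, longest scaffold first.

    Scaffolds shorter than ``min_scaffold_len`` stay in the table but are
    flagged ``below_min_len`` (the published maps drop them from display
    only). The result carries ``top_fraction`` — the share of genes on the
    single most gene-dense scaffold — as a DataFrame attribute.
    """
    counts: dict[str, int] = {}
    for g in genes:
        counts[g.scaffold] = counts.get(g.scaffold, 0) + 1
    rows = []
    for scaf, cnt in counts.items():
        length = scaffold_lengths.get(scaf)
        rows.append(
            {
                "scaffold": scaf,
                "length": length if length is not None else np.nan,
                "n_genes": cnt,
                "below_min_len": (length is not None and length <= min_scaffold_len),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["length", "scaffold"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    total = sum(counts.values())
    df.attrs["top_fraction"] = (max(counts.values()) / total) if total else math.nan
    return df


def write_pair_table(pairs: Sequence[GenePairRecord], path) -> None:
    pd.DataFrame(
        {
            "gene_a": [p.gene_a for p in pairs],
            "gene_b": [p.gene_b for p in pairs],
            "phylo_dist": [p.phylo_dist for p in pairs],
            "genomic_dist": [
                "NA" if p.genomic_dist is None else int(p.genomic_dist) for p in pairs
            ],
            "clade_class": [p.clade_class for p in pairs],
            "scaffold_class": [p.scaffold_class for p in pairs],
        }
    ).to_csv(path, sep="\t", index=False)


def plot_distance_scatter(pairs: Sequence[GenePairRecord], path) -> None:
    """Scatter (intrascaffold) of genomic vs phylogenetic distance, by clade class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for cls, color in ((INTRACLADE, "tab:red"), (INTERCLADE, "tab:gray")):
        xs = [p.phylo_dist for p in pairs if p.clade_class == cls and p.genomic_dist is not None]
        ys = [p.genomic_dist for p in pairs if p.clade_class == cls and p.genomic_dist is not None]
        ax.scatter(xs, ys, s=8, alpha=0.5, color=color, label=cls)
    ax.set_xlabel("phylogenetic distance (subs/site)")
    ax.set_ylabel("genomic distance (bp)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
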