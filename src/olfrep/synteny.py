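"""Landmark-anchored microsynteny comparison.

V2R clusters in jawed vertebrates sit between two landmark genes,
phospholipase C eta (Plch1) and membrane metallo-endopeptidase (Mme/Nep).
This module compares the gene neighbourhoods around such landmarks across
assemblies or species: liftover matches between assembly versions are
filtered at E < 1e-100 and identity > 99%, flanking genes (eight per side
by default) are related through a precomputed homology map, and shared gene
content plus order conservation (monotone in either direction, so a whole-
block inversion still counts as conserved) are reported. A separate check
asks whether any family gene lies near a landmark's scaffold position —
"near" meaning within 50 Mbp on the same scaffold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .screen import CandidateGene

__all__ = [
    "SyntenyRegion",
    "LiftoverMatch",
    "filter_liftover",
    "compare_microsynteny",
    "landmark_distance_check",
    "read_region_table",
]


@dataclass(frozen=True)
class SyntenyRegion:
    """An anchor gene and its coordinate-ordered flanking genes."""

    species: str
    anchor_gene: str
    flanking: tuple[tuple[str, str], ...]  # (gene_id, strand), ordered by coordinate

    def __post_init__(self) -> None:
        if self.anchor_gene not in {g for g, _ in self.flanking}:
            raise ValueError(
                f"anchor {self.anchor_gene!r} missing from region gene list"
            )

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.flanking]


@dataclass(frozen=True)
class LiftoverMatch:
    """One BLASTN match carrying a source interval to a target assembly."""

    source_id: str
    target_id: str
    evalue: float
    percent_identity: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError(
                f"identity outside [0, 100]: {self.percent_identity}"
            )


def filter_liftover(
    matches: Iterable[LiftoverMatch],
    max_evalue: float = 1e-100,
    min_identity: float = 99.0,
) -> tuple[list[LiftoverMatch], set[str]]:
    """Keep matches with E < 1e-100 and identity > 99% (both strict).

    When one source has several accepted targets, only the best is kept
    (lowest E-value, then highest identity) and the source id is returned
    in the ambiguity set.
    """
    accepted: dict[str, list[LiftoverMatch]] = {}
    for m in matches:
        if m.evalue < max_evalue and m.percent_identity > min_identity:
            accepted.setdefault(m.source_id, []).append(m)
    kept: list[LiftoverMatch] = []
    ambiguous: set[str] = set()
    for src in sorted(accepted):
        ms = sorted(
            accepted[src], key=lambda m: (m.evalue, -m.percent_identity, m.target_id)
        )
        kept.append(ms[0])
        if len(ms) > 1:
            ambiguous.add(src)
    return kept, ambiguous


def _is_monotone(seq: Sequence[int]) -> bool:
    if len(seq) < 2:
        return True
    inc = all(seq[i] < seq[i + 1] for i in range(len(seq) - 1))
    dec = all(seq[i] > seq[i + 1] for i in range(len(seq) - 1))
    return inc or dec


def compare_microsynteny(
    region_a: SyntenyRegion,
    region_b: SyntenyRegion,
    homology_map: Iterable[tuple[str, str]],
) -> dict:
    """Shared-gene count, order conservation and presence/absence table.

    ``homology_map`` relates region_a gene ids to region_b gene ids (pairs
    in either orientation). Order is conserved when the region_b positions
    of the shared genes, read in region_a order, are strictly monotone in
    either direction.
    """
    if not region_a.flanking or not region_b.flanking:
        raise ValueError("empty synteny region")
    partners: dict[str, str] = {}
    b_ids = set(region_b.gene_ids)
    a_ids = set(region_a.gene_ids)
    for x, y in homology_map:
        if x in a_ids and y in b_ids:
            partners.setdefault(x, y)
        elif y in a_ids and x in b_ids:
            partners.setdefault(y, x)

    b_pos = {g: i for i, g in enumerate(region_b.gene_ids)}
    table = []
    shared_positions = []
    for g in region_a.gene_ids:
        partner = partners.get(g)
        table.append({"gene_a": g, "gene_b": partner if partner else "absent"})
        if partner is not None and partner in b_pos:
            shared_positions.append(b_pos[partner])
    return {
        "shared": len(shared_positions),
        "order_conserved": _is_monotone(shared_positions) and len(shared_positions) > 0,
        "table": pd.DataFrame(table),
    }


def landmark_distance_check(
    landmark_genes: Sequence[CandidateGene],
    family_genes: Sequence[CandidateGene],
    far_threshold: int = 50_000_000,
) -> list[dict]:
    """Per landmark: co-scaffold family genes, nearest distance, is_far flag.

    ``is_far`` is true when no family gene sits within ``far_threshold`` bp
    of the landmark on its scaffold — i.e. the scaffold holds "no or
    substantially distant" family genes.
    """
    reports = []
    for lm in landmark_genes:
        co = [g for g in family_genes if g.scaffold == lm.scaffold]
        dists = [round(abs(g.midpoint - lm.midpoint)) for g in co]
        nearest = min(dists) if dists else None
        reports.append(
            {
                "landmark": lm.gene_id,
                "scaffold": lm.scaffold,
                "co_scaffold_family_genes": sorted(g.gene_id for g in co),
                "nearest_distance_bp": nearest,
                "is_far": nearest is None or nearest > far_threshold,
            }
        )
    return reports


def read_region_table(path) -> dict[tuple[str, str], SyntenyRegion]:
    """Read region TSV (species, anchor, gene_id, scaffold, start, end, strand).

    Returns regions keyed by (species, anchor), genes ordered by start.
    """
    df = pd.read_csv(path, sep="\t")
    regions: dict[tuple[str, str], SyntenyRegion] = {}
    for (species, anchor), grp in df.groupby(["species", "anchor"]):
        grp = grp.sort_values("start")
        regions[(str(species), str(anchor))] = SyntenyRegion(
            species=str(species),
            anchor_gene=str(anchor),
            flanking=tuple(
                (str(r.gene_id), str(r.strand)) for r in grp.itertuples(index=False)
            ),
        )
    return regions
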