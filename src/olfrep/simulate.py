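"""Ground-truthed gene-family simulator: tandem duplication with dispersal.

The generator emulates the expansion of a chemosensory receptor family in a
draft genome assembly. Starting from ``n_founders`` genes on distinct
scaffolds, each duplication event copies a uniformly chosen gene: with
probability ``p_tandem`` the copy lands on the parent's scaffold at the
nearest free position within 5-50 kb (tandem duplication, the mechanism
behind paralog clusters), otherwise it disperses to a uniformly chosen
scaffold and position (chromosomal rearrangement). Every event is recorded
as a bifurcation in the true gene tree with exponential branch lengths, so
founder lineages are true clades; lineage nodes with >= 5 leaves receive
high bootstrap-like supports, every other internal node a low support,
which makes the bootstrap-gated clade rule recover the founder lineages
exactly.

The output bundles everything the downstream pipeline consumes — newick
tree, candidate coordinates, forward/reciprocal/genome-level hit tables
(family members pass every screening threshold, decoys fail), domain
envelopes, and an organ-biased log-normal TPM matrix — together with the
ground truth, so each pipeline stage can be tested against known answers
with no external data.

All randomness flows through one ``numpy`` Generator keyed by ``seed``;
identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .distribution import ProximitySummary, build_pair_table, proximity_summary
from .expression import ORGANS
from .phylo import ELSE_LABEL, SupportTree
from .screen import CandidateGene, DomainAnnotation, HitRecord, OUTFMT6_COLUMNS

__all__ = [
    "SimConfig",
    "SimTruth",
    "PlacementError",
    "simulate_repertoire",
    "true_clade_assignment",
    "measure_truth",
]

GENE_LEN = 1_000  # bp footprint of every simulated gene


class PlacementError(RuntimeError):
    """No free position for a new gene copy; use a larger scaffold_len."""


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    Defaults mirror a mid-sized chemosensory repertoire: three founder
    lineages expanded to 48 genes (the size of the hagfish OR family, with
    its three major clades), a strong tandem bias, and 5-50 kb tandem
    offsets so paralog clusters span tens of kilobases on ~100 Mbp
    scaffolds. Expression: the focal organ draws TPM from
    LogNormal(mu_hi, sigma) (median ~e^3 ≈ 20 TPM) and the eight other
    organs from LogNormal(mu_lo, sigma) (median ~0.14 TPM).
    """

    n_founders: int = 3
    n_events: int = 45
    p_tandem: float = 0.85
    tandem_offset_range: tuple[int, int] = (5_000, 50_000)
    n_scaffolds: int = 10
    scaffold_len: int = 100_000_000
    branch_rate: float = 0.1
    support_hi: tuple[int, int] = (90, 100)
    support_lo: tuple[int, int] = (20, 60)
    expr_mu_hi: float = 3.0
    expr_mu_lo: float = -2.0
    expr_sigma: float = 1.0
    n_decoys: int = 20
    family: str = "OR"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_tandem <= 1.0):
            raise ValueError("p_tandem must lie in [0, 1]")
        lo, hi = self.tandem_offset_range
        if not (0 < lo <= hi):
            raise ValueError("invalid tandem_offset_range")
        if self.n_founders < 1 or self.n_scaffolds < self.n_founders:
            raise ValueError("need 1 <= n_founders <= n_scaffolds")
        if self.support_lo[1] > self.support_hi[0]:
            raise ValueError("support ranges must not overlap")


class _Node:
    __slots__ = ("name", "children", "length", "support")

    def __init__(self, name=None, length=0.0):
        self.name = name
        self.children: list[_Node] = []
        self.length = length
        self.support: int | None = None

    def newick(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c.newick() for c in self.children)
        sup = "" if self.support is None else str(self.support)
        return f"({inner}){sup}:{self.length:.6f}"


@dataclass
class SimTruth:
    """Everything the simulator knows: inputs for the pipeline plus truth."""

    config: SimConfig
    tree: SupportTree
    founder_lineage: dict[str, str]
    genes: list[CandidateGene]
    forward_hits: list[HitRecord]
    reverse_hits: list[HitRecord]
    genome_hits: list[HitRecord]
    domains: list[DomainAnnotation]
    expression: pd.DataFrame
    scaffold_lengths: dict[str, int]
    known_family_ids: set[str]
    decoy_ids: list[str]
    provenance: list[dict] = field(default_factory=list)

    @property
    def member_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def write(self, outdir) -> None:
        """Emit every standard input format the pipeline reads."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.tree.write_newick(outdir / "tree.nwk")
        _write_outfmt6(self.forward_hits, outdir / "forward_hits.tsv")
        _write_outfmt6(self.reverse_hits, outdir / "reverse_hits.tsv")
        _write_outfmt6(self.genome_hits, outdir / "genome_hits.tsv", genomic=True)
        pd.DataFrame(
            {
                "seq_id": [d.seq_id for d in self.domains],
                "domain_name": [d.domain_name for d in self.domains],
                "env_start": [d.env_start for d in self.domains],
                "env_end": [d.env_end for d in self.domains],
                "score": [d.score for d in self.domains],
            }
        ).to_csv(outdir / "domains.tsv", sep="\t", index=False)
        from .screen import write_candidate_table

        write_candidate_table(self.genes, outdir / "coordinates.tsv")
        self.expression.to_csv(outdir / "expression.tsv", sep="\t")
        pd.DataFrame(
            sorted(self.scaffold_lengths.items()), columns=["scaffold", "length"]
        ).to_csv(outdir / "scaffold_lengths.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "gene_id": self.member_ids,
                "founder_lineage": [self.founder_lineage[g] for g in self.member_ids],
                "scaffold": [g.scaffold for g in self.genes],
                "position": [g.start for g in self.genes],
            }
        ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
        with open(outdir / "known_family_ids.txt", "w") as fh:
            for kid in sorted(self.known_family_ids):
                fh.write(kid + "\n")
        with open(outdir / "peptides.fasta", "w") as fh:
            for gid in self.member_ids + self.decoy_ids:
                fh.write(f">{gid}\n" + "M" + "A" * 348 + "\n")
        with open(outdir / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=1)


def _write_outfmt6(hits, path, genomic: bool = False) -> None:
    rows = []
    for h in hits:
        if genomic:
            if h.subject_strand == "+":
                sstart, send = h.subject_start + 1, h.subject_end
            else:
                sstart, send = h.subject_end, h.subject_start + 1
        else:
            sstart, send = 1, h.align_len
        rows.append(
            [
                h.query_id, h.subject_id, h.percent_identity, h.align_len,
                0, 0, 1, h.align_len, sstart, send, h.evalue, h.bitscore,
            ]
        )
    pd.DataFrame(rows, columns=OUTFMT6_COLUMNS).to_csv(
        path, sep="\t", index=False, header=False
    )


class _ScaffoldMap:
    """Occupied-interval bookkeeping with nearest-free-slot queries."""

    def __init__(self, length: int):
        self.length = length
        self.starts: list[int] = []  # sorted gene starts (all genes GENE_LEN long)

    def _free(self, start: int) -> bool:
        if start < 0 or start + GENE_LEN > self.length:
            return False
        i = bisect.bisect_left(self.starts, start)
        if i < len(self.starts) and self.starts[i] < start + GENE_LEN:
            return False
        if i > 0 and self.starts[i - 1] + GENE_LEN > start:
            return False
        return True

    def nearest_free_in(self, lo: int, hi: int, from_low: bool) -> int | None:
        """Nearest free start within [lo, hi], scanning from one end.

        Candidate starts are the window edge and the ends of occupied
        intervals, so the nearest admissible slot is found exactly.
        """
        cands = [lo] if from_low else [hi]
        i = bisect.bisect_left(self.starts, lo - GENE_LEN)
        while i < len(self.starts) and self.starts[i] <= hi + GENE_LEN:
            cands.append(self.starts[i] + GENE_LEN)  # just past an occupied gene
            cands.append(self.starts[i] - GENE_LEN)  # just before one
            i += 1
        cands = [c for c in cands if lo <= c <= hi and self._free(c)]
        if not cands:
            return None
        return min(cands) if from_low else max(cands)

    def place(self, start: int) -> None:
        bisect.insort(self.starts, start)


def simulate_repertoire(config: SimConfig) -> SimTruth:
    """Run the duplication process and emit a fully ground-truthed dataset."""
    rng = np.random.default_rng(config.seed)
    scaffolds = [f"scaf{i + 1:02d}" for i in range(config.n_scaffolds)]
    scaffold_lengths = {s: config.scaffold_len for s in scaffolds}
    maps = {s: _ScaffoldMap(config.scaffold_len) for s in scaffolds}

    n_total = config.n_founders + config.n_events
    gene_ids = [f"g{i + 1:03d}" for i in range(n_total)]

    # founders on distinct scaffolds
    founder_scafs = list(rng.choice(config.n_scaffolds, size=config.n_founders,
                                    replace=False))
    placement: dict[str, tuple[str, int, str]] = {}  # gene -> (scaffold, start, strand)
    founder_lineage: dict[str, str] = {}
    leaf_nodes: dict[str, _Node] = {}
    root = _Node()
    provenance: list[dict] = []

    for i in range(config.n_founders):
        gid = gene_ids[i]
        scaf = scaffolds[int(founder_scafs[i])]
        start = int(rng.integers(0, config.scaffold_len - GENE_LEN))
        while not maps[scaf]._free(start):
            start = int(rng.integers(0, config.scaffold_len - GENE_LEN))
        maps[scaf].place(start)
        strand = "+" if rng.random() < 0.5 else "-"
        placement[gid] = (scaf, start, strand)
        founder_lineage[gid] = f"L{i + 1}"
        node = _Node(name=gid, length=float(rng.exponential(config.branch_rate)))
        leaf_nodes[gid] = node
        root.children.append(node)
        provenance.append({"event": "found", "gene": gid, "scaffold": scaf,
                           "position": start})

    lineage_roots = {f"L{i + 1}": root.children[i] for i in range(config.n_founders)}

    extant = list(gene_ids[: config.n_founders])
    next_idx = config.n_founders
    lo_off, hi_off = config.tandem_offset_range
    for ev in range(config.n_events):
        parent = extant[int(rng.integers(len(extant)))]
        child = gene_ids[next_idx]
        next_idx += 1
        pscaf, pstart, pstrand = placement[parent]
        tandem = rng.random() < config.p_tandem
        if tandem:
            smap = maps[pscaf]
            # downstream window first, then upstream, nearest slot each time
            start = smap.nearest_free_in(pstart + lo_off, pstart + hi_off, from_low=True)
            if start is None:
                start = smap.nearest_free_in(pstart - hi_off, pstart - lo_off,
                                             from_low=False)
            if start is None:
                raise PlacementError(
                    f"no free tandem slot near {parent} on {pscaf}; "
                    "increase scaffold_len or tandem_offset_range"
                )
            scaf, strand = pscaf, pstrand
        else:
            for _ in range(1000):
                scaf = scaffolds[int(rng.integers(config.n_scaffolds))]
                start = int(rng.integers(0, config.scaffold_len - GENE_LEN))
                if maps[scaf]._free(start):
                    break
            else:
                raise PlacementError(
                    "no free position for dispersed copy; increase scaffold_len"
                )
            strand = "+" if rng.random() < 0.5 else "-"
        maps[scaf].place(start)
        placement[child] = (scaf, start, strand)
        founder_lineage[child] = founder_lineage[parent]

        # bifurcation: the parent's leaf becomes an internal node
        pnode = leaf_nodes[parent]
        new_parent_leaf = _Node(name=parent,
                                length=float(rng.exponential(config.branch_rate)))
        child_leaf = _Node(name=child,
                           length=float(rng.exponential(config.branch_rate)))
        pnode.name = None
        pnode.children = [new_parent_leaf, child_leaf]
        if pnode in lineage_roots.values():
            pass  # lineage root may itself bifurcate; it stays the lineage node
        leaf_nodes[parent] = new_parent_leaf
        leaf_nodes[child] = child_leaf
        extant.append(child)
        provenance.append(
            {"event": "duplication", "parent": parent, "gene": child,
             "mode": "tandem" if tandem else "dispersal",
             "scaffold": scaf, "position": start}
        )

    # supports: founder-lineage nodes with >= 5 leaves draw from support_hi,
    # every other internal node from support_lo
    lineage_sizes = {
        lin: sum(1 for g in founder_lineage.values() if g == lin)
        for lin in {f"L{i + 1}" for i in range(config.n_founders)}
    }

    def assign_supports(node: _Node) -> None:
        for c in node.children:
            assign_supports(c)
        if node.children:
            node.support = int(rng.integers(config.support_lo[0],
                                            config.support_lo[1] + 1))

    tree_root = root if len(root.children) > 1 else root.children[0]
    assign_supports(tree_root)
    for lin, node in lineage_roots.items():
        if node.children and lineage_sizes[lin] >= 5:
            node.support = int(rng.integers(config.support_hi[0],
                                            config.support_hi[1] + 1))
    tree_root.support = None

    newick = tree_root.newick() + ";"
    tree = SupportTree.read_newick(newick)

    genes = [
        CandidateGene(
            gene_id=g, family=config.family, source="gene_model",
            scaffold=placement[g][0], start=placement[g][1],
            end=placement[g][1] + GENE_LEN, strand=placement[g][2],
        )
        for g in gene_ids
    ]

    # --- hit, domain and expression tables ---------------------------------
    known_family_ids = {f"fam_ref_{k}" for k in range(1, 6)}
    fam_refs = sorted(known_family_ids)
    decoy_ids = [f"decoy{k + 1:03d}" for k in range(config.n_decoys)]

    forward, reverse, genome_hits, domains = [], [], [], []
    for g in gene_ids:
        scaf, start, strand = placement[g]
        ev = 10.0 ** rng.uniform(-80, -50)
        alen = int(rng.integers(300, 401))
        forward.append(HitRecord(
            query_id=g, subject_id=f"query_ref_{int(rng.integers(1, 5))}",
            evalue=ev, align_len=alen,
            percent_identity=float(np.round(rng.uniform(40, 70), 1)),
            bitscore=float(np.round(rng.uniform(400, 800), 1)),
        ))
        reverse.append(HitRecord(
            query_id=g, subject_id=fam_refs[int(rng.integers(len(fam_refs)))],
            evalue=10.0 ** rng.uniform(-80, -50), align_len=int(rng.integers(300, 401)),
            bitscore=float(np.round(rng.uniform(400, 800), 1)),
        ))
        # two split HSPs per gene exercise the locus joiner
        genome_hits.append(HitRecord(
            query_id=f"query_ref_1", subject_id=scaf,
            evalue=10.0 ** rng.uniform(-80, -50), align_len=140,
            subject_scaffold=scaf, subject_start=start, subject_end=start + 400,
            subject_strand=strand, bitscore=300.0,
        ))
        genome_hits.append(HitRecord(
            query_id=f"query_ref_1", subject_id=scaf,
            evalue=10.0 ** rng.uniform(-80, -50), align_len=130,
            subject_scaffold=scaf, subject_start=start + 600,
            subject_end=start + GENE_LEN, subject_strand=strand, bitscore=280.0,
        ))
        cov = int(rng.integers(220, 321))
        domains.append(DomainAnnotation(seq_id=g, domain_name="TM7_3",
                                        env_start=20, env_end=20 + cov - 1,
                                        score=float(np.round(rng.uniform(100, 300), 1))))

    for i, d in enumerate(decoy_ids):
        if rng.random() < 0.5:
            forward.append(HitRecord(
                query_id=d, subject_id="query_ref_1",
                evalue=float(np.round(10.0 ** rng.uniform(-2, 1), 6)),
                align_len=int(rng.integers(260, 400)), bitscore=50.0,
            ))
        else:
            forward.append(HitRecord(
                query_id=d, subject_id="query_ref_1",
                evalue=10.0 ** rng.uniform(-40, -20),
                align_len=int(rng.integers(50, 151)), bitscore=80.0,
            ))
        # best reverse hit is an unrelated GPCR, a family ref only second-best
        reverse.append(HitRecord(
            query_id=d, subject_id=f"unrelated_gpcr_{i + 1}",
            evalue=1e-60, align_len=320, bitscore=500.0,
        ))
        reverse.append(HitRecord(
            query_id=d, subject_id=fam_refs[0],
            evalue=1e-20, align_len=300, bitscore=200.0,
        ))
        if rng.random() < 0.5:
            # a failing domain record: for coverage-screened families (V2R)
            # a short TM7_3 envelope, otherwise a non-7TM domain entirely
            if config.family in ("V2R", "CaSR", "V2R-like"):
                cov = int(rng.integers(30, 151))
                domains.append(DomainAnnotation(seq_id=d, domain_name="TM7_3",
                                                env_start=10, env_end=10 + cov - 1,
                                                score=20.0))
            else:
                domains.append(DomainAnnotation(seq_id=d, domain_name="Pkinase",
                                                env_start=10,
                                                env_end=10 + int(rng.integers(50, 200)),
                                                score=20.0))

    tpm = np.empty((n_total, len(ORGANS)))
    for i, g in enumerate(gene_ids):
        for j, organ in enumerate(ORGANS):
            mu = config.expr_mu_hi if organ == "olfactory organ" else config.expr_mu_lo
            tpm[i, j] = rng.lognormal(mean=mu, sigma=config.expr_sigma)
    expression = pd.DataFrame(np.round(tpm, 4), index=gene_ids, columns=list(ORGANS))
    expression.index.name = "gene_id"

    return SimTruth(
        config=config, tree=tree, founder_lineage=founder_lineage, genes=genes,
        forward_hits=forward, reverse_hits=reverse, genome_hits=genome_hits,
        domains=domains, expression=expression, scaffold_lengths=scaffold_lengths,
        known_family_ids=known_family_ids, decoy_ids=decoy_ids,
        provenance=provenance,
    )


def true_clade_assignment(sim: SimTruth, min_size: int = 5) -> dict[str, str]:
    """Clade labels from the true founder lineages (>= min_size members);
    genes from smaller lineages are Else, mirroring the inference-side rule."""
    sizes: dict[str, int] = {}
    for lin in sim.founder_lineage.values():
        sizes[lin] = sizes.get(lin, 0) + 1
    big = sorted((l for l, s in sizes.items() if s >= min_size),
                 key=lambda l: (-sizes[l], l))
    label = {lin: f"Clade{i + 1}" for i, lin in enumerate(big)}
    return {
        g: label.get(lin, ELSE_LABEL) for g, lin in sim.founder_lineage.items()
    }


def measure_truth(sim: SimTruth, threshold_bp: int = 10_000_000) -> ProximitySummary:
    """Proximity summary computed from true clades and true coordinates."""
    clades = true_clade_assignment(sim)
    pairs = build_pair_table(sim.genes, clades, sim.tree)
    return proximity_summary(pairs, threshold_bp)
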