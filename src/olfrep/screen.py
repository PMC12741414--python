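"""Candidate-gene screening from homology and domain hit tables.

The screen turns raw BLAST-style alignment hits and Pfam-style domain hits
into a deduplicated set of candidate chemosensory receptor genes:

1. forward-hit filtering against E-value / alignment-length thresholds
   (separate E-value cutoffs for searches against gene models vs. the
   genome assembly);
2. reciprocal confirmation — the best reverse hit of a candidate must fall
   inside a curated set of known family members;
3. a domain filter — any seven-transmembrane domain for OR/V1R/TAAR
   candidates, or >= 200 aa of cumulative TM7_3 coverage for V2Rs;
4. joining of split TBLASTN loci on the genome (same scaffold and strand,
   inter-hit gap under 100 kb) with 900 bp of flanking sequence; and
5. reconciliation of gene-model candidates with genome-predicted loci.

All E-value thresholds are strict (``<``); length/coverage thresholds are
non-strict (``>=``). A multi-HSP sequence passes if any single hit passes.
Internal coordinates are 0-based half-open; TSV/BED writers convert to each
format's native convention.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

__all__ = [
    "HitRecord",
    "DomainAnnotation",
    "ScreenThresholds",
    "CandidateGene",
    "MergedLocus",
    "filter_forward_hits",
    "reciprocal_confirm",
    "apply_domain_filter",
    "join_split_loci",
    "reconcile_candidates",
    "read_blast_tabular",
    "read_domain_table",
    "write_candidate_table",
    "write_locus_bed",
]

#: families screened with the "any 7tm-class domain" rule
_ANY_7TM_FAMILIES = {"OR", "V1R", "TAAR"}
#: families screened with the cumulative TM7_3 coverage rule
_COVERAGE_FAMILIES = {"V2R", "CaSR", "V2R-like"}


@dataclass(frozen=True)
class HitRecord:
    """One pairwise alignment hit (a single HSP)."""

    query_id: str
    subject_id: str
    evalue: float
    align_len: int
    percent_identity: float = 0.0
    subject_scaffold: str = ""
    subject_start: int = 0
    subject_end: int = 0
    subject_strand: str = "n/a"
    bitscore: float = 0.0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative E-value for {self.query_id}: {self.evalue}")
        if self.align_len < 1:
            raise ValueError(
                f"alignment length must be >= 1 for {self.query_id}: {self.align_len}"
            )
        if self.subject_scaffold and self.subject_start > self.subject_end:
            # normalise minus-strand coordinates to start <= end
            lo, hi = self.subject_end, self.subject_start
            object.__setattr__(self, "subject_start", lo)
            object.__setattr__(self, "subject_end", hi)

    @property
    def has_coordinates(self) -> bool:
        return bool(self.subject_scaffold)


@dataclass(frozen=True)
class DomainAnnotation:
    """One domain envelope on a peptide (HMMER domtblout-like)."""

    seq_id: str
    domain_name: str
    env_start: int
    env_end: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.env_start > self.env_end:
            raise ValueError(
                f"domain envelope reversed for {self.seq_id}: "
                f"{self.env_start} > {self.env_end}"
            )

    @property
    def coverage(self) -> int:
        return self.env_end - self.env_start + 1


@dataclass(frozen=True)
class ScreenThresholds:
    """Screening cutoffs.

    Defaults follow the published search protocol: E < 1e-3 and >= 250 aa
    against gene models, E < 1e-10 and >= 250 aa against the genome,
    >= 200 aa of TM7_3 coverage for V2Rs, < 100 kb gap for joining split
    TBLASTN loci, 900 bp of flanking sequence.
    """

    max_evalue_proteome: float = 1e-3
    min_alen: int = 250
    max_evalue_genome: float = 1e-10
    min_domain_coverage_v2r: int = 200
    max_join_gap: int = 100_000
    flank: int = 900

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"threshold {f.name} must be positive")


@dataclass(frozen=True)
class CandidateGene:
    """A screened repertoire gene with family label and genomic interval.

    ``start``/``end`` are 0-based half-open.
    """

    gene_id: str
    family: str
    source: Literal["gene_model", "genome_predicted"]
    scaffold: str
    start: int
    end: int
    strand: Literal["+", "-"]
    peptide_len: int = 0
    has_nterm_domain: bool = False
    flag: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty interval for {self.gene_id}: [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand for {self.gene_id}: {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "CandidateGene") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.strand == other.strand
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class MergedLocus:
    """A genomic locus merged from split alignment hits, flanks applied."""

    scaffold: str
    start: int
    end: int
    strand: str
    member_hits: tuple[str, ...]


def _hit_passes(hit: HitRecord, max_evalue: float, min_alen: int) -> bool:
    return hit.evalue < max_evalue and hit.align_len >= min_alen


def filter_forward_hits(
    hits: Iterable[HitRecord],
    thresholds: ScreenThresholds | None = None,
    mode: Literal["proteome", "genome"] = "proteome",
) -> set[str]:
    """Return query ids with at least one hit passing the forward filter.

    ``mode`` selects the E-value cutoff: ``proteome`` (gene-model BLASTP,
    E < 1e-3) or ``genome`` (TBLASTN, E < 1e-10); the alignment-length
    floor (>= 250 aa) is shared. Evaluated per hit: a sequence survives if
    any of its HSPs passes.
    """
    thresholds = thresholds or ScreenThresholds()
    if mode == "proteome":
        max_evalue = thresholds.max_evalue_proteome
    elif mode == "genome":
        max_evalue = thresholds.max_evalue_genome
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return {
        h.query_id for h in hits if _hit_passes(h, max_evalue, thresholds.min_alen)
    }


def best_hit(hits: Sequence[HitRecord]) -> HitRecord:
    """Best hit by minimum E-value, then maximum bitscore, then subject id."""
    if not hits:
        raise ValueError("no hits to rank")
    return min(hits, key=lambda h: (h.evalue, -h.bitscore, h.subject_id))


def reciprocal_confirm(
    candidate_ids: Iterable[str],
    reverse_hits: Iterable[HitRecord],
    known_family_ids: set[str],
    thresholds: ScreenThresholds | None = None,
) -> set[str]:
    """Confirm candidates whose best reverse hit lands in the family panel.

    The reverse search plays the role of the reciprocal BLASTP against
    outgroup proteomes: a candidate is kept iff its best passing reverse
    hit (min E-value; ties broken by max bitscore, then lexicographic
    subject id) is a known member of the expected family. Candidates with
    no passing reverse hit are rejected.
    """
    if not known_family_ids:
        raise ValueError("known_family_ids must be non-empty")
    thresholds = thresholds or ScreenThresholds()
    by_query: dict[str, list[HitRecord]] = {}
    for h in reverse_hits:
        if _hit_passes(h, thresholds.max_evalue_proteome, thresholds.min_alen):
            by_query.setdefault(h.query_id, []).append(h)
    confirmed = set()
    for cid in candidate_ids:
        hits = by_query.get(cid)
        if hits and best_hit(hits).subject_id in known_family_ids:
            confirmed.add(cid)
    return confirmed


def _union_coverage(envelopes: Iterable[tuple[int, int]]) -> int:
    """Total length covered by the union of closed aa intervals."""
    ivals = sorted(envelopes)
    total = 0
    cur_start: int | None = None
    cur_end = -1
    for s, e in ivals:
        if cur_start is None or s > cur_end + 1:
            if cur_start is not None:
                total += cur_end - cur_start + 1
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_start is not None:
        total += cur_end - cur_start + 1
    return total


def apply_domain_filter(
    candidate_ids: Iterable[str],
    domains: Iterable[DomainAnnotation],
    family: str,
    thresholds: ScreenThresholds | None = None,
) -> set[str]:
    """Keep candidates passing the family's seven-transmembrane domain rule.

    OR/V1R/TAAR: any 7tm-class domain annotation suffices. V2R (and its
    CaSR / V2R-like outparalogs): the union of TM7_3 envelopes must cover
    at least ``min_domain_coverage_v2r`` (default 200) amino acids.
    """
    thresholds = thresholds or ScreenThresholds()
    by_seq: dict[str, list[DomainAnnotation]] = {}
    for d in domains:
        by_seq.setdefault(d.seq_id, []).append(d)

    if family in _ANY_7TM_FAMILIES:
        def passes(seq_id: str) -> bool:
            return any(
                "7tm" in d.domain_name.lower() or "tm7" in d.domain_name.lower()
                for d in by_seq.get(seq_id, ())
            )
    elif family in _COVERAGE_FAMILIES:
        def passes(seq_id: str) -> bool:
            envs = [
                (d.env_start, d.env_end)
                for d in by_seq.get(seq_id, ())
                if d.domain_name == "TM7_3"
            ]
            return bool(envs) and _union_coverage(envs) >= thresholds.min_domain_coverage_v2r
    else:
        raise ValueError(f"unknown family label {family!r}")

    return {cid for cid in candidate_ids if passes(cid)}


def join_split_loci(
    genome_hits: Sequence[HitRecord],
    thresholds: ScreenThresholds | None = None,
    scaffold_lengths: Mapping[str, int] | None = None,
) -> list[MergedLocus]:
    """Merge split TBLASTN hits into loci and apply flanking sequence.

    Hits on the same scaffold and strand whose nearest-end gap is strictly
    below ``max_join_gap`` are merged transitively; each merged locus is
    extended by ``flank`` bp on both sides, clipped at 0 and at the
    scaffold length when known. Because genes split across exons produce
    several HSPs, this recovers one locus per gene for downstream coding
    prediction.
    """
    thresholds = thresholds or ScreenThresholds()
    for h in genome_hits:
        if not h.subject_scaffold or h.subject_strand not in ("+", "-"):
            raise ValueError(
                f"hit {h.query_id}->{h.subject_id} lacks scaffold or strand"
            )
    groups: dict[tuple[str, str], list[HitRecord]] = {}
    for h in genome_hits:
        groups.setdefault((h.subject_scaffold, h.subject_strand), []).append(h)

    loci: list[MergedLocus] = []
    for (scaffold, strand), hits in sorted(groups.items()):
        hits.sort(key=lambda h: (h.subject_start, h.subject_end, h.query_id))
        cluster: list[HitRecord] = []
        cluster_end = -1

        def flush() -> None:
            if not cluster:
                return
            start = min(h.subject_start for h in cluster) - thresholds.flank
            end = max(h.subject_end for h in cluster) + thresholds.flank
            start = max(start, 0)
            if scaffold_lengths and scaffold in scaffold_lengths:
                end = min(end, scaffold_lengths[scaffold])
            loci.append(
                MergedLocus(
                    scaffold=scaffold,
                    start=start,
                    end=end,
                    strand=strand,
                    member_hits=tuple(h.query_id for h in cluster),
                )
            )

        for h in hits:
            gap = h.subject_start - cluster_end
            if cluster and gap < thresholds.max_join_gap:
                cluster.append(h)
                cluster_end = max(cluster_end, h.subject_end)
            else:
                flush()
                cluster = [h]
                cluster_end = h.subject_end
        flush()
    loci.sort(key=lambda l: (l.scaffold, l.start, l.strand))
    return loci


def _peptide_identity(a: str, b: str) -> float:
    """Percent identity over the shorter sequence, by global alignment."""
    import edlib

    if not a or not b:
        return 0.0
    res = edlib.align(a, b, task="path", mode="NW")
    matches = 0
    for n, op in _cigar_ops(res["cigar"]):
        if op == "=":
            matches += n
    return 100.0 * matches / min(len(a), len(b))


def _cigar_ops(cigar: str):
    num = ""
    for c in cigar:
        if c.isdigit():
            num += c
        else:
            yield int(num), c
            num = ""


def reconcile_candidates(
    model_set: Sequence[CandidateGene],
    genome_set: Sequence[CandidateGene],
    peptides: Mapping[str, str] | None = None,
    min_identity: float = 99.0,
) -> list[CandidateGene]:
    """Unify gene-model and genome-predicted candidates with provenance flags.

    A genome-predicted locus is ``matched`` to a gene-model candidate when
    their intervals overlap by >= 1 bp on the same strand, or — when the
    model entry carries no usable coordinates — when peptide identity over
    the shorter sequence is >= ``min_identity``. Matched pairs collapse to
    one gene keeping the gene-model id; the rest are flagged ``model_only``
    or ``genome_only``.
    """
    ids = [g.gene_id for g in model_set] + [g.gene_id for g in genome_set]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate gene_ids across inputs: {sorted(dupes)}")

    matched_genome: set[str] = set()
    out: list[CandidateGene] = []
    for m in model_set:
        partner = None
        for g in genome_set:
            if g.gene_id in matched_genome:
                continue
            if m.scaffold and g.overlaps(m):
                partner = g
                break
            if (not m.scaffold) and peptides is not None:
                pid = _peptide_identity(
                    peptides.get(m.gene_id, ""), peptides.get(g.gene_id, "")
                )
                if pid >= min_identity:
                    partner = g
                    break
        if partner is not None:
            matched_genome.add(partner.gene_id)
            out.append(dataclasses.replace(m, flag="matched"))
        else:
            out.append(dataclasses.replace(m, flag="model_only"))
    for g in genome_set:
        if g.gene_id not in matched_genome:
            out.append(dataclasses.replace(g, flag="genome_only"))
    return out


# ---------------------------------------------------------------------------
# file interfaces

#: BLAST -outfmt 6 default column order
OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_tabular(path, with_coordinates: bool = False) -> list[HitRecord]:
    """Read BLAST ``-outfmt 6`` TSV into :class:`HitRecord` objects.

    With ``with_coordinates=True`` the subject id is interpreted as a
    scaffold name and sstart/send as genomic coordinates; sstart > send
    encodes the minus strand (TBLASTN convention).
    """
    df = pd.read_csv(path, sep="\t", names=OUTFMT6_COLUMNS, comment="#")
    records = []
    for row in df.itertuples(index=False):
        if with_coordinates:
            strand = "+" if row.sstart <= row.send else "-"
            lo, hi = sorted((int(row.sstart), int(row.send)))
            rec = HitRecord(
                query_id=str(row.qseqid), subject_id=str(row.sseqid),
                evalue=float(row.evalue), align_len=int(row.length),
                percent_identity=float(row.pident),
                subject_scaffold=str(row.sseqid),
                subject_start=lo - 1, subject_end=hi,  # to 0-based half-open
                subject_strand=strand, bitscore=float(row.bitscore),
            )
        else:
            rec = HitRecord(
                query_id=str(row.qseqid), subject_id=str(row.sseqid),
                evalue=float(row.evalue), align_len=int(row.length),
                percent_identity=float(row.pident), bitscore=float(row.bitscore),
            )
        records.append(rec)
    return records


def read_domain_table(path) -> list[DomainAnnotation]:
    """Read the simplified domain-hit TSV (seq_id, domain_name, env_start, env_end, score)."""
    df = pd.read_csv(path, sep="\t")
    return [
        DomainAnnotation(
            seq_id=str(r.seq_id), domain_name=str(r.domain_name),
            env_start=int(r.env_start), env_end=int(r.env_end), score=float(r.score),
        )
        for r in df.itertuples(index=False)
    ]


def read_candidate_table(path) -> list[CandidateGene]:
    """Read a candidate table written by :func:`write_candidate_table`."""
    df = pd.read_csv(path, sep="\t")
    return [
        CandidateGene(
            gene_id=str(r.gene_id), family=str(r.family), source=str(r.source),
            scaffold=str(r.scaffold), start=int(r.start) - 1, end=int(r.end),
            strand=str(r.strand), flag="" if pd.isna(r.flag) else str(r.flag),
        )
        for r in df.itertuples(index=False)
    ]


def write_candidate_table(candidates: Sequence[CandidateGene], path) -> None:
    """Write candidates as TSV with 1-based inclusive coordinates."""
    pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in candidates],
            "family": [c.family for c in candidates],
            "source": [c.source for c in candidates],
            "scaffold": [c.scaffold for c in candidates],
            "start": [c.start + 1 for c in candidates],
            "end": [c.end for c in candidates],
            "strand": [c.strand for c in candidates],
            "flag": [c.flag for c in candidates],
        }
    ).to_csv(path, sep="\t", index=False)


def write_locus_bed(loci: Sequence[MergedLocus], path) -> None:
    """Write merged loci as 6-column BED (0-based half-open)."""
    with open(path, "w") as fh:
        for i, l in enumerate(loci):
            name = f"locus{i + 1}|" + ",".join(l.member_hits)
            fh.write(f"{l.scaffold}\t{l.start}\t{l.end}\t{name}\t0\t{l.strand}\n")
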