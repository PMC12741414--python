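"""End-to-end orchestration: screen → clades → distribution → expression.

The pipeline consumes a YAML config naming the input tables for one gene
family, runs each stage in order, writes stage outputs as TSV sidecars and
a single machine-readable JSON report whose counts mirror the narrative of
a repertoire study: candidates by provenance, clade sizes, intraclade /
interclade proximity fractions, top-scaffold concentration, and
organ-specificity counts. Stage-by-stage input/output counts are logged so
filter attrition is auditable.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import distribution, expression, phylo, screen

logger = logging.getLogger("olfrep")

REPORT_VERSION = 1


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    """Paths and parameters for one family's analysis."""

    family: str
    forward_hits: Path
    reverse_hits: Path
    domains: Path
    tree: Path
    coordinates: Path
    scaffold_lengths: Path
    known_family_ids: list[str]
    outdir: Path
    genome_hits: Path | None = None
    expression: Path | None = None
    outgroup: list[str] = field(default_factory=list)
    mode: str = "proteome"
    thresholds: screen.ScreenThresholds = field(default_factory=screen.ScreenThresholds)
    clade_min_size: int = 5
    clade_min_support: float = 85.0
    proximity_threshold_bp: int = 10_000_000
    focal_organ: str = "olfactory organ"
    expressed_threshold: float = 1.0
    fractional_supports: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any], base: Path = Path(".")) -> "PipelineConfig":
        inputs = raw.get("inputs", {})

        def p(key, required=True):
            v = inputs.get(key)
            if v is None:
                if required:
                    raise ConfigError(f"config missing required input path: {key!r}")
                return None
            path = (base / v).resolve() if not Path(v).is_absolute() else Path(v)
            if not path.exists():
                raise ConfigError(f"input file for {key!r} does not exist: {path}")
            return path

        kfi = raw.get("known_family_ids")
        if isinstance(kfi, str):
            kfi_path = p("known_family_ids") if "known_family_ids" in inputs else (
                (base / kfi) if not Path(kfi).is_absolute() else Path(kfi)
            )
            if not kfi_path.exists():
                raise ConfigError(f"known_family_ids file not found: {kfi_path}")
            kfi = [l.strip() for l in open(kfi_path) if l.strip()]
        if not kfi:
            raise ConfigError("known_family_ids must be provided and non-empty")

        thr = raw.get("thresholds", {})
        clade = raw.get("clade", {})
        expr = raw.get("expression_params", {})
        return cls(
            family=raw.get("family", "OR"),
            forward_hits=p("forward_hits"),
            reverse_hits=p("reverse_hits"),
            domains=p("domains"),
            tree=p("tree"),
            coordinates=p("coordinates"),
            scaffold_lengths=p("scaffold_lengths"),
            genome_hits=p("genome_hits", required=False),
            expression=p("expression", required=False),
            known_family_ids=list(kfi),
            outgroup=list(raw.get("outgroup", []) or []),
            mode=raw.get("mode", "proteome"),
            thresholds=screen.ScreenThresholds(**thr),
            clade_min_size=int(clade.get("min_size", 5)),
            clade_min_support=float(clade.get("min_support", 85)),
            proximity_threshold_bp=int(raw.get("proximity_threshold_bp", 10_000_000)),
            focal_organ=expr.get("focal_organ", "olfactory organ"),
            expressed_threshold=float(expr.get("expressed_threshold", 1.0)),
            fractional_supports=bool(raw.get("fractional_supports", False)),
            outdir=Path(raw.get("outdir", "olfrep_out")),
        )


def summarize_counts(
    candidates: Sequence[screen.CandidateGene],
    clades: Mapping[str, str],
    calls_summary: Mapping[str, int] | None,
) -> dict:
    """Per-family count block; errors on mismatched gene sets."""
    cand_ids = {c.gene_id for c in candidates}
    clade_ids = set(clades)
    if cand_ids != clade_ids:
        diff = sorted(cand_ids ^ clade_ids)
        raise ValueError(f"gene sets differ between candidates and clades: {diff}")
    sizes: dict[str, int] = {}
    for lbl in clades.values():
        sizes[lbl] = sizes.get(lbl, 0) + 1
    block = {
        "n_candidates": len(candidates),
        "by_flag": {
            f: sum(1 for c in candidates if c.flag == f)
            for f in sorted({c.flag for c in candidates})
        },
        "clade_sizes": dict(sorted(sizes.items())),
    }
    assert sum(sizes.values()) == len(candidates)
    if calls_summary is None:
        block["expression"] = "absent"
    else:
        block["expression"] = dict(calls_summary)
    return block


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the analysis report (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report_warnings: list[str] = []

    # --- screen ------------------------------------------------------------
    fwd = screen.read_blast_tabular(config.forward_hits)
    rev = screen.read_blast_tabular(config.reverse_hits)
    survivors = screen.filter_forward_hits(fwd, config.thresholds, mode=config.mode)
    logger.info("screen/forward: %d hits -> %d sequences pass", len(fwd), len(survivors))
    confirmed = screen.reciprocal_confirm(
        survivors, rev, set(config.known_family_ids), config.thresholds
    )
    logger.info("screen/reciprocal: %d -> %d confirmed", len(survivors), len(confirmed))
    doms = screen.read_domain_table(config.domains)
    final_ids = screen.apply_domain_filter(
        confirmed, doms, config.family, config.thresholds
    )
    logger.info("screen/domain: %d -> %d pass %s rule",
                len(confirmed), len(final_ids), config.family)

    all_coords = screen.read_candidate_table(config.coordinates)
    candidates = [c for c in all_coords if c.gene_id in final_ids]
    screen.write_candidate_table(candidates, outdir / "candidates.tsv")

    if config.genome_hits is not None:
        ghits = screen.read_blast_tabular(config.genome_hits, with_coordinates=True)
        scaf_lens = _read_scaffold_lengths(config.scaffold_lengths)
        loci = screen.join_split_loci(ghits, config.thresholds, scaf_lens)
        screen.write_locus_bed(loci, outdir / "merged_loci.bed")
        logger.info("screen/join: %d genome hits -> %d loci", len(ghits), len(loci))

    report: dict[str, Any] = {
        "report_version": REPORT_VERSION,
        "family": config.family,
    }

    if not candidates:
        report_warnings.append("no candidates survived screening")
        report.update(
            {"counts": {"n_candidates": 0}, "proximity": None,
             "scaffold_occupancy": None, "warnings": report_warnings}
        )
        _write_report(report, outdir)
        return report

    # --- clades ------------------------------------------------------------
    tree = phylo.SupportTree.read_newick(
        str(config.tree), fractional_supports=config.fractional_supports
    )
    if config.outgroup:
        tree = phylo.root_with_outgroup(tree, config.outgroup)
    focal = [c.gene_id for c in candidates]
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        clades = phylo.extract_clades(
            tree, focal, min_size=config.clade_min_size,
            min_support=config.clade_min_support,
        )
        report_warnings.extend(str(w.message) for w in wlist)
    phylo.write_clade_table(clades, outdir / "clades.tsv")

    # --- genomic distribution ---------------------------------------------
    if len(candidates) >= 2:
        pairs = distribution.build_pair_table(candidates, clades, tree)
        distribution.write_pair_table(pairs, outdir / "pairs.tsv")
        prox = distribution.proximity_summary(pairs, config.proximity_threshold_bp)
        prox_dict = prox.as_dict()
    else:
        prox_dict = None
        report_warnings.append("fewer than two candidates; no pair statistics")
    scaf_lens = _read_scaffold_lengths(config.scaffold_lengths)
    occ = distribution.scaffold_occupancy(candidates, scaf_lens)
    occ.to_csv(outdir / "scaffold_occupancy.tsv", sep="\t", index=False)

    # --- expression --------------------------------------------------------
    calls_summary = None
    if config.expression is not None:
        mat = expression.read_tpm_matrix(config.expression)
        present = [g for g in focal if g in mat.index]
        absent = sorted(set(focal) - set(present))
        if absent:
            report_warnings.append(
                f"{len(absent)} candidates missing from expression matrix"
            )
        if present:
            calls, calls_summary = expression.classify_specificity(
                mat.loc[present], config.focal_organ, config.expressed_threshold
            )
            expression.write_calls(calls, outdir / "expression_calls.tsv")

    report["counts"] = summarize_counts(candidates, clades, calls_summary)
    report["proximity"] = prox_dict
    report["scaffold_occupancy"] = {
        "top_fraction": round(float(occ.attrs["top_fraction"]), 3),
        "n_scaffolds_occupied": int(len(occ)),
    }
    report["warnings"] = report_warnings
    _write_report(report, outdir)
    return report


def _read_scaffold_lengths(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["scaffold"].astype(str), df["length"].astype(int)))


def _write_report(report: dict, outdir: Path) -> None:
    with open(Path(outdir) / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
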