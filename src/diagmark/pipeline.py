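"""End-to-end authentication workflow over single loci and loci combinations.

For each requested locus combination the pipeline concatenates the loci,
counts informative and species-specific nucleotides per constituent locus
(positions stay locus-local, as diagnostic tables are conventionally
reported), builds distance trees, roots them with the outgroup, and scores
per-taxon monophyly into a discrimination success rate.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .core_io import (Alignment, LocusPartition, TaxonMap, concatenate,
                      read_fasta_alignment, read_taxon_map)
from .diagnostic_sites import (call_indel_events, call_species_specific_snps,
                               classify_columns, count_informative_sites,
                               diagnostic_report, write_report)
from .distances import distance_matrix
from .diversity_scan import call_hotspots, sliding_window_pi, write_hotspots, write_windows
from .phylo import (Tree, bootstrap_support, discrimination_success_rate,
                    nj_tree, root_with_outgroup, upgma_tree, write_newick)

logger = logging.getLogger(__name__)

POLICIES = ("single", "pairs", "triples", "all", "explicit")


@dataclass
class PipelineConfig:
    alignment_paths: dict[str, str]  # locus -> FASTA path
    taxon_map_path: str
    model: str = "t3p"
    gamma_shape: float | None = None
    tree_methods: tuple[str, ...] = ("nj",)
    bootstrap_replicates: int = 0
    seed: int = 0
    combination_policy: str = "all"
    explicit_combinations: tuple[tuple[str, ...], ...] = ()
    scan_window: int = 600
    scan_step: int = 200
    scan_threshold: float = 0.05

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        raw["explicit_combinations"] = tuple(
            tuple(c) for c in raw.get("explicit_combinations", ()))
        raw["tree_methods"] = tuple(raw.get("tree_methods", ("nj",)))
        return cls(**raw)


@dataclass
class CombinationResult:
    loci: tuple[str, ...]
    n_informative: int
    n_species_specific: int
    n_taxa_with_specific: int
    rates: dict[str, float]  # tree method -> discrimination rate (%)
    trees: dict[str, Tree] = field(default_factory=dict)


def combinations(loci: Sequence[str], policy: str,
                 explicit: Sequence[Sequence[str]] = ()) -> list[tuple[str, ...]]:
    """Locus subsets under a policy, in deterministic lexicographic order."""
    if not loci:
        raise ValueError("need at least one locus")
    ordered = sorted(loci)
    if policy == "single":
        return [(l,) for l in ordered]
    if policy == "pairs":
        return list(itertools.combinations(ordered, 2))
    if policy == "triples":
        return list(itertools.combinations(ordered, 3))
    if policy == "all":
        out: list[tuple[str, ...]] = []
        for k in range(1, len(ordered) + 1):
            out.extend(itertools.combinations(ordered, k))
        return out
    if policy == "explicit":
        combos = []
        for combo in explicit:
            unknown = set(combo) - set(ordered)
            if unknown:
                raise ValueError(f"unknown loci in explicit combination: {sorted(unknown)}")
            combos.append(tuple(sorted(combo)))
        return combos
    raise ValueError(f"unknown combination policy {policy!r}; choose from {POLICIES}")


def analyze_combination(
    combo: Sequence[str],
    alignments: dict[str, Alignment],
    taxon_map: TaxonMap,
    model: str = "t3p",
    gamma_shape: float | None = None,
    tree_methods: Sequence[str] = ("nj",),
    bootstrap_replicates: int = 0,
    seed: int = 0,
) -> CombinationResult:
    """Diagnostics, trees and discrimination rate for one loci combination."""
    per_locus = [alignments[l] for l in combo]
    if len(per_locus) == 1:
        combined, partition = per_locus[0], LocusPartition(
            [(per_locus[0].name, 1, per_locus[0].length)])
    else:
        combined, partition = concatenate(per_locus)

    n_informative = 0
    n_specific = 0
    taxa_with = set()
    for aln in per_locus:
        sub = aln.subset(combined.accessions)
        summary = classify_columns(sub, taxon_map)
        n_informative += count_informative_sites(summary)
        snps = call_species_specific_snps(sub, taxon_map)
        indels = [e for e in call_indel_events(sub, taxon_map) if e.taxon]
        n_specific += len(snps) + sum(e.length for e in indels)
        taxa_with |= {s.taxon for s in snps} | {e.taxon for e in indels}

    rates: dict[str, float] = {}
    trees: dict[str, Tree] = {}
    for method in tree_methods:
        if bootstrap_replicates > 0:
            tree = bootstrap_support(combined, taxon_map, model, method,
                                     replicates=bootstrap_replicates,
                                     seed=seed, gamma_shape=gamma_shape)
        else:
            matrix = distance_matrix(combined, model, gamma_shape)
            tree = nj_tree(matrix) if method == "nj" else upgma_tree(matrix)
        outgroup = [a for a in combined.accessions if a in taxon_map.outgroup]
        rooted = root_with_outgroup(tree, outgroup)
        report = discrimination_success_rate(rooted, taxon_map)
        rates[method] = report.rate_percent
        trees[method] = rooted

    return CombinationResult(
        loci=tuple(combo),
        n_informative=n_informative,
        n_species_specific=n_specific,
        n_taxa_with_specific=len(taxa_with),
        rates=rates,
        trees=trees,
    )


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> list[CombinationResult]:
    """Run scan, diagnostics, trees and discrimination over all combinations.

    Writes windows.tsv/hotspots.tsv (per locus), diagnostics.tsv,
    combinations.tsv, Newick trees and run.log under ``out_dir``. A failing
    combination is logged and skipped; the others proceed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "trees").mkdir(exist_ok=True)

    log_handler = logging.FileHandler(out / "run.log")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root_logger = logging.getLogger("diagmark")
    root_logger.addHandler(log_handler)
    root_logger.setLevel(logging.INFO)

    cfg_hash = hashlib.sha256(
        json.dumps(config.__dict__, sort_keys=True, default=str).encode()).hexdigest()[:12]
    logger.info("pipeline start: seed=%d model=%s config_hash=%s",
                config.seed, config.model, cfg_hash)

    try:
        alignments = {locus: read_fasta_alignment(path, name=locus)
                      for locus, path in config.alignment_paths.items()}
        taxon_map = read_taxon_map(config.taxon_map_path)

        # windowed diversity per locus where the window fits
        for locus, aln in alignments.items():
            if aln.length >= config.scan_window:
                windows = sliding_window_pi(aln, config.scan_window, config.scan_step)
                write_windows(windows, out / f"windows.{locus}.tsv")
                write_hotspots(call_hotspots(windows, config.scan_threshold),
                               out / f"hotspots.{locus}.tsv")

        # per-locus diagnostic-site table
        all_rows = []
        for locus, aln in alignments.items():
            snps = call_species_specific_snps(aln, taxon_map)
            indels = call_indel_events(aln, taxon_map)
            all_rows.extend(diagnostic_report(snps, indels, locus=locus, alignment=aln))
        write_report(all_rows, out / "diagnostics.tsv")

        combos = combinations(list(alignments), config.combination_policy,
                              config.explicit_combinations)
        results: list[CombinationResult] = []
        for combo in combos:
            try:
                res = analyze_combination(
                    combo, alignments, taxon_map,
                    model=config.model, gamma_shape=config.gamma_shape,
                    tree_methods=config.tree_methods,
                    bootstrap_replicates=config.bootstrap_replicates,
                    seed=config.seed)
            except Exception:
                logger.exception("combination %s failed; skipping", "+".join(combo))
                continue
            results.append(res)
            for method, tree in res.trees.items():
                write_newick(tree, out / "trees" / f"{'+'.join(combo)}.{method}.nwk")

        with open(out / "combinations.tsv", "w") as fh:
            methods = list(config.tree_methods)
            fh.write("loci\tn_informative\tn_species_specific\tn_taxa_with_specific\t"
                     + "\t".join(f"rate_{m}" for m in methods) + "\n")
            for res in results:
                fh.write("+".join(res.loci)
                         + f"\t{res.n_informative}\t{res.n_species_specific}"
                         + f"\t{res.n_taxa_with_specific}\t"
                         + "\t".join(f"{res.rates[m]:.1f}" for m in methods) + "\n")
        logger.info("pipeline done: %d combinations", len(results))
        return results
    finally:
        root_logger.removeHandler(log_handler)
        log_handler.close()
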