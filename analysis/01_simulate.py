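#!/usr/bin/env python
"""Generate the study datasets: a seeded six-taxon multi-locus simulation and
the deterministic worked-example panel, written under results/data/.

The simulated dataset mirrors the design of a market-sample authentication
study: six ingroup taxa, five accessions each, one outgroup, four chloroplast
amplicon-sized loci, three fixed private SNPs per taxon in the first locus,
low intra-taxon background noise. The worked-example panel plants every
published diagnostic substitution and the 24-bp taxon-private insertion at
their printed alignment positions over a 37-accession panel.
"""

from pathlib import Path

from diagmark.core_io import write_fasta_alignment, write_taxon_map
from diagmark.synthetic_data import (private_snp_config, simulate_dataset,
                                     worked_example_panel)

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 42


def main() -> None:
    sim_dir = OUT / "simulated"
    sim_dir.mkdir(parents=True, exist_ok=True)
    config = private_snp_config(seed=SEED)
    alignments, taxon_map, truth = simulate_dataset(config)
    for locus, aln in alignments.items():
        write_fasta_alignment(aln, sim_dir / f"{locus}.fasta")
    write_taxon_map(taxon_map, sim_dir / "taxa.tsv")
    truth.write_tsv(sim_dir / "truth.tsv")
    print(f"simulated dataset (seed {SEED}): "
          f"{len(taxon_map.ingroup_accessions())} ingroup accessions, "
          f"{len(alignments)} locus/loci, "
          f"{len(truth.snps)} planted private SNPs -> {sim_dir}")

    panel_dir = OUT / "worked_example"
    panel_dir.mkdir(parents=True, exist_ok=True)
    alignments, taxon_map = worked_example_panel()
    for locus, aln in alignments.items():
        write_fasta_alignment(aln, panel_dir / f"{locus}.fasta")
    write_taxon_map(taxon_map, panel_dir / "taxa.tsv")
    print(f"worked-example panel: {len(taxon_map.ingroup_accessions())} accessions, "
          f"loci {', '.join(alignments)} -> {panel_dir}")


if __name__ == "__main__":
    main()
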