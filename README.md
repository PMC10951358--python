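# diagmark

Chloroplast-barcode species authentication for multi-accession panels:
sliding-window nucleotide-diversity hotspot discovery, species-specific
SNP/InDel diagnostic-site calling, distance-based phylogenetics (NJ/UPGMA
under p, JC69, K2P and T3P models), and a monophyly-based discrimination
success rate — with a seeded synthetic-data generator so the whole pipeline
is testable end to end without downloads.

## Who this is for

Groups authenticating medicinal plant material (e.g. *Patrinia* herbal
samples) from amplicon panels: given per-locus multiple-sequence alignments
and a sample-to-taxon map, the toolkit finds which alignment columns
diagnose each taxon, builds distance trees rooted with an outgroup, and
quantifies how many taxa resolve as clean clades.

## The statistics at the core

* **Nucleotide diversity** per sliding window,
  `π = (1/L_u) Σ_c [ #mismatching pairs at c / C(n,2) ]` over columns with
  no gap or ambiguity in any sequence; windows (default 600 bp, step 200 bp)
  with `π > 0.05` merge into divergence hotspots — the candidate barcode
  regions.
* **Species-specific SNPs**: columns where one taxon is fixed for a base no
  other ingroup accession carries (and all others have defined bases), and
  **InDel events**: maximal gap-pattern runs private to one taxon.
* **Distances**: Kimura 2-parameter
  `d = −½ln(1−2P−Q) − ¼ln(1−2Q)` and Tamura 3-parameter
  `d = −h·ln(1−P/h−Q) − ½(1−h)·ln(1−2Q)`, `h = 2θ(1−θ)`, with optional
  gamma rate correction.
* **Discrimination success rate**: on the outgroup-rooted NJ (or UPGMA)
  tree, `100 × n_monophyletic_taxa / n_taxa`.

## Worked example

```bash
python analysis/01_simulate.py            # datasets under results/data/
python analysis/02_scan_hotspots.py       # windowed pi + hotspots
python analysis/03_diagnostic_sites.py    # species-specific SNPs/InDels
python analysis/04_trees_discrimination.py  # trees + discrimination rates
```

`03_diagnostic_sites.py` runs the callers on a deterministic 37-accession,
six-taxon, four-locus panel with planted diagnostics and prints:

```
species-specific variable nucleotides per taxon:
  Patrinia scabiosifolia: 6 SNP(s)
  Patrinia heterophylla: 2 SNP(s)
  Patrinia monandra: 0 SNP(s)
  Patrinia villosa subsp. villosa: 1 SNP(s) + 1 InDel event(s)
  Patrinia scabra: 3 SNP(s)
  Patrinia villosa subsp. punctifolia: 5 SNP(s)
```

i.e. each taxon's private substitutions, plus one 24-bp taxon-private
insertion (psaI-ycf4, columns 185–208) for *P. villosa* subsp. *villosa*;
*P. monandra* has none because its only candidate column is masked by
missing sequence in other accessions. `04_trees_discrimination.py` then
reports, for the simulated six-taxon dataset (seed 42, three fixed private
SNPs per taxon, background noise 0.002):

```
  discrimination success rate: 100.0%
```

meaning all six taxa form clean clades in the outgroup-rooted NJ tree, and
sweeps all 15 loci combinations of the worked-example panel (single loci
resolve 50.0–83.3%; the four-locus combination reaches 100.0%).

There is also a CLI for ad-hoc use, e.g.:

```bash
diagmark scan --alignment plastome.fasta --window 600 --step 200 --threshold 0.05
diagmark call-sites --alignment petA.fasta --taxa map.tsv
diagmark tree --alignment petA.fasta --taxa map.tsv --method nj --model t3p --seed 42
```

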