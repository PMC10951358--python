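"""Synthetic multi-locus alignments with known planted diagnostics.

The generator emulates the structure of a multi-accession herbal
authentication study: several ingroup taxa sampled with a handful of
accessions each, very low intra-taxon diversity, fixed inter-taxon diagnostic
substitutions, contiguous insertion/deletion events private to one taxon, and
a single divergent outgroup used only for rooting. Locus lengths default to
chloroplast amplicon sizes (roughly 300-750 bp).

Every run is reproducible from its seed, and a machine-readable truth table
records the planted features in final alignment coordinates (insertions shift
downstream columns).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_io import Alignment, TaxonMap

_BASES = np.array(list("ACGT"))

#: Six ingroup taxa mirroring a multi-species authentication panel.
DEFAULT_TAXA = (
    "Patrinia scabiosifolia",
    "Patrinia heterophylla",
    "Patrinia monandra",
    "Patrinia villosa subsp. villosa",
    "Patrinia scabra",
    "Patrinia villosa subsp. punctifolia",
)

DEFAULT_LOCI = (("atpB", 430), ("petA", 735), ("psaI-ycf4", 340), ("rpl2-rpl23", 460))

OUTGROUP_TAXON = "Valeriana officinalis"
OUTGROUP_ACCESSION = "OUT01"


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedSnp:
    locus: str
    column: int
    taxon: str
    state: str


@dataclass(frozen=True)
class PlantedIndel:
    locus: str
    start: int
    length: int
    taxon: str
    inserted: str | None = None  # None -> deletion of existing columns

    @property
    def is_insertion(self) -> bool:
        return self.inserted is not None


@dataclass
class SimulationConfig:
    """Study-design parameters for one simulated dataset.

    background_rate is the per-site, per-accession probability of an
    intra-taxon substitution (uniform over the three alternative bases);
    outgroup_divergence is the per-site substitution probability applied to
    the single outgroup copy of the ancestor.
    """

    taxa: tuple[str, ...] = DEFAULT_TAXA
    accessions_per_taxon: int = 5
    loci: tuple[tuple[str, int], ...] = DEFAULT_LOCI
    planted_snps: tuple[PlantedSnp, ...] = ()
    planted_indels: tuple[PlantedIndel, ...] = ()
    background_rate: float = 0.002
    outgroup_divergence: float = 0.05
    gc_content: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        lengths = dict(self.loci)
        for s in self.planted_snps:
            if s.locus not in lengths:
                raise ConfigError(f"planted SNP names unknown locus {s.locus!r}")
            if not 1 <= s.column <= lengths[s.locus]:
                raise ConfigError(f"planted SNP column {s.column} outside {s.locus}")
            if s.taxon not in self.taxa:
                raise ConfigError(f"planted SNP names unknown taxon {s.taxon!r}")
        for ind in self.planted_indels:
            if ind.locus not in lengths:
                raise ConfigError(f"planted indel names unknown locus {ind.locus!r}")
            if ind.length < 1 or ind.start < 1:
                raise ConfigError("indel start/length must be positive")
            if not ind.is_insertion and ind.start + ind.length - 1 > lengths[ind.locus]:
                raise ConfigError(f"planted deletion exceeds {ind.locus}")
            if ind.is_insertion and len(ind.inserted) != ind.length:
                raise ConfigError("inserted sequence length mismatch")
        # overlap check in pre-insertion coordinates, per locus
        for locus, _ in self.loci:
            spans = [(s.column, s.column) for s in self.planted_snps if s.locus == locus]
            spans += [(i.start, i.start + i.length - 1)
                      for i in self.planted_indels if i.locus == locus]
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 <= e1:
                    raise ConfigError(
                        f"planted features overlap in {locus}: [{s1},{e1}] and [{s2},{e2}]")
        if not 0 <= self.background_rate <= 1 or not 0 <= self.outgroup_divergence <= 1:
            raise ConfigError("rates must be probabilities")


@dataclass
class TruthTable:
    """Planted features in final (post-insertion) alignment coordinates."""

    snps: list[PlantedSnp] = field(default_factory=list)
    indels: list[tuple[str, int, int, str, str, str]] = field(default_factory=list)
    # (locus, start, end, taxon, polarity, sequence-or-empty)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("kind\tlocus\tstart\tend\ttaxon\tstate\n")
            for s in self.snps:
                fh.write(f"snp\t{s.locus}\t{s.column}\t{s.column}\t{s.taxon}\t{s.state}\n")
            for locus, start, end, taxon, polarity, seq in self.indels:
                fh.write(f"{polarity}\t{locus}\t{start}\t{end}\t{taxon}\t{seq}\n")


def _slug(taxon: str) -> str:
    return "".join(re.sub(r"[^A-Za-z0-9]+", "", w).capitalize() for w in taxon.split())


def accession_names(config: SimulationConfig) -> dict[str, list[str]]:
    """Deterministic accession identifiers per taxon."""
    return {
        taxon: [f"{_slug(taxon)}_{k + 1:02d}" for k in range(config.accessions_per_taxon)]
        for taxon in config.taxa
    }


def simulate_dataset(config: SimulationConfig) -> tuple[dict[str, Alignment], TaxonMap, TruthTable]:
    """Simulate per-locus alignments, the taxon map, and the truth table.

    Per locus: a random ancestral sequence is copied to every accession;
    planted SNPs fix a taxon-private state (the ancestor is forced to a
    different base, which all other taxa keep); planted insertions add gap
    columns everywhere except the target taxon, deletions gap the target
    taxon; i.i.d. background substitutions are applied per ingroup accession
    away from planted columns; the outgroup derives from the ancestor.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    names = accession_names(config)

    assignments: dict[str, str] = {}
    for taxon in config.taxa:
        for acc in names[taxon]:
            assignments[acc] = taxon
    assignments[OUTGROUP_ACCESSION] = OUTGROUP_TAXON
    taxon_map = TaxonMap(assignments=assignments, outgroup={OUTGROUP_ACCESSION})

    ingroup_accs = [a for t in config.taxa for a in names[t]]
    truth = TruthTable()
    alignments: dict[str, Alignment] = {}

    p_gc = config.gc_content / 2.0
    base_probs = np.array([0.5 - p_gc, p_gc, p_gc, 0.5 - p_gc])  # A C G T

    for locus, length in config.loci:
        ancestor = rng.choice(_BASES, size=length, p=base_probs)

        snps = [s for s in config.planted_snps if s.locus == locus]
        indels = sorted((i for i in config.planted_indels if i.locus == locus),
                        key=lambda i: i.start)
        planted_cols = {s.column for s in snps}
        for ind in indels:
            planted_cols.update(range(ind.start, ind.start + ind.length))

        # force the ancestor away from each planted diagnostic state
        for s in snps:
            if ancestor[s.column - 1] == s.state:
                alternatives = [b for b in "ACGT" if b != s.state]
                ancestor[s.column - 1] = rng.choice(alternatives)

        rows = {acc: ancestor.copy() for acc in ingroup_accs}
        for s in snps:
            for acc in names[s.taxon]:
                rows[acc][s.column - 1] = s.state

        # background substitutions, avoiding planted columns
        free_cols = np.array([c for c in range(length) if (c + 1) not in planted_cols],
                             dtype=int)
        for acc in ingroup_accs:
            hits = free_cols[rng.random(free_cols.size) < config.background_rate]
            for c in hits:
                current = rows[acc][c]
                rows[acc][c] = rng.choice([b for b in "ACGT" if b != current])

        # outgroup from the ancestor
        out_row = ancestor.copy()
        hits = free_cols[rng.random(free_cols.size) < config.outgroup_divergence]
        for c in hits:
            out_row[c] = rng.choice([b for b in "ACGT" if b != out_row[c]])
        rows[OUTGROUP_ACCESSION] = out_row

        # realize indels; insertions right-to-left so earlier coords are stable
        matrix = {acc: list(row) for acc, row in rows.items()}
        all_accs = ingroup_accs + [OUTGROUP_ACCESSION]
        for ind in reversed(indels):
            members = set(names[ind.taxon])
            if ind.is_insertion:
                insert_at = ind.start - 1
                for acc in all_accs:
                    block = (list(ind.inserted) if acc in members
                             else ["-"] * ind.length)
                    matrix[acc][insert_at:insert_at] = block
            else:
                for acc in members:
                    for c in range(ind.start - 1, ind.start - 1 + ind.length):
                        matrix[acc][c] = "-"

        # final coordinates: planted columns shift by upstream insertion lengths
        def final_pos(col: int) -> int:
            shift = sum(i.length for i in indels if i.is_insertion and i.start <= col)
            return col + shift

        for s in snps:
            truth.snps.append(PlantedSnp(locus=locus, column=final_pos(s.column),
                                         taxon=s.taxon, state=s.state))
        for ind in indels:
            if ind.is_insertion:
                start = ind.start + sum(i.length for i in indels
                                        if i.is_insertion and i.start < ind.start)
                seq = ind.inserted
                polarity = "insertion"
            else:
                start = final_pos(ind.start)
                seq = ""
                polarity = "deletion"
            truth.indels.append((locus, start, start + ind.length - 1,
                                 ind.taxon, polarity, seq or ""))

        alignments[locus] = Alignment(
            name=locus,
            accessions=all_accs,
            sequences=["".join(matrix[acc]) for acc in all_accs],
        )

    return alignments, taxon_map, truth


def private_snp_config(
    seed: int,
    n_taxa: int = 6,
    accessions_per_taxon: int = 5,
    locus_length: int = 700,
    snps_per_taxon: int = 3,
    background_rate: float = 0.002,
    outgroup_divergence: float = 0.05,
    locus: str = "locus1",
) -> SimulationConfig:
    """One-locus design with fixed private SNPs for every taxon.

    Columns are assigned deterministically (evenly spread, taxon-interleaved)
    and each taxon receives ``snps_per_taxon`` diagnostic states drawn from
    the seed, so every taxon is separable from every other in this locus.
    """
    taxa = tuple(DEFAULT_TAXA[:n_taxa]) if n_taxa <= len(DEFAULT_TAXA) else tuple(
        f"Taxon_{i + 1}" for i in range(n_taxa))
    rng = np.random.default_rng(seed)
    total = n_taxa * snps_per_taxon
    if total > locus_length:
        raise ConfigError("locus too short for the requested planted SNPs")
    columns = np.linspace(1, locus_length, num=total, dtype=int)
    columns = np.unique(columns)
    if columns.size < total:
        raise ConfigError("locus too short to spread planted SNPs")
    snps = []
    for k, col in enumerate(columns):
        taxon = taxa[k % n_taxa]
        state = str(rng.choice(_BASES))
        snps.append(PlantedSnp(locus=locus, column=int(col), taxon=taxon, state=state))
    return SimulationConfig(
        taxa=taxa,
        accessions_per_taxon=accessions_per_taxon,
        loci=((locus, locus_length),),
        planted_snps=tuple(snps),
        background_rate=background_rate,
        outgroup_divergence=outgroup_divergence,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Deterministic worked-example fixture

#: Collector-number accession codes per taxon for the worked-example panel.
FIXTURE_ACCESSIONS = {
    "Patrinia scabiosifolia": ["L083", "L082", "L119", "L121", "L437",
                               "L438", "L481", "L482", "Z22076"],
    "Patrinia heterophylla": ["L089", "L088", "L466", "L467", "L469",
                              "L471", "L476"],
    "Patrinia monandra": ["L103", "L105", "L435", "L436", "L475",
                          "L479", "L480"],
    "Patrinia villosa subsp. villosa": ["L403", "L092", "L094", "L095",
                                        "L096", "L097", "L464", "L465",
                                        "L472", "L473", "L477", "L478"],
    "Patrinia scabra": ["L483"],
    "Patrinia villosa subsp. punctifolia": ["L484"],
}

FIXTURE_OUTGROUP = "NC_045052"

VILLOSA_INSERTION = "GAAGGGGTATGTTATTATTTTATT"  # 24 bp, psaI-ycf4 185-208

#: Species-specific substitutions: locus -> [(column, taxon, state, shared_state)]
FIXTURE_SNPS = {
    "atpB": [
        (41, "Patrinia villosa subsp. punctifolia", "G", "A"),
        (83, "Patrinia scabra", "A", "G"),
        (212, "Patrinia heterophylla", "C", "A"),
    ],
    "petA": [
        (194, "Patrinia heterophylla", "G", "T"),
        (221, "Patrinia scabiosifolia", "C", "T"),
        (548, "Patrinia scabra", "T", "C"),
    ],
    "psaI-ycf4": [
        (89, "Patrinia scabiosifolia", "G", "T"),
        (162, "Patrinia scabra", "G", "A"),
    ],
    "rpl2-rpl23": [
        (141, "Patrinia scabiosifolia", "A", "T"),
        (165, "Patrinia villosa subsp. punctifolia", "G", "C"),
        (173, "Patrinia villosa subsp. villosa", "C", "G"),
        (264, "Patrinia villosa subsp. punctifolia", "G", "T"),
        (265, "Patrinia villosa subsp. punctifolia", "T", "A"),
        (266, "Patrinia villosa subsp. punctifolia", "T", "A"),
        (336, "Patrinia scabiosifolia", "C", "G"),
        (337, "Patrinia scabiosifolia", "C", "T"),
        (362, "Patrinia scabiosifolia", "C", "T"),
    ],
}

FIXTURE_LOCUS_LENGTHS = {"atpB": 430, "petA": 735, "psaI-ycf4": 340, "rpl2-rpl23": 1090}

# petA column 24: all monandra accessions read A where others share G, but a
# few accessions of other taxa lack sequence at the alignment start, which
# disqualifies the column as a species-specific SNP.
_PETA_SUBSTITUTION_LIKE = (24, "Patrinia monandra", "A", "G")
_PETA_TRUNCATED = {"L088": 30, "L082": 27}  # accession -> leading gap length


def worked_example_panel(seed: int = 7) -> tuple[dict[str, Alignment], TaxonMap]:
    """Deterministic four-locus alignment set with the worked-example
    diagnostics planted at their printed positions.

    Encodes 6 + 5 + 3 + 2 + 1 + 0 species-specific substitutions for the six
    taxa, the 24-bp taxon-private insertion at psaI-ycf4 185-208, and a
    substitution-like column (petA 24) masked by missing leading sequence in
    two accessions of other taxa. Invariant elsewhere across the ingroup; the
    outgroup carries its own deterministic divergence.
    """
    rng = np.random.default_rng(seed)
    assignments: dict[str, str] = {}
    for taxon, accs in FIXTURE_ACCESSIONS.items():
        for acc in accs:
            assignments[acc] = taxon
    assignments[FIXTURE_OUTGROUP] = OUTGROUP_TAXON
    taxon_map = TaxonMap(assignments=assignments, outgroup={FIXTURE_OUTGROUP})
    ingroup = [a for accs in FIXTURE_ACCESSIONS.values() for a in accs]
    all_accs = ingroup + [FIXTURE_OUTGROUP]

    alignments: dict[str, Alignment] = {}
    for locus, length in FIXTURE_LOCUS_LENGTHS.items():
        ancestor = rng.choice(_BASES, size=length)
        for col, _, state, shared in FIXTURE_SNPS[locus]:
            ancestor[col - 1] = shared
        if locus == "petA":
            ancestor[_PETA_SUBSTITUTION_LIKE[0] - 1] = _PETA_SUBSTITUTION_LIKE[3]

        rows = {acc: ancestor.copy() for acc in all_accs}
        for col, taxon, state, _ in FIXTURE_SNPS[locus]:
            for acc in FIXTURE_ACCESSIONS[taxon]:
                rows[acc][col - 1] = state

        if locus == "petA":
            col, taxon, state, _ = _PETA_SUBSTITUTION_LIKE
            for acc in FIXTURE_ACCESSIONS[taxon]:
                rows[acc][col - 1] = state
            for acc, gap_len in _PETA_TRUNCATED.items():
                rows[acc][:gap_len] = "-"

        if locus == "psaI-ycf4":
            villosa = set(FIXTURE_ACCESSIONS["Patrinia villosa subsp. villosa"])
            for acc in all_accs:
                block = (list(VILLOSA_INSERTION) if acc in villosa
                         else ["-"] * len(VILLOSA_INSERTION))
                rows[acc][184:208] = block

        # outgroup divergence away from diagnostic and gapped columns
        reserved = {c for c, *_ in FIXTURE_SNPS[locus]}
        if locus == "petA":
            reserved |= set(range(1, 31))
        if locus == "psaI-ycf4":
            reserved |= set(range(185, 209))
        out = rows[FIXTURE_OUTGROUP]
        for c in range(length):
            if (c + 1) not in reserved and rng.random() < 0.03:
                out[c] = rng.choice([b for b in "ACGT" if b != out[c]])

        alignments[locus] = Alignment(
            name=locus,
            accessions=all_accs,
            sequences=["".join(rows[acc]) for acc in all_accs],
        )
    return alignments, taxon_map
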