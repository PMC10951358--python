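"""Variable-site classification and species-specific SNP/InDel calling.

Given a taxon-labelled alignment, this module identifies:

* per-column classification (invariant / variable / parsimony-informative /
  singleton), the basis of informative-nucleotide counts;
* species-specific SNPs: columns where one taxon's accessions all share a
  base that no other ingroup accession carries, and every other ingroup
  accession has a defined base there;
* InDel events: maximal runs of contiguous columns sharing one per-accession
  gap/base presence pattern, attributed to a taxon when the pattern exactly
  separates that taxon from the rest of the ingroup.

The outgroup is excluded from all specificity and informativeness
computations; its accessions may be absent from or present in the alignment.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .core_io import BASES, GAP, Alignment, LocusPartition, TaxonMap


class MappingError(KeyError):
    """An ingroup accession lacks a taxon assignment."""


class CoordinateError(ValueError):
    """A position falls outside the locus partition."""


@dataclass(frozen=True)
class DiagnosticSite:
    """A species-specific SNP at one alignment column."""

    column: int
    taxon: str
    state: str
    other_states: tuple[str, ...]
    kind: str = "species_specific_snp"


@dataclass(frozen=True)
class IndelEvent:
    """A maximal contiguous gap/base presence pattern.

    ``pattern`` maps accession -> True when the accession carries sequence
    (not gaps) over the run. ``taxon`` is set only when the pattern exactly
    partitions one ingroup taxon from all other ingroup accessions.
    """

    start: int
    end: int
    pattern: tuple[tuple[str, bool], ...]
    taxon: str | None
    polarity: str  # insertion | deletion | unpolarized
    edge: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ColumnSummary:
    counts: dict[str, Counter]  # taxon -> base counter over {A,C,G,T}
    missing: int
    invariant: bool
    variable: bool
    parsimony_informative: bool
    singleton: bool


@dataclass
class SiteSummary:
    """Per-column taxon-state tallies and classification flags."""

    columns: list[ColumnSummary] = field(default_factory=list)

    def n_variable(self) -> int:
        return sum(c.variable for c in self.columns)

    def n_invariant(self) -> int:
        return sum(c.invariant for c in self.columns)


def _ingroup_rows(alignment: Alignment, taxon_map: TaxonMap) -> list[tuple[str, str, str]]:
    """(accession, taxon, sequence) for ingroup rows; errors on unmapped."""
    rows = []
    for acc, seq in zip(alignment.accessions, alignment.sequences):
        if acc in taxon_map.outgroup:
            continue
        if acc not in taxon_map.assignments:
            raise MappingError(f"accession {acc!r} has no taxon assignment")
        rows.append((acc, taxon_map.assignments[acc], seq))
    return rows


def classify_columns(alignment: Alignment, taxon_map: TaxonMap) -> SiteSummary:
    """Tally bases per taxon per column and set classification flags.

    A column is variable when >= 2 distinct bases occur among defined
    (A/C/G/T) ingroup states; parsimony-informative when >= 2 bases are each
    carried by >= 2 accessions; singleton when variable but not informative.
    """
    rows = _ingroup_rows(alignment, taxon_map)
    summary = SiteSummary()
    for col in range(alignment.length):
        counts: dict[str, Counter] = {}
        pooled: Counter = Counter()
        missing = 0
        for _, taxon, seq in rows:
            ch = seq[col]
            if ch in BASES:
                counts.setdefault(taxon, Counter())[ch] += 1
                pooled[ch] += 1
            else:
                missing += 1
        n_states = len(pooled)
        variable = n_states >= 2
        informative = sum(1 for c in pooled.values() if c >= 2) >= 2 and variable
        summary.columns.append(ColumnSummary(
            counts=counts,
            missing=missing,
            invariant=n_states == 1,
            variable=variable,
            parsimony_informative=informative,
            singleton=variable and not informative,
        ))
    return summary


def count_informative_sites(summary: SiteSummary) -> int:
    """Number of parsimony-informative columns."""
    return sum(c.parsimony_informative for c in summary.columns)


def call_species_specific_snps(alignment: Alignment, taxon_map: TaxonMap) -> list[DiagnosticSite]:
    """Columns where one taxon is fixed for a base absent from every other taxon.

    A column is disqualified for taxon T when any non-T ingroup accession has
    a gap or ambiguity there, mirroring the refusal to call substitutions
    where other accessions show no nucleotide.
    """
    rows = _ingroup_rows(alignment, taxon_map)
    taxa = taxon_map.ingroup_taxa()
    if len(taxa) < 2:
        raise ValueError("species-specific SNP calling needs >= 2 ingroup taxa")

    sites: list[DiagnosticSite] = []
    for col in range(alignment.length):
        by_taxon: dict[str, set[str]] = {t: set() for t in taxa}
        states: dict[str, list[str]] = {t: [] for t in taxa}
        for _, taxon, seq in rows:
            ch = seq[col]
            by_taxon[taxon].add(ch)
            states[taxon].append(ch)
        for taxon in taxa:
            own = by_taxon[taxon]
            if len(own) != 1:
                continue
            state = next(iter(own))
            if state not in BASES:
                continue
            others = [ch for t in taxa if t != taxon for ch in states[t]]
            if any(ch not in BASES for ch in others):
                continue
            if state in others:
                continue
            sites.append(DiagnosticSite(
                column=col + 1,
                taxon=taxon,
                state=state,
                other_states=tuple(sorted(set(others))),
            ))
    return sites


def call_indel_events(alignment: Alignment, taxon_map: TaxonMap) -> list[IndelEvent]:
    """Merge contiguous identical gap/base presence patterns into events.

    Polarity: ``insertion`` when exactly one ingroup taxon carries sequence,
    ``deletion`` when exactly one carries the gap, else ``unpolarized``.
    Events touching either alignment end are flagged ``edge=True``.
    """
    rows = _ingroup_rows(alignment, taxon_map)
    accs = [acc for acc, _, _ in rows]
    taxon_of = {acc: taxon for acc, taxon, _ in rows}
    seqs = {acc: seq for acc, _, seq in rows}
    taxa = {t: set(taxon_map.accessions_of(t)) & set(accs)
            for t in taxon_map.ingroup_taxa()}

    def col_pattern(col: int) -> tuple[bool, ...]:
        return tuple(seqs[acc][col] != GAP for acc in accs)

    events: list[IndelEvent] = []
    run_start: int | None = None
    run_pat: tuple[bool, ...] | None = None

    def close(start: int, end: int, pat: tuple[bool, ...]) -> None:
        present = {acc for acc, p in zip(accs, pat) if p}
        absent = set(accs) - present
        seq_taxa = {taxon_of[a] for a in present}
        gap_taxa = {taxon_of[a] for a in absent}
        # polarity decides attribution: a single sequence-bearing taxon whose
        # accessions are exactly the bearers is an insertion in that taxon; a
        # single gap-bearing taxon is a deletion; otherwise unattributed
        taxon = None
        if present and absent and len(seq_taxa) == 1 and present == taxa.get(
                next(iter(seq_taxa)), set()):
            taxon, polarity = next(iter(seq_taxa)), "insertion"
        elif present and absent and len(gap_taxa) == 1 and absent == taxa.get(
                next(iter(gap_taxa)), set()):
            taxon, polarity = next(iter(gap_taxa)), "deletion"
        else:
            polarity = "unpolarized"
        events.append(IndelEvent(
            start=start, end=end,
            pattern=tuple(zip(accs, pat)),
            taxon=taxon, polarity=polarity,
            edge=(start == 1 or end == alignment.length),
        ))

    for col in range(alignment.length):
        pat = col_pattern(col)
        has_gap = not all(pat)
        if has_gap:
            if run_pat == pat:
                continue
            if run_pat is not None:
                close(run_start, col, run_pat)  # type: ignore[arg-type]
            run_start, run_pat = col + 1, pat
        else:
            if run_pat is not None:
                close(run_start, col, run_pat)  # type: ignore[arg-type]
                run_start = run_pat = None
    if run_pat is not None:
        close(run_start, alignment.length, run_pat)  # type: ignore[arg-type]
    return events


def diagnostic_report(
    sites: Sequence[DiagnosticSite],
    indels: Sequence[IndelEvent],
    partition: LocusPartition | None = None,
    locus: str | None = None,
    alignment: Alignment | None = None,
) -> list[dict]:
    """Tabulate diagnostic SNPs and species-specific InDels.

    Rows carry locus-local 1-based positions. With a ``partition``, global
    columns on a concatenated alignment are mapped back to their locus;
    otherwise ``locus`` names the single region.
    """
    def place(column: int) -> tuple[str, int]:
        if partition is not None:
            try:
                return partition.locate(column)
            except Exception as exc:
                raise CoordinateError(str(exc)) from exc
        return locus or "", column

    rows = []
    for s in sites:
        loc, pos = place(s.column)
        rows.append({
            "locus": loc, "position": str(pos), "taxon": s.taxon,
            "kind": "SNP", "state": s.state,
            "others": "/".join(s.other_states),
        })
    for e in indels:
        if e.taxon is None:
            continue
        loc_s, pos_s = place(e.start)
        loc_e, pos_e = place(e.end)
        if loc_s != loc_e:
            raise CoordinateError(
                f"indel {e.start}-{e.end} spans locus boundary {loc_s}/{loc_e}")
        seq = ""
        if alignment is not None and e.polarity == "insertion":
            bearer = next(acc for acc, p in e.pattern if p)
            seq = alignment.sequence(bearer)[e.start - 1:e.end]
        rows.append({
            "locus": loc_s, "position": f"{pos_s}-{pos_e}", "taxon": e.taxon,
            "kind": e.polarity, "state": seq, "others": "gap",
        })
    rows.sort(key=lambda r: (r["locus"], int(str(r["position"]).split("-")[0])))
    return rows


def write_report(rows: Sequence[dict], path: str | Path) -> None:
    cols = ["locus", "position", "taxon", "kind", "state", "others"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(str(r[c]) for c in cols) + "\n")
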