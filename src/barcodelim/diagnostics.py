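"""Character-based DNA-barcoding diagnostics.

The character-based approach to species identification looks for *pure
simple diagnostic characters*: nucleotide states that are fixed within one
species and absent from every other focal species at a homologous site.
This module collapses strain-level alignments to per-species state sets,
codes indel characters, lists informative sites (any site variable among
the focal strains, including within-species polymorphism) and calls the
diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .alignment_io import (
    Alignment,
    CharacterStateTable,
    SiteRecord,
    SpeciesPartition,
    iupac_to_set,
)
from .errors import ContractViolation, ValidationError

__all__ = [
    "DiagnosticCall",
    "collapse_to_species_states",
    "code_indels",
    "build_character_table",
    "find_informative_sites",
    "call_pure_diagnostics",
    "summarize_delimitation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiagnosticCall:
    """A state fixed in one species and absent from all other focal species."""

    locus: str
    position: int
    kind: str  # "substitution" | "indel"
    species: str
    state: str
    region: str = ""


def _species_pools(
    alignment: Alignment, partition: SpeciesPartition, focal_only: bool
) -> dict[str, list[str]]:
    partition.validate_alignment(alignment)
    if focal_only:
        species = sorted(partition.focal_species)
    else:
        species = sorted({partition.species_of(s) for s in alignment.strains})
    pools = {sp: partition.strains_of(sp, within=alignment.strains) for sp in species}
    for sp, pool in pools.items():
        if not pool:
            raise ContractViolation(
                f"{alignment.locus}: species {sp!r} has no strains in the alignment"
            )
    return pools


def collapse_to_species_states(
    alignment: Alignment,
    partition: SpeciesPartition,
    focal_only: bool = True,
) -> CharacterStateTable:
    """Collapse strains to per-species nucleotide state sets, keeping only
    variable columns.

    The state set of a species at a column is the union over its strains of
    the expanded character (ambiguity codes and ``?`` contribute their full
    IUPAC set, so missing data reduces diagnosability rather than inflating
    it).  Columns where every considered strain carries one identical
    unambiguous state are dropped, as are columns falling inside gapped
    regions (those are handled by :func:`code_indels`).
    """
    pools = _species_pools(alignment, partition, focal_only)
    considered = [s for pool in pools.values() for s in pool]
    sites: list[SiteRecord] = []
    for col in range(alignment.n_sites):
        chars = {s: alignment.sequence(s)[col] for s in considered}
        if "-" in chars.values():
            continue  # indel territory
        observed = set(chars.values())
        if len(observed) == 1 and observed <= set("ACGT"):
            continue  # invariant column
        states = {
            sp: frozenset().union(*(iupac_to_set(chars[s]) for s in pool))
            for sp, pool in pools.items()
        }
        if len({st for st in states.values()}) == 1 and all(
            len(st) == 1 for st in states.values()
        ):
            continue  # ambiguity codes collapsed to one shared state
        sites.append(SiteRecord(alignment.position(col), "substitution", states))
    counts = {sp: len(pool) for sp, pool in pools.items()}
    return CharacterStateTable(alignment.locus, sites, counts)


def _gap_blocks(alignment: Alignment, strains: list[str]) -> list[tuple[int, int]]:
    """Maximal contiguous column intervals with an identical, nonempty set
    of gapped strains (0-based, inclusive)."""
    blocks: list[tuple[int, int]] = []
    prev_set: frozenset[str] = frozenset()
    start = -1
    for col in range(alignment.n_sites):
        gapped = frozenset(
            s for s in strains if alignment.sequence(s)[col] == "-"
        )
        if gapped != prev_set:
            if prev_set:
                blocks.append((start, col - 1))
            start = col
            prev_set = gapped
    if prev_set:
        blocks.append((start, alignment.n_sites - 1))
    return blocks


def code_indels(
    alignment: Alignment,
    partition: SpeciesPartition,
    focal_only: bool = True,
) -> list[SiteRecord]:
    """Code gap runs as presence/absence indel characters.

    Each maximal block of contiguous columns sharing an identical set of
    gapped strains becomes one indel character.  A strain's state is
    ``absent`` if it is gapped over the block and ``present:<motif>``
    (its own ungapped bases) otherwise; the record's canonical motif is the
    per-column majority consensus of the carriers.  Staggered gap runs
    (boundaries differing between strains) are split into minimal
    identically-bounded blocks, with a warning.  Blocks invariant across the
    considered species are dropped.
    """
    pools = _species_pools(alignment, partition, focal_only)
    considered = [s for pool in pools.values() for s in pool]
    blocks = _gap_blocks(alignment, considered)

    # flag gap runs that span block boundaries (staggered gaps)
    for s in considered:
        seq = alignment.sequence(s)
        run_start = None
        for col in range(alignment.n_sites + 1):
            gapped = col < alignment.n_sites and seq[col] == "-"
            if gapped and run_start is None:
                run_start = col
            elif not gapped and run_start is not None:
                run = (run_start, col - 1)
                if run not in blocks:
                    logger.warning(
                        "%s: staggered gap run %s in strain %s split into "
                        "identically-bounded blocks",
                        alignment.locus, run, s,
                    )
                run_start = None

    records: list[SiteRecord] = []
    for start, end in blocks:
        strain_state: dict[str, str] = {}
        carrier_motifs: list[str] = []
        for s in considered:
            piece = alignment.sequence(s)[start : end + 1]
            if set(piece) == {"-"}:
                strain_state[s] = "absent"
            else:
                motif = piece.replace("-", "")
                strain_state[s] = f"present:{motif}"
                carrier_motifs.append(motif)
        if not carrier_motifs:
            continue  # nobody considered carries the insertion
        width = max(len(m) for m in carrier_motifs)
        consensus = []
        for i in range(width):
            col_chars = [m[i] for m in carrier_motifs if len(m) > i]
            best = max(sorted(set(col_chars)), key=col_chars.count)
            consensus.append(best)
        states = {
            sp: frozenset(strain_state[s] for s in pool)
            for sp, pool in pools.items()
        }
        if len(set(states.values())) == 1 and all(
            len(st) == 1 for st in states.values()
        ):
            continue  # invariant indel
        records.append(
            SiteRecord(
                alignment.position(start),
                "indel",
                states,
                motif="".join(consensus),
            )
        )
    return records


def build_character_table(
    alignment: Alignment,
    partition: SpeciesPartition,
    focal_only: bool = True,
) -> CharacterStateTable:
    """Substitution and indel characters combined, ordered by position."""
    table = collapse_to_species_states(alignment, partition, focal_only)
    table.sites.extend(code_indels(alignment, partition, focal_only))
    table.sites.sort(key=lambda s: s.position)
    return table


def find_informative_sites(table: CharacterStateTable) -> list[SiteRecord]:
    """All sites variable among the focal strains, ordered by position.

    This deliberately includes sites whose only variation is a
    within-species polymorphism, and counts indel characters as sites.
    """
    informative = []
    for site in table.sites:
        state_sets = list(site.states.values())
        if len(set(state_sets)) == 1 and all(len(s) == 1 for s in state_sets):
            continue
        informative.append(site)
    return sorted(informative, key=lambda s: (s.region, s.position))


def call_pure_diagnostics(
    table: CharacterStateTable, focal_species: set[str] | None = None
) -> list[DiagnosticCall]:
    """Call pure simple diagnostics: states fixed in one species and absent
    from every other focal species at that site.

    A species polymorphic at a site is never diagnosed there, even if one
    of its states is private.
    """
    calls: list[DiagnosticCall] = []
    for site in table.sites:
        species = [
            sp for sp in site.states
            if focal_species is None or sp in focal_species
        ]
        for sp in species:
            own = site.states[sp]
            if len(own) != 1:
                continue
            (state,) = own
            others = frozenset().union(
                *(site.states[o] for o in species if o != sp)
            ) if len(species) > 1 else frozenset()
            if state not in others:
                calls.append(
                    DiagnosticCall(
                        table.locus, site.position, site.kind, sp, state,
                        region=site.region,
                    )
                )
    return calls


def summarize_delimitation(
    tables: dict[str, CharacterStateTable],
    diagnostic_calls: dict[str, list[DiagnosticCall]],
    monophyly_results: dict[str, dict[str, bool]] | None = None,
) -> pd.DataFrame:
    """Tabulate informative-site and diagnostic counts per locus x species,
    with monophyly verdicts and grand totals per species.

    ``monophyly_results`` maps locus -> species -> bool; species without a
    verdict are reported as ``untested``.
    """
    species_sets = {
        locus: frozenset(t.counts) for locus, t in tables.items()
    }
    if len(set(species_sets.values())) > 1:
        raise ValidationError(
            f"species sets differ across loci: {dict(species_sets)}"
        )
    rows = []
    all_species = sorted(next(iter(species_sets.values()), frozenset()))
    for locus, table in tables.items():
        informative = find_informative_sites(table)
        calls = diagnostic_calls.get(locus, [])
        for sp in all_species:
            verdict = "untested"
            if monophyly_results and sp in monophyly_results.get(locus, {}):
                verdict = "yes" if monophyly_results[locus][sp] else "no"
            rows.append(
                {
                    "locus": locus,
                    "species": sp,
                    "n_informative_sites": len(informative),
                    "n_diagnostics": sum(1 for c in calls if c.species == sp),
                    "monophyletic": verdict,
                }
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        totals = (
            df.groupby("species", as_index=False)[
                ["n_informative_sites", "n_diagnostics"]
            ]
            .sum()
            .assign(locus="total", monophyletic="untested")
        )
        df = pd.concat([df, totals[df.columns]], ignore_index=True)
    return df
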