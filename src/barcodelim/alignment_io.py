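"""Readers, writers and in-memory containers for alignments, species maps,
character-state tables and Newick trees.

Conventions enforced here and relied on by the rest of the package:

* Alignment characters are uppercase and drawn from the four nucleotides,
  the IUPAC ambiguity codes, ``-`` (alignment gap) and ``?`` (fully
  missing data).  ``U`` is normalized to ``T`` on input.
* Site positions are 1-based and reported in the coordinate system of a
  named reference sequence per locus: ``position = column + ref_offset - 1``
  for a 1-based column index.
* Species names are opaque labels; no taxonomy parsing is attempted.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import dendropy
from Bio import SeqIO

from .errors import AlignmentError, ContractViolation, FormatError

__all__ = [
    "IUPAC_TO_SET",
    "SET_TO_IUPAC",
    "Strain",
    "Alignment",
    "SpeciesPartition",
    "SiteRecord",
    "CharacterStateTable",
    "iupac_to_set",
    "set_to_iupac",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "read_species_map",
    "write_species_map",
    "read_character_table",
    "write_character_table",
    "read_newick",
    "write_newick",
]

#: IUPAC nucleotide ambiguity codes, e.g. R = A/G (purines), Y = C/T
#: (pyrimidines), used throughout to denote within-species polymorphism.
IUPAC_TO_SET: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

SET_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_TO_SET.items()}

#: Characters permitted in an alignment row.
ALLOWED_CHARS = frozenset(IUPAC_TO_SET) | {"-", "?"}


def iupac_to_set(code: str) -> frozenset[str]:
    """Expand a single IUPAC code to its nucleotide set.

    ``?`` expands to the full set {A,C,G,T} (fully missing data).
    """
    if code == "?":
        return frozenset("ACGT")
    try:
        return IUPAC_TO_SET[code]
    except KeyError:
        raise FormatError(f"unknown IUPAC code: {code!r}") from None


def set_to_iupac(states: frozenset[str] | set[str]) -> str:
    """Collapse a nonempty subset of {A,C,G,T} to its IUPAC code."""
    states = frozenset(states)
    if not states:
        raise ContractViolation("cannot encode an empty state set")
    try:
        return SET_TO_IUPAC[states]
    except KeyError:
        raise ContractViolation(f"not a nucleotide subset: {sorted(states)}") from None


@dataclass
class Strain:
    """A sequenced isofemale line with its species assignment."""

    strain_id: str
    species: str
    role: str = "focal"  # "focal" | "outgroup"
    locality: str | None = None


@dataclass
class Alignment:
    """A rectangular strain x site character matrix for one locus."""

    locus: str
    strains: list[str]
    sequences: list[str]
    ref_offset: int = 1
    ref_name: str = ""

    def __post_init__(self) -> None:
        if len(self.strains) != len(self.sequences):
            raise AlignmentError("strains and sequences differ in number")
        if not self.sequences or not self.sequences[0]:
            raise AlignmentError(f"{self.locus}: empty alignment")
        width = len(self.sequences[0])
        for sid, seq in zip(self.strains, self.sequences):
            if len(seq) != width:
                raise AlignmentError(
                    f"{self.locus}: ragged alignment, strain {sid} has length "
                    f"{len(seq)}, expected {width}"
                )
            for col, ch in enumerate(seq, start=1):
                if ch not in ALLOWED_CHARS:
                    raise FormatError(
                        f"{self.locus}: illegal character {ch!r} in strain "
                        f"{sid} at column {col}"
                    )
        if self.ref_offset < 1:
            raise ContractViolation("ref_offset must be >= 1")
        if len(set(self.strains)) != len(self.strains):
            raise FormatError(f"{self.locus}: duplicate strain ids")

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0])

    def sequence(self, strain_id: str) -> str:
        return self.sequences[self.strains.index(strain_id)]

    def column(self, index: int) -> dict[str, str]:
        """Characters at a 0-based column, keyed by strain id."""
        return {s: seq[index] for s, seq in zip(self.strains, self.sequences)}

    def position(self, index: int) -> int:
        """Reference coordinate of a 0-based column index."""
        return index + self.ref_offset


@dataclass
class SpeciesPartition:
    """Strain -> species map with focal / outgroup designation."""

    mapping: dict[str, str]
    focal_species: set[str]
    outgroup_strains: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.focal_species:
            raise ContractViolation("focal_species must be nonempty")
        for sid in self.outgroup_strains:
            if self.mapping.get(sid) in self.focal_species:
                raise ContractViolation(
                    f"outgroup strain {sid} belongs to a focal species"
                )

    def species_of(self, strain_id: str) -> str:
        return self.mapping[strain_id]

    def strains_of(self, species: str, within: list[str] | None = None) -> list[str]:
        pool = within if within is not None else list(self.mapping)
        return [s for s in pool if self.mapping.get(s) == species]

    def focal_strains(self, within: list[str] | None = None) -> list[str]:
        pool = within if within is not None else list(self.mapping)
        return [s for s in pool if self.mapping.get(s) in self.focal_species]

    def validate_alignment(self, alignment: Alignment) -> None:
        missing = [s for s in alignment.strains if s not in self.mapping]
        if missing:
            from .errors import ValidationError

            raise ValidationError(
                f"{alignment.locus}: strains absent from species map: {missing}"
            )


@dataclass
class SiteRecord:
    """Per-species character states at one reference position.

    ``kind`` is ``"substitution"`` (states are nucleotide sets) or
    ``"indel"`` (states are ``present:<motif>`` / ``absent`` strings).
    ``motif`` holds the canonical (consensus) inserted motif for indels.
    """

    position: int
    kind: str
    states: dict[str, frozenset[str]]
    region: str = ""
    motif: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise FormatError(f"position must be a positive integer: {self.position}")
        if self.kind not in ("substitution", "indel"):
            raise FormatError(f"unknown site kind: {self.kind!r}")
        for sp, st in self.states.items():
            if not st:
                raise ContractViolation(
                    f"empty state set for {sp} at position {self.position}"
                )
            if self.kind == "substitution" and not st <= frozenset("ACGT"):
                raise ContractViolation(
                    f"substitution states must be nucleotides at {self.position}: "
                    f"{sorted(st)}"
                )


@dataclass
class CharacterStateTable:
    """Per-site, per-species state sets for one locus (with strain counts)."""

    locus: str
    sites: list[SiteRecord]
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        return list(self.counts)


def read_fasta_alignment(
    path, locus: str, ref_offset: int = 1, ref_name: str = ""
) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Characters are uppercased and ``U`` is normalized to ``T``.
    """
    strains, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        strains.append(rec.id)
        seqs.append(str(rec.seq).upper().replace("U", "T"))
    if not strains:
        raise FormatError(f"{path}: no FASTA records")
    return Alignment(locus, strains, seqs, ref_offset=ref_offset, ref_name=ref_name)


def write_fasta_alignment(alignment: Alignment, path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(alignment.strains, alignment.sequences):
            fh.write(f">{sid}\n{seq}\n")


def read_species_map(path) -> SpeciesPartition:
    """Read a species-map TSV (columns: strain_id, species, role[, locality])."""
    mapping: dict[str, str] = {}
    focal: set[str] = set()
    outgroup: set[str] = set()
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty species map")
    header = [c.strip() for c in lines[0].split("\t")]
    for col in ("strain_id", "species", "role"):
        if col not in header:
            raise FormatError(f"{path}: missing column {col!r}")
    idx = {c: header.index(c) for c in header}
    for ln in lines[1:]:
        cells = [c.strip() for c in ln.split("\t")]
        sid = cells[idx["strain_id"]]
        species = cells[idx["species"]]
        role = cells[idx["role"]].lower()
        if sid in mapping:
            raise FormatError(f"{path}: duplicate strain_id {sid!r}")
        if not species:
            raise FormatError(f"{path}: empty species for strain {sid!r}")
        if role not in ("focal", "outgroup"):
            raise FormatError(f"{path}: unknown role {role!r} for {sid!r}")
        mapping[sid] = species
        if role == "focal":
            focal.add(species)
        else:
            outgroup.add(sid)
    if not mapping:
        raise FormatError(f"{path}: species map has no strains")
    return SpeciesPartition(mapping, focal, outgroup)


def write_species_map(partition: SpeciesPartition, path) -> None:
    with open(path, "w") as fh:
        fh.write("strain_id\tspecies\trole\n")
        for sid in partition.mapping:
            role = "outgroup" if sid in partition.outgroup_strains else "focal"
            fh.write(f"{sid}\t{partition.mapping[sid]}\t{role}\n")


# --- character-state table TSV dialect ------------------------------------
#
# Header comments carry the locus name and per-species strain counts; the
# body has one row per site with one state column per species.  Substitution
# states are written as IUPAC codes; indel states as "present:<motif>" /
# "-" (absent), with polymorphism as slash-separated alternatives.  An
# em-dash is accepted as "absent" on read (tables in the literature use it).

_ABSENT_IN = {"-", "—", "absent"}


def _parse_state(cell: str, kind: str) -> frozenset[str]:
    cell = cell.strip()
    if kind == "substitution":
        states: set[str] = set()
        for code in cell.split("/"):
            states |= iupac_to_set(code.strip().upper())
        return frozenset(states)
    parts: set[str] = set()
    for alt in cell.split("/"):
        alt = alt.strip()
        if alt in _ABSENT_IN or alt.lower() == "deletion":
            parts.add("absent")
        elif alt.lower().startswith("present:"):
            motif = alt.split(":", 1)[1].strip().upper()
            if not motif:
                raise FormatError(f"indel motif empty in state {cell!r}")
            parts.add(f"present:{motif}")
        else:
            # bare motif means presence of that motif
            parts.add(f"present:{alt.upper()}")
    return frozenset(parts)


def _format_state(states: frozenset[str], kind: str) -> str:
    if kind == "substitution":
        return set_to_iupac(states)
    return "/".join(sorted(states)).replace("absent", "-") if states else "-"


def read_character_table(path) -> CharacterStateTable:
    """Read a character-state table TSV (the in-memory form of a published
    diagnostic-nucleotide table)."""
    locus = ""
    counts: dict[str, int] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    body: list[str] = []
    for ln in lines:
        if ln.startswith("# locus:"):
            locus = ln.split(":", 1)[1].strip()
        elif ln.startswith("# N:"):
            for item in ln.split(":", 1)[1].strip().split("\t"):
                sp, _, n = item.rpartition("=")
                counts[sp.strip()] = int(n)
        elif not ln.startswith("#"):
            body.append(ln)
    if not body:
        raise FormatError(f"{path}: no table body")
    header = body[0].split("\t")
    if header[:3] != ["position", "region", "kind"]:
        raise FormatError(f"{path}: expected columns position, region, kind first")
    species = header[3:]
    sites: list[SiteRecord] = []
    for ln in body[1:]:
        cells = ln.split("\t")
        try:
            position = int(cells[0])
        except ValueError:
            raise FormatError(f"{path}: position not an integer: {cells[0]!r}") from None
        if position < 1:
            raise FormatError(f"{path}: position must be positive: {position}")
        region = cells[1] if cells[1] != "." else ""
        kind = cells[2]
        states = {
            sp: _parse_state(cell, kind) for sp, cell in zip(species, cells[3:])
        }
        motif = ""
        if kind == "indel":
            present = sorted(
                {s[len("present:"):] for st in states.values() for s in st
                 if s.startswith("present:")}
            )
            motif = present[0] if present else ""
        sites.append(SiteRecord(position, kind, states, region=region, motif=motif))
    for sp in species:
        counts.setdefault(sp, 0)
    return CharacterStateTable(locus, sites, counts)


def write_character_table(table: CharacterStateTable, path) -> None:
    species = table.species or sorted(
        {sp for site in table.sites for sp in site.states}
    )
    with open(path, "w") as fh:
        fh.write(f"# locus: {table.locus}\n")
        fh.write(
            "# N: " + "\t".join(f"{sp}={table.counts.get(sp, 0)}" for sp in species)
            + "\n"
        )
        fh.write("position\tregion\tkind\t" + "\t".join(species) + "\n")
        for site in sorted(table.sites, key=lambda s: (s.region, s.position)):
            cells = [str(site.position), site.region or ".", site.kind]
            cells += [_format_state(site.states[sp], site.kind) for sp in species]
            fh.write("\t".join(cells) + "\n")


def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a :class:`dendropy.Tree`."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise FormatError(f"Newick parse error: {exc}") from exc
    return tree

def write_newick(tree: dendropy.Tree) -> str:
    out = _io.StringIO()
    tree.write(
        file=out,
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    return out.getvalue().strip()
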