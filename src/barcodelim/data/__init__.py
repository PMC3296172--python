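"""Curated character-state tables for the *D. lini* sibling-species clade.

One table per locus (ND2, COI-COII, ITS1-ITS2), giving the per-species
nucleotide states at every informative site among the focal strains, with
within-species polymorphism as IUPAC codes and the ITS2 indel characters
coded as presence/absence.  Site numbering follows the per-locus reference
conventions (ND2 on *D. obscura*; COI and COII each on *D. yakuba*; ITS on
*D. ogumai*).
"""

from importlib import resources

from ..alignment_io import CharacterStateTable, read_character_table

_FILES = {
    "ND2": "nd2_lini_clade.tsv",
    "COI-COII": "coi_coii_lini_clade.tsv",
    "ITS": "its_lini_clade.tsv",
}


def load_reference_table(locus: str) -> CharacterStateTable:
    """Load the curated character-state table for a locus.

    ``locus`` is one of ``"ND2"``, ``"COI-COII"``, ``"ITS"``.
    """
    try:
        fname = _FILES[locus]
    except KeyError:
        raise KeyError(f"no reference table for locus {locus!r}; "
                       f"choose from {sorted(_FILES)}") from None
    ref = resources.files(__package__) / fname
    with resources.as_file(ref) as path:
        return read_character_table(path)


def reference_loci() -> list[str]:
    return list(_FILES)
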