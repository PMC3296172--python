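"""Character-based barcoding: state collapsing, indel coding, diagnostics."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from barcodelim.alignment_io import (
    Alignment,
    CharacterStateTable,
    SiteRecord,
    SpeciesPartition,
    iupac_to_set,
)
from barcodelim.diagnostics import (
    build_character_table,
    call_pure_diagnostics,
    code_indels,
    collapse_to_species_states,
    find_informative_sites,
    summarize_delimitation,
)
from barcodelim.errors import ContractViolation, ValidationError


def make_partition(assignment: dict[str, str]) -> SpeciesPartition:
    return SpeciesPartition(dict(assignment), set(assignment.values()))


def make_alignment(rows: dict[str, str], locus="toy", ref_offset=1) -> Alignment:
    return Alignment(locus, list(rows), list(rows.values()), ref_offset=ref_offset)


THREE_SPECIES = {
    "l1": "lini", "l2": "lini",
    "h1": "ohnishii", "h2": "ohnishii",
    "g1": "ogumai", "g2": "ogumai",
}


class TestCollapse:
    def test_fixed_difference_kept(self):
        aln = make_alignment({"l1": "T", "l2": "T", "h1": "T", "h2": "T",
                              "g1": "C", "g2": "C"}, ref_offset=155)
        table = collapse_to_species_states(aln, make_partition(THREE_SPECIES))
        assert len(table.sites) == 1
        site = table.sites[0]
        assert site.position == 155
        assert site.states == {"lini": frozenset("T"), "ohnishii": frozenset("T"),
                               "ogumai": frozenset("C")}

    def test_invariant_column_dropped(self):
        aln = make_alignment({s: "A" for s in THREE_SPECIES})
        table = collapse_to_species_states(aln, make_partition(THREE_SPECIES))
        assert table.sites == []

    def test_within_species_polymorphism_rendered_as_ambiguity(self):
        aln = make_alignment({"l1": "A", "l2": "A", "h1": "A", "h2": "G",
                              "g1": "A", "g2": "A"})
        table = collapse_to_species_states(aln, make_partition(THREE_SPECIES))
        assert len(table.sites) == 1
        assert table.sites[0].states["ohnishii"] == frozenset("AG")

    def test_ambiguity_code_in_input_expanded(self):
        aln = make_alignment({"l1": "R", "l2": "A", "h1": "A", "h2": "A",
                              "g1": "A", "g2": "A"})
        table = collapse_to_species_states(aln, make_partition(THREE_SPECIES))
        assert table.sites[0].states["lini"] == frozenset("AG")

    def test_strain_counts_recorded(self):
        aln = make_alignment({s: "A" for s in THREE_SPECIES})
        table = collapse_to_species_states(aln, make_partition(THREE_SPECIES))
        assert table.counts == {"lini": 2, "ohnishii": 2, "ogumai": 2}

    def test_species_without_strains_rejected(self):
        part = SpeciesPartition({"l1": "lini"}, {"lini", "ghost"})
        aln = make_alignment({"l1": "A"})
        with pytest.raises(ContractViolation):
            collapse_to_species_states(aln, part)


class TestIndelCoding:
    def test_polymorphic_multibase_indel(self):
        block = "GTCAATAATAAAAT"
        gap = "-" * 14
        rows = {
            "l1": f"AA{block}CC", "l2": f"AA{block}CC",
            "h1": f"AA{block}CC", "h2": f"AA{gap}CC",
            "g1": f"AA{block}CC", "g2": f"AA{block}CC",
        }
        records = code_indels(make_alignment(rows, ref_offset=310),
                              make_partition(THREE_SPECIES))
        assert len(records) == 1
        rec = records[0]
        assert rec.position == 312 and rec.motif == block
        assert rec.states["lini"] == frozenset([f"present:{block}"])
        assert rec.states["ohnishii"] == frozenset([f"present:{block}", "absent"])

    def test_single_column_private_insertion(self):
        rows = {"l1": "AA-CC", "l2": "AA-CC", "h1": "AA-CC", "h2": "AA-CC",
                "g1": "AATCC", "g2": "AATCC"}
        records = code_indels(make_alignment(rows), make_partition(THREE_SPECIES))
        assert len(records) == 1
        rec = records[0]
        assert rec.position == 3 and rec.motif == "T"
        assert rec.states["ogumai"] == frozenset(["present:T"])
        assert rec.states["lini"] == frozenset(["absent"])

    def test_no_gaps_no_records(self):
        rows = {s: "ACGT" for s in THREE_SPECIES}
        assert code_indels(make_alignment(rows), make_partition(THREE_SPECIES)) == []

    def test_staggered_gaps_split_into_blocks(self):
        # h2's run covers columns 2-4, g strains' run covers 3-4:
        # minimal identically-bounded blocks are [2,2] and [3,4]
        rows = {"l1": "AACCG", "l2": "AACCG", "h1": "AACCG", "h2": "A---G",
                "g1": "AA--G", "g2": "AA--G"}
        records = code_indels(make_alignment(rows), make_partition(THREE_SPECIES))
        assert [r.position for r in records] == [2, 3]


class TestInformativeSites:
    def test_fixed_and_polymorphic_sites_informative(self):
        table = CharacterStateTable("toy", [
            SiteRecord(155, "substitution",
                       {"a": frozenset("T"), "b": frozenset("T"), "c": frozenset("C")}),
            SiteRecord(552, "substitution",
                       {"a": frozenset("A"), "b": frozenset("AG"), "c": frozenset("A")}),
        ], {"a": 2, "b": 2, "c": 2})
        assert [s.position for s in find_informative_sites(table)] == [155, 552]

    def test_uniform_site_not_informative(self):
        table = CharacterStateTable("toy", [
            SiteRecord(10, "substitution",
                       {"a": frozenset("A"), "b": frozenset("A"), "c": frozenset("A")}),
        ], {"a": 1, "b": 1, "c": 1})
        assert find_informative_sites(table) == []


def states_table(rows: dict[int, tuple[str, str, str]]) -> CharacterStateTable:
    """Build a 3-species table from IUPAC codes per position."""
    sites = [
        SiteRecord(pos, "substitution",
                   {"lini": iupac_to_set(a), "ohnishii": iupac_to_set(b),
                    "ogumai": iupac_to_set(c)})
        for pos, (a, b, c) in rows.items()
    ]
    return CharacterStateTable("toy", sites, {"lini": 7, "ohnishii": 4, "ogumai": 2})


class TestPureDiagnostics:
    def test_fixed_in_one_absent_in_others(self):
        calls = call_pure_diagnostics(states_table({155: ("T", "T", "C")}))
        assert [(c.position, c.species, c.state) for c in calls] == [
            (155, "ogumai", "C")
        ]

    def test_state_inside_other_species_polymorphism_blocks_call(self):
        assert call_pure_diagnostics(states_table({14: ("R", "A", "G")})) == []

    def test_shared_polymorphism_blocks_call(self):
        assert call_pure_diagnostics(states_table({487: ("S", "S", "G")})) == []

    def test_polymorphic_candidate_never_diagnosed(self):
        assert call_pure_diagnostics(states_table({345: ("A", "A", "R")})) == []

    def test_indel_presence_absence_are_comparable_states(self):
        table = CharacterStateTable("toy", [
            SiteRecord(326, "indel",
                       {"lini": frozenset(["absent"]),
                        "ohnishii": frozenset(["absent"]),
                        "ogumai": frozenset(["present:T"])}, motif="T"),
        ], {"lini": 6, "ohnishii": 2, "ogumai": 2})
        calls = call_pure_diagnostics(table)
        assert [(c.species, c.state) for c in calls] == [("ogumai", "present:T")]


def brute_force_diagnostics(aln, partition):
    """Independent checker: test the fixed-in-one / absent-in-others
    condition per column per species directly on the raw alignment."""
    species = sorted(partition.focal_species)
    pools = {sp: partition.strains_of(sp, within=aln.strains) for sp in species}
    found = set()
    for col in range(aln.n_sites):
        col_chars = {s: aln.sequence(s)[col] for s in aln.strains}
        if "-" in col_chars.values():
            continue
        observed = set(col_chars.values())
        if len(observed) == 1 and observed <= set("ACGT"):
            continue  # invariant column: not a candidate site
        for sp in species:
            expanded = [iupac_to_set(col_chars[s]) for s in pools[sp]]
            union = frozenset().union(*expanded)
            if len(union) != 1:
                continue  # not fixed
            (x,) = union
            others = frozenset().union(
                *(iupac_to_set(col_chars[s]) for o in species if o != sp
                  for s in pools[o])
            )
            if x not in others:
                found.add((aln.position(col), sp, x))
    return found


@given(
    data=st.data(),
    n_strains=st.integers(4, 8),
    n_sites=st.integers(5, 30),
)
def test_diagnostics_agree_with_brute_force(data, n_strains, n_sites):
    """Pipeline calls equal a direct per-site check on random alignments."""
    alphabet = "ACGTACGTACGTRYN?"  # mostly plain bases, some ambiguity
    rows = {
        f"s{i}": "".join(
            data.draw(st.sampled_from(alphabet)) for _ in range(n_sites)
        )
        for i in range(n_strains)
    }
    assignment = {
        f"s{i}": f"sp{data.draw(st.integers(0, 2))}" for i in range(n_strains)
    }
    partition = make_partition(assignment)
    aln = make_alignment(rows)
    table = build_character_table(aln, partition)
    calls = call_pure_diagnostics(table, partition.focal_species)
    got = {(c.position, c.species, c.state) for c in calls
           if c.kind == "substitution"}
    assert got == brute_force_diagnostics(aln, partition)


def test_adding_conflicting_strain_destroys_call():
    """Monotonicity: a strain carrying the diagnostic state in another
    species removes the call; redundant strains never create new calls."""
    rows = {"l1": "TA", "l2": "TA", "h1": "TA", "h2": "TA", "g1": "CA", "g2": "CA"}
    part = make_partition(THREE_SPECIES)
    base_calls = call_pure_diagnostics(
        build_character_table(make_alignment(rows), part), part.focal_species
    )
    assert {(c.position, c.species) for c in base_calls} == {(1, "ogumai")}

    # ohnishii gains a strain carrying ogumai's diagnostic C at column 1
    rows2 = dict(rows, h3="CA")
    part2 = make_partition(dict(THREE_SPECIES, h3="ohnishii"))
    calls2 = call_pure_diagnostics(
        build_character_table(make_alignment(rows2), part2), part2.focal_species
    )
    assert calls2 == []

    # a strain carrying only already-present states changes nothing
    rows3 = dict(rows, l3="TA")
    part3 = make_partition(dict(THREE_SPECIES, l3="lini"))
    calls3 = call_pure_diagnostics(
        build_character_table(make_alignment(rows3), part3), part3.focal_species
    )
    assert {(c.position, c.species) for c in calls3} == {(1, "ogumai")}


class TestSummary:
    def test_counts_and_monophyly_columns(self):
        table = states_table({155: ("T", "T", "C"), 552: ("A", "R", "A")})
        calls = call_pure_diagnostics(table)
        df = summarize_delimitation(
            {"toy": table}, {"toy": calls},
            {"toy": {"lini": False, "ohnishii": False, "ogumai": True}},
        )
        row = df[(df.locus == "toy") & (df.species == "ogumai")].iloc[0]
        assert row.n_informative_sites == 2
        assert row.n_diagnostics == 1
        assert row.monophyletic == "yes"
        lini = df[(df.locus == "toy") & (df.species == "lini")].iloc[0]
        assert lini.n_diagnostics == 0 and lini.monophyletic == "no"
        totals = df[df.locus == "total"]
        assert totals.n_diagnostics.sum() == 1

    def test_diagnostics_never_exceed_informative_sites(self, default_dataset):
        alns, part, _ = default_dataset
        tables = {n: build_character_table(a, part) for n, a in alns.items()}
        calls = {n: call_pure_diagnostics(t, part.focal_species)
                 for n, t in tables.items()}
        df = summarize_delimitation(tables, calls)
        assert (df.n_diagnostics <= df.n_informative_sites).all()

    def test_mismatched_species_sets_rejected(self):
        t1 = states_table({1: ("A", "A", "G")})
        t2 = CharacterStateTable("other", [], {"lini": 1, "extra": 1})
        with pytest.raises(ValidationError):
            summarize_delimitation({"a": t1, "b": t2}, {})

    def test_empty_table_gives_zeros(self):
        t = CharacterStateTable("toy", [], {"a": 1, "b": 1})
        df = summarize_delimitation({"toy": t}, {"toy": []})
        assert (df[df.locus == "toy"].n_informative_sites == 0).all()
        assert (df[df.locus == "toy"].n_diagnostics == 0).all()
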