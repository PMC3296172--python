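"""Synthetic multi-locus datasets with the structure the analysis assumes.

The generator evolves sequences along a strain-level tree derived from a
dated (ultrametric, ages in Mya) species tree: each species contributes a
star of strains attached at a fixed within-species depth, branch durations
are converted to expected substitutions/site by a single clock rate, and
characters evolve under the Kimura two-parameter model (transition /
transversion rate ratio ``kappa``).  Optional indel blocks emulate a
multi-base insertion that is polymorphic within one species, and a private
single-base insertion.

The default scenario mirrors the *D. lini* clade study system: three focal
sibling species (7 + 4 + 2 strains) whose crown node sits at 1.42 Mya with
a very recent 0.17-Mya split, a *D. kikkawai*-like outgroup splitting at
2.23 Mya, and a calibration pair (*melanogaster* / *simulans* analogues)
diverging at 5.4 Mya; loci of 926 + 842 + 674 = 2442 aligned sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import yaml

from .alignment_io import Alignment, SpeciesPartition
from .errors import ContractViolation, ScenarioError

__all__ = [
    "LocusSpec",
    "IndelSpec",
    "SimulationScenario",
    "TruthRecord",
    "simulate_strain_tree",
    "simulate_sequences",
    "inject_indel",
    "default_lini_scenario",
    "generate_dataset",
    "load_scenario",
    "save_scenario",
]


@dataclass
class LocusSpec:
    name: str
    length: int
    ref_offset: int = 1
    ref_name: str = ""

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ScenarioError(f"locus {self.name}: length must be >= 1")


@dataclass
class IndelSpec:
    """A planted insertion block.

    ``carriers`` are the species whose strains carry the inserted bases;
    strains of every other species receive gaps over the block.  Within
    ``polymorphic_species`` (one of the carriers) each strain instead
    carries the *deletion* with probability ``frequency``.
    """

    locus: str
    start: int  # 1-based first column of the block within the locus
    length: int
    carriers: set[str]
    polymorphic_species: str | None = None
    frequency: float = 0.5

    def __post_init__(self) -> None:
        if self.length < 1 or self.start < 1:
            raise ScenarioError("indel start and length must be >= 1")
        if self.polymorphic_species is not None and not (
            0.0 < self.frequency < 1.0
        ):
            raise ScenarioError("polymorphic indel frequency must be in (0,1)")


@dataclass
class SimulationScenario:
    """Everything needed to generate one multi-locus dataset."""

    species_newick: str  # ultrametric, branch lengths in My
    strains: dict[str, list[str]]  # species -> strain ids
    focal_species: set[str]
    rate: float  # substitutions/site/My
    kappa: float  # transition/transversion rate ratio
    within_species_depth: float  # Mya; star depth of conspecific strains
    loci: list[LocusSpec]
    indels: list[IndelSpec] = field(default_factory=list)
    calibration_species: tuple[str, str] = ("melanogaster", "simulans")
    calibration_age: float = 5.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate <= 0 or self.kappa <= 0:
            raise ScenarioError("rate and kappa must be positive")
        if self.within_species_depth < 0:
            raise ScenarioError("within_species_depth must be >= 0")

    @property
    def outgroup_species(self) -> set[str]:
        return set(self.strains) - self.focal_species

    def partition(self) -> SpeciesPartition:
        mapping = {
            sid: sp for sp, sids in self.strains.items() for sid in sids
        }
        outgroup = {
            sid
            for sp in self.outgroup_species
            for sid in self.strains[sp]
        }
        return SpeciesPartition(mapping, set(self.focal_species), outgroup)

    def calibration_strains(self) -> set[str]:
        return {
            sid for sp in self.calibration_species for sid in self.strains[sp]
        }


@dataclass
class TruthRecord:
    """Ground truth for downstream checks, reproducible from (scenario, seed)."""

    species_newick: str  # ages in Mya
    strain_newick: str  # branch lengths in substitutions/site
    node_ages: dict[str, float]  # named species-tree nodes -> age (Mya)
    change_counts: dict[str, np.ndarray]  # locus -> per-site edge-change counts
    indels: list[IndelSpec]
    seed: int


def _species_tree(scenario: SimulationScenario) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=scenario.species_newick,
        schema="newick",
        preserve_underscores=True,
    )
    tree.is_rooted = True
    return tree


def simulate_strain_tree(scenario: SimulationScenario) -> dendropy.Tree:
    """Expand the dated species tree into a strain-level tree with branch
    lengths in expected substitutions/site.

    Species with k > 1 strains contribute a star of strains whose lineages
    coalesce at ``within_species_depth`` Mya on the species' ancestral
    lineage.  When that depth predates the species' own origin the star is
    attached to the ancestral lineage shared with its sister species, and
    sibling species reaching the same ancestral edge merge into one star:
    this models retained ancestral polymorphism (incomplete lineage
    sorting), leaving very recent species without exclusive genealogical
    history.  Single-strain species contribute their lineage directly.
    """
    tree = _species_tree(scenario)
    w = scenario.within_species_depth
    ages: dict[dendropy.Node, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ages[node] = 0.0
        else:
            child = node.child_nodes()[0]
            ages[node] = ages[child] + (child.edge.length or 0.0)

    groups: dict[dendropy.Node, list[str]] = {}
    for leaf in list(tree.leaf_node_iter()):
        species = leaf.taxon.label
        try:
            strain_ids = scenario.strains[species]
        except KeyError:
            raise ScenarioError(f"no strains specified for species {species!r}")
        if not strain_ids:
            raise ScenarioError(f"species {species!r} has zero strains")
        if len(strain_ids) == 1:
            leaf.taxon.label = strain_ids[0]
            continue
        anchor = leaf
        while anchor.parent_node is not None and ages[anchor.parent_node] <= w:
            anchor = anchor.parent_node
        if anchor.parent_node is None:
            raise ScenarioError(
                f"within_species_depth {w} reaches beyond the species-tree "
                f"root ({ages[anchor]} Mya)"
            )
        groups.setdefault(anchor, []).extend(strain_ids)

    for anchor, strain_ids in groups.items():
        parent = anchor.parent_node
        star = dendropy.Node()
        parent.remove_child(anchor)
        parent.add_child(star)
        star.edge.length = ages[parent] - w
        for sid in strain_ids:
            child = dendropy.Node()
            child.edge.length = w
            star.add_child(child)
            child.taxon = tree.taxon_namespace.new_taxon(sid)

    # drop replaced species taxa and convert durations to subs/site
    tree.purge_taxon_namespace()
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * scenario.rate
    return tree


def _k80_step(
    states: np.ndarray, d: float, kappa: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Evolve integer-encoded states (A=0, G=1, C=2, T=3) along a branch of
    length ``d`` expected substitutions/site.  Returns (new states, changed
    mask)."""
    if d <= 0.0:
        return states.copy(), np.zeros(len(states), dtype=bool)
    beta_t = d / (kappa + 2.0)
    alpha_t = kappa * beta_t
    e_tv = np.exp(-4.0 * beta_t)
    e_ts = np.exp(-2.0 * (alpha_t + beta_t))
    p_same = 0.25 + 0.25 * e_tv + 0.5 * e_ts
    p_ts = 0.25 + 0.25 * e_tv - 0.5 * e_ts
    p_tv = 0.25 - 0.25 * e_tv  # each of the two transversion targets
    u = rng.random(len(states))
    new = states.copy()
    ts_mask = (u >= p_same) & (u < p_same + p_ts)
    tv1_mask = (u >= p_same + p_ts) & (u < p_same + p_ts + p_tv)
    tv2_mask = u >= p_same + p_ts + p_tv
    new[ts_mask] = states[ts_mask] ^ 1  # flip within purine/pyrimidine class
    other_low = 2 * (1 - states // 2)  # first base of the other class
    new[tv1_mask] = other_low[tv1_mask]
    new[tv2_mask] = other_low[tv2_mask] + 1
    return new, new != states


_ALPHABET = np.array(list("AGCT"))


def simulate_sequences(
    strain_tree: dendropy.Tree,
    locus_length: int,
    kappa: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    locus: str = "locus",
    ref_offset: int = 1,
    ref_name: str = "",
) -> tuple[Alignment, np.ndarray]:
    """Evolve a root sequence (uniform over {A,C,G,T}) along the tree under
    the K2P process.  Returns the alignment and per-site counts of edges on
    which the character state changed."""
    if rng is None:
        rng = np.random.default_rng(seed)
    states: dict[dendropy.Node, np.ndarray] = {}
    changes = np.zeros(locus_length, dtype=int)
    root = strain_tree.seed_node
    states[root] = rng.integers(0, 4, size=locus_length)
    strains: list[str] = []
    seqs: list[str] = []
    for node in strain_tree.preorder_node_iter():
        if node is not root:
            parent_states = states[node.parent_node]
            d = node.edge.length or 0.0
            states[node], changed = _k80_step(parent_states, d, kappa, rng)
            changes += changed
        if node.is_leaf():
            strains.append(node.taxon.label)
            seqs.append("".join(_ALPHABET[states[node]]))
    return (
        Alignment(locus, strains, seqs, ref_offset=ref_offset, ref_name=ref_name),
        changes,
    )


def inject_indel(
    alignment: Alignment,
    spec: IndelSpec,
    partition: SpeciesPartition,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Alignment:
    """Replace the block's bases with gaps in strains lacking the insertion.

    Strains of carrier species keep their simulated bases; strains of the
    polymorphic species carry the deletion with probability ``frequency``;
    all other strains are gapped.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    lo, hi = spec.start - 1, spec.start - 1 + spec.length
    if hi > alignment.n_sites:
        raise ScenarioError(
            f"indel {spec.start}+{spec.length} does not fit locus "
            f"{alignment.locus} ({alignment.n_sites} sites)"
        )
    for seq in alignment.sequences:
        if "-" in seq[lo:hi]:
            raise ScenarioError(
                f"indel region {spec.start}-{spec.start + spec.length - 1} "
                "overlaps a previously injected indel"
            )
    new_seqs = []
    for sid, seq in zip(alignment.strains, alignment.sequences):
        species = partition.species_of(sid)
        if species == spec.polymorphic_species:
            gapped = bool(rng.random() < spec.frequency)
        else:
            gapped = species not in spec.carriers
        if gapped:
            seq = seq[:lo] + "-" * spec.length + seq[hi:]
        new_seqs.append(seq)
    return Alignment(
        alignment.locus,
        list(alignment.strains),
        new_seqs,
        ref_offset=alignment.ref_offset,
        ref_name=alignment.ref_name,
    )


#: Default node ages (Mya) of the study system's species tree.
DEFAULT_AGES = {
    "focal_stem": 2.23,  # lini-clade ancestor splits from the kikkawai-like outgroup
    "focal_crown": 1.42,  # D. ogumai splits from D. lini + D. ohnishii
    "shallow_split": 0.17,  # D. ohnishii splits from D. lini
    "calibration": 5.4,  # melanogaster / simulans divergence
    "root": 8.0,  # subgroup split joining the calibration pair (artifact choice)
}


def default_lini_scenario(seed: int = 0) -> SimulationScenario:
    """The default study-system scenario: 7 + 4 + 2 focal strains, an
    outgroup at 2.23 Mya, a 5.4-Mya calibration pair, three loci totalling
    2442 sites, a 14-bp insertion polymorphic within *D. ohnishii* and a
    1-bp insertion private to *D. ogumai*."""
    a = DEFAULT_AGES
    newick = (
        "((melanogaster:{cal},simulans:{cal}):{up},"
        "(kikkawai:{stem},(ogumai:{crown},(lini:{sh},ohnishii:{sh}):{c2}):{s2}):{k2});"
    ).format(
        cal=a["calibration"],
        up=a["root"] - a["calibration"],
        stem=a["focal_stem"],
        crown=a["focal_crown"],
        sh=a["shallow_split"],
        c2=a["focal_crown"] - a["shallow_split"],
        s2=a["focal_stem"] - a["focal_crown"],
        k2=a["root"] - a["focal_stem"],
    )
    strains = {
        "lini": ["TW3146", "DHS315", "DHS410", "DHS501",
                 "NKS9212", "NKS9231", "NKS9242"],
        "ohnishii": ["MMY309", "MMY326", "MLN24", "MLN45"],
        "ogumai": ["RGN3", "RGN206"],
        "kikkawai": ["OGS4"],
        "melanogaster": ["MEL"],
        "simulans": ["SIM"],
    }
    all_species = set(strains)
    return SimulationScenario(
        species_newick=newick,
        strains=strains,
        focal_species={"lini", "ohnishii", "ogumai"},
        rate=0.02,
        kappa=4.0,
        # deeper than the 0.17-Mya split: the two youngest species share
        # ancestral polymorphism and have no exclusive genealogical history
        within_species_depth=0.25,
        loci=[
            LocusSpec("ND2", 926, ref_offset=34, ref_name="D. obscura"),
            LocusSpec("COI-COII", 842, ref_offset=1, ref_name="D. yakuba"),
            LocusSpec("ITS", 674, ref_offset=1, ref_name="D. ogumai"),
        ],
        indels=[
            IndelSpec("ITS", 312, 14, carriers=all_species,
                      polymorphic_species="ohnishii", frequency=0.5),
            IndelSpec("ITS", 326, 1, carriers={"ogumai"}),
        ],
        calibration_species=("melanogaster", "simulans"),
        calibration_age=a["calibration"],
        seed=seed,
    )


def generate_dataset(
    scenario: SimulationScenario, seed: int | None = None
) -> tuple[dict[str, Alignment], SpeciesPartition, TruthRecord]:
    """Simulate all loci of a scenario.

    All randomness flows from a single generator seeded with ``seed``
    (default: the scenario's own seed), so output is bit-exactly
    reproducible from (scenario, seed).
    """
    if seed is None:
        seed = scenario.seed
    rng = np.random.default_rng(seed)
    strain_tree = simulate_strain_tree(scenario)
    partition = scenario.partition()
    alignments: dict[str, Alignment] = {}
    change_counts: dict[str, np.ndarray] = {}
    for locus in scenario.loci:
        aln, changes = simulate_sequences(
            strain_tree,
            locus.length,
            scenario.kappa,
            rng=rng,
            locus=locus.name,
            ref_offset=locus.ref_offset,
            ref_name=locus.ref_name,
        )
        for spec in scenario.indels:
            if spec.locus == locus.name:
                aln = inject_indel(aln, spec, partition, rng=rng)
        alignments[locus.name] = aln
        change_counts[locus.name] = changes
    truth = TruthRecord(
        species_newick=scenario.species_newick,
        strain_newick=strain_tree.as_string(schema="newick").strip(),
        node_ages=dict(DEFAULT_AGES),
        change_counts=change_counts,
        indels=list(scenario.indels),
        seed=seed,
    )
    return alignments, partition, truth


def save_scenario(scenario: SimulationScenario, path) -> None:
    doc = {
        "species_newick": scenario.species_newick,
        "strains": {sp: list(s) for sp, s in scenario.strains.items()},
        "focal_species": sorted(scenario.focal_species),
        "rate": scenario.rate,
        "kappa": scenario.kappa,
        "within_species_depth": scenario.within_species_depth,
        "loci": [
            {"name": l.name, "length": l.length,
             "ref_offset": l.ref_offset, "ref_name": l.ref_name}
            for l in scenario.loci
        ],
        "indels": [
            {"locus": i.locus, "start": i.start, "length": i.length,
             "carriers": sorted(i.carriers),
             "polymorphic_species": i.polymorphic_species,
             "frequency": i.frequency}
            for i in scenario.indels
        ],
        "calibration_species": list(scenario.calibration_species),
        "calibration_age": scenario.calibration_age,
        "seed": scenario.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_scenario(path) -> SimulationScenario:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        return SimulationScenario(
            species_newick=doc["species_newick"],
            strains={sp: list(s) for sp, s in doc["strains"].items()},
            focal_species=set(doc["focal_species"]),
            rate=float(doc["rate"]),
            kappa=float(doc["kappa"]),
            within_species_depth=float(doc["within_species_depth"]),
            loci=[LocusSpec(**l) for l in doc["loci"]],
            indels=[
                IndelSpec(
                    locus=i["locus"], start=i["start"], length=i["length"],
                    carriers=set(i["carriers"]),
                    polymorphic_species=i.get("polymorphic_species"),
                    frequency=i.get("frequency", 0.5),
                )
                for i in doc.get("indels", [])
            ],
            calibration_species=tuple(doc["calibration_species"]),
            calibration_age=float(doc["calibration_age"]),
            seed=int(doc.get("seed", 0)),
        )
    except KeyError as exc:
        raise ContractViolation(f"scenario file missing key: {exc}") from None
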