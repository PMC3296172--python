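"""Concatenation into a supermatrix and single-point calibration dating.

Dating proceeds in two steps on a rooted tree with branch lengths in
substitutions/site: (1) *mean path length* ultrametricization — each
internal node's height is the average path length from the node to its
descendant tips, clamped so a parent is never shallower than a child; and
(2) linear scaling so that the node calibrated to a known age (here the
*D. melanogaster* / *D. simulans* split at 5.4 Mya by default) gets exactly
that age:  age(v) = height(v) * T_cal / height(calibration MRCA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

from .alignment_io import Alignment
from .errors import ContractViolation, DegenerateCalibrationError, ValidationError

__all__ = [
    "Supermatrix",
    "CalibrationPoint",
    "DatedTree",
    "concatenate_loci",
    "ultrametricize",
    "calibrate_ages",
]

DEFAULT_CALIBRATION_AGE_MYA = 5.4


@dataclass
class Supermatrix:
    """Concatenated multi-locus alignment with per-locus column ranges."""

    strains: list[str]
    sequences: list[str]
    partitions: list[tuple[str, int, int]]  # (locus, start, end), 1-based incl.

    def __post_init__(self) -> None:
        expected = 1
        for locus, start, end in self.partitions:
            if start != expected or end < start:
                raise ContractViolation(
                    f"partitions must tile the supermatrix; {locus} spans "
                    f"{start}-{end}, expected start {expected}"
                )
            expected = end + 1
        width = expected - 1
        for sid, seq in zip(self.strains, self.sequences):
            if len(seq) != width:
                raise ContractViolation(
                    f"strain {sid}: sequence length {len(seq)} != partition "
                    f"total {width}"
                )

    @property
    def width(self) -> int:
        return self.partitions[-1][2] if self.partitions else 0

    def to_alignment(self, locus: str = "concatenated") -> Alignment:
        return Alignment(locus, list(self.strains), list(self.sequences))


@dataclass
class CalibrationPoint:
    """A clade whose MRCA has a known age in Mya."""

    clade: set[str]
    age: float = DEFAULT_CALIBRATION_AGE_MYA

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ContractViolation("calibration age must be positive")
        if len(self.clade) < 2:
            raise ContractViolation("calibration clade needs >= 2 strains")


@dataclass
class DatedTree:
    """Rooted tree with ultrametricized node heights and calibrated ages."""

    tree: dendropy.Tree
    heights: dict[dendropy.Node, float]
    ages: dict[dendropy.Node, float]
    clamped_nodes: list[dendropy.Node] = field(default_factory=list)

    def age_of_mrca(self, strains: set[str]) -> float:
        node = self.tree.mrca(taxon_labels=sorted(strains))
        if node is None:
            raise ContractViolation(f"no MRCA for {sorted(strains)}")
        return self.ages[node]


def concatenate_loci(
    alignments: list[Alignment], mode: str = "intersection"
) -> Supermatrix:
    """Concatenate per-locus alignments column-wise over shared strains.

    ``mode="intersection"`` (default) keeps only strains present in every
    locus, preserving the strain order of the first alignment;
    ``mode="pad"`` keeps the union, padding missing strains with ``?``.
    """
    if not alignments:
        raise ContractViolation("need at least one alignment")
    if mode not in ("intersection", "pad"):
        raise ContractViolation(f"unknown concatenation mode: {mode!r}")
    if mode == "intersection":
        shared = set(alignments[0].strains)
        for aln in alignments[1:]:
            shared &= set(aln.strains)
        strains = [s for s in alignments[0].strains if s in shared]
        if not strains:
            raise ValidationError("no strain is present in every locus")
    else:
        strains = list(alignments[0].strains)
        seen = set(strains)
        for aln in alignments[1:]:
            for s in aln.strains:
                if s not in seen:
                    strains.append(s)
                    seen.add(s)

    partitions: list[tuple[str, int, int]] = []
    pieces: dict[str, list[str]] = {s: [] for s in strains}
    start = 1
    for aln in alignments:
        width = aln.n_sites
        partitions.append((aln.locus, start, start + width - 1))
        start += width
        for s in strains:
            if s in aln.strains:
                pieces[s].append(aln.sequence(s))
            else:
                pieces[s].append("?" * width)
    return Supermatrix(strains, ["".join(pieces[s]) for s in strains], partitions)


def ultrametricize(rooted_tree: dendropy.Tree) -> tuple[
    dict[dendropy.Node, float], list[dendropy.Node]
]:
    """Mean-path-length node heights for a rooted tree.

    height(v) = mean over descendant tips of the path length from v to the
    tip; tips have height 0.  Heights are then clamped top-down so that
    h(parent) >= h(child); clamped nodes are returned for reporting.
    """
    heights: dict[dendropy.Node, float] = {}
    # postorder: accumulate (sum of tip path lengths, tip count)
    agg: dict[dendropy.Node, tuple[float, int]] = {}
    for node in rooted_tree.postorder_node_iter():
        if node.is_leaf():
            agg[node] = (0.0, 1)
            heights[node] = 0.0
        else:
            total, count = 0.0, 0
            for child in node.child_nodes():
                s, c = agg[child]
                total += s + c * (child.edge.length or 0.0)
                count += c
            agg[node] = (total, count)
            heights[node] = total / count
    clamped: list[dendropy.Node] = []
    for node in rooted_tree.preorder_node_iter():
        parent = node.parent_node
        if parent is not None and not node.is_leaf():
            if heights[node] > heights[parent]:
                heights[node] = heights[parent]
                clamped.append(node)
    return heights, clamped


def calibrate_ages(
    rooted_tree: dendropy.Tree,
    heights: dict[dendropy.Node, float],
    calibration: CalibrationPoint,
    clamped_nodes: list[dendropy.Node] | None = None,
) -> DatedTree:
    """Convert node heights to ages in Mya by linear scaling at one node."""
    mrca = rooted_tree.mrca(taxon_labels=sorted(calibration.clade))
    if mrca is None:
        raise ContractViolation(
            f"calibration clade has no MRCA: {sorted(calibration.clade)}"
        )
    h_cal = heights[mrca]
    if h_cal <= 0.0:
        raise DegenerateCalibrationError(
            "calibration node height is zero; cannot scale to absolute time"
        )
    factor = calibration.age / h_cal
    ages = {node: h * factor for node, h in heights.items()}
    return DatedTree(rooted_tree, heights, ages, clamped_nodes or [])
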