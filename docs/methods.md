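# Methods

## The delimitation problem

Three sibling species — *Drosophila lini*, *D. ohnishii* and *D. ogumai* —
are nearly indistinguishable morphologically but partially reproductively
isolated.  Given multiple isofemale strains per species sequenced at
*ND2*, *COI-COII* and ITS1-ITS2, two barcoding questions are asked per
locus: does each species form a clade in the gene tree (phylogeny-based
delimitation), and does any site carry a state fixed in one species and
absent from the others (character-based delimitation)?  A third analysis
dates the splits on a concatenated tree using one external calibration.

## Character-based diagnostics

Strains are collapsed to per-species state sets per aligned column.  A
strain's character contributes its expanded IUPAC set; `?` contributes
{A,C,G,T}.  This is deliberately conservative: missing or ambiguous data
can only widen a species' state set and therefore *remove* candidate
diagnostics, never create them.

* **Informative site** — any column variable among the focal strains,
  including columns whose only variation is a within-species polymorphism
  (rendered as an ambiguity code, e.g. A/G → R).  This is intentionally
  weaker than parsimony-informativeness, which would drop
  polymorphism-only sites.
* **Pure simple diagnostic** — species *S* at site *p* with state set
  {x} (fixed) such that x is not in the union of the other focal species'
  sets at *p*.  A species polymorphic at *p* is never diagnosed there.
  Diagnostics are computed among focal species only; outgroups are
  excluded from the comparison.
* **Indel coding** — each maximal run of contiguous columns with an
  identical set of gapped strains becomes one presence/absence character
  (staggered runs split into minimal identically-bounded blocks, with a
  warning).  A strain's "present" state records its own ungapped motif, so
  carriers with different motifs count as different states; the character's
  canonical motif is the per-column majority consensus of carriers.
  Columns inside gapped regions are excluded from substitution coding, so
  an indel region contributes exactly one character.

## Distances, trees, support

K2P distances use P (transition proportion) and Q (transversion
proportion) over the columns where both sequences carry a plain
nucleotide; gaps, `?` and ambiguity codes are pairwise-deleted, the common
default of distance-matrix software.  Pairs with no shared columns raise
an undefined-distance error; pairs beyond the model's valid range
(1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0) raise a saturation error naming the pair.

NJ follows Saitou & Nei's Q-criterion.  Two numerical conventions make
results reproducible and well-formed: exact ties in Q are broken by the
lexicographically smallest pair of cluster representatives (a cluster is
represented by its smallest strain label), and negative branch-length
estimates are clamped to zero with the deficit moved to the sister branch.

Bootstrap support for each internal edge of the full-data NJ tree is the
percentage of column-resampled replicates whose NJ tree contains the same
bipartition (supports are mapped onto the full-data topology, not a
consensus tree).  Replicates with an undefined pairwise distance are
redrawn and counted.  Internal edges of length zero are reported with
support 0: they are unresolved, and the deterministic tie-break would
otherwise hand them spurious unanimous support.  Monophyly of a strain set
on a rooted tree means some node's descendant set equals it exactly;
singletons are trivially monophyletic.  The per-locus concordance summary
is the plain fraction of loci whose rooted tree contains a clade — a
deliberate lightweight substitute for Bayesian concordance factors, which
are out of scope.

## Concatenation and dating

Loci are concatenated over the strains present in every locus
(intersection, default) or over the union with `?`-padding; partitions
record 1-based inclusive column ranges.  Dating is a two-step
transformation of the rooted NJ tree:

1. **Mean path length (MPL) heights** — h(v) = average path length from v
   to its descendant tips.  Since NJ branch lengths need not be clock-like,
   a child's height can exceed its parent's; such heights are clamped to
   the parent's and the clamp reported rather than failing.
2. **Single-point calibration** — age(v) = h(v) · T_cal / h(v_cal), with
   the *melanogaster*/*simulans* node at T_cal = 5.4 Mya by default.  Ages
   are scale-equivariant: rescaling all branch lengths leaves them
   unchanged.

MPL is the simplest defensible clock estimator for an NJ tree; no claim is
made that it matches any particular legacy software's dating routine.
Rate smoothing, relaxed clocks and age confidence intervals are out of
scope.

## The synthetic-data generator

The generator emulates the study design, not any particular dataset.  Its
species tree places the focal crown (the *D. ogumai* split) at 1.42 Mya
and the *D. lini* / *D. ohnishii* split at 0.17 Mya, with a
*D. kikkawai*-like outgroup at the 2.23-Mya focal stem, the calibration
pair splitting at 5.4 Mya, and a root at 8.0 Mya joining the two subgroups
(the root age is an artifact choice; only relative depths below the
calibration node matter downstream).

Strain sampling follows the study: 7 + 4 + 2 focal strains, one strain per
outgroup species.  Conspecific strains coalesce in a star at a fixed
within-species depth on their species' ancestral lineage.  When that depth
predates a species' origin, the star attaches to the shared ancestral
lineage and sibling species reaching the same edge merge into one star —
the default depth of 0.25 My therefore leaves *D. lini* and *D. ohnishii*
with *no* exclusive genealogical history, a deliberately crude emulation
of incomplete lineage sorting that reproduces the observed pattern
(intermingled strains, zero diagnostics) without a coalescent model.  A
star is not a coalescent: it has no variance in coalescence times and no
topology within species, so within-species tree shape carries no signal.

Sequences evolve site-independently under the K2P process (uniform root
state; transition/transversion rate ratio kappa) along branch lengths in
expected substitutions/site (duration × rate).  Defaults, chosen once as
field-realistic values and recorded here because the study system provides
none: rate 0.02 substitutions/site/My (calibration depth 5.4 My →
~0.11 substitutions/site root-to-tip, a typical fast-mtDNA scale),
kappa 4.0.  Two indels are planted in ITS: a 14-bp block
(GTCAATAATAAAAT-like coordinates 312–325) carried by all species but
deleted with probability 0.5 per *D. ohnishii* strain, and a 1-bp
insertion private to *D. ogumai* at position 326.  All randomness flows
from one seeded generator; outputs are bit-exactly reproducible from
(scenario, seed).

What passing simulation tests does and does not show: they demonstrate
that the pipeline recovers planted ages (mean error of the two deepest
focal nodes well under 15% over 20 replicates at 2442 sites) and the
qualitative delimitation asymmetry under the model's own assumptions
(strict clock, no rate variation among sites or lineages, star
genealogies, no recombination, no introgression).  Real data violate all
of these to some degree; in particular the generator cannot test
robustness to rate heterogeneity or to gene flow.

## Problem sizes and tolerances

The acceptance script and the recovery tests use 20 replicates of the
default 2442-site, 16-strain scenario — enough for the replicate mean of
each node age to stabilise well inside the 15% band — and the oracle
checks use exhaustive additive-matrix recovery for up to 6 taxa plus
brute-force monophyly on 12-leaf trees.  Numerical tolerances: NJ
symmetry check 1e−9; additive-matrix recovery asserted to 1e−9; K2P
closed-form agreement to 1e−12.

## Known limitations

* Character tables assume the focal species sets match across loci;
  per-locus strain counts may differ (ITS covers fewer strains).
* The two-range COI/COII reference numbering lives in the character-table
  `region` column; `Alignment` itself carries a single offset.
* MPL dating inherits NJ's branch-length noise; for very unclocklike trees
  many clamps will be reported and ages should be read sceptically.
* Bootstrap on alignments with heavy missing data can redraw many
  replicates; the count is logged.
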