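# barcodelim

Character-based DNA barcoding, distance phylogenetics and calibrated
divergence dating for delimiting sibling species — built around the
*Drosophila lini* clade (*D. lini*, *D. ohnishii*, *D. ogumai*), three
morphologically near-indistinguishable species whose strains were sequenced
at two mitochondrial loci (*ND2*, *COI-COII*) and the nuclear ITS1-ITS2
region.

The package is for systematists and molecular ecologists who want to ask,
for a small clade with multiple strains per species: *which species can DNA
barcoding actually diagnose, and what does the multilocus phylogeny say
about their ages?*  It implements:

* **Pure simple diagnostic characters.**  Strains are collapsed to
  per-species state sets (within-species polymorphism as IUPAC codes,
  e.g. R = A/G); a site diagnoses species *S* iff *S* is fixed for a state
  *x* there and *x* is absent from every other focal species.  Indel blocks
  are coded as presence/absence characters with their motif.
* **K2P / Neighbor-Joining phylogenetics.**  Kimura 2-parameter distances
  d = −½·ln[(1 − 2P − Q)·√(1 − 2Q)] (P transitions, Q transversions) with
  pairwise deletion of gaps/missing data, Saitou–Nei NJ with deterministic
  tie-breaking, nonparametric bootstrap supports, outgroup rooting and
  species-monophyly tests.
* **Calibrated dating.**  Concatenation into a partitioned supermatrix,
  mean-path-length ultrametricization of the NJ tree, and linear scaling of
  node heights at a single calibration node (default: the
  *D. melanogaster* / *D. simulans* split at 5.4 Mya).
* **A synthetic-data generator** reproducing the study design: a dated
  species tree (focal stem 2.23 Mya, crown 1.42 Mya, a 0.17-Mya split
  shallower than the within-species coalescent depth), K2P sequence
  evolution, and the 14-bp ITS2 insertion polymorphic within *D. ohnishii*.

## Worked example

Curated per-locus character-state tables for the clade ship with the
package.  Calling diagnostics on the *ND2* table:

```sh
$ barcodelim diagnose --table src/barcodelim/data/nd2_lini_clade.tsv
locus: ND2
informative sites: 20
diagnostics for D. lini: 0
diagnostics for D. ogumai: 11
diagnostics for D. ohnishii: 0
  155	substitution	D. ogumai	C
  342	substitution	D. ogumai	T
  411	substitution	D. ogumai	G
  ...
```

Of the 20 sites that vary among the 13 focal strains, 11 carry a nucleotide
fixed in *D. ogumai* and absent from its siblings — that species is fully
diagnosable — while *D. lini* and *D. ohnishii*, whose strains intermingle
in the gene trees, have none.  The same pattern holds for *COI-COII*
(12 informative sites, 5 diagnostics) and ITS (4 sites, 2 substitutions
plus a private 1-bp insertion).

The full pipeline on a simulated dataset:

```sh
barcodelim simulate --scenario default --out demo --seed 1
barcodelim tree --alignment demo/ND2.fasta --species-map demo/species_map.tsv \
    --bootstrap 200 --seed 1
```

which prints the rooted Newick tree with bootstrap percentages and, per
focal species, a monophyly verdict (`ogumai: monophyletic`,
`lini: non-monophyletic`, ...).  `barcodelim run-all --config config.yaml`
adds concatenation, dating and a TSV report mirroring the per-locus
diagnostic tables; `node_ages.tsv` lists each clade's height
(substitutions/site) and calibrated age (Mya).

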