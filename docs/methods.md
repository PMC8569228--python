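# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `evasinclass`. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Problem setting

Evasins are secreted tick salivary proteins that bind host chemokines;
class A binds CC-chemokines and class B binds CXC-chemokines. Candidate
evasin-like proteins are recovered from transcriptome-derived protein
sequences by homology to the ~50 biochemically characterized evasins, and
their relationship to the characterized proteins is resolved with a
distance-based phylogeny rooted at the midpoint (no outgroup species
exists: no evasin is known from a lineage diverging before the
Prostriate/Metastriate split). The two clades descending from the root
define the classes.

## Mature-protein derivation and filtering

The protein start is the **first methionine** of each sequence, applied
literally (upstream non-Met residues are ignored; a record with no Met is
dropped with its own reason, since it cannot satisfy the rule). The
signal-peptide cleavage position comes from a pluggable
`CleavageProvider`:

* **table provider** — a TSV of per-record 1-based mature-start positions,
  the normal route for real data (fill it from any dedicated
  signal-peptide predictor's output);
* **heuristic provider** — a deliberately simple hydrophobicity rule
  matched to the synthetic generator: within positions 2..`window`
  (default 20) of the Met-anchored sequence, call a signal peptide when at
  least 8 residues are hydrophobic (`AILVFMW`) and cleave after the last
  hydrophobic residue of the window. It is a stand-in for exercising the
  pipeline end-to-end, not a predictor for real proteins.

Filters: records lacking a signal peptide and records with `*` anywhere in
the predicted **mature** sequence are dropped (`no_signal`,
`internal_stop`). A stop upstream of the mature start does not drop a
record, because the filter is defined on the mature protein only.
Filtering partitions the input (every record kept or dropped with exactly
one reason) and is idempotent on the kept set.

## Homology screen

Every candidate mature sequence is aligned against every query with exact
Smith–Waterman under affine gaps (Gotoh; BLOSUM62; BLAST-style gap cost
`11 + k·1` for a length-k gap). Scores become expectation values via the
Karlin–Altschul form `E = K·m·n·e^(−λS)` with `K = 0.041`, `λ = 0.267`
(values typical of gapped BLOSUM62 scoring), `m` the query length and `n`
the summed candidate lengths unless overridden. A candidate is kept iff
its best E-value is **strictly** below the threshold (default `1e-4`).
"Distinct sequences" is read minimally: byte-identical mature sequences
collapse to the lexicographically smallest id, with the collapse map
written as an artifact (`dedup_map.tsv`).

This reproduces the keep/drop *decision* of a BLAST screen at a permissive
threshold, not BLAST's composition-adjusted statistics; on real data,
candidates sitting within a factor of a few of E ≈ 1e-4 may fall on the
other side of the boundary than a true BLAST run would place them.

## Motif scanning

Patterns are compiled from PROSITE-style strings (`C-x(3)-C-...`);
whitespace inside a printed pattern is treated as typesetting noise. The
scanner enumerates **all** anchor placements compatible with the gap
ranges (depth-first, leftmost start anchor first, shorter gaps first), so
overlapping occurrences are all reported; `x` matches any residue
including cysteine (standard PROSITE semantics — extra cysteines in gaps
must not block a match, since cysteine count is tallied separately). The
pattern is unanchored: the full mature sequence is scanned, as no
N-terminal window is part of the motif definitions. Spans are computed
from the compiled pattern (Cys6: 29–37 residues; Cys8: 69–81).

## Alignment

Progressive alignment in the ClustalW mould: pairwise global affine-gap
alignments (exact DP, end gaps penalized) give distances
`1 − fraction identical`; a UPGMA guide tree (average linkage,
lexicographic tie-breaks) orders profile–profile merges; profile columns
are scored by the average substitution score over all residue pairs (gap
symbols score 0) and gaps opened at a merge are propagated to all members
("once a gap, always a gap"). DP tie-breaks prefer match/mismatch over
gaps, then a gap in the first profile — making the result deterministic
for a fixed input order. Input-order *independence* is not promised:
progressive alignment is order-sensitive through tie-breaks.

The default matrix is BLOSUM62 with Gonnet-250 (`GONNET1992`) selectable.
Downstream distances are identity-based, so the matrix choice moves column
placement only at the margins; it is a logged configuration knob.

## Distances, NJ, bootstrap, midpoint root

* **Identity distance**: `d = sqrt(1 − matches/compared)` per pair, with
  pairwise deletion (only mutually non-gap columns compared) as the
  default and complete deletion as an option. A pair with zero comparable
  columns gets `d = 1` with a warning.
* **Neighbour joining** (Saitou–Nei): join the pair minimizing
  `Q(i,j) = (r−2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k)`; branch lengths by the
  standard two-point formulas; a negative length estimate is clamped to
  zero with the deficit moved to the sibling edge (preserving the pair's
  path length); Q ties are broken by the smallest index pair in the
  current cluster ordering, with the merged cluster taking the lower slot.
  On additive matrices the tree's path lengths reproduce the input to
  machine precision (asserted in tests against randomly generated additive
  trees, and cross-checked topologically against scikit-bio's independent
  NJ).
* **Bootstrap** (default 100 replicates): columns resampled with
  replacement, same count; a replicate's occasional all-gap columns are
  removed (they carry no signal); support of an internal edge = fraction
  of replicate trees containing the same leaf bipartition (bipartitions
  compared as canonical leaf sets, branch lengths ignored). Deterministic
  given the seed. Supports are fractions in [0, 1], rendered ×100 as
  Newick internal-node labels.
* **Midpoint root**: root at the midpoint of the longest leaf-to-leaf
  path, which provably minimizes the maximum root-to-leaf depth
  (= diameter/2, the property the tests assert); ties among equally long
  paths break by the lexicographically smallest leaf-label pair; a
  midpoint landing exactly on a node yields a zero-length root edge. An
  all-zero-length tree is an error (midpoint undefined) with a pointer to
  inspect the distance matrix.

## Classification

`root_partition` returns the leaf sets of the root's two children (larger
first, then smallest-leaf). Classes are named by **lineage majority**, not
size: the clade with the larger Metastriate fraction is `A1`/`B1`
(ties: larger clade, then smallest leaf). Rationale: the published class
definitions anchor A1 to Metastriate and A2 to Prostriate ticks, so
lineage is the semantic anchor. Purity (largest lineage fraction) is
always reported; under scheme A a purity below 1.0 warns (the real class A
tree separates lineages perfectly), under scheme B mixing is expected and
silent. Genus→lineage mapping is an explicit table (Ixodes → Prostriate;
Amblyomma, Dermacentor, Hyalomma, Rhipicephalus → Metastriate), extensible
by TSV; an unknown genus (e.g. a soft tick such as *Ornithodoros*) is an
error, never a silent default. No bootstrap threshold gates
classification; the support of the class-defining edges is reported
alongside.

Subclades (`B1.1`/`B1.2`) come from the two children of the node defining
a clade, labelled by the same convention. The two evasin families are
analysed as two independent pipeline runs (one tree per family), never as
one mixed tree.

## Summaries

Count tables are long TSVs keyed by species or lineage × class, counting
distinct record ids; species counts sum to their lineage rollup. The
binding summary counts **distinct chemokines** per species/lineage split
by chemokine class (CC/CXC/CX3C/XC; unknown tags are errors) — a chemokine
bound by several evasins of one species counts once. (The alternative,
counting evasin–chemokine pairs, is a one-line change but is not the
default.) The heatmap information file has one row per record with the
four annotation circles: lineage, Cys6/Cys8 presence, cysteine count, and
number of chemokines bound (blank for uncharacterized records). Binding
annotations enter as a user-supplied TSV compiled from published binding
data; the test suite uses small synthetic tables.

## Synthetic data: what it emulates, what it does not

Each non-decoy precursor is `M` + signal peptide + mature body. The signal
peptide is hydrophobic-biased (85% from `AILVFMW`, at least 8 hydrophobic
residues, last position hydrophobic) so the heuristic provider recovers
the true cleavage site exactly; the first mature residue is kept
hydrophilic (unless it is a motif anchor cysteine, which also breaks the
hydrophobic run) so the boundary is unambiguous. Mature bodies carry one
planted motif occurrence with gap widths sampled uniformly within each
stated range; all non-anchor positions are drawn from the 19-letter
non-cysteine alphabet, so the planted anchors are the only cysteines and
accidental motif matches are impossible by construction (a "none"-motif
body contains no cysteines at all).

Two-lineage divergence: the lineage-2 ancestor derives from the lineage-1
ancestor by substituting non-anchor sites at the between-lineage rate
(default 0.40 expected substitutions/site) and re-planting its own motif;
members substitute their ancestor's non-anchor sites at the within-lineage
rate (default 0.05). Anchor cysteines never mutate (the real families
conserve their frameworks), and substitutions never introduce cysteine.
Defaults (10+10 sequences, mature length 90, signal length 20, 0.05/0.40
rates, one decoy of each kind) are the package's study conditions: the
real data give no numeric divergence rates, so the defaults were chosen
once as a regime a two-clade tree should clearly resolve — between-rate
well above within-rate — and are asserted as a config invariant
(within < between) because the planted partition is otherwise
unrecoverable.

Decoys: `no_signal` records replace the signal peptide with hydrophilic
residues (and are omitted from the cleavage table); `stop` records carry a
`*` at a random non-anchor mature position; `unrelated` records have an
independently drawn mature body with no homology to the ancestors —
removed by the screen, not the ingest filters. The generator is
deterministic: identical config+seed yield byte-identical files.

Not emulated: codon-level evolution, indels (substitution-only), rate
heterogeneity across sites, compositional bias of real tick proteins, and
realistic signal-peptide architecture. Passing tests therefore demonstrate
the correctness and internal consistency of the algorithms and the
recoverability of a clean two-clade signal — not performance on real
transcriptome data, where divergence is deeper, alignment is harder and
BLAST/SignalP statistics differ from the desk-scale stand-ins.

## Problem sizes and reproducibility

The acceptance script analyses a 20-seed panel at the default condition
(23 records/run, 100 bootstrap replicates) plus 200 random alignment pairs
and 50 random trees for the oracle checks — sizes chosen so a complete
from-scratch rerun finishes in about a minute on one CPU while every
stochastic claim still rests on a multi-seed panel. All randomness flows
from a single top-level seed via fixed per-stage derivations
(`numpy.random.SeedSequence`); manifests contain artifact checksums, the
configuration hash, seed and version — and deliberately no timestamp — so
identical config+seed reproduce byte-identical manifests.

## Known limitations

* BLAST's composition-based statistics are not reproduced; the screen's
  E-values agree in decision, not in value.
* The progressive aligner is a single-pass ClustalW-style implementation:
  no sequence weighting, no position-specific gap penalties, no iterative
  refinement.
* The heuristic cleavage provider is only meaningful on data following the
  generator's signal model.
* Reproduction of the published class A/B trees (205/87 clade sizes,
  species tallies) requires the deposited record lists, which are not
  distributed here; the corresponding acceptance test fails until those
  files are supplied.
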