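# Methods

## Data model

The analysis substrate is an organism × trait **abundance** matrix of
non-negative integer copy counts, with an organism metadata table
(superkingdom ∈ {A, B, E}, lifestyle, annotation-coverage fraction).
**Occurrence** is always derived as abundance ≥ 1 and never stored
separately; every statistic in the package reduces to these two views.

Dataset construction applies, in order: (i) the coverage filter — an
organism is retained when its annotation coverage is ≥ the threshold
(default 0.5; inclusive, so an organism at exactly 50% stays) or when
coverage was never assessed; (ii) optionally the free-living filter
(anything not explicitly `free_living` is dropped); (iii) removal of
traits on an explicit exclusion list; (iv) removal of traits left with
zero occurrence after the organism filters.  Both organism-filter counts
are reported independently (an organism can fail both), and the identity
`retained = input − exclusion hits − zero-occurrence drops` is asserted on
every run.  Strain-level exclusion is the metadata curator's job (a
lifestyle/level column), not inferred from organism names.

## Statistics and conventions

**Venn census.** Presence of a trait in a superkingdom is existential
(≥ 1 organism); group labels concatenate letters in A < B < E order.  The
partition property (seven mutually exclusive groups summing to the trait
total) is enforced by construction and audited end-to-end.

**f-values.** f(trait, s) = occurrences in superkingdom *s* / organism
count of *s*.  The denominator is always the superkingdom's full retained
organism count; the Venn group only selects which superkingdoms are
reported for a trait (where f is necessarily > 0).  Panel summaries use
linear-interpolation quartiles; the tail count uses strict f > 0.8.
Near-universality uses the **overall** f across all retained organisms
(strictly > 0.90 by default), the weaker and simpler reading of the two
possible conventions; the per-superkingdom variant is computable from the
same profiles.

**Display precision.** Computation is full double precision throughout;
display truncates (floors) rather than rounds fractional values: per-trait
f at 3 decimals (so 1/652 reports 0.001) and mapped percentages at 2
decimals (so 1871/1924 reports 97.24%).  Integer percentage shares round
to the nearest percent.  Decisions (e.g. transfer calls) never depend on
display precision.

**HGT rule.** Applied only to AB, AE, BE traits.  The call criterion is
|f_former − f_latter| > θ with θ = 0.6 by default and a strict boundary:
a difference of exactly 0.6 yields no call (an absolute float-noise guard
of 1e-12 keeps representable boundaries like 0.8 − 0.2 below threshold).
Direction is purely the sign of the difference — donor is the high-spread
side; exact ties need no tie-break (difference 0).  The rule is
deliberately conservative: it detects only donor-ubiquitous /
recipient-scarce patterns and cannot see rapid intra-superkingdom or
reciprocal transfers.

**Abundance summaries.** Per-organism group totals are transformed as
log10(x + 1) — the +1 keeps organisms with zero abundance in a group in the
panel — and summarised by a five-number summary with Tukey 1.5×IQR
outliers; extreme organisms are named with ties broken by organism id.
The per-organism total (not a per-trait statistic) is the default because
the age proxy is about how much of a group's repertoire a genome carries.

**Ontology mapping.** Only is_a edges are traversed; part_of/regulates are
ignored.  Level-1 terms are the direct is_a children of the single root.
A terminal maps to the set of level-1 ancestors it reaches; multi-parent
terminals count once per parent, so the breakdown table total can exceed
the mapped count.  A terminal that *is* level-1 (or the root, or
disconnected, or absent from the DAG) has no level-1 parent and is
recorded as unmapped with a distinct reason code
(`level1_terminal` / `root_terminal` / `disconnected` / `missing`).
"Terminal" status is supplied by the caller, not recomputed from DAG
leaves.  The breakdown does not hard-code a level-1 count; it reports
whatever the input DAG defines.

**Node distance.** For each leaf, k counts the internal nodes on the
root-to-leaf path (root included, leaf excluded); nd = (k − 1)/(K − 1)
with K the maximum, and nd ≡ 0 for a star tree.  This anchoring makes a
root-adjacent leaf exactly 0 and the deepest leaves exactly 1, matching
the 0-to-1 scale convention; whether prior formulations counted the root
is not decisive, and this choice is documented as the package's
convention.  Branch lengths are ignored, so nd is invariant to rescaling;
polytomies contribute one node each.  Traits absent from the tree are
dropped from timelines with a logged count, never imputed.  The
most-ancient-per-group rule is minimum nd, ties broken by maximum total
abundance, then by trait id.

## The synthetic-data generator

`ScenarioParams` defaults encode the full-scale census conditions: 70
archaeal, 652 bacterial and 259 eukaryal organisms and a ~1,700-trait
repertoire.  The generative history, on a three-tick integer epoch clock:

| parameter | default | meaning |
|---|---|---|
| `n_core` | 1110 | urancestral traits, born epoch 0, initially in every organism |
| `archaeal_loss_rate` | 0.29 | per-trait probability of loss on the archaeal stem (removes the trait from **all** A organisms → a true BE trait) |
| `archaeal_lineage_loss_rate` | 0.25 | per trait × A-organism patchy loss; lowers archaeal f of surviving ABE traits without changing their class |
| `n_specific` | (10, 164, 373) | A-/B-/E-specific innovations; B-specific born epoch 1, A- and E-specific jointly epoch 2; per-trait spread ~ U(0.05, 0.6) |
| `late_bacterial_loss_rate` | 0.10 | probability a bacterial organism is flagged reduced |
| `reduction_depth` | 0.5 | per-trait drop probability inside a reduced genome |
| `duplication_growth` | 4.0 | per-epoch multiplicative abundance factor |
| `base_abundance_mean` | 3.0 | mean copies of an epoch-age-0 trait |
| `n_hgt` | 30 | planted transfers; donor spread ~ U(0.9, 1.0) realised with a ceiling (f_donor ≥ draw), recipient ~ U(0.0, 0.2) with a floor and a one-organism minimum |

Copy numbers are geometric draws with mean
`base × growth^(current_epoch − birth_epoch)`: any light-tailed positive
integer distribution satisfies the tested monotonicity (older ⇒ more
abundant); geometric was chosen for its single-parameter mean control.
Transfers are planted as spread patterns (donor-wide, recipient-narrow),
not as event histories, because the detector observes spreads only.  Two
stem-loss components exist because the all-or-nothing stem loss changes a
trait's Venn class while only the patchy lineage loss can depress the
archaeal medians of surviving ABE traits; both signatures are in the test
suite.  Traits driven extinct by reduction are dropped from the emitted
matrix and listed in the ground truth.  A deterministic survivor rule
(rather than an extra random draw) rescues core traits whose archaeal
block empties under patchy loss, keeping the random stream independent of
the loss realisation so loss rates can be compared at a fixed seed.

The companion generators emit an is_a DAG (single root, configurable
level-1 count, terminals at depth ≥ 2, optional second parentage) and an
epoch-consistent trait tree: a pectinate backbone with one polytomy per
birth epoch, so leaf depth is strictly increasing in epoch and nd is a
perfect rank transform of birth order.  Everything is bit-deterministic
given the parameter set and seed.

The default split of A-specific versus E-specific innovation counts is a
scenario choice consistent with archaeal unique traits being rare and
eukaryal innovation dominating; only their sum is constrained by the
full-scale census structure being emulated.

**What the generator does not emulate.**  Loss is homogeneous across
traits, so at full scale no trait survives in *all* 981 organisms and the
strictly universal core is empty under default noise — unlike real
censuses, where a small core of translation/replication traits resists
loss; universal-core behaviour is therefore tested under loss-free
scenarios.  There is no annotation error, no correlated loss between
related organisms, no AB/AE membership from differential loss (those
groups arise only via planted transfers), no intra-superkingdom transfer,
and no sequence-level realism.  Passing recovery tests shows the pipeline
computes its statistics correctly and that the statistics separate the
planted signals; it does not validate the biological inferences on real
data.

## Problem sizes and determinism

The shipped analysis and the acceptance script use the full-scale default
scenario (981 organisms × ~1,700 traits; seconds on one core); the test
suite uses scaled-down scenarios (~70 organisms × ~100 traits) and 20-seed
replicate sweeps for the property checks, sizes chosen to exercise every
code path with comfortable margins.  The analysis stages are fully
deterministic; all randomness lives in the generator and flows from a
single seed, and pipeline reruns are byte-identical.

## Known limitations

* The HGT rule is threshold-based and direction is inferred from spread
  alone; it cannot distinguish transfer from differential loss that mimics
  it — by design, the framework treats the call set as "probable" flux.
* Level-1 mapping ignores non-is_a relationships; ontologies whose
  semantics lean on part_of will under-map.
* nd uses topology only; trees with heavily unbalanced sampling compress
  the age scale.
* The coverage filter order relative to the lifestyle filter does not
  affect the retained set, but organisms failing both are counted in both
  reported tallies.
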