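# phyletica

Comparative phyletic-pattern analysis of molecular trait repertoires across
the three superkingdoms of cellular life — Archaea (A), Bacteria (B) and
Eukarya (E).

## The problem and the approach

Deep phylogenies of cellular life are fragile: sequence saturation,
discordant paralog rootings and horizontal gene transfer (HGT) all erode the
signal.  An alternative is to compare, without building a tree of organisms,
how conserved molecular *traits* — protein fold superfamilies (SCOP-style
ids such as `c.37.1`) or terminal molecular-function GO terms — are used and
reused across the genomes of contemporary organisms.  `phyletica`
implements that inferential framework as a tested pipeline over an
organism × trait abundance matrix:

1. **Venn census** — each trait with nonzero occurrence falls into exactly
   one of seven mutually exclusive sharing classes {A, B, E, AB, AE, BE,
   ABE}, determined by which superkingdoms contain it.  Large shared
   classes are vertical traces (common descent); small ones point to loss,
   transfer or convergence.
2. **Spread (f-values)** — for a trait and superkingdom *s*,
   *f* = (number of *s*-organisms carrying the trait) / (number of
   *s*-organisms), from 0 (absent) to 1 (omnipresent).  The pipeline
   extracts the universal core (*f* = 1 everywhere) and near-universal
   cohort (overall *f* > 0.90), and summarises each (group, superkingdom)
   panel with quartiles and the *f* > 0.8 tail count.
3. **HGT rule** — for a two-superkingdom trait, let *f_former* and
   *f_latter* be its f-values in the first and second letter of its group
   label.  If |*f_former* − *f_latter*| > 0.6 the joint presence is called
   a probable horizontal acquisition, directed from the high-spread donor
   to the low-spread recipient; the remainder is the group's vertical
   residual.
4. **Abundance as age** — older traits have had more time to duplicate, so
   per-organism, per-group abundance totals (summarised on a log10(x+1)
   scale with Tukey 1.5×IQR outliers) index the relative age of each Venn
   group.
5. **Ontology mapping** — terminal molecular-function terms are climbed
   through is_a links to their level-1 parents (the direct children of the
   ontology root); multi-parent terminals count once per parent.
6. **Timelines** — a rooted trait tree yields a node-distance age per
   trait: with *k* internal nodes on the root-to-leaf path and *K* the
   maximum over leaves, *nd* = (*k* − 1)/(*K* − 1), from 0 (most ancient)
   to 1 (most derived); joined with Venn groups and abundances this orders
   trait origins in relative time.

Because the underlying proteome/functionome snapshots are not
redistributable, the package ships a first-class synthetic-data generator
(`phyletica.simulate`) that emulates the diversification scenario the
framework probes — urancestral core, early archaeal stem loss, ordered
superkingdom-specific innovation (Bacteria first), late bacterial
reduction, duplication growth, planted transfers — and emits ground truth
so every stage's recovery can be scored exactly.

## Worked example

```bash
python analysis/01_simulate_dataset.py   # writes results/data/
python analysis/02_venn_census.py
python analysis/04_hgt_flux.py
```

prints (seed 20131231, the shipped scenario):

```
1687 traits partitioned:
  ABE:   775  (46%)
   AB:    11  (1%)
   AE:     7  (0%)
   BE:   347  (21%)
    A:    10  (1%)
    B:   164  (10%)
    E:   373  (22%)
BE versus AB+AE size ratio: 19.3x (the archaeal stem-loss signature)
...
30 transfer calls across AB/AE/BE (30 planted)
  BE: B->E: 6, E->B: 6; vertical residual 335 of 347
recovery against ground truth: precision 1.000, recall 1.000
```

Reading: the urancestral core dominates (ABE), archaeal stem loss makes BE
far larger than AB and AE, Eukarya-specific innovations outnumber the other
specific classes, and the f-difference rule recovers every planted transfer
with no false positives.  The remaining numbered scripts cover spread
panels, abundance-age summaries, level-1 mapping and nd timelines.

The same stages are available programmatically (`phyletica.run_pipeline`)
and through a CLI:

```bash
phyletica simulate --out data --seed 7
phyletica run-all --matrix data/matrix.tsv --metadata data/metadata.tsv \
    --ontology data/ontology.obo --tree data/tree.nwk --out out
```

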