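# sdscam

Quantitative toolkit for studying self/non-self recognition by sDscam, the
shortened Down syndrome cell adhesion molecule of Chelicerata. sDscam
isoforms mediate strictly homophilic *trans* binding through their variable
Ig1 domain and *cis* dimerization through their FNIII1-3 domains, and are
thought to assemble into an intermembrane zipper whose chain termination at
isoform mismatches lets neurons with limited isoform repertoires tell self
from non-self.

The package is aimed at structural biologists and quantitative
neuroscientists who want to re-run or extend the analysis chain behind such
studies: quantifying cell-aggregation assays, computing isoform-sharing
statistics, simulating the zipper chain-termination model, and measuring
structures.

## What it computes

- **Aggregation percentage** (`sdscam.aggquant`): binarize a micrograph,
  label connected objects, and report the fraction of foreground pixels in
  objects larger than 300 px (~3 cells); objects of 300 px or fewer count
  as "no aggregation".
- **Coaggregation (CoAg) index** (`sdscam.coag`): parse the image into
  squares slightly larger than one cell, drop squares containing no cells,
  and report the fraction of remaining squares holding both colors.
  Index < 0.1 ⇒ segregated populations, ≥ 0.2 ⇒ intermixed.
- **Repertoire overlap** (`sdscam.repertoire_stats`): with two neurons each
  drawing k isoforms uniformly without replacement from a pool of N, the
  shared count m is hypergeometric and
  P(m ≥ 1) = 1 − C(N−k, k)/C(N, k), evaluated in log space; a seeded
  Monte-Carlo estimator cross-checks it.
- **Zipper chain-termination model** (`sdscam.zipper`): extensions are
  i.i.d. gates with per-step success q = |A ∩ B|/k, so a chain survives a
  recognition threshold of L* links with probability q^L*. The module
  simulates chain growth, reports the closed form, and tabulates the
  tolerance curve Σ_m P(m)·(m/k)^L*.
- **Structure metrics** (`sdscam.structmetrics`): PDB/mmCIF reading
  (gemmi), Kabsch superposition RMSD, multi-copy RMSD summaries,
  Shrake–Rupley SASA, buried interface area (ΔSASA), interface residues and
  salt bridges, N-glycosylation sequons (N-X-S/T, X ≠ P), sequence-logo
  information content, pairwise identity, and the intermembrane geometry
  d = 2h + (2·L_arm − o)·sin θ.
- **Synthetic data** (`sdscam.synthcells`): seeded generators for assay-like
  two-color cell fields, repertoire pairs with exact sharing, and toy
  structures with known transforms, so the whole pipeline is testable
  without downloads.

## Worked example

```python
>>> from sdscam import coag, synthcells, zipper
>>> from sdscam.repertoire_stats import overlap_probability_analytic

>>> stats = overlap_probability_analytic(20000, 50)
>>> round(stats.p_overlap, 4)
0.1178

>>> img = synthcells.generate_cell_field(100, 100, "coaggregate", seed=1)
>>> round(coag.coag_index(img).coag_index, 3), coag.coag_index(img).classification
(0.419, 'intermixed')

>>> a, b = synthcells.generate_repertoire_pair(20000, 50, 25, seed=2)
>>> result = zipper.simulate_zipper_growth(
...     zipper.ZipperParams(a, b, threshold_links=5, reps=100_000, seed=3))
>>> result.q, result.closed_form, round(result.recognition_fraction, 4)
(0.5, 0.03125, 0.0319)
```

Two neurons sharing even half their 50 isoforms (q = 0.5) trigger a
5-link zipper only ~3% of the time, while two random neurons overlap at all
with probability ~0.118 (~12%) — the chain-termination tolerance in action.

The same operations are exposed on the command line via the `sdscam`
console script (`sdscam stats overlap`, `sdscam synth image`,
`sdscam quantify coag`, `sdscam zipper simulate`, `sdscam struct rmsd`, …).

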