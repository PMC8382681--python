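# phylomosaic

Tools for assembling and diagnosing sparse multilocus phylogenetic
supermatrices: concatenation with partition bookkeeping, composite-taxon
construction, per-marker saturation and concordance diagnostics,
contamination screening, and single-marker jackknife sensitivity — plus a
built-in simulator so every stage can be exercised and validated on synthetic
data.

## The problem

PCR-based multilocus datasets (the setting here is drosophilid fly
systematics: ~10–20 nuclear and mitochondrial markers of 300–2,000 sites over
hundreds of taxa) are sparse: each marker is typically sequenced for only
30–80% of the taxa. Concatenating such markers into a supermatrix raises
three recurring questions this package answers quantitatively:

- **How saturated is each marker?** Multiple substitutions at the same site
  erode signal. Per marker, every taxon pair contributes an *observed*
  distance *p* (mismatch proportion over shared unambiguous sites) and an
  *inferred* distance *d* (patristic distance on the marker's gene tree). The
  ordinary-least-squares slope of *p* on *d* is the saturation level: near 1
  means the marker is essentially unsaturated, values toward 0 mean heavy
  saturation.
- **How concordant is each marker with the reference topology?** For each
  internal branch (bipartition) of the reference tree, restrict its two sides
  to the taxa a gene tree samples. If either side keeps fewer than 2 taxa the
  branch is *missing* (not assessable) for that marker; otherwise it is
  *concordant* iff the restricted split occurs in the gene tree. Per-marker
  concordance is `100 · concordant / (total − missing)`. Per-branch, the gene
  concordance factor (gCF) is the percentage of assessing gene trees that
  contain the branch, and the site concordance factor (sCF) is the mean
  fraction of decisive sites supporting the branch over sampled quartets.
- **How fragile is the topology?** A composite-taxon matrix replaces each
  monophyletic group with one chimeric terminal assembled, marker by marker,
  from the group's least-diverging sequence — raising occupancy and damping
  long branches. A leave-one-marker-out jackknife then reports the
  Robinson–Foulds distance of each reduced-matrix tree to the full-matrix
  tree.

Desk-scale tree inference throughout is Jukes–Cantor-corrected neighbor
joining (exact on additive distance matrices); the package deliberately does
not reimplement likelihood or Bayesian tree search.

## Worked example

The package bundles the per-marker statistics table of a published 17-marker,
83-taxon drosophilid supermatrix (`phylomosaic.example_data`). Recomputing the
concordance summaries from the raw printed counts:

```python
from phylomosaic import concordance as cc, example_data as ex

rows = [
    cc.MarkerConcordance(
        r.marker, r.n_concordant,
        r.n_nodes_total - r.n_concordant - r.n_missing,
        r.n_missing, r.n_nodes_total,
        cc.concordance_percentage(r.n_concordant, r.n_nodes_total, r.n_missing),
    )
    for r in ex.DROSOPHILID_MARKER_STATS
]
mean, lo, hi = cc.concordance_summary(rows, subset=ex.NEW_MARKERS)
print(f"new markers: mean {mean:.1f}%, range {lo:.1f}-{hi:.1f}%")
```

prints

```
new markers: mean 65.0%, range 46.2-90.9%
```

i.e. the nine newly designed developmental-gene markers average 65%
concordance with the reference topology, spanning 46.2% (*en*) to 90.9%
(*Dll*) — on par with the eight long-established markers (mean 64.9% by the
same recomputation). Each percentage is `100 · concordant / (80 − missing)`,
where 80 is the number of internal branches of a resolved unrooted 83-taxon
tree (n − 3).

A fully synthetic end-to-end run:

```sh
phylomosaic simulate --n-taxa 16 --n-groups 3 --dropout 0.3 --seed 11 --out-dir demo/data
phylomosaic run demo/data/markers/*.fasta \
    --taxonomy demo/data/taxonomy.tsv \
    --reference demo/data/species_tree.nwk \
    --seed 11 --out-dir demo/out
```

writes the supermatrix and partition file, QC flags, per-marker report
(occupancy, informative sites, saturation slope, concordance counts),
per-node gCF/sCF table, composite matrix with provenance, jackknife scan, and
a digest manifest. In `demo/out/report.tsv` the slow marker `m01`
(rate multiplier 0.25×) shows saturation slope 0.846 while the faster `m03`
shows 0.631 — the slope ordering tracks the simulated rates.

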