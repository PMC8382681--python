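# Methods

This note records the models, conventions and numerical choices behind
phylomosaic, and what the synthetic-data validation does and does not show.

## Data model and missingness semantics

An `Alignment` is one marker's equal-length nucleotide rows keyed by taxon;
a `Supermatrix` is the concatenation of several markers over the union of
their taxa, with an ordered partition table of half-open 0-based column
intervals (written 1-based inclusive in the RAxML dialect). Two missing-data
symbols are deliberately distinguished:

- `?` — the taxon was never sequenced for this marker (concatenation fills
  whole segments with it);
- `-` — an alignment gap inside a sequenced marker.

Both are excluded from every distance and site-pattern computation, but they
are distinguished in occupancy reporting, since "marker absent" and "gappy
alignment" have different curation implications. IUPAC ambiguity codes are
carried through verbatim but treated like missing data wherever states are
counted (informative sites, p-distances, sCF decisiveness): this is the
conservative common practice, and it makes every statistic a function of
unambiguous {A,C,G,T} observations only.

Gap-threshold trimming retains exactly the columns whose fraction of
non-missing residues is ≥ `gt` (default 0.5). This reproduces only the
gap-threshold component of trimAl-style filtering; similarity-based column
scores are intentionally not emulated, so the trim is a partial stand-in and
is documented as such in the API.

## Distances and desk-scale tree inference

Observed distances are p-distances under pairwise deletion with a minimum
overlap of 30 shared unambiguous sites (below which the pair is *absent*,
not zero — a sparse matrix otherwise manufactures spurious zero distances).
The Jukes–Cantor correction −(3/4)·ln(1 − 4p/3) is undefined at p ≥ 0.75;
such saturated pairs are recorded absent with a warning rather than raised,
since one bad pair should not abort a matrix-wide computation.

Topology inference everywhere in the package is neighbor joining on
JC-corrected distances: the Q-criterion agglomeration with deterministic
lowest-(row, column) tie-breaking, negative branch-length estimates clamped
to zero, and a final three-point formula at the trifurcating base. On an
exactly additive matrix NJ reproduces the generating topology and branch
lengths exactly (tested to 1e-9). NJ replaces the maximum-likelihood and
Bayesian searches a production study would run in external software; the
package's role is the analysis layer around tree inference, not the
inference engine, and every function that consumes a tree accepts externally
estimated trees.

All tree comparisons are unrooted: bipartitions are extracted after ignoring
the rooting bifurcation, canonicalized as the side containing the
lexicographically smallest taxon, and Robinson–Foulds is the symmetric
difference of bipartition sets, normalized by 2(n − 3).

## Saturation regression

Per marker, every taxon pair with a defined p-distance contributes one point
(inferred patristic distance on the *x* axis, observed p-distance on *y*);
the OLS slope with intercept is the saturation level. The intercept is
estimated, not forced through the origin — "simple linear regression" read
literally, and the intercept itself is a useful diagnostic (a large positive
intercept signals distance inflation at short divergences). Pairs excluded
by the overlap floor are excluded from the mean-distance summaries too, so
the reported means and the regression see the same data. Mean observed and
mean inferred distances are arithmetic means over included pairs. Inferred
distances come from the marker's own gene tree because saturation is a
per-gene property; using a supermatrix tree instead is supported but logged
loudly, as it conflates marker-specific rate variation into the slope.

## Concordance bookkeeping

A reference branch restricted to a gene tree's taxa is *missing* when either
restricted side has < 2 taxa; *concordant* when the restricted split occurs
in the gene tree; otherwise *discordant*. An unresolved restricted split
counts as discordant, not missing: the gene could assess the branch and
fails to support it. The per-marker percentage is computed over assessable
branches only — this assessability rule reproduces the row arithmetic of the
bundled drosophilid statistics table exactly (percentage =
concordant/(total − missing), with 80 = 83 − 3 total branches), which is the
evidence that the "missing nodes" column of such tables counts
non-assessable branches under incomplete taxon overlap.

gCF per branch is the percentage of gene trees containing the branch among
those able to assess it. sCF per branch samples quartets (one taxon from
each of the four leaf blocks around the branch; default 100 quartets, seeded
mandatorily): a site is decisive for a quartet iff all four residues are
unambiguous and form exactly two states twice each, and supports the branch
iff the states pair the two same-side taxa. sCF is the mean over quartets
(with ≥ 1 decisive site) of the supporting fraction. Around a fully
unresolved local context (polytomy) the blocks are undefined and sCF is
reported absent.

## Composite taxa

"Least diverging" is operationalized as minimal mean patristic distance to
all other leaves of the marker's gene tree, falling back to minimal mean
defined p-distance against the other marker rows when no gene tree is
available; ties break lexicographically. Root-to-tip distance was rejected
because gene trees here are unrooted. Selection is per-marker independent,
so a composite terminal may combine different source species across markers
— the provenance sidecar records every choice with its criterion value.
Groups that are not monophyletic on the reference tree abort construction
unless explicitly overridden, since composites are only defensible for
unambiguous monophyletic units. Divergence is measured against all leaves of
the gene tree rather than within the group: the within-group alternative is
unstable for groups of 2 (both members tie by symmetry).

## QC screens

Near-identical flagging reports cross-group pairs with p-distance below a
threshold (default 0.005 — index-hopping-scale identity, well below genuine
interspecific divergence for these markers; exposed as a flag). Misplacement
flagging reports taxa whose exclusion restores their group's monophyly,
tested only for groups with ≥ 3 members present (with 2 members the test is
vacuous). Both screens only report; deletion is left to the analyst,
mirroring the manual curation step they emulate.

## Synthetic data: what it emulates and what it does not

The generator draws a pure-birth (Yule) topology, rescales it to a root-tip
height of 0.5 expected substitutions/site (at rate multiplier 1), evolves
each marker under a GTR model (default: transition/transversion-biased
exchangeabilities 1,4,1,1,4,1 and mildly AT-rich frequencies 0.3/0.2/0.2/0.3,
rate matrix normalized to unit mean rate), applies per-marker rate
multipliers, and masks (taxon, marker) blocks independently. Defaults are
study-shaped: 40 taxa in 8 monophyletic groups, 12 markers of 300–2,000
sites with multipliers 0.25–4×, 35% dropout (~65% occupancy). With these
settings per-marker mean inferred distances span roughly 0.2–2.5 and the
fastest markers approach saturation, matching the regime the diagnostics are
meant for. Gene trees are the species tree with branch lengths scaled by the
marker's multiplier (what a per-marker estimate would see), optionally
NNI-perturbed for discordant mode.

Deliberate simplifications: no indels (gaps arise only via masking), no
among-site rate variation, no coalescent/ILS gene-tree discordance (NNI
perturbation exercises the concordance bookkeeping without modelling a
biological discordance process), and dropout independent of clade or rate.
Passing tests therefore validate the *accounting* — concordance counts,
saturation ordering, composite provenance, jackknife arithmetic — not the
behavior of the statistics under realistic alignment error or deep
coalescent conflict.

## Numerical and test-design choices

- NJ topology-recovery properties condition on species trees whose shortest
  internal edge is ≥ 0.01–0.015 substitutions/site. Random Yule trees contain
  arbitrarily short internodes that no finite alignment can resolve; the
  floor is an identifiability condition, not a tuning of the method.
- Problem sizes in tests and the reproduction script (8–36 taxa, 3–12
  markers, 300–3,000 sites) are chosen as the smallest instances at which
  each property is informative; all oracle-equivalence checks run on
  ≤ 12-leaf instances where brute-force enumeration is exact.
- Printed percentage tables round half-up; recomputations are compared at
  the printed precision under that convention.
- Reported percentages carry one decimal, distances and slopes three, in the
  report TSV; full precision is available through the API.

## Known limitations

NJ topologies degrade on large sparse matrices (distance noise and JC
misspecification against GTR data); for production trees, export the
supermatrix and partition file to a likelihood engine and feed the resulting
trees back into the diagnostics. The sCF estimator skips quartets with no
decisive site, which upward-biases sCF for very short or very gappy
branches with few informative quartets. Composite selection assumes the
taxonomy's groups are the analysis units; it does not delimit groups from
the tree.
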