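# scentmark

Analysis of individual nest-entrance scent marks from GC/MS peak tables.

Solitary bees (e.g. the mason bee *Osmia cornuta*) nest in dense
aggregations of similar-looking cavities and re-find their own nest partly
by smell: each female deposits a chemical tag at her nest entrance. Given
integrated GC/MS peak areas for nest-mark samples (filter-paper sleeves
from the entrance), head extracts, Dufour's gland extracts and ambient
control sleeves, `scentmark` answers three questions:

1. **Are tags individually distinctive?** Marks of the same nest should be
   chemically more similar than marks of different nests.
2. **Where do tag compounds come from?** Each compound is attributed to
   Dufour's gland secretion, the cuticular/head bouquet, both, or an
   exogenous (environmental) source.
3. **How faithfully does a tag render its owner?** Marks are compared with
   gland extracts and with an estimated per-bee total bouquet.

## Method

Peak areas are compositional: only relative proportions carry meaning, and
total intensity varies with body size and extraction yield. The pipeline
therefore works on quantile-normalized, centered log-ratio transformed
data. For sample *j* with peak areas *Y<sub>ij</sub>*:

```
clr(Y_ij) = ln( Y_ij / g(Y_j) ),    g(Y_j) = geometric mean over i
```

after every sample has been forced onto the common distribution of mean
order statistics (quantile normalization). Compounds must be present in
all samples of the analysis set and above the ambient background measured
on control sleeves; individual-specific "private" substances are screened
for explicitly.

Collinearity of homologous hydrocarbon series is absorbed by PCA on the
correlation matrix, retaining every factor with eigenvalue > 1. Pairwise
similarity is the squared Euclidean distance (SED) between factor-score
vectors — small SED = high similarity. After pruning extreme isolated
values (> Q3 + 3·IQR), a binomial-logit GLM of the pair label (same vs
different individual) on SED yields a Wald chi-square *W* testing whether
same-identity pairs are systematically more similar.

Source attribution uses two screens on normalized mean areas: compounds
whose ln(mark/gland) quotient deserts the regression band against the
Kovats retention index (a volatility proxy) are removed from the
gland-derived set, and compounds more than two-fold enriched in marks
relative to the head+gland sum are discarded as exogenous. For the rest,
the head:gland ratio assigns contribution factors (ratio ≤ 2 → both
sources, else the dominant one), and factors applied to each bee's
normalized extracts yield her estimated total bouquet.

Results are visualized as UPGMA-clustered heatmaps with deterministic
dendrogram sorting, plus a tag-adjacency count (how many nests have their
two sleeves on adjacent leaves).

A fully seeded synthetic-data generator emulates the study design — 25
bees × {2 sequential mark sleeves, head extract, Dufour's gland extract}
plus 3 control sleeves over a 59-compound panel (alkanes C21–C31, 5-/7-/9-
alkenes, esters, alcohols, aldehydes, methyl-branched alkanes) — with
per-bee individual signatures, between-sleeve drift, environmental
enrichment and per-sample intensity bias, and returns the generative
ground truth for parameter-recovery tests. See `docs/methods.md` for the
model and its calibration.

## Worked example

```sh
scentmark run --simulate --seed 1 --out run1
```

prints

```
run dir: run1
marks: n = 1225 pairs, W = 49.750, p = 1.746e-12; 21 factors explaining 83.67% of the variance
```

meaning: all 1225 mark pairs (25 same-nest, 1200 different-nest) entered
the GLM, the PCA kept 21 factors with eigenvalue > 1 covering 83.67% of
the variance, and same-nest marks are significantly more similar than
different-nest marks (Wald W = 49.8, p < 0.001). `run1/summary.json`
additionally reports the per-class median SEDs (same-nest 23.1 vs
different-nest 42.0 for this seed), the substance-retention tally
(59 of 59 synthetic compounds), and the tag-adjacency count (23 of 25
nests have their two sleeves on adjacent dendrogram leaves). The same
pipeline runs on your own data via
`scentmark run --input DIR --out ...` where `DIR` holds `areas.csv`,
`samples.csv` and `compounds.csv` (see `scentmark simulate` output for the
format), and the other comparisons via
`--comparison gland-vs-marks|bouquet-vs-marks`.

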