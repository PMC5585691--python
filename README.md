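# gutlink

Joint spatial and temporal analysis of gut microbiota OTU tables: where
taxa live along the GI tract, how they interact day to day, and whether
the two views agree.

The package is for microbial ecologists who have (a) an OTU count table
from biopsies at several GI sites with replicates and/or (b) a dense daily
fecal time series, and want the standard analysis chain — normalization,
diversity/ordination, spatial-pattern classification, pairwise interaction
inference, cooccurrence, and cross-modal concordance — as tested,
scriptable functions. A ground-truthed simulator of both study arms is a
first-class citizen, so every estimator ships with recovery experiments.

## The models at the core

**Spatial structure.** Each taxon's relative abundance profile over seven
sites (terminal ileum → rectum, 3 replicates each) is classified into six
categories: monotonous gradients ascending/descending (**MGA/MGD**, OLS
trend on site position under both an ordinal and an anatomical-distance
convention), broken-stick gradients with a breakpoint (**GAB/GDB**, a
continuous hinge regression `y ~ pos + max(0, pos − bp)` at candidate
sites AC/TC/DC, tested via the hinge term), and habitat
specialists/avoiders (**HS/HA**, an exact conditional test for a mean
difference between two groups of negative-binomially distributed raw
counts, with common dispersion estimated by conditional maximum
likelihood; BH FDR across taxa).

**Temporal interactions.** For every ordered taxon pair (i, j), the
discrete-time model

    x_{i,t+1} − x_{i,t} = α_ij + β_ij · x_{j,t}

is fitted by OLS on log relative abundances (pseudocount 0.5), giving a
nonsymmetric interaction matrix β. After Benjamini-Hochberg correction
(significance at adjusted p < 0.01), the sign pattern of each unordered
pair maps to an ecological category: +/+ cooperation, −/− competition,
+/0 commensalism, −/0 amensalism, +/− parasitism. Robustness is checked
by refitting the full system on time-permuted predictors (100 replicates):
on sound data the permuted p-values are uniform around 0.5 and nothing
survives BH.

**Cooccurrence and concordance.** Symmetric association matrices via
Spearman and via SparCC (basis correlations from log-ratio variances of
compositional counts, Dirichlet-resampled, with iterative strong-pair
exclusion), each in a temporal flavor (daily samples) and a spatial flavor
(per-site mean profiles). The concordance module partitions pairwise
correlations by time-series significance and tests the location shift by
Wilcoxon rank-sum — the headline pattern being that temporally competing
taxa cooccur spatially.

## Worked example

The `analysis/` scripts run the whole chain on a simulated study (20
taxa, 139 daily fecal samples, 7×3 biopsies, competing pairs placed in
shared spatial niches):

```sh
python analysis/01_simulate.py
python analysis/02_diversity_ordination.py
python analysis/03_spatial_classification.py
python analysis/04_interactions.py
python analysis/05_cooccurrence.py
python analysis/06_concordance.py
```

`04_interactions.py` prints, for the shipped seed:

```
380 ordered-pair models; 9 significant (BH p < 0.01)
sign accuracy on strong true couplings among significant calls: 1.00
permutation null: mean raw p = 0.500; 100% of replicates with zero significant models
```

380 is the full n²−n system for n = 20; each significant coefficient's
sign matched the generator's truth; and the permutation check behaved as
a calibrated null. `06_concordance.py` then prints:

```
  spatial_spearman   mean_sig +0.607  mean_nonsig -0.049  Wilcoxon p 1.96e-04
  spatial_sparcc     mean_sig +0.342  mean_nonsig -0.022  Wilcoxon p 1.72e-04
```

— the spatial correlations of pairs flagged by the time-series models sit
far above those of unflagged pairs: the competing taxa are the colocalized
ones, by construction of the simulation, recovered by the analysis.

Equivalent functionality is exposed on the command line (`gutlink
normalize | filter | diversity | anosim | spatial-classify | interactions
| cooccur | simulate | concordance`), and `gutlink run --config cfg.yaml
--out-dir out/` chains all stages over a YAML config with a reproducibility
manifest.

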