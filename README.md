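# sussol

Sustainable solvent selection and substitution for chemists and formulators.
Given a table of solvents described by physical properties (boiling point,
Hansen solubility parameters, water solubility, ... — 22 columns in the
default schema), the package answers two questions:

1. **Selection** — what does the solvent space look like, and which solvents
   meet my property constraints?  (metric MDS map, range filters, Hansen
   subsetting)
2. **Substitution** — which solvents are *statistically significant*
   stand-ins for the one I want to replace, and how safe are they?
   (SOM ensemble clustering + stability statistics + CHEM21 SH&E scores)

## Method

Solvent property columns are min–max scaled to [0, 1] (optionally weighted)
and clustered on a Kohonen self-organizing map: a `width x height` grid of
`U` neurons whose prototype vectors are trained online
(`y <- y + gamma (x - y)` inside a shrinking grid neighbourhood).  Solvents
sharing a best-matching unit form a cluster.

Because a single SOM run depends on its random initialization, the map is
trained `B` times and co-clustering is aggregated pairwise.  With the
per-run indicator `NEIGH_ij(r)` (1 iff solvents *i*, *j* sit within Chebyshev
grid radius *r*; *r* = 0 means the same neuron), the stability statistic is

    STAB_ij(r) = sum_b NEIGH_ij^b(r) / B

Under the null of an unorganized map a pair co-clusters with probability
`p = nu/U` per run, `nu = (2r+1)^2`, so the neighbour count is
Binomial(B, p).  When `B*p > 10` and `B*(1-p) > 10`, the two-sided band

    B*p ± z_(1-alpha/2) * sqrt(B*p*(1-p))

separates significant neighbours (count above the upper limit — substitution
candidates) from significant non-neighbours (below the lower limit).
Candidates are ranked by Hansen distance
`Ra = sqrt(4 dD^2 + dP^2 + dH^2)` to the query, or by CHEM21-style
safety/health/environment scores (1–10, green/yellow/red, overall
Recommended/Problematic/Hazardous) computed from flash point, H-statements,
boiling point and REACH status.

For selection, the pairwise Euclidean feature distances are embedded in 2D
by metric MDS (SMACOF majorization from a classical-scaling start); the
normalized stress `sigma_n = sum (d_ij - dhat_ij)^2 / sum d_ij^2` reports the
unexplained share of the dissimilarities, and Pearson correlations between
the axes and the raw properties help interpret the dimensionless map.

## Worked example

No public dataset ships with full 22-property coverage, so the package
generates one with known structure (three chemical families: alkane-like,
alcohol-like, ketone-like):

```
$ sussol synth blobs --k 3 --n 8 --seed 13 --hazards --out blobs.csv --labels labels.csv
24 solvents in 3 clusters -> blobs.csv

$ sussol substitute --dataset blobs.csv --query ketone_00 \
    --width 3 --height 1 --runs 30 --seed 2 --sort she --out candidates.csv
band (4.9, 15.1); 7 significant candidates -> candidates.csv
warning: Gaussian approximation invalid (need runs > 10 x neurons)
```

With B = 30 runs on U = 3 neurons the null expects a pair together in
30/3 = 10 runs; counts outside (4.9, 15.1) are significant at alpha = 0.05
(the warning notes that B = 10·U sits exactly on the validity boundary of
the normal approximation).  The candidate list contains only the query's own
family, each pair co-clustering in all 30 runs (STAB = 1.0):

```
candidate,count,stab,hansen_distance,S,H,E,overall
ketone_02,30,1.0,0.839258931742854,6,3,3,Problematic
ketone_04,30,1.0,1.0069657607548468,6,3,3,Problematic
ketone_06,30,1.0,1.428706010362775,6,3,3,Problematic
```

`count` is the number of runs in which the candidate shared the query's
neuron, `hansen_distance` is Ra in MPa^1/2, and S/H/E are the CHEM21-style
scores (here yellow safety scores from the low flash point of small ketones).
The same table can be mapped for selection:

```
$ sussol mds --dataset blobs.csv --out coords.csv
sigma_n = 0.0262, fit = 0.9738, variance share (2 components) = 0.770 -> coords.csv
```

i.e. the 2D map reproduces 97.4% of the dissimilarity variation.

The package also ships a transcription of a published worked example — the
co-clustering record of d-limonene with 20 hydrocarbon solvents over a
250-run ensemble on a 5x5 map (`sussol.examples`) — used as a regression
fixture for the stability statistics.

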