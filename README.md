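# mirconcord

Cross-species analysis of dysregulated microRNAs and genes in liver disease
models, packaged as a tested, reusable pipeline. It addresses a common
problem in comparative transcriptomics: two differential-expression (DE)
experiments — say, human MASH-driven hepatocellular carcinoma versus control
tissue, and a zebrafish HCC model versus wild type — each produce a table of
log2 fold-changes and p-values, and we want a principled, multiplicity-aware
answer to *which homologous features are dysregulated in the same direction
in both species*. Around that core, the package provides the companion
statistics such studies need: factorial (genotype × diet) gene-dependency
classification, miRNA seed-site scanning with enrichment testing, exact
multi-set intersection statistics, and nuclear morphometry from imaging
detection tables. A synthetic-data module generates every input with planted
ground truth, so the whole pipeline is testable offline.

## The statistics at the core

**Combined-evidence concordance.** For each homolog pair the two per-species
raw p-values are combined with Fisher's product method,

```
χ² = −2 Σᵢ ln pᵢ ,   χ² ~ χ²(2k),  k = 2,
```

giving a combined p from the χ²(4) upper tail. Combined p-values are
Benjamini–Hochberg adjusted across all evaluated pairs, and a pair is called
when q ≤ α (default 0.05) **and** the two log2 fold-changes share a sign
(directional concordance; an L2FC of exactly 0 is never concordant).
Within-species paralogs mapping to one partner (e.g. dre-miR-21-1/-2 to one
human miR-21) are first collapsed, by default to the paralog with the
smallest raw p.

**Factorial gene classes.** Over the four contrasts of a 2×2 genotype × diet
design (A: WT-HCD vs WT-NCD, B: OE-NCD vs WT-NCD, C: OE-HCD vs WT-HCD,
D: OE-HCD vs OE-NCD), genes are classified by set logic: *diet-dependent*
(same-direction significant in A and D, silent in B and C),
*miR-21-dependent* (same-direction in B and C), *divergent* (opposite
directions in A and C), and *miR-21-and-HCD-dependent* (C and D, silent
in B).

**Overlap statistics.** Two-set overlaps use the two-sided Fisher's exact
test; m-set overlaps use an exact test under the model of m sets drawn
independently and uniformly without replacement from a background of size N,
with the intersection-size distribution computed by iterated hypergeometric
convolution, expectation `N·∏(sᵢ/N)`, fold enrichment observed/expected, and
an upper-tail p. Shared significant genes can additionally be partitioned by
direction pair (up/up, down/down, discordant).

**Seed sites and morphometry.** A transparent seed-match scanner classifies
3′UTR loci into 6mer / 7mer-A1 / 7mer-m8 / 8mer site types from miRNA
positions 2–8 and tests a query list's seed-containing proportion against a
genome background. The morphometry module computes pixel calibration, ROI
polygon area, nuclear density per 1000 µm², and mean nearest-neighbour
inter-nuclear distance from detection-centroid tables.

## Worked example

Simulate a paired-species experiment with 10% planted concordant homologs at
a 5-sd effect, then screen it:

```python
from mirconcord import SimDEPairConfig, simulate_de_pair, concordance_screen

cfg = SimDEPairConfig(n_homologs=500, prop_concordant=0.1, effect_mu=5.0, seed=42)
human, fish, homology, truth = simulate_de_pair(cfg)
evidence, summary = concordance_screen(human, fish, homology, alpha=0.05)
print(summary)
```

```
{'n_pairs_evaluated': 500, 'n_pairs_dropped': 0, 'n_called': 46,
 'n_up': 24, 'n_down': 22, 'alpha': 0.05, 'paralog_policy': 'min_p'}
```

Of 500 homolog pairs, 46 are called concordantly dysregulated (24 up,
22 down). The per-pair evidence table carries the combined statistic:

```
     pair_id  l2fc_human  l2fc_fish      chi2   p_combined   q_combined direction
hsa-mir-0004   -5.922886  -5.900897 78.019420 4.575764e-16 4.575764e-14      down
hsa-mir-0017   -4.192992  -4.429463 44.140140 5.999834e-09 5.999834e-08      down
hsa-mir-0027   -4.483702  -6.807697 74.318932 2.776203e-15 1.735127e-13      down
```

Checking the calls against the planted truth gives recall 1.0 at an
observed false-discovery proportion of 0.022 — the screen recovers every
planted concordant homolog while keeping false calls below the nominal 5%
FDR level. A single combination is equally direct:
`fisher_combine([0.01, 0.04])` returns `(15.648, 4, 0.00353)`.

The same analyses are available from the shell:

```sh
mirconcord simulate --n-homologs 500 --effect-mu 5 --seed 42 --out-dir sim/
mirconcord concordance --human sim/human.tsv --fish sim/fish.tsv \
    --map sim/homology.tsv --alpha 0.05 --out concordance.tsv
mirconcord classify --a A.tsv --b B.tsv --c C.tsv --d D.tsv --out classes.tsv
mirconcord enrich multiset --gmt sets.gmt --background-n 20988 --out overlap.tsv
mirconcord morphometry --detections nuclei.csv --roi roi.csv --out morpho.json
```

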