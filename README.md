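# ovitrace

Toolkit for tracing livestock settlement history from mitochondrial
control-region sequences. Given an aligned set of mtDNA sequences with
per-animal breed/region metadata, a phylogenetic tree, and per-breed
climate summaries, `ovitrace` computes:

- **Diversity and neutrality statistics** per population: haplotype count
  H, haplotype diversity H<sub>d</sub> = n/(n−1)·(1 − Σp<sub>i</sub>²),
  nucleotide diversity π, segregating / singleton / parsimony-informative
  sites, Tajima's D, Fu & Li's D\* and F\*, and Fu's F<sub>s</sub> from the
  Ewens sampling distribution of haplotype counts.
- **Median-joining haplotype networks** (Bandelt et al. construction with
  majority-consensus median vectors and MP-style pruning), star
  contraction, cutoff-based network groups and breed-by-group count
  matrices.
- **Terminal-branch affinity matrices**: for each leaf of a labelled tree,
  its *level-1 neighbours* are the other leaves of the smallest clade
  containing it; tallying neighbour breeds per focal breed yields an
  asymmetric breed-connection matrix whose row percentages quantify
  between-population affinity, aggregable from breeds to regions and
  comparable (Pearson r over paired cells) with network-derived counts.
- **Demographic expansion inference**: mismatch distributions, the sudden
  expansion model of Rogers & Harpending — expected pairwise-difference
  distribution F<sub>i</sub>(τ, θ₀, θ₁) — fitted by least SSD, parametric
  bootstrap goodness-of-fit, and two dating calibrations: τ = 2μt with a
  parsimony-estimated segment rate μ, and a regression through
  archaeological (τ, age) anchors.
- **AMOVA** (among groups / among breeds within groups / within breeds)
  with Φ statistics and permutation p-values, plus haplogroup assignment
  against reference sequences and Shannon haplogroup diversity.
- **Climate–genetic correlations** with the pluviometric coefficient
  Q₃ = 3.43R/(M−m) and standard variable transforms.
- A **coalescent synthetic-data generator** (msprime-backed) producing
  multi-breed, multi-founder scenarios with known truth for every stage.

## Worked example

Simulate a survey of three breeds in which breed `X` draws 30% of its
founders from the same maternal lineage as the foreign breed `Y`, then ask
the terminal-branch affinity method to recover that fraction:

```python
import pandas as pd
from ovitrace import newick_extra as ne, structure, synthetic_data as sd

cfg = sd.planted_admixture_scenario(foreign_fraction=0.3, seed=7)
aln, meta, truth = sd.simulate_scenario(cfg)
D = structure.pairwise_difference_matrix(aln)
tree = ne.nj_tree(pd.DataFrame(D, index=aln.ids, columns=aln.ids))
M = ne.affinity_matrix(tree, {i: meta[i]["breed"] for i in aln.ids},
                       percent=True)
print(M.round(1))
```

```
      X     Y     Z
X  31.2  24.9  43.9
Y  32.0  31.3  36.7
Z  28.2   0.0  71.8
```

Row `X` reads: 24.9% of breed X's terminal-branch connections point at the
foreign breed Y — close to the planted 30% founder fraction — while the
purely native breed Z has no Y connections at all. A single replicate is
noisy; averaged over replicate simulations the X→Y share settles within a
few points of the planted fraction.

Dating the settlement waves by regression through archaeological anchors
(Italian group τ = 6.0 at 8,000 years B.P., Iberian group τ = 5.5 at
7,500 years B.P.):

```python
from ovitrace import demography as dg
dg.calibrate_dates([(6.0, 8000.0), (5.5, 7500.0)], [5.1, 6.6])
# [{'tau': 5.1, 'date_bp': 7100.000000000004},
#  {'tau': 6.6, 'date_bp': 8599.999999999996}]
```

A τ of 5.1 dates the younger wave at 7,100 years B.P. and a τ of 6.6 the
older one at 8,600 years B.P.

The same analyses are available from the shell:

```bash
ovitrace simulate --seed 7 --out sim/
ovitrace stats --fasta sim/alignment.fasta --meta sim/metadata.tsv
ovitrace network --fasta sim/alignment.fasta --meta sim/metadata.tsv --cutoff 12
ovitrace newick-extra --tree sim/tree.nwk --meta sim/metadata.tsv --by region
ovitrace run --config pipeline.yaml
```

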