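# radiascope

Quartet-discordance, locus-selection and trait-signal analyses for
family-level phylogenomic radiations, with a multispecies-coalescent (MSC)
synthetic-data generator that supplies every input with known ground truth.

Rapid radiations — the avian one around the Cretaceous–Palaeogene boundary
being the archetype — leave genomes full of gene-tree/species-tree
discordance from incomplete lineage sorting (ILS) and, at some nodes,
ancestral hybridization. Resolving them from whole-genome alignments
involves a long chain of bespoke computations around the standard tools:
selecting 1-kb loci from 10-kb alignment windows, filtering fragmentary
sequences, counting per-branch quartet support, testing polytomy and
ILS-vs-hybridization hypotheses, screening loci for model violations,
subsampling designs over loci and taxa, converting quartet support into
effective-population-size trajectories, and perturbation experiments on
phylogenetic trait signal. `radiascope` packages that chain as tested,
reusable procedures for people who build or review such pipelines.

## The statistics at the core

Around each internal branch of a binary species tree the four adjacent
taxon groups (A, B | C, D) define three possible quartet resolutions. Under
the MSC, a branch of length *d* coalescent units yields the matching
resolution with probability

    q1 = 1 − (2/3) e^(−d),

and each alternative with (1/3) e^(−d); the package counts the three
resolutions across gene trees without enumerating tuples, inverts the
formula to estimate *d* (capped when q1 saturates), computes the local
posterior probability of each resolution under an exponential branch-length
prior, a 2-df chi-square polytomy test, and one-sided chi-square
asymmetry tests with Benjamini–Hochberg correction (under pure ILS the two
alternative frequencies are equal; a consistent excess of one signals
introgression). A branch of duration *T* Ma satisfies
T/d = 2 · (generation time) · Ne, which turns dual branch lengths into an
Ne trajectory through time. Trait machinery covers lambda-scaled Brownian
motion, ML estimation of Pagel's λ, phylogenetic GLS residuals, and the
taxon-misplacement / forced-convergence experiments.

## Worked example

Simulate a six-taxon radiation, draw 2,000 MSC gene trees, and annotate
every internal species-tree branch:

```python
import radiascope as r
from radiascope import msc, quartets

model = msc.simulate_species_tree(6, birth_rate=0.2, seed=42)
gene_trees = msc.simulate_gene_trees(model, 2000, seed=1)
support = quartets.branch_quartet_frequencies(model.tree, gene_trees)
for b in support:
    q1, q2, q3 = b.frequencies
    d = quartets.coalescent_branch_length(q1).d
    pp = quartets.local_posterior(b)[0]
    print(sorted(b.branch), round(q1, 3), round(d, 3), round(pp, 3))
```

Output (columns: branch clade, q1, q2, q3, estimated d, true d, local
posterior, polytomy p):

```
branch                 q1     q2     q3   d_hat  d_true  localPP   poly_p
t2,t5               0.912  0.045  0.043   2.029   1.948    1.000        0
t3,t4,t6            0.402  0.303  0.295   0.108   0.132    1.000  5.5e-10
t3,t4               0.921  0.035  0.044   2.129   2.096    1.000        0
```

The two long branches are near-saturated (q1 ≈ 0.92, d ≈ 2) while the short
`t3,t4,t6` branch shows heavy ILS: its quartet frequencies approach the
1/3-each polytomy expectation, yet with 2,000 loci the polytomy null is
still firmly rejected (p ≈ 5.5e-10) and the estimated coalescent length
(0.108) tracks the generating value (0.132).

The same analyses run from the shell (`radiascope simulate`, `radiascope
quartets annotate`, `radiascope traits lambda`, ...), and
`radiascope run config.yaml` executes the full simulate → quartets →
diagnostics → subsampling → rates → traits pipeline with a checksummed
manifest.

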