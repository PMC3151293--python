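# mpsdesign

Design simulator for **two-stage family-based exome (MPS) sequencing studies
of complex disease**.

Suppose a common disease (population risk ~2%) owes part of its familial
aggregation to very rare, moderate-to-high-penetrance alleles scattered over
many genes. A classic gene-discovery design sequences the exomes of one to
three affected members of a small number of very high-risk pedigrees
(stage I), filters the thousands of rare variants every exome carries, and
then screens the surviving candidate genes in a larger panel of more modestly
loaded families (stage II). `mpsdesign` quantifies, for a grid of genetic
architectures, sample sizes and variant-filtering strategies:

* how many **true susceptibility genes** survive to stage II,
* how many **false genes** must be screened there, and
* what the whole study **costs**.

It is aimed at statistical geneticists planning family-based sequencing
studies, and at anyone wanting a transparent, testable reimplementation of
this class of power/cost calculation.

## The model in brief

**Architectures.** Each susceptibility gene has aggregate risk-allele
frequency *q* = 10⁻⁴, sporadic (non-carrier) risk *f₀* = 0.02, and carrier
penetrance *f₁* = GRR·*f₀* (dominant). With loci acting multiplicatively,
the number of loci consistent with an aggregate first-degree familial
relative risk of 1.33 is *N* = log 1.33 / log λ, where the per-locus λ is
computed by exact enumeration of the parent–offspring genotype distribution.
For GRR = 20, 15, 10, 7.5, 5 this gives N = 8, 15, 35, 68, 179 (presets
`"I"`–`"V"`).

**Pedigree probabilities.** Conditional carrier probabilities given every
member's affection status are computed exactly by Elston–Stewart peeling
(implemented as variable elimination over the three-genotype network), and
IBD sharing of rare neutral variants by exact enumeration of inheritance
vectors. Requiring concordance between two sequenced relatives of degree *D*
removes (2^(D+1)−2)/(2^(D+1)−1) of irrelevant variants — 14/15 (93%) for
first cousins.

**Stage I.** Each sequenced exome carries 400 rare missense background
variants (30% survive a bioinformatics filter) plus 20 truncating/splice
variants, thrown uniformly over 25 000 genes; true genes segregate with the
index case's conditional carrier probability and are detected with 90%
sensitivity. Five gene filters (`N1RV`, `N1TS`, `N2RV`, `N2TS`, `N3RV`)
combine concordance, multiple-pedigree and variant-type requirements.

**Stage II.** A gene is validated when ≥ k of n pedigrees (default 3 of 250)
carry a qualifying variant — an exact binomial tail, evaluated at the
index-carrier probability for true genes and at 0.001/pedigree for unrelated
genes.

**Cost.** `4000·N_p·N_s + 10·250·n_genes` USD (one exome = 400 candidate-gene
screens).

## Worked example

```python
>>> from mpsdesign import MODELS, fig1a, joint_carrier_probability
>>> from mpsdesign.experiments import DesignCell, run_grid
>>> # probability the sequenced cousin shares the index case's allele
>>> round(joint_carrier_probability(fig1a(), MODELS["II"], [11], condition_on=8), 3)
0.724
>>> grid = run_grid([DesignCell("II", "N1TS", 20, 1)], seed=1, n_replicates=100)
>>> grid[["mean_true", "mean_false", "mean_cost"]].round(2)
   mean_true  mean_false  mean_cost
0      12.61      397.03  1104100.0
```

Under the GRR-15 architecture (15 true genes), sequencing one exome in each
of 20 high-risk pedigrees and keeping only genes with a truncating/splice
variant passes ~12.6 true and ~397 false genes to stage II, for a total
study cost of ~$1.10M.

The same numbers are available from the command line:

```bash
mpsdesign models --preset all
mpsdesign stage2 --n 250 --k 3 --p 0.001     # -> 0.00214022
mpsdesign simulate --models II --filters N1TS --n-pedigrees 20 \
    --n-sequenced 1 --replicates 100 --seed 1
mpsdesign cost --n-pedigrees 20 --n-sequenced 1 --genes 409.6
```

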