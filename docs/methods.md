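# Methods

This note documents the models and procedures implemented in `mpsdesign`,
the choices made where the design was genuinely open, and what the shipped
synthetic inputs do and do not represent.

## Genetic architectures (`genetic_models`)

Each susceptibility gene is modelled as a single biallelic locus whose rare
"risk allele" aggregates all pathogenic variants in the gene:

* aggregate risk-allele frequency `q` (default 1e-4),
* sporadic rate `f0` = P(disease | non-carrier) (default 0.02),
* genotype relative risk `grr`, so carriers have penetrance `f1 = grr*f0`.

Penetrance is dominant: homozygotes (frequency `q**2` ~ 1e-8) are treated as
carriers. The prevalence `K` and the locus-specific first-degree familial
relative risk `lambda` are computed by exact enumeration of the
parent–offspring joint genotype distribution under Hardy–Weinberg
equilibrium and Mendelian transmission; for these parameters the
parent–offspring and sibling ratios agree to printed precision, as does the
variance-components approximation `lambda ~ 1 + V_A/(2K^2)` (a unit test
enforces agreement within 5e-4 for `q <= 1e-3`).

The number of loci needed for an aggregate familial relative risk of 1.33
under multiplicative loci is `N = log(1.33)/log(lambda)`, computed from the
*unrounded* `lambda` and rounded to the nearest integer. This reproduces
N = 8, 15, 35, 68, 179 for the five presets (GRR 20, 15, 10, 7.5, 5). Note
the preset with GRR 7.5 has exact `lambda = 1.0042`; a 4-decimal rounding of
that value is the only way to obtain N = 68.

## Pedigree probabilities (`pedigree`)

Conditional genotype distributions given all affection statuses are computed
exactly by peeling, implemented as greedy variable elimination over the
pedigree's genotype network (founder Hardy–Weinberg priors, Mendelian
transmission factors, penetrance evidence). Elimination is exact for any
pedigree, including marriage/inbreeding loops, at exponential cost only in
the loop cut-width; the property suite checks agreement with brute-force
3^n enumeration on random pedigrees of up to 10 members at 1e-10. Unknown
phenotypes contribute likelihood 1 (the standard missing-data convention).

Rare neutral ("background") variants are assumed to recur in a family only
by descent. Sharing probabilities come from two sources that the tests
cross-check: the kinship recursion (`pairwise_sharing_probability` = twice
the kinship coefficient for outbred pairs) and exact enumeration of
inheritance vectors (`ibd_carrier_set_distribution`), which also yields the
full joint distribution of which sequenced members carry a variant carried
by one of them. The closed-form concordance exclusion for two relatives of
degree D, `(2**(D+1)-2)/(2**(D+1)-1)`, falls out as `1 - phi/(2-phi)` with
`phi = 2**-D`; for richer sets of relatives `concordance_exclusion`
accumulates the expected union member-by-member (every sequenced exome
carries the same expected variant load) and divides the expected fully
concordant count by it.

## The shipped pedigrees (`fixtures`)

The two reference families are available only as a drawing in the source
material, so they are encoded from the printed constraints and shipped as
editable fixtures (`data/fig1a.ped`, `data/fig1b.ped`); if the drawing is
read differently, the fixtures — not the algorithms — should change.

Structure (both panels share it): a founder couple (IDs 1–2) with three
children (3, 5, 6); 3 and 6 each have two children with married-in spouses
(4, 7); the index case 8 and his first cousin 11 sit in generation III with
siblings 9 and 10, and 5 is their aunt. This structure is forced by the
published background-variant counts for multi-individual designs: the
index's variants must be shared 1/8 with the second sequenced member and
1/16 with both others, which identifies (8, 11) as first cousins and 5 as
avuncular to both.

Affection statuses were selected so that exact peeling reproduces the
printed anchor probabilities:

* stage-I family (`fig1a`, sequenced 8, 5, 11; affected also 1, 4, 7):
  P(11 carries | 8 carries) = 0.724 and P(5 and 11 carry | 8 carries) =
  0.677 under the GRR-15 architecture (anchors 0.73 / 0.67, tolerance 0.01);
* stage-II family (`fig1b`, index 8 plus father 3 and cousin 11 affected):
  per-gene index carrier probabilities 0.0615 / 0.0408 / 0.0193 / 0.0106 /
  0.0044 across the five architectures (anchors 0.061 … 0.005).

Two residuals are worth knowing. First, the three-way concordance exclusion
computed for this structure is 38/39 = 97.4%, slightly below the published
~98% (45/46); no cousin-pedigree consistent with the pairwise 1/8 sharing
yields exactly 45/46 under union accounting, and 97.4% is within the
calibration tolerance used throughout. Second, the stage-I index carrier
probability implied by the published true-gene yields (~0.073 per gene under
GRR 15) cannot be reconciled with the 0.73/0.67 sharing anchors in any
reading of an 11-member structure; the fixture honours the sharing anchors,
so reproduced true-gene counts for the largest designs run higher than the
published ones (e.g. ~14.6 vs ~10.9 true genes for GRR 15, N1RV, 20
pedigrees). False-gene counts, which drive cost, are unaffected.

`make_random_pedigree` grows random acyclic families (child ids always
follow parent ids) purely to exercise the peeling-vs-enumeration property
tests; it makes no attempt at demographic realism.

## Stage-I simulation (`stage1`)

Per sequenced exome: 400 rare missense background variants, of which the
bioinformatics filter (conservation, severity, splicing prediction) passes
30%, plus 20 truncating/splice-junction (TSJ) variants, which are not
subject to that filter. These counts are post-frequency-filter by
construction. Variants are assigned uniformly over 25 000 genes.

When 2–3 relatives are sequenced, background variants are allocated
sequentially: the j-th member's novel variants (carried by no earlier
member) are shared with later members according to the exact conditional
IBD carrier-set distribution, and each member is topped up to its nominal
total. This preserves per-individual totals exactly and every pairwise and
higher-order expected overlap; it is a variant-level approximation of
resampling genotypes that is equivalent in expectation. The missense filter
is applied per *variant* (a shared variant passes or fails for all its
carriers). A concordant variant is one carried by every sequenced member.

True genes segregate independently of one another: each of the N genes is
carried by the index case with the fixture-derived conditional carrier
probability. (An at-most-one-gene-per-family rule is untenable: under the
weakest architecture the expected number of segregating genes per high-risk
family exceeds one.) A segregating variant is TSJ with probability
`p_tsj_true` (default 0.5; 0.3/0.7 explored), detected with sensitivity 0.9
(once per familial variant by default; a config switch draws detection per
individual), and, if missense, passes the bioinformatics filter with
probability 0.9. Concordance among sequenced relatives occurs with the
joint carrier probability conditional on the index carrying. True and false
genes are tallied separately; the ~1e-4 per-gene-per-pedigree chance of a
background variant landing in a true gene is ignored.

Filters follow the published table: `N1RV`/`N1TS` pass genes with a
(concordant, when ≥2 are sequenced) rare / truncating variant; `N2RV`,
`N2TS`, `N3RV` require variants in ≥2 or ≥3 distinct pedigrees, at least
one contributing pedigree concordant, and (for `N2TS`) at least one variant
truncating. Set containment (`N3RV ⊆ N2RV ⊆ N1RV`, etc.) is enforced by
property tests.

## Stage II (`stage2`) and cost (`cost`)

Validation probabilities are exact binomial upper tails; no normal or
Poisson approximation is used. The published "expected false positives"
figure uses the rounded per-gene probability 0.002 — both that chain
(P(>2 of 300) = 0.023) and the unrounded one (p_gene = 0.00214,
P = 0.0273) are reported. The validation table is generated from the
nominal per-pedigree probabilities (0.061 … 0.005), insulating it from the
pedigree reading; a separate calibration test ties the fixture to those
numbers. True-gene qualifying probabilities in stage II are *not*
attenuated by sequencing sensitivity or the bioinformatics filter (the
published probabilities use carrier probability directly; HRM/DHPLC
screening of a known candidate gene has near-complete sensitivity).

Cost: `exome_cost*N_p*N_s + gene_screen_cost*n_stage2_samples*n_genes`,
with fractional (replicate-averaged) gene counts costed without rounding.
All three constants are overridable (per-exome $4000, per-gene-per-sample
$10, 250 stage-II samples).

## Replicates, seeding and problem sizes (`experiments`)

Design cells sharing (model, N_p, N_s) reuse the same simulations. Every
replicate's generator is derived from `SeedSequence(seed,
spawn_key=(model, N_p, N_s, replicate))`, so results are bit-identical for
a given seed and independent of evaluation order or parallelisation. The
default grid mirrors the published one (5 architectures x 5 filters x
N_p in {10, 20, 30, 40, 60, 80} x N_s in {1, 2, 3}, 100 replicates). The
acceptance script and test suite use 100 replicates x 5 architectures for
the Monte-Carlo targets (standard error of the false-gene mean < 2 genes)
and complete in seconds; the full default grid runs in a few minutes.

## What the synthetic inputs do not capture

Real exomes differ from this generator in ways that matter for absolute
(not comparative) conclusions: variant counts vary across individuals,
capture platforms and ancestries; background variants cluster in large,
polymorphic genes rather than falling uniformly over 25 000 equal-sized
genes; bioinformatics-filter pass rates are gene- and variant-specific;
allelic series within a gene are collapsed into one aggregate allele; and
linkage disequilibrium, de-novo mutation and genotyping error are ignored.
Passing tests therefore demonstrate internal consistency with the stated
model, not calibration against any particular sequencing platform or
disease.
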