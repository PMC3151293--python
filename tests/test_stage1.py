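import numpy as np
import pytest

from mpsdesign.experiments import make_design
from mpsdesign.fixtures import fig1a
from mpsdesign.genetic_models import MODELS
from mpsdesign.stage1 import (
    FILTERS,
    ModelContext,
    VariantProfile,
    _passing_genes,
    apply_filter,
    expected_distinct_genes,
    simulate_background,
    simulate_replicate,
    simulate_true_genes,
    VariantTable,
)

PROFILE = VariantProfile()


def table(rows):
    """Variant table from (ped, gene, tsj, conc) tuples."""
    if not rows:
        return VariantTable.empty()
    ped, gene, tsj, conc = map(np.array, zip(*rows))
    return VariantTable(ped, gene, tsj.astype(bool), conc.astype(bool))


class TestFilterSemantics:
    def test_single_concordant_tsj_passes_single_pedigree_filters_only(self):
        t = table([(0, 7, True, True)])
        for name, expected in [("N1TS", 1), ("N1RV", 1), ("N2RV", 0), ("N3RV", 0)]:
            got = _passing_genes(t, FILTERS[name], 2)
            assert got.size == expected, name

    def test_two_pedigrees_without_concordance_fail_n2rv_when_two_sequenced(self):
        t = table([(0, 7, False, False), (1, 7, False, False)])
        assert _passing_genes(t, FILTERS["N2RV"], 2).size == 0
        # one concordant observation rescues the gene
        t2 = table([(0, 7, False, True), (1, 7, False, False)])
        assert _passing_genes(t2, FILTERS["N2RV"], 2).tolist() == [7]

    def test_n2ts_needs_a_truncating_variant(self):
        t = table([(0, 7, False, True), (1, 7, False, True)])
        assert _passing_genes(t, FILTERS["N2TS"], 2).size == 0
        t2 = table([(0, 7, True, True), (1, 7, False, True)])
        assert _passing_genes(t2, FILTERS["N2TS"], 2).tolist() == [7]

    def test_multiple_variants_in_one_pedigree_count_once(self):
        t = table([(0, 7, False, True), (0, 7, False, True)])
        assert _passing_genes(t, FILTERS["N2RV"], 1).size == 0

    def test_filter_containment_invariants(self, rng):
        design = make_design(8, 2)
        bg = simulate_background(PROFILE, design, rng)
        genes = {
            name: set(_passing_genes(bg, FILTERS[name], 2).tolist())
            for name in FILTERS
        }
        assert genes["N3RV"] <= genes["N2RV"] <= genes["N1RV"]
        assert genes["N2TS"] <= genes["N2RV"]
        assert genes["N1TS"] <= genes["N1RV"]


class TestBackgroundSimulation:
    def test_empty_profile_passes_nothing(self, rng):
        profile = VariantProfile(n_rms=0, n_tsj=0)
        design = make_design(10, 1)
        bg = simulate_background(profile, design, rng)
        assert len(bg) == 0
        for name in FILTERS:
            assert _passing_genes(bg, FILTERS[name], 1).size == 0

    def test_distinct_gene_closed_form_small_genome(self, rng):
        # oracle: throw M variants at G genes, count distinct; compare to
        # G(1 - (1-1/G)^M)
        G, M, reps = 50, 30, 2000
        counts = [len(np.unique(rng.integers(0, G, M))) for _ in range(reps)]
        assert np.mean(counts) == pytest.approx(expected_distinct_genes(M, G), rel=0.01)

    def test_single_sequenced_false_gene_mean_matches_closed_form(self, rng):
        design = make_design(10, 1)
        counts = []
        for _ in range(40):
            bg = simulate_background(PROFILE, design, rng)
            counts.append(_passing_genes(bg, FILTERS["N1RV"], 1).size)
        expect = expected_distinct_genes(10 * (400 * 0.3 + 20))
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expect) < 3 * se + 1.0

    def test_cousin_concordant_count_matches_retention(self, rng):
        # mean concordant background variants per 2-cousin pedigree is
        # (400 * 0.3 + 20) / 8 = 17.5
        design = make_design(60, 2)
        bg = simulate_background(PROFILE, design, rng)
        conc_per_ped = bg.concordant.sum() / 60
        assert conc_per_ped == pytest.approx(17.5, rel=0.1)
        # and the concordant fraction of the pedigree union is ~ 1/15
        n_ped = 60
        union = len(np.unique(bg.gene * n_ped + bg.ped))
        assert bg.concordant.sum() / union == pytest.approx(1 / 15, rel=0.1)

    def test_per_individual_totals_are_preserved(self, rng):
        # each sequenced member carries exactly n_tsj truncating variants
        design = make_design(30, 3)
        bg = simulate_background(VariantProfile(n_rms=0), design, rng)
        per_ped_tsj = np.bincount(bg.ped[bg.tsj], minlength=30)
        # union per pedigree <= 3 * 20, >= 20; concordant carried by all 3
        assert per_ped_tsj.min() >= 20 and per_ped_tsj.max() <= 60


class TestTrueGeneSimulation:
    def test_zero_sensitivity_passes_nothing(self, rng):
        profile = VariantProfile(sensitivity=0.0)
        design = make_design(10, 1)
        ctx = ModelContext.from_pedigree(MODELS["II"], design.pedigree, design.members)
        t = simulate_true_genes(ctx, profile, design, rng)
        assert len(t) == 0

    def test_all_truncating_makes_n1ts_equal_n1rv(self, rng):
        profile = VariantProfile(p_tsj_true=1.0)
        design = make_design(20, 1)
        ctx = ModelContext.from_pedigree(MODELS["II"], design.pedigree, design.members)
        t = simulate_true_genes(ctx, profile, design, rng)
        assert len(t) > 0 and t.tsj.all()
        rv = _passing_genes(t, FILTERS["N1RV"], 1)
        ts = _passing_genes(t, FILTERS["N1TS"], 1)
        assert rv.tolist() == ts.tolist()

    def test_concordance_rate_matches_pedigree_probability(self, rng):
        design = make_design(400, 2)
        ctx = ModelContext.from_pedigree(MODELS["II"], design.pedigree, design.members)
        t = simulate_true_genes(ctx, VariantProfile(), design, rng)
        rate = t.concordant.mean()
        se = np.sqrt(rate * (1 - rate) / len(t))
        assert abs(rate - ctx.p_concordant) < 4 * se
        # and the pedigree probability itself is the published ~0.73
        assert ctx.p_concordant == pytest.approx(0.73, abs=0.01)

    def test_false_counts_do_not_depend_on_disease_model(self):
        results = {}
        for name in MODELS:
            design = make_design(6, 2)
            ctx = ModelContext.from_pedigree(MODELS[name], design.pedigree, design.members)
            rng = np.random.default_rng(77)
            results[name] = {
                f: r.n_false_genes
                for f, r in simulate_replicate(ctx, PROFILE, design, rng).items()
            }
        first = next(iter(results.values()))
        assert all(r == first for r in results.values())


class TestApplyFilter:
    def test_true_and_false_counted_separately(self, rng):
        design = make_design(10, 1)
        ctx = ModelContext.from_pedigree(MODELS["I"], design.pedigree, design.members)
        bg = simulate_background(PROFILE, design, rng)
        tg = simulate_true_genes(ctx, PROFILE, design, rng)
        res = apply_filter(FILTERS["N1RV"], bg, tg, 1)
        assert res.n_true_genes <= ctx.n_loci
        assert res.n_false_genes > 0
        assert np.all(res.true_genes_passed < ctx.n_loci)

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            VariantProfile(sensitivity=1.5)
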