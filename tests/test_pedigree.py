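import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mpsdesign.fixtures import fig1a, fixture_path, make_random_pedigree
from mpsdesign.genetic_models import MODELS, GeneticModel
from mpsdesign.pedigree import (
    AFFECTED,
    UNAFFECTED,
    UNKNOWN,
    Individual,
    Pedigree,
    PedigreeError,
    background_retention,
    carrier_probability,
    genotype_posterior,
    ibd_carrier_set_distribution,
    joint_carrier_probability,
    kinship,
    pairwise_sharing_probability,
    read_ped,
    write_ped,
)
from conftest import brute_force_joint

M2 = MODELS["II"]


def trio(affection=(UNKNOWN, UNKNOWN, AFFECTED)):
    return Pedigree(
        "T",
        [
            Individual(1, 0, 0, 1, affection[0]),
            Individual(2, 0, 0, 2, affection[1]),
            Individual(3, 1, 2, 1, affection[2], sequenced=True),
        ],
    )


class TestPedFileIO:
    def test_round_trip(self, tmp_path):
        peds = [trio(), fig1a()]
        path = tmp_path / "fams.ped"
        write_ped(peds, path)
        assert read_ped(path) == peds

    def test_shipped_fig1a_fixture(self):
        (ped,) = read_ped(fixture_path("fig1a.ped"))
        assert len(ped) == 11
        assert set(ped.sequenced_ids) == {8, 5, 11}
        assert all(ped[i].affection == AFFECTED for i in ped.sequenced_ids)
        assert ped == fig1a()

    @pytest.mark.parametrize(
        "line, message",
        [
            ("F 3 1 2 1 2", "not in pedigree"),  # parents absent from file
            ("F 1 0 2 1 2\nF 2 0 0 2 1", "one parent missing"),
            ("F 1 0 0 3 2", "unknown sex"),
            ("F 1 0 0 1 7", "unknown affection"),
            ("F 1 0 0 1", "6 or 7 columns"),
            ("F 1 0 0 one 2", "invalid literal"),
        ],
    )
    def test_malformed_files_report_errors(self, tmp_path, line, message):
        path = tmp_path / "bad.ped"
        path.write_text(line + "\n")
        with pytest.raises(PedigreeError, match=message):
            read_ped(path)

    def test_cyclic_pedigree_rejected(self):
        with pytest.raises(PedigreeError, match="ancestor"):
            Pedigree(
                "C",
                [
                    Individual(1, 3, 2, 1),
                    Individual(2, 0, 0, 2),
                    Individual(3, 1, 2, 1),
                ],
            )


class TestCarrierProbability:
    def test_isolated_founder_has_hardy_weinberg_prior(self):
        ped = Pedigree("F", [Individual(1, 0, 0, 1, UNKNOWN)])
        q = M2.q
        assert carrier_probability(ped, M2, 1) == pytest.approx(2 * q * (1 - q) + q * q)

    def test_affected_fully_penetrant_no_phenocopies(self):
        # f0 -> 0 with full carrier penetrance: an affected person must carry
        model = GeneticModel("det", 1e-4, 1e-12, 1e12)
        ped = Pedigree("F", [Individual(1, 0, 0, 1, AFFECTED)])
        assert carrier_probability(ped, model, 1) > 1 - 1e-6

    def test_posterior_sums_to_one_everywhere(self):
        ped = fig1a()
        for iid in ped.ids:
            assert genotype_posterior(ped, M2, iid).sum() == pytest.approx(1.0)

    def test_conditioning_on_self_is_certain(self):
        assert joint_carrier_probability(fig1a(), M2, [8], condition_on=8) == 1.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        n=st.integers(min_value=1, max_value=8),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
        q=st.floats(min_value=1e-5, max_value=0.3),
        f0=st.floats(min_value=1e-3, max_value=0.3),
        grr=st.floats(min_value=1.0, max_value=3.0),
    )
    def test_peeling_equals_enumeration(self, n, seed, q, f0, grr):
        """Exact peeling must agree with 3**n brute-force enumeration."""
        model = GeneticModel("h", q, f0, grr)
        ped = make_random_pedigree(n, np.random.default_rng(seed))
        person = ped.ids[int(np.random.default_rng(seed + 1).integers(n))]
        brute = brute_force_joint(ped, model, [person])
        total = brute.sum()
        assert total > 0
        assert np.allclose(
            genotype_posterior(ped, model, person), brute / total, atol=1e-10
        )

    def test_joint_probability_against_enumeration(self):
        ped = fig1a()
        brute = brute_force_joint(ped, M2, [8, 11, 5])
        p_cond = brute[1:, 1:, 1:].sum() / brute[1:, :, :].sum()
        assert joint_carrier_probability(ped, M2, [11, 5], condition_on=8) == (
            pytest.approx(p_cond, abs=1e-12)
        )


class TestKinshipAndSharing:
    def test_parent_child(self):
        assert pairwise_sharing_probability(trio(), 1, 3) == pytest.approx(0.5)

    def test_first_cousins(self):
        assert pairwise_sharing_probability(fig1a(), 8, 11) == pytest.approx(1 / 8)

    def test_avuncular(self):
        assert pairwise_sharing_probability(fig1a(), 8, 5) == pytest.approx(1 / 4)

    def test_unrelated_founders(self):
        assert pairwise_sharing_probability(fig1a(), 1, 2) == 0.0

    def test_same_individual_rejected(self):
        with pytest.raises(ValueError):
            pairwise_sharing_probability(fig1a(), 8, 8)


class TestBackgroundRetention:
    def test_first_cousins_exclude_14_of_15(self):
        assert 1 - background_retention(3) == pytest.approx(14 / 15)

    def test_siblings_retain_one_third(self):
        assert background_retention(1) == pytest.approx(1 / 3)

    def test_vanishes_for_distant_relatives(self):
        assert background_retention(30) < 1e-8

    def test_degree_zero_rejected(self):
        with pytest.raises(ValueError):
            background_retention(0)

    def test_matches_pairwise_ibd_on_the_pedigree(self):
        # retention = phi / (2 - phi) with phi the IBD sharing probability
        phi = pairwise_sharing_probability(fig1a(), 8, 11)
        assert background_retention(3) == pytest.approx(phi / (2 - phi))


class TestCarrierSetDistribution:
    def test_fig1a_marginals_and_three_way(self):
        dist = ibd_carrier_set_distribution(fig1a(), [8, 5, 11])
        nu = dist[8]
        assert nu.sum() == pytest.approx(1.0)
        p5 = sum(p for m, p in enumerate(nu) if m >> 1 & 1)
        p11 = sum(p for m, p in enumerate(nu) if m >> 2 & 1)
        assert p5 == pytest.approx(pairwise_sharing_probability(fig1a(), 8, 5))
        assert p11 == pytest.approx(pairwise_sharing_probability(fig1a(), 8, 11))
        assert nu[0b111] == pytest.approx(1 / 16)

    def test_every_mask_contains_the_carrier(self):
        dist = ibd_carrier_set_distribution(fig1a(), [8, 11])
        for j, iid in enumerate([8, 11]):
            nu = dist[iid]
            off = [p for m, p in enumerate(nu) if not (m >> j & 1)]
            assert sum(off) == 0.0
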