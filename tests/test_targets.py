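import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import urimir as u
from urimir.io import TargetDB
from urimir.targets import dersimonian_laird


def db(name, *edges):
    return TargetDB(name, frozenset(edges))


class TestConsensus:
    DBS = [
        db("db1", ("m1", "g1"), ("m1", "g2")),
        db("db2", ("m1", "g1"), ("m2", "g3")),
        db("db3", ("m2", "g3"), ("m1", "g4")),
    ]

    def test_two_of_three_kept_one_dropped(self):
        cmap = u.consensus_targets(self.DBS, min_db=2)
        assert cmap.targets == {"m1": {"g1"}, "m2": {"g3"}}

    def test_min_db_one_is_union_three_is_intersection(self):
        union = u.consensus_targets(self.DBS, min_db=1)
        assert union.targets["m1"] == {"g1", "g2", "g4"}
        inter = u.consensus_targets(self.DBS, min_db=3)
        assert inter.targets == {}

    def test_min_db_above_database_count_rejected(self):
        with pytest.raises(ValueError):
            u.consensus_targets(self.DBS, min_db=4)


class TestHillLogOdds:
    def test_unit_fold_change_is_zero(self):
        assert u.hill_log_odds(1.0) == 0.0

    def test_closed_form_values(self):
        assert u.hill_log_odds(2.0) == pytest.approx(math.log(2), abs=1e-12)
        # FC = 2^-DDCq with DDCq = 2 gives FC 0.25 and log-odds -2 ln 2
        assert u.hill_log_odds(0.25) == pytest.approx(-2 * math.log(2), abs=1e-12)

    def test_nonpositive_fc_rejected(self):
        with pytest.raises(ValueError):
            u.hill_log_odds(0.0)
        with pytest.raises(ValueError):
            u.hill_log_odds(-1.0)

    def test_hill_coefficient_scales_log_odds(self):
        assert u.hill_log_odds(2.0, hill_coefficient=3) == pytest.approx(3 * math.log(2))

    @given(st.floats(min_value=1e-6, max_value=1e6))
    @settings(deadline=None)
    def test_antisymmetric_under_inversion(self, fc):
        assert u.hill_log_odds(1.0 / fc) == pytest.approx(-u.hill_log_odds(fc), abs=1e-9)


def dl_bruteforce(effects, ses):
    """Independent plain-loop evaluation of the DerSimonian-Laird formulas."""
    k = len(effects)
    w = [1.0 / s**2 for s in ses]
    ybar = sum(wi * yi for wi, yi in zip(w, effects)) / sum(w)
    q = sum(wi * (yi - ybar) ** 2 for wi, yi in zip(w, effects))
    denom = sum(w) - sum(wi**2 for wi in w) / sum(w)
    tau2 = max(0.0, (q - (k - 1)) / denom)
    ws = [1.0 / (s**2 + tau2) for s in ses]
    pooled = sum(wi * yi for wi, yi in zip(ws, effects)) / sum(ws)
    se = sum(ws) ** -0.5
    return pooled, se, tau2


class TestMetaAnalysis:
    def test_worked_two_study_example(self):
        # effects 1.0 and 3.0, both se 0.5: Q = 8, tau2 = 1.75, pooled = 2, se = 1
        pooled, se, tau2 = dersimonian_laird([1.0, 3.0], [0.5, 0.5])
        assert pooled == pytest.approx(2.0, abs=1e-12)
        assert se == pytest.approx(1.0, abs=1e-12)
        assert tau2 == pytest.approx(1.75, abs=1e-12)

    def test_homogeneous_effects_give_zero_tau2(self):
        pooled, _, tau2 = dersimonian_laird([2.0, 2.0], [0.4, 0.6])
        assert pooled == pytest.approx(2.0)
        assert tau2 == 0.0

    def test_single_study_degenerates(self):
        assert dersimonian_laird([1.5], [0.3]) == (1.5, 0.3, 0.0)

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(100):
            k = int(rng.integers(2, 8))
            effects = rng.normal(0, 2, k)
            ses = rng.uniform(0.1, 1.5, k)
            got = dersimonian_laird(effects, ses)
            want = dl_bruteforce(list(effects), list(ses))
            np.testing.assert_allclose(got, want, rtol=1e-10)
            assert min(effects) - 1e-12 <= got[0] <= max(effects) + 1e-12

    def test_invalid_se_rejected(self):
        with pytest.raises(ValueError):
            dersimonian_laird([1.0], [0.0])


class TestGeneProfiles:
    CMAP = u.ConsensusMap(targets={"m1": {"g1"}, "m2": {"g1"}, "m3": {"g2"}})

    def test_strong_negative_pool_calls_mrna_down(self):
        summaries = {"m1": (-2.0, 0.3), "m2": (-2.2, 0.3)}
        prof = u.gene_meta_analysis(summaries, self.CMAP, "g1")
        assert prof.direction == "mRNA_down"
        assert prof.p < 0.001
        assert prof.log_odds == pytest.approx(-prof.pooled_ddcq * math.log(2))

    def test_weak_evidence_is_indeterminate(self):
        summaries = {"m3": (0.2, 0.5)}
        prof = u.gene_meta_analysis(summaries, self.CMAP, "g2")
        assert prof.direction == "indeterminate"

    def test_untargeted_gene_rejected(self):
        with pytest.raises(ValueError):
            u.gene_meta_analysis({"m1": (0, 1)}, self.CMAP, "g99")

    def test_functional_profile_split(self):
        summaries = {"m1": (-2.0, 0.2), "m2": (-2.0, 0.2), "m3": (3.0, 0.2)}
        profiles = u.profile_genes(summaries, self.CMAP)
        up, down = u.functional_profile(profiles)
        assert down == {"g1"}   # miRNAs up (negative DDCq) repress g1
        assert up == {"g2"}

    def test_empty_profiles_give_empty_sets(self):
        assert u.functional_profile([]) == (set(), set())
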