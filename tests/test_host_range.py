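"""Susceptibility matrices, host range, strata and redundancy."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_bool_matrix
from phagekit.host_range import (
    LYSIS_ZONE,
    NO_EFFECT,
    OUTCOMES,
    PLAQUE,
    PanelStrain,
    PlaquingObservation,
    category_fractions,
    classify_resistance,
    consensus_call,
    host_range,
    matrix_from_iauc,
    matrix_from_plaquing,
    redundancy_distribution,
    stratified_coverage,
)
from phagekit.kinetics import InhibitionScore


def obs(strain, agent, run, outcome):
    return PlaquingObservation(strain_id=strain, agent_id=agent, run=run, outcome=outcome)


def score(strain, agent, iauc, replicate=1):
    return InhibitionScore(
        strain_id=strain,
        agent_id=agent,
        auc_sample=(1 - iauc) * 100,
        auc_control=100.0,
        iauc=iauc,
        susceptible=iauc >= 0.2,
        replicate=replicate,
    )


class TestConsensusCall:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (PLAQUE, LYSIS_ZONE, LYSIS_ZONE),
            (PLAQUE, PLAQUE, PLAQUE),
            (LYSIS_ZONE, NO_EFFECT, NO_EFFECT),
        ],
    )
    def test_lower_plaquing_efficiency_wins(self, a, b, expected):
        assert consensus_call(obs("s", "a", 1, a), obs("s", "a", 2, b)) == expected

    def test_is_a_meet_operation(self):
        rank = {NO_EFFECT: 0, LYSIS_ZONE: 1, PLAQUE: 2}
        for a, b in itertools.product(OUTCOMES, OUTCOMES):
            out = consensus_call(obs("s", "x", 1, a), obs("s", "x", 2, b))
            rev = consensus_call(obs("s", "x", 1, b), obs("s", "x", 2, a))
            assert out == rev  # commutative
            assert rank[out] <= min(rank[a], rank[b])  # never higher
            assert consensus_call(obs("s", "x", 1, a), obs("s", "x", 2, a)) == a

    def test_mismatched_cell_rejected(self):
        with pytest.raises(ValueError, match="same strain and agent"):
            consensus_call(obs("s1", "a", 1, PLAQUE), obs("s2", "a", 2, PLAQUE))


class TestMatrixFromIauc:
    def test_thresholding(self):
        m = matrix_from_iauc([score("s1", "a", 0.5), score("s2", "a", 0.1)])
        assert m.calls[0, m.strain_ids.index("s1"), 0]
        assert not m.calls[0, m.strain_ids.index("s2"), 0]

    def test_empty_scores_give_empty_matrix(self):
        m = matrix_from_iauc([])
        assert len(m.strains) == 0 and len(m.agents) == 0

    def test_random_table_matches_elementwise_oracle(self, rng):
        scores = [
            score(f"s{i:02d}", f"a{j}", float(rng.uniform(-0.2, 1.2)))
            for i in range(20)
            for j in range(5)
        ]
        m = matrix_from_iauc(scores)
        for sc in scores:
            i = m.strain_ids.index(sc.strain_id)
            j = m.agents.index(sc.agent_id)
            assert m.calls[0, i, j] == (sc.iauc >= 0.2)

    def test_duplicate_cell_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            matrix_from_iauc([score("s1", "a", 0.5), score("s1", "a", 0.6)])

    def test_missing_cells_marked_absent(self):
        m = matrix_from_iauc([score("s1", "a", 0.5), score("s2", "b", 0.5)])
        assert m.present.sum() == 2


class TestMatrixFromPlaquing:
    def test_lysis_zone_counts_as_susceptible(self):
        m = matrix_from_plaquing([obs("s1", "a", 1, LYSIS_ZONE)])
        assert m.calls[0, 0, 0]

    def test_no_effect_not_susceptible(self):
        m = matrix_from_plaquing([obs("s1", "a", 1, NO_EFFECT)])
        assert not m.calls[0, 0, 0]

    def test_conservative_consensus_applied(self):
        m = matrix_from_plaquing(
            [obs("s1", "a", 1, PLAQUE), obs("s1", "a", 2, NO_EFFECT)], consensus=True
        )
        assert m.n_replicates == 1
        assert not m.calls[0, 0, 0]

    def test_consensus_requires_two_runs(self):
        with pytest.raises(ValueError, match="exactly 2 runs"):
            matrix_from_plaquing([obs("s1", "a", 1, PLAQUE)], consensus=True)


class TestHostRange:
    def test_worked_example_counts_then_normalized_sd(self):
        # replicates with 10 and 12 susceptible strains of 82
        calls = np.zeros((2, 82, 1), dtype=bool)
        calls[0, :10, 0] = True
        calls[1, :12, 0] = True
        m = make_bool_matrix(calls, agents=["a"])
        est = host_range(m, "a")
        assert est.mean_fraction == pytest.approx(11 / 82)
        assert est.sd_fraction == pytest.approx(np.std([10, 12], ddof=1) / 82)
        assert est.n_strains == 82

    def test_all_susceptible(self):
        m = make_bool_matrix(np.ones((3, 10, 1), dtype=bool), agents=["a"])
        est = host_range(m, "a")
        assert est.mean_fraction == 1.0 and est.sd_fraction == 0.0

    def test_single_replicate_sd_zero(self):
        m = make_bool_matrix(np.ones((1, 5, 1), dtype=bool), agents=["a"])
        assert host_range(m, "a").sd_fraction == 0.0

    def test_agreeing_replicates_have_zero_sd(self, rng):
        col = rng.random(30) < 0.5
        calls = np.stack([col, col, col])[:, :, None]
        m = make_bool_matrix(calls, agents=["a"])
        assert host_range(m, "a").sd_fraction == 0.0

    def test_unknown_agent_rejected(self):
        m = make_bool_matrix(np.ones((1, 2, 1), dtype=bool), agents=["a"])
        with pytest.raises(KeyError):
            host_range(m, "zz")


def categorical_matrix(best_outcomes, n_reps=1):
    """Single-agent matrix whose per-strain outcome equals the given list."""
    codes = {PLAQUE: "P", LYSIS_ZONE: "L", NO_EFFECT: "N"}
    n = len(best_outcomes)
    outcomes = np.full((n_reps, n, 1), "", dtype="<U1")
    calls = np.zeros((n_reps, n, 1), dtype=bool)
    for r in range(n_reps):
        for i, o in enumerate(best_outcomes):
            outcomes[r, i, 0] = codes[o]
            calls[r, i, 0] = o != NO_EFFECT
    return make_bool_matrix(calls, agents=["a"], outcomes=outcomes)


class TestCategoryFractions:
    def test_all_no_effect(self):
        f = category_fractions(categorical_matrix([NO_EFFECT] * 4))
        assert (f.plaque_pct, f.lysis_pct, f.coverage_pct) == (0.0, 0.0, 0.0)

    def test_every_strain_plaques(self):
        f = category_fractions(categorical_matrix([PLAQUE] * 6))
        assert (f.plaque_pct, f.lysis_pct, f.coverage_pct) == (100.0, 0.0, 100.0)

    def test_categories_conserve_to_100(self, rng):
        outs = list(rng.choice(OUTCOMES, size=40))
        f = category_fractions(categorical_matrix(outs))
        assert f.plaque_pct + f.lysis_pct + f.no_effect_pct == pytest.approx(100.0)

    def test_best_outcome_across_agents(self):
        # strain plaques for one agent, lysis for the other -> counted as plaque
        outcomes = np.array([[["P", "L"]]], dtype="<U1")
        calls = np.ones((1, 1, 2), dtype=bool)
        m = make_bool_matrix(calls, agents=["a", "b"], outcomes=outcomes)
        f = category_fractions(m)
        assert f.plaque_pct == 100.0 and f.lysis_pct == 0.0


class TestClassifyResistance:
    def test_esbl_breakpoint_inclusive(self):
        assert "ESBL" in classify_resistance({"ceftriaxone": 2.0})

    def test_cre_breakpoint_strict(self):
        flags = classify_resistance({"meropenem": 2.0})
        assert "CRE" not in flags
        assert "CRE" in classify_resistance({"meropenem": 2.1})

    def test_low_mics_give_no_flags(self):
        mics = {d: 0.25 for d in ("ceftriaxone", "meropenem", "ciprofloxacin")}
        assert classify_resistance(mics) == frozenset()

    def test_fqr_breakpoints(self):
        assert "FQR" in classify_resistance({"ciprofloxacin": 1.0})
        assert "FQR" in classify_resistance({"levofloxacin": 2.0})

    def test_mdr_needs_three_classes(self):
        two = {"ceftriaxone": 64.0, "ciprofloxacin": 4.0}
        assert "MDR" not in classify_resistance(two)
        three = dict(two, gentamicin=16.0)
        assert "MDR" in classify_resistance(three)

    def test_unknown_drug_warns_and_is_ignored(self):
        with pytest.warns(UserWarning, match="unknown drug"):
            flags = classify_resistance({"unobtainium": 99.0})
        assert flags == frozenset()

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        mics=st.dictionaries(
            st.sampled_from(
                ["ceftriaxone", "meropenem", "ciprofloxacin", "gentamicin", "ampicillin"]
            ),
            st.floats(0.01, 64.0),
            min_size=1,
        ),
        bumps=st.dictionaries(
            st.sampled_from(["ceftriaxone", "meropenem", "ciprofloxacin"]),
            st.floats(0.0, 64.0),
        ),
    )
    def test_monotone_in_mic(self, mics, bumps):
        base = classify_resistance(mics)
        raised = dict(mics)
        for drug, bump in bumps.items():
            raised[drug] = raised.get(drug, 0.0) + bump
        assert base <= classify_resistance(raised)


class TestStratifiedCoverage:
    def test_all_covered_carbapenem_stratum(self):
        strains = [
            PanelStrain(strain_id=f"b{i}", resistance_flags=frozenset({"CRE"}))
            for i in range(5)
        ]
        m = make_bool_matrix(np.ones((1, 5, 2), dtype=bool), strains=strains)
        res = stratified_coverage(m, m.agents, "CRE")
        assert res.estimate.mean_fraction == 1.0
        assert (res.n_susceptible, res.n_resistant) == (5, 0)

    def test_fluoroquinolone_fraction_rounds_to_printed_value(self):
        strains = [
            PanelStrain(strain_id=f"b{i}", resistance_flags=frozenset({"FQR"}))
            for i in range(198)
        ]
        calls = np.zeros((1, 198, 1), dtype=bool)
        calls[0, :176, 0] = True
        m = make_bool_matrix(calls, strains=strains, agents=["a"])
        res = stratified_coverage(m, ["a"], "FQR")
        assert round(100 * res.estimate.mean_fraction, 1) == 88.9
        assert (res.n_susceptible, res.n_resistant) == (176, 22)

    def test_zero_susceptible_stratum(self):
        strains = [PanelStrain(strain_id="b1", phylogroup="B2")]
        m = make_bool_matrix(np.zeros((1, 1, 1), dtype=bool), strains=strains, agents=["a"])
        assert stratified_coverage(m, ["a"], "B2").estimate.mean_fraction == 0.0

    def test_empty_stratum_rejected(self):
        m = make_bool_matrix(np.ones((1, 2, 1), dtype=bool), agents=["a"])
        with pytest.raises(ValueError, match="empty stratum"):
            stratified_coverage(m, ["a"], "CRE")


class TestRedundancyDistribution:
    def test_every_strain_hit_by_all_agents(self):
        m = make_bool_matrix(np.ones((1, 10, 4), dtype=bool))
        np.testing.assert_allclose(redundancy_distribution(m, m.agents), 1.0)

    def test_printed_two_cap_fraction(self):
        # 59 of 72 strains hit by >= 2 agents
        calls = np.zeros((1, 72, 4), dtype=bool)
        calls[0, :59, :2] = True
        calls[0, 59:67, 0] = True
        m = make_bool_matrix(calls)
        dist = redundancy_distribution(m, m.agents)
        assert round(100 * dist[2], 1) == 81.9

    def test_matches_exhaustive_counting(self, rng):
        calls = rng.random((1, 30, 4)) < 0.4
        m = make_bool_matrix(calls)
        dist = redundancy_distribution(m, m.agents)
        counts = calls[0].sum(axis=1)
        for k in range(5):
            assert dist[k] == pytest.approx((counts >= k).mean())

    def test_k0_is_one_and_nonincreasing(self, rng):
        calls = rng.random((2, 25, 5)) < 0.3
        m = make_bool_matrix(calls)
        dist = redundancy_distribution(m, m.agents)
        assert dist[0] == 1.0
        assert np.all(np.diff(dist) <= 1e-12)


class TestPanelStrainConsistency:
    def test_flags_must_match_mic_table(self):
        with pytest.raises(ValueError, match="inconsistent"):
            PanelStrain(
                strain_id="b1",
                resistance_flags=frozenset({"ESBL"}),
                mic_table={"ceftriaxone": 0.25},
            )

    def test_consistent_flags_accepted(self):
        s = PanelStrain(
            strain_id="b1",
            resistance_flags=frozenset({"ESBL"}),
            mic_table={"ceftriaxone": 4.0},
        )
        assert "ESBL" in s.resistance_flags
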