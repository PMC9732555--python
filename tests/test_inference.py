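"""Exact inference: hand-computed posteriors, prior recovery, distress
queries, error paths, and equivalence with the brute-force joint oracle."""

import pytest

from clusterbn import (
    EvidenceError,
    ZeroProbabilityEvidence,
    build_network,
    distress_profile,
    generate_fixture,
    joint_configuration_probability,
    posterior_marginals,
)
from clusterbn.parameters import (
    BaselineSpec,
    DISORDERS,
    DistressLink,
    InfluenceArc,
    ParameterSet,
    PrevalenceEntry,
    SymptomSpec,
)

from conftest import oracle_posterior


def toy_ps(prior=0.2, q=0.8, leak=0.1):
    """One disorder, one binary symptom."""
    ps = ParameterSet()
    ps.prevalence.append(PrevalenceEntry("ATS", prior, prior / 2, 0.7))
    ps.symptoms.append(SymptomSpec("DSM-ATS-01", "DSM",
                                   ("absent", "present"), "absent"))
    ps.baselines.append(BaselineSpec("DSM-ATS-01", base_present=leak))
    ps.arcs.append(InfluenceArc("ATS", "DSM-ATS-01", "toward_present", q))
    return ps


class TestHandBayes:
    def test_symptom_present(self):
        model = build_network(toy_ps(), distress=False)
        rep = posterior_marginals(model, {"DSM-ATS-01": "present"}, ["ATS"])
        # 0.2*0.8 / (0.2*0.8 + 0.8*0.1) = 2/3
        assert rep.prob("ATS", "present") == pytest.approx(2 / 3, abs=1e-12)

    def test_symptom_absent(self):
        model = build_network(toy_ps(), distress=False)
        rep = posterior_marginals(model, {"DSM-ATS-01": "absent"}, ["ATS"])
        # 0.2*0.2 / (0.2*0.2 + 0.8*0.9) = 1/19
        assert rep.prob("ATS", "present") == pytest.approx(1 / 19, abs=1e-12)

    def test_posterior_normalizes(self):
        model = build_network(toy_ps(), distress=False)
        rep = posterior_marginals(model, {"DSM-ATS-01": "present"}, ["ATS"])
        assert sum(rep.posteriors["ATS"].values()) == pytest.approx(1.0,
                                                                    abs=1e-12)


class TestPriorRecovery:
    def test_clinical_priors(self, builtin_model, builtin_ps):
        rep = posterior_marginals(builtin_model, {}, list(DISORDERS))
        for p in builtin_ps.prevalence:
            assert rep.prob(p.disorder, "present") == \
                pytest.approx(p.clinical, abs=1e-12)

    def test_general_priors(self, builtin_model_general, builtin_ps):
        rep = posterior_marginals(builtin_model_general, {}, list(DISORDERS))
        for p in builtin_ps.prevalence:
            assert rep.prob(p.disorder, "present") == \
                pytest.approx(p.general, abs=1e-12)


class TestJointConfiguration:
    def test_all_absent_empty_evidence_is_the_prior_product(self,
                                                            builtin_model):
        config = {d: "absent" for d in DISORDERS}
        expected = 1.0
        for d in DISORDERS:
            expected *= 1.0 - builtin_model.nodes[d].prior
        got = joint_configuration_probability(builtin_model, config, {})
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.490836, abs=1e-6)

    def test_empty_evidence_equals_prior_product_for_any_config(
            self, builtin_model):
        config = {d: s for d, s in zip(
            DISORDERS, ("present", "absent", "present", "absent", "absent"))}
        expected = 1.0
        for d in DISORDERS:
            p = builtin_model.nodes[d].prior
            expected *= p if config[d] == "present" else 1.0 - p
        assert joint_configuration_probability(builtin_model, config, {}) \
            == pytest.approx(expected, abs=1e-12)

    def test_single_finding_multiplies_the_likelihood_factor(
            self, builtin_model):
        config = {d: "absent" for d in DISORDERS}
        config["BDL"] = "present"
        prior = 1.0
        for d in DISORDERS:
            p = builtin_model.nodes[d].prior
            prior *= p if config[d] == "present" else 1.0 - p
        got = joint_configuration_probability(
            builtin_model, config, {"DSM-BDL-03": "present"})
        assert got == pytest.approx(prior * 0.886, abs=1e-12)

    def test_summing_configs_reproduces_posterior_marginals(
            self, builtin_model):
        import itertools
        ev = {"DSM-BDL-03": "present", "LPF-Identity": "high"}
        weights = {}
        for combo in itertools.product(("absent", "present"), repeat=5):
            config = dict(zip(DISORDERS, combo))
            weights[combo] = joint_configuration_probability(
                builtin_model, config, ev)
        total = sum(weights.values())
        p_bdl = sum(w for c, w in weights.items()
                    if c[DISORDERS.index("BDL")] == "present") / total
        rep = posterior_marginals(builtin_model, ev, ["BDL"])
        assert rep.prob("BDL", "present") == pytest.approx(p_bdl, abs=1e-9)

    def test_partial_configuration_rejected(self, builtin_model):
        with pytest.raises(EvidenceError, match="all roots"):
            joint_configuration_probability(builtin_model,
                                            {"BDL": "present"}, {})


class TestDistressQueries:
    def test_all_group_parents_neutral_gives_zero(self, builtin_model):
        ev = {f"DSM-BDL-{i:02d}": "absent" for i in range(1, 10)}
        rep = posterior_marginals(builtin_model, ev, ["PD-DSM-BDL"])
        assert rep.prob("PD-DSM-BDL", "present") == pytest.approx(0.0,
                                                                  abs=1e-12)

    def test_single_present_symptom_rest_absent(self, builtin_model):
        ev = {f"DSM-BDL-{i:02d}": ("present" if i == 3 else "absent")
              for i in range(1, 10)}
        rep = posterior_marginals(builtin_model, ev, ["PD-DSM-BDL"])
        assert rep.prob("PD-DSM-BDL", "present") == pytest.approx(0.764,
                                                                  abs=1e-12)

    def test_single_present_symptom_alone_is_a_lower_bound(self,
                                                           builtin_model):
        rep = posterior_marginals(builtin_model, {"DSM-BDL-03": "present"},
                                  ["PD-DSM-BDL"])
        assert rep.prob("PD-DSM-BDL", "present") >= 0.764

    def test_two_symptom_group_noisy_or(self):
        ps = toy_ps()
        ps.symptoms.append(SymptomSpec("DSM-ATS-02", "DSM",
                                       ("absent", "present"), "absent"))
        ps.baselines.append(BaselineSpec("DSM-ATS-02", base_present=0.1))
        ps.arcs.append(InfluenceArc("ATS", "DSM-ATS-02", "toward_present",
                                    0.8))
        ps.distress += [DistressLink("DSM-ATS-01", 0.5, "PD-DSM-ATS"),
                        DistressLink("DSM-ATS-02", 0.5, "PD-DSM-ATS")]
        model = build_network(ps)
        rep = posterior_marginals(
            model, {"DSM-ATS-01": "present", "DSM-ATS-02": "present"},
            ["PD-DSM-ATS"])
        assert rep.prob("PD-DSM-ATS", "present") == pytest.approx(0.75,
                                                                  abs=1e-12)

    def test_general_distress_tracks_disorder_posterior(self, builtin_model):
        rep = distress_profile(builtin_model, {})
        # empty evidence: P(general distress) = 1 - prod(1 - pd_d * prior_d)
        expected = 1.0
        for d, pd in zip(DISORDERS, (0.700, 0.871, 0.614, 0.729, 0.621)):
            expected *= 1.0 - pd * builtin_model.nodes[d].prior
        assert rep.prob("PD-General", "present") == \
            pytest.approx(1.0 - expected, abs=1e-12)

    def test_profile_covers_all_fourteen_nodes(self, builtin_model):
        rep = distress_profile(builtin_model, {})
        assert len(rep.posteriors) == 14


class TestErrorPaths:
    def test_target_observed(self, builtin_model):
        with pytest.raises(EvidenceError, match="target is observed"):
            posterior_marginals(builtin_model, {"BDL": "present"}, ["BDL"])

    def test_unknown_state(self, builtin_model):
        with pytest.raises(EvidenceError, match="unknown state"):
            posterior_marginals(builtin_model, {"DSM-BDL-03": "maybe"},
                                ["BDL"])

    def test_zero_probability_evidence(self):
        # deterministic symptom: q=1, leak=0; observing it absent while
        # clamping the disorder present is contradictory
        model = build_network(toy_ps(q=1.0, leak=0.0), distress=False)
        with pytest.raises(ZeroProbabilityEvidence):
            posterior_marginals(
                model, {"ATS": "present", "DSM-ATS-01": "absent"}, [])


class TestMonotonicity:
    def test_present_finding_never_lowers_a_parent_disorder(self,
                                                            builtin_model):
        """Noisy-OR likelihood ratios are >= 1 per parent, so adding a
        present binary finding cannot lower any parent's posterior."""
        base = posterior_marginals(builtin_model, {}, list(DISORDERS))
        for sid in ("DSM-ATS-03", "DSM-BDL-08", "MD-Denial",
                    "MD-Passive-aggression", "DSM-NAR-07"):
            parents = builtin_model.nodes[sid].parents
            rep = posterior_marginals(builtin_model, {sid: "present"},
                                      list(DISORDERS))
            for d in parents:
                assert rep.prob(d, "present") >= \
                    base.prob(d, "present") - 1e-12

    def test_all_antisocial_criteria_raise_both_ats_and_bdl(self,
                                                            builtin_model):
        """Entering the seven DSM antisocial criteria as present raises both
        the antisocial and the borderline posterior above their clinical
        priors (three criteria are shared arcs)."""
        ev = {f"DSM-ATS-{i:02d}": "present" for i in range(1, 8)}
        rep = posterior_marginals(builtin_model, ev, ["ATS", "BDL"])
        assert rep.prob("ATS", "present") > 0.124
        assert rep.prob("BDL", "present") > 0.193


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_random_fixture_networks_match_joint_enumeration(self, seed):
        """Configuration-enumeration inference agrees with the dense joint
        oracle to 1e-9 on seeded <=12-node fixtures, including queries on
        symptom and distress targets with mixed evidence."""
        ps = generate_fixture(seed, n_disorders=2, n_symptoms=5,
                              graded_fraction=0.5)
        model = build_network(ps, "clinical")
        assert len(model.nodes) <= 12
        sids = model.symptom_ids
        ev = {sids[0]: model.nodes[sids[0]].states[-1]}
        if len(sids) > 1:
            ev[sids[1]] = model.nodes[sids[1]].states[0]
        targets = model.disorder_ids + model.distress_ids + sids[2:3]
        targets = [t for t in targets if t not in ev]
        rep = posterior_marginals(model, ev, targets)
        for target in targets:
            expected = oracle_posterior(model, ev, target)
            for state, p in expected.items():
                assert rep.prob(target, state) == pytest.approx(p, abs=1e-9)

    @pytest.mark.parametrize("seed", [3, 7])
    def test_distress_evidence_marginalizes_symptom_parents(self, seed):
        """A finding on a distress node induces closed-form marginalization
        over its unobserved symptom parents; the oracle confirms it."""
        ps = generate_fixture(seed, n_disorders=2, n_symptoms=4,
                              graded_fraction=0.5)
        model = build_network(ps, "clinical")
        distress_node = model.distress_ids[0]
        ev = {distress_node: "present"}
        targets = model.disorder_ids + \
            [s for s in model.nodes[distress_node].parents
             if model.nodes[s].role == "symptom"][:1]
        rep = posterior_marginals(model, ev, targets)
        for target in targets:
            expected = oracle_posterior(model, ev, target)
            for state, p in expected.items():
                assert rep.prob(target, state) == pytest.approx(p, abs=1e-9)
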