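import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cmcdcm import (
    BMSResult,
    EvidenceTable,
    Posterior,
    PriorSpec,
    ParamPrior,
    WINNING_ARCHITECTURE_ID,
    WINNING_EXTRINSIC_ID,
    WINNING_INTRINSIC_ID,
    bpa,
    build_architecture_space,
    build_extrinsic_space,
    build_intrinsic_space,
    default_network,
    ffx_bms,
)
from cmcdcm.io import model_card


@pytest.fixture(scope="module")
def arch_space():
    return build_architecture_space()


@pytest.fixture(scope="module")
def ext_space():
    return build_extrinsic_space(default_network())


@pytest.fixture(scope="module")
def stage2(ext_space):
    return ext_space[WINNING_EXTRINSIC_ID]


@pytest.fixture(scope="module")
def int_space(stage2):
    return build_intrinsic_space(stage2)


class TestArchitectureSpace:
    def test_nine_architectures(self, arch_space):
        assert len(arch_space) == 9
        assert len(set(arch_space.ids)) == 9

    def test_input_always_bilateral_a1(self, arch_space):
        for mid, m in arch_space.models:
            nz = [m.sources[i].name for i in np.flatnonzero(m.c)]
            assert sorted(nz) == ["lA1", "rA1"], mid

    def test_winner_structure(self, arch_space):
        m = arch_space[WINNING_ARCHITECTURE_ID]
        idx = m.index_of
        assert set(idx) == {"lA1", "rA1", "lSTG", "rSTG", "rIPS", "rIFG"}
        # fronto-parietal sources interconnected
        assert m.af[idx["rIFG"], idx["rIPS"]] > 0
        assert m.ab[idx["rIPS"], idx["rIFG"]] > 0
        # both connect bilaterally with STG
        for fp in ("rIPS", "rIFG"):
            for stg in ("lSTG", "rSTG"):
                assert m.af[idx[fp], idx[stg]] > 0
                assert m.ab[idx[stg], idx[fp]] > 0

    def test_hierarchy_respected_everywhere(self, arch_space):
        for mid, m in arch_space.models:
            levels = np.array([s.level for s in m.sources])
            up = levels[:, None] > levels[None, :]
            assert np.all(m.af[~up] == 0), mid
            assert np.all(m.ab[~up.T] == 0), mid

    def test_missing_required_source_rejected(self):
        from cmcdcm import default_sources

        with pytest.raises(ValueError, match="rIPS"):
            build_architecture_space([s for s in default_sources() if s.name != "rIPS"])


class TestExtrinsicSpace:
    def test_sixteen_models(self, ext_space):
        assert len(ext_space) == 16

    def test_null_null_has_no_targets(self, ext_space):
        m = ext_space["ext_att-N_exp-N"]
        assert all(not s.extrinsic and not s.intrinsic for s in m.modulations)

    def test_backward_only_attention_members(self, ext_space):
        for exp_opt in ("F", "B", "R", "N"):
            m = ext_space[f"ext_att-B_exp-{exp_opt}"]
            att = next(s for s in m.modulations if s.factor == "attention")
            assert att.extrinsic and all(t.direction == "backward" for t in att.extrinsic)

    def test_winner_member_semantics(self, ext_space):
        m = ext_space[WINNING_EXTRINSIC_ID]
        att = next(s for s in m.modulations if s.factor == "attention")
        exp = next(s for s in m.modulations if s.factor == "expectation")
        assert {t.direction for t in att.extrinsic} == {"backward"}
        assert {t.direction for t in exp.extrinsic} == {"forward", "backward"}

    def test_fp_interconnection_not_modulated(self, ext_space):
        m = ext_space["ext_att-R_exp-R"]
        for spec in m.modulations:
            for t in spec.extrinsic:
                assert not (
                    {t.src, t.dst} == {"rIPS", "rIFG"}
                ), "IPS<->IFG link must stay unmodulated"


class TestIntrinsicSpace:
    def test_eighty_one_models(self, int_space):
        assert len(int_space) == 81

    def test_null_null_is_stage2_winner(self, int_space, stage2):
        m = int_space["int_att-Null_exp-Null"]
        assert model_card(m) == model_card(stage2.with_modulations(
            stage2.modulations, name="int_att-Null_exp-Null"
        ))

    def test_winning_member_targets_a1_interneurons(self, int_space):
        m = int_space[WINNING_INTRINSIC_ID]
        att = next(s for s in m.modulations if s.factor == "attention")
        assert sorted(t.source for t in att.intrinsic) == ["lA1", "rA1"]
        assert {t.population for t in att.intrinsic} == {"II"}
        # stage-2 extrinsic modulation is retained
        assert att.extrinsic and all(t.direction == "backward" for t in att.extrinsic)

    def test_level_options_target_expected_sources(self, int_space):
        fp = int_space["int_att-FP_II_exp-Null"]
        att = next(s for s in fp.modulations if s.factor == "attention")
        assert sorted(t.source for t in att.intrinsic) == ["rIFG", "rIPS"]
        full = int_space["int_att-Full_SP_exp-Null"]
        att = next(s for s in full.modulations if s.factor == "attention")
        assert len(att.intrinsic) == 6
        assert {t.population for t in att.intrinsic} == {"SP"}

    def test_activity_dependent_flag_propagates(self, stage2):
        int_space = build_intrinsic_space(stage2, activity_dependent=True)
        m = int_space[WINNING_INTRINSIC_ID]
        att = next(s for s in m.modulations if s.factor == "attention")
        assert att.activity_dependent


class TestFFXBMS:
    def test_group_evidence_sums_subjects(self):
        t = EvidenceTable(np.array([[1.0, 2.0], [3.0, 4.0]]), ["s1", "s2"], ["m1", "m2"])
        res = ffx_bms(t)
        assert res.group_evidence == {"m1": 4.0, "m2": 6.0}
        assert res.best == "m2" and res.runner_up == "m1"
        assert res.log_bf_runner_up == pytest.approx(2.0)

    def test_three_nat_lead_probability(self):
        t = EvidenceTable(np.array([[3.0, 0.0]]), ["s"], ["a", "b"])
        res = ffx_bms(t)
        assert res.probabilities["a"] == pytest.approx(math.exp(3) / (1 + math.exp(3)), abs=1e-12)

    def test_32_nat_lead_exceeds_99_percent(self):
        t = EvidenceTable(np.array([[32.0, 0.0, -5.0]]), ["s"], ["a", "b", "c"])
        res = ffx_bms(t)
        assert res.probabilities["a"] > 0.99

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(-1e4, 1e4))
    def test_normalization_and_shift_invariance(self, seed, shift):
        rng = np.random.default_rng(seed)
        vals = rng.normal(0, 50, (3, 4))
        ids = [f"m{i}" for i in range(4)]
        a = ffx_bms(EvidenceTable(vals, ["s1", "s2", "s3"], ids))
        b = ffx_bms(EvidenceTable(vals + shift / 3, ["s1", "s2", "s3"], ids))
        assert sum(a.probabilities.values()) == pytest.approx(1.0, abs=1e-12)
        for m in ids:
            assert a.probabilities[m] == pytest.approx(b.probabilities[m], abs=1e-9)

    def test_softmax_monotonicity(self):
        vals = np.array([[1.0, 2.0, 3.0]])
        base = ffx_bms(EvidenceTable(vals, ["s"], ["a", "b", "c"]))
        bumped = ffx_bms(EvidenceTable(vals + [[0.5, 0, 0]], ["s"], ["a", "b", "c"]))
        assert bumped.probabilities["a"] > base.probabilities["a"]

    def test_incomplete_table_rejected(self):
        t = EvidenceTable(np.array([[1.0, np.nan]]), ["s"], ["a", "b"])
        with pytest.raises(ValueError, match="complete"):
            ffx_bms(t)

    def test_single_model_degenerate_case(self):
        res = ffx_bms(EvidenceTable(np.array([[5.0]]), ["s"], ["only"]))
        assert res.best == "only" and res.runner_up is None
        assert res.probabilities["only"] == pytest.approx(1.0)


def make_posterior(mean, cov, names=None):
    mean = np.atleast_1d(np.asarray(mean, float))
    cov = np.atleast_2d(np.asarray(cov, float))
    names = names or [f"p{i}" for i in range(mean.size)]
    return Posterior(
        mean=mean, cov=cov, param_names=names, lam=0.0, lam_var=1.0,
        free_energy=0.0, accuracy=0.0, complexity=0.0,
        f_trace=np.array([0.0]), converged=True,
    )


class TestBPA:
    def test_identical_posteriors_pool_precision(self):
        posts = [make_posterior([1.0, -2.0], np.diag([0.5, 2.0])) for _ in range(4)]
        res = bpa(posts, correct_prior=False)
        assert np.allclose(res.mean, [1.0, -2.0])
        assert np.allclose(res.cov, np.diag([0.5 / 4, 2.0 / 4]))

    def test_two_gaussian_closed_form(self):
        res = bpa([make_posterior(0.0, 1.0), make_posterior(2.0, 1.0)], correct_prior=False)
        assert res.mean[0] == pytest.approx(1.0)
        assert res.cov[0, 0] == pytest.approx(0.5)

    def test_prior_correction_recovers_prior(self):
        prior = PriorSpec(params=[ParamPrior("p0", 0.3, 2.0)])
        posts = [make_posterior(0.3, 2.0) for _ in range(5)]
        res = bpa(posts, prior=prior, correct_prior=True)
        assert res.mean[0] == pytest.approx(0.3, abs=1e-12)
        assert res.cov[0, 0] == pytest.approx(2.0, abs=1e-12)

    def test_variance_reduction_without_correction(self):
        posts = [
            make_posterior([0.1, 0.2], np.diag([1.0, 0.5])),
            make_posterior([0.3, -0.1], np.diag([2.0, 0.25])),
        ]
        res = bpa(posts, correct_prior=False)
        for post in posts:
            assert np.all(np.diag(res.cov) < np.diag(post.cov) + 1e-12)

    def test_directional_probabilities(self):
        res = bpa([make_posterior(2.0, 1.0), make_posterior(2.0, 1.0)], correct_prior=False)
        # mean 2, sd sqrt(1/2): P(>0) = Phi(2 / sqrt(0.5))
        from scipy.special import ndtr

        assert res.p_positive[0] == pytest.approx(float(ndtr(2 / math.sqrt(0.5))))
        assert res.p_positive[0] + res.p_negative[0] == pytest.approx(1.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bpa([make_posterior(0.0, 1.0), make_posterior([0.0, 1.0], np.eye(2))],
                correct_prior=False)

    def test_indefinite_pooled_precision_rejected(self):
        # posteriors broader than the prior make the corrected pool indefinite
        prior = PriorSpec(params=[ParamPrior("p0", 0.0, 0.1)])
        posts = [make_posterior(0.0, 10.0) for _ in range(3)]
        with pytest.raises(np.linalg.LinAlgError):
            bpa(posts, prior=prior, correct_prior=True)
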