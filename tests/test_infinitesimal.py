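import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from infdom.ibd import (PairIdentitySet, ParentalIdentitySet,
                        pair_identities, parental_identity_set)
from infdom.infinitesimal import (MvnSpec, conditional_shared_moments,
                                  cross_family_cov,
                                  family_residual_components, joint_trait_mvn,
                                  mvn_condition, parent_offspring_shared_cov,
                                  residual_variance, shared_moments,
                                  trait_cov, trait_moments)
from infdom.pedigree import make_random_pedigree
from infdom.trait_model import (VarianceComponents,
                                make_biallelic_dominance_model,
                                variance_components)

ZERO_PID = ParentalIdentitySet(F11=0, F22=0, F12=0, F112=0, F122=0, F1122=0,
                               Ft_1212=0, Ft_1122=0)


def random_vc(seed, biallelic=False):
    rng = np.random.default_rng(seed)
    if biallelic:
        model = make_biallelic_dominance_model(40, seed=seed)
        return variance_components(model)
    return VarianceComponents(
        sigma_A2=float(rng.uniform(0.1, 1.0)),
        sigma_D2=float(rng.uniform(0.0, 0.5)),
        iota=float(rng.normal(0, 0.5)),
        iota_star=float(rng.uniform(0, 0.3)),
        sigma_DI2=float(rng.uniform(0, 0.3)),
        sigma_ADI=float(rng.normal(0, 0.2)))


def pedigree_pids():
    ped = make_random_pedigree(6, 6, selfing_allowed=True, seed=13)
    out = []
    for t in (2, 4, 6):
        for ind in ped.generation_members(t)[:3]:
            out.append(parental_identity_set(ped, ind.id))
    return out


PIDS = pedigree_pids() + [ZERO_PID]


def test_zero_identity_baselines():
    vc = random_vc(1)
    sm = shared_moments(vc, ZERO_PID)
    assert sm.mean == 0.0
    assert sm.variance == pytest.approx(vc.sigma_A2 / 2 + vc.sigma_D2 / 4,
                                        abs=1e-12)
    assert residual_variance(vc, ZERO_PID) == pytest.approx(
        vc.sigma_A2 / 2 + 3 * vc.sigma_D2 / 4, abs=1e-12)
    C1, C2 = parent_offspring_shared_cov(vc, ZERO_PID)
    assert C1 == pytest.approx(vc.sigma_A2 / 2, abs=1e-12)
    assert C2 == pytest.approx(vc.sigma_A2 / 2, abs=1e-12)
    fr = family_residual_components(vc, ZERO_PID)
    assert fr["VRA"] == pytest.approx(vc.sigma_A2 / 2, abs=1e-12)
    assert fr["VRD"] == pytest.approx(3 * vc.sigma_D2 / 4, abs=1e-12)
    assert fr["VRA_RD"] == 0.0


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_sum_rule_on_pedigree_identities(seed):
    vc = random_vc(seed)
    for pid in PIDS:
        lhs = shared_moments(vc, pid).variance + residual_variance(vc, pid)
        rhs = trait_moments(vc, pid.F12).var_Z
        assert lhs == pytest.approx(rhs, abs=1e-10)


def test_purely_additive_reductions():
    vc = VarianceComponents(sigma_A2=0.8, sigma_D2=0, iota=0, iota_star=0,
                            sigma_DI2=0, sigma_ADI=0)
    for pid in PIDS:
        sm = shared_moments(vc, pid)
        assert sm.mean == 0.0
        assert sm.variance == pytest.approx(
            0.4 * (1 + 0.5 * (pid.F11 + pid.F22) + 2 * pid.F12), abs=1e-12)
        assert residual_variance(vc, pid) == pytest.approx(
            0.4 * (1 - 0.5 * (pid.F11 + pid.F22)), abs=1e-12)
        C1, _ = parent_offspring_shared_cov(vc, pid)
        assert C1 == pytest.approx(0.4 * (1 + pid.F11 + 2 * pid.F12),
                                   abs=1e-12)
        selfed_degenerate = (pid.F11 == pid.F22
                             and pid.F12 == 0.5 * (1 + pid.F11))
        if not selfed_degenerate:
            cm = conditional_shared_moments(vc, pid, 0.3, -0.9)
            assert cm.mean == pytest.approx((0.3 - 0.9) / 2, abs=1e-10)
            assert cm.variance == pytest.approx(0.0, abs=1e-10)
        else:
            # the purely additive parental matrix is exactly singular here
            cm = conditional_shared_moments(vc, pid, 0.3, 0.3, selfing=True)
            assert cm.variance == pytest.approx(0.0, abs=1e-10)


def test_trait_moments_values_and_validation():
    vc = random_vc(3)
    tm = trait_moments(vc, 0.0)
    assert tm.E_Z == vc.z_bar_0
    assert tm.var_Z == pytest.approx(vc.sigma_A2 + vc.sigma_D2, abs=1e-12)
    tm = trait_moments(vc, 0.5)
    assert tm.E_Z - vc.z_bar_0 == pytest.approx(0.5 * vc.iota, abs=1e-12)
    assert tm.var_script_A == pytest.approx(1.5 * vc.sigma_A2, abs=1e-12)
    with pytest.raises(ValueError):
        trait_moments(vc, 1.2)


def test_biallelic_var_script_D_reduction():
    vc = random_vc(7, biallelic=True)
    assert vc.sigma_D2 == pytest.approx(vc.iota_star, abs=1e-12)
    for F in (0.0, 0.3, 0.8):
        tm = trait_moments(vc, F)
        assert tm.var_script_D == pytest.approx(
            vc.sigma_D2 * (1 - F * F) + vc.sigma_DI2 * F, abs=1e-12)


def test_cross_family_cov_cases():
    vc = random_vc(4)
    zero_pair = PairIdentitySet(Fab=0, Faa=0, Fbb=0, Faab=0, Fabb=0,
                                Faabb=0, Ft_abab=0, Ft_aabb=0)
    assert cross_family_cov(vc, zero_pair) == 0.0
    va = VarianceComponents(sigma_A2=1.0, sigma_D2=0, iota=0, iota_star=0,
                            sigma_DI2=0, sigma_ADI=0)
    pair = PairIdentitySet(Fab=0.25, Faa=0, Fbb=0, Faab=0, Fabb=0,
                           Faabb=0, Ft_abab=0.25, Ft_aabb=0)
    assert cross_family_cov(va, pair) == pytest.approx(0.5, abs=1e-12)
    # halved-sigma_ADI variant only changes the three-gene term
    pair2 = PairIdentitySet(Fab=0.2, Faa=0.1, Fbb=0.1, Faab=0.05, Fabb=0.05,
                            Faabb=0.02, Ft_abab=0.1, Ft_aabb=0.03)
    full = cross_family_cov(vc, pair2)
    half = cross_family_cov(vc, pair2, sigma_ADI_halved=True)
    assert full - half == pytest.approx(0.05 * vc.sigma_ADI, abs=1e-12)


def test_sib_consistency_additive_term():
    # For full sibs, 2 F_ij sigma_A2 equals the shared-variance additive term
    ped = make_random_pedigree(8, 4, selfing_allowed=True, seed=21)
    vc = VarianceComponents(sigma_A2=1.0, sigma_D2=0, iota=0, iota_star=0,
                            sigma_DI2=0, sigma_ADI=0)
    child = ped.generation_members(4)[0]
    pid = parental_identity_set(ped, child.id)
    # build a sibling pair by reusing the same parents: identities of two
    # children of the same pair
    sibs = [i for i in ped.generation_members(4)
            if (i.parent1, i.parent2) == (child.parent1, child.parent2)]
    if len(sibs) >= 2:
        pair = pair_identities(ped, sibs[0].id, sibs[1].id)
        assert cross_family_cov(vc, pair) == pytest.approx(
            shared_moments(vc, pid).variance, abs=1e-10)


def test_family_residual_split_identity():
    for seed in range(3):
        vc = random_vc(seed, biallelic=True)
        for pid in PIDS:
            fr = family_residual_components(vc, pid)
            assert fr["VRA"] + fr["VRD"] + 2 * fr["VRA_RD"] == pytest.approx(
                residual_variance(vc, pid), abs=1e-10)
            # bi-allelic closed form for VRD
            vrd = (0.25 * vc.sigma_DI2
                   * (3 * pid.F12 - pid.F1122 - pid.F112 - pid.F122)
                   + 0.25 * vc.sigma_D2
                   * (3 - pid.F11 - pid.F22 - pid.F1122 - pid.Ft_1122
                      - 1.5 * pid.Ft_1212))
            assert fr["VRD"] == pytest.approx(vrd, abs=1e-10)


def test_conditional_moments_at_mean_and_selfing():
    vc = random_vc(5)
    ped = make_random_pedigree(6, 5, selfing_allowed=True, seed=17)
    pid = parental_identity_set(ped, ped.generation_members(5)[0].id)
    m1 = trait_moments(vc, pid.F11)
    m2 = trait_moments(vc, pid.F22)
    cm = conditional_shared_moments(vc, pid, m1.E_Z, m2.E_Z)
    assert cm.mean == pytest.approx(vc.iota * pid.F12, abs=1e-10)
    assert cm.variance <= shared_moments(vc, pid).variance + 1e-12
    # selfing path (a model-derived vc: synthetic components need not satisfy
    # the Cauchy-Schwarz constraints that keep the joint Gaussian PSD)
    vcb = random_vc(5, biallelic=True)
    chain = make_random_pedigree(1, 3, selfing_allowed=True, seed=0)
    pid_self = parental_identity_set(chain, chain.generation_members(3)[0].id)
    cs = conditional_shared_moments(vcb, pid_self, 0.4, 0.4, selfing=True)
    assert np.isfinite(cs.mean) and cs.variance >= -1e-12
    va = VarianceComponents(sigma_A2=1.0, sigma_D2=0, iota=0, iota_star=0,
                            sigma_DI2=0, sigma_ADI=0)
    with pytest.raises(ValueError, match="selfing"):
        conditional_shared_moments(va, pid_self, 0.4, 0.4, selfing=False)


def test_conditioning_two_routes_agree():
    vc = random_vc(6)
    ped = make_random_pedigree(6, 4, selfing_allowed=True, seed=19)
    ind = ped.generation_members(4)[0]
    pid = parental_identity_set(ped, ind.id)
    pair = PairIdentitySet(Fab=pid.F12, Faa=pid.F11, Fbb=pid.F22,
                           Faab=pid.F112, Fabb=pid.F122, Faabb=pid.F1122,
                           Ft_abab=pid.Ft_1212, Ft_aabb=pid.Ft_1122)
    m1, m2 = trait_moments(vc, pid.F11), trait_moments(vc, pid.F22)
    sm = shared_moments(vc, pid)
    C1, C2 = parent_offspring_shared_cov(vc, pid)
    c12 = trait_cov(vc, pair)
    spec = MvnSpec(mean=[m1.E_Z, m2.E_Z, sm.mean],
                   cov=np.array([[m1.var_Z, c12, C1],
                                 [c12, m2.var_Z, C2],
                                 [C1, C2, sm.variance]]),
                   labels=["z1", "z2", "ad"])
    cond = mvn_condition(spec, {"z1": 0.5, "z2": -0.1})
    cm = conditional_shared_moments(vc, pid, 0.5, -0.1)
    assert cond.mean[0] == pytest.approx(cm.mean, abs=1e-10)
    assert cond.cov[0, 0] == pytest.approx(cm.variance, abs=1e-10)


def test_mvn_spec_validation():
    with pytest.raises(ValueError):
        MvnSpec(mean=[0.0], cov=[[1.0, 0.0]], labels=["a"])
    with pytest.raises(ValueError):
        MvnSpec(mean=[0.0, 0.0], cov=[[1.0, 0.5], [0.4, 1.0]],
                labels=["a", "b"])
    with pytest.raises(ValueError):
        MvnSpec(mean=[0.0, 0.0], cov=[[1.0, 2.0], [2.0, 1.0]],
                labels=["a", "b"])
    with pytest.raises(ValueError):
        MvnSpec(mean=[0.0, 0.0], cov=np.eye(2), labels=["a", "a"])


def test_mvn_condition_properties():
    spec = MvnSpec(mean=[0.0, 0.0], cov=[[1.0, 0.6], [0.6, 1.0]],
                   labels=["x", "y"])
    assert mvn_condition(spec, {}) is spec
    c = mvn_condition(spec, {"y": 2.0})
    assert c.mean[0] == pytest.approx(1.2, abs=1e-12)
    assert c.cov[0, 0] == pytest.approx(0.64, abs=1e-12)
    with pytest.raises(KeyError):
        mvn_condition(spec, {"zz": 1.0})


def test_mvn_condition_idempotent_order_independent():
    ped = make_random_pedigree(5, 3, seed=23)
    vc = random_vc(8)
    ids = [i.id for i in ped.generation_members(3)] \
        + [ped.generation_members(2)[0].id]
    spec = joint_trait_mvn(ped, vc, ids)
    a = mvn_condition(mvn_condition(spec, {ids[0]: 0.2}), {ids[1]: -0.4})
    b = mvn_condition(spec, {ids[0]: 0.2, ids[1]: -0.4})
    assert np.allclose(a.mean, b.mean, atol=1e-10)
    assert np.allclose(a.cov, b.cov, atol=1e-10)


def test_joint_trait_mvn_diagonal_matches_trait_moments():
    ped = make_random_pedigree(5, 4, selfing_allowed=True, seed=29)
    vc = random_vc(9)
    ids = [i.id for i in ped.generation_members(4)]
    spec = joint_trait_mvn(ped, vc, ids)
    from infdom.ibd import inbreeding
    for k, i in enumerate(ids):
        tm = trait_moments(vc, inbreeding(ped, i))
        assert spec.mean[k] == pytest.approx(tm.E_Z, abs=1e-12)
        assert spec.cov[k, k] == pytest.approx(tm.var_Z, abs=1e-12)
    noisy = joint_trait_mvn(ped, vc, ids, observed=True)
    assert np.allclose(np.diag(noisy.cov) - np.diag(spec.cov), vc.sigma_E2)


@settings(max_examples=30, deadline=None)
@given(seed=st.integers(0, 10**6))
def test_property_sum_rule_synthetic_biallelic(seed):
    vc = random_vc(seed % 7, biallelic=True)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(PIDS))
    pid = PIDS[idx]
    lhs = shared_moments(vc, pid).variance + residual_variance(vc, pid)
    assert lhs == pytest.approx(trait_moments(vc, pid.F12).var_Z, abs=1e-10)
    fr = family_residual_components(vc, pid)
    assert fr["VRA"] + fr["VRD"] + 2 * fr["VRA_RD"] == pytest.approx(
        residual_variance(vc, pid), abs=1e-10)
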