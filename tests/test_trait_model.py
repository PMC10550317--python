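import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from infdom.trait_model import (AncestralModel, LocusModel,
                                VarianceComponents,
                                make_biallelic_dominance_model,
                                normalize_effects, sample_founder_genotypes,
                                trait_value, trait_values,
                                variance_components)


def random_locus(rng, k):
    nu = rng.dirichlet(np.ones(k) * 2)
    raw = rng.normal(size=(k, k))
    raw = 0.5 * (raw + raw.T)
    return nu, raw


@settings(max_examples=50, deadline=None)
@given(seed=st.integers(0, 10**6), k=st.integers(2, 5))
def test_normalize_effects_properties(seed, k):
    rng = np.random.default_rng(seed)
    nu, raw = random_locus(rng, k)
    mu, eta, phi = normalize_effects(raw, nu)
    # exact reconstruction
    assert np.allclose(mu + eta[:, None] + eta[None, :] + phi, raw,
                       atol=1e-12)
    # normalization constraints
    assert abs(nu @ eta) < 1e-10
    assert np.max(np.abs(nu @ phi)) < 1e-10
    assert np.allclose(phi, phi.T, atol=1e-12)
    # idempotence: normalizing the already-normalized residual is a no-op
    mu2, eta2, phi2 = normalize_effects(phi, nu)
    assert abs(mu2) < 1e-10
    assert np.max(np.abs(eta2)) < 1e-10
    assert np.allclose(phi2, phi, atol=1e-10)


def test_normalize_effects_validation():
    with pytest.raises(ValueError):
        normalize_effects(np.zeros((2, 3)), np.array([0.5, 0.5]))
    with pytest.raises(ValueError):
        normalize_effects(np.array([[0.0, 1.0], [0.0, 0.0]]),
                          np.array([0.5, 0.5]))
    with pytest.raises(ValueError):
        normalize_effects(np.zeros((2, 2)), np.array([0.7, 0.7]))


def test_locus_model_validation():
    with pytest.raises(ValueError):
        LocusModel(("a", "A"), nu=[0.5, 0.5], eta=[0.0, 0.0],
                   phi=[[0.0, 1.0], [0.0, 0.0]])
    with pytest.raises(ValueError):
        LocusModel(("a", "A"), nu=[0.9, 0.5], eta=[0.0, 0.0],
                   phi=np.zeros((2, 2)))


def test_variance_components_single_locus_brute_force():
    # exact components vs direct enumeration of the genotype distribution
    rng = np.random.default_rng(5)
    nu, raw = random_locus(rng, 3)
    mu, eta, phi = normalize_effects(raw, nu)
    model = AncestralModel([LocusModel(("x", "y", "z"), nu, eta, phi, mu)])
    vc = variance_components(model)
    assert vc.sigma_A2 == pytest.approx(2 * nu @ eta**2, abs=1e-12)
    assert vc.sigma_D2 == pytest.approx(nu @ phi**2 @ nu, abs=1e-12)
    d = np.diag(phi)
    assert vc.iota == pytest.approx(nu @ d, abs=1e-12)
    assert vc.iota_star == pytest.approx((nu @ d) ** 2, abs=1e-12)
    assert vc.sigma_DI2 == pytest.approx(nu @ d**2 - (nu @ d) ** 2, abs=1e-12)
    assert vc.sigma_ADI == pytest.approx(2 * nu @ (eta * d), abs=1e-12)
    # HW founder variance equals sigma_A2 + sigma_D2 exactly (M=1)
    g = nu[:, None] * nu[None, :]
    z = eta[:, None] + eta[None, :] + phi
    assert np.sum(g * z**2) == pytest.approx(vc.sigma_A2 + vc.sigma_D2,
                                             abs=1e-12)


def test_variance_components_requires_normalized():
    loc = LocusModel(("a", "A"), nu=[0.5, 0.5], eta=[1.0, 1.0],
                     phi=np.zeros((2, 2)))
    with pytest.raises(ValueError, match="normalized"):
        variance_components(AncestralModel([loc]))


@pytest.mark.parametrize("dialect", ["sample_counts", "continuous"])
def test_make_biallelic_model_structure(dialect):
    model = make_biallelic_dominance_model(50, seed=1, freq_dialect=dialect)
    assert model.M == 50
    assert model.is_normalized()
    for loc in model.loci:
        p = loc.nu[1]
        assert 1 / 60 - 1e-12 <= p <= 59 / 60 + 1e-12
        # complete dominance: raw values are -1/+1, reconstruct and check
        raw = loc.mu + loc.eta[:, None] + loc.eta[None, :] + loc.phi
        assert np.allclose(np.abs(raw), 1.0, atol=1e-10)
        assert raw[1, 1] == pytest.approx(1.0) and \
            raw[0, 0] == pytest.approx(-1.0)
        assert abs(raw[0, 1]) == pytest.approx(1.0)
    vc = variance_components(model)
    # bi-allelic identity: sigma_D2 == iota_star exactly
    assert vc.sigma_D2 == pytest.approx(vc.iota_star, abs=1e-12)


def test_sample_counts_frequencies_on_grid():
    model = make_biallelic_dominance_model(200, seed=3,
                                           freq_dialect="sample_counts")
    p = np.array([loc.nu[1] for loc in model.loci])
    assert np.allclose(np.round(p * 60), p * 60, atol=1e-9)


def test_dominance_direction_bias():
    # with c_H > 0 the dominant-plus direction is more frequent
    model = make_biallelic_dominance_model(4000, seed=2, c_H=1.0)
    raw_het = np.array([loc.mu + loc.eta[0] + loc.eta[1] + loc.phi[0, 1]
                        for loc in model.loci])
    share_plus = (raw_het > 0).mean()
    H = 0.5 + 1.0 / np.sqrt(4000)
    assert abs(share_plus - H) < 3 * np.sqrt(H * (1 - H) / 4000)


def test_founder_sampling_matches_nu():
    model = make_biallelic_dominance_model(30, seed=4)
    geno = sample_founder_genotypes(model, 20_000, seed=9)
    assert geno.shape == (20_000, 30, 2)
    p_hat = (geno == 1).mean(axis=(0, 2))
    p = np.array([loc.nu[1] for loc in model.loci])
    se = np.sqrt(p * (1 - p) / 40_000)
    assert np.all(np.abs(p_hat - p) < 4 * np.maximum(se, 1e-4))


def test_trait_values_single_locus_manual():
    nu = np.array([0.5, 0.5])
    mu, eta, phi = normalize_effects(np.array([[-1.0, 1.0], [1.0, 1.0]]), nu)
    model = AncestralModel([LocusModel(("a", "A"), nu, eta, phi, mu)],
                           z_bar_0=2.0)
    g = np.array([[[0, 1]]])
    expected = 2.0 + eta[0] + eta[1] + phi[0, 1]
    assert trait_values(model, g)[0] == pytest.approx(expected, abs=1e-12)
    assert trait_value(model, g[0]) == pytest.approx(expected, abs=1e-12)


def test_json_round_trip(tmp_path):
    model = make_biallelic_dominance_model(10, seed=6, sigma_E2=0.3)
    path = tmp_path / "model.json"
    model.to_json(path)
    back = AncestralModel.from_json(path)
    assert back.M == 10 and back.sigma_E2 == 0.3
    for a, b in zip(model.loci, back.loci):
        assert np.allclose(a.nu, b.nu) and np.allclose(a.phi, b.phi)
    vc1, vc2 = variance_components(model), variance_components(back)
    assert vc1.sigma_A2 == pytest.approx(vc2.sigma_A2, abs=1e-12)
    # file is valid JSON
    json.loads(path.read_text())


def test_purely_additive_flag():
    nu = np.array([0.3, 0.7])
    mu, eta, phi = normalize_effects(np.array([[0.0, 1.0], [1.0, 2.0]]), nu)
    model = AncestralModel([LocusModel(("a", "A"), nu, eta, phi, mu)])
    vc = variance_components(model)
    assert vc.purely_additive()
    assert vc.sigma_D2 == pytest.approx(0.0, abs=1e-12)


def test_write_vcf_round_trip(tmp_path):
    import pysam

    from infdom.trait_model import write_vcf
    model = make_biallelic_dominance_model(5, seed=7)
    geno = sample_founder_genotypes(model, 3, seed=8)
    path = tmp_path / "founders.vcf"
    write_vcf(geno, model, path, sample_ids=["i0", "i1", "i2"])
    with pysam.VariantFile(str(path)) as vf:
        recs = list(vf)
    assert len(recs) == 5
    got = np.array([[rec.samples[s]["GT"] for s in ("i0", "i1", "i2")]
                    for rec in recs]).transpose(1, 0, 2)
    assert np.array_equal(got, geno)
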