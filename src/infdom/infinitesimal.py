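"""Closed-form infinitesimal-model predictions with dominance.

Given the ancestral variance components and exact identity coefficients from
the pedigree, these formulas predict — without simulating genotypes — the
moments of the trait and of its shared/residual family decomposition:

* shared family component ``A + D``: mean and variance from the parents'
  identity set, plus its covariance across families;
* residual component ``RA + RD``: variance, and its split into additive,
  dominance and cross parts;
* individual traits: mean, variance and pairwise covariance as functions of
  the identity coefficients, including the classical additive/dominance
  decomposition of the variance;
* parent-offspring covariances and the Gaussian conditional moments of the
  shared component given the parental trait values;
* a generic joint multivariate normal over any set of pedigree members, with
  standard conditioning.

Everything here is a pure function of ``(VarianceComponents, identity sets)``
— no pedigree access inside the formulas — except the convenience
constructor :func:`joint_trait_mvn` which gathers the identities itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ibd import (PairIdentitySet, ParentalIdentitySet, inbreeding,
                  pair_identities, parental_identity_set)
from .pedigree import Pedigree
from .trait_model import VarianceComponents

__all__ = ["SharedMoments", "ConditionalMoments", "TraitMoments", "MvnSpec",
           "shared_moments", "residual_variance", "cross_family_cov",
           "trait_moments", "trait_cov", "parent_offspring_shared_cov",
           "conditional_shared_moments", "family_residual_components",
           "joint_trait_mvn", "mvn_condition"]

_SYM_TOL = 1e-12
_EIG_TOL = -1e-10


@dataclass(frozen=True)
class SharedMoments:
    """Mean and variance of the shared family component A + D."""

    mean: float
    variance: float


@dataclass(frozen=True)
class ConditionalMoments:
    """Moments of A + D given the parental trait values.

    The conditional variance does not depend on the observed values; the
    parent-offspring covariances ``C1``/``C2`` are reported for inspection.
    """

    mean: float
    variance: float
    C1: float
    C2: float


@dataclass(frozen=True)
class TraitMoments:
    """Individual trait moments as functions of the inbreeding coefficient.

    ``script_A`` is the full additive part (A + RA), ``script_D`` the full
    dominance deviation (D + RD); Z = z_bar_0 + script_A + script_D.
    """

    E_Z: float
    var_Z: float
    E_script_A: float
    E_script_D: float
    var_script_A: float
    var_script_D: float
    cov_script_AD: float


@dataclass
class MvnSpec:
    """A labelled multivariate normal (mean, covariance, labels)."""

    mean: np.ndarray
    cov: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        n = len(self.labels)
        if self.mean.shape != (n,) or self.cov.shape != (n, n):
            raise ValueError("inconsistent MvnSpec shapes")
        if len(set(self.labels)) != n:
            raise ValueError("labels must be unique")
        if np.max(np.abs(self.cov - self.cov.T), initial=0.0) > _SYM_TOL:
            raise ValueError("covariance must be symmetric")
        if n and np.linalg.eigvalsh(self.cov).min() < _EIG_TOL:
            raise ValueError("covariance must be positive semi-definite")

    def __getitem__(self, label: str) -> tuple[float, float]:
        k = self.labels.index(label)
        return float(self.mean[k]), float(self.cov[k, k])


def shared_moments(vc: VarianceComponents,
                   pid: ParentalIdentitySet) -> SharedMoments:
    """Mean and variance of the within-family shared component A + D."""
    F11, F22, F12 = pid.F11, pid.F22, pid.F12
    mean = vc.iota * F12
    variance = (
        0.5 * vc.sigma_A2 * (1.0 + 0.5 * (F11 + F22) + 2.0 * F12)
        + vc.sigma_ADI * (F12 + 0.5 * (pid.F112 + pid.F122))
        + 0.25 * (vc.sigma_DI2 + vc.iota_star)
        * (F12 + pid.F112 + pid.F122 + pid.F1122)
        + 0.25 * vc.iota_star * pid.Ft_1212
        - vc.iota_star * F12 * F12
        + 0.25 * vc.sigma_D2 * ((1.0 - F12) + (F22 - pid.F122)
                                + (F11 - pid.F112) + pid.Ft_1122
                                + 0.5 * pid.Ft_1212))
    return SharedMoments(mean=mean, variance=variance)


def residual_variance(vc: VarianceComponents,
                      pid: ParentalIdentitySet) -> float:
    """Variance of the mean-zero residual component RA + RD."""
    F11, F22, F12 = pid.F11, pid.F22, pid.F12
    return (
        0.5 * vc.sigma_A2 * (1.0 - 0.5 * (F11 + F22))
        + 0.25 * (vc.sigma_DI2 + vc.iota_star)
        * (3.0 * F12 - pid.F1122 - pid.F112 - pid.F122)
        + 0.25 * vc.sigma_D2 * (3.0 * (1.0 - F12) - (F11 - pid.F112)
                                - (F22 - pid.F122) - pid.Ft_1122
                                - 0.5 * pid.Ft_1212)
        + vc.sigma_ADI * (F12 - 0.5 * (pid.F112 + pid.F122))
        - 0.25 * vc.iota_star * pid.Ft_1212)


def cross_family_cov(vc: VarianceComponents, pair: PairIdentitySet,
                     sigma_ADI_halved: bool = False) -> float:
    """Covariance of the shared components (A_i+D_i) and (A_j+D_j).

    The identity set is for the pair (i, j) itself, a = i and b = j.  The
    same expression gives the trait covariance Cov(Z_i, Z_j) (the residuals
    of distinct individuals are uncorrelated); see :func:`trait_cov`.
    ``sigma_ADI_halved`` switches the three-gene coefficient from the
    printed (F_iij + F_ijj) to its halved variant.
    """
    c_adi = 0.5 if sigma_ADI_halved else 1.0
    return (2.0 * pair.Fab * vc.sigma_A2
            + c_adi * (pair.Faab + pair.Fabb) * vc.sigma_ADI
            + pair.Ft_abab * vc.sigma_D2
            + pair.Faabb * (vc.sigma_DI2 + vc.iota_star)
            - vc.iota ** 2 * pair.Faa * pair.Fbb
            + vc.iota_star * pair.Ft_aabb)


def trait_cov(vc: VarianceComponents, pair: PairIdentitySet,
              sigma_ADI_halved: bool = False) -> float:
    """Cov(Z_i, Z_j) for distinct individuals — same form as Eq. 7."""
    return cross_family_cov(vc, pair, sigma_ADI_halved=sigma_ADI_halved)


def trait_moments(vc: VarianceComponents, F_ii: float) -> TraitMoments:
    """Individual trait moments from the inbreeding coefficient alone."""
    if not 0.0 <= F_ii <= 1.0:
        raise ValueError("F_ii must lie in [0, 1]")
    F = F_ii
    var_A = vc.sigma_A2 * (1.0 + F)
    var_D = (vc.sigma_D2 * (1.0 - F) + vc.sigma_DI2 * F
             + vc.iota_star * (F - F * F))
    cov_AD = vc.sigma_ADI * F
    return TraitMoments(
        E_Z=vc.z_bar_0 + vc.iota * F,
        var_Z=var_A + var_D + 2.0 * cov_AD,
        E_script_A=0.0,
        E_script_D=vc.iota * F,
        var_script_A=var_A,
        var_script_D=var_D,
        cov_script_AD=cov_AD)


def parent_offspring_shared_cov(vc: VarianceComponents,
                                pid: ParentalIdentitySet
                                ) -> tuple[float, float]:
    """(C(i, i[1]), C(i, i[2])): covariance of A_i + D_i with each parent's Z."""
    def one_side(Fpp, Fpo, Fppo):
        return (0.5 * vc.sigma_A2 * (1.0 + Fpp + 2.0 * Fpo)
                + 0.5 * vc.sigma_ADI * (Fpp + Fpo + 2.0 * Fppo)
                + vc.sigma_D2 * (Fpo - Fppo)
                + (vc.sigma_DI2 + vc.iota_star) * Fppo
                - vc.iota ** 2 * Fpp * Fpo)
    C1 = one_side(pid.F11, pid.F12, pid.F112)
    C2 = one_side(pid.F22, pid.F12, pid.F122)
    return C1, C2


def conditional_shared_moments(vc: VarianceComponents,
                               pid: ParentalIdentitySet,
                               z1: float, z2: float,
                               selfing: bool = False,
                               sigma_E2: float | None = None
                               ) -> ConditionalMoments:
    """Moments of A + D given the two parental trait values.

    The parents' joint distribution is bivariate normal with variances from
    their inbreeding coefficients (``pid.F11``, ``pid.F22``) and covariance
    from their pair identities; the shared component is conditioned on it by
    standard Gaussian regression.  ``sigma_E2`` (default: the model's value
    in ``vc``) is added to the parental variances when conditioning on noisy
    observed traits; pass 0.0 to condition on the genetic values.

    When the two parents are the same individual (``selfing=True``), ``z1``
    is the single parental trait and the univariate analogue is used; the
    bivariate matrix would be singular in that case.
    """
    if sigma_E2 is None:
        sigma_E2 = vc.sigma_E2
    sm = shared_moments(vc, pid)
    C1, C2 = parent_offspring_shared_cov(vc, pid)
    m1 = trait_moments(vc, pid.F11)
    if selfing:
        v1 = m1.var_Z + sigma_E2
        mean = sm.mean + C1 * (z1 - m1.E_Z) / v1
        variance = sm.variance - C1 * C1 / v1
        return ConditionalMoments(mean=mean, variance=variance, C1=C1, C2=C2)
    m2 = trait_moments(vc, pid.F22)
    pair = PairIdentitySet(Fab=pid.F12, Faa=pid.F11, Fbb=pid.F22,
                           Faab=pid.F112, Fabb=pid.F122, Faabb=pid.F1122,
                           Ft_abab=pid.Ft_1212, Ft_aabb=pid.Ft_1122)
    c12 = trait_cov(vc, pair)
    sigma = np.array([[m1.var_Z + sigma_E2, c12],
                      [c12, m2.var_Z + sigma_E2]])
    det = sigma[0, 0] * sigma[1, 1] - c12 * c12
    if det <= 1e-12 * max(sigma[0, 0] * sigma[1, 1], 1e-300):
        raise ValueError(
            "singular parental trait covariance; if the two parents are the "
            "same individual use selfing=True (univariate conditioning)")
    c = np.array([C1, C2])
    dz = np.array([z1 - m1.E_Z, z2 - m2.E_Z])
    w = np.linalg.solve(sigma, dz)
    mean = sm.mean + float(c @ w)
    variance = sm.variance - float(c @ np.linalg.solve(sigma, c))
    return ConditionalMoments(mean=mean, variance=variance, C1=C1, C2=C2)


def family_residual_components(vc: VarianceComponents,
                               pid: ParentalIdentitySet) -> dict[str, float]:
    """Split the residual variance into {VRA, VRD, VRA_RD}.

    ``VRA`` is the variance of RA, ``VRD`` of RD and ``VRA_RD`` their
    covariance; ``VRA + VRD + 2 VRA_RD = residual_variance`` exactly (VRD is
    defined as the remainder of the term-by-term split, which for bi-allelic
    components, where sigma_D2 equals iota_star, reduces to the classical
    closed form).
    """
    VRA = 0.5 * vc.sigma_A2 * (1.0 - pid.FW)
    VRA_RD = 0.5 * vc.sigma_ADI * (pid.F12 - pid.F3)
    VRD = residual_variance(vc, pid) - VRA - 2.0 * VRA_RD
    return {"VRA": VRA, "VRD": VRD, "VRA_RD": VRA_RD}


def joint_trait_mvn(ped: Pedigree, vc: VarianceComponents,
                    individuals: Sequence[str],
                    observed: bool = False) -> MvnSpec:
    """Joint Gaussian of the (asymptotic) trait values of pedigree members.

    ``observed=True`` adds ``vc.sigma_E2`` to every diagonal entry, giving
    the distribution of the noisy observed traits Z-tilde.
    """
    ids = list(individuals)
    n = len(ids)
    mean = np.empty(n)
    cov = np.empty((n, n))
    for a in range(n):
        F = inbreeding(ped, ids[a])
        tm = trait_moments(vc, F)
        mean[a] = tm.E_Z
        cov[a, a] = tm.var_Z + (vc.sigma_E2 if observed else 0.0)
        for b in range(a):
            c = trait_cov(vc, pair_identities(ped, ids[a], ids[b]))
            cov[a, b] = cov[b, a] = c
    return MvnSpec(mean=mean, cov=cov, labels=ids)


def mvn_condition(spec: MvnSpec,
                  observed: Mapping[str, float]) -> MvnSpec:
    """Condition a labelled Gaussian on observed coordinates.

    Returns the conditional law of the remaining coordinates; conditioning is
    idempotent and independent of the order in which values are supplied.
    """
    if not observed:
        return spec
    unknown_labels = [l for l in spec.labels if l not in observed]
    obs_labels = [l for l in spec.labels if l in observed]
    if len(obs_labels) != len(observed):
        missing = set(observed) - set(spec.labels)
        raise KeyError(f"observed labels not in spec: {sorted(missing)}")
    iu = [spec.labels.index(l) for l in unknown_labels]
    io = [spec.labels.index(l) for l in obs_labels]
    Soo = spec.cov[np.ix_(io, io)]
    try:
        sol = np.linalg.solve(Soo, np.eye(len(io)))
    except np.linalg.LinAlgError:
        raise ValueError("singular observed covariance block; add "
                         "environmental noise (sigma_E2 > 0) to regularize"
                         ) from None
    Suo = spec.cov[np.ix_(iu, io)]
    dz = np.array([observed[l] for l in obs_labels]) - spec.mean[io]
    mean = spec.mean[iu] + Suo @ sol @ dz
    cov = spec.cov[np.ix_(iu, iu)] - Suo @ sol @ Suo.T
    cov = 0.5 * (cov + cov.T)
    cov[np.abs(cov) < 1e-15] = 0.0
    return MvnSpec(mean=mean, cov=cov, labels=unknown_labels)
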