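"""Ancestral locus models: allele distributions, effect normalization and
variance components.

A trait is controlled by M unlinked loci.  Locus l has an allele distribution
``nu_l`` in the ancestral population, an additive-effect table ``eta_l`` and a
symmetric dominance table ``phi_l`` (both order one; the single 1/sqrt(M)
scale factor lives in trait assembly).  Effects are normalized so that

    E[eta(chi)] = 0,   E[phi(chi, x')] = 0 for every allele x',

which makes the additive and dominance parts orthogonal in the (random
mating, Hardy-Weinberg, linkage-equilibrium) base population.  The classical
variance components — additive and dominance variances, inbreeding depression
and its locus-wise spread, and the inbred additive-dominance covariance — are
exact sums over the allele distributions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

__all__ = ["LocusModel", "AncestralModel", "VarianceComponents",
           "normalize_effects", "variance_components",
           "make_biallelic_dominance_model", "sample_founder_genotypes",
           "trait_value", "trait_values", "write_vcf"]

_NORM_TOL = 1e-9


@dataclass
class LocusModel:
    """One locus: allele labels, ancestral frequencies and effect tables."""

    alleles: tuple[str, ...]
    nu: np.ndarray          # (k,) allele distribution
    eta: np.ndarray         # (k,) additive effects (normalized, order one)
    phi: np.ndarray         # (k, k) symmetric dominance deviations
    mu: float = 0.0         # mean of the raw genotype values under nu x nu

    def __post_init__(self) -> None:
        self.nu = np.asarray(self.nu, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        k = len(self.alleles)
        if self.nu.shape != (k,) or self.eta.shape != (k,) \
                or self.phi.shape != (k, k):
            raise ValueError("inconsistent table shapes")
        if np.any(self.nu < 0) or abs(self.nu.sum() - 1.0) > _NORM_TOL:
            raise ValueError("nu must be a probability vector")
        if not np.allclose(self.phi, self.phi.T, atol=_NORM_TOL):
            raise ValueError("phi must be symmetric")

    @property
    def k(self) -> int:
        return len(self.alleles)

    def is_normalized(self, tol: float = _NORM_TOL) -> bool:
        return (abs(float(self.nu @ self.eta)) <= tol
                and np.max(np.abs(self.nu @ self.phi)) <= tol)


@dataclass
class AncestralModel:
    """A collection of loci plus the global trait parameters.

    The genetic trait value is
    ``Z = z_bar_0 + M**-0.5 * sum_l (eta_l(g1) + eta_l(g2) + phi_l(g1, g2))``.
    ``sigma_E2`` is the environmental variance of the observed trait.
    """

    loci: list[LocusModel]
    z_bar_0: float = 0.0
    sigma_E2: float = 0.0

    @property
    def M(self) -> int:
        return len(self.loci)

    @property
    def B(self) -> float:
        """Uniform bound on the scaled effect tables."""
        return max(max(np.max(np.abs(l.eta)), np.max(np.abs(l.phi)))
                   for l in self.loci)

    @property
    def k_max(self) -> int:
        return max(l.k for l in self.loci)

    def is_normalized(self, tol: float = _NORM_TOL) -> bool:
        return all(l.is_normalized(tol) for l in self.loci)

    # dense padded tables used by the vectorized simulator -------------------

    def tables(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(nu, eta, phi) padded to (M, k_max) / (M, k_max, k_max)."""
        cached = getattr(self, "_tables", None)
        if cached is not None:
            return cached
        M, k = self.M, self.k_max
        nu = np.zeros((M, k))
        eta = np.zeros((M, k))
        phi = np.zeros((M, k, k))
        for l, loc in enumerate(self.loci):
            nu[l, :loc.k] = loc.nu
            eta[l, :loc.k] = loc.eta
            phi[l, :loc.k, :loc.k] = loc.phi
        self._tables = (nu, eta, phi)
        return self._tables

    # JSON round trip --------------------------------------------------------

    def to_json(self, path) -> None:
        doc = {"z_bar_0": self.z_bar_0, "sigma_E2": self.sigma_E2,
               "M": self.M, "B": self.B,
               "loci": [{"alleles": list(l.alleles), "nu": l.nu.tolist(),
                         "eta": l.eta.tolist(), "phi": l.phi.tolist(),
                         "mu": l.mu} for l in self.loci]}
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "AncestralModel":
        with open(path) as fh:
            doc = json.load(fh)
        loci = [LocusModel(alleles=tuple(d["alleles"]), nu=d["nu"],
                           eta=d["eta"], phi=d["phi"], mu=d.get("mu", 0.0))
                for d in doc["loci"]]
        return cls(loci=loci, z_bar_0=doc["z_bar_0"],
                   sigma_E2=doc.get("sigma_E2", 0.0))


@dataclass(frozen=True)
class VarianceComponents:
    """Classical components of the ancestral population.

    ``sigma_A2``: additive variance; ``sigma_D2``: dominance variance;
    ``iota``: inbreeding depression (coefficient of F_ii in the trait mean);
    ``iota_star``: mean squared locus-specific inbreeding depression;
    ``sigma_DI2``: variance of dominance effects in fully inbred individuals;
    ``sigma_ADI``: covariance of additive and dominance effects in inbred
    individuals.
    """

    sigma_A2: float
    sigma_D2: float
    iota: float
    iota_star: float
    sigma_DI2: float
    sigma_ADI: float
    z_bar_0: float = 0.0
    sigma_E2: float = 0.0

    def purely_additive(self) -> bool:
        return (self.sigma_D2 == 0 and self.iota == 0 and self.iota_star == 0
                and self.sigma_DI2 == 0 and self.sigma_ADI == 0)


def normalize_effects(raw: np.ndarray, nu: np.ndarray
                      ) -> tuple[float, np.ndarray, np.ndarray]:
    """Split a symmetric genotype-value table into mean + additive + dominance.

    ``mu = E[g]``, ``eta(x) = E[g(x, chi)] - mu`` and
    ``phi(x, x') = g(x, x') - mu - eta(x) - eta(x')`` with expectations under
    ``nu``; the reconstruction ``g = mu + eta + eta' + phi`` is an identity
    and the returned tables satisfy the normalization constraints exactly.
    """
    raw = np.asarray(raw, dtype=float)
    nu = np.asarray(nu, dtype=float)
    if raw.ndim != 2 or raw.shape[0] != raw.shape[1]:
        raise ValueError("raw genotype table must be square")
    if not np.allclose(raw, raw.T, atol=_NORM_TOL):
        raise ValueError("raw genotype table must be symmetric")
    if np.any(nu < 0) or abs(nu.sum() - 1.0) > _NORM_TOL:
        raise ValueError("nu must be a probability vector")
    mu = float(nu @ raw @ nu)
    eta = raw @ nu - mu
    phi = raw - mu - eta[:, None] - eta[None, :]
    return mu, eta, phi


def variance_components(model: AncestralModel) -> VarianceComponents:
    """Exact Table-style variance components of a normalized ancestral model."""
    if not model.is_normalized():
        raise ValueError("model effects are not normalized; apply "
                         "normalize_effects per locus first")
    M = model.M
    e_eta2 = e_phi2 = e_d = e_d2 = e_eta_d = 0.0
    for loc in model.loci:
        d = np.diag(loc.phi)
        e_eta2 += float(loc.nu @ loc.eta ** 2)
        e_phi2 += float(loc.nu @ (loc.phi ** 2) @ loc.nu)
        ed = float(loc.nu @ d)
        e_d += ed
        e_d2 += ed * ed
        e_eta_d += float(loc.nu @ (loc.eta * d))
    e_dd2 = sum(float(l.nu @ np.diag(l.phi) ** 2) for l in model.loci)
    return VarianceComponents(
        sigma_A2=2.0 * e_eta2 / M,
        sigma_D2=e_phi2 / M,
        iota=e_d / np.sqrt(M),
        iota_star=e_d2 / M,
        sigma_DI2=(e_dd2 - e_d2) / M,
        sigma_ADI=2.0 * e_eta_d / M,
        z_bar_0=model.z_bar_0,
        sigma_E2=model.sigma_E2)


def _sample_frequencies(M: int, rng: np.random.Generator, dialect: str,
                        two_N_ref: int, eps: float) -> np.ndarray:
    """Near-neutral allele frequencies conditioned to segregate.

    ``sample_counts``: frequencies on the grid i/2N, i = 1..2N-1, with weights
    proportional to (i(2N-i))**(eps-1) — allele counts in a reference sample
    of 2N genes under the neutral low-mutation spectrum.
    ``continuous``: density proportional to (p(1-p))**(eps-1) on
    (1/2N, 1-1/2N); sampled uniformly on the logit scale with a rejection
    correction (the target is within a factor (1/4)**eps of logit-uniform).
    """
    lo, hi = 1.0 / two_N_ref, 1.0 - 1.0 / two_N_ref
    if dialect == "sample_counts":
        i = np.arange(1, two_N_ref)
        w = (i * (two_N_ref - i)).astype(float) ** (eps - 1.0)
        w /= w.sum()
        return rng.choice(i, size=M, p=w) / float(two_N_ref)
    if dialect == "continuous":
        out = np.empty(0)
        a, b = logit(lo), logit(hi)
        while out.size < M:
            n_draw = max(2 * (M - out.size), 64)
            p = expit(rng.uniform(a, b, size=n_draw))
            accept = rng.random(n_draw) < (p * (1 - p)) ** eps / 0.25 ** eps
            out = np.concatenate([out, p[accept]])
        return out[:M]
    raise ValueError(f"unknown frequency dialect {dialect!r}")


def make_biallelic_dominance_model(M: int, seed: int = 0, c_H: float = 1.0,
                                   freq_dialect: str = "sample_counts",
                                   two_N_ref: int = 60, eps: float = 0.001,
                                   sigma_E2: float = 0.0) -> AncestralModel:
    """Base population of M bi-allelic loci with complete dominance.

    Each locus has scaled genotype values -1:-1:+1 (the "+" allele recessive)
    or -1:+1:+1 (the "+" allele dominant); the dominant-plus direction is
    drawn with probability H = 1/2 + c_H/sqrt(M), which balances the per-locus
    inbreeding depressions so that their scaled sum iota stays bounded as M
    grows.  Allele frequencies come from the near-neutral segregating spectrum
    (see :func:`_sample_frequencies`).  Effects are normalized per locus; the
    ancestral mean is reported as 0 (components are deviations from it).
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    rng = np.random.default_rng(seed)
    p = _sample_frequencies(M, rng, freq_dialect, two_N_ref, eps)
    H = 0.5 + c_H / np.sqrt(M)
    dominant_plus = rng.random(M) < H
    loci = []
    for l in range(M):
        nu = np.array([1.0 - p[l], p[l]])     # index 0 = "a", 1 = "A" (plus)
        if dominant_plus[l]:
            raw = np.array([[-1.0, 1.0], [1.0, 1.0]])
        else:
            raw = np.array([[-1.0, -1.0], [-1.0, 1.0]])
        mu, eta, phi = normalize_effects(raw, nu)
        loci.append(LocusModel(alleles=("a", "A"), nu=nu, eta=eta, phi=phi,
                               mu=mu))
    return AncestralModel(loci=loci, z_bar_0=0.0, sigma_E2=sigma_E2)


def sample_founder_genotypes(model: AncestralModel, n_founders: int,
                             seed: int = 0,
                             rng: np.random.Generator | None = None
                             ) -> np.ndarray:
    """(n, M, 2) allele indices; every gene copy an independent draw from nu.

    Hardy-Weinberg and linkage equilibrium hold by construction.  ``rng``
    takes precedence over ``seed`` when given.
    """
    if n_founders < 1:
        raise ValueError("n_founders must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    nu, _, _ = model.tables()
    cum = np.cumsum(nu, axis=1)                      # (M, k)
    u = rng.random((n_founders, model.M, 2))
    geno = (u[..., None] >= cum[None, :, None, :]).sum(axis=-1)
    return geno.astype(np.int8)


def trait_values(model: AncestralModel, genotypes: np.ndarray) -> np.ndarray:
    """Genetic trait values Z for an (n, M, 2) genotype array."""
    genotypes = np.asarray(genotypes)
    if genotypes.ndim == 2:
        genotypes = genotypes[None]
    n, M, _ = genotypes.shape
    if M != model.M:
        raise ValueError("genotype/model locus-count mismatch")
    _, eta, phi = model.tables()
    if genotypes.max(initial=0) >= model.k_max or genotypes.min(initial=0) < 0:
        raise IndexError("allele index out of range")
    li = np.arange(M)
    g1, g2 = genotypes[..., 0], genotypes[..., 1]
    per_locus = eta[li, g1] + eta[li, g2] + phi[li, g1, g2]
    return model.z_bar_0 + per_locus.sum(axis=1) / np.sqrt(M)


def trait_value(model: AncestralModel, genotype_row: np.ndarray) -> float:
    """Genetic trait value of a single (M, 2) genotype."""
    return float(trait_values(model, np.asarray(genotype_row)[None])[0])


def write_vcf(genotypes: np.ndarray, model: AncestralModel, path,
              sample_ids: Sequence[str] | None = None,
              contig: str = "synth1") -> None:
    """Export bi-allelic genotypes as a phased VCF (one sample per individual).

    Loci are placed as sites on a synthetic contig; they are unlinked in the
    model regardless of coordinate.  Allele index 0 maps to REF, 1 to ALT.
    """
    import pysam

    genotypes = np.asarray(genotypes)
    n, M, _ = genotypes.shape
    if any(l.k != 2 for l in model.loci):
        raise ValueError("VCF export supports bi-allelic loci only")
    if sample_ids is None:
        sample_ids = [f"ind{i}" for i in range(n)]
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={1000 * (M + 1)}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in sample_ids:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for l in range(M):
            rec = vf.new_record(contig=contig, start=1000 * (l + 1),
                                alleles=("A", "T"), id=f"L{l}")
            for i, s in enumerate(sample_ids):
                rec.samples[s]["GT"] = (int(genotypes[i, l, 0]),
                                        int(genotypes[i, l, 1]))
                rec.samples[s].phased = True
            vf.write(rec)
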