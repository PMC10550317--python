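"""Gene-dropping simulation of trait values down a pedigree.

Genotypes descend by Mendelian inheritance: gene copy 1 of individual i is a
fair-coin pick between the two genes of parent i[1] (indicator X), copy 2
between the genes of parent i[2] (indicator Y).  The genetic value of every
non-founder splits exactly into

    Z = z_bar_0 + A + D + RA + RD,

where A and D (the *shared* component) average the additive and dominance
effects over the four parental genes and are common to all full sibs, while
RA and RD (the *residual* component, mean zero) collect the centered
Mendelian-sampling terms.  Founders carry their whole genetic deviation in
RA + RD (their A and D are defined as zero), so the identity above holds
uniformly.  The observed trait adds environmental noise: Z_tilde = Z + E.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Pedigree
from .trait_model import AncestralModel, sample_founder_genotypes, trait_values

__all__ = ["TraitDecomposition", "simulate_pedigree_traits",
           "within_family_sample", "truncation_selection_sim",
           "genic_vs_total_variance", "empirical_moments"]


@dataclass
class TraitDecomposition:
    """Per-individual trait components (all arrays of equal length)."""

    ids: list[str]
    generation: np.ndarray
    A: np.ndarray
    D: np.ndarray
    RA: np.ndarray
    RD: np.ndarray
    E: np.ndarray
    z_bar_0: float = 0.0

    @property
    def Z(self) -> np.ndarray:
        return self.z_bar_0 + self.A + self.D + self.RA + self.RD

    @property
    def Z_tilde(self) -> np.ndarray:
        return self.Z + self.E

    @property
    def A_part(self) -> np.ndarray:
        """The classical additive component: A + RA."""
        return self.A + self.RA

    @property
    def D_part(self) -> np.ndarray:
        """The classical dominance deviation: D + RD."""
        return self.D + self.RD

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "generation": self.generation,
                             "A": self.A, "D": self.D, "RA": self.RA,
                             "RD": self.RD, "E": self.E, "Z": self.Z,
                             "Z_tilde": self.Z_tilde})


def _lookup_tables(model: AncestralModel):
    _, eta, phi = model.tables()
    li = np.arange(model.M)
    return eta, phi, li


def _family_components(model, g11, g12, g21, g22):
    """Shared A, D from the four parental gene arrays (each (n, M))."""
    eta, phi, li = _lookup_tables(model)
    rootM = np.sqrt(model.M)
    A = (eta[li, g11] + eta[li, g12] + eta[li, g21] + eta[li, g22]
         ).sum(axis=-1) / (2.0 * rootM)
    D = (phi[li, g11, g21] + phi[li, g11, g22] + phi[li, g12, g21]
         + phi[li, g12, g22]).sum(axis=-1) / (4.0 * rootM)
    return A, D


def _residual_components(model, g11, g12, g21, g22, X, Y):
    """RA, RD from the centered inheritance indicators (X, Y gene-1 picks)."""
    eta, phi, li = _lookup_tables(model)
    rootM = np.sqrt(model.M)
    Xc, Yc = X - 0.5, Y - 0.5
    RA = (Xc * (eta[li, g11] - eta[li, g12])
          + Yc * (eta[li, g21] - eta[li, g22])).sum(axis=-1) / rootM
    RD = ((X * Y - 0.25) * phi[li, g11, g21]
          + (X * (1 - Y) - 0.25) * phi[li, g11, g22]
          + ((1 - X) * Y - 0.25) * phi[li, g12, g21]
          + ((1 - X) * (1 - Y) - 0.25) * phi[li, g12, g22]
          ).sum(axis=-1) / rootM
    return RA, RD


def truncation_selection_sim(ped: Pedigree, model: AncestralModel,
                             n_candidates: int = 2, seed: int = 0,
                             select_on: str = "Z",
                             noise: str = "independent"
                             ) -> tuple[np.ndarray, tuple, TraitDecomposition]:
    """Within-family truncation selection down a fixed pedigree.

    Pedigree relatedness is retained; working down the pedigree, each
    individual's genotype is the trait-maximal of ``n_candidates`` independent
    Mendelian draws from its (already realized) parents.  ``n_candidates=1``
    reproduces the neutral gene drop exactly (same random streams).

    ``select_on``: "Z" ranks candidates on the genetic value (the default;
    the environmental component is disregarded during selection) or "Z_tilde"
    (noise drawn per candidate).  ``noise``: "independent" per individual, or
    "family" (shared by all individuals with the same ordered parent pair in
    a generation).

    Returns (genotypes, (X, Y) inheritance indicators, decomposition).
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    if select_on not in ("Z", "Z_tilde"):
        raise ValueError("select_on must be 'Z' or 'Z_tilde'")
    if noise not in ("independent", "family"):
        raise ValueError("noise must be 'independent' or 'family'")
    ss = np.random.SeedSequence(seed)
    founder_rng, inherit_rng, noise_rng = map(np.random.default_rng, ss.spawn(3))

    n, M = len(ped), model.M
    gens = ped.generations()
    parents = ped.parent_indices()
    sigma_E = np.sqrt(model.sigma_E2)

    geno = np.zeros((n, M, 2), dtype=np.int8)
    Xind = np.zeros((n, M), dtype=np.int8)
    Yind = np.zeros((n, M), dtype=np.int8)
    A = np.zeros(n)
    D = np.zeros(n)
    RA = np.zeros(n)
    RD = np.zeros(n)
    E = np.zeros(n)

    founder_idx = np.flatnonzero(parents[:, 0] < 0)
    geno[founder_idx] = sample_founder_genotypes(model, len(founder_idx),
                                                 rng=founder_rng)
    zf = trait_values(model, geno[founder_idx]) - model.z_bar_0
    eta, phi, li = _lookup_tables(model)
    rootM = np.sqrt(M)
    g1, g2 = geno[founder_idx, :, 0], geno[founder_idx, :, 1]
    RA[founder_idx] = (eta[li, g1] + eta[li, g2]).sum(axis=-1) / rootM
    RD[founder_idx] = (phi[li, g1, g2]).sum(axis=-1) / rootM

    def draw_noise(members):
        if sigma_E == 0:
            return np.zeros(len(members))
        if noise == "independent":
            return noise_rng.normal(0.0, sigma_E, size=len(members))
        pairs = [tuple(parents[k]) for k in members]
        uniq = sorted(set(pairs))
        per_pair = dict(zip(uniq, noise_rng.normal(0.0, sigma_E, len(uniq))))
        return np.array([per_pair[p] for p in pairs])

    E[founder_idx] = draw_noise(founder_idx)

    for t in range(1, int(gens.max()) + 1):
        members = np.flatnonzero(gens == t)
        m = len(members)
        p1, p2 = parents[members, 0], parents[members, 1]
        g11, g12 = geno[p1, :, 0], geno[p1, :, 1]
        g21, g22 = geno[p2, :, 0], geno[p2, :, 1]
        At, Dt = _family_components(model, g11, g12, g21, g22)

        X = inherit_rng.integers(0, 2, size=(n_candidates, m, M), dtype=np.int8)
        Y = inherit_rng.integers(0, 2, size=(n_candidates, m, M), dtype=np.int8)
        RAc, RDc = _residual_components(model, g11[None], g12[None],
                                        g21[None], g22[None], X, Y)
        score = At[None] + Dt[None] + RAc + RDc
        if select_on == "Z_tilde":
            Ec = (noise_rng.normal(0.0, sigma_E, size=(n_candidates, m))
                  if sigma_E else np.zeros((n_candidates, m)))
            best = np.argmax(score + Ec, axis=0)
            Et = Ec[best, np.arange(m)]
        else:
            best = np.argmax(score, axis=0)
            Et = draw_noise(members)
        bm = (best, np.arange(m))
        Xb, Yb = X[bm], Y[bm]
        geno[members, :, 0] = np.where(Xb == 1, g11, g12)
        geno[members, :, 1] = np.where(Yb == 1, g21, g22)
        Xind[members], Yind[members] = Xb, Yb
        A[members], D[members] = At, Dt
        RA[members], RD[members] = RAc[bm], RDc[bm]
        E[members] = Et

    decomp = TraitDecomposition(ids=[i.id for i in ped.individuals],
                                generation=gens, A=A, D=D, RA=RA, RD=RD, E=E,
                                z_bar_0=model.z_bar_0)
    return geno, (Xind, Yind), decomp


def simulate_pedigree_traits(ped: Pedigree, model: AncestralModel,
                             seed: int = 0, noise: str = "independent"
                             ) -> tuple[np.ndarray, tuple, TraitDecomposition]:
    """Neutral gene drop: Mendelian inheritance with no selection.

    Equivalent to :func:`truncation_selection_sim` with a single candidate.
    """
    return truncation_selection_sim(ped, model, n_candidates=1, seed=seed,
                                    noise=noise)


def within_family_sample(model: AncestralModel, parent1_genotype: np.ndarray,
                         parent2_genotype: np.ndarray, n_offspring: int,
                         seed: int = 0
                         ) -> tuple[TraitDecomposition, np.ndarray]:
    """Independent Mendelian offspring of one fixed parent pair.

    A and D are constant across the family; RA and RD are independent across
    offspring.  Selfing is expressed by passing the same genotype twice.
    """
    rng = np.random.default_rng(seed)
    M = model.M
    p1 = np.asarray(parent1_genotype)
    p2 = np.asarray(parent2_genotype)
    g11, g12 = p1[None, :, 0], p1[None, :, 1]
    g21, g22 = p2[None, :, 0], p2[None, :, 1]
    A, D = _family_components(model, g11, g12, g21, g22)
    X = rng.integers(0, 2, size=(n_offspring, M), dtype=np.int8)
    Y = rng.integers(0, 2, size=(n_offspring, M), dtype=np.int8)
    RA, RD = _residual_components(model, g11, g12, g21, g22, X, Y)
    geno = np.empty((n_offspring, M, 2), dtype=np.int8)
    geno[:, :, 0] = np.where(X == 1, g11, g12)
    geno[:, :, 1] = np.where(Y == 1, g21, g22)
    decomp = TraitDecomposition(
        ids=[f"off{i}" for i in range(n_offspring)],
        generation=np.ones(n_offspring, dtype=np.int64),
        A=np.full(n_offspring, A[0]), D=np.full(n_offspring, D[0]),
        RA=RA, RD=RD, E=np.zeros(n_offspring), z_bar_0=model.z_bar_0)
    return decomp, geno


def genic_vs_total_variance(model: AncestralModel, genotypes: np.ndarray,
                            grouping: np.ndarray) -> pd.DataFrame:
    """Total vs genic additive/dominance variance components per group.

    The per-individual additive contribution of locus l is
    ``(eta(g1) + eta(g2)) / sqrt(M)`` and the dominance contribution
    ``phi(g1, g2) / sqrt(M)``.  *Total* components are population variances
    (and covariance) of the summed contributions; *genic* components sum the
    per-locus variances, dropping the cross-locus (linkage-disequilibrium)
    terms.  Variances are population (ddof=0) moments within each group.
    """
    genotypes = np.asarray(genotypes)
    grouping = np.asarray(grouping)
    eta, phi, li = _lookup_tables(model)
    rootM = np.sqrt(model.M)
    a = (eta[li, genotypes[:, :, 0]] + eta[li, genotypes[:, :, 1]]) / rootM
    d = phi[li, genotypes[:, :, 0], genotypes[:, :, 1]] / rootM
    rows = []
    for grp in pd.unique(grouping):
        sel = grouping == grp
        if not sel.any():
            raise ValueError(f"empty group {grp!r}")
        ag, dg = a[sel], d[sel]
        asum, dsum = ag.sum(axis=1), dg.sum(axis=1)
        cov_tot = float(np.mean(asum * dsum) - asum.mean() * dsum.mean())
        cov_gen = float((np.mean(ag * dg, axis=0)
                         - ag.mean(axis=0) * dg.mean(axis=0)).sum())
        rows.append({
            "group": grp,
            "VA_total": float(asum.var()),
            "VD_total": float(dsum.var()),
            "cov_AD_total": cov_tot,
            "VG_total": float((asum + dsum).var()),
            "VA_genic": float(ag.var(axis=0).sum()),
            "VD_genic": float(dg.var(axis=0).sum()),
            "cov_AD_genic": cov_gen,
            "VG_genic": float((ag + dg).var(axis=0).sum()),
        })
    return pd.DataFrame(rows).set_index("group")


def empirical_moments(decomp: TraitDecomposition,
                      grouping: np.ndarray) -> pd.DataFrame:
    """Group means/variances/covariance of the classical components.

    The additive part is A + RA, the dominance deviation D + RD and
    G their sum; population (ddof=0) moments within each group.
    """
    grouping = np.asarray(grouping)
    Ap, Dp = decomp.A_part, decomp.D_part
    rows = []
    for grp in pd.unique(grouping):
        sel = grouping == grp
        a, d = Ap[sel], Dp[sel]
        rows.append({
            "group": grp, "n": int(sel.sum()),
            "mean_A": float(a.mean()), "mean_D": float(d.mean()),
            "mean_G": float((a + d).mean()),
            "var_A": float(a.var()), "var_D": float(d.var()),
            "cov_AD": float(np.mean(a * d) - a.mean() * d.mean()),
            "var_G": float((a + d).var()),
        })
    return pd.DataFrame(rows).set_index("group")
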