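"""Family-level predictions: shared/residual components and conditioning.

For a chosen family the closed forms predict the mean and variance of the
shared component (A + D), the split of the Mendelian-sampling variance into
(VRA, VRD, VRA_RD), and the Gaussian update of the shared component after
observing the parental traits.  A 100,000-offspring simulation checks them.
"""

import numpy as np

from infdom import (ExperimentConfig, conditional_shared_moments,
                    family_experiment, family_residual_components,
                    joint_trait_mvn, make_biallelic_dominance_model,
                    make_random_pedigree, mvn_condition,
                    parental_identity_set, residual_variance, shared_moments,
                    simulate_pedigree_traits, variance_components,
                    within_family_sample)

model = make_biallelic_dominance_model(M=1000, seed=1)
vc = variance_components(model)

ped = make_random_pedigree(8, 4, seed=3)
kid = ped.generation_members(4)[0]
pid = parental_identity_set(ped, kid.id)
sm = shared_moments(vc, pid)
fr = family_residual_components(vc, pid)
print(f"family of {kid.id} (parents {kid.parent1}, {kid.parent2}):")
print(f"  F11={pid.F11:.4f} F22={pid.F22:.4f} F12={pid.F12:.4f}")
print(f"  shared (A+D): mean = {sm.mean:+.4f}, variance = {sm.variance:.4f}")
print(f"  residual variance = {residual_variance(vc, pid):.4f} "
      f"(VRA={fr['VRA']:.4f}, VRD={fr['VRD']:.4f}, VRA_RD={fr['VRA_RD']:+.4f})")

# simulate a huge family from one realization of the parents
geno, _, dec = simulate_pedigree_traits(ped, model, seed=11)
i1, i2 = ped.index(kid.parent1), ped.index(kid.parent2)
fam, _ = within_family_sample(model, geno[i1], geno[i2], 100_000, seed=12)
print(f"  simulated 1e5 offspring: Var(RA) = {fam.RA.var():.4f}, "
      f"Var(RD) = {fam.RD.var():.4f}, Cov = {np.cov(fam.RA, fam.RD)[0,1]:+.4f}")

# condition the shared component on the observed parental traits
z1, z2 = dec.Z[i1], dec.Z[i2]
cm = conditional_shared_moments(vc, pid, z1, z2)
print(f"\nobserved parental traits z1 = {z1:+.3f}, z2 = {z2:+.3f}")
print(f"  E[A+D | z1, z2] = {cm.mean:+.4f} (this family's realized value "
      f"{fam.A[0] + fam.D[0]:+.4f}, conditional sd {np.sqrt(cm.variance):.3f})")
print(f"  Var(A+D | z1, z2) = {cm.variance:.4f} "
      "(independent of the observed values)")

# the same conditioning through the generic multivariate-normal interface
ids = [kid.parent1, kid.parent2]
spec = joint_trait_mvn(ped, vc, ids + [ped.generation_members(4)[1].id])
cond = mvn_condition(spec, {ids[0]: z1, ids[1]: z2})
print(f"\nMVN route, another gen-4 individual given the same observations: "
      f"mean = {cond.mean[0]:+.4f}, sd = {np.sqrt(cond.cov[0,0]):.4f}")

# many families at once (a small version of the residual-component scatter)
fam_table = family_experiment(ExperimentConfig(
    n_per_generation=30, M=500, n_replicates=2, n_families=12,
    n_offspring=400, seed=9))
print("\nper-family residual components (12 random founder pairs):")
print(fam_table[["selfed", "VRA_emp", "VRA_pred", "VRD_emp", "VRD_pred"]]
      .round(4).to_string())
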