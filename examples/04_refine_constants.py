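"""Recover stability constants from synthetic titration data.

Generates a seeded six-replicate study of the binary Cu/Tyr system
(250 points per curve, Gaussian pH noise sigma = 0.005), then refines all
four copper-complex log beta values starting 0.3 log units off.
"""

import cuspec

FREE = ("CuH2(Tyr)", "CuH(Tyr)", "CuH2(Tyr)2", "CuH(Tyr)2")

study = cuspec.generate_study("Cu_Tyr", 6, cuspec.NoiseModel(0.005, seed=1))
truth = {n: study.truth.species_by_name(n).log_beta for n in FREE}

spec = cuspec.RefinementSpec(study.truth, FREE, study.curves)
result = cuspec.refine(spec, {n: v + 0.3 for n, v in truth.items()})

print(f"{'species':<12} {'truth':>7} {'refined':>9} {'sigma':>7}")
for name in FREE:
    print(f"{name:<12} {truth[name]:>7.2f} "
          f"{result.log_beta_hat[name]:>9.3f} {result.sigma[name]:>7.4f}")
print(f"Sigma = {result.Sigma_stat:.4f} over "
      f"{sum(len(c) for c in study.curves)} points")

# With 1500 well-behaved points the constants come back within a few
# thousandths of a log unit and the reported sigmas are of the same order
# as the true estimation error.
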