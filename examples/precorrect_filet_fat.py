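"""Pre-correct filet fat for body weight and compare genetic correlations.

Fat measured at a common age correlates with growth because bigger fish are
fatter; preFF = FF - b1*BW removes the within-year-class weight regression.
The script prints the fitted slopes, verifies the exact orthogonality of the
corrected trait with body weight, and refits bivariate animal models to show
the genetic correlation with growth moving from positive toward the negative
value seen when fat is recorded at a common body weight.
"""

import numpy as np

import censherit as ch

design = ch.SimulationDesign(
    n_sires=60, n_dams=120, offspring_per_family_sa=10,
    offspring_per_family_sw=2, missing_rate=0.0, seed=13,
)
pop = ch.simulate_population(design)
pheno, fits = ch.precorrect_table(pop.phenotypes)

for yc, fit in fits.items():
    print(f"{yc}: FF = {fit.beta0:.2f} + {fit.beta1:.2f} * BW  (n = {fit.n})")

sa = pheno[(pheno["group"] == "SA") & pheno["preFF"].notna()]
for yc, grp in sa.groupby("year_class"):
    x = grp["body_weight_kg"]
    cov = np.mean((grp["preFF"] - grp["preFF"].mean()) * (x - x.mean()))
    print(f"{yc}: sample cov(preFF, BW) = {cov:.2e} (exactly zero by construction)")

cfg = ch.ChainConfig(n_iterations=4000, burn_in_iterations=1500, thinning_interval=3, seed=3)
table = ch.compare_correlations(
    pop.pedigree, pheno, None,
    pairs=[("FF_SA", "GR_SA"), ("preFF_SA", "GR_SA")],
    config=cfg,
)
print("\n", table.round(2).to_string())
print("\nThe corrected trait's genetic correlation with growth drops well "
      "below the uncorrected one, mirroring the switch in sign seen between "
      "same-age and same-weight recording.")
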