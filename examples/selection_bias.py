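"""Selection-bias correction of per-event growth-rate means.

Because only the largest fish are harvested at each threshold event, the
naive mean growth rate of the recorded fish overstates the mean of all fish
alive in the tank.  The censored model imputes phantom growth phenotypes for
the unharvested fish; averaging observed and imputed values recovers the
all-fish mean.  This script prints naive vs model-estimated vs true means.
"""

import censherit as ch

design = ch.SimulationDesign(
    n_sires=50, n_dams=100,
    offspring_per_family_sa=4, offspring_per_family_sw=14,
    seed=11,
)
pop = ch.simulate_population(design)
model = ch.CensoredGibbsModel(pop.pedigree, pop.phenotypes, pop.growth)
chain = model.run_chain(
    ch.ChainConfig(n_iterations=1500, burn_in_iterations=500, thinning_interval=2, seed=2)
)
em = ch.estimate_event_means(chain, pop.growth)
truth = pop.truth.copy()
truth["sampling_group"] = truth["year_class"] + ":ev" + truth["event_index"].astype(str)
m = em.merge(truth, on="sampling_group")

print("sampling_group  observed  estimated  true-all-fish  (g/day)")
for r in m.itertuples(index=False):
    print(f"{r.sampling_group:14s}  {r.observed_mean:7.2f}  {r.estimated_mean:8.2f}  "
          f"{r.true_mean_gr:12.2f}")
print("\nThe observed means exceed the truth at threshold events (selection), "
      "while the model's estimates track the all-fish means.")
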