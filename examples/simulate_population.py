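"""Generate a synthetic salmon population under sequential threshold slaughter.

Builds a nested-mating-design population (each dam mated to one sire, each
sire to at most two dams), splits every family between a same-age (SA) and a
same-weight (SW) group, runs the six-event slaughter protocol and prints the
per-event accounting plus the records-per-fish histogram.
"""

import censherit as ch

design = ch.SimulationDesign(
    n_sires=30, n_dams=60,
    offspring_per_family_sa=8, offspring_per_family_sw=12,
    seed=2021,
)
pop = ch.simulate_population(design)

print(f"{len(pop.pedigree)} animals in the pedigree "
      f"({design.n_sires} sires, {design.n_dams} dams, {len(pop.animals)} offspring)")
print(f"{len(pop.phenotypes)} phenotype rows, {len(pop.growth)} growth rows\n")

print("status counts:", pop.growth["status"].value_counts().to_dict(), "\n")

obs = pop.growth[pop.growth["status"].str.startswith("observed")]
per_event = obs.groupby("sampling_group").agg(
    n=("animal", "size"), mean_gr=("growth_rate", "mean")
).round(2)
print("observed fish and mean growth rate (g/day) per sampling group:")
print(per_event.to_string(), "\n")

hist = ch.count_records(pop.growth)
print("records per fish (observed + phantom-eligible censored):")
print(hist["observed_and_censored"])
print("\nEach fish has 2-10 rows: one initial weighing plus one row per "
      "slaughter event until it is harvested; the declining observed means "
      "show that the fastest growers leave the tank first.")
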