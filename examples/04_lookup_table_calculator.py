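"""Build a calculator lookup table and use it like the online tool.

Precomputes predictive mean/SD over a dense (age, education, gender,
language) grid, then scores raw values by nearest-node lookup — the
same mechanism the hosted normative calculator uses, run locally."""

import hdnorms as hn

config = hn.GeneratorConfig.table1_default()
truth = hn.default_truth(config)
cohort = hn.sample_scores(hn.sample_demographics(config, 3000, seed=30), truth, seed=31)
fit = hn.fit_model(hn.ModelSpec("sdmt", "gam"), cohort, hn.McmcConfig(seed=32))

table = hn.build_lookup({"sdmt": fit})
print(f"lookup table: {len(table.cells):,} cells "
      f"({len(table.grid.age_grid())} ages x {len(table.grid.edu_grid())} education "
      f"levels x 2 genders x {len(table.grid.languages)} languages)")

for raw in (35, 50, 60, 75):
    s = hn.lookup_z(table, "sdmt", age=48, edu=14, sex="f", lang="en", raw=raw)
    print(f"SDMT raw {raw:3d}: z = {s.z:+.2f}, percentile {s.percentile:5.1f}, {s.band}")
print()
print("z is the distance from the demographically expected score in units of")
print("the posterior-predictive SD; the band colors mirror the calculator's")
print("traffic-light reading (within +/-1 SD = normal).")

direct = hn.compute_z(fit, 48.2, 14.3, "f", "en", 50.0)
via_table = hn.lookup_z(table, "sdmt", 48.2, 14.3, "f", "en", 50.0)
print(f"\noff-node agreement: direct z = {direct.z:+.3f}, table z = {via_table.z:+.3f}")
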