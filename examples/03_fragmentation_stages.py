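"""Derive fragmentation-stage masks from simulated dated peptides and
watch phylogenetic signal degrade.

Dated peptide sets are simulated with age-dependent site survival,
mapped back onto the alignment to build a coverage profile, and reduced
to the four canonical stages ("100 ka" ... "10 Ma"). A tree is inferred
from each reduced alignment and compared to the generating tree.
"""

from enamelphylo.pipeline import ExperimentConfig, build_scenario, run_fragmentation_experiment

config = ExperimentConfig(seeds=(0, 1, 2))
scenario = build_scenario(config, seed=0)
profile = scenario.profile

covered = sum(int((v > 0).sum()) for v in profile.counts.values())
print(f"coverage profile: {covered}/{profile.total_width} columns recovered "
      f"by {len(profile.sample_ages)} simulated samples")
print("TUFT1 columns retained at '100 ka':",
      scenario.masks["100 ka"].retained["TUFT1"].size,
      "(no ancient TUFT1 peptides exist)")

report = run_fragmentation_experiment(config)
print(f"\n{'stage':>10} {'width':>6} {'fraction':>9} {'mean RF':>8}")
means = report.mean_rf_by_stage()
df = report.to_frame()
for stage in config.stage_fractions:
    sub = df[df.stage == stage]
    print(f"{stage:>10} {int(sub.width.mean()):>6} "
          f"{sub.retained_fraction.mean():>9.2f} {means[stage]:>8.1f}")
print("\nRF distance to the true tree grows as less sequence survives —"
      " the fragmentation-stage degradation trend.")
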