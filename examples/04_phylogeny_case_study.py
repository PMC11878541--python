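"""Place a fragmented 'fossil' taxon among full-length references.

Only the target taxon's row is fragmented (case-study mode); everyone
else keeps full-length sequences. The inferred tree is checked for the
split grouping the target with its true sister clade, and bootstrap
support is reported.
"""

from enamelphylo import fragmentation as frag
from enamelphylo.phylo import bootstrap_support, nj_builder
from enamelphylo.pipeline import ExperimentConfig, build_scenario, run_case_study
from enamelphylo.treecmp import check_rank_monophyly

config = ExperimentConfig(seeds=(0, 1, 2, 3, 4), case_stage="100 ka")
report = run_case_study(config)
rate = report.placement_rate()
print(f"target placed with its true sister clade in {rate:.0%} of runs "
      f"(stage '100 ka', {len(report.placements)} seeded runs)")

# bootstrap support on one mixed alignment
scenario = build_scenario(config, seed=0)
target = scenario.dataset.msa.taxa[-1]
mixed = frag.apply_mask_case_study(
    scenario.dataset.msa, scenario.masks["100 ka"], [target]
)
boot = bootstrap_support(mixed, n_replicates=50, builder=nj_builder(), seed=0)
strong = sum(1 for v in boot.supports.values() if v >= 0.95)
print(f"bootstrap: {strong}/{len(boot.supports)} splits with support >= 0.95 "
      f"({boot.n_skipped} replicates skipped)")
# high support on most splits despite one fragmented row mirrors the
# reference-scaffold design of paleoproteomic case studies
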