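"""From scan results to the two marker components of a prediction scenario.

Shows the full selection chain for the scenario 'WB-50K+MBQTL6-10/2':
candidates below p < 1e-6 from the multi-breed scan, LD pruning at
R^2 = 0.95, at most 10 variants per 2-Mb peak interval, and the removal of
the selected QTL variants from the array (50K-style) component so the two
components stay disjoint.
"""

import seqblup as sb

config = sb.RunConfig(scenarios=["WB-50K+MBQTL6-10/2"])
ctx = sb.pipeline.PipelineContext(config)
dataset, arch, _ = ctx.data()
scenario = sb.parse_scenario("WB-50K+MBQTL6-10/2")

candidates = sb.threshold_select(ctx.multibreed_table(), scenario.t, dataset)
pruned = sb.ld_prune(candidates, dataset, animal_ids=ctx.split().all_training())
limited = sb.limit_per_interval(pruned, scenario.n, scenario.w)
components = sb.assemble_components(ctx.base_panel(), limited["variant_id"].tolist(), scenario)

print(f"scenario {scenario.name}")
print(f"  candidates below 10^-{scenario.t}:  {len(candidates)}")
print(f"  after LD pruning (R^2 <= 0.95): {len(pruned)}")
print(f"  after {scenario.n}-per-{scenario.w}-Mb windows: {len(limited)}")
print(f"  array component: {len(components.array_component)} variants, "
      f"QTL component: {len(components.qtl_component)} (disjoint)")
print(components.to_frame(dataset).query("component == 'QTL'").to_string(index=False))
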