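"""Run the whole chain: simulate -> predict -> synth -> analyze.

Writes trials/responses, predicted and synthetic curves, AUC tables,
ANOVA tables and a per-ROI report under ./out-example, then prints the
report (predicted vs synthetically measured effect directions per ROI).
"""

from tripletask import PipelineConfig, run_pipeline

config = PipelineConfig(n_subjects=6, blocks=3, seed=42, out_dir="out-example")
result = run_pipeline(config)

print(result.report)
print("Outputs written:")
for name, path in sorted(result.paths.items()):
    print(f"  {name:18s} {path}")
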