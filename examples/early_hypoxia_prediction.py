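"""Early FMISO uptake predicts later fibrosis progression; early CT does not.

Simulates a bleomycin-vehicle arm, quantifies the day-9 markers and the
day-9 -> day-23 change in mean lung density (the progression score), and
prints their Pearson correlations.
"""

from fibropet import PhantomSpec
from fibropet.pipeline import run_phantom_study
from fibropet.stats import early_marker_correlations, progression_table

spec = PhantomSpec(shape=(64, 64, 64), spacing_mm=(0.375, 0.375, 0.375))
metrics, truth, _ = run_phantom_study(spec, {"BLM": 10}, seed=3, days=[9, 23])

prog = progression_table(metrics)
print("per-animal progression (deltaCT D9-D23, HU):")
print(prog.round(1).to_string(index=False))
print()
print(early_marker_correlations(metrics).round(3).to_string(index=False))
print()
print("Only the day-9 hypoxia signal correlates with subsequent density gain:")
print("the destined-to-consolidate halo is FMISO-avid while still CT-normal.")
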