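"""Recover a planted memory-modulated coupling with gPPI.

Plants a seed x memory-quality interaction (beta = 0.5) from anterior
hippocampus to parahippocampal cortex, then estimates it with the gPPI
regression: target ~ intercepts + seed + psych regressors + seed x psych.
"""

from mnemonet import connectivity, gppi, scoring
from mnemonet.synthgen import (
    BehavioralParams, NeuralParams, StudyDesign,
    generate_behavior, generate_design, generate_timeseries,
)

design = StudyDesign(n_subjects=1)
trials = generate_behavior(generate_design(design, seed=6), BehavioralParams(), seed=7)
scored = scoring.score_trials(trials, {"color": 57.0, "scene": 30.0})

planted = (("aHIPP", "PHC", "quality", 0.5),)
ts = generate_timeseries(scored, NeuralParams(modulations=planted, seed=8), design)
ts.trials = scored

model = connectivity.build_event_model(scored, design)
clean = connectivity.denoise(ts, model, include_task=False)
quality = gppi.build_quality_modulator(scored, design)
remember = gppi.build_remember_boxcar(scored, design)

rois = list(design.roi_names)
fit = gppi.fit_gppi(
    clean.data[:, rois.index("aHIPP")], clean.data[:, rois.index("PHC")],
    {"remember": remember, "quality": quality}, clean.run_ids)
null = gppi.fit_gppi(
    clean.data[:, rois.index("ANG")], clean.data[:, rois.index("OFC")],
    {"remember": remember, "quality": quality}, clean.run_ids)

print("planted aHIPP -> PHC quality interaction: beta = 0.5")
print(f"  recovered: beta = {fit['quality']['beta']:.3f} "
      f"(SE {fit['quality']['se']:.3f})")
print(f"  unplanted ANG -> OFC pair: beta = {null['quality']['beta']:.3f} "
      f"(SE {null['quality']['se']:.3f})")
print()
print("The interaction beta measures how much seed->target coupling grows")
print("per unit of trial memory quality (the 0-3 composite score). The")
print("unplanted control pair is several times smaller; its residual value")
print("reflects the shared task-evoked response, which correlates all ROIs.")
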