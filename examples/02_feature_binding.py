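"""Measure whether episodic features are remembered together.

Generates a 28-subject cohort with a planted across-feature memory
dependency, scores each trial, and computes the corrected dependency
statistic (observed co-retrieval minus the independent-model expectation)
with a group t test.
"""

from mnemonet import scoring
from mnemonet.dependency import group_dependency_stats, subject_dependency_table
from mnemonet.synthgen import BehavioralParams, StudyDesign, generate_behavior, generate_design

design = StudyDesign.full()
params = BehavioralParams(dependency_strength=0.15)

trials = generate_design(design, seed=1)
trials = generate_behavior(trials, params, seed=2)
scored = scoring.score_trials(trials, {"color": 57.0, "scene": 30.0})

table = subject_dependency_table(scored)
stats = group_dependency_stats(table).set_index("measure")

print(f"cohort: {design.n_subjects} subjects x {design.n_trials} trials, "
      f"planted dependency strength {params.dependency_strength}")
for pair in ("emotion_color", "emotion_scene", "color_scene"):
    row = stats.loc[f"dependency_{pair}"]
    print(f"  {pair:15s} corrected dependency = {row['mean']:+.3f}  "
          f"t({int(row['df'])}) = {row['t']:.2f}, p = {row['p']:.2g}")
row = stats.loc["z_precision_precision"]
print(f"  color-scene precision correlation (Fisher z) = {row['mean']:+.3f}  "
      f"t({int(row['df'])}) = {row['t']:.2f}, p = {row['p']:.2g}")
print()
print("Positive corrected dependency: features are retrieved or forgotten")
print("together beyond what independent retrieval predicts. Precision stays")
print("uncorrelated because the generator couples success, not precision.")
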