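"""Background connectivity during encoding vs retrieval.

Simulates one subject's multi-run ROI time series with a retrieval-specific
boost in between-network covariance, removes task-evoked and nuisance
signal, computes HRF-weighted correlation matrices per task condition, and
compares Louvain modularity and network density between conditions.
"""

from mnemonet import connectivity, scoring
from mnemonet.synthgen import (
    BehavioralParams, NeuralParams, StudyDesign,
    generate_behavior, generate_design, generate_timeseries,
)

design = StudyDesign.full()
design = type(design)(n_subjects=1)
trials = generate_behavior(generate_design(design, seed=3), BehavioralParams(), seed=4)
scored = scoring.score_trials(trials, {"color": 57.0, "scene": 30.0})

ts = generate_timeseries(scored, NeuralParams(seed=5), design)
ts.trials = scored
model = connectivity.build_event_model(scored, design)
clean = connectivity.denoise(ts, model, include_task=True, on_collinear="drop")

print(f"{design.n_blocks} runs x {design.scans_per_run} scans at TR "
      f"{design.tr_seconds}s, {design.n_rois} ROIs (5 PM, 5 AT, 2 HIPP)")
for cond in connectivity.CONDITIONS:
    mat = connectivity.weighted_correlation_matrix(clean, model.weights[cond], cond)
    thr = connectivity.threshold_matrix(mat, 0.25)
    q, _ = connectivity.louvain_modularity(thr, seed=0)
    dens = connectivity.network_density(thr)
    print(f"  {cond:9s}: Q = {q:.3f}  within-network density = {dens['within']:.3f}"
          f"  between-network density = {dens['between']:.3f}")
print()
print("Retrieval shows lower modularity and higher between-network density")
print("than encoding: the planted between-network coupling during remember")
print("events makes the PM / AT / hippocampus graph less compartmentalized.")
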