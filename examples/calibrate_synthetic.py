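"""Recover known behavioural parameters from synthetic observations.

Generates a synthetic tracer-profile series from known parameters
(ground truth attached), then calibrates the model against it with the
two-stage pipeline: simulated annealing to localise the optimum on the
noisy sum-of-squares surface, then replicated quasi-Newton refinement on
a common-random-number objective. A small grid is used so the example
runs in seconds; the same code calibrates experiment-scale data.
"""

from dataclasses import replace

from bioturb import ModelParams, SimConfig, generate_synthetic
from bioturb.calibration import run_fit_pipeline

truth = ModelParams(activity=0.6, distance=2.5, downwards=0.5,
                    range_frac=1.0, tracerdif=0.9)
config = SimConfig(d=60, w=300, d_lum=8, n_steps=16, seed=1)
dataset = generate_synthetic(truth, config)

start = replace(truth, distance=4.0, tracerdif=0.8)
fixed = ("activity", "downwards", "range_frac")  # activity held at truth
sann, polish = run_fit_pipeline(dataset.series, config, start, fixed,
                                sann_budget=80, n_replicates=3, base_seed=7)

print(f"truth:     distance = {truth.distance:.3f}  tracerdif = {truth.tracerdif:.3f}")
print(f"annealing: distance = {sann.params.distance:.3f}  "
      f"tracerdif = {sann.params.tracerdif:.3f}")
print(f"refined:   distance = {polish.replicate_mean['distance']:.3f} "
      f"+/- {polish.replicate_sd['distance']:.3f}  "
      f"tracerdif = {polish.replicate_mean['tracerdif']:.3f} "
      f"+/- {polish.replicate_sd['tracerdif']:.3f}")
# The refined distance sits within a few percent of the generating value;
# tracerdif is resolved less sharply (its effect on a short series is
# subtle). The +/- figures are the spread across refinement replicates,
# i.e. the sampling noise of the fit itself.
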