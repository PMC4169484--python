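"""A full mechanical attrition run on a synthetic flax population.

Generates 10,000 fibres (80% intact 3-7 mm segments, 20% fines), runs
the step-wise breakage simulation with the default weakening schedule
(M_u/P: 400 µm, -25% per step, floor 40 µm) and reports the
length-weighted length-class shares per step and the detected
stagnation point.
"""

from fibresim import (
    SimConfig,
    SyntheticPopulationConfig,
    detect_stagnation,
    generate_initial_population,
    run_attrition,
)
from fibresim.analysis import series_from_trajectory

pop = generate_initial_population(SyntheticPopulationConfig(seed=1))
print(f"initial population: {len(pop)} fibres, mean length {pop.mean_length:.0f} µm")

traj = run_attrition(pop.lengths, config=SimConfig(seed=1))
print(f"run: {traj.n_steps} steps, stop reason '{traj.stop_reason}', "
      f"{traj.final_active_lengths.size} fibres still active\n")

series = series_from_trajectory(traj)
print("step  M_u/P   <0.25  0.25-0.5  0.5-3  3-7 mm   (share of total length)")
for label, dist in zip(series.labels, series.distributions):
    if label <= 16 or label == traj.n_steps:
        mu = traj.steps[label - 1].mu_over_p if label else traj.schedule.initial_mu_over_p
        s = dist.shares
        print(f"{label:4d} {mu:6.1f}   {s[0]:.3f}    {s[1]:.3f}   {s[2]:.3f}  {s[3]:.3f}")

step = detect_stagnation(series, tol=0.01, patience=2)
final = series.distributions[-1].shares
print(
    f"\nstagnation detected at step {step}: from there on, consecutive distributions\n"
    f"differ by <1% total variation while {final[1:].sum():.0%} of the length is still in\n"
    "classes above 0.25 mm — attrition stops because the surviving fibres are\n"
    "shorter than the minimum breakable length, not because they are all dust."
)
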