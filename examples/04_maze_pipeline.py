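"""End-to-end maze analysis: navigate-vs-goal coupling contrast.

Simulates a maze session (beam-crossing events at S8/S9/S10/G1, coupling
injected at the navigation positions only), runs the full pipeline — epoch
extraction, bad-channel screen, best-channel selection, per-epoch MI and
distribution correlation, Kruskal-Wallis with Dunn's post hoc — and prints
the position-wise contrast the flight and maze experiments both show:
coupling present while navigating, gone at the goal.
"""

import numpy as np

from pacnav import (
    AnalysisConfig,
    MazeSession,
    PacSimConfig,
    run_maze_analysis,
    simulate_maze_session,
)

pac = PacSimConfig(seed=8, depth=0.9, noise_sd=10.0)
rec, events = simulate_maze_session(
    12, ["S8", "S9", "S10", "G1"], 2000.0, pac, seed=8, n_channels=8
)
cfg = AnalysisConfig(task="maze", seed=0, n_surrogates=100, compute_comodulograms=False)
result = run_maze_analysis(cfg, MazeSession(rec, events), goal="G1")

print(f"best channel: {result.best_channel}")
print(result.epoch_table.groupby("label")[["mi", "corr"]].mean().round(4))
kw = result.tests["positions_corr"]
print(f"\nKruskal-Wallis on corr: H = {kw.statistic:.1f}, df = {kw.df}, p = {kw.p:.2g}")
print("significant Dunn pairs:", kw.significant_pairs())
circ = result.circular
print(
    f"theta phase at envelope peaks: avgAng = {np.degrees(circ.avg_ang):.1f} deg, "
    f"r = {circ.r:.2f}, Rayleigh p = {circ.rayleigh_p:.2g}"
)

print(
    "\nNavigation positions carry high MI and near-1 correlation with the"
    "\nstandard distribution; the goal position does not, and Dunn's test"
    "\nsingles out exactly the navigation-vs-goal pairs."
)
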