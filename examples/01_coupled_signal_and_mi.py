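"""Simulate a coupled LFP and measure its modulation index.

Builds a 10 s single-channel signal in which the 150 Hz envelope follows a
raised cosine of the 6 Hz theta phase (depth 0.9), then runs the full MI
pipeline (band-pass, Hilbert phase/envelope, 50 ms edge trim, 20-degree phase
bins, normalized KL distance) on the coupled signal and on a depth-0 control.
"""

from pacnav import PacSimConfig, mi_for_pair, simulate_pac_signal

for depth in (0.9, 0.0):
    cfg = PacSimConfig(seed=1, depth=depth)
    rec = simulate_pac_signal(cfg)
    mi = mi_for_pair(rec.data[:, 0], cfg.fs, (3.0, 6.0), (140.0, 180.0))
    print(f"depth {depth:.1f}: MI = {mi:.5f}")

print(
    "\nMI is 0 for a phase-independent envelope and grows toward 1 as the"
    "\nenvelope concentrates at one theta phase; the coupled signal should"
    "\nsit orders of magnitude above the uncoupled control."
)
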