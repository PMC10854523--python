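"""Scan the full comodulogram grid and locate the injected frequency pair.

The grid covers phase frequencies 2-20 Hz (step 1) against amplitude
frequencies 20-180 Hz (step 5); each cell is the MI of that band pair.  The
simulation injects coupling at (6 Hz, 150 Hz), so the map's argmax should land
on that cell and a white-noise control should stay near zero everywhere.
"""

import numpy as np

from pacnav import PacSimConfig, comodulogram, simulate_pac_signal

cfg = PacSimConfig(seed=7, depth=0.9, f_p=6.0, f_A=150.0)
x = simulate_pac_signal(cfg).data[:, 0]
cm = comodulogram(x, cfg.fs)
fp, fa = cm.argmax()
print(f"coupled map:  {cm.mi.shape[0]} x {cm.mi.shape[1]} cells, "
      f"max MI {cm.max():.4f} at phase {fp:g} Hz / amplitude {fa:g} Hz")

noise = np.random.default_rng(7).standard_normal(x.size) * 15.0
cm0 = comodulogram(noise, cfg.fs)
print(f"noise map:    max MI {cm0.max():.4f} (no structure anywhere)")

print(
    "\nThe argmax of the coupled map recovers the injected (6, 150) Hz pair;"
    "\nthe noise map's ceiling is the estimator's small-sample bias floor."
)
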