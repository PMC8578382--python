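"""Subunit counting from GFP photobleaching.

Simulates per-spot bleach-step counts for tetramers with imperfect per-subunit
detection, fits a binomial with four sites, and demonstrates automated step
counting on a noisy staircase trace.
"""

import numpy as np

from smbind import count_bleach_steps, fit_binomial, generate_bleach_counts

counts = generate_bleach_counts(500, p_detect=0.82, rng=np.random.default_rng(1))
fit = fit_binomial(counts=counts)
print("bleach-step counts over 500 spots:", np.bincount(counts, minlength=5))
print(f"binomial(4, p) fit: p = {fit.p_hat:.3f} "
      f"[{fit.ci_low:.3f}, {fit.ci_high:.3f}]  (true detection 0.82)")

# automated step counting on one noisy staircase (2 subunits detected)
rng = np.random.default_rng(2)
stair = np.concatenate([np.full(100, 2000.0), np.full(100, 1000.0), np.zeros(100)])
stair += rng.normal(0, 100, stair.size)
steps, flags = count_bleach_steps(stair)
print(f"\nnoisy staircase trace: {steps} downward steps detected "
      f"(flags: {flags or 'none'})")
print("spots with more than four steps would indicate multiple channels and "
      "are excluded upstream of the binomial fit")
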