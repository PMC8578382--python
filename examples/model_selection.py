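"""Fit aggregated-Markov kinetic models and rank them by BIC.

Simulates two hours of single-site binding from a model with two bound
conformations (unbound <-> bound <-> bound*), restricts the records to
isolated binding events, then fits both the one-bound-state and the
two-bound-state schemes and ranks them. The generating model should win
decisively (delta BIC >> 10).
"""

import numpy as np

from smbind import (
    OptimizerConfig,
    bic_rank,
    fit_model,
    model_catalog,
    simulate_channel_markov,
    truncate_to_max_bound,
)

DT = 0.05
CONC = 100e-9  # 100 nM
TRUE = {"kon": 3e6, "koff": 2.0, "b12": 1.0, "b21": 0.5}

catalog = model_catalog()
m_b, c_b = catalog["M1.B"]
classes, _ = simulate_channel_markov(
    m_b, TRUE, CONC, 144_000, DT, rng=np.random.default_rng(6))
data = truncate_to_max_bound([classes], [CONC], max_bound=1,
                             frame_interval_s=DT)
print(f"simulated {data.n_frames * DT / 3600:.1f} h at 100 nM "
      f"({len(data.segments)} segments after truncation)")

config = OptimizerConfig(n_starts=4, seed=0)
fits = [fit_model(*catalog[name], data, config) for name in ("M1.A", "M1.B")]
for fit in fits:
    rates = {k: f"{v:.3g}" for k, v in fit.params.items()}
    print(f"{fit.model_name}: logL = {fit.loglik:.1f}, k = {fit.k_free}, {rates}")

table = bic_rank(fits)
print("\nBIC ranking (smaller is better):")
print(table[["model", "k_free", "bic", "delta_bic"]].to_string(index=False))
print("\nThe two-bound-state scheme is preferred: bound dwell times are "
      "biexponential, which a single bound state cannot produce.")
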