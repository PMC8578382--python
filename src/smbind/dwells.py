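"""Dwell-time and occupancy statistics from idealized bound-count series.

Covers: channel-level dwell extraction with boundary censoring, per-ligand
bound-dwell reconstruction under random / first-in-first-out / last-out
unbinding-assignment policies, dead-time-truncated exponential-mixture maximum
likelihood, sequential-event correlation, the second-binding latency statistic,
time-weighted bound-count distributions, binomial occupancy and bleach-step
fits, and automated photobleach step counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .idealize import _make_segment, merge_similar_segments, segment_trace

__all__ = [
    "DwellRecord",
    "ExpMixtureFit",
    "BinomialFit",
    "extract_channel_dwells",
    "assign_site_bound_dwells",
    "fit_exponential_mixture",
    "sequential_event_correlation",
    "second_latency_distribution",
    "bound_count_distribution",
    "fit_binomial",
    "count_bleach_steps",
]


@dataclass(frozen=True)
class DwellRecord:
    """One sojourn at a constant bound-count level."""

    molecule_id: str | None
    start_s: float
    end_s: float
    kind: str  # "bound" | "unbound"
    level: int
    censored_left: bool = False
    censored_right: bool = False

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def censored(self) -> bool:
        return self.censored_left or self.censored_right


@dataclass
class ExpMixtureFit:
    """Maximum-likelihood exponential mixture, left-truncated at a dead time."""

    weights: np.ndarray
    taus: np.ndarray
    dead_time_s: float
    loglik: float
    n: int
    converged: bool = True
    flags: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.taus)

    @property
    def weighted_tau(self) -> float:
        """Weighted time constant sum(a_i * tau_i)."""
        return float(np.dot(self.weights, self.taus))


@dataclass
class BinomialFit:
    """Binomial(n_sites, p) fit with a profile-likelihood 95% CI."""

    n_sites: int
    p_hat: float
    ci_low: float
    ci_high: float
    loglik: float


def extract_channel_dwells(
    counts: np.ndarray,
    frame_interval_s: float,
    molecule_id: str | None = None,
) -> list[DwellRecord]:
    """Maximal constant-count intervals of an idealized trace.

    Dwells touching the start or end of the record are flagged as censored;
    censored dwells are excluded from mixture MLE by default.
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        return []
    change = np.flatnonzero(np.diff(counts)) + 1
    bounds = np.concatenate(([0], change, [counts.size]))
    out = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        level = int(counts[a])
        out.append(DwellRecord(
            molecule_id=molecule_id,
            start_s=a * frame_interval_s,
            end_s=b * frame_interval_s,
            kind="bound" if level >= 1 else "unbound",
            level=level,
            censored_left=(a == 0),
            censored_right=(b == counts.size),
        ))
    return out


def assign_site_bound_dwells(
    counts: np.ndarray,
    frame_interval_s: float,
    policy: str = "random",
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Per-ligand bound durations from a channel-level count series.

    For bound periods with several occupied sites the order of unbinding is
    ambiguous; each unbinding closes one open ligand interval chosen uniformly
    at random (``random``, seeded), oldest first (``fifo``) or newest first
    (``lilo``). Ligands still open at the record end are censored and dropped.
    """
    if policy not in {"random", "fifo", "lilo"}:
        raise ValueError(f"unknown policy {policy!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    counts = np.asarray(counts)
    # open ligand intervals in binding order; ligands already bound at the
    # record start are left-censored (start None) and contribute no duration
    open_starts: list[int | None] = [None] * (int(counts[0]) if counts.size else 0)
    durations: list[float] = []
    prev = int(counts[0]) if counts.size else 0
    for t in range(1, counts.size):
        cur = int(counts[t])
        d = cur - prev
        if d > 0:
            open_starts.extend([t] * d)
        elif d < 0:
            for _ in range(-d):
                if not open_starts:
                    raise ValueError("unbinding with no open ligand interval")
                if policy == "random":
                    idx = int(rng.integers(len(open_starts)))
                elif policy == "fifo":
                    idx = 0
                else:  # lilo: the first ligand to bind is the last to unbind
                    idx = len(open_starts) - 1
                start = open_starts.pop(idx)
                if start is not None:
                    durations.append((t - start) * frame_interval_s)
        prev = cur
    return np.asarray(durations)


# ---------------------------------------------------------------------------
# exponential mixture MLE with dead time


def _mixture_negloglik(params: np.ndarray, t: np.ndarray, k: int, t_d: float) -> float:
    taus = np.exp(params[:k])
    if k == 1:
        w = np.array([1.0])
    else:
        z = np.concatenate((params[k:], [0.0]))
        z = z - z.max()
        w = np.exp(z) / np.exp(z).sum()
    # left-truncated density: f(t)/S(t_d)
    log_comp = (np.log(w)[None, :] - np.log(taus)[None, :]
                - t[:, None] / taus[None, :])
    m = log_comp.max(axis=1, keepdims=True)
    log_f = m[:, 0] + np.log(np.exp(log_comp - m).sum(axis=1))
    surv = np.dot(w, np.exp(-t_d / taus))
    return float(-(log_f.sum() - t.size * np.log(surv)))


def fit_exponential_mixture(
    durations: np.ndarray,
    k: int = 2,
    dead_time_s: float = 0.0,
    n_starts: int = 8,
    rng: np.random.Generator | int | None = 0,
) -> ExpMixtureFit:
    """MLE of a k-component exponential mixture left-truncated at a dead time.

    Durations below the dead time are rejected. Optimization is multistart
    L-BFGS-B over log time constants and softmax weights; components are
    returned sorted by ascending time constant.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    t = np.asarray(durations, dtype=float)
    if t.size == 0:
        raise ValueError("no durations to fit")
    if np.any(t < dead_time_s - 1e-12):
        raise ValueError("durations below the dead time")
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    flags = {}
    if np.unique(t).size < k:
        flags["degenerate_support"] = True

    if k == 1:
        # closed form for the truncated exponential: tau = mean(t) - t_d
        tau = max(float(t.mean() - dead_time_s), 1e-9)
        ll = -_mixture_negloglik(np.log([tau]), t, 1, dead_time_s)
        return ExpMixtureFit(
            weights=np.array([1.0]), taus=np.array([tau]),
            dead_time_s=dead_time_s, loglik=ll, n=t.size, flags=flags,
        )

    mean = max(float(t.mean() - dead_time_s), 1e-6)
    best = None
    for s in range(n_starts):
        scales = rng.uniform(-1.5, 1.5, size=k) if s else np.linspace(-1.0, 1.0, k)
        x0 = np.concatenate((np.log(mean) + scales, rng.normal(0, 0.5, size=k - 1)))
        res = optimize.minimize(
            _mixture_negloglik, x0, args=(t, k, dead_time_s),
            method="L-BFGS-B",
        )
        if best is None or res.fun < best.fun:
            best = res
    taus = np.exp(best.x[:k])
    z = np.concatenate((best.x[k:], [0.0]))
    z = z - z.max()
    w = np.exp(z) / np.exp(z).sum()
    order = np.argsort(taus)
    return ExpMixtureFit(
        weights=w[order], taus=taus[order],
        dead_time_s=dead_time_s, loglik=float(-best.fun), n=t.size,
        converged=bool(best.success), flags=flags,
    )


# ---------------------------------------------------------------------------
# correlations, latencies, occupancy


def sequential_event_correlation(
    dwells_by_molecule: dict[str, np.ndarray],
    n_bins: int = 20,
) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Correlation between sequential singly-bound event durations.

    ``dwells_by_molecule`` maps molecule id to its ordered singly-bound dwell
    durations (seconds). Consecutive pairs (t_i, t_{i+1}) are pooled across
    molecules; the Pearson correlation is computed on log durations (dwells
    span decades). Returns (pairs, correlation, 2-D histogram, bin edges).
    """
    pairs = [
        (d[i], d[i + 1])
        for d in dwells_by_molecule.values()
        for i in range(len(d) - 1)
    ]
    pairs = np.asarray(pairs, dtype=float).reshape(-1, 2)
    if pairs.shape[0] < 2:
        return pairs, 0.0, np.zeros((n_bins, n_bins)), np.array([])
    logp = np.log10(pairs)
    if np.allclose(logp[:, 0].std(), 0) or np.allclose(logp[:, 1].std(), 0):
        return pairs, 0.0, np.zeros((n_bins, n_bins)), np.array([])
    r = float(np.corrcoef(logp[:, 0], logp[:, 1])[0, 1])
    edges = np.linspace(logp.min(), logp.max(), n_bins + 1)
    hist, _, _ = np.histogram2d(logp[:, 0], logp[:, 1], bins=(edges, edges))
    return pairs, r, hist, edges


def second_latency_distribution(
    count_series: list[np.ndarray],
    frame_interval_s: float,
) -> np.ndarray:
    """Latencies from binding of the first ligand to binding of the second.

    For every 0->1 transition, the elapsed time until the next 1->2 transition
    is recorded provided the singly-bound level persists until then; sojourns
    that return to zero first are excluded.
    """
    latencies = []
    for counts in count_series:
        counts = np.asarray(counts)
        for t in np.flatnonzero((counts[:-1] == 0) & (counts[1:] == 1)):
            u = t + 1
            while u < counts.size - 1 and counts[u + 1] == 1:
                u += 1
            if u < counts.size - 1 and counts[u + 1] >= 2:
                latencies.append((u + 1 - (t + 1)) * frame_interval_s)
    return np.asarray(latencies)


def bound_count_distribution(
    count_series: list[np.ndarray], max_count: int = 4
) -> np.ndarray:
    """Time-weighted bound-count distribution P(k), k = 0..max_count, pooled
    over molecules."""
    if not count_series:
        raise ValueError("no idealized traces supplied")
    total = np.zeros(max_count + 1)
    for counts in count_series:
        counts = np.asarray(counts)
        total += np.bincount(np.clip(counts, 0, max_count),
                             minlength=max_count + 1)
    return total / total.sum()


def fit_binomial(
    distribution: np.ndarray | None = None,
    counts: np.ndarray | None = None,
    n_sites: int = 4,
    n_obs: int | None = None,
) -> BinomialFit:
    """MLE binomial fit with profile-likelihood 95% CI.

    Supply either a (time-weighted) distribution over 0..n_sites together with
    the number of observations behind it, or raw per-observation counts (e.g.
    bleach steps per spot; counts above n_sites must be excluded upstream).
    """
    if counts is not None:
        counts = np.asarray(counts)
        if np.any(counts > n_sites) or np.any(counts < 0):
            raise ValueError("counts outside 0..n_sites")
        n_k = np.bincount(counts, minlength=n_sites + 1).astype(float)
    elif distribution is not None:
        dist = np.asarray(distribution, dtype=float)
        if dist.size != n_sites + 1:
            raise ValueError(f"distribution must have {n_sites + 1} entries")
        n_obs = n_obs if n_obs is not None else 10_000
        n_k = dist * n_obs
    else:
        raise ValueError("supply distribution or counts")

    total = n_k.sum()
    ks = np.arange(n_sites + 1)
    p_hat = float(np.dot(ks, n_k) / (n_sites * total))

    def loglik(p: float) -> float:
        p = min(max(p, 1e-12), 1 - 1e-12)
        return float(np.dot(n_k, stats.binom.logpmf(ks, n_sites, p)))

    ll_hat = loglik(p_hat)
    crit = stats.chi2.ppf(0.95, df=1) / 2.0

    def bound(lo: float, hi: float) -> float:
        f = lambda p: loglik(p) - (ll_hat - crit)
        try:
            return float(optimize.brentq(f, lo, hi, xtol=1e-8))
        except ValueError:
            return lo if f(lo) < 0 else hi

    ci_low = 0.0 if p_hat <= 1e-12 else bound(1e-9, p_hat)
    ci_high = 1.0 if p_hat >= 1 - 1e-12 else bound(p_hat, 1 - 1e-9)
    return BinomialFit(
        n_sites=n_sites, p_hat=p_hat,
        ci_low=ci_low, ci_high=ci_high, loglik=ll_hat,
    )


def count_bleach_steps(
    gfp_trace: np.ndarray,
    penalty: float = 1.0,
    min_step_sd: float = 2.0,
    min_dwell_frames: int = 5,
) -> tuple[int, dict]:
    """Automated count of downward photobleach steps in a GFP trace.

    The trace is segmented and merged like a binding trace; because bleach
    levels persist for seconds while fluorophore blinking causes only brief
    dips, segments shorter than ``min_dwell_frames`` are absorbed into the
    neighbour with the closer mean before counting. The step count is the
    number of boundaries where the level decreases; an upward step larger than
    ``min_step_sd`` noise SDs is flagged for manual review.
    Returns (n_steps, flags).
    """
    x = np.asarray(gfp_trace, dtype=float)
    segs = merge_similar_segments(x, segment_trace(x, penalty=penalty))
    changed = True
    while changed and len(segs) > 1:
        changed = False
        for i, s in enumerate(segs):
            if s.n_frames >= min_dwell_frames:
                continue
            d_prev = abs(s.mean - segs[i - 1].mean) if i > 0 else np.inf
            d_next = abs(s.mean - segs[i + 1].mean) if i + 1 < len(segs) else np.inf
            if d_prev <= d_next:
                segs[i - 1] = _make_segment(x, segs[i - 1].start, s.end)
            else:
                segs[i + 1] = _make_segment(x, s.start, segs[i + 1].end)
            del segs[i]
            changed = True
            break
        if changed:
            segs = merge_similar_segments(x, segs)
    flags: dict = {}
    steps = 0
    noise = float(np.median([s.sd for s in segs])) if len(segs) > 1 else 0.0
    resolve = min_step_sd * max(noise, 1e-9)
    for a, b in zip(segs[:-1], segs[1:]):
        if a.mean - b.mean > resolve:
            steps += 1
        elif b.mean - a.mean > resolve:
            flags["non_monotone"] = True
    return steps, flags
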