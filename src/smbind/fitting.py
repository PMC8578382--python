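"""Maximum-likelihood fitting of aggregated-Markov models to idealized data.

The likelihood is frame-discretized: per concentration, the frame transition
matrix is A = exp(Q*dt) and the forward recursion keeps only states whose
class (bound-ligand count) matches the observed count at each frame. Each
truncation segment starts from the equilibrium distribution restricted and
renormalized to the states of its first observed class, so the first frame of
a segment carries no likelihood. The one-frame dead time is inherent to this
discretization (no dwell shorter than a frame is representable); no
continuous-time missed-event correction is applied.

Model comparison uses BIC = -2 logL + k_free * ln(n_frames) with n_frames the
number of frames entering the likelihood, and the dispersion of BIC across
seeded molecule folds, each fold independently refit.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .models import (
    ConstraintSet,
    KineticModel,
    build_generator_matrix,
    equilibrium_distribution,
    transition_matrix,
)

__all__ = [
    "SegmentedData",
    "OptimizerConfig",
    "FitResult",
    "truncate_to_max_bound",
    "segment_loglikelihood",
    "fit_model",
    "fold_bics",
    "bic_rank",
]

_CHUNK = 256  # frames between forward-vector renormalizations
_LOG_ZERO = -1e30


@dataclass
class SegmentedData:
    """Per-segment class sequences with concentration and molecule labels."""

    segments: list[np.ndarray]
    concentrations_M: list[float]
    molecule_ids: list[str]
    frame_interval_s: float
    dead_time_frames: int = 1

    def __post_init__(self) -> None:
        if not (len(self.segments) == len(self.concentrations_M) == len(self.molecule_ids)):
            raise ValueError("segments, concentrations and molecule ids must align")
        if any(len(s) == 0 for s in self.segments):
            raise ValueError("empty segment")

    @property
    def n_frames(self) -> int:
        return int(sum(len(s) for s in self.segments))

    def subset(self, molecule_ids: set[str]) -> "SegmentedData":
        keep = [i for i, m in enumerate(self.molecule_ids) if m in molecule_ids]
        return SegmentedData(
            segments=[self.segments[i] for i in keep],
            concentrations_M=[self.concentrations_M[i] for i in keep],
            molecule_ids=[self.molecule_ids[i] for i in keep],
            frame_interval_s=self.frame_interval_s,
            dead_time_frames=self.dead_time_frames,
        )

    def data_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.float64(self.frame_interval_s).tobytes())
        for seg, conc, mol in zip(self.segments, self.concentrations_M, self.molecule_ids):
            h.update(mol.encode())
            h.update(np.float64(conc).tobytes())
            h.update(np.asarray(seg, dtype=np.int8).tobytes())
        return h.hexdigest()


def truncate_to_max_bound(
    count_series: list[np.ndarray],
    concentrations_M: list[float],
    max_bound: int,
    frame_interval_s: float,
    molecule_ids: list[str] | None = None,
) -> SegmentedData:
    """Remove frames with more than ``max_bound`` bound ligands.

    The surviving runs of each molecule become independent segments; molecules
    whose every frame exceeds the bound contribute no segments.
    """
    if molecule_ids is None:
        molecule_ids = [f"mol{i}" for i in range(len(count_series))]
    segments, concs, mols = [], [], []
    for counts, conc, mol in zip(count_series, concentrations_M, molecule_ids):
        counts = np.asarray(counts)
        keep = counts <= max_bound
        edges = np.diff(np.concatenate(([0], keep.view(np.int8), [0])))
        for a, b in zip(np.flatnonzero(edges == 1), np.flatnonzero(edges == -1)):
            segments.append(counts[a:b].astype(np.int8))
            concs.append(conc)
            mols.append(mol)
    return SegmentedData(segments, concs, mols, frame_interval_s)


# ---------------------------------------------------------------------------
# forward likelihood


def _run_length_encode(classes: np.ndarray) -> list[tuple[int, int]]:
    change = np.flatnonzero(np.diff(classes)) + 1
    bounds = np.concatenate(([0], change, [classes.size]))
    return [(int(classes[a]), int(b - a)) for a, b in zip(bounds[:-1], bounds[1:])]


class _LikelihoodEngine:
    """Caches per-concentration transition matrices and their class-masked
    powers within one likelihood evaluation."""

    def __init__(self, model: KineticModel, params: dict, dt: float):
        self.model = model
        self.params = params
        self.dt = dt
        self.class_arr = np.asarray(model.class_map)
        self._per_conc: dict[float, tuple[np.ndarray, np.ndarray]] = {}
        self._powers: dict[tuple[float, int, int], np.ndarray] = {}

    def _conc_setup(self, conc: float):
        if conc not in self._per_conc:
            Q = build_generator_matrix(self.model, self.params, conc)
            A = transition_matrix(Q, self.dt)
            pi = equilibrium_distribution(Q)
            self._per_conc[conc] = (A, pi)
        return self._per_conc[conc]

    def _masked_power(self, conc: float, cls: int, d: int) -> np.ndarray:
        key = (conc, cls, d)
        if key in self._powers:
            return self._powers[key]
        A, _ = self._conc_setup(conc)
        if d == 1:
            M = A * (self.class_arr == cls)[None, :]
        else:
            half = self._masked_power(conc, cls, d // 2)
            M = half @ half
            if d % 2:
                M = M @ self._masked_power(conc, cls, 1)
        self._powers[key] = M
        return M

    def segment_loglik(self, classes: np.ndarray, conc: float) -> float:
        A, pi = self._conc_setup(conc)
        runs = _run_length_encode(np.asarray(classes))
        c0, d0 = runs[0]
        w = pi * (self.class_arr == c0)
        s = w.sum()
        if s <= 0:
            return _LOG_ZERO
        w = w / s  # first frame renormalized: contributes no likelihood
        ll = 0.0
        remaining = [(c0, d0 - 1)] + runs[1:]
        for cls, d in remaining:
            while d > 0:
                step = min(d, _CHUNK)
                w_prev = w
                w = w @ self._masked_power(conc, cls, step)
                s = w.sum()
                if s <= 0 and step > 1:
                    # chunked power underflowed; the per-frame product may
                    # still be representable (extreme rates) — retry frame-wise
                    w = w_prev
                    M1 = self._masked_power(conc, cls, 1)
                    for _ in range(step):
                        w = w @ M1
                        s = w.sum()
                        if s <= 0:
                            return _LOG_ZERO
                        ll += np.log(s)
                        w = w / s
                    d -= step
                    continue
                if s <= 0:
                    return _LOG_ZERO
                ll += np.log(s)
                w = w / s
                d -= step
        return float(ll)


def segment_loglikelihood(
    model: KineticModel,
    params: dict[str, float],
    data: SegmentedData,
) -> float:
    """Total forward log-likelihood over all segments and concentrations."""
    observed = {int(c) for seg in data.segments for c in np.unique(seg)}
    available = set(model.class_map)
    if not observed <= available:
        raise ValueError(
            f"observed classes {sorted(observed - available)} have no states in {model.name}"
        )
    eng = _LikelihoodEngine(model, params, data.frame_interval_s)
    return float(sum(
        eng.segment_loglik(seg, conc)
        for seg, conc in zip(data.segments, data.concentrations_M)
    ))


# ---------------------------------------------------------------------------
# optimization


@dataclass(frozen=True)
class OptimizerConfig:
    n_starts: int = 10
    seed: int = 0
    rate_bounds: tuple[float, float] = (1e-4, 1e4)  # s^-1; binding params scaled
    start_range: tuple[float, float] = (1e-2, 1e2)
    maxiter: int = 300
    hessian_step: float = 1e-3


@dataclass
class FitResult:
    model_name: str
    free_names: tuple[str, ...]
    free_values: np.ndarray
    params: dict[str, float]
    standard_errors: dict[str, float]
    loglik: float
    k_free: int
    n_frames: int
    data_hash: str
    converged: bool = True
    fold_bics: np.ndarray | None = None
    flags: dict = field(default_factory=dict)

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.k_free * np.log(self.n_frames)


def _param_scales(model: KineticModel, free: tuple[str, ...], data: SegmentedData):
    """Concentration scale per free parameter: binding rates live in
    M^-1 s^-1, so their bounds/starts are divided by a reference ligand
    concentration (geometric mean of the data's concentrations)."""
    concs = np.asarray(data.concentrations_M, dtype=float)
    c_ref = float(np.exp(np.mean(np.log(concs)))) if np.all(concs > 0) else 1.0
    binding = model.binding_params()
    return np.array([c_ref if p in binding else 1.0 for p in free]), c_ref


def _negloglik_factory(model, constraints, data, free_names):
    def nll(log_rates: np.ndarray) -> float:
        free = dict(zip(free_names, np.exp(log_rates)))
        params = constraints.resolve(model, free)
        try:
            ll = segment_loglikelihood(model, params, data)
        except (ValueError, np.linalg.LinAlgError):
            return -_LOG_ZERO
        if not np.isfinite(ll):
            return -_LOG_ZERO
        return -ll
    return nll


def _numerical_hessian(f, x: np.ndarray, step: float) -> np.ndarray:
    n = x.size
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = step
            ej = np.zeros(n); ej[j] = step
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / step**2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * step**2)
    return H


def fit_model(
    model: KineticModel,
    constraints: ConstraintSet,
    data: SegmentedData,
    config: OptimizerConfig = OptimizerConfig(),
) -> FitResult:
    """Constrained maximum-likelihood fit.

    Free rates are optimized in log space (constraints applied by
    reparametrization) with multistart L-BFGS-B from log-uniform draws.
    Standard errors come from the inverse numerical Hessian in log-rate space,
    mapped to rate units by the delta method.
    """
    constraints.validate(model)
    free_names = constraints.free_names(model)
    if not free_names:
        raise ValueError("model has no free parameters")
    scales, _ = _param_scales(model, free_names, data)
    lo = np.log(config.rate_bounds[0] / scales)
    hi = np.log(config.rate_bounds[1] / scales)
    s_lo = np.log(config.start_range[0] / scales)
    s_hi = np.log(config.start_range[1] / scales)
    nll = _negloglik_factory(model, constraints, data, free_names)

    rng = np.random.default_rng(config.seed)
    bounds = list(zip(lo, hi))
    best = None
    for s in range(config.n_starts):
        x0 = (s_lo + s_hi) / 2 if s == 0 else rng.uniform(s_lo, s_hi)
        f0 = nll(x0)
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": config.maxiter},
        )
        if res.fun >= f0 - 1e-9:
            # bounded line search can stall on a flat start; derivative-free
            # restart is cheap at this dimensionality
            res = optimize.minimize(
                nll, x0, method="Nelder-Mead", bounds=bounds,
                options={"maxiter": 200 * len(x0), "xatol": 1e-6, "fatol": 1e-9},
            )
        if best is None or res.fun < best.fun:
            best = res
    # gradient polish from the best point found
    polish = optimize.minimize(
        nll, best.x, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": config.maxiter},
    )
    if polish.fun < best.fun:
        best = polish

    converged = bool(best.success) and best.fun < -_LOG_ZERO / 2
    free_values = np.exp(best.x)
    params = constraints.resolve(model, dict(zip(free_names, free_values)))

    se: dict[str, float] = {}
    flags: dict = {}
    try:
        H = _numerical_hessian(nll, best.x, config.hessian_step)
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        if np.any(diag <= 0):
            flags["hessian_not_pd"] = True
        se_log = np.sqrt(np.abs(diag))
        se = {n: float(v * s) for n, v, s in zip(free_names, free_values, se_log)}
    except np.linalg.LinAlgError:
        flags["hessian_singular"] = True

    return FitResult(
        model_name=model.name,
        free_names=free_names,
        free_values=free_values,
        params=params,
        standard_errors=se,
        loglik=float(-best.fun),
        k_free=len(free_names),
        n_frames=data.n_frames,
        data_hash=data.data_hash(),
        converged=converged,
        flags=flags,
    )


def fold_bics(
    model: KineticModel,
    constraints: ConstraintSet,
    data: SegmentedData,
    n_folds: int = 5,
    seed: int = 0,
    config: OptimizerConfig = OptimizerConfig(),
) -> np.ndarray:
    """BIC of independent refits on seeded random molecule folds.

    Molecules (not frames) are partitioned so kinetic correlations within one
    molecule stay inside a fold.
    """
    molecules = sorted(set(data.molecule_ids))
    if len(molecules) < n_folds:
        raise ValueError("fewer molecules than folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(molecules))
    folds = np.array_split(perm, n_folds)
    out = []
    for fold in folds:
        subset = data.subset({molecules[i] for i in fold})
        out.append(fit_model(model, constraints, subset, config).bic)
    return np.asarray(out)


def bic_rank(fits: list[FitResult]) -> pd.DataFrame:
    """Rank fits by BIC on a shared data set.

    Returns a table with logL, free-parameter count, BIC, delta-BIC relative to
    the best model, and (when per-fold BICs are attached) the SD of the
    mean-centered fold BICs.
    """
    hashes = {f.data_hash for f in fits}
    if len(hashes) != 1:
        raise ValueError("fits were not computed on the same data set")
    rows = []
    for f in fits:
        fold_sd = (
            float(np.std(f.fold_bics - f.fold_bics.mean(), ddof=1))
            if f.fold_bics is not None and len(f.fold_bics) > 1 else np.nan
        )
        rows.append({
            "model": f.model_name, "loglik": f.loglik, "k_free": f.k_free,
            "n_frames": f.n_frames, "bic": f.bic, "fold_bic_sd": fold_sd,
        })
    table = pd.DataFrame(rows).sort_values("bic").reset_index(drop=True)
    table["delta_bic"] = table["bic"] - table["bic"].iloc[0]
    return table
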