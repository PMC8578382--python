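"""Aggregated-Markov (hidden Markov) kinetic models of ligand binding.

States carry a ligation count (the observed class: number of bound ligands)
and an optional conformation tag; emissions are deterministic (a state is
observed only through its class). Transition rates are named parameters, with
binding transitions scaled linearly by ligand concentration. Constraint sets
express fixed values and monomial ties (value = coef * prod(base_i^exp_i)),
which covers equality ties, statistical factors and split-cooperativity
constraints such as kon2 = sqrt(f) * kon1, koff2 = koff1 / sqrt(f).

The catalog covers single-site models (one binding step; classes 0/1) with up
to two bound and two unbound conformations, and two-site models (classes
0/1/2) ranging from sequential identical-independent binding through models
with bound-state conformational exchange, unliganded exchange, a two-
conformation MWC scheme, and per-subunit exchange, plus variants with the
second-step binding equilibrium constrained to fixed 10- or 100-fold positive
or negative cooperativity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

__all__ = [
    "State",
    "Transition",
    "KineticModel",
    "ConstraintSet",
    "build_generator_matrix",
    "transition_matrix",
    "equilibrium_distribution",
    "model_catalog",
]


@dataclass(frozen=True)
class State:
    label: str
    ligation: int
    conformation: str = ""


@dataclass(frozen=True)
class Transition:
    """rate(from -> to) = multiplier * param * concentration^conc_exponent."""

    frm: str
    to: str
    param: str
    multiplier: float = 1.0
    conc_exponent: int = 0


@dataclass(frozen=True)
class KineticModel:
    name: str
    states: tuple[State, ...]
    transitions: tuple[Transition, ...]

    def __post_init__(self) -> None:
        labels = [s.label for s in self.states]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate state labels")
        index = {s.label: i for i, s in enumerate(self.states)}
        for t in self.transitions:
            if t.frm not in index or t.to not in index:
                raise ValueError(f"transition {t} references unknown state")
            dlig = self.states[index[t.to]].ligation - self.states[index[t.frm]].ligation
            if dlig == 1 and t.conc_exponent != 1:
                raise ValueError(f"binding transition {t.frm}->{t.to} needs conc_exponent=1")
            if dlig != 1 and t.conc_exponent != 0:
                raise ValueError(f"non-binding transition {t.frm}->{t.to} must have conc_exponent=0")
            if t.multiplier <= 0:
                raise ValueError("transition multipliers must be positive")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def state_index(self) -> dict[str, int]:
        return {s.label: i for i, s in enumerate(self.states)}

    @property
    def class_map(self) -> tuple[int, ...]:
        return tuple(s.ligation for s in self.states)

    @property
    def param_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t in self.transitions:
            seen.setdefault(t.param)
        return tuple(seen)

    def binding_params(self) -> set[str]:
        """Parameters used with concentration scaling (units M^-1 s^-1)."""
        return {t.param for t in self.transitions if t.conc_exponent == 1}


@dataclass(frozen=True)
class ConstraintSet:
    """Fixed values and monomial ties over model parameters.

    ``ties[name] = (coef, ((base, exp), ...))`` sets the parameter to
    coef * prod(free[base]^exp); bases must be free parameters, which keeps the
    constraint graph trivially acyclic.
    """

    fixed: dict[str, float] = field(default_factory=dict)
    ties: dict[str, tuple[float, tuple[tuple[str, float], ...]]] = field(
        default_factory=dict
    )

    def free_names(self, model: KineticModel) -> tuple[str, ...]:
        bound = set(self.fixed) | set(self.ties)
        return tuple(p for p in model.param_names if p not in bound)

    def validate(self, model: KineticModel) -> None:
        free = set(self.free_names(model))
        for name, (coef, bases) in self.ties.items():
            if coef <= 0:
                raise ValueError(f"tie coefficient for {name} must be positive")
            for base, _exp in bases:
                if base not in free:
                    raise ValueError(
                        f"tie {name} references {base}, which is not a free parameter"
                    )
        for name, value in self.fixed.items():
            if value < 0:
                raise ValueError(f"fixed value for {name} must be nonnegative")

    def resolve(self, model: KineticModel, free_values: dict[str, float]) -> dict[str, float]:
        """Full parameter dictionary from free parameter values."""
        params = dict(self.fixed)
        params.update(free_values)
        for name, (coef, bases) in self.ties.items():
            params[name] = coef * math.prod(
                free_values[base] ** exp for base, exp in bases
            )
        missing = set(model.param_names) - set(params)
        if missing:
            raise ValueError(f"missing parameter values: {sorted(missing)}")
        return params


def build_generator_matrix(
    model: KineticModel, params: dict[str, float], concentration_M: float
) -> np.ndarray:
    """CTMC generator: q_ij = mult * k_ij * [L]^b_ij, rows summing to zero."""
    if concentration_M < 0:
        raise ValueError("concentration must be nonnegative")
    idx = model.state_index
    Q = np.zeros((model.n_states, model.n_states))
    for t in model.transitions:
        try:
            k = params[t.param]
        except KeyError:
            raise KeyError(f"unknown parameter {t.param!r}") from None
        if k < 0:
            raise ValueError(f"negative rate for {t.param}")
        Q[idx[t.frm], idx[t.to]] += t.multiplier * k * concentration_M**t.conc_exponent
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def transition_matrix(Q: np.ndarray, dt: float) -> np.ndarray:
    """Frame-interval transition probabilities A = exp(Q*dt)."""
    if dt < 0:
        raise ValueError("dt must be nonnegative")
    A = expm(Q * dt)
    A = np.clip(A, 0.0, None)
    return A / A.sum(axis=1, keepdims=True)


def equilibrium_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution: pi Q = 0, sum(pi) = 1."""
    n = Q.shape[0]
    M = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(M, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# model catalog


def _m(name, states, transitions) -> KineticModel:
    return KineticModel(
        name=name,
        states=tuple(State(*s) for s in states),
        transitions=tuple(Transition(*t) for t in transitions),
    )


def _single_site_models() -> dict[str, tuple[KineticModel, ConstraintSet]]:
    none = ConstraintSet()
    out: dict[str, tuple[KineticModel, ConstraintSet]] = {}

    out["M1.A"] = (_m("M1.A",
        [("U", 0), ("B", 1)],
        [("U", "B", "kon", 1.0, 1), ("B", "U", "koff")]), none)

    out["M1.B"] = (_m("M1.B",
        [("U", 0), ("B1", 1), ("B2", 1)],
        [("U", "B1", "kon", 1.0, 1), ("B1", "U", "koff"),
         ("B1", "B2", "b12"), ("B2", "B1", "b21")]), none)

    out["M1.C"] = (_m("M1.C",
        [("B1", 1), ("U", 0), ("B2", 1)],
        [("U", "B1", "kon1", 1.0, 1), ("B1", "U", "koff1"),
         ("U", "B2", "kon2", 1.0, 1), ("B2", "U", "koff2")]), none)

    out["M1.D"] = (_m("M1.D",
        [("U", 0), ("B1", 1), ("B2", 1)],
        [("U", "B1", "kon1", 1.0, 1), ("B1", "U", "koff1"),
         ("B1", "B2", "b12"), ("B2", "B1", "b21"),
         ("U", "B2", "kon2", 1.0, 1), ("B2", "U", "koff2")]), none)

    out["M1.E"] = (_m("M1.E",
        [("U1", 0), ("U2", 0, "c"), ("B1", 1), ("B2", 1, "c")],
        [("U1", "U2", "u12"), ("U2", "U1", "u21"),
         ("U1", "B1", "kon", 1.0, 1), ("B1", "U1", "koff"),
         ("B1", "B2", "b12"), ("B2", "B1", "b21")]), none)

    out["M1.F"] = (_m("M1.F",
        [("U1", 0), ("U2", 0, "c"), ("B1", 1), ("B2", 1, "c")],
        [("U1", "U2", "u12"), ("U2", "U1", "u21"),
         ("U1", "B1", "kon1", 1.0, 1), ("B1", "U1", "koff1"),
         ("B1", "B2", "b12"), ("B2", "B1", "b21"),
         ("U2", "B2", "kon2", 1.0, 1), ("B2", "U2", "koff2")]), none)
    return out


def _identity_tie(target: str, base: str):
    return (1.0, ((base, 1.0),))


_INDEPENDENT_BINDING = {
    "kon2": (1.0, (("kon1", 1.0),)),
    "koff2": (1.0, (("koff1", 1.0),)),
}


def _coop_binding_ties(f: float):
    """Split-cooperativity constraint: the second-step equilibrium is f-fold
    the identical-independent expectation, split evenly: kon2 = sqrt(f)*kon1,
    koff2 = koff1/sqrt(f)."""
    rf = math.sqrt(f)
    return {
        "kon2": (rf, (("kon1", 1.0),)),
        "koff2": (1.0 / rf, (("koff1", 1.0),)),
    }


def _two_site_sequential() -> KineticModel:
    # statistical factors for four... two exchangeable sites: two free sites
    # bind at twice the per-site rate; two bound ligands unbind at twice the
    # per-ligand rate
    return _m("M2.A",
        [("S0", 0), ("S1", 1), ("S2", 2)],
        [("S0", "S1", "kon1", 2.0, 1), ("S1", "S0", "koff1"),
         ("S1", "S2", "kon2", 1.0, 1), ("S2", "S1", "koff2", 2.0)])


def _two_site_exchange(with_unliganded: bool, name: str) -> KineticModel:
    states = [("S0", 0), ("S1", 1), ("S1c", 1, "c"), ("S2", 2), ("S2c", 2, "c")]
    transitions = [
        ("S0", "S1", "kon1", 2.0, 1), ("S1", "S0", "koff1"),
        ("S1", "S2", "kon2", 1.0, 1), ("S2", "S1", "koff2", 2.0),
        ("S1", "S1c", "a1"), ("S1c", "S1", "b1"),
        ("S2", "S2c", "a2"), ("S2c", "S2", "b2"),
    ]
    if with_unliganded:
        states.insert(1, ("S0c", 0, "c"))
        transitions += [("S0", "S0c", "a0"), ("S0c", "S0", "b0")]
    return _m(name, states, transitions)


def _two_site_mwc() -> KineticModel:
    # Two global conformations R/A; binding with statistical factors in each;
    # exchange rates at ligation n carry the per-ligand equilibrium factor
    # phi = (konA*koffR)/(konR*koffA), split as sqrt(phi) per direction so
    # every cycle satisfies detailed balance.
    states = [("R0", 0, "R"), ("R1", 1, "R"), ("R2", 2, "R"),
              ("A0", 0, "A"), ("A1", 1, "A"), ("A2", 2, "A")]
    transitions = [
        ("R0", "R1", "konR", 2.0, 1), ("R1", "R0", "koffR"),
        ("R1", "R2", "konR", 1.0, 1), ("R2", "R1", "koffR", 2.0),
        ("A0", "A1", "konA", 2.0, 1), ("A1", "A0", "koffA"),
        ("A1", "A2", "konA", 1.0, 1), ("A2", "A1", "koffA", 2.0),
        ("R0", "A0", "l0"), ("A0", "R0", "m0"),
        ("R1", "A1", "l1"), ("A1", "R1", "m1"),
        ("R2", "A2", "l2"), ("A2", "R2", "m2"),
    ]
    return _m("M2.E", states, transitions)


def _mwc_exchange_ties(phi_bases=None, f: float | None = None):
    """Exchange-rate ties l_n = l0*phi^(n/2), m_n = m0*phi^(-n/2).

    With ``f`` given, phi is fixed to f (cooperativity-constrained variants);
    otherwise phi is the derived monomial of the four binding rates.
    """
    if f is not None:
        half = math.sqrt(f)
        return {
            "l1": (half, (("l0", 1.0),)), "l2": (f, (("l0", 1.0),)),
            "m1": (1.0 / half, (("m0", 1.0),)), "m2": (1.0 / f, (("m0", 1.0),)),
        }
    phi_half = (("konA", 0.5), ("koffR", 0.5), ("konR", -0.5), ("koffA", -0.5))
    phi_full = (("konA", 1.0), ("koffR", 1.0), ("konR", -1.0), ("koffA", -1.0))
    neg = lambda bases: tuple((b, -e) for b, e in bases)
    return {
        "l1": (1.0, (("l0", 1.0),) + phi_half),
        "l2": (1.0, (("l0", 1.0),) + phi_full),
        "m1": (1.0, (("m0", 1.0),) + neg(phi_half)),
        "m2": (1.0, (("m0", 1.0),) + neg(phi_full)),
    }


def _two_site_subunit(name: str) -> KineticModel:
    # Symmetrized product of two sites, each U <-> B <-> C; channel states are
    # occupation multisets (nU, nB, nC). Binding params are indexed by the
    # step (first or second ligand), exchange params by the ligation level.
    states = [("UU", 0), ("UB", 1), ("UC", 1, "c"),
              ("BB", 2), ("BC", 2, "c"), ("CC", 2, "cc")]
    transitions = [
        ("UU", "UB", "kon1", 2.0, 1), ("UB", "UU", "koff1"),
        ("UB", "BB", "kon2", 1.0, 1), ("BB", "UB", "koff2", 2.0),
        ("UC", "BC", "kon2", 1.0, 1), ("BC", "UC", "koff2"),
        ("UB", "UC", "a1"), ("UC", "UB", "b1"),
        ("BB", "BC", "a2", 2.0), ("BC", "BB", "b2"),
        ("BC", "CC", "a2"), ("CC", "BC", "b2", 2.0),
    ]
    return _m(name, states, transitions)


_SUBUNIT_EXCHANGE_TIES = {
    "a2": (1.0, (("a1", 1.0),)),
    "b2": (1.0, (("b1", 1.0),)),
}


def model_catalog() -> dict[str, tuple[KineticModel, ConstraintSet]]:
    """Named kinetic models with their constraint sets.

    Single-site models M1.A-F; two-site models M2.A_i/c, M2.B, M2.C_i/c,
    M2.D_i/c, M2.E, M2.F_ii/ci/ic; and for M2.C/D/E/F, variants with the
    second-step binding equilibrium (for M2.E, the per-ligand conformational
    equilibrium factor) fixed to 10- or 100-fold positive (p10/p100) or
    negative (n10/n100) cooperativity, split evenly between on and off rates.
    """
    catalog = _single_site_models()

    seq = _two_site_sequential()
    catalog["M2.A_i"] = (seq, ConstraintSet(ties=dict(_INDEPENDENT_BINDING)))
    catalog["M2.A_c"] = (seq, ConstraintSet())

    catalog["M2.B"] = (_m("M2.B",
        [("S0", 0), ("S1", 1), ("S2a", 2), ("S2b", 2, "alt")],
        [("S0", "S1", "kon1", 2.0, 1), ("S1", "S0", "koff1"),
         ("S1", "S2a", "kon2a", 1.0, 1), ("S2a", "S1", "koff2a", 2.0),
         ("S1", "S2b", "kon2b", 1.0, 1), ("S2b", "S1", "koff2b", 2.0)]),
        ConstraintSet())

    mc = _two_site_exchange(False, "M2.C")
    md = _two_site_exchange(True, "M2.D")
    catalog["M2.C_i"] = (mc, ConstraintSet(ties=dict(_INDEPENDENT_BINDING)))
    catalog["M2.C_c"] = (mc, ConstraintSet())
    catalog["M2.D_i"] = (md, ConstraintSet(ties=dict(_INDEPENDENT_BINDING)))
    catalog["M2.D_c"] = (md, ConstraintSet())

    me = _two_site_mwc()
    catalog["M2.E"] = (me, ConstraintSet(ties=_mwc_exchange_ties()))

    mf = _two_site_subunit("M2.F")
    catalog["M2.F_ii"] = (mf, ConstraintSet(
        ties={**_INDEPENDENT_BINDING, **_SUBUNIT_EXCHANGE_TIES}))
    catalog["M2.F_ci"] = (mf, ConstraintSet(ties=dict(_SUBUNIT_EXCHANGE_TIES)))
    catalog["M2.F_ic"] = (mf, ConstraintSet(ties=dict(_INDEPENDENT_BINDING)))

    for f, tag in [(10.0, "p10"), (100.0, "p100"), (0.1, "n10"), (0.01, "n100")]:
        coop = _coop_binding_ties(f)
        catalog[f"M2.C_{tag}"] = (mc, ConstraintSet(ties=dict(coop)))
        catalog[f"M2.D_{tag}"] = (md, ConstraintSet(ties=dict(coop)))
        catalog[f"M2.F_{tag}"] = (mf, ConstraintSet(
            ties={**coop, **_SUBUNIT_EXCHANGE_TIES}))
        catalog[f"M2.E_{tag}"] = (me, ConstraintSet(ties={
            **_mwc_exchange_ties(f=f),
            "konA": _identity_tie("konA", "konR"),
            "koffA": _identity_tie("koffA", "koffR"),
        }))

    for model, constraints in catalog.values():
        constraints.validate(model)
    return catalog
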