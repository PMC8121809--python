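"""First-order reaction-network machinery for photocycle kinetics.

A photocycle is modelled as a network of first-order reactions between named
intermediate states (K, L₁, L₁′, L₂, M, N/O, …) that is prepared instantly by
the laser flash at ``t = 0`` and drains back into the absorbing ``"ground"``
state.  The population vector obeys ``dP/dt = Q·P`` with the rate matrix

    Q[j, i] = k(i → j)   for i ≠ j,      Q[i, i] = −Σ_j k(i → j),

so that columns sum to zero and total population is conserved.  Because
photocycle rates span some seven decades, populations are evaluated through
the eigendecomposition of ``Q`` (exact for the model class) rather than by
stiff numerical integration; a scaling-and-squaring matrix exponential is the
fallback for (near-)degenerate spectra.

Observable kinetics are reported as half-lives ``t₁/₂ = τ ln 2 = ln 2 / k``,
the convention used when comparing FTIR, UV/VIS and electrophysiological
transition tables.

The module also carries a catalogue of candidate topologies for the L
intermediate of GtACR1 — the anion channelrhodopsin's conducting state forms
in two kinetic steps, which is compatible with several arrangements of the
three L sub-states (parallel branches, branches with slow exchange, or a
strictly sequential chain).
"""

from __future__ import annotations

import math
from collections.abc import Callable, Mapping
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "GROUND",
    "LN2",
    "KineticScheme",
    "RateMatrix",
    "rate_matrix",
    "populations",
    "population_exponentials",
    "apparent_rates",
    "halflife_from_tau",
    "halflife_from_rate",
    "rate_from_halflife",
    "tau_from_halflife",
    "solve_l2_m_rates",
    "TemplateParam",
    "SchemeTemplate",
    "l_topology_catalogue",
    "get_template",
    "GTACR1_FTIR_HALFLIVES",
    "GTACR1_UVVIS_HALFLIVES",
    "scheme_to_dict",
    "scheme_from_dict",
    "save_scheme",
    "load_scheme",
]

GROUND = "ground"
LN2 = math.log(2.0)

#: Photocycle transition half-lives (seconds) from global fits of merged
#: step-scan + rapid-scan FTIR data: T1 (K decay) … T6 (ground-state recovery).
GTACR1_FTIR_HALFLIVES = (4.5e-7, 1.8e-5, 1.9e-3, 3.5e-2, 1.07e-1, 4.4)

#: The corresponding transition half-lives from time-resolved UV/VIS data.
GTACR1_UVVIS_HALFLIVES = (3.0e-6, 2.3e-5, 2.3e-3, 2.3e-2, 2.0e-1, 3.5)


# ---------------------------------------------------------------------------
# half-life / time-constant / rate conversions
# ---------------------------------------------------------------------------

def _require_positive(x: float, name: str) -> float:
    x = float(x)
    if not (x > 0 and math.isfinite(x)):
        raise ValueError(f"{name} must be positive and finite, got {x!r}")
    return x


def halflife_from_tau(tau: float) -> float:
    """t₁/₂ = τ·ln 2 (seconds)."""
    return _require_positive(tau, "tau") * LN2


def halflife_from_rate(k: float) -> float:
    """t₁/₂ = ln 2 / k for a first-order rate constant k (s⁻¹)."""
    return LN2 / _require_positive(k, "k")


def rate_from_halflife(halflife: float) -> float:
    """k = ln 2 / t₁/₂ (s⁻¹)."""
    return LN2 / _require_positive(halflife, "halflife")


def tau_from_halflife(halflife: float) -> float:
    """τ = t₁/₂ / ln 2 (seconds)."""
    return _require_positive(halflife, "halflife") / LN2


# ---------------------------------------------------------------------------
# schemes and rate matrices
# ---------------------------------------------------------------------------

@dataclass
class KineticScheme:
    """A first-order reaction network describing one closed photocycle.

    ``states`` must include ``"ground"``, the absorbing post-cycle state.
    ``rates`` are directed edges ``(from_state, to_state, k)`` with k in s⁻¹.
    ``initial`` holds the population fractions prepared by the flash at
    ``t = 0⁺`` (they must sum to one); ``conducting`` flags the ion-conducting
    (open-channel) states.  Every non-ground state must be reachable from the
    initial population and must drain to ground — an open-ended network is not
    a photocycle.
    """

    states: tuple[str, ...]
    rates: tuple[tuple[str, str, float], ...]
    initial: dict[str, float]
    conducting: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.states = tuple(str(s) for s in self.states)
        if len(set(self.states)) != len(self.states):
            raise ValueError("duplicate state names")
        if GROUND not in self.states:
            raise ValueError(f"scheme must contain the {GROUND!r} state")
        self.rates = tuple((str(a), str(b), float(k)) for a, b, k in self.rates)
        seen = set()
        for a, b, k in self.rates:
            if a not in self.states or b not in self.states:
                raise ValueError(f"rate {a}→{b} references an unknown state")
            if a == b:
                raise ValueError(f"self-edge on state {a!r}")
            if a == GROUND:
                raise ValueError("ground is absorbing: no rates may leave it")
            if not (k > 0 and math.isfinite(k)):
                raise ValueError(f"rate {a}→{b} must be positive and finite, got {k!r}")
            if (a, b) in seen:
                raise ValueError(f"duplicate edge {a}→{b}")
            seen.add((a, b))
        init = {s: float(self.initial.get(s, 0.0)) for s in self.states}
        if any(v < -1e-12 for v in init.values()):
            raise ValueError("initial fractions must be non-negative")
        total = sum(init.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"initial fractions must sum to 1, got {total!r}")
        self.initial = init
        cond = dict(self.conducting)
        for s in cond:
            if s not in self.states:
                raise ValueError(f"conducting flag for unknown state {s!r}")
        self.conducting = {s: bool(cond.get(s, False)) for s in self.states}
        self._check_connectivity()

    def _check_connectivity(self) -> None:
        forward: dict[str, list[str]] = {s: [] for s in self.states}
        backward: dict[str, list[str]] = {s: [] for s in self.states}
        for a, b, _ in self.rates:
            forward[a].append(b)
            backward[b].append(a)

        def reach(seeds, adj):
            seen = set(seeds)
            stack = list(seeds)
            while stack:
                for nxt in adj[stack.pop()]:
                    if nxt not in seen:
                        seen.add(nxt)
                        stack.append(nxt)
            return seen

        seeds = [s for s, v in self.initial.items() if v > 0]
        reached = reach(seeds, forward)
        orphans = [s for s in self.states if s != GROUND and s not in reached]
        if orphans:
            raise ValueError(f"states not reachable from the initial population: {orphans}")
        draining = reach([GROUND], backward)
        stuck = [s for s in self.states if s != GROUND and s not in draining]
        if stuck:
            raise ValueError(f"states that do not drain to ground: {stuck}")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        return self.states.index(state)

    @property
    def nonground_states(self) -> tuple[str, ...]:
        return tuple(s for s in self.states if s != GROUND)

    def is_irreversible(self) -> bool:
        """True when the reaction graph is acyclic (a DAG into ground)."""
        adj: dict[str, list[str]] = {s: [] for s in self.states}
        for a, b, _ in self.rates:
            adj[a].append(b)
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {s: WHITE for s in self.states}

        def visit(u: str) -> bool:
            color[u] = GRAY
            for v in adj[u]:
                if color[v] == GRAY:
                    return False
                if color[v] == WHITE and not visit(v):
                    return False
            color[u] = BLACK
            return True

        return all(visit(s) for s in self.states if color[s] == WHITE)


@dataclass
class RateMatrix:
    """Matrix form of a kinetic scheme: ``dP/dt = Q·P``."""

    states: tuple[str, ...]
    Q: np.ndarray

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        n = len(self.states)
        if self.Q.shape != (n, n):
            raise ValueError("Q must be square with one row per state")
        off = self.Q - np.diag(np.diag(self.Q))
        if np.any(off < 0):
            raise ValueError("off-diagonal rate entries must be non-negative")
        colsum = self.Q.sum(axis=0)
        if np.max(np.abs(colsum)) > 1e-9 * max(1.0, float(np.max(np.abs(self.Q)))):
            raise ValueError("columns of Q must sum to zero (population conservation)")


def rate_matrix(scheme: KineticScheme) -> RateMatrix:
    """Build the rate matrix Q of a validated scheme."""
    n = scheme.n_states
    Q = np.zeros((n, n))
    for a, b, k in scheme.rates:
        ia, ib = scheme.index(a), scheme.index(b)
        Q[ib, ia] += k
        Q[ia, ia] -= k
    return RateMatrix(states=scheme.states, Q=Q)


def _initial_vector(scheme: KineticScheme) -> np.ndarray:
    return np.array([scheme.initial[s] for s in scheme.states])


def _eigendecomposition(Q: np.ndarray):
    lam, V = np.linalg.eig(Q)
    mag = float(np.max(np.abs(lam))) if lam.size else 0.0
    complex_ok = mag == 0.0 or float(np.max(np.abs(lam.imag))) <= 1e-9 * mag
    re = np.sort(lam.real)
    gaps = np.diff(re)
    degenerate = bool(np.any(gaps < 1e-9 * max(mag, 1e-300))) if re.size > 1 else False
    return lam, V, complex_ok, degenerate


def populations(scheme: KineticScheme, times) -> np.ndarray:
    """Population fractions ``P(t) = exp(Qt)·P(0)``, shape (n_states, n_times).

    Each column sums to one; entries lie in [0, 1].  Uses the eigendecomposition
    of Q when its spectrum is real and non-degenerate (relative gap ≥ 1e−9),
    otherwise the scaling-and-squaring matrix exponential.
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t <= 0):
        raise ValueError("all times must be strictly positive")
    Q = rate_matrix(scheme).Q
    p0 = _initial_vector(scheme)
    lam, V, complex_ok, degenerate = _eigendecomposition(Q)
    if complex_ok and not degenerate:
        c = np.linalg.solve(V, p0.astype(complex))
        P = (V * c) @ np.exp(np.outer(lam, t))
        P = P.real
    else:
        P = np.column_stack([scipy.linalg.expm(Q * ti) @ p0 for ti in t])
    # eigenroute round-off can leave tiny negatives / overshoots
    np.clip(P, 0.0, 1.0, out=P)
    return P


def population_exponentials(scheme: KineticScheme):
    """Closed-form exponential decomposition of the non-ground populations.

    Returns ``(rates, X, states)`` with rates sorted descending such that
    ``P_s(t) = Σ_i X[s, i]·exp(−rates[i]·t)`` for every non-ground state ``s``.
    Raises for oscillatory (complex-eigenvalue) or degenerate spectra, where
    the pure-exponential decomposition does not exist in this form.
    """
    Q = rate_matrix(scheme).Q
    p0 = _initial_vector(scheme)
    lam, V, complex_ok, degenerate = _eigendecomposition(Q)
    if not complex_ok:
        raise ValueError("scheme has complex eigenvalues (oscillatory network)")
    if degenerate:
        raise ValueError("scheme has (near-)degenerate eigenvalues")
    c = np.linalg.solve(V, p0.astype(complex))
    contrib = (V * c).real  # state × eigenmode contribution matrix
    lam = lam.real
    mag = float(np.max(np.abs(lam)))
    nonzero = np.where(np.abs(lam) > 1e-12 * mag)[0]
    order = nonzero[np.argsort(lam[nonzero])]  # most negative first → fastest rate first
    rates = -lam[order]
    ng = [i for i, s in enumerate(scheme.states) if s != GROUND]
    X = contrib[np.ix_(ng, order)]
    return rates, X, scheme.nonground_states


def apparent_rates(scheme: KineticScheme, return_multiplicity: bool = False):
    """Negated non-zero eigenvalues of Q, sorted descending.

    These are the observable exponential rates of any trace generated by the
    scheme; for an irreversible chain they equal the individual step rates.
    With ``return_multiplicity=True`` returns ``(unique_rates, counts)``
    where near-coincident rates (relative gap < 1e−9) are clustered.
    Raises for complex eigenvalue pairs: oscillatory networks are outside the
    multi-exponential model class.
    """
    Q = rate_matrix(scheme).Q
    lam = np.linalg.eigvals(Q)
    mag = float(np.max(np.abs(lam)))
    if mag > 0 and float(np.max(np.abs(lam.imag))) > 1e-9 * mag:
        raise ValueError(
            "scheme has complex eigenvalues (oscillatory network); "
            "such schemes are outside the exponential model class"
        )
    lam = lam.real
    nonzero = lam[np.abs(lam) > 1e-12 * max(mag, 1e-300)]
    rates = np.sort(-nonzero)[::-1]
    if not return_multiplicity:
        return rates
    uniq: list[float] = []
    counts: list[int] = []
    for r in rates:
        if uniq and abs(uniq[-1] - r) <= 1e-9 * max(abs(r), abs(uniq[-1])):
            counts[-1] += 1
        else:
            uniq.append(float(r))
            counts.append(1)
    return np.array(uniq), np.array(counts)


# ---------------------------------------------------------------------------
# L-intermediate topology catalogue
# ---------------------------------------------------------------------------

def solve_l2_m_rates(k_app_fast: float, k_app_slow: float, reverse_ratio: float):
    """Edge rates of the L₂ ⇌ M → N/O block from its *apparent* rates.

    The reversible block

        L₂ →(k_f) M,   M →(r·k_f) L₂,   M →(k_m) N/O

    has apparent (eigenvalue) rates whose sum is ``k_f(1+r) + k_m`` and whose
    product is ``k_f·k_m``.  Given the two observed closing rates and the
    reversibility ratio ``r = k_rev/k_fwd``, this inverts the 2×2 eigenvalue
    problem so that simulated kinetics reproduce the printed transition
    half-lives regardless of ``r``.  For ``r = 0`` it reduces to the
    irreversible chain ``k_f = k_app_fast``, ``k_m = k_app_slow``.

    Returns ``(k_fwd, k_rev, k_m)``.
    """
    kf_app = _require_positive(k_app_fast, "k_app_fast")
    ks_app = _require_positive(k_app_slow, "k_app_slow")
    r = float(reverse_ratio)
    if r < 0:
        raise ValueError("reverse_ratio must be >= 0")
    if r == 0.0:
        return kf_app, 0.0, ks_app
    s, p = kf_app + ks_app, kf_app * ks_app
    disc = s * s - 4.0 * (1.0 + r) * p
    if disc < 0:
        raise ValueError(
            f"apparent rates {kf_app:g}, {ks_app:g} not realizable with reverse_ratio={r:g}"
        )
    k_fwd = (s + math.sqrt(disc)) / (2.0 * (1.0 + r))
    k_m = p / k_fwd
    return k_fwd, r * k_fwd, k_m


@dataclass(frozen=True)
class TemplateParam:
    """One named, bounded rate (or fraction) parameter of a scheme template."""

    name: str
    default: float
    lower: float
    upper: float
    log_scale: bool = True


@dataclass(frozen=True)
class SchemeTemplate:
    """A parameterized photocycle topology that builds validated schemes."""

    name: str
    description: str
    params: tuple[TemplateParam, ...]
    builder: Callable[..., KineticScheme]

    def defaults(self) -> dict[str, float]:
        return {p.name: p.default for p in self.params}

    def build(self, **overrides: float) -> KineticScheme:
        known = {p.name for p in self.params}
        unknown = set(overrides) - known
        if unknown:
            raise ValueError(f"unknown parameters for template {self.name!r}: {sorted(unknown)}")
        kwargs = self.defaults()
        kwargs.update(overrides)
        return self.builder(**kwargs)


_K = tuple(rate_from_halflife(h) for h in GTACR1_FTIR_HALFLIVES)
_EPS_FRACTION = 1e-9


def _tail_edges(k_close, reverse_ratio, k_m_decay, k_recovery):
    edges = [("L2", "M", k_close)]
    if reverse_ratio > 0:
        edges.append(("M", "L2", reverse_ratio * k_close))
    edges += [("M", "NO", k_m_decay), ("NO", GROUND, k_recovery)]
    return edges


def _build_parallel(k_K, phi, k_open_fast, k_open_slow, k_close,
                    reverse_ratio, k_m_decay, k_recovery, k_exchange=0.0):
    """K branches into L1 (fraction phi) and L1' which both feed conducting L2."""
    states = [GROUND, "K", "L1", "L1p", "L2", "M", "NO"]
    edges: list[tuple[str, str, float]] = []
    has_l1 = phi > _EPS_FRACTION
    has_l1p = phi < 1.0 - _EPS_FRACTION
    if not has_l1p and k_exchange <= 0:
        states.remove("L1p")
    if not has_l1 and k_exchange <= 0:
        states.remove("L1")
    if has_l1:
        edges.append(("K", "L1", phi * k_K))
    if has_l1p:
        edges.append(("K", "L1p", (1.0 - phi) * k_K))
    if "L1" in states:
        edges.append(("L1", "L2", k_open_fast))
    if "L1p" in states:
        edges.append(("L1p", "L2", k_open_slow))
    if k_exchange > 0 and "L1" in states and "L1p" in states:
        edges.append(("L1", "L1p", k_exchange))
        edges.append(("L1p", "L1", k_exchange))
    edges += _tail_edges(k_close, reverse_ratio, k_m_decay, k_recovery)
    return KineticScheme(
        states=tuple(states),
        rates=tuple(edges),
        initial={"K": 1.0},
        conducting={"L2": True},
    )


def _build_sequential(k_K, k_l1_decay, k_l1p_decay, k_close,
                      reverse_ratio, k_m_decay, k_recovery):
    """Strict chain K → L1 → L1' → L2 with L1' already conducting."""
    edges = [
        ("K", "L1", k_K),
        ("L1", "L1p", k_l1_decay),
        ("L1p", "L2", k_l1p_decay),
    ] + _tail_edges(k_close, reverse_ratio, k_m_decay, k_recovery)
    return KineticScheme(
        states=(GROUND, "K", "L1", "L1p", "L2", "M", "NO"),
        rates=tuple(edges),
        initial={"K": 1.0},
        conducting={"L1p": True, "L2": True},
    )


def _build_unbranched(k_K, k_open, k_close, reverse_ratio, k_m_decay, k_recovery):
    """Reduced model with a single (merged) L state before the open L2."""
    edges = [("K", "L1", k_K), ("L1", "L2", k_open)] + _tail_edges(
        k_close, reverse_ratio, k_m_decay, k_recovery
    )
    return KineticScheme(
        states=(GROUND, "K", "L1", "L2", "M", "NO"),
        rates=tuple(edges),
        initial={"K": 1.0},
        conducting={"L2": True},
    )


def _rate_param(name, default):
    return TemplateParam(name, default, 1e-3, 1e8, log_scale=True)


_TAIL_PARAMS = (
    _rate_param("k_close", _K[3]),
    TemplateParam("reverse_ratio", 0.3, 0.0, 3.0, log_scale=False),
    _rate_param("k_m_decay", _K[4]),
    _rate_param("k_recovery", _K[5]),
)

PARALLEL = SchemeTemplate(
    name="parallel",
    description=(
        "Two L1 sub-states arise in parallel from K (branching fraction phi "
        "toward the fast-opening branch) and both decay to the conducting L2."
    ),
    params=(
        _rate_param("k_K", _K[0]),
        TemplateParam("phi", 0.7, 0.02, 0.98, log_scale=False),
        _rate_param("k_open_fast", _K[1]),
        _rate_param("k_open_slow", _K[2]),
    ) + _TAIL_PARAMS,
    builder=_build_parallel,
)

PARALLEL_EXCHANGE = SchemeTemplate(
    name="parallel-exchange",
    description="As 'parallel' plus a slow symmetric L1 ⇌ L1' exchange.",
    params=PARALLEL.params + (_rate_param("k_exchange", 50.0),),
    builder=_build_parallel,
)

SEQUENTIAL = SchemeTemplate(
    name="sequential",
    description=(
        "Strictly sequential K → L1 → L1' → L2 with the pore already formed "
        "in L1' and extended in L2."
    ),
    params=(
        _rate_param("k_K", _K[0]),
        _rate_param("k_l1_decay", _K[1]),
        _rate_param("k_l1p_decay", _K[2]),
    ) + _TAIL_PARAMS,
    builder=_build_sequential,
)

UNBRANCHED = SchemeTemplate(
    name="unbranched",
    description="Reduced control model with a single merged L state (one opening step).",
    params=(
        _rate_param("k_K", _K[0]),
        _rate_param("k_open", _K[1]),
    ) + _TAIL_PARAMS,
    builder=_build_unbranched,
)

_TEMPLATES = {t.name: t for t in (PARALLEL, PARALLEL_EXCHANGE, SEQUENTIAL, UNBRANCHED)}


def l_topology_catalogue() -> tuple[SchemeTemplate, ...]:
    """Candidate kinetic topologies for the two-step formation of the open state."""
    return tuple(_TEMPLATES.values())


def get_template(name: str) -> SchemeTemplate:
    try:
        return _TEMPLATES[name]
    except KeyError:
        raise ValueError(
            f"unknown topology template {name!r}; available: {sorted(_TEMPLATES)}"
        ) from None


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def scheme_to_dict(scheme: KineticScheme) -> dict:
    return {
        "states": list(scheme.states),
        "rates": [[a, b, k] for a, b, k in scheme.rates],
        "initial": {s: v for s, v in scheme.initial.items() if v != 0.0},
        "conducting": {s: True for s, v in scheme.conducting.items() if v},
    }


def scheme_from_dict(d: Mapping) -> KineticScheme:
    return KineticScheme(
        states=tuple(d["states"]),
        rates=tuple((a, b, float(k)) for a, b, k in d["rates"]),
        initial=dict(d.get("initial", {})),
        conducting=dict(d.get("conducting", {})),
    )


def save_scheme(scheme: KineticScheme, path) -> None:
    import json

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(scheme_to_dict(scheme), fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_scheme(path) -> KineticScheme:
    import yaml

    with open(path, encoding="utf-8") as fh:
        return scheme_from_dict(yaml.safe_load(fh))
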