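"""Stage- and genotype-structured population dynamics.

State per node, for ``G`` genotypes (canonical cube ordering):

- ``E_g, L_g, P_g``: egg / larva / pupa counts per genotype;
- ``M_g``: adult males per genotype;
- ``F[gf, gm]``: mated adult females indexed by their own genotype ``gf``
  and their mate's genotype ``gm``.

Two integration routes are provided over the same vector field: an
adaptive ODE integrator (:func:`simulate_ode`) and an explicit-Euler
rollout with ``n_sub`` substeps per day (:func:`rollout_discrete`).  The
Euler update is the *shared code path* used by the decision module, so a
returned optimal schedule re-simulated here reproduces the optimizer's
internal states exactly.

Daily temperature is held piecewise constant within each day.  Releases
are start-of-day impulses added to the adult-male compartment of the
released genotype; reported day-``t`` states include day-``t`` releases,
so the day-1 state equals the initial state whenever no day-1 release is
scheduled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .errors import ConfigurationError, NumericalError, StabilityError
from .genetics import GenotypeSet, InheritanceCube
from .thermal import SpeciesParams, stage_rates_at

__all__ = [
    "StateLayout",
    "Node",
    "Network",
    "ReleaseEvent",
    "ReleaseSchedule",
    "Trajectory",
    "rhs",
    "simulate_ode",
    "rollout_discrete",
    "equilibrium_state",
    "wild_female_count",
    "wild_female_series",
    "wild_female_by_genotype",
]

_NEG_TOL = 1e-9


class StateLayout:
    """Index arithmetic for the per-node state vector of length ``4G + G**2``."""

    _cache: dict = {}

    def __new__(cls, n_genotypes: int):
        key = int(n_genotypes)
        inst = cls._cache.get(key)
        if inst is None:
            inst = super().__new__(cls)
            cls._cache[key] = inst
        return inst

    def __init__(self, n_genotypes: int):
        if hasattr(self, "n"):
            return
        G = int(n_genotypes)
        self.G = G
        self.E = slice(0, G)
        self.L = slice(G, 2 * G)
        self.P = slice(2 * G, 3 * G)
        self.M = slice(3 * G, 4 * G)
        self.F = slice(4 * G, 4 * G + G * G)
        self.n = 4 * G + G * G

    def pack(self, E, L, P, M, F) -> np.ndarray:
        x = np.empty(self.n)
        x[self.E], x[self.L], x[self.P], x[self.M] = E, L, P, M
        x[self.F] = np.asarray(F, dtype=float).reshape(-1)
        return x

    def females(self, x: np.ndarray) -> np.ndarray:
        """View of the mated-female block as ``(..., G, G)``."""
        return x[..., self.F].reshape(x.shape[:-1] + (self.G, self.G))


@dataclass(frozen=True)
class Node:
    """One well-mixed geographic patch."""

    name: str
    species: SpeciesParams
    K: float  # larval carrying capacity

    def __post_init__(self):
        if self.K <= 0:
            raise ConfigurationError(f"node {self.name!r}: carrying capacity K must be > 0")


@dataclass(frozen=True)
class Network:
    """Nodes plus adult per-day migration rates ``migration[from, to]``."""

    nodes: tuple[Node, ...]
    migration: np.ndarray = None

    def __post_init__(self):
        nodes = tuple(self.nodes)
        object.__setattr__(self, "nodes", nodes)
        N = len(nodes)
        mig = self.migration
        mig = np.zeros((N, N)) if mig is None else np.asarray(mig, dtype=float)
        if mig.shape != (N, N):
            raise ConfigurationError(f"migration matrix must be {N}x{N}")
        if np.any(np.diag(mig) != 0):
            raise ConfigurationError("migration diagonal must be zero")
        if np.any(mig < 0):
            raise ConfigurationError("migration rates must be >= 0")
        object.__setattr__(self, "migration", mig)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node_index(self, name: str) -> int:
        for i, nd in enumerate(self.nodes):
            if nd.name == name:
                return i
        raise KeyError(f"unknown node {name!r}")


@dataclass(frozen=True)
class ReleaseEvent:
    day: int
    node: str
    genotype: str
    count: float


@dataclass(frozen=True)
class ReleaseSchedule:
    """Released modified adult males: one entry per (day, node, genotype)."""

    entries: tuple[ReleaseEvent, ...]
    horizon: int

    def __post_init__(self):
        object.__setattr__(self, "entries", tuple(self.entries))
        for e in self.entries:
            if e.count < 0:
                raise ConfigurationError(f"release count must be >= 0 (day {e.day})")
            if not 1 <= e.day <= self.horizon:
                raise ConfigurationError(
                    f"release day {e.day} outside horizon 1..{self.horizon}"
                )

    @classmethod
    def empty(cls, horizon: int) -> "ReleaseSchedule":
        return cls(entries=(), horizon=horizon)

    def validate_genotypes(self, genotypes: GenotypeSet) -> None:
        modified = {genotypes.labels[i] for i in genotypes.modified_subset}
        for e in self.entries:
            if e.genotype not in modified:
                raise ConfigurationError(
                    f"release genotype {e.genotype!r} is not in the modified subset {sorted(modified)}"
                )

    def to_impulses(self, network: Network, genotypes: GenotypeSet) -> np.ndarray:
        """Dense ``(horizon, n_nodes, G)`` male-impulse array."""
        self.validate_genotypes(genotypes)
        out = np.zeros((self.horizon, network.n_nodes, len(genotypes)))
        for e in self.entries:
            out[e.day - 1, network.node_index(e.node), genotypes.index(e.genotype)] += e.count
        return out


@dataclass(frozen=True)
class Trajectory:
    """Daily states: ``states[t-1]`` has shape ``(n_nodes, layout.n)``."""

    days: np.ndarray
    states: np.ndarray
    node_names: tuple[str, ...]
    genotype_labels: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(np.diff(self.days) <= 0):
            raise ConfigurationError("trajectory days must be strictly increasing")

    @property
    def layout(self) -> StateLayout:
        return StateLayout(len(self.genotype_labels))

    @property
    def horizon(self) -> int:
        return int(self.days[-1])

    def state_at(self, day: int) -> np.ndarray:
        idx = np.searchsorted(self.days, day)
        if idx >= len(self.days) or self.days[idx] != day:
            raise IndexError(f"day {day} not in trajectory (1..{self.horizon})")
        return self.states[idx]


# ---------------------------------------------------------------------------
# Vector field


def _prepare_rates(temps: np.ndarray, network: Network):
    """Evaluate thermal responses for every (day, node).

    Returns per-day arrays ``theta (T, N, 3)``, ``mu (T, N, 4)``,
    ``nu (T, N)`` in stage order (egg, larva, pupa[, adult]).
    """
    temps = np.asarray(temps, dtype=float)
    if temps.ndim == 1:
        temps = temps[:, None]
    T_end, N = temps.shape
    if N != network.n_nodes:
        raise ConfigurationError(
            f"temperature series covers {N} nodes, network has {network.n_nodes}"
        )
    theta = np.empty((T_end, N, 3))
    mu = np.empty((T_end, N, 4))
    nu = np.empty((T_end, N))
    for n, node in enumerate(network.nodes):
        for t in range(T_end):
            r = stage_rates_at(temps[t, n], node.species)
            theta[t, n] = (r.development["egg"], r.development["larva"], r.development["pupa"])
            mu[t, n] = (
                r.mortality["egg"],
                r.mortality["larva"],
                r.mortality["pupa"],
                r.mortality["adult"],
            )
            nu[t, n] = r.fecundity
    return theta, mu, nu


def _migrate(mig: np.ndarray, A: np.ndarray, node_axis_from_end: int) -> np.ndarray:
    """Net adult migration for a per-node array ``A`` (node axis at position
    ``-node_axis_from_end``)."""
    if not mig.any():
        return 0.0
    out_rate = mig.sum(axis=1)
    if node_axis_from_end == 2:
        inflow = np.einsum("pn,...pg->...ng", mig, A)
        outflow = out_rate[:, None] * A
    else:
        inflow = np.einsum("pn,...pfg->...nfg", mig, A)
        outflow = out_rate[:, None, None] * A
    return inflow - outflow


def _deriv(x, theta, mu, nu, K, mig, cube: InheritanceCube):
    """Time derivative of ``x`` with shape ``(..., N, ns)``.

    ``theta (N,3)``, ``mu (N,4)``, ``nu (N,)``, ``K (N,)`` are the rates of
    the current day; broadcasts over any leading batch dimensions of ``x``.
    """
    G = len(cube.genotypes)
    lay = StateLayout(G)
    E, L, P, M = x[..., lay.E], x[..., lay.L], x[..., lay.P], x[..., lay.M]
    F = lay.females(x)

    th_E, th_L, th_P = theta[:, 0, None], theta[:, 1, None], theta[:, 2, None]
    mu_E, mu_L, mu_P, mu_A = mu[:, 0, None], mu[:, 1, None], mu[:, 2, None], mu[:, 3, None]

    # egg production: mothers of genotype gf mated to gm lay nu*beta_gf eggs/day,
    # distributed over offspring genotypes by the cube
    lam = nu[:, None, None] * cube.beta[:, None] * F
    egg_in = np.einsum("...fm,fmg->...g", lam, cube.probs)

    L_tot = L.sum(axis=-1, keepdims=True)
    emerg = 0.5 * th_P * P  # per-sex emergence flux from pupae

    # mating: a newly emerged female mates a male of genotype gm with
    # probability proportional to eta_gm * M_gm (0 when no males at all)
    wM = cube.eta * M
    denom = wM.sum(axis=-1, keepdims=True)
    frac = np.where(denom > 0, wM / np.where(denom > 0, denom, 1.0), 0.0)

    dE = egg_in - (th_E + mu_E) * E
    dL = th_E * E - (th_L + mu_L * (1.0 + L_tot / K[:, None])) * L
    dP = th_L * L - (th_P + mu_P) * P
    dM = cube.s_male * emerg - mu_A * M + _migrate(mig, M, 2)
    F_in = (cube.s_female * emerg)[..., :, None] * frac[..., None, :]
    dF = F_in - mu_A[..., None] * F + _migrate(mig, F, 3)

    dx = np.empty_like(x)
    dx[..., lay.E], dx[..., lay.L], dx[..., lay.P], dx[..., lay.M] = dE, dL, dP, dM
    dx[..., lay.F] = dF.reshape(dF.shape[:-2] + (G * G,))
    return dx


def _migrate_vjp(mig: np.ndarray, lam: np.ndarray, node_axis_from_end: int) -> np.ndarray:
    """Transpose of :func:`_migrate` (same out-rate, transposed inflow)."""
    if not mig.any():
        return 0.0
    out_rate = mig.sum(axis=1)
    if node_axis_from_end == 2:
        inflow = np.einsum("np,...pg->...ng", mig, lam)
        outflow = out_rate[:, None] * lam
    else:
        inflow = np.einsum("np,...pfg->...nfg", mig, lam)
        outflow = out_rate[:, None, None] * lam
    return inflow - outflow


def _deriv_vjp(x, lam, theta, mu, nu, K, mig, cube: InheritanceCube):
    """Vector-Jacobian product ``(d _deriv / d x)^T @ lam`` at state ``x``.

    Exact transpose of :func:`_deriv`; used by the decision module's
    adjoint gradient.  Shapes as in :func:`_deriv`.
    """
    G = len(cube.genotypes)
    lay = StateLayout(G)
    E, L, P, M = x[..., lay.E], x[..., lay.L], x[..., lay.P], x[..., lay.M]
    F = lay.females(x)
    lE, lL, lP, lM = lam[..., lay.E], lam[..., lay.L], lam[..., lay.P], lam[..., lay.M]
    lF = lay.females(lam)

    th_E, th_L, th_P = theta[:, 0, None], theta[:, 1, None], theta[:, 2, None]
    mu_E, mu_L, mu_P, mu_A = mu[:, 0, None], mu[:, 1, None], mu[:, 2, None], mu[:, 3, None]
    Kc = K[:, None]

    L_tot = L.sum(axis=-1, keepdims=True)
    wM = cube.eta * M
    denom = wM.sum(axis=-1, keepdims=True)
    safe = np.where(denom > 0, denom, 1.0)
    frac = np.where(denom > 0, wM / safe, 0.0)
    emerg = 0.5 * th_P * P

    gE = -(th_E + mu_E) * lE + th_E * lL
    crowd = th_L + mu_L * (1.0 + L_tot / Kc)
    gL = -crowd * lL - (mu_L / Kc) * (L * lL).sum(axis=-1, keepdims=True) + th_L * lP
    # pupae feed emergence of males and of mated females (via s and frac)
    gP = (
        -(th_P + mu_P) * lP
        + 0.5 * th_P * cube.s_male * lM
        + 0.5 * th_P * cube.s_female * (frac[..., None, :] * lF).sum(axis=-1)
    )
    # males shift the mating fractions
    A = ((cube.s_female * emerg)[..., :, None] * lF).sum(axis=-2)  # (..., N, G) over mates
    gM = -mu_A * lM + _migrate_vjp(mig, lM, 2)
    gM = gM + np.where(
        denom > 0, (cube.eta / safe) * (A - (frac * A).sum(axis=-1, keepdims=True)), 0.0
    )
    # females: egg production (through the cube) and own mortality/migration
    gF = (
        nu[:, None, None]
        * cube.beta[:, None]
        * np.einsum("...g,fmg->...fm", lE, cube.probs)
        - mu_A[..., None] * lF
        + _migrate_vjp(mig, lF, 3)
    )

    g = np.empty_like(x)
    g[..., lay.E], g[..., lay.L], g[..., lay.P], g[..., lay.M] = gE, gL, gP, gM
    g[..., lay.F] = gF.reshape(gF.shape[:-2] + (G * G,))
    return g


def rhs(state: np.ndarray, temps_now, network: Network, cube: InheritanceCube) -> np.ndarray:
    """Derivative of the full network state at instantaneous temperatures.

    ``state`` has shape ``(..., n_nodes, 4G + G**2)``; ``temps_now`` is one
    temperature per node (scalar accepted for a single node).
    """
    temps_now = np.atleast_1d(np.asarray(temps_now, dtype=float))
    theta, mu, nu = _prepare_rates(temps_now[None, :], network)
    K = np.array([nd.K for nd in network.nodes])
    return _deriv(state, theta[0], mu[0], nu[0], K, network.migration, cube)


# ---------------------------------------------------------------------------
# Discrete rollout (shared with the decision model)


def _euler_day(x, theta, mu, nu, K, mig, cube, n_sub: int):
    dt = 1.0 / n_sub
    for _ in range(n_sub):
        x = x + dt * _deriv(x, theta, mu, nu, K, mig, cube)
    return x


def _euler_day_record(x, theta, mu, nu, K, mig, cube, n_sub: int):
    """As :func:`_euler_day` but also returns the substep input states."""
    dt = 1.0 / n_sub
    subs = np.empty((n_sub,) + x.shape)
    for s in range(n_sub):
        subs[s] = x
        x = x + dt * _deriv(x, theta, mu, nu, K, mig, cube)
    return x, subs


def rollout_core(
    x0: np.ndarray,
    theta_all: np.ndarray,
    mu_all: np.ndarray,
    nu_all: np.ndarray,
    K: np.ndarray,
    mig: np.ndarray,
    cube: InheritanceCube,
    impulses: np.ndarray,
    n_sub: int,
    check_negative: bool = True,
):
    """Explicit-Euler rollout over the full horizon.

    ``x0``: ``(..., N, ns)``; ``impulses``: ``(T, N, G)`` or batched
    ``(..., T, N, G)`` male releases.  Returns daily states
    ``(..., T, N, ns)`` (day ``t`` recorded after applying its release).
    This function is the single source of the update expressions used by
    both :func:`rollout_discrete` and the NLP constraint substitution in
    the decision module.
    """
    if n_sub < 1:
        raise ConfigurationError("n_sub must be >= 1")
    T_end = theta_all.shape[0]
    G = len(cube.genotypes)
    lay = StateLayout(G)
    x = np.array(x0, dtype=float)
    batched_imp = impulses.ndim > 3
    out = np.empty(x.shape[:-2] + (T_end,) + x.shape[-2:])
    for t in range(T_end):
        imp = impulses[..., t, :, :] if batched_imp else impulses[t]
        x[..., lay.M] = x[..., lay.M] + imp
        out[..., t, :, :] = x
        if check_negative and x.min() < -_NEG_TOL:
            raise StabilityError(
                f"state went negative on day {t + 1} "
                f"(min {x.min():.3e}); increase n_sub (currently {n_sub})"
            )
        if t < T_end - 1:
            x = _euler_day(x, theta_all[t], mu_all[t], nu_all[t], K, mig, cube, n_sub)
    return out


def rollout_discrete(
    init: np.ndarray,
    temps: np.ndarray,
    network: Network,
    cube: InheritanceCube,
    schedule: ReleaseSchedule | None = None,
    n_sub: int = 4,
) -> Trajectory:
    """Explicit-Euler twin of :func:`simulate_ode` (step ``1/n_sub`` day)."""
    temps = np.asarray(temps, dtype=float)
    if temps.ndim == 1:
        temps = temps[:, None]
    T_end = temps.shape[0]
    schedule = schedule or ReleaseSchedule.empty(T_end)
    if schedule.horizon != T_end:
        raise ConfigurationError(
            f"schedule horizon {schedule.horizon} != temperature horizon {T_end}"
        )
    theta, mu, nu = _prepare_rates(temps, network)
    K = np.array([nd.K for nd in network.nodes])
    impulses = schedule.to_impulses(network, cube.genotypes)
    x0 = np.asarray(init, dtype=float).reshape(network.n_nodes, StateLayout(len(cube.genotypes)).n)
    states = rollout_core(x0, theta, mu, nu, K, network.migration, cube, impulses, n_sub)
    return Trajectory(
        days=np.arange(1, T_end + 1),
        states=states,
        node_names=tuple(nd.name for nd in network.nodes),
        genotype_labels=tuple(cube.genotypes.labels),
        meta={"mode": "discrete", "n_sub": n_sub},
    )


# ---------------------------------------------------------------------------
# Adaptive ODE simulation


def simulate_ode(
    init: np.ndarray,
    temps: np.ndarray,
    network: Network,
    cube: InheritanceCube,
    schedule: ReleaseSchedule | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> Trajectory:
    """Adaptive integration with daily piecewise-constant temperature.

    Each release is an impulse on the adult-male compartment at the start
    of its day; states are reported at integer days (post-impulse) and
    clamped to zero below ``-1e-9``.
    """
    temps = np.asarray(temps, dtype=float)
    if temps.ndim == 1:
        temps = temps[:, None]
    T_end = temps.shape[0]
    schedule = schedule or ReleaseSchedule.empty(T_end)
    if schedule.horizon != T_end:
        raise ConfigurationError(
            f"schedule horizon {schedule.horizon} != temperature horizon {T_end}"
        )
    theta, mu, nu = _prepare_rates(temps, network)
    K = np.array([nd.K for nd in network.nodes])
    G = len(cube.genotypes)
    lay = StateLayout(G)
    N = network.n_nodes
    impulses = schedule.to_impulses(network, cube.genotypes)
    mig = network.migration

    x = np.asarray(init, dtype=float).reshape(N, lay.n).copy()
    states = np.empty((T_end, N, lay.n))
    for t in range(T_end):
        x[:, lay.M] += impulses[t]
        states[t] = x
        if t == T_end - 1:
            break

        def f(_, y, t=t):
            return _deriv(y.reshape(N, lay.n), theta[t], mu[t], nu[t], K, mig, cube).ravel()

        sol = solve_ivp(f, (0.0, 1.0), x.ravel(), method="RK45", rtol=rtol, atol=atol)
        if not sol.success:
            raise NumericalError(f"ODE integration failed on day {t + 1}: {sol.message}")
        x = sol.y[:, -1].reshape(N, lay.n)

    if states.min() < -_NEG_TOL:
        raise NumericalError(
            f"ODE states fell below the negativity tolerance (min {states.min():.3e})"
        )
    np.clip(states, 0.0, None, out=states)
    return Trajectory(
        days=np.arange(1, T_end + 1),
        states=states,
        node_names=tuple(nd.name for nd in network.nodes),
        genotype_labels=tuple(cube.genotypes.labels),
        meta={"mode": "ode", "rtol": rtol, "atol": atol},
    )


# ---------------------------------------------------------------------------
# Equilibrium


def equilibrium_state(
    species: SpeciesParams,
    cube: InheritanceCube,
    K: float,
    T_ref: float,
    residual_tol: float = 1e-8,
) -> np.ndarray:
    """Steady state of the single-node vector field at constant ``T_ref``.

    All mass sits on the first wild genotype (a closed-form balance gives
    the seed, then a root solve polishes it on the wild-compartment
    support).  Returns the zero state with a warning when the net
    reproduction at ``T_ref`` cannot sustain the population.
    """
    if K <= 0:
        raise ConfigurationError("carrying capacity K must be > 0")
    G = len(cube.genotypes)
    lay = StateLayout(G)
    wild = cube.genotypes.wild_subset
    if not wild:
        raise ConfigurationError("cube has no wild genotype")
    w = wild[0]
    r = stage_rates_at(T_ref, species)
    th_E, th_L, th_P = (r.development[s] for s in ("egg", "larva", "pupa"))
    mu_E, mu_L, mu_P, mu_A = (r.mortality[s] for s in ("egg", "larva", "pupa", "adult"))
    nu = r.fecundity
    if mu_A <= 0 or mu_L <= 0:
        raise ConfigurationError("adult and larval mortality must be > 0 at T_ref")

    growth = (
        nu * cube.beta[w] * cube.s_female[w] * th_E * th_L * th_P
        / (2.0 * mu_A * (th_E + mu_E) * (th_P + mu_P))
        if (th_E + mu_E) > 0 and (th_P + mu_P) > 0
        else 0.0
    )
    x = np.zeros(lay.n)
    if growth <= th_L + mu_L:
        warnings.warn(
            f"non-viable parameters at T_ref={T_ref} (net reproduction below "
            "replacement); returning the zero state",
            stacklevel=2,
        )
        return x

    L = K * (growth - th_L - mu_L) / mu_L
    P = th_L * L / (th_P + mu_P)
    F = cube.s_female[w] * th_P * P / (2.0 * mu_A)
    M = cube.s_male[w] * th_P * P / (2.0 * mu_A)
    E = nu * cube.beta[w] * F / (th_E + mu_E)
    x[lay.E.start + w] = E
    x[lay.L.start + w] = L
    x[lay.P.start + w] = P
    x[lay.M.start + w] = M
    x[lay.F.start + w * G + w] = F

    node = Node(name="eq", species=species, K=K)
    net = Network(nodes=(node,))
    support = [lay.E.start + w, lay.L.start + w, lay.P.start + w, lay.M.start + w]
    support += [lay.F.start + wf * G + wm for wf in wild for wm in wild]
    support = np.array(support)

    def resid(v):
        y = x.copy()
        y[support] = v
        return rhs(y[None, :], T_ref, net, cube)[0, support]

    sol = root(resid, x[support], method="hybr", tol=1e-12)
    y = x.copy()
    y[support] = sol.x
    res = np.linalg.norm(rhs(y[None, :], T_ref, net, cube))
    scale = np.linalg.norm(y)
    if res > residual_tol * max(scale, 1.0):
        raise NumericalError(
            f"equilibrium solve did not converge: residual {res:.3e} vs "
            f"tolerance {residual_tol * max(scale, 1.0):.3e}"
        )
    return np.clip(y, 0.0, None)


# ---------------------------------------------------------------------------
# Objective-facing summaries


def wild_female_by_genotype(traj: Trajectory, genotypes: GenotypeSet) -> np.ndarray:
    """``(T, n_wild)`` wild females per own-genotype, summed over mates and nodes."""
    lay = traj.layout
    G = lay.G
    F = traj.states[..., lay.F].reshape(traj.states.shape[0], -1, G, G)
    wild = list(genotypes.wild_subset)
    return F[:, :, wild, :].sum(axis=(1, 3))


def wild_female_series(traj: Trajectory, genotypes: GenotypeSet) -> np.ndarray:
    """Total wild adult females per day (summed over genotype, mate, node)."""
    return wild_female_by_genotype(traj, genotypes).sum(axis=1)


def wild_female_count(traj: Trajectory, t: int, genotypes: GenotypeSet) -> float:
    """Wild adult females on day ``t`` — females counted by their own genotype."""
    if not 1 <= t <= traj.horizon:
        raise IndexError(f"day {t} outside horizon 1..{traj.horizon}")
    return float(wild_female_series(traj, genotypes)[t - 1])
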