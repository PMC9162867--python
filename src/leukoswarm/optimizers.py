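"""Five population metaheuristics behind one box-bounded optimize() call.

African Buffalo Optimization (ABO), Artificial Bee Colony (ABC),
Cockroach Swarm Optimization (CSO), Imperialist Competitive Algorithm
(ICA) and Social Spider Optimization (SSO), each implemented from its
published update rules over real vectors in a box.  Shared contracts:

* a single seeded ``numpy`` Generator drives every random draw, so
  identical (objective, config) pairs give bit-identical histories;
* positions are clipped to the box after every move;
* the best-ever solution is tracked outside the population (elitism), so
  the recorded history is monotone in the optimization direction.

Internally everything minimizes a cost; maximization negates the user
fitness and un-negates reported values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ObjectiveSpec",
    "OptimizerConfig",
    "OptimizationResult",
    "ABOParams",
    "ABCParams",
    "CSOParams",
    "ICAParams",
    "SSOParams",
    "optimize",
    "ALGORITHMS",
]

ALGORITHMS = ("ABO", "ABC", "CSO", "ICA", "SSO")


@dataclass
class ObjectiveSpec:
    """Fitness function over a box [lower, upper]^D."""

    fitness: callable
    lower: np.ndarray
    upper: np.ndarray
    direction: str = "minimize"  # minimize | maximize

    def __post_init__(self):
        self.lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        self.upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if self.lower.shape != self.upper.shape or (self.lower >= self.upper).any():
            raise ValueError("need lower < upper elementwise")
        if self.direction not in ("minimize", "maximize"):
            raise ValueError(f"bad direction {self.direction!r}")

    @property
    def dim(self) -> int:
        return len(self.lower)


@dataclass
class ABOParams:
    lq1: float = 0.6  # herd-best learning factor
    lq2: float = 0.4  # personal-best learning factor
    jitter: str = "sign"  # "sign": +-0.5 equiprobable; "uniform": U(-0.5, 0.5)
    restart_patience: int = 20  # stagnant iterations before herd restart


@dataclass
class ABCParams:
    employed_frac: float = 0.6
    onlooker_frac: float = 0.5
    n_scouts: int = 1
    trial_limit: int | None = None  # default 0.5 * D * N
    z: float = 1.0  # neighborhood half-width for the phi draw


@dataclass
class CSOParams:
    step: float = 2.0  # chase coefficient; >1 lets moves overshoot the target
    visual: float | None = None  # Euclidean radius; default 0.15 * |range|
    disperse_period: int = 10
    disperse_scale: float = 0.25  # random step, fraction of box range
    ruthless_mode: str = "replace_with_best"  # or "zero"


@dataclass
class ICAParams:
    n_imperialists: int = 4
    c: float = 1.5  # assimilation coefficient in (1, 2)
    phi: float = math.pi / 8  # deviation bound (radians)
    zeta: float = 0.1  # colony-cost weight in empire total cost
    revolution_rate: float = 0.1


@dataclass
class SSOParams:
    female_frac: float | None = None  # None -> drawn U(0.6, 0.7) at init
    P: float = 0.7  # attraction probability in the female move
    mating_radius: float | None = None  # default mean(range) / 2


@dataclass
class OptimizerConfig:
    algorithm: str = "SSO"
    population: int = 30
    iterations: int = 100
    seed: int = 0
    abo: ABOParams = field(default_factory=ABOParams)
    abc: ABCParams = field(default_factory=ABCParams)
    cso: CSOParams = field(default_factory=CSOParams)
    ica: ICAParams = field(default_factory=ICAParams)
    sso: SSOParams = field(default_factory=SSOParams)

    def validate(self):
        if self.algorithm.upper() not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
            )
        if self.population < 4:
            raise ValueError("population must be >= 4")
        if not (1.0 < self.ica.c < 2.0):
            raise ValueError("ICA c must be in (1, 2)")
        if not (0.0 < self.ica.zeta < 1.0):
            raise ValueError("ICA zeta must be in (0, 1)")
        if self.ica.n_imperialists >= self.population:
            raise ValueError("n_imperialists must be < population")
        if self.cso.visual is not None and self.cso.visual <= 0:
            raise ValueError("CSO visual must be > 0")


@dataclass
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray  # best-so-far fitness after each iteration (user direction)
    evaluations: int
    seed: int


class _Tracker:
    """Cost bookkeeping: counts evaluations, keeps the best-ever solution."""

    def __init__(self, obj: ObjectiveSpec):
        self.obj = obj
        self.sign = 1.0 if obj.direction == "minimize" else -1.0
        self.evaluations = 0
        self.best_cost = np.inf
        self.best_pos: np.ndarray | None = None
        self.history: list[float] = []

    def cost(self, x: np.ndarray) -> float:
        self.evaluations += 1
        c = self.sign * float(self.obj.fitness(x))
        if c < self.best_cost:
            self.best_cost = c
            self.best_pos = x.copy()
        return c

    def cost_many(self, X: np.ndarray) -> np.ndarray:
        return np.array([self.cost(x) for x in X])

    def record(self):
        self.history.append(self.sign * self.best_cost)

    def result(self, seed: int) -> OptimizationResult:
        return OptimizationResult(
            best_position=self.best_pos.copy(),
            best_fitness=self.sign * self.best_cost,
            history=np.array(self.history),
            evaluations=self.evaluations,
            seed=seed,
        )


def _clip(X: np.ndarray, obj: ObjectiveSpec) -> np.ndarray:
    return np.clip(X, obj.lower, obj.upper)


def _init_uniform(n: int, obj: ObjectiveSpec, rng) -> np.ndarray:
    return obj.lower + rng.random((n, obj.dim)) * (obj.upper - obj.lower)


# ---------------------------------------------------------------------------
# ABO
# ---------------------------------------------------------------------------


def abo_update(v, f, bq_pos, bz_pos, lq1, lq2, jitter):
    """One herd move: new exploitation f' and location v' (pure arithmetic).

    f' = f + lq1 (bz - v) + lq2 (bq - v);  v' = v + f' + jitter, where
    ``jitter`` is the +-0.5 term (one value per buffalo, broadcast, or a
    full matrix for the uniform variant).
    """
    f_new = f + lq1 * (bz_pos - v) + lq2 * (bq_pos - v)
    v_new = v + f_new + jitter
    return f_new, v_new


def _run_abo(obj, cfg, rng, tracker):
    p = cfg.abo
    N, D = cfg.population, obj.dim
    v = _init_uniform(N, obj, rng)
    f = np.zeros((N, D))
    costs = tracker.cost_many(v)
    bq_pos, bq_cost = v.copy(), costs.copy()
    stagnant = 0
    for _ in range(cfg.iterations):
        if p.jitter == "sign":
            jit = np.where(rng.random(N) < 0.5, -0.5, 0.5)[:, None]
        else:
            jit = rng.uniform(-0.5, 0.5, size=(N, D))
        prev_best = tracker.best_cost
        f, v = abo_update(v, f, bq_pos, tracker.best_pos, p.lq1, p.lq2, jit)
        v = _clip(v, obj)
        costs = tracker.cost_many(v)
        better = costs < bq_cost
        bq_pos[better], bq_cost[better] = v[better], costs[better]
        if tracker.best_cost < prev_best:
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= p.restart_patience:  # herd restart, best-ever kept
                v = _init_uniform(N, obj, rng)
                f = np.zeros((N, D))
                costs = tracker.cost_many(v)
                bq_pos, bq_cost = v.copy(), costs.copy()
                stagnant = 0
        tracker.record()


# ---------------------------------------------------------------------------
# ABC
# ---------------------------------------------------------------------------


def abc_neighbor(y_n, y_m, phi):
    """Candidate food source: current source perturbed toward/away a partner."""
    return y_n + phi * (y_n - y_m)


def _abc_selection_probs(costs: np.ndarray) -> np.ndarray:
    """Nectar-proportional probabilities from min-shifted (negated) costs."""
    nectar = costs.max() - costs
    total = nectar.sum()
    if total <= 0:
        return np.full(len(costs), 1.0 / len(costs))
    return nectar / total


def _run_abc(obj, cfg, rng, tracker):
    p = cfg.abc
    S, D = cfg.population, obj.dim
    limit = p.trial_limit if p.trial_limit is not None else max(1, int(0.5 * D * S))
    pos = _init_uniform(S, obj, rng)
    costs = tracker.cost_many(pos)
    trials = np.zeros(S, dtype=int)
    n_employed = max(1, round(p.employed_frac * S))
    n_onlooker = max(1, round(p.onlooker_frac * S))

    def try_neighbor(i):
        m = int(rng.integers(S - 1))
        m = m if m < i else m + 1
        phi = rng.uniform(-p.z, p.z, size=D)
        cand = _clip(abc_neighbor(pos[i], pos[m], phi), obj)
        c = tracker.cost(cand)
        if c < costs[i]:
            pos[i], costs[i], trials[i] = cand, c, 0
        else:
            trials[i] += 1

    for _ in range(cfg.iterations):
        for i in rng.permutation(S)[:n_employed]:  # employed phase
            try_neighbor(int(i))
        probs = _abc_selection_probs(costs)  # onlooker phase
        for i in rng.choice(S, size=n_onlooker, p=probs):
            try_neighbor(int(i))
        exhausted = np.flatnonzero(trials > limit)  # scout phase
        if len(exhausted):
            worst = exhausted[np.argsort(-trials[exhausted])][: p.n_scouts]
            for i in worst:
                pos[i] = _init_uniform(1, obj, rng)[0]
                costs[i] = tracker.cost(pos[i])
                trials[i] = 0
        tracker.record()


# ---------------------------------------------------------------------------
# CSO
# ---------------------------------------------------------------------------


def cso_chase(a, target, step, rand):
    """Chase-swarming move toward a local/global optimum."""
    return a + step * rand * (target - a)


def _run_cso(obj, cfg, rng, tracker):
    p = cfg.cso
    N, D = cfg.population, obj.dim
    rng_range = obj.upper - obj.lower
    visual = p.visual if p.visual is not None else 0.15 * float(np.linalg.norm(rng_range))
    pos = _init_uniform(N, obj, rng)
    costs = tracker.cost_many(pos)
    for it in range(1, cfg.iterations + 1):
        # chase swarming: local best within visual range, or global best
        d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
        within = d2 <= visual**2
        for j in range(N):
            neigh = np.flatnonzero(within[j])
            local = int(neigh[np.argmin(costs[neigh])])
            target = tracker.best_pos if local == j else pos[local]
            pos[j] = cso_chase(pos[j], target, p.step, rng.random())
        pos = _clip(pos, obj)
        costs = tracker.cost_many(pos)
        if p.disperse_period and it % p.disperse_period == 0:  # dispersing
            pos = _clip(
                pos + rng.uniform(-1, 1, size=(N, D)) * p.disperse_scale * rng_range,
                obj,
            )
            costs = tracker.cost_many(pos)
        y = int(rng.integers(N))  # ruthless behaviour
        if p.ruthless_mode == "replace_with_best":
            pos[y] = tracker.best_pos
            costs[y] = tracker.best_cost
        else:
            pos[y] = _clip(np.zeros(D), obj)
            costs[y] = tracker.cost(pos[y])
        tracker.record()


# ---------------------------------------------------------------------------
# ICA
# ---------------------------------------------------------------------------


def ica_initial_powers(imp_costs: np.ndarray) -> np.ndarray:
    """Imperialist power P_q from normalized costs Z_q = max t - t_q."""
    z = imp_costs.max() - imp_costs
    if z.sum() <= 0:
        return np.full(len(imp_costs), 1.0 / len(imp_costs))
    return z / z.sum()


def ica_empire_powers(imp_costs, colony_mean_costs, zeta):
    """Total cost AT_q, its normalization NAT_q, and power EP_q per empire.

    AT_q = t_q + zeta * mean(colony costs); NAT_q = max_s AT_s - AT_q;
    EP_q = NAT_q / sum NAT (uniform when all empires tie).
    """
    at = np.asarray(imp_costs, float) + zeta * np.asarray(colony_mean_costs, float)
    nat = at.max() - at
    ep = np.full(len(at), 1.0 / len(at)) if nat.sum() <= 0 else nat / nat.sum()
    return at, nat, ep


class _Empire:
    __slots__ = ("imp_pos", "imp_cost", "col_pos", "col_cost")

    def __init__(self, imp_pos, imp_cost, col_pos, col_cost):
        self.imp_pos, self.imp_cost = imp_pos, imp_cost
        self.col_pos, self.col_cost = col_pos, col_cost


def _run_ica(obj, cfg, rng, tracker):
    p = cfg.ica
    N, D = cfg.population, obj.dim
    pos = _init_uniform(N, obj, rng)
    costs = tracker.cost_many(pos)
    order = np.argsort(costs, kind="stable")
    M = p.n_imperialists
    imp_idx, col_idx = order[:M], order[M:]
    powers = ica_initial_powers(costs[imp_idx])
    n_col = len(col_idx)
    counts = np.floor(powers * n_col).astype(int)  # round{P_q M_col}, drift-safe
    frac = powers * n_col - counts
    for q in np.argsort(-frac, kind="stable")[: n_col - counts.sum()]:
        counts[q] += 1
    empires: list[_Empire] = []
    start = 0
    shuffled = rng.permutation(col_idx)
    for q in range(M):
        mine = shuffled[start : start + counts[q]]
        start += counts[q]
        empires.append(
            _Empire(pos[imp_idx[q]].copy(), float(costs[imp_idx[q]]),
                    pos[mine].copy(), costs[mine].copy())
        )

    for _ in range(cfg.iterations):
        for emp in empires:
            for ci in range(len(emp.col_cost)):  # assimilation
                diff = emp.imp_pos - emp.col_pos[ci]
                dist = float(np.linalg.norm(diff))
                if dist > 0:
                    eps = rng.uniform(0.0, p.c * dist)
                    theta = rng.uniform(-p.phi, p.phi, size=D)
                    move = eps * diff / dist + eps * np.tan(theta) / max(1.0, D**0.5)
                    emp.col_pos[ci] = _clip(emp.col_pos[ci] + move, obj)
                if rng.random() < p.revolution_rate:  # revolution
                    emp.col_pos[ci] = _init_uniform(1, obj, rng)[0]
                emp.col_cost[ci] = tracker.cost(emp.col_pos[ci])
            if len(emp.col_cost):  # colony/imperialist exchange
                b = int(np.argmin(emp.col_cost))
                if emp.col_cost[b] < emp.imp_cost:
                    emp.col_pos[b], emp.imp_pos = emp.imp_pos.copy(), emp.col_pos[b].copy()
                    emp.col_cost[b], emp.imp_cost = emp.imp_cost, float(emp.col_cost[b])
        if len(empires) > 1:  # imperialist competition
            means = [e.col_cost.mean() if len(e.col_cost) else 0.0 for e in empires]
            at, _, ep = ica_empire_powers(
                np.array([e.imp_cost for e in empires]), np.array(means), p.zeta
            )
            weakest = int(np.argmax(at))
            d_vec = ep - rng.random(len(empires))
            d_vec[weakest] = -np.inf
            winner = int(np.argmax(d_vec))
            weak = empires[weakest]
            win = empires[winner]
            if len(weak.col_cost):
                wc = int(np.argmax(weak.col_cost))
                win.col_pos = np.vstack([win.col_pos, weak.col_pos[wc]])
                win.col_cost = np.append(win.col_cost, weak.col_cost[wc])
                weak.col_pos = np.delete(weak.col_pos, wc, axis=0)
                weak.col_cost = np.delete(weak.col_cost, wc)
            else:  # empty empire collapses into the winner
                win.col_pos = np.vstack([win.col_pos, weak.imp_pos])
                win.col_cost = np.append(win.col_cost, weak.imp_cost)
                empires.pop(weakest)
        tracker.record()


# ---------------------------------------------------------------------------
# SSO
# ---------------------------------------------------------------------------


def sso_weights(costs: np.ndarray) -> np.ndarray:
    """Fitness weights in [0, 1]; best spider -> 1.  Flat landscape -> all 1."""
    worst, best = costs.max(), costs.min()
    if worst == best:
        return np.ones(len(costs))
    return (worst - costs) / (worst - best)


def sso_vibration(w_b: float, d: float) -> float:
    """Vibration perceived from spider b at distance d: w_b * exp(-d^2)."""
    return float(w_b * math.exp(-(d**2)))


def sso_female_move(fa, a_n, v_n, a_h, v_h, alpha, beta, delta, rand, attract):
    """Female position update (attraction branch when ``attract``)."""
    sgn = 1.0 if attract else -1.0
    return (
        fa
        + sgn * alpha * v_n * (a_n - fa)
        + sgn * beta * v_h * (a_h - fa)
        + delta * (rand - 0.5)
    )


def _run_sso(obj, cfg, rng, tracker):
    p = cfg.sso
    N, D = cfg.population, obj.dim
    frac = p.female_frac if p.female_frac is not None else rng.uniform(0.6, 0.7)
    n_f = max(1, min(N - 1, round(frac * N)))
    radius = (
        p.mating_radius
        if p.mating_radius is not None
        else float((obj.upper - obj.lower).mean()) / 2.0
    )
    pos = _init_uniform(N, obj, rng)
    costs = tracker.cost_many(pos)
    females = np.arange(n_f)
    males = np.arange(n_f, N)
    for _ in range(cfg.iterations):
        w = sso_weights(costs)
        dist = np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2))
        h = int(np.argmin(costs))
        new_pos = pos.copy()
        for c in females:
            heavier = np.flatnonzero(w > w[c])
            if len(heavier):
                nrst = int(heavier[np.argmin(dist[c, heavier])])
            else:
                nrst = h
            v_n = sso_vibration(w[nrst], dist[c, nrst])
            v_h = sso_vibration(w[h], dist[c, h])
            alpha, beta, delta, r = rng.random(4)
            attract = rng.random() < p.P
            new_pos[c] = sso_female_move(
                pos[c], pos[nrst], v_n, pos[h], v_h, alpha, beta, delta, r, attract
            )
        w_males = w[males]
        med = float(np.median(w_males))
        mean_male = (pos[males] * w_males[:, None]).sum(axis=0) / max(
            w_males.sum(), 1e-300
        )
        for c in males:
            alpha, delta, r = rng.random(3)
            if w[c] >= med:  # dominant: court the nearest female
                nf = int(females[np.argmin(dist[c, females])])
                v_f = sso_vibration(w[nf], dist[c, nf])
                new_pos[c] = pos[c] + alpha * v_f * (pos[nf] - pos[c]) + delta * (r - 0.5)
            else:  # non-dominant: drift to the weighted male centre
                new_pos[c] = pos[c] + alpha * (mean_male - pos[c])
        pos = _clip(new_pos, obj)
        costs = tracker.cost_many(pos)
        w = sso_weights(costs)
        dist = np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2))
        med = float(np.median(w[males]))
        for c in males:  # mating within the radius
            if w[c] < med:
                continue
            near_f = females[dist[c, females] < radius]
            if not len(near_f):
                continue
            parents = np.concatenate([[c], near_f])
            pw = w[parents]
            probs = pw / pw.sum() if pw.sum() > 0 else np.full(len(parents), 1 / len(parents))
            pick = rng.choice(len(parents), size=D, p=probs)
            child = pos[parents[pick], np.arange(D)]
            child_cost = tracker.cost(child)
            worst = int(np.argmax(costs))
            if child_cost < costs[worst]:
                pos[worst], costs[worst] = child, child_cost
        tracker.record()


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

_RUNNERS = {
    "ABO": _run_abo,
    "ABC": _run_abc,
    "CSO": _run_cso,
    "ICA": _run_ica,
    "SSO": _run_sso,
}


def optimize(obj: ObjectiveSpec, cfg: OptimizerConfig) -> OptimizationResult:
    """Run the configured algorithm; deterministic for a fixed seed.

    With ``iterations=0`` the result is the best of the random initial
    population.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    tracker = _Tracker(obj)
    algo = cfg.algorithm.upper()
    if cfg.iterations == 0:
        init = _init_uniform(cfg.population, obj, rng)
        tracker.cost_many(init)
        tracker.record()
    else:
        _RUNNERS[algo](obj, cfg, rng, tracker)
    return tracker.result(cfg.seed)
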