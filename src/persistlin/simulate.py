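"""Stochastic lineage simulators for cell-fate models M0-M3.

All four models share the same pre-drug engine: a discrete-time (step dt)
age-structured branching process in which each live cell divides in a step
with probability 1 - exp(-h(age) dt), where h is the hazard of the pre-drug
intermitotic-time (IMT) EMG.  Models M1/M3 additionally let every live cell
switch between a drug-sensitive state S' and a pre-persister state P' with
per-step probabilities k*dt (daughters inherit the mother's state at
division).  The models differ after drug addition:

M0  age-structured competition: division and death hazards (from the
    post-drug IMT and AT EMGs) race in every time step; the event type is
    chosen by the hazard ratio h_m / (h_m + h_a).
M1  pure pre-drug determination: S' cells at drug time die with certainty;
    P' cells divide or survive-without-dividing; daughters re-draw from the
    same P' rules.
M2  pure drug-induced fates: every cell is statistically identical and
    draws a fate (die / divide / stay) i.i.d. from a concentration-dependent
    probability triple.
M3  combination: fates are drawn from a fate matrix F conditioned on the
    cell's state at drug time; daughters of post-drug divisions inherit that
    state and re-draw from F.  Waiting times to an assigned fate are drawn
    directly from the post-drug IMT (division) or AT (death) EMG — with a
    single non-competing hazard this is exactly the dt -> 0 limit of the
    stepping scheme.

"Stay" cells are censored at t_end and count downstream as persisters.
Founder lineage labels double as barcodes and propagate unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .emg import EMGParams, emg_hazard
from .growth import _emg_horizon
from .lineage import CellRecord, ExperimentConfig, ExperimentTable

__all__ = [
    "TransitionMatrix",
    "FateMatrix",
    "SimConfig",
    "SimResult",
    "simulate",
    "simulate_M0",
    "simulate_M1",
    "simulate_M2",
    "simulate_M3",
    "stationary_age_sample",
]


def stationary_age_sample(imt: EMGParams, n: int, rng) -> np.ndarray:
    """Founder ages from the stationary age distribution of an
    exponentially growing age-structured population, density proportional
    to exp(-gamma a) S(a) with gamma the Euler-Lotka rate.

    Cells plated from a growing culture are caught mid-cycle, so founders
    seeded this way begin dividing immediately rather than after one full
    intermitotic time.
    """
    from .emg import emg_sf
    from .growth import HazardModel, euler_lotka_rate

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    gamma = euler_lotka_rate(HazardModel.from_emg(imt)).gamma
    hi = imt.mean + 6.0 * np.sqrt(imt.variance)
    a = np.linspace(0.0, hi, 2000)
    w = np.exp(-gamma * a) * emg_sf(a, imt)
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    return np.interp(rng.random(n), cdf, a)

S_PRIME, P_PRIME = 0, 1
STATE_NAMES = {S_PRIME: "S'", P_PRIME: "P'"}
FATE_NAMES = ("die", "divide", "stay")


@dataclass(frozen=True)
class TransitionMatrix:
    """Per-hour switching rates between S' and P' before drug."""

    k_sp: float  # S' -> P'
    k_ps: float  # P' -> S'

    def __post_init__(self) -> None:
        if self.k_sp < 0 or self.k_ps < 0:
            raise ValueError("transition rates must be >= 0")

    @property
    def stationary_p(self) -> float:
        """Stationary P' fraction k_sp / (k_sp + k_ps); 0.5 if both zero."""
        tot = self.k_sp + self.k_ps
        return 0.5 if tot == 0 else self.k_sp / tot


@dataclass(frozen=True)
class FateMatrix:
    """State-conditioned fate probabilities (die, divide, stay)."""

    s_prime: tuple[float, float, float]
    p_prime: tuple[float, float, float]

    def __post_init__(self) -> None:
        for name, row in (("s_prime", self.s_prime), ("p_prime", self.p_prime)):
            r = np.asarray(row, dtype=float)
            if r.min() < 0 or r.max() > 1 or abs(r.sum() - 1.0) > 1e-9:
                raise ValueError(f"fate row {name} must be probabilities summing to 1")

    def row(self, state: int) -> np.ndarray:
        return np.asarray(self.s_prime if state == S_PRIME else self.p_prime)


@dataclass
class SimConfig:
    """Full parameterization of a simulated drug-treatment experiment."""

    model: str = "M3"
    n_founders: int = 49
    t_drug: float = 48.0
    t_end: float = 120.0
    dt: float = 0.05
    pre_imt: EMGParams = field(default_factory=lambda: EMGParams(13.0, 2.5, 0.15))
    post_imt: EMGParams = field(default_factory=lambda: EMGParams(20.0, 5.0, 0.10))
    post_at: EMGParams = field(default_factory=lambda: EMGParams(10.0, 4.0, 0.12))
    transitions: TransitionMatrix = field(
        default_factory=lambda: TransitionMatrix(9e-3, 9e-3)
    )
    fates: FateMatrix = field(
        default_factory=lambda: FateMatrix((0.9125, 0.05, 0.0375), (0.35, 0.10, 0.55))
    )
    m2_fates: tuple[float, float, float] = (0.64, 0.10, 0.26)
    # None => all founders age 0; 'stationary' => fresh draws per run from
    # the stationary renewal age distribution of pre_imt; else an array
    initial_ages: np.ndarray | str | None = None
    initial_p_fraction: float | None = None  # None => stationary of T
    tracking_mode: str = "full_tree"
    snapshot_round: bool = False
    snapshot_interval: float = 0.5
    concentration_label: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model not in ("M0", "M1", "M2", "M3"):
            raise ValueError(f"unknown model {self.model!r}")
        if not (0 < self.t_drug < self.t_end):
            raise ValueError("require 0 < t_drug < t_end")
        means = [self.pre_imt.mean, self.post_imt.mean, self.post_at.mean]
        m = min(means)
        if self.dt >= m:
            raise ValueError(f"dt={self.dt} >= shortest mean event time {m:.3g}")
        if self.dt >= m / 5.0:
            warnings.warn(
                f"dt={self.dt} is not small against the mean event time {m:.3g}; "
                "discretization bias may be visible",
                stacklevel=2,
            )
        k = max(self.transitions.k_sp, self.transitions.k_ps)
        if k * self.dt >= 0.01:
            warnings.warn(
                f"switching probability per step k*dt={k * self.dt:.3g} >= 0.01",
                stacklevel=2,
            )

    def experiment_config(self) -> ExperimentConfig:
        return ExperimentConfig(
            t_drug=self.t_drug,
            t_end=self.t_end,
            snapshot_interval=self.snapshot_interval,
            tracking_mode=self.tracking_mode,
            concentration_label=self.concentration_label,
        )


@dataclass
class SimResult:
    """Simulated experiment with full ground truth."""

    table: ExperimentTable
    annotations: pd.DataFrame  # cell_id, state_at_birth, state_at_drug, fate
    config: SimConfig
    seed: int | None

    def population_curve(self, time_grid=None):
        from .lineage import population_curve

        return population_curve(self.table, time_grid)


# --------------------------------------------------------------------------
# internal record store


class _Store:
    def __init__(self) -> None:
        self.parent: list[int | None] = []
        self.lineage: list[int] = []
        self.birth: list[float] = []
        self.end: list[float] = []
        self.event: list[str] = []
        self.tracked: list[bool] = []
        self.state_birth: list[int] = []
        self.state_drug: list[int | None] = []
        self.fate: list[str | None] = []

    def add(self, parent, lineage, birth, state) -> int:
        self.parent.append(parent)
        self.lineage.append(lineage)
        self.birth.append(birth)
        self.end.append(np.nan)
        self.event.append("")
        self.tracked.append(True)
        self.state_birth.append(state)
        self.state_drug.append(None)
        self.fate.append(None)
        return len(self.parent) - 1

    def close(self, idx, end, event) -> None:
        self.end[idx] = end
        self.event[idx] = event


def _hazard_table(params: EMGParams, dt: float) -> np.ndarray:
    """Per-step event probabilities 1 - exp(-h(age) dt) on the age grid."""
    horizon = _emg_horizon(params, None)
    ages = np.arange(0.0, horizon + dt, dt)
    h = emg_hazard(ages, params)
    return 1.0 - np.exp(-np.maximum(h, 0.0) * dt)


def _pos_sample(params: EMGParams, rng: np.random.Generator) -> float:
    """One EMG waiting-time draw, floored at a tiny positive value."""
    v = rng.normal(params.mu, params.sigma) + rng.exponential(1.0 / params.lam)
    return max(v, 1e-9)


# --------------------------------------------------------------------------
# pre-drug engine


def _run_pre_drug(cfg: SimConfig, store: _Store, rng: np.random.Generator):
    """Step the pre-drug branching process; returns live (indices, ages, states)."""
    switching = cfg.model in ("M1", "M3")
    p_div = _hazard_table(cfg.pre_imt, cfg.dt)
    n_steps = int(round(cfg.t_drug / cfg.dt))

    p_frac = (
        cfg.initial_p_fraction
        if cfg.initial_p_fraction is not None
        else cfg.transitions.stationary_p
    )
    if cfg.model in ("M0", "M2"):
        states0 = np.zeros(cfg.n_founders, dtype=np.int8)
    else:
        states0 = (rng.random(cfg.n_founders) < p_frac).astype(np.int8)
    if cfg.initial_ages is None:
        ages0 = np.zeros(cfg.n_founders, dtype=np.int64)
    elif isinstance(cfg.initial_ages, str):
        if cfg.initial_ages != "stationary":
            raise ValueError(f"unknown initial_ages mode {cfg.initial_ages!r}")
        ages_h = stationary_age_sample(cfg.pre_imt, cfg.n_founders, rng)
        ages0 = np.round(ages_h / cfg.dt).astype(np.int64)
    else:
        ages0 = np.round(np.asarray(cfg.initial_ages) / cfg.dt).astype(np.int64)

    idx = np.array(
        [store.add(None, lin, 0.0, int(s)) for lin, s in enumerate(states0)],
        dtype=np.int64,
    )
    ages = ages0.copy()
    states = states0.copy()

    forward = cfg.tracking_mode == "forward_lineage"
    p_sp = cfg.transitions.k_sp * cfg.dt
    p_ps = cfg.transitions.k_ps * cfg.dt
    max_age = len(p_div) - 1

    for step in range(1, n_steps + 1):
        t = step * cfg.dt
        if idx.size == 0:
            break
        if switching and (p_sp > 0 or p_ps > 0):
            u = rng.random(idx.size)
            flip = np.where(states == S_PRIME, u < p_sp, u < p_ps)
            states = np.where(flip, 1 - states, states).astype(np.int8)
        p = p_div[np.minimum(ages, max_age)]
        div = rng.random(idx.size) < p
        if div.any():
            new_idx, new_ages, new_states = [], [], []
            for i in np.flatnonzero(div):
                mother = int(idx[i])
                store.close(mother, t, "division")
                lin = store.lineage[mother]
                st = int(states[i])
                d1 = store.add(mother, lin, t, st)
                d2 = store.add(mother, lin, t, st)
                if forward:
                    keep, drop = (d1, d2) if rng.random() < 0.5 else (d2, d1)
                    store.tracked[drop] = False
                    store.close(drop, t, "censored")
                    new_idx.append(keep)
                    new_ages.append(0)
                    new_states.append(st)
                else:
                    new_idx.extend([d1, d2])
                    new_ages.extend([0, 0])
                    new_states.extend([st, st])
            keepmask = ~div
            idx = np.concatenate([idx[keepmask], np.array(new_idx, dtype=np.int64)])
            ages = np.concatenate(
                [ages[keepmask] + 1, np.array(new_ages, dtype=np.int64)]
            )
            states = np.concatenate(
                [states[keepmask], np.array(new_states, dtype=np.int8)]
            )
        else:
            ages = ages + 1
    return idx, ages, states


# --------------------------------------------------------------------------
# post-drug phases


def _post_drug_m0(cfg: SimConfig, store: _Store, rng, idx, states):
    """Competing-hazard stepping: division vs death race each time step."""
    p_m_tab = _hazard_table(cfg.post_imt, cfg.dt)
    p_a_tab = _hazard_table(cfg.post_at, cfg.dt)
    # raw hazards for the type ratio
    from .emg import emg_hazard as _hz

    horizon = max(len(p_m_tab), len(p_a_tab))
    age_grid = np.arange(horizon) * cfg.dt
    h_m = np.maximum(_hz(age_grid, cfg.post_imt), 0.0)
    h_a = np.maximum(_hz(age_grid, cfg.post_at), 0.0)
    p_net = 1.0 - np.exp(-(h_m + h_a) * cfg.dt)
    ratio_m = np.where(h_m + h_a > 0, h_m / np.maximum(h_m + h_a, 1e-300), 1.0)

    for i, st in zip(idx, states):
        store.state_drug[int(i)] = int(st)

    ages = np.zeros(idx.size, dtype=np.int64)  # post-drug clock restarts
    n_steps = int(round((cfg.t_end - cfg.t_drug) / cfg.dt))
    forward = cfg.tracking_mode == "forward_lineage"
    max_age = horizon - 1

    for step in range(1, n_steps + 1):
        t = cfg.t_drug + step * cfg.dt
        if idx.size == 0:
            break
        a = np.minimum(ages, max_age)
        happened = rng.random(idx.size) < p_net[a]
        is_div = rng.random(idx.size) < ratio_m[a]
        new_idx, new_ages = [], []
        for i in np.flatnonzero(happened):
            cell = int(idx[i])
            if is_div[i]:
                store.close(cell, t, "division")
                lin = store.lineage[cell]
                d1 = store.add(cell, lin, t, store.state_birth[cell])
                d2 = store.add(cell, lin, t, store.state_birth[cell])
                if forward:
                    keep, drop = (d1, d2) if rng.random() < 0.5 else (d2, d1)
                    store.tracked[drop] = False
                    store.close(drop, t, "censored")
                    new_idx.append(keep)
                    new_ages.append(0)
                else:
                    new_idx.extend([d1, d2])
                    new_ages.extend([0, 0])
            else:
                store.close(cell, t, "death")
        keep = ~happened
        idx = np.concatenate([idx[keep], np.array(new_idx, dtype=np.int64)])
        ages = np.concatenate([ages[keep] + 1, np.array(new_ages, dtype=np.int64)])
    for i in idx:
        store.close(int(i), cfg.t_end, "censored")


def _fate_row(cfg: SimConfig, state: int) -> np.ndarray:
    if cfg.model == "M2":
        return np.asarray(cfg.m2_fates, dtype=float)
    if cfg.model == "M1":
        if state == S_PRIME:
            return np.array([1.0, 0.0, 0.0])
        row = cfg.fates.row(P_PRIME).copy()
        row[0] = 0.0
        s = row.sum()
        return row / s if s > 0 else np.array([0.0, 0.0, 1.0])
    return cfg.fates.row(state)


def _post_drug_fated(cfg: SimConfig, store: _Store, rng, idx, states):
    """M1/M2/M3: draw a fate per cell at drug time (and per daughter at
    birth), then a waiting time from the single corresponding EMG."""
    forward = cfg.tracking_mode == "forward_lineage"
    stack: list[tuple[int, float, int]] = []  # (record idx, clock start, state)
    for i, st in zip(idx, states):
        store.state_drug[int(i)] = int(st)
        stack.append((int(i), cfg.t_drug, int(st)))
    while stack:
        cell, start, st = stack.pop()
        fate = int(rng.choice(3, p=_fate_row(cfg, st)))
        store.fate[cell] = FATE_NAMES[fate]
        if fate == 2:  # stay: survive without dividing
            store.close(cell, cfg.t_end, "censored")
            continue
        wait = _pos_sample(cfg.post_at if fate == 0 else cfg.post_imt, rng)
        t_event = start + wait
        if t_event > cfg.t_end:
            store.close(cell, cfg.t_end, "censored")
            continue
        if fate == 0:
            store.close(cell, t_event, "death")
            continue
        store.close(cell, t_event, "division")
        lin = store.lineage[cell]
        d1 = store.add(cell, lin, t_event, st)
        d2 = store.add(cell, lin, t_event, st)
        store.state_drug[d1] = st
        store.state_drug[d2] = st
        if forward:
            keep, drop = (d1, d2) if rng.random() < 0.5 else (d2, d1)
            store.tracked[drop] = False
            store.close(drop, t_event, "censored")
            stack.append((keep, t_event, st))
        else:
            stack.append((d1, t_event, st))
            stack.append((d2, t_event, st))


# --------------------------------------------------------------------------
# assembly


def _build_result(cfg: SimConfig, store: _Store, seed) -> SimResult:
    snap = cfg.snapshot_interval

    def rnd(t: float) -> float:
        if not cfg.snapshot_round:
            return t
        return float(np.floor(t / snap + 1e-9) * snap)

    records = []
    ids = [f"c{i:06d}" for i in range(len(store.parent))]
    for i, cid in enumerate(ids):
        records.append(
            CellRecord(
                cell_id=cid,
                parent_id=None if store.parent[i] is None else ids[store.parent[i]],
                lineage_id=f"L{store.lineage[i]:04d}",
                birth_time=rnd(store.birth[i]),
                end_time=cfg.t_end
                if (store.tracked[i] and store.event[i] == "censored")
                else rnd(store.end[i]),
                end_event=store.event[i],
                tracked=store.tracked[i],
            )
        )
    table = ExperimentTable(records, cfg.experiment_config())
    ann = pd.DataFrame(
        {
            "cell_id": ids,
            "state_at_birth": [STATE_NAMES.get(s) for s in store.state_birth],
            "state_at_drug": [
                None if s is None else STATE_NAMES[s] for s in store.state_drug
            ],
            "fate": store.fate,
        }
    )
    return SimResult(table=table, annotations=ann, config=cfg, seed=seed)


def simulate(config: SimConfig, seed=None) -> SimResult:
    """Run the configured model; seeded runs are bit-reproducible."""
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    store = _Store()
    idx, ages, states = _run_pre_drug(config, store, rng)
    if config.model == "M0":
        _post_drug_m0(config, store, rng, idx, states)
    else:
        _post_drug_fated(config, store, rng, idx, states)
    return _build_result(config, store, seed)


def simulate_M0(config: SimConfig, seed=None) -> SimResult:
    return simulate(replace(config, model="M0"), seed)


def simulate_M1(config: SimConfig, seed=None) -> SimResult:
    return simulate(replace(config, model="M1"), seed)


def simulate_M2(config: SimConfig, seed=None) -> SimResult:
    return simulate(replace(config, model="M2"), seed)


def simulate_M3(config: SimConfig, seed=None) -> SimResult:
    return simulate(replace(config, model="M3"), seed)
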