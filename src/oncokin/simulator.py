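"""Discrete-time simulation of the tumor cell population under chemotherapy.

The tumor is treated as a macroscopically homogeneous, well-mixed population
(constant cell density, default 1e6 cells/mm^3), so volume is cell count /
density and relative volume changes are density-invariant.  Time advances in
fixed ticks (default 1 h).  Cycling cells carry an intra-cycle age; the G0,
apoptotic and necrotic compartments are memoryless with mean residence
``T_G0``/``T_A``/``T_N``.  Chemotherapy administrations are instantaneous:
lethally hit cells enter a rudimentary cell cycle and transfer to the
apoptotic pool at the end of the death phase dictated by the drug (end of S
for gemcitabine, end of G2 for cisplatin, end of M for vinorelbine and
docetaxel); dormant cells are hit only by cell-cycle non-specific drugs
(cisplatin) and must re-enter the cycle to die.

Two propagation modes are provided: ``expectation`` (deterministic
mean-field propagation, used wherever reproducibility matters) and
``stochastic`` (per-transition binomial/multinomial sampling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model_core import KineticParameters, ProfileUnreachable

__all__ = [
    "DrugSpec",
    "DRUG_CATALOGUE",
    "Administration",
    "TreatmentSchedule",
    "TumorState",
    "Trajectory",
    "initialize_state",
    "step",
    "apply_administration",
    "simulate",
    "doubling_time",
    "discrete_growth_factor",
    "DEFAULT_CELL_DENSITY",
    "DEFAULT_PHASE_FRACTIONS",
    "DEFAULT_DT",
]

DEFAULT_CELL_DENSITY = 1.0e6      # cells per mm^3
DEFAULT_PHASE_FRACTIONS = (0.40, 0.39, 0.19, 0.02)   # G1, S, G2, M shares of T_C
DEFAULT_DT = 1.0                  # hours

_DEATH_PHASES = ("end-of-S", "end-of-G2", "end-of-M")


@dataclass(frozen=True)
class DrugSpec:
    """Mechanism abstraction of a chemotherapeutic agent.

    ``hits_G0`` marks cell-cycle non-specific drugs that also damage dormant
    cells; ``death_phase`` is the cycle point where lethally hit cells enter
    the apoptotic pathway; ``CKR`` is the fraction of cells with
    proliferative capacity lethally hit per administration.
    """

    name: str
    hits_G0: bool
    death_phase: str
    CKR: float = 0.0

    def __post_init__(self):
        if self.death_phase not in _DEATH_PHASES:
            raise ValueError(f"death_phase must be one of {_DEATH_PHASES}")
        if not 0.0 <= self.CKR <= 1.0:
            raise ValueError(f"CKR must lie in [0, 1], got {self.CKR}")

    def with_ckr(self, ckr: float) -> "DrugSpec":
        return DrugSpec(self.name, self.hits_G0, self.death_phase, ckr)


DRUG_CATALOGUE = {
    "cisplatin": DrugSpec("cisplatin", hits_G0=True, death_phase="end-of-G2"),
    "gemcitabine": DrugSpec("gemcitabine", hits_G0=False, death_phase="end-of-S"),
    "vinorelbine": DrugSpec("vinorelbine", hits_G0=False, death_phase="end-of-M"),
    "docetaxel": DrugSpec("docetaxel", hits_G0=False, death_phase="end-of-M"),
}


@dataclass(frozen=True)
class Administration:
    time_h: float
    drugs: tuple          # drug names

    def resolve(self, ckr: dict) -> list:
        specs = []
        for name in self.drugs:
            if name not in DRUG_CATALOGUE:
                raise KeyError(f"unknown drug {name!r}")
            specs.append(DRUG_CATALOGUE[name].with_ckr(ckr.get(name, 0.0)))
        return specs


@dataclass
class TreatmentSchedule:
    """Timed drug administrations, hours from simulation start."""

    administrations: list

    def __post_init__(self):
        times = [a.time_h for a in self.administrations]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("administration times must be strictly increasing")
        for a in self.administrations:
            for name in a.drugs:
                if name not in DRUG_CATALOGUE:
                    raise KeyError(f"unknown drug {name!r}")

    @classmethod
    def from_day_drug(cls, rows: Sequence, onset_shift_days: float = 0.0) -> "TreatmentSchedule":
        """Build from (day, drug) rows with day 1 = treatment onset."""
        by_time: dict = {}
        for day, drug in rows:
            t = (float(day) - 1.0 + onset_shift_days) * 24.0
            by_time.setdefault(t, []).append(str(drug))
        admins = [Administration(t, tuple(by_time[t])) for t in sorted(by_time)]
        return cls(admins)

    @property
    def empty(self) -> bool:
        return not self.administrations


# ---------------------------------------------------------------------------
# Precomputed per-tick kinetics
# ---------------------------------------------------------------------------

def _phase_ticks(total: int, fractions) -> tuple:
    """Split a cycle of `total` ticks into G1/S/G2/M, each at least one tick."""
    if total < 4:
        raise ValueError("cell cycle must span at least 4 ticks (one per phase)")
    raw = [f * total for f in fractions]
    ticks = [int(math.floor(r)) for r in raw]
    rema = sorted(range(4), key=lambda i: raw[i] - ticks[i], reverse=True)
    i = 0
    while sum(ticks) < total:
        ticks[rema[i % 4]] += 1
        i += 1
    for j in range(4):
        while ticks[j] == 0:
            k = int(np.argmax(ticks))
            ticks[k] -= 1
            ticks[j] += 1
    return tuple(ticks)


class _ClassKinetics:
    """Tick-level constants for one proliferative class (stem or LIMP)."""

    def __init__(self, T_C, T_G0, P_G0toG1, R_A, dt, phase_fractions):
        self.T = max(4, int(round(T_C / dt)))
        self.phases = _phase_ticks(self.T, phase_fractions)
        g1, s, g2, m = self.phases
        self.end_S = g1 + s
        self.end_G2 = g1 + s + g2
        self.end_M = self.T
        self.s_A = math.exp(-R_A * dt)
        # G0: exponential death (rate R_A) then exit with probability dt/T_G0
        # among survivors, so the mean residence is exactly T_G0
        q = min(1.0, dt / T_G0)
        self.s_g0 = self.s_A * (1.0 - q)
        leave = 1.0 - self.s_g0
        self.w_die = (1.0 - self.s_A) / leave if leave > 0 else 0.0
        self.w_exit = self.s_A * q / leave if leave > 0 else 0.0
        self.P_G0 = P_G0toG1
        self._rem_cache: dict = {}

    def boundary(self, death_phase: str) -> int:
        return {"end-of-S": self.end_S, "end-of-G2": self.end_G2,
                "end-of-M": self.end_M}[death_phase]

    def remaining_ticks(self, death_phase: str) -> np.ndarray:
        """Ticks until death for a cell hit at each intra-cycle age.

        A cell past its death phase completes the current cycle without
        dividing and proceeds to the death phase of the rudimentary cycle.
        """
        if death_phase not in self._rem_cache:
            b = self.boundary(death_phase)
            tau = np.arange(self.T)
            rem = np.where(tau < b, b - tau, self.T - tau + b)
            self._rem_cache[death_phase] = rem
        return self._rem_cache[death_phase]


class _Kinetics:
    def __init__(self, params: KineticParameters, dt, phase_fractions):
        params.validate()
        p = params
        self.dt = dt
        self.p = p
        self.stem = _ClassKinetics(p.T_C_stem, p.T_G0_stem, p.P_G0toG1_stem,
                                   p.R_A, dt, phase_fractions)
        self.limp = _ClassKinetics(p.T_C_limp, p.T_G0_limp, p.P_G0toG1_limp,
                                   p.R_A, dt, phase_fractions)
        # memoryless compartments use linear per-tick probabilities so that
        # the mean residence (and hence the steady-state occupancy ratio
        # inflow/(a + rate)) is exact rather than biased by dt
        loss = p.R_ADiff + p.R_NDiff
        self.s_D = 1.0 - min(1.0, loss * dt)
        self.w_adiff = p.R_ADiff / loss if loss > 0 else 0.0
        self.w_ndiff = p.R_NDiff / loss if loss > 0 else 0.0
        self.s_TA = 1.0 - min(1.0, dt / p.T_A)
        self.s_TN = 1.0 - min(1.0, dt / p.T_N)


# ---------------------------------------------------------------------------
# State
# ---------------------------------------------------------------------------

@dataclass
class TumorState:
    """Occupancy of every model compartment at one instant.

    Cycling cells are indexed by lineage (stem, LIMP generation) and
    intra-cycle age tick; dormant, DIFF and dead-cell pools are scalars
    (their residence is memoryless).  Cells lethally hit by chemotherapy are
    kept in per-class buckets indexed by the ticks remaining until their
    programmed death.
    """

    clock: float
    kin: _Kinetics
    cell_density: float
    cyc_s: np.ndarray          # (T_stem,)
    cyc_l: np.ndarray          # (N_LIMP, T_limp)
    g0_s: float
    g0_l: np.ndarray           # (N_LIMP,)
    diff: float
    apop: float
    necr: float
    hit_cyc_s: np.ndarray      # (T_stem + 1,) remaining-tick buckets
    hit_cyc_l: np.ndarray      # (T_limp + 1,)
    hit_g0_s: float = 0.0
    hit_g0_l: float = 0.0
    removed: float = 0.0       # cumulative cleared dead cells (bookkeeping)
    born: float = 0.0          # cumulative net births (bookkeeping)

    @property
    def living(self) -> float:
        return (self.cyc_s.sum() + self.cyc_l.sum() + self.g0_s
                + float(self.g0_l.sum()) + self.diff
                + self.hit_cyc_s.sum() + self.hit_cyc_l.sum()
                + self.hit_g0_s + self.hit_g0_l)

    @property
    def total_cells(self) -> float:
        return self.living + self.apop + self.necr

    @property
    def volume(self) -> float:
        """Tumor volume in mm^3 (living plus not-yet-cleared dead cells)."""
        return self.total_cells / self.cell_density

    def compartment_counts(self) -> dict:
        return {
            "stem": float(self.cyc_s.sum() + self.g0_s),
            "limp": float(self.cyc_l.sum() + self.g0_l.sum()),
            "diff": float(self.diff),
            "cycling": float(self.cyc_s.sum() + self.cyc_l.sum()),
            "g0": float(self.g0_s + self.g0_l.sum()),
            "hit": float(self.hit_cyc_s.sum() + self.hit_cyc_l.sum()
                         + self.hit_g0_s + self.hit_g0_l),
            "apoptotic": float(self.apop),
            "necrotic": float(self.necr),
        }

    def copy(self) -> "TumorState":
        return TumorState(
            clock=self.clock, kin=self.kin, cell_density=self.cell_density,
            cyc_s=self.cyc_s.copy(), cyc_l=self.cyc_l.copy(),
            g0_s=self.g0_s, g0_l=self.g0_l.copy(), diff=self.diff,
            apop=self.apop, necr=self.necr,
            hit_cyc_s=self.hit_cyc_s.copy(), hit_cyc_l=self.hit_cyc_l.copy(),
            hit_g0_s=self.hit_g0_s, hit_g0_l=self.hit_g0_l,
            removed=self.removed, born=self.born)


# ---------------------------------------------------------------------------
# Balanced-growth initialization
# ---------------------------------------------------------------------------

def _class_discrete(kc: _ClassKinetics, P_sleep, lam):
    """Per-newborn stationary occupancies of one class at growth factor lam."""
    if P_sleep > 0 and lam <= kc.s_g0:
        # dormant pool decays slower than the population shrinks: no
        # balanced composition exists
        raise ProfileUnreachable(
            "g0_pool_divergent",
            "G0 residence exceeds the population turnover time of a shrinking tumor")
    reentry = 0.0 if P_sleep * kc.P_G0 == 0 else \
        kc.P_G0 * (1.0 - kc.s_g0) * kc.w_exit / (lam - kc.s_g0)
    gamma = (1.0 - P_sleep) + P_sleep * reentry
    # cyc[0] per unit newborn flux, then geometric age profile with ratio s_A/lam
    c0 = gamma / lam
    ratio = kc.s_A / lam
    ages = ratio ** np.arange(kc.T)
    D = gamma * (kc.s_A ** kc.T) / lam ** kc.T   # discounted mitoses per newborn
    g0 = 0.0 if P_sleep == 0 else P_sleep / (lam - kc.s_g0)
    return c0, ages, g0, D


def discrete_growth_factor(params: KineticParameters, dt: float = DEFAULT_DT,
                           phase_fractions=DEFAULT_PHASE_FRACTIONS) -> float:
    """Per-tick growth factor λ of the discrete-time dynamics.

    Root of the discrete stem-cell renewal equation; ``ln λ / dt`` is the
    realized intrinsic growth rate of the simulator, which differs from the
    continuous-time rate only through tick quantization.
    """
    kin = _Kinetics(params, dt, phase_fractions)
    kc = kin.stem
    P_sleep = params.P_sleep
    P_sym = params.P_sym

    def g(lam):
        _, _, _, D = _class_discrete(kc, P_sleep, lam)
        return (1.0 + P_sym) * D - 1.0

    lo = math.exp(-0.1 * dt)
    if P_sleep > 0:
        lo = max(lo, kc.s_g0 + 1e-12)
    hi = math.exp(0.1 * dt)
    glo, ghi = g(lo), g(hi)
    if glo * ghi > 0:
        raise ProfileUnreachable("no_growth_rate_root",
                                 "discrete renewal equation has no root in bracket")
    return brentq(g, lo, hi, xtol=1e-16, rtol=1e-14)


def initialize_state(initial_volume: float, params: KineticParameters, *,
                     dt: float = DEFAULT_DT,
                     cell_density: float = DEFAULT_CELL_DENSITY,
                     phase_fractions=DEFAULT_PHASE_FRACTIONS,
                     mode: str = "expectation",
                     rng: Optional[np.random.Generator] = None) -> TumorState:
    """Balanced-growth initial state of a tumor of the given volume.

    Compartment sizes and intra-cycle age profiles are the exact stationary
    profile of the discrete-time update (age density ∝ (e^{-R_A dt}/λ)^age),
    so that free growth is exponential from the first tick.
    """
    if initial_volume <= 0:
        raise ValueError("initial_volume must be positive")
    kin = _Kinetics(params, dt, phase_fractions)
    lam = discrete_growth_factor(params, dt, phase_fractions)
    p = params

    c0s, ages_s, g0s_per_nb, D_s = _class_discrete(kin.stem, p.P_sleep, lam)
    c0l, ages_l, g0l_per_nb, D_l = _class_discrete(kin.limp, p.P_sleep, lam)

    # newborn fluxes per unit stem mitosis flux
    f_S = 1.0 + p.P_sym
    amp = 2.0 * D_l
    f_gens = (1.0 - p.P_sym) * amp ** np.arange(p.N_LIMP)
    m_last = f_gens[-1] * D_l

    cyc_s = f_S * c0s * ages_s
    cyc_l = np.outer(f_gens, c0l * ages_l)
    g0_s = f_S * g0s_per_nb
    g0_l = f_gens * g0l_per_nb
    diff = 2.0 * m_last / (lam - kin.s_D)

    # dead-cell pools: per-tick inflow at stationarity
    cyc_tot = cyc_s.sum() + cyc_l.sum()
    g0_tot = g0_s + g0_l.sum()
    leave_s = g0_s * (1.0 - kin.stem.s_g0)
    leave_l = g0_l.sum() * (1.0 - kin.limp.s_g0)
    diff_leave = diff * (1.0 - kin.s_D)
    phi_A = ((1.0 - kin.stem.s_A) * cyc_s.sum()
             + (1.0 - kin.limp.s_A) * cyc_l.sum()
             + leave_s * kin.stem.w_die + leave_l * kin.limp.w_die
             + diff_leave * kin.w_adiff)
    phi_N = (leave_s * kin.stem.w_exit * (1.0 - kin.stem.P_G0)
             + leave_l * kin.limp.w_exit * (1.0 - kin.limp.P_G0)
             + diff_leave * kin.w_ndiff)
    if lam <= kin.s_D or lam <= kin.s_TA or lam <= kin.s_TN or lam <= kin.limp.s_g0:
        raise ProfileUnreachable(
            "pool_divergent",
            "a dead-cell or dormant pool outlives the population turnover of "
            "a shrinking tumor; no balanced composition exists")
    apop = phi_A / (lam - kin.s_TA)
    necr = phi_N / (lam - kin.s_TN)

    total = cyc_tot + g0_tot + diff + apop + necr
    scale = initial_volume * cell_density / total
    state = TumorState(
        clock=0.0, kin=kin, cell_density=cell_density,
        cyc_s=cyc_s * scale, cyc_l=cyc_l * scale,
        g0_s=g0_s * scale, g0_l=g0_l * scale, diff=diff * scale,
        apop=apop * scale, necr=necr * scale,
        hit_cyc_s=np.zeros(kin.stem.T + 1), hit_cyc_l=np.zeros(kin.limp.T + 1))
    if mode == "stochastic":
        # randomized rounding keeps the integer initial state unbiased even
        # for compartments holding a fraction of a cell per age bin
        rng = rng if rng is not None else np.random.default_rng()

        def rround(x):
            fl = np.floor(x)
            return fl + (rng.random(np.shape(x)) < (x - fl))

        for name in ("cyc_s", "cyc_l", "g0_l", "hit_cyc_s", "hit_cyc_l"):
            setattr(state, name, rround(getattr(state, name)))
        for name in ("g0_s", "diff", "apop", "necr"):
            setattr(state, name, float(rround(getattr(state, name))))
    return state


# ---------------------------------------------------------------------------
# One tick
# ---------------------------------------------------------------------------

def _binom(rng, n, p):
    return rng.binomial(np.asarray(np.round(n), dtype=np.int64), p)


def step(state: TumorState, rng: Optional[np.random.Generator] = None) -> TumorState:
    """Advance the state by one tick (in place); returns the state.

    Expectation mode propagates means; pass a seeded generator for
    per-transition binomial sampling.  Order within a tick: spontaneous
    losses, mitosis, newborn routing, dormancy/DIFF turnover, hit-cohort
    progression, dead-cell-pool clearance.
    """
    kin = state.kin
    p = kin.p
    stoch = rng is not None
    apop_in = 0.0
    necr_in = 0.0

    # --- spontaneous apoptosis of cycling cells, then mitosis and ageing
    if stoch:
        d_s = _binom(rng, state.cyc_s, 1.0 - kin.stem.s_A)
        d_l = _binom(rng, state.cyc_l, 1.0 - kin.limp.s_A)
        apop_in += d_s.sum() + d_l.sum()
        surv_s = state.cyc_s - d_s
        surv_l = state.cyc_l - d_l
    else:
        apop_in += (1.0 - kin.stem.s_A) * state.cyc_s.sum() \
            + (1.0 - kin.limp.s_A) * state.cyc_l.sum()
        surv_s = kin.stem.s_A * state.cyc_s
        surv_l = kin.limp.s_A * state.cyc_l
    m_s = float(surv_s[-1])
    m_l = surv_l[:, -1].copy()
    state.cyc_s = np.roll(surv_s, 1)
    state.cyc_s[0] = 0.0
    state.cyc_l = np.roll(surv_l, 1, axis=1)
    state.cyc_l[:, 0] = 0.0

    # --- division outcomes
    if stoch:
        sym = float(_binom(rng, m_s, p.P_sym))
        nb_s = m_s + sym
        nb_first = m_s - sym
    else:
        nb_s = (1.0 + p.P_sym) * m_s
        nb_first = (1.0 - p.P_sym) * m_s
    nb_l = np.empty(p.N_LIMP)
    nb_l[0] = nb_first
    nb_l[1:] = 2.0 * m_l[:-1]
    diff_in = 2.0 * float(m_l[-1])
    state.born += m_s + float(m_l.sum())

    # --- G0 turnover, then newborn routing
    def g0_update(g0, kc, nb):
        nonlocal apop_in, necr_in
        if stoch:
            leave = _binom(rng, g0, 1.0 - kc.s_g0)
            die = _binom(rng, leave, kc.w_die)
            exits = leave - die
            to_g1 = _binom(rng, exits, kc.P_G0)
            to_sleep = _binom(rng, nb, p.P_sleep)
        else:
            leave = (1.0 - kc.s_g0) * g0
            die = kc.w_die * leave
            exits = leave - die
            to_g1 = kc.P_G0 * exits
            to_sleep = p.P_sleep * nb
        apop_in += np.sum(die)
        necr_in += np.sum(exits - to_g1)
        new_g0 = g0 - leave + to_sleep
        g1_in = nb - to_sleep + to_g1
        return new_g0, g1_in

    state.g0_s, g1_s = g0_update(state.g0_s, kin.stem, nb_s)
    state.g0_l, g1_l = g0_update(state.g0_l, kin.limp, nb_l)
    state.cyc_s[0] = g1_s
    state.cyc_l[:, 0] = g1_l

    # --- DIFF turnover
    if stoch:
        leave_d = float(_binom(rng, state.diff, 1.0 - kin.s_D))
        a_d = float(_binom(rng, leave_d, kin.w_adiff))
    else:
        leave_d = (1.0 - kin.s_D) * state.diff
        a_d = kin.w_adiff * leave_d
    apop_in += a_d
    necr_in += leave_d - a_d
    state.diff = state.diff - leave_d + diff_in

    # --- lethally hit cohorts
    apop_in += float(state.hit_cyc_s[1]) + float(state.hit_cyc_l[1])
    state.hit_cyc_s = np.roll(state.hit_cyc_s, -1)
    state.hit_cyc_s[[-1, 0]] = 0.0
    state.hit_cyc_l = np.roll(state.hit_cyc_l, -1)
    state.hit_cyc_l[[-1, 0]] = 0.0

    def hit_g0_update(hg0, kc, hit_buckets):
        nonlocal apop_in, necr_in
        if stoch:
            leave = float(_binom(rng, hg0, 1.0 - kc.s_g0))
            die = float(_binom(rng, leave, kc.w_die))
            exits = leave - die
            to_g1 = float(_binom(rng, exits, kc.P_G0))
        else:
            leave = (1.0 - kc.s_g0) * hg0
            die = kc.w_die * leave
            exits = leave - die
            to_g1 = kc.P_G0 * exits
        apop_in += die
        necr_in += exits - to_g1
        # re-entering hit G0 cells die at the end of G2 of the rudimentary cycle
        hit_buckets[kc.end_G2] += to_g1
        return hg0 - leave

    state.hit_g0_s = hit_g0_update(state.hit_g0_s, kin.stem, state.hit_cyc_s)
    state.hit_g0_l = hit_g0_update(state.hit_g0_l, kin.limp, state.hit_cyc_l)

    # --- dead-cell pools
    if stoch:
        clr_a = float(_binom(rng, state.apop, 1.0 - kin.s_TA))
        clr_n = float(_binom(rng, state.necr, 1.0 - kin.s_TN))
    else:
        clr_a = (1.0 - kin.s_TA) * state.apop
        clr_n = (1.0 - kin.s_TN) * state.necr
    state.apop = state.apop - clr_a + apop_in
    state.necr = state.necr - clr_n + necr_in
    state.removed += clr_a + clr_n

    state.clock += kin.dt
    return state


# ---------------------------------------------------------------------------
# Drug administration
# ---------------------------------------------------------------------------

def apply_administration(state: TumorState, drugs: Sequence[DrugSpec],
                         ckf_stem: Optional[float] = None,
                         rng: Optional[np.random.Generator] = None) -> TumorState:
    """Apply an instantaneous administration of one or more drugs (in place).

    In each proliferative phase the summed kill fraction min(1, ΣCKR) of LIMP
    cells and min(1, CKF_stem·ΣCKR) of stem cells is marked as hit, allocated
    among the drugs proportionally to CKR so each cohort carries its drug's
    death phase.  Dormant cells are hit only by drugs with ``hits_G0``.
    """
    if not drugs:
        return state
    kin = state.kin
    if ckf_stem is None:
        ckf_stem = kin.p.CKF_stem
    ckr_tot = sum(d.CKR for d in drugs)
    if ckr_tot <= 0:
        return state
    k_l = min(1.0, ckr_tot)
    k_s = min(1.0, ckf_stem * ckr_tot)
    ckr_g0 = sum(d.CKR for d in drugs if d.hits_G0)
    kg_l = min(1.0, ckr_g0)
    kg_s = min(1.0, ckf_stem * ckr_g0)
    stoch = rng is not None

    def take(arr, frac):
        if stoch:
            hit = rng.binomial(np.asarray(np.round(arr), dtype=np.int64), frac)
            return arr - hit, np.asarray(hit, dtype=float)
        hit = frac * arr
        return arr - hit, hit

    state.cyc_s, hit_s = take(state.cyc_s, k_s)
    state.cyc_l, hit_l = take(state.cyc_l, k_l)
    hit_l_age = hit_l.sum(axis=0)
    for d in drugs:
        share = d.CKR / ckr_tot
        rem_s = kin.stem.remaining_ticks(d.death_phase)
        rem_l = kin.limp.remaining_ticks(d.death_phase)
        np.add.at(state.hit_cyc_s, rem_s, share * hit_s)
        np.add.at(state.hit_cyc_l, rem_l, share * hit_l_age)
    if ckr_g0 > 0:
        state.g0_s, hg_s = take(state.g0_s, kg_s)
        state.g0_l, hg_l = take(state.g0_l, kg_l)
        state.hit_g0_s += float(np.sum(hg_s))
        state.hit_g0_l += float(np.sum(hg_l))
    return state


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Volume and compartment time series sampled every tick."""

    time_h: np.ndarray
    volume_mm3: np.ndarray
    compartments: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        data = {"time_h": self.time_h, "volume_mm3": self.volume_mm3}
        data.update(self.compartments)
        return pd.DataFrame(data)

    def volume_at(self, t_h: float) -> float:
        idx = int(np.argmin(np.abs(self.time_h - t_h)))
        return float(self.volume_mm3[idx])


def simulate(initial_volume: float, params: KineticParameters,
             schedule: Optional[TreatmentSchedule], duration_days: float, *,
             mode: str = "expectation", seed: Optional[int] = None,
             ckr: Optional[dict] = None, ckf_stem: Optional[float] = None,
             dt: float = DEFAULT_DT, cell_density: float = DEFAULT_CELL_DENSITY,
             phase_fractions=DEFAULT_PHASE_FRACTIONS,
             record_compartments: bool = True,
             state: Optional[TumorState] = None) -> Trajectory:
    """Simulate tumor growth and treatment response.

    ``schedule`` times are hours from simulation start; ``ckr`` maps drug
    name to its cell kill rate.  Expectation mode is bit-reproducible;
    stochastic mode requires a ``seed``.
    """
    if mode not in ("expectation", "stochastic"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = None
    if mode == "stochastic":
        if seed is None:
            raise ValueError("stochastic mode requires a seed")
        rng = np.random.default_rng(seed)
    if state is None:
        state = initialize_state(initial_volume, params, dt=dt,
                                 cell_density=cell_density,
                                 phase_fractions=phase_fractions, mode=mode,
                                 rng=rng)
    ckr = ckr or {}
    admins = []
    if schedule is not None:
        admins = [(a.time_h, a.resolve(ckr)) for a in schedule.administrations]
        if admins and admins[0][0] < -1e-9:
            raise ValueError("administration before simulation start; shift the clock")
    n_ticks = int(round(duration_days * 24.0 / dt))
    times = np.empty(n_ticks + 1)
    vols = np.empty(n_ticks + 1)
    comp_keys = ("stem", "limp", "diff", "cycling", "g0", "hit",
                 "apoptotic", "necrotic")
    comps = {k: np.empty(n_ticks + 1) for k in comp_keys} if record_compartments else {}

    def record(i):
        times[i] = state.clock
        vols[i] = state.volume
        if record_compartments:
            cc = state.compartment_counts()
            for key in comp_keys:
                comps[key][i] = cc[key]

    next_adm = 0
    t0 = state.clock
    for i in range(n_ticks + 1):
        while next_adm < len(admins) and admins[next_adm][0] <= state.clock - t0 + 1e-9:
            apply_administration(state, admins[next_adm][1], ckf_stem, rng)
            next_adm += 1
        record(i)
        if i < n_ticks:
            step(state, rng)
    return Trajectory(time_h=times, volume_mm3=vols, compartments=comps)


@dataclass
class DoublingTimeFit:
    days: float
    negative_growth: bool
    r_squared: float

    def __float__(self):
        return self.days


def doubling_time(trajectory: Trajectory, skip_hours: float = 0.0) -> DoublingTimeFit:
    """Volume doubling time from a log-linear least-squares fit.

    ``skip_hours`` discards the initial transient (typically 2·T_C).  A
    non-positive slope yields a negative doubling time with the
    ``negative_growth`` flag set; a flat trajectory reports infinity.
    """
    mask = trajectory.time_h >= skip_hours
    t = trajectory.time_h[mask]
    v = trajectory.volume_mm3[mask]
    if t.size < 2 or np.any(v <= 0):
        raise ValueError("need at least two positive-volume points")
    logv = np.log(v)
    slope, intercept = np.polyfit(t, logv, 1)
    resid = logv - (slope * t + intercept)
    ss_tot = float(np.sum((logv - logv.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    if abs(slope) <= 1e-12:   # flat to numerical precision
        return DoublingTimeFit(days=math.inf, negative_growth=False, r_squared=r2)
    days = math.log(2.0) / slope / 24.0
    return DoublingTimeFit(days=days, negative_growth=slope < 0, r_squared=r2)
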