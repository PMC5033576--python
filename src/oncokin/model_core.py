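"""Cell-kinetic model types, balanced-exponential-growth mathematics and calibration.

The tumor population model distinguishes five cell categories: cancer stem
cells (unlimited mitotic potential), LIMP cells (LImited Mitotic Potential
progenitors that differentiate terminally after ``N_LIMP`` divisions), DIFF
cells (terminally differentiated, unable to divide), and the apoptotic and
necrotic dead-cell pools.  Stem and LIMP cells are either cycling through
G1/S/G2/M (total duration ``T_C``) or dormant in G0 (mean residence
``T_G0``).  A fully developed tumor with time-invariant kinetics settles
into *balanced exponential growth*: every compartment grows like
``e^{a t}`` while the compartment fractions stay constant.  This module
provides

* the renewal equation linking the intrinsic growth rate ``a`` to the
  stem-cell kinetic parameters, and its inverses (``solve_growth_rate``,
  ``calibrate_p_sleep``);
* the closed-form steady-state composition of the growing population
  (``balanced_composition``);
* calibration of the dependent parameters (``P_sleep``, ``R_NDiff``,
  ``T_A``, ``T_N``, ``N_LIMP``) from macroscopic proliferation targets
  (volume doubling time, growth fraction, apoptotic/necrotic/stem-cell
  fractions) — ``calibrate_full`` chains them.

All durations are in hours, rates in 1/h, the doubling time in days.
"""

from __future__ import annotations

import dataclasses
import io
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

__all__ = [
    "KineticParameters",
    "ProliferationProfile",
    "GrowthSolution",
    "CalibrationResult",
    "ProfileUnreachable",
    "solve_growth_rate",
    "calibrate_p_sleep",
    "calibrate_r_ndiff",
    "calibrate_t_a",
    "calibrate_t_n",
    "solve_n_limp",
    "balanced_composition",
    "calibrate_full",
    "report_duration_hours",
    "PARAM_COLUMNS",
]

#: Growth-rate search bracket, 1/h.  Doubling times of 26–700 days map to
#: |a| < 1.2e-3 1/h, comfortably inside.
GROWTH_RATE_BRACKET = (-0.1, 0.1)

LN2 = math.log(2.0)

PARAM_COLUMNS = [
    "T_C_stem", "T_C_limp", "T_G0_stem", "T_G0_limp", "T_A", "T_N",
    "R_A", "R_ADiff", "R_NDiff", "P_G0toG1_stem", "P_G0toG1_limp",
    "P_sym", "P_sleep", "N_LIMP", "CKF_stem",
]


class ProfileUnreachable(ValueError):
    """A proliferation profile cannot be realised by any valid parameter set.

    Carries a machine-readable ``reason`` code so that sampling workflows can
    use reachability as a filter predicate instead of crashing.
    """

    def __init__(self, reason: str, message: str = ""):
        self.reason = reason
        super().__init__(message or reason)


@dataclass
class KineticParameters:
    """Free-growth and therapy-resistance parameters of the cell-kinetic model.

    ``T_C``/``T_G0``/``P_G0toG1`` are defined separately for the stem and
    LIMP classes; the remaining transition fractions and rates are shared.
    The cell-kill factor of LIMP cells is fixed at 1, so only the stem-cell
    factor ``CKF_stem`` is a parameter.
    """

    T_C_stem: float          # cell-cycle duration of stem cells, h
    T_C_limp: float          # cell-cycle duration of LIMP cells, h
    T_G0_stem: float         # mean G0 residence of stem cells, h
    T_G0_limp: float         # mean G0 residence of LIMP cells, h
    R_A: float               # spontaneous apoptosis rate of stem/LIMP cells, 1/h
    R_ADiff: float           # apoptosis rate of DIFF cells, 1/h
    P_G0toG1_stem: float     # fraction of dormant stem cells re-entering the cycle
    P_G0toG1_limp: float     # fraction of dormant LIMP cells re-entering the cycle
    P_sym: float             # fraction of stem mitoses that are symmetric
    CKF_stem: float = 0.5    # stem-cell kill factor (chemoresistance multiplier)
    # Dependent parameters — filled in by calibration or supplied directly.
    P_sleep: Optional[float] = None   # newborn fraction entering G0 after mitosis
    R_NDiff: Optional[float] = None   # necrosis rate of DIFF cells, 1/h
    T_A: Optional[float] = None       # apoptosis-product clearance time, h
    T_N: Optional[float] = None       # necrosis-product clearance time, h
    N_LIMP: Optional[int] = None      # LIMP mitoses before terminal differentiation

    def validate(self) -> None:
        for name in ("T_C_stem", "T_C_limp", "T_G0_stem", "T_G0_limp", "T_A", "T_N"):
            v = getattr(self, name)
            if v is None or v <= 0:
                raise ValueError(f"{name} must be a positive duration, got {v}")
        for name in ("R_A", "R_ADiff", "R_NDiff"):
            v = getattr(self, name)
            if v is None or v < 0:
                raise ValueError(f"{name} must be a nonnegative rate, got {v}")
        for name in ("P_G0toG1_stem", "P_G0toG1_limp", "P_sym", "P_sleep", "CKF_stem"):
            v = getattr(self, name)
            if v is None or not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.N_LIMP is None or self.N_LIMP < 1:
            raise ValueError(f"N_LIMP must be an integer >= 1, got {self.N_LIMP}")

    def replace(self, **kw) -> "KineticParameters":
        return dataclasses.replace(self, **kw)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {c: getattr(self, c) for c in PARAM_COLUMNS}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParameters":
        kw = {c: d[c] for c in PARAM_COLUMNS if c in d}
        if "N_LIMP" in kw and kw["N_LIMP"] is not None:
            kw["N_LIMP"] = int(round(kw["N_LIMP"]))
        return cls(**kw)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "KineticParameters":
        if hasattr(source, "read") or "\n" in str(source):
            data = yaml.safe_load(source if hasattr(source, "read") else io.StringIO(str(source)))
        else:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        return cls.from_dict(data)


def params_to_frame(sets: Iterable[KineticParameters]) -> pd.DataFrame:
    """Flatten parameter sets to one row each, columns named by Table-4 symbol."""
    return pd.DataFrame([p.to_dict() for p in sets], columns=PARAM_COLUMNS)


def params_from_frame(df: pd.DataFrame) -> list[KineticParameters]:
    return [KineticParameters.from_dict(row._asdict() if hasattr(row, "_asdict") else dict(row))
            for _, row in df.iterrows()]


@dataclass
class ProliferationProfile:
    """Macroscopic proliferation targets that calibration inverts into parameters.

    ``GF`` and ``SF`` are fractions of living cells, ``AF`` and ``NF``
    fractions of total (living + dead) cells.
    """

    T_d: float   # volume doubling time, days
    GF: float    # growth fraction: cycling / living
    AF: float    # apoptotic / total
    NF: float    # necrotic / total
    SF: float    # stem / living

    def validate(self) -> None:
        if self.T_d <= 0:
            raise ValueError("T_d must be positive for a viable tumor")
        for name in ("GF", "AF", "NF", "SF"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.AF + self.NF >= 1.0:
            raise ValueError("AF + NF must be < 1")

    @property
    def a(self) -> float:
        """Intrinsic exponential growth rate, 1/h."""
        return LN2 / (self.T_d * 24.0)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ProliferationProfile":
        if hasattr(source, "read") or "\n" in str(source):
            data = yaml.safe_load(source if hasattr(source, "read") else io.StringIO(str(source)))
        else:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        return cls(**data)


@dataclass
class GrowthSolution:
    """Steady-state description of a balanced exponentially growing tumor.

    Fractions of living cells: ``SF`` (stem), ``LF`` (LIMP), ``diff_fraction``
    (DIFF), ``GF`` (cycling), ``QF`` (dormant); fractions of total cells:
    ``AF`` (apoptotic), ``NF`` (necrotic).  ``ratio_*`` are the population
    ratios used by the calibration algebra.
    """

    a: float                 # intrinsic growth rate, 1/h
    T_d: float               # ln2/a in days (negative for shrinking tumors)
    negative_growth: bool
    A: float                 # mitosis flux per cycling cell (dimensionless intermediate)
    B: float                 # G0 occupancy per unit mitosis flux (intermediate)
    ratio_A_P: float         # N_A / N_P
    ratio_N_P: float         # N_N / N_P
    ratio_S_L: float         # N_S / N_L
    SF: float
    LF: float
    diff_fraction: float
    GF: float
    QF: float
    AF: float
    NF: float
    SLF: float               # SF / LF
    SDF: float               # SF / diff_fraction
    living_fraction: float   # living / total


# ---------------------------------------------------------------------------
# Growth-rate renewal equation
# ---------------------------------------------------------------------------

def _kappa(a: float, R_A: float, T_G0: float) -> float:
    """Discounted probability weight that a G0 exit is a cycle re-entry.

    G0 residence is memoryless with mean ``T_G0``; competing risks are the
    exit (rate 1/T_G0) and spontaneous apoptosis (rate R_A), discounted by
    the population growth ``a``.
    """
    return (1.0 / T_G0) / (a + R_A + 1.0 / T_G0)


def _renewal_lhs(a: float, p: KineticParameters) -> float:
    """(1+P_sym)·[(1−P_sleep) + P_sleep·P_G0toG1·κ]·e^{−(a+R_A)T_C} for stem cells.

    Balanced growth at rate ``a`` requires this discounted stem-cell
    reproduction number to equal 1.
    """
    kap = _kappa(a, p.R_A, p.T_G0_stem)
    gamma = (1.0 - p.P_sleep) + p.P_sleep * p.P_G0toG1_stem * kap
    return (1.0 + p.P_sym) * gamma * math.exp(-(a + p.R_A) * p.T_C_stem)


def solve_growth_rate(params: KineticParameters, *, full: bool = True) -> GrowthSolution:
    """Solve the stem-cell renewal equation for the intrinsic growth rate ``a``.

    The equation is solved by bracketed root finding on
    ``a ∈ [-0.1, 0.1] 1/h`` (restricted to the domain right of the pole at
    ``a = -(R_A + 1/T_G0)`` when dormancy re-entry contributes).  With
    ``full=True`` the complete balanced composition is returned.
    """
    if params.P_sleep is None or not 0.0 <= params.P_sleep <= 1.0:
        raise ProfileUnreachable("p_sleep_out_of_range",
                                 f"P_sleep={params.P_sleep} outside [0, 1]")
    lo, hi = GROWTH_RATE_BRACKET
    if params.P_sleep * params.P_G0toG1_stem > 0:
        pole = -(params.R_A + 1.0 / params.T_G0_stem)
        lo = max(lo, pole * (1.0 - 1e-12) + 1e-12)

    def f(a):
        return _renewal_lhs(a, params) - 1.0

    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ProfileUnreachable(
            "no_growth_rate_root",
            f"renewal equation has no root in [{lo:.3g}, {hi:.3g}] 1/h for "
            f"T_C_stem={params.T_C_stem}, T_G0_stem={params.T_G0_stem}, "
            f"P_sym={params.P_sym}, P_sleep={params.P_sleep}")
    a = brentq(f, lo, hi, xtol=1e-16, rtol=1e-14)
    if full:
        return balanced_composition(params, a=a)
    T_d = math.inf if a == 0 else LN2 / a / 24.0
    return GrowthSolution(a=a, T_d=T_d, negative_growth=a < 0, A=math.nan,
                          B=math.nan, ratio_A_P=math.nan, ratio_N_P=math.nan,
                          ratio_S_L=math.nan, SF=math.nan, LF=math.nan,
                          diff_fraction=math.nan, GF=math.nan, QF=math.nan,
                          AF=math.nan, NF=math.nan, SLF=math.nan, SDF=math.nan,
                          living_fraction=math.nan)


def _ilt(y: float, T: float) -> float:
    """Integrated discounted residence (1 - e^{-yT})/y, stable as y -> 0."""
    if abs(y * T) < 1e-8:
        return T * (1.0 - 0.5 * y * T)
    return -math.expm1(-y * T) / y


def balanced_composition(params: KineticParameters, a: Optional[float] = None) -> GrowthSolution:
    """Closed-form steady-state composition of the exponentially growing tumor.

    Stem and LIMP kinetics may differ.  Flux bookkeeping, per unit stem
    mitosis flux: each stem mitosis yields ``1+P_sym`` stem newborns and
    ``1-P_sym`` first-generation LIMP newborns; LIMP generation ``g``
    newborn flux is amplified by ``2·D_L`` per generation, where ``D_L`` is
    the discounted per-newborn mitosis probability; terminal mitoses feed
    the DIFF pool.  Dead-cell pools are memoryless with means ``T_A``/``T_N``.
    """
    params.validate()
    if a is None:
        a = solve_growth_rate(params, full=False).a
    p = params
    aR = a + p.R_A

    def class_coeffs(T_C, T_G0, P_G0):
        kap = _kappa(a, p.R_A, T_G0)
        gamma = (1.0 - p.P_sleep) + p.P_sleep * P_G0 * kap
        E = math.exp(-aR * T_C)
        g0_per_nb = p.P_sleep / (aR + 1.0 / T_G0)        # G0 cells per unit newborn flux
        cyc_per_nb = gamma * _ilt(aR, T_C)               # cycling cells per unit newborn flux
        D = gamma * E                                    # discounted mitoses per newborn
        return g0_per_nb, cyc_per_nb, D, kap

    g0_S, cyc_S, D_S, _ = class_coeffs(p.T_C_stem, p.T_G0_stem, p.P_G0toG1_stem)
    g0_L, cyc_L, D_L, _ = class_coeffs(p.T_C_limp, p.T_G0_limp, p.P_G0toG1_limp)

    f_S = 1.0 + p.P_sym                      # stem newborn flux per stem mitosis
    f1 = 1.0 - p.P_sym                       # LIMP gen-1 newborn flux
    amp = 2.0 * D_L
    n = p.N_LIMP
    # sum of newborn fluxes over LIMP generations, and terminal mitosis flux
    if abs(amp - 1.0) < 1e-12:
        f_sum = f1 * n
    else:
        f_sum = f1 * (amp ** n - 1.0) / (amp - 1.0)
    f_last = f1 * amp ** (n - 1)
    diff_inflow = 2.0 * f_last * D_L

    N_stem = f_S * (cyc_S + g0_S)
    N_limp = f_sum * (cyc_L + g0_L)
    N_P = f_S * cyc_S + f_sum * cyc_L
    N_G0 = f_S * g0_S + f_sum * g0_L
    denom_D = a + p.R_ADiff + p.R_NDiff
    if denom_D <= 0:
        raise ProfileUnreachable("diff_pool_divergent",
                                 "DIFF turnover slower than population shrinkage")
    N_D = diff_inflow / denom_D

    phi_A = p.R_A * (N_P + N_G0) + p.R_ADiff * N_D
    phi_N = ((1.0 - p.P_G0toG1_stem) / p.T_G0_stem * f_S * g0_S
             + (1.0 - p.P_G0toG1_limp) / p.T_G0_limp * f_sum * g0_L
             + p.R_NDiff * N_D)
    N_A = phi_A / (a + 1.0 / p.T_A)
    N_N = phi_N / (a + 1.0 / p.T_N)

    living = N_P + N_G0 + N_D
    total = living + N_A + N_N
    A = aR / math.expm1(aR * p.T_C_stem) if aR != 0 else 1.0 / p.T_C_stem
    B = (1.0 + p.P_sym) * p.P_sleep / (aR + 1.0 / p.T_G0_stem)
    SF = N_stem / living
    LF = N_limp / living
    diff_fraction = N_D / living
    GF = N_P / living
    QF = N_G0 / living
    T_d = math.inf if a == 0 else LN2 / a / 24.0
    return GrowthSolution(
        a=a, T_d=T_d, negative_growth=a < 0, A=A, B=B,
        ratio_A_P=N_A / N_P, ratio_N_P=N_N / N_P,
        ratio_S_L=N_stem / N_limp if N_limp > 0 else math.inf,
        SF=SF, LF=LF, diff_fraction=diff_fraction, GF=GF, QF=QF,
        AF=N_A / total, NF=N_N / total,
        SLF=SF / LF if LF > 0 else math.inf,
        SDF=SF / diff_fraction if diff_fraction > 0 else math.inf,
        living_fraction=living / total)


# ---------------------------------------------------------------------------
# Calibration of the dependent parameters (stem and LIMP kinetics identical)
# ---------------------------------------------------------------------------
#
# The closed forms below assume stem and LIMP cells share T_C, T_G0 and
# P_G0toG1 (the stem values are read); this is how the baseline profiles are
# constructed.  The subtype LHS workflow also samples shared kinetics.

def calibrate_p_sleep(profile: ProliferationProfile, independents: KineticParameters) -> float:
    """Dormancy-entry fraction that yields the target doubling time.

    Inverts the stem-cell renewal equation at ``a = ln2/(24·T_d)``:
    ``P_sleep = [1 − e^{(a+R_A)T_C}/(1+P_sym)] / [1 − P_G0toG1·κ]``.
    """
    p = independents
    a = profile.a
    num = 1.0 - math.exp((a + p.R_A) * p.T_C_stem) / (1.0 + p.P_sym)
    den = 1.0 - p.P_G0toG1_stem * _kappa(a, p.R_A, p.T_G0_stem)
    ps = num / den
    if not 0.0 <= ps <= 1.0:
        raise ProfileUnreachable(
            "p_sleep_out_of_range",
            f"calibrated P_sleep={ps:.6g} outside [0, 1] for T_d={profile.T_d} d")
    return ps


def calibrate_r_ndiff(profile: ProliferationProfile, independents: KineticParameters) -> float:
    """DIFF-cell necrosis rate that yields the target growth fraction.

    From the living-cell balance ``1/GF = 1 + A·B + (1−P_sym)·A/(a+R_ADiff+R_NDiff)``:
    ``R_NDiff = (1−P_sym) / [(1/GF − 1)/A − B] − a − R_ADiff``.
    """
    p = independents
    if not 0.0 < profile.GF < 1.0:
        raise ProfileUnreachable("gf_out_of_range", f"GF={profile.GF} not in (0, 1)")
    a = profile.a
    aR = a + p.R_A
    A = aR / math.expm1(aR * p.T_C_stem)
    B = (1.0 + p.P_sym) * p.P_sleep / (aR + 1.0 / p.T_G0_stem)
    denom = (1.0 / profile.GF - 1.0) / A - B
    if denom <= 0:
        raise ProfileUnreachable("r_ndiff_negative",
                                 f"GF={profile.GF} above the maximum reachable value")
    r = (1.0 - p.P_sym) / denom - a - p.R_ADiff
    if r < 0:
        raise ProfileUnreachable("r_ndiff_negative",
                                 f"calibrated R_NDiff={r:.6g} < 0 (profile unreachable)")
    return r


def _pool_ratios(profile: ProliferationProfile):
    """Apoptotic- and necrotic-to-proliferating population ratios.

    ``N_A/N_P = (AF/GF)/(1−AF−NF)`` and likewise for necrosis: AF and NF are
    fractions of total cells, GF of living cells, and living/total = 1−AF−NF.
    """
    living = 1.0 - profile.AF - profile.NF
    return (profile.AF / profile.GF) / living, (profile.NF / profile.GF) / living


def _flux_terms(profile: ProliferationProfile, p: KineticParameters):
    a = profile.a
    aR = a + p.R_A
    A = aR / math.expm1(aR * p.T_C_stem)
    B = (1.0 + p.P_sym) * p.P_sleep / (aR + 1.0 / p.T_G0_stem)
    AB = A * B                                     # N_G0 / N_P
    ND_NP = (1.0 - p.P_sym) * A / (a + p.R_ADiff + p.R_NDiff)
    return a, A, AB, ND_NP


def calibrate_t_a(profile: ProliferationProfile, independents: KineticParameters) -> float:
    """Apoptosis clearance time that yields the target apoptotic fraction.

    The apoptotic pool receives spontaneous deaths of cycling and dormant
    cells (rate ``R_A``) and of DIFF cells (rate ``R_ADiff``), and clears
    memorylessly: ``N_A = Φ_A/(a + 1/T_A)``, inverted for ``T_A``.
    """
    if profile.AF == 0:
        return 0.0
    p = independents
    a, A, AB, ND_NP = _flux_terms(profile, p)
    ratio_A_P, _ = _pool_ratios(profile)
    phi_A = p.R_A * (1.0 + AB) + p.R_ADiff * ND_NP      # inflow per cycling cell
    inv = phi_A / ratio_A_P - a
    if inv <= 0:
        raise ProfileUnreachable("t_a_nonpositive",
                                 f"AF={profile.AF} above the maximum reachable value")
    return 1.0 / inv


def calibrate_t_n(profile: ProliferationProfile, independents: KineticParameters) -> float:
    """Necrosis clearance time that yields the target necrotic fraction.

    Necrotic inflow: dormant cells whose G0 exit is not a cycle re-entry,
    plus DIFF necrosis: ``Φ_N = (1−P_G0toG1)·N_G0/T_G0 + R_NDiff·N_D``.
    """
    if profile.NF == 0:
        return 0.0
    p = independents
    a, A, AB, ND_NP = _flux_terms(profile, p)
    _, ratio_N_P = _pool_ratios(profile)
    phi_N = (1.0 - p.P_G0toG1_stem) / p.T_G0_stem * AB + p.R_NDiff * ND_NP
    inv = phi_N / ratio_N_P - a
    if inv <= 0:
        raise ProfileUnreachable("t_n_nonpositive",
                                 f"NF={profile.NF} above the maximum reachable value")
    return 1.0 / inv


def stem_to_limp_ratio(profile: ProliferationProfile, independents: KineticParameters) -> float:
    """N_S/N_L implied by the stem-fraction target: SF/[(1+N_G0/N_P)·GF − SF]."""
    p = independents
    a = profile.a
    aR = a + p.R_A
    A = aR / math.expm1(aR * p.T_C_stem)
    B = (1.0 + p.P_sym) * p.P_sleep / (aR + 1.0 / p.T_G0_stem)
    AB = A * B
    denom = (1.0 + AB) * profile.GF - profile.SF
    if denom <= 0 or profile.SF <= 0:
        raise ProfileUnreachable("sf_out_of_range",
                                 f"SF={profile.SF} incompatible with GF={profile.GF}")
    return profile.SF / denom


def solve_n_limp(profile: ProliferationProfile, independents: KineticParameters,
                 n_max: int = 64) -> int:
    """LIMP mitosis count matching the stem-fraction target.

    Solves ``Σ_{n=0}^{N−1} 2^n/(1+P_sym)^{n+1} = 1/[(1−P_sym)·N_S/N_L]``
    over the integers, returning the ``N`` minimising the residual.
    """
    p = independents
    r = stem_to_limp_ratio(profile, p)
    target = 1.0 / ((1.0 - p.P_sym) * r)
    best_n, best_err = None, math.inf
    s = 0.0
    for n in range(n_max):
        s += 2.0 ** n / (1.0 + p.P_sym) ** (n + 1)
        err = abs(s - target)
        if err < best_err:
            best_n, best_err = n + 1, err
    if best_n is None or (best_n == n_max and target > s):
        raise ProfileUnreachable("n_limp_out_of_range",
                                 f"no N_LIMP in [1, {n_max}] fits SF={profile.SF}")
    return best_n


@dataclass
class CalibrationResult:
    """Outcome of ``calibrate_full``: a parameter set, or the reasons it failed.

    Unreachable profiles are a *result*, not an exception: the subtype LHS
    workflow uses reachability as a filter.
    """

    ok: bool
    params: Optional[KineticParameters]
    reasons: list

    def __bool__(self):
        return self.ok


def calibrate_full(profile: ProliferationProfile, independents: KineticParameters,
                   mode: str = "baseline") -> CalibrationResult:
    """Chain the dependent-parameter calibrations for a full parameter set.

    ``mode="baseline"``: five dependents (P_sleep, R_NDiff, T_A, T_N, N_LIMP).
    ``mode="lhs"``: N_LIMP (and CKF_stem) are supplied with the independents
    and only the four continuous dependents are solved.
    """
    if mode not in ("baseline", "lhs"):
        raise ValueError(f"unknown calibration mode {mode!r}")
    profile.validate()
    p = independents
    reasons: list[str] = []
    try:
        p = p.replace(P_sleep=calibrate_p_sleep(profile, p))
        p = p.replace(R_NDiff=calibrate_r_ndiff(profile, p))
        p = p.replace(T_A=calibrate_t_a(profile, p))
        p = p.replace(T_N=calibrate_t_n(profile, p))
        if mode == "baseline":
            p = p.replace(N_LIMP=solve_n_limp(profile, p))
        elif p.N_LIMP is None:
            raise ValueError("lhs mode requires N_LIMP among the independents")
    except ProfileUnreachable as exc:
        reasons.append(exc.reason)
        return CalibrationResult(ok=False, params=None, reasons=reasons)
    return CalibrationResult(ok=True, params=p, reasons=[])


def report_duration_hours(hours: float) -> int:
    """Report a clearance duration as a whole number of hours, rounding up.

    Clearance times are reported conservatively at the simulator's one-hour
    tick so that the residence of death products is never understated.
    """
    return int(math.ceil(hours - 1e-9))
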