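"""OFAT and LHS/PRCC sensitivity machinery for the cell-kill-rate estimator.

*OFAT*: each parameter is perturbed ±10% (±5% for the strongly influential
fractions ``P_sym`` and ``P_sleep``) around its baseline, the output (the
estimated ``CKR_sum``) is recomputed, and the percentage output change is
normalised by the percentage change actually applied (integer parameters are
rounded, so the applied change can deviate from the nominal one).  The
variability-weighted score multiplies the mean elasticity by range/mean of
the parameter under a uniform distribution.

*LHS*: stratified uniform sampling (exactly one point per equal-probability
stratum per dimension), rescaled to each parameter's range; integer
parameters rounded.

*PRCC*: inputs and output are replaced by their ranks (ties get average
ranks); each input's partial correlation with the output, controlling for
the remaining inputs, is the Pearson correlation of the residuals of
rank-space linear regressions on the controls.  Significance uses the t
distribution with N − 2 − (number of controls) degrees of freedom;
P < .01 is flagged as significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .model_core import (KineticParameters, ProfileUnreachable,
                         balanced_composition)

__all__ = [
    "TABLE4_RANGES",
    "ParameterRanges",
    "OfatMeasure",
    "ofat_measures",
    "ofat_score",
    "ofat_study",
    "lhs_sample",
    "FilterResult",
    "apply_filters",
    "prcc",
    "proliferation_features",
    "shrinkage_scenario_case",
    "scenario_ckr_sum",
    "FEATURE_NAMES",
]

#: Free-growth parameter value ranges (literature-survey bounds).
TABLE4_RANGES = {
    "T_C_stem": (18.0, 134.0),
    "T_C_limp": (18.0, 134.0),
    "T_G0_stem": (90.0, 1200.0),
    "T_G0_limp": (90.0, 1200.0),
    "T_A": (1.0, 25.0),
    "T_N": (1.0, 200.0),
    "R_A": (0.0, 0.001),
    "R_ADiff": (0.0001, 0.02),
    "R_NDiff": (0.0, 0.02),
    "P_G0toG1_stem": (0.0, 1.0),
    "P_G0toG1_limp": (0.0, 1.0),
    "P_sym": (0.0, 0.4),
    "P_sleep": (0.0, 1.0),
    "N_LIMP": (8, 24),
    "CKF_stem": (0.0, 1.0),
}

INTEGER_PARAMS = frozenset({"N_LIMP"})

#: Parameters perturbed by ±5% instead of ±10% in the OFAT study.
NARROW_DELTA_PARAMS = frozenset({"P_sym", "P_sleep"})

FEATURE_NAMES = ("T_d", "SF", "LF", "GF", "QF", "AF", "NF", "SLF", "SDF")


@dataclass
class ParameterRanges:
    """Per-parameter [lo, hi] bounds with integer flags and linkage groups.

    ``linked`` maps a sampled name to the parameter fields it populates
    (e.g. a shared ``T_C`` drives both stem and LIMP cycle times).
    """

    bounds: dict
    integer: frozenset = INTEGER_PARAMS
    linked: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"empty range for {name}: [{lo}, {hi}]")

    @property
    def names(self) -> list:
        return list(self.bounds)

    def expand(self, row: dict) -> dict:
        out = {}
        for name, value in row.items():
            for target in self.linked.get(name, (name,)):
                out[target] = value
        return out


# ---------------------------------------------------------------------------
# OFAT
# ---------------------------------------------------------------------------

@dataclass
class OfatMeasure:
    parameter: str
    sm_plus: float          # elasticity for the upward perturbation
    sm_minus: float         # elasticity for the downward perturbation
    applied_plus: float     # relative input change actually applied
    applied_minus: float
    failed: bool = False


def _perturb(baseline: KineticParameters, which: str, rel: float):
    value = getattr(baseline, which)
    new = value * (1.0 + rel)
    if which in INTEGER_PARAMS:
        new = int(round(new))
        if new == value:     # rounding swallowed the perturbation entirely
            new = value + (1 if rel > 0 else -1)
    applied = (new - value) / value
    return baseline.replace(**{which: new}), applied


def ofat_measures(evaluate: Callable[[KineticParameters], float],
                  baseline: KineticParameters, which: str,
                  delta: Optional[float] = None) -> OfatMeasure:
    """Elasticities of ``evaluate`` to a ±delta perturbation of one parameter.

    The denominator uses the magnitude of the input change actually applied
    (which differs from ±delta for integer parameters after rounding), so a
    monotone increasing response yields SM+ > 0 > SM-.
    """
    if delta is None:
        delta = 0.05 if which in NARROW_DELTA_PARAMS else 0.10
    base_out = evaluate(baseline)
    if base_out == 0:
        raise ValueError("baseline output is zero; elasticity undefined")
    sms, applied = [], []
    failed = False
    for sign in (+1, -1):
        p, app = _perturb(baseline, which, sign * delta)
        try:
            out = evaluate(p)
            # normalise by the magnitude of the applied change, keeping the
            # sign of the output change: a positive input-output correlation
            # then shows as SM+ > 0 and SM- < 0, and the score's
            # |(SM+ - SM-)/2| averages the two magnitudes
            sms.append(((out - base_out) / base_out) / abs(app))
        except Exception:
            sms.append(math.nan)
            failed = True
        applied.append(app)
    return OfatMeasure(parameter=which, sm_plus=sms[0], sm_minus=sms[1],
                       applied_plus=applied[0], applied_minus=applied[1],
                       failed=failed)


def ofat_score(sm_plus: float, sm_minus: float,
               value_range: tuple) -> float:
    """Variability-weighted sensitivity score |(SM_plus - SM_minus)/2| * range/mean.

    The mean assumes a uniform distribution over the value range.
    """
    lo, hi = value_range
    mean = 0.5 * (lo + hi)
    if mean == 0:
        raise ValueError("zero-mean parameter range; score undefined")
    return abs(0.5 * (sm_plus - sm_minus)) * (hi - lo) / mean


def ofat_study(evaluate: Callable[[KineticParameters], float],
               baseline: KineticParameters,
               parameters: Sequence[str],
               ranges: Optional[dict] = None) -> pd.DataFrame:
    """Run ofat_measures over several parameters and attach scores."""
    ranges = ranges or TABLE4_RANGES
    rows = []
    for name in parameters:
        m = ofat_measures(evaluate, baseline, name)
        score = math.nan
        if name in ranges and not m.failed:
            score = ofat_score(m.sm_plus, m.sm_minus, ranges[name])
        rows.append({"parameter": name, "SM_plus": m.sm_plus,
                     "SM_minus": m.sm_minus, "SC": score,
                     "applied_plus": m.applied_plus,
                     "applied_minus": m.applied_minus, "failed": m.failed})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Latin hypercube sampling
# ---------------------------------------------------------------------------

def lhs_sample(ranges, N: int, seed) -> pd.DataFrame:
    """Latin hypercube sample of N rows over the given parameter ranges.

    Per column, exactly one point falls in each of the N equal strata of
    [0, 1] before rescaling to [lo, hi]; integer parameters are rounded
    after rescaling.  Deterministic for a fixed (ranges, N, seed).
    """
    if N < 2:
        raise ValueError("LHS needs N >= 2")
    if not isinstance(ranges, ParameterRanges):
        ranges = ParameterRanges(bounds=dict(ranges))
    names = ranges.names
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(N)
    data = {}
    for j, name in enumerate(names):
        lo, hi = ranges.bounds[name]
        col = lo + (hi - lo) * unit[:, j]
        if name in ranges.integer:
            col = np.round(col).astype(int)
        data[name] = col
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Biological filters
# ---------------------------------------------------------------------------

@dataclass
class FilterResult:
    mask: np.ndarray             # True = kept
    reasons: list                # list[list[str]] per row
    counts: dict                 # reason -> number of rows carrying it

    @property
    def n_kept(self) -> int:
        return int(self.mask.sum())


#: Exclusion thresholds of the two filtering presets.
SENSITIVITY_PRESET = {"min_T_d": 26.0, "max_SF": 1e-3}
CLINICAL_PRESET = {"max_SF": 1e-3, "max_T_A": 24.0, "max_T_N": 200.0,
                   "max_R_NDiff": 0.02, "T_d_rel_tol": 0.10}


def _row_params(row: dict) -> KineticParameters:
    return KineticParameters.from_dict(row)


def apply_filters(sample: pd.DataFrame, preset: str,
                  target_T_d: Optional[float] = None) -> FilterResult:
    """Mask biologically non-relevant parameter sets, with reason codes.

    ``preset="sensitivity"`` (free LHS over all parameters): excludes
    negative or undefined growth rates, doubling times below 26 days and
    stem-cell fractions above 1 per mille.  ``preset="clinical"`` (subtype-
    calibrated sample): excludes unreachable calibrations (negative
    ``P_sleep``/``R_NDiff``), realized doubling times beyond ±10% of the
    subtype target, stem fractions above 1 per mille, ``T_A`` > 24 h,
    ``T_N`` > 200 h and ``R_NDiff`` > 0.02 1/h.
    """
    if preset not in ("sensitivity", "clinical"):
        raise ValueError(f"unknown preset {preset!r}")
    if preset == "clinical" and target_T_d is None:
        raise ValueError("clinical preset needs the subtype target_T_d")
    n = len(sample)
    mask = np.ones(n, dtype=bool)
    reasons: list = [[] for _ in range(n)]
    for i, (_, row) in enumerate(sample.iterrows()):
        row_reasons = _filter_row(dict(row), preset, target_T_d)
        reasons[i] = row_reasons
        if row_reasons:
            mask[i] = False
    counts: dict = {}
    for rs in reasons:
        for r in rs:
            counts[r] = counts.get(r, 0) + 1
    return FilterResult(mask=mask, reasons=reasons, counts=counts)


def _filter_row(row: dict, preset: str, target_T_d) -> list:
    out = []
    if preset == "sensitivity":
        try:
            comp = balanced_composition(_row_params(row))
        except (ProfileUnreachable, ValueError) as exc:
            return [getattr(exc, "reason", "invalid_parameters")]
        if comp.negative_growth or not math.isfinite(comp.T_d):
            return ["negative_growth"]
        if comp.T_d < SENSITIVITY_PRESET["min_T_d"]:
            out.append("T_d_below_26d")
        if comp.SF > SENSITIVITY_PRESET["max_SF"]:
            out.append("SF_above_1_permille")
        return out
    # clinical preset: rows carry calibrated dependents and derived features
    if row.get("unreachable_reason"):
        return [str(row["unreachable_reason"])]
    pr = CLINICAL_PRESET
    if not (0.0 <= row["P_sleep"] <= 1.0):
        out.append("P_sleep_out_of_range")
    if row["R_NDiff"] < 0:
        out.append("R_NDiff_negative")
    elif row["R_NDiff"] > pr["max_R_NDiff"]:
        out.append("R_NDiff_above_0.02")
    if row["T_A"] <= 0 or row["T_A"] > pr["max_T_A"]:
        out.append("T_A_outside_(0,24]h")
    if row["T_N"] <= 0 or row["T_N"] > pr["max_T_N"]:
        out.append("T_N_outside_(0,200]h")
    if "SF" in row and row["SF"] > pr["max_SF"]:
        out.append("SF_above_1_permille")
    if "realized_T_d" in row:
        if not math.isfinite(row["realized_T_d"]) or row["realized_T_d"] <= 0:
            out.append("negative_growth")
        elif abs(row["realized_T_d"] - target_T_d) > pr["T_d_rel_tol"] * target_T_d:
            out.append("T_d_beyond_10pct")
    return out


# ---------------------------------------------------------------------------
# PRCC
# ---------------------------------------------------------------------------

def prcc(inputs, output, names: Optional[Sequence[str]] = None,
         alpha: float = 0.01) -> pd.DataFrame:
    """Partial rank correlation of each input with the output.

    Controls for all remaining inputs.  Returns a frame with columns
    ``parameter``, ``prcc``, ``p_value``, ``significant``.
    """
    if isinstance(inputs, pd.DataFrame):
        names = list(inputs.columns) if names is None else list(names)
        X = inputs.to_numpy(dtype=float)
    else:
        X = np.asarray(inputs, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])] if names is None else list(names)
    y = np.asarray(output, dtype=float)
    n, p = X.shape
    if n <= p + 2:
        raise ValueError(f"need N > P + 2 (got N={n}, P={p})")
    ranks_X = np.column_stack([stats.rankdata(X[:, j]) for j in range(p)])
    ranks_y = stats.rankdata(y)
    dof = n - 2 - (p - 1)
    rows = []
    ones = np.ones((n, 1))
    for j in range(p):
        controls = np.delete(ranks_X, j, axis=1)
        Z = np.hstack([ones, controls])
        # rank-deficiency check: collinear controls make the partial
        # correlation ill-defined
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise np.linalg.LinAlgError(
                f"collinear control columns when excluding {names[j]!r}")
        beta_x, *_ = np.linalg.lstsq(Z, ranks_X[:, j], rcond=None)
        beta_y, *_ = np.linalg.lstsq(Z, ranks_y, rcond=None)
        rx = ranks_X[:, j] - Z @ beta_x
        ry = ranks_y - Z @ beta_y
        denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
        r = float(rx @ ry) / denom if denom > 0 else 0.0
        r = max(-1.0, min(1.0, r))
        if abs(r) >= 1.0:
            pval = 0.0
        else:
            t = r * math.sqrt(dof / (1.0 - r * r))
            pval = 2.0 * stats.t.sf(abs(t), dof)
        rows.append({"parameter": names[j], "prcc": r, "p_value": pval,
                     "significant": pval < alpha})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Virtual-tumor scenario used by the sensitivity studies
# ---------------------------------------------------------------------------

def shrinkage_scenario_case(target_reduction_pct: float = 72.0,
                            initial_volume: float = 925.0,
                            pre_growth_days: float = 7.0,
                            n_cycles: int = 3,
                            partner: str = "gemcitabine",
                            ckr_b: float = 0.2,
                            measure_day: float = 49.0):
    """The virtual tumor against which sensitivity of CKR_sum is measured.

    A 925 mm^3 sphere grows freely for one week, then receives three
    three-week cisplatin+partner cycles (partner repeated on day 8 of each
    cycle); the target is a 72% volume reduction, relative to the initial
    volume, on simulation day 49.  Packaged as a synthetic clinical case so
    the CKR root-solver applies unchanged.
    """
    from .estimation import ClinicalCase   # local import to avoid a cycle
    rows = []
    for k in range(n_cycles):
        day1 = 1 + 21 * k
        rows.append((day1, partner))
        rows.append((day1, "cisplatin"))
        rows.append((day1 + 7, partner))
    rows = [(d, drug) for d, drug in sorted(rows)
            if d - 1 + pre_growth_days <= measure_day]
    v1 = initial_volume * (1.0 - target_reduction_pct / 100.0)
    return ClinicalCase(case_id="virtual-72pct", histology="SCC",
                        V0=initial_volume, V1=v1,
                        interval_cts=measure_day,
                        interval_ct1_to_onset=pre_growth_days,
                        schedule_rows=rows, CKR_B=ckr_b)


def scenario_ckr_sum(params: KineticParameters, ckr_b: float = 0.2,
                     case=None, **sim_kw) -> float:
    """Estimated CKR_sum (cisplatin + partner) for the shrinkage scenario."""
    from .estimation import estimate_ckr_cis
    if case is None:
        case = shrinkage_scenario_case(ckr_b=ckr_b)
    return estimate_ckr_cis(case, params, ckr_b, **sim_kw) + ckr_b


@dataclass
class PrccStudy:
    """Result of the LHS -> CKR_sum -> PRCC pipeline.

    ``frame`` holds the surviving parameter sets with their estimated
    CKR_sum and proliferation features; ``prcc_parameters`` correlates
    CKR_sum with the sampled model parameters, ``prcc_features`` with the
    macroscopic features (T_d, SF, LF, GF, QF, AF, NF).
    """

    frame: pd.DataFrame
    prcc_parameters: pd.DataFrame
    prcc_features: pd.DataFrame
    n_sampled: int
    n_survivors: int
    n_estimated: int
    filter_counts: dict


def lhs_prcc_pipeline(N: int, seed, *, ranges=None, ckr_b: float = 0.2,
                      **sim_kw) -> PrccStudy:
    """Global sensitivity of the estimated CKR_sum over the parameter space.

    Draws a Latin hypercube over the free-growth parameter ranges, discards
    biologically non-relevant sets (negative growth, doubling time below 26
    days, stem fraction above 1 per mille), root-solves the cisplatin CKR
    for the 72%-shrinkage virtual-tumor scenario per surviving set, and
    runs both PRCC studies (inputs = model parameters; inputs =
    proliferation features at diagnosis).
    """
    from .estimation import CKRNoSolution, estimate_ckr_cis
    ranges = dict(ranges or TABLE4_RANGES)
    sample = lhs_sample(ranges, N, seed)
    filt = apply_filters(sample, "sensitivity")
    survivors = sample[filt.mask].reset_index(drop=True)
    case = shrinkage_scenario_case(ckr_b=ckr_b)
    rows = []
    for _, srow in survivors.iterrows():
        params = KineticParameters.from_dict(dict(srow))
        rec = dict(srow)
        try:
            ckr_cis = estimate_ckr_cis(case, params, ckr_b, **sim_kw)
            rec["CKR_sum"] = ckr_cis + ckr_b
        except (CKRNoSolution, ProfileUnreachable):
            rec["CKR_sum"] = math.nan
        rec.update(proliferation_features(params))
        rows.append(rec)
    frame = pd.DataFrame(rows)
    good = frame.dropna(subset=["CKR_sum"])
    param_names = list(ranges)
    prcc_params = prcc(good[param_names], good["CKR_sum"])
    feat_names = ["T_d", "SF", "LF", "GF", "QF", "AF", "NF"]
    prcc_feats = prcc(good[feat_names], good["CKR_sum"])
    return PrccStudy(frame=frame, prcc_parameters=prcc_params,
                     prcc_features=prcc_feats, n_sampled=N,
                     n_survivors=len(survivors), n_estimated=len(good),
                     filter_counts=filt.counts)


def proliferation_features(params: KineticParameters) -> dict:
    """Macroscopic proliferation features of the balanced-growth tumor.

    The features refer to the untreated tumor at diagnosis: doubling time
    and the population constitution (stem/LIMP fractions of living cells,
    growth and dormant fractions, apoptotic/necrotic fractions of total
    cells, and the stem-to-LIMP and stem-to-DIFF ratios).
    """
    comp = balanced_composition(params)
    return {"T_d": comp.T_d, "SF": comp.SF, "LF": comp.LF, "GF": comp.GF,
            "QF": comp.QF, "AF": comp.AF, "NF": comp.NF, "SLF": comp.SLF,
            "SDF": comp.SDF}
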