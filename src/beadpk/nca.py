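"""Non-compartmental analysis of concentration-time profiles.

Implements the standard NCA parameter set: linear-trapezoid AUC over the
quantifiable span, terminal log-linear regression (with ``beta = slope *
(-2.303)`` and ``T1/2 = 0.693 / beta``, using the printed decimal constants
rather than ln(2)/ln(10) so the reported formulas are reproduced verbatim),
observed Cmax/Tmax, extrapolation to infinite time by ``C_last / k``,
dose-normalised AUC, clearance (CL for IV, apparent CL/F for bead
delivery) and cross-route bioavailability.

BLOQ handling: points below the limit of quantification that precede the
first quantifiable point enter the AUC as concentration 0; embedded and
trailing BLOQ points are excluded from both the AUC span and the terminal
fit (no imputation).

Terminal-window policy (the "lambda-z" choice): among candidate windows
consisting of the last ``m`` quantifiable points strictly after Tmax
(``m = 3 ... all``), the fit with the highest adjusted R-squared wins; ties
go to the longer window.  An explicit time range overrides the search.

A fit is *accepted* only when the slope is negative and statistically
established (``|slope| >= t_min * SE(slope)``, default ``t_min = 2``).
Flat or indeterminate terminal phases are thereby classified as
non-conforming — the study this emulates likewise excluded half-lives for
"insufficient or non-conforming data" — rather than being allowed to
produce arbitrarily large ``C_last/k`` extrapolations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError, InsufficientDataError
from .profiles import ConcentrationProfile, DoseRecord, Route, SummaryStat

__all__ = [
    "LambdaZPolicy",
    "TerminalFit",
    "NCAResult",
    "BioavailabilityResult",
    "auc_trapezoid",
    "fit_terminal_slope",
    "half_life",
    "cmax_tmax",
    "extrapolate_auc",
    "normalize_auc",
    "clearance",
    "bioavailability",
    "run_nca",
    "summarize",
]

#: printed-formula constants: T1/2 = HALF_LIFE_NUMERATOR / beta,
#: beta = slope * (-LOG10_TO_LN)
HALF_LIFE_NUMERATOR = 0.693
LOG10_TO_LN = 2.303

#: extrapolated AUC fraction above which a quality flag is raised
EXTRAPOLATION_FLAG_THRESHOLD = 0.20

#: extrapolated AUC fraction above which AUC(0-inf) and everything derived
#: from it are considered non-conforming (the tail would exceed the observed
#: area) and reported as absent
EXTRAPOLATION_VALIDITY_LIMIT = 0.50

DEFAULT_REFERENCE_DOSE_MG = 174.0


@dataclass(frozen=True)
class LambdaZPolicy:
    """Terminal-window selection policy.

    ``min_points`` is the smallest admissible window; ``t_start_h`` /
    ``t_end_h``, when set, pin the window to an explicit time range instead
    of the adjusted-R^2 search.  ``t_min`` is the minimum t-statistic of the
    (negative) slope for the fit to be accepted; 0 disables the precision
    requirement and accepts any negative slope.
    """

    min_points: int = 3
    t_start_h: float | None = None
    t_end_h: float | None = None
    t_min: float = 2.0

    def __post_init__(self):
        if self.min_points < 3:
            raise DomainError("min_points must be >= 3")
        if self.t_min < 0:
            raise DomainError("t_min must be >= 0")


DEFAULT_POLICY = LambdaZPolicy()


@dataclass(frozen=True)
class TerminalFit:
    """Terminal log-linear regression result."""

    slope_log10_per_h: float
    beta_per_h: float
    k_per_h: float
    se_k_per_h: float
    r_squared: float
    n_points: int
    t_first_h: float
    t_last_h: float
    accepted: bool


@dataclass
class NCAResult:
    """All per-profile NCA parameters; absent fields are None with a flag."""

    subject_id: str
    phase: str
    route: str
    analyte: str
    dose_mg: float
    auc_0_t_ng_h_ml: float | None = None
    auc_0_inf_ng_h_ml: float | None = None
    n_auc_0_inf_ng_h_ml: float | None = None
    extrapolated_fraction: float | None = None
    t_half_h: float | None = None
    c_max_ng_ml: float | None = None
    t_max_min: float | None = None
    clearance_ml_min: float | None = None
    terminal: TerminalFit | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def k_per_h(self) -> float | None:
        return self.terminal.k_per_h if self.terminal is not None else None


@dataclass(frozen=True)
class BioavailabilityResult:
    """Per-subject, per-cycle bioavailability of the bead route vs IV."""

    subject_id: str
    cycle: str
    f_percent: float


def _auc_series(profile: ConcentrationProfile) -> tuple[np.ndarray, np.ndarray]:
    """Times/concentrations entering the AUC: leading BLOQ as 0, embedded
    and trailing BLOQ dropped, span ending at the last quantifiable point."""
    pts = profile.points
    quant_idx = [i for i, p in enumerate(pts) if p.quantifiable]
    if not quant_idx:
        return np.array([]), np.array([])
    first, last = quant_idx[0], quant_idx[-1]
    times, concs = [], []
    for i, p in enumerate(pts[: last + 1]):
        if i < first:
            times.append(p.time_h)
            concs.append(0.0)
        elif p.quantifiable:
            times.append(p.time_h)
            concs.append(p.conc_ng_ml)
    return np.array(times), np.array(concs)


def auc_trapezoid(profile: ConcentrationProfile) -> float:
    """Linear-trapezoid AUC (ng*h/ml) over the quantifiable span."""
    times, concs = _auc_series(profile)
    if len(times) < 2:
        raise InsufficientDataError(
            f"AUC needs >= 2 usable points, got {len(times)} "
            f"({profile.subject_id}/{profile.phase.value}/{profile.analyte.value})"
        )
    return float(np.trapezoid(concs, times))


def _ols_log10(times: np.ndarray, concs: np.ndarray) -> tuple[float, float, float]:
    """OLS slope of log10(conc) on time, the fit's R^2, and SE(slope)."""
    y = np.log10(concs)
    n = len(times)
    tbar, ybar = times.mean(), y.mean()
    sxx = float(np.sum((times - tbar) ** 2))
    sxy = float(np.sum((times - tbar) * (y - ybar)))
    syy = float(np.sum((y - ybar) ** 2))
    slope = sxy / sxx
    if syy == 0.0:
        r2 = 1.0 if slope == 0.0 else 0.0
    else:
        r2 = min(1.0, max(0.0, sxy * sxy / (sxx * syy)))
    rss = max(syy - slope * sxy, 0.0)
    se = math.sqrt(rss / (n - 2) / sxx) if n > 2 else 0.0
    return slope, r2, se


def fit_terminal_slope(
    profile: ConcentrationProfile, policy: LambdaZPolicy = DEFAULT_POLICY
) -> TerminalFit:
    """Fit the terminal elimination slope on log10 concentrations.

    Only quantifiable points strictly after Tmax are eligible.  A fit whose
    slope is non-negative, or not statistically established at the policy's
    ``t_min``, is returned with ``accepted=False`` (non-conforming data).
    """
    pts = [p for p in profile.quantifiable_points() if p.conc_ng_ml > 0]
    if not pts:
        raise InsufficientDataError("no quantifiable points for terminal fit")
    c_max = max(p.conc_ng_ml for p in pts)
    t_max = min(p.time_h for p in pts if p.conc_ng_ml == c_max)
    eligible = [p for p in pts if p.time_h > t_max]
    if policy.t_start_h is not None:
        eligible = [p for p in eligible if p.time_h >= policy.t_start_h]
    if policy.t_end_h is not None:
        eligible = [p for p in eligible if p.time_h <= policy.t_end_h]
    if len(eligible) < policy.min_points:
        raise InsufficientDataError(
            f"terminal fit needs >= {policy.min_points} quantifiable points "
            f"after Tmax, got {len(eligible)}"
        )
    times = np.array([p.time_h for p in eligible])
    concs = np.array([p.conc_ng_ml for p in eligible])

    if policy.t_start_h is not None or policy.t_end_h is not None:
        candidate_sizes = [len(eligible)]
    else:
        candidate_sizes = range(policy.min_points, len(eligible) + 1)

    # prefer conforming windows (negative, statistically established slope);
    # fall back to the best overall window, returned as rejected
    best: tuple[bool, float, int] | None = None  # (conforming, adj R^2, m)
    best_fit: tuple[float, float, float, int] | None = None
    for m in candidate_sizes:
        t_win, c_win = times[-m:], concs[-m:]
        slope, r2, se = _ols_log10(t_win, c_win)
        adj = 1.0 - (1.0 - r2) * (m - 1) / (m - 2)
        conforming = slope < 0 and (
            policy.t_min == 0 or se == 0 or -slope >= policy.t_min * se
        )
        key = (conforming, adj, m)
        if best is None or key > best:
            best = key
            best_fit = (slope, r2, se, m)

    slope, r2, se, m = best_fit
    beta = slope * (-LOG10_TO_LN)
    established = bool(best[0])
    return TerminalFit(
        slope_log10_per_h=slope,
        beta_per_h=beta,
        k_per_h=beta,
        se_k_per_h=se * LOG10_TO_LN,
        r_squared=r2,
        n_points=m,
        t_first_h=float(times[-m]),
        t_last_h=float(times[-1]),
        accepted=established,
    )


def half_life(k_per_h: float) -> float:
    """Terminal half-life ``0.693 / k`` in hours."""
    if not k_per_h > 0:
        raise DomainError(f"k_per_h must be > 0, got {k_per_h!r}")
    return HALF_LIFE_NUMERATOR / k_per_h


def cmax_tmax(profile: ConcentrationProfile) -> tuple[float, float]:
    """Maximum observed quantifiable concentration and its time in minutes.

    Ties are broken by the earliest time.
    """
    pts = profile.quantifiable_points()
    if not pts:
        raise InsufficientDataError("all points are BLOQ; no Cmax")
    c_max = max(p.conc_ng_ml for p in pts)
    t_max = min(p.time_h for p in pts if p.conc_ng_ml == c_max)
    return float(c_max), float(t_max * 60.0)


def extrapolate_auc(auc_0_t: float, c_last: float, k_per_h: float) -> float:
    """AUC extended to infinite time: ``AUC(0-t) + C_last / k``."""
    if not k_per_h > 0:
        raise DomainError(f"k_per_h must be > 0, got {k_per_h!r}")
    if not c_last >= 0:
        raise DomainError(f"c_last must be >= 0, got {c_last!r}")
    return auc_0_t + c_last / k_per_h


def normalize_auc(
    auc_0_inf: float, dose_mg: float, reference_dose_mg: float = DEFAULT_REFERENCE_DOSE_MG
) -> float:
    """Rescale AUC(0-inf) linearly to the reference dose (linear PK)."""
    if not dose_mg > 0:
        raise DomainError(f"dose_mg must be > 0, got {dose_mg!r}")
    if not reference_dose_mg > 0:
        raise DomainError("reference_dose_mg must be > 0")
    return auc_0_inf * reference_dose_mg / dose_mg


def clearance(dose_mg: float, auc_0_inf_ng_h_ml: float) -> float:
    """Dose / AUC(0-inf) in ml/min (CL for IV, CL/F for bead delivery)."""
    if not dose_mg > 0 or not auc_0_inf_ng_h_ml > 0:
        raise DomainError("dose and AUC must be > 0 for clearance")
    return dose_mg * 1e6 / auc_0_inf_ng_h_ml / 60.0


def bioavailability(n_auc_bead: float, n_auc_iv: float) -> float:
    """Bead-route bioavailability in percent: 100 * nAUC_bead / nAUC_iv."""
    if not n_auc_bead > 0 or not n_auc_iv > 0:
        raise DomainError("normalised AUCs must be > 0")
    return 100.0 * n_auc_bead / n_auc_iv


def run_nca(
    profile: ConcentrationProfile,
    dose_record: DoseRecord | None = None,
    config=None,
) -> NCAResult:
    """Full NCA of one profile with "where possible" semantics.

    Every sub-parameter whose precondition fails is left absent and a flag
    recorded; no failure of one parameter blocks the others.  ``config``
    may supply ``reference_dose_mg``, ``lambda_z_policy`` and
    ``max_extrapolated_fraction``.

    AUC(0-inf) is reported only while the extrapolated tail stays within
    ``max_extrapolated_fraction`` of the total; beyond that the terminal
    phase is too poorly determined for the extension (and the clearance and
    normalised exposure derived from it) to mean anything, and those fields
    are left absent with an ``extrapolation_exceeds_limit`` flag.
    """
    reference_dose = getattr(config, "reference_dose_mg", DEFAULT_REFERENCE_DOSE_MG)
    policy = getattr(config, "lambda_z_policy", DEFAULT_POLICY)
    max_extrap = getattr(
        config, "max_extrapolated_fraction", EXTRAPOLATION_VALIDITY_LIMIT
    )
    dose = dose_record.dose_mg if dose_record is not None else profile.dose_mg

    result = NCAResult(
        subject_id=profile.subject_id,
        phase=profile.phase.value,
        route=profile.route.value,
        analyte=profile.analyte.value,
        dose_mg=dose,
    )

    try:
        result.c_max_ng_ml, result.t_max_min = cmax_tmax(profile)
    except InsufficientDataError:
        result.flags.append("no_quantifiable_points")
        return result

    try:
        result.auc_0_t_ng_h_ml = auc_trapezoid(profile)
    except InsufficientDataError:
        result.flags.append("auc_insufficient_points")

    try:
        fit = fit_terminal_slope(profile, policy)
        result.terminal = fit
        if not fit.accepted:
            result.flags.append(
                "terminal_slope_nonnegative"
                if fit.slope_log10_per_h >= 0
                else "terminal_slope_not_established"
            )
    except InsufficientDataError:
        result.flags.append("terminal_fit_insufficient_points")

    fit = result.terminal
    if fit is not None and fit.accepted:
        result.t_half_h = half_life(fit.k_per_h)
        if result.auc_0_t_ng_h_ml is not None:
            quant = profile.quantifiable_points()
            c_last = quant[-1].conc_ng_ml
            auc_inf = extrapolate_auc(result.auc_0_t_ng_h_ml, c_last, fit.k_per_h)
            extrap = (auc_inf - result.auc_0_t_ng_h_ml) / auc_inf
            result.extrapolated_fraction = extrap
            if extrap > max_extrap:
                result.flags.append("extrapolation_exceeds_limit")
            else:
                result.auc_0_inf_ng_h_ml = auc_inf
                if extrap > EXTRAPOLATION_FLAG_THRESHOLD:
                    result.flags.append("high_extrapolation")
                result.n_auc_0_inf_ng_h_ml = normalize_auc(auc_inf, dose, reference_dose)
                result.clearance_ml_min = clearance(dose, auc_inf)

    return result


def summarize(values) -> SummaryStat:
    """Arithmetic mean, sample SD (n-1) and CV% of a list of values."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise DomainError("summarize requires at least one value")
    mean = float(arr.mean())
    sd = 0.0 if arr.size == 1 else float(arr.std(ddof=1))
    if mean != 0.0:
        cv = 100.0 * sd / mean
    else:
        cv = 0.0 if sd == 0.0 else math.nan
    return SummaryStat(mean=mean, sd=sd, cv_percent=cv, n=int(arr.size))
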