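"""Forward compartmental models for both delivery routes, and model fitting.

The disposition model is a two-compartment mammillary model parameterised by
clearance ``CL`` (ml/min), central volume ``V1`` (ml), inter-compartmental
flow ``Q`` (ml/min) and peripheral volume ``V2`` (ml).  Internally these are
converted to first-order micro-constants (per hour)::

    k10 = CL/V1,   k12 = Q/V1,   k21 = Q/V2

and to the hybrid macro-constants ``alpha > beta > 0`` (roots of
``s**2 - (k10+k12+k21)*s + k10*k21``).  The unit-bolus impulse response of
the central compartment is the bi-exponential

    C(t) = (dose/V1) * (A exp(-alpha t) + B exp(-beta t)),
    A = (alpha-k21)/(alpha-beta),  B = (k21-beta)/(alpha-beta).

Two inputs are modelled:

* ``simulate_iv`` — constant-rate infusion of a given duration.  Sample
  times are expressed on the *post-infusion clock* (time since the end of
  the infusion), matching how the blood-sampling schedule is anchored; the
  function offsets internally.
* ``simulate_bead`` — drug-eluting-bead delivery: a fraction of the loaded
  dose is displaced into the suspension medium and acts as an immediate
  intra-arterial bolus, while the remainder elutes from the beads as a slow
  first-order release (rate ``k_release``).  When the release rate is slower
  than the disposition beta phase the terminal slope of the plasma curve is
  governed by the release ("flip-flop" kinetics).

Concentrations are in ng/ml throughout (dose mg * 1e6 / volume ml).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .exceptions import DomainError, InsufficientDataError

__all__ = [
    "DispositionParams",
    "BeadInputParams",
    "CompartmentalFit",
    "two_compartment_bolus",
    "infusion_concentration",
    "simulate_iv",
    "first_order_input_concentration",
    "simulate_bead",
    "fit_model",
]

# Relative exponent gap below which the first-order-input solution switches
# to its degenerate (k_release -> lambda) limit to avoid catastrophic
# cancellation.
_DEGENERATE_RTOL = 1e-9


@dataclass(frozen=True)
class DispositionParams:
    """Two-compartment disposition parameters (clearance parameterisation)."""

    cl_ml_min: float
    v1_ml: float
    q_ml_min: float
    v2_ml: float

    def __post_init__(self):
        for name in ("cl_ml_min", "v1_ml", "q_ml_min", "v2_ml"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be > 0, got {getattr(self, name)!r}")

    # -- micro constants (per hour) -------------------------------------
    @property
    def k10_per_h(self) -> float:
        return self.cl_ml_min * 60.0 / self.v1_ml

    @property
    def k12_per_h(self) -> float:
        return self.q_ml_min * 60.0 / self.v1_ml

    @property
    def k21_per_h(self) -> float:
        return self.q_ml_min * 60.0 / self.v2_ml

    def macro_constants(self) -> tuple[float, float, float, float]:
        """Hybrid constants ``(alpha, beta, A, B)`` of the bolus response.

        ``A`` and ``B`` are the dimensionless amplitude fractions
        (``A + B == 1``).
        """
        k10, k12, k21 = self.k10_per_h, self.k12_per_h, self.k21_per_h
        s = k10 + k12 + k21
        disc = s * s - 4.0 * k10 * k21
        root = np.sqrt(disc)
        alpha = 0.5 * (s + root)
        beta = 0.5 * (s - root)
        if not (alpha > 0 and beta > 0):
            raise DomainError("disposition parameters give non-positive macro constants")
        a_frac = (alpha - k21) / (alpha - beta)
        b_frac = (k21 - beta) / (alpha - beta)
        return alpha, beta, a_frac, b_frac

    def scaled(self, cl_multiplier: float = 1.0) -> "DispositionParams":
        """Copy with clearance multiplied by ``cl_multiplier``."""
        return DispositionParams(
            self.cl_ml_min * cl_multiplier, self.v1_ml, self.q_ml_min, self.v2_ml
        )


@dataclass(frozen=True)
class BeadInputParams:
    """Input model for drug-eluting-bead delivery.

    ``bolus_fraction`` is the fraction of the loaded dose displaced into the
    suspension medium and delivered as an immediate bolus (observed range
    0.05-0.15); the remaining ``1 - bolus_fraction`` elutes with first-order
    rate ``k_release_per_h``.
    """

    dose_mg: float
    bolus_fraction: float = 0.10
    k_release_per_h: float = 0.219

    def __post_init__(self):
        if not self.dose_mg > 0:
            raise DomainError("dose_mg must be > 0")
        if not 0.0 <= self.bolus_fraction <= 1.0:
            raise DomainError("bolus_fraction must be in [0, 1]")
        if not self.k_release_per_h > 0:
            raise DomainError("k_release_per_h must be > 0")


def _check_times(times_h: np.ndarray) -> np.ndarray:
    times = np.asarray(times_h, dtype=float)
    if np.any(times < 0):
        raise DomainError("times must be >= 0")
    return times


def two_compartment_bolus(
    params: DispositionParams, dose_mg: float, times_h
) -> np.ndarray:
    """Central-compartment concentration (ng/ml) after an IV bolus at t=0."""
    if not dose_mg >= 0:
        raise DomainError("dose_mg must be >= 0")
    times = _check_times(times_h)
    alpha, beta, a_frac, b_frac = params.macro_constants()
    scale = dose_mg * 1e6 / params.v1_ml
    return scale * (a_frac * np.exp(-alpha * times) + b_frac * np.exp(-beta * times))


def infusion_concentration(
    params: DispositionParams,
    dose_mg: float,
    infusion_duration_h: float,
    t_since_infusion_start_h,
) -> np.ndarray:
    """Concentration on the *dose clock* (t=0 at the start of the infusion).

    Exact superposition solution for a constant-rate infusion of
    ``dose_mg`` over ``infusion_duration_h`` into the central compartment.
    """
    if not dose_mg >= 0:
        raise DomainError("dose_mg must be >= 0")
    if not infusion_duration_h > 0:
        raise DomainError("infusion_duration_h must be > 0")
    times = _check_times(t_since_infusion_start_h)
    alpha, beta, a_frac, b_frac = params.macro_constants()
    rate_scale = dose_mg * 1e6 / infusion_duration_h / params.v1_ml  # ng/ml/h * (1/h)
    t_cap = np.minimum(times, infusion_duration_h)
    t_post = np.maximum(times - infusion_duration_h, 0.0)
    conc = np.zeros_like(times)
    for lam, w in ((alpha, a_frac), (beta, b_frac)):
        conc += (w / lam) * (1.0 - np.exp(-lam * t_cap)) * np.exp(-lam * t_post)
    return rate_scale * conc


def simulate_iv(
    params: DispositionParams,
    dose_mg: float,
    infusion_duration_h: float,
    times_h,
) -> np.ndarray:
    """IV-infusion concentrations at times on the post-infusion clock.

    ``times_h`` are elapsed hours since the *end* of the infusion (the
    sampling time origin); the infusion history is accounted for internally.
    """
    times = _check_times(times_h)
    return infusion_concentration(
        params, dose_mg, infusion_duration_h, times + infusion_duration_h
    )


def first_order_input_concentration(
    params: DispositionParams, amount_mg: float, k_input_per_h: float, times_h
) -> np.ndarray:
    """Response to a first-order input of ``amount_mg`` at rate ``k_input``.

    Handles near-degeneracy between the input rate and either hybrid
    constant via the analytic ``t exp(-lambda t)`` limit.
    """
    if not amount_mg >= 0:
        raise DomainError("amount_mg must be >= 0")
    if not k_input_per_h > 0:
        raise DomainError("k_input_per_h must be > 0")
    times = _check_times(times_h)
    alpha, beta, a_frac, b_frac = params.macro_constants()
    ka = k_input_per_h
    scale = amount_mg * 1e6 * ka / params.v1_ml
    conc = np.zeros_like(times)
    for lam, w in ((alpha, a_frac), (beta, b_frac)):
        if abs(ka - lam) <= _DEGENERATE_RTOL * max(ka, lam):
            conc += w * times * np.exp(-lam * times)
        else:
            conc += (w / (ka - lam)) * (np.exp(-lam * times) - np.exp(-ka * times))
    return scale * conc


def simulate_bead(
    disposition: DispositionParams, input_params: BeadInputParams, times_h
) -> np.ndarray:
    """Plasma concentration after bead delivery (bolus + slow release).

    Superposition of the immediate-bolus response of
    ``bolus_fraction * dose`` and the first-order-release response of the
    remaining dose.  The time origin is the completion of the embolization.
    """
    times = _check_times(times_h)
    bolus_mg = input_params.bolus_fraction * input_params.dose_mg
    release_mg = input_params.dose_mg - bolus_mg
    conc = two_compartment_bolus(disposition, bolus_mg, times)
    if release_mg > 0:
        conc = conc + first_order_input_concentration(
            disposition, release_mg, input_params.k_release_per_h, times
        )
    return conc


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

IV_MODEL = "iv_two_compartment"
BEAD_MODEL = "bead_bolus_release"

_IV_PARAM_NAMES = ("cl_ml_min", "v1_ml", "q_ml_min", "v2_ml")
_BEAD_PARAM_NAMES = _IV_PARAM_NAMES + ("bolus_fraction", "k_release_per_h")

DEFAULT_BOUNDS = {
    "cl_ml_min": (1.0, 1e4),
    "v1_ml": (100.0, 1e6),
    "q_ml_min": (1.0, 1e4),
    "v2_ml": (100.0, 1e7),
    "bolus_fraction": (1e-3, 1.0),
    "k_release_per_h": (1e-3, 10.0),
}


@dataclass
class CompartmentalFit:
    """Result of a nonlinear least-squares compartmental fit."""

    model_kind: str
    estimates: dict[str, float]
    objective: float
    converged: bool
    n_iter: int
    flags: list[str] = field(default_factory=list)


def _predict(model_kind: str, values: dict[str, float], profile) -> np.ndarray:
    disp = DispositionParams(
        values["cl_ml_min"], values["v1_ml"], values["q_ml_min"], values["v2_ml"]
    )
    times = np.array([p.time_h for p in profile.quantifiable_points()])
    if model_kind == IV_MODEL:
        return simulate_iv(disp, profile.dose_mg, profile.infusion_duration_h, times)
    inp = BeadInputParams(
        profile.dose_mg, values["bolus_fraction"], values["k_release_per_h"]
    )
    return simulate_bead(disp, inp, times)


def fit_model(
    profile,
    model_kind: str,
    init: dict[str, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_starts: int = 20,
    seed: int = 0,
) -> CompartmentalFit:
    """Fit a compartmental model to a profile by log-scale least squares.

    Minimises ``sum((log10 C_obs - log10 C_pred)**2)`` over the quantifiable
    points, with a seeded multi-start (log-uniform draws within ``bounds``;
    ``init``, when given, is used as the first start).  Non-convergence is
    reported via ``converged=False``, never as an exception.

    Parameters are fitted on a log scale, which enforces positivity;
    ``bolus_fraction`` is additionally capped at 1.
    """
    if model_kind == IV_MODEL:
        names = _IV_PARAM_NAMES
    elif model_kind == BEAD_MODEL:
        names = _BEAD_PARAM_NAMES
    else:
        raise DomainError(f"unknown model_kind {model_kind!r}")

    pts = profile.quantifiable_points()
    if len(pts) < len(names) + 2:
        raise InsufficientDataError(
            f"{model_kind} has {len(names)} parameters; need at least "
            f"{len(names) + 2} quantifiable points, got {len(pts)}"
        )
    obs = np.array([p.conc_ng_ml for p in pts])
    log_obs = np.log10(np.maximum(obs, 1e-12))

    merged = dict(DEFAULT_BOUNDS)
    if bounds:
        merged.update(bounds)
    lo = np.log(np.array([merged[n][0] for n in names]))
    hi = np.log(np.array([merged[n][1] for n in names]))

    def residuals(log_params: np.ndarray) -> np.ndarray:
        values = dict(zip(names, np.exp(log_params)))
        try:
            pred = _predict(model_kind, values, profile)
        except DomainError:
            return np.full_like(log_obs, 1e6)
        return np.log10(np.maximum(pred, 1e-12)) - log_obs

    rng = np.random.default_rng(seed)
    starts = []
    if init is not None:
        starts.append(np.log(np.array([float(init[n]) for n in names])))
    while len(starts) < n_starts:
        starts.append(rng.uniform(lo, hi))

    best = None
    total_iter = 0
    for x0 in starts:
        try:
            res = least_squares(residuals, np.clip(x0, lo, hi), bounds=(lo, hi))
        except Exception:  # a pathological start must not kill the search
            continue
        total_iter += int(res.nfev)
        if res.success and (best is None or res.cost < best.cost):
            best = res

    if best is None:
        return CompartmentalFit(model_kind, {}, np.inf, False, total_iter, ["no_converged_start"])

    estimates = dict(zip(names, np.exp(best.x)))
    flags = []
    for i, name in enumerate(names):
        if best.x[i] - lo[i] < 1e-3 or hi[i] - best.x[i] < 1e-3:
            flags.append(f"{name}_at_bound")
    objective = float(2.0 * best.cost)  # least_squares cost = 0.5 * sum(res**2)
    return CompartmentalFit(model_kind, estimates, objective, True, total_iter, flags)
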