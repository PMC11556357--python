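"""Two-stage binocular contrast gain control model.

The model takes the (normalized) contrasts shown to the left and right
eyes and produces a scalar response in two stages.  Stage 1 is a
monocular gain pool with divisive interocular suppression::

    Stage1_L = C_L**m / (S + C_L + omega * C_R)

(and symmetrically for the right eye).  The two monocular responses sum
(``binsum``) and pass through a second, binocular gain control stage::

    Stage2 = binsum**p / (Z + binsum**q)

Discrimination thresholds are the smallest target increment for which
the response difference between the target and null intervals of a 2IFC
trial reaches the criterion ``k``.  Dividing the response difference by
the internal noise ``k / tau`` converts it to d-prime, where ``tau`` is
d-prime at the 75%-correct detection threshold.

All contrasts are in linear units normalized to the monocular detection
threshold of the relevant stimulus; decibel conversion is applied only
for reporting and regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "TAU",
    "GainParams",
    "EyePair",
    "OcularArrangement",
    "DipperCurve",
    "stage1_response",
    "model_response",
    "arrange_contrasts",
    "dprime",
    "dprime_to_pc",
    "solve_threshold",
    "solve_thresholds",
    "dipper_curve",
    "summarize_dipper",
    "MEESE_2006",
    "PUBLISHED_PARAMS",
]

#: d-prime at a 75%-correct 2IFC detection threshold: Phi^-1(0.75) * sqrt(2).
TAU: float = float(norm.ppf(0.75) * math.sqrt(2.0))

ARRANGEMENTS = ("monocular", "binocular", "half_binocular", "dichoptic")


class ParameterError(ValueError):
    """A gain-control parameter violates its constraints."""


class SolverError(RuntimeError):
    """The threshold solver found no criterion crossing in its bracket."""


@dataclass(frozen=True)
class GainParams:
    """The seven free parameters of the two-stage model plus ``tau``.

    Parameters
    ----------
    p, q
        Stage-2 numerator / denominator exponents (dimensionless).
    m
        Stage-1 excitatory exponent; controls binocular summation at
        threshold (ratio ~ 2**(1/m)).
    S
        Stage-1 saturation constant, in normalized contrast units.
    Z
        Stage-2 saturation constant.
    omega
        Weight of interocular suppression; omega = 1 yields ocularity
        invariance (monocular and binocular handles converge).
    k
        Response-difference criterion at threshold; k/tau is the
        internal additive noise standard deviation.
    tau
        d-prime at detection threshold.  Fixed by the 75%-correct
        threshold convention; override only for non-standard criteria.
    """

    p: float
    q: float
    m: float
    S: float
    Z: float
    omega: float
    k: float
    tau: float = TAU

    def __post_init__(self) -> None:
        if not (self.m > 0 and self.p > 0 and self.q > 0):
            raise ParameterError("exponents m, p, q must be positive")
        if not (self.S > 0 and self.k > 0):
            raise ParameterError("S and k must be positive")
        if self.Z < 0 or self.omega < 0:
            raise ParameterError("Z and omega must be non-negative")
        if not all(
            math.isfinite(v)
            for v in (self.p, self.q, self.m, self.S, self.Z, self.omega, self.k)
        ):
            raise ParameterError("parameters must be finite")

    def replace(self, **kwargs) -> "GainParams":
        return replace(self, **kwargs)


#: Canonical published parameter set for achromatic gratings
#: (p, q, m, S, Z, omega, k).
MEESE_2006 = GainParams(p=7.99, q=6.59, m=1.28, S=0.99, Z=0.08, omega=1.00, k=0.19)

#: Fitted parameter sets for each stimulus type: least-squares ("simplex")
#: fits to averaged thresholds and modal posterior ("bayes") estimates
#: from the hierarchical trial-level fits.
PUBLISHED_PARAMS: dict[str, GainParams] = {
    "meese2006": MEESE_2006,
    "simplex_achromatic": GainParams(5.96, 4.69, 1.34, 0.87, 0.13, 1.00, 0.20),
    "simplex_lm": GainParams(7.77, 5.19, 1.17, 0.55, 0.07, 1.00, 0.17),
    "simplex_s": GainParams(16.01, 11.56, 1.13, 0.33, 0.00, 0.99, 0.27),
    "simplex_disc": GainParams(5.62, 4.51, 1.26, 0.95, 0.25, 0.89, 0.13),
    "bayes_achromatic": GainParams(7.06, 5.63, 1.27, 0.63, 0.08, 0.98, 0.30),
    "bayes_lm": GainParams(5.11, 3.63, 1.24, 1.22, 0.03, 1.05, 0.19),
    "bayes_s": GainParams(6.78, 5.34, 1.24, 0.61, 0.01, 0.95, 0.34),
    "bayes_disc": GainParams(7.16, 5.76, 1.25, 0.65, 0.13, 0.87, 0.24),
}


@dataclass(frozen=True)
class EyePair:
    """Left/right eye contrasts (normalized units) for one interval."""

    left: float
    right: float

    def __post_init__(self) -> None:
        if not (
            math.isfinite(self.left)
            and math.isfinite(self.right)
            and self.left >= 0
            and self.right >= 0
        ):
            raise ValueError("eye contrasts must be finite and non-negative")


@dataclass(frozen=True)
class OcularArrangement:
    """One of the four ocular configurations of the 2IFC task.

    ``tag`` selects how pedestal P and target increment T map onto the
    two eyes in the target and null intervals (see :func:`arrange_contrasts`);
    ``target_eye`` swaps the left/right roles.
    """

    tag: str
    target_eye: str = "left"

    def __post_init__(self) -> None:
        if self.tag not in ARRANGEMENTS:
            raise ValueError(f"unknown arrangement tag {self.tag!r}")
        if self.target_eye not in ("left", "right"):
            raise ValueError(f"target_eye must be 'left' or 'right', got {self.target_eye!r}")


@dataclass(frozen=True)
class DipperCurve:
    """Thresholds as a function of pedestal contrast for one arrangement."""

    arrangement: OcularArrangement
    pedestals: tuple[float, ...]
    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.pedestals) != len(self.thresholds):
            raise ValueError("pedestals and thresholds must have equal length")
        ped = np.asarray(self.pedestals, dtype=float)
        thr = np.asarray(self.thresholds, dtype=float)
        if ped.size:
            if np.any(np.diff(ped) <= 0):
                raise ValueError("pedestals must be strictly increasing")
            if not (np.all(np.isfinite(thr)) and np.all(thr > 0)):
                raise ValueError("thresholds must be finite and positive")


def stage1_response(c_driving, c_other, params: GainParams):
    """Monocular stage-1 response with interocular suppression.

    ``c_driving**m / (S + c_driving + omega * c_other)``.  Accepts
    scalars or arrays; zero driving contrast gives exactly zero.
    """
    c = np.asarray(c_driving, dtype=float)
    o = np.asarray(c_other, dtype=float)
    if np.any(c < 0) or np.any(o < 0):
        raise ValueError("contrasts must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(c > 0, c**params.m / (params.S + c + params.omega * o), 0.0)
    if r.ndim == 0:
        return float(r)
    return r


def model_response(left, right, params: GainParams):
    """Full two-stage response to the pair of eye contrasts.

    ``binsum**p / (Z + binsum**q)`` where ``binsum`` sums the two
    stage-1 responses.  Zero input in both eyes gives exactly zero
    (also when Z = 0, where the expression is otherwise 0/0).
    """
    binsum = np.asarray(
        stage1_response(left, right, params) + stage1_response(right, left, params)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(binsum > 0, binsum**params.p / (params.Z + binsum**params.q), 0.0)
    if r.ndim == 0:
        return float(r)
    return r


def response_to_pair(eyes: EyePair, params: GainParams) -> float:
    """:func:`model_response` on an :class:`EyePair`."""
    return float(model_response(eyes.left, eyes.right, params))


def arrange_contrasts(
    pedestal: float, target: float, arr: OcularArrangement
) -> tuple[EyePair, EyePair]:
    """Map (pedestal, target) to per-eye contrasts in both intervals.

    Returns ``(target_interval, null_interval)``:

    - monocular:      (P+T, 0) / (P, 0)
    - binocular:      (P+T, P+T) / (P, P)
    - half_binocular: (P+T, P) / (P, P)
    - dichoptic:      (T, P) / (0, P)

    with left/right swapped when ``arr.target_eye == "right"``.
    """
    if pedestal < 0 or target < 0:
        raise ValueError("pedestal and target must be non-negative")
    P, T = float(pedestal), float(target)
    if arr.tag == "monocular":
        tgt, nul = (P + T, 0.0), (P, 0.0)
    elif arr.tag == "binocular":
        tgt, nul = (P + T, P + T), (P, P)
    elif arr.tag == "half_binocular":
        tgt, nul = (P + T, P), (P, P)
    elif arr.tag == "dichoptic":
        tgt, nul = (T, P), (0.0, P)
    else:  # pragma: no cover - guarded by OcularArrangement
        raise ValueError(f"unknown arrangement tag {arr.tag!r}")
    if arr.target_eye == "right":
        tgt, nul = tgt[::-1], nul[::-1]
    return EyePair(*tgt), EyePair(*nul)


def _response_difference(target, pedestal, arr: OcularArrangement, params: GainParams):
    """Stage-2 response difference between target and null intervals.

    Vectorized: ``target`` and ``pedestal`` broadcast against each other.
    """
    T = np.asarray(target, dtype=float)
    P = np.asarray(pedestal, dtype=float)
    T, P = np.broadcast_arrays(T, P)
    if arr.tag == "monocular":
        rt = model_response(P + T, np.zeros_like(T), params)
        rn = model_response(P, np.zeros_like(P), params)
    elif arr.tag == "binocular":
        rt = model_response(P + T, P + T, params)
        rn = model_response(P, P, params)
    elif arr.tag == "half_binocular":
        rt = model_response(P + T, P, params)
        rn = model_response(P, P, params)
    else:  # dichoptic
        rt = model_response(T, P, params)
        rn = model_response(np.zeros_like(P), P, params)
    return rt - rn


def dprime(
    target: float, pedestal: float, arr: OcularArrangement, params: GainParams
):
    """Signal-detection d-prime for a target increment on a pedestal.

    The response difference divided by the internal noise ``k / tau``.
    May be negative for dichoptic arrangements at small targets on large
    pedestals (the "swan" region), where a weak target suppresses the
    mask more than it excites the detecting mechanism.
    """
    diff = _response_difference(target, pedestal, arr, params)
    out = diff / (params.k / params.tau)
    if np.ndim(out) == 0:
        return float(out)
    return out


def dprime_to_pc(dp, lapse: float = 0.0):
    """2AFC percent correct from d-prime: ``lapse/2 + (1-lapse)*Phi(d'/sqrt(2))``.

    With lapse = 0 this is the standard unbiased 2AFC link, giving
    exactly 75% correct at d' = tau.  Negative d-prime yields
    below-chance performance.
    """
    pc = norm.cdf(np.asarray(dp, dtype=float) / math.sqrt(2.0))
    out = lapse / 2.0 + (1.0 - lapse) * pc
    if out.ndim == 0:
        return float(out)
    return out


def solve_thresholds(
    pedestals,
    arr: OcularArrangement,
    params: GainParams,
    tol: float = 1e-6,
    bracket: tuple[float, float] = (1e-4, 1e4),
    grid_points: int = 64,
) -> np.ndarray:
    """Vectorized threshold solve over an array of pedestals.

    For each pedestal, scans a log-spaced grid for the first upward
    crossing of ``response difference - k`` and refines it by bisection
    in log contrast.  The first crossing matters: dichoptic response
    differences are non-monotonic in the swan region, and the threshold
    contract is the *smallest* criterion-reaching target.
    """
    peds = np.asarray(pedestals, dtype=float)
    if np.any(peds < 0):
        raise ValueError("pedestals must be non-negative")
    grid = np.logspace(math.log10(bracket[0]), math.log10(bracket[1]), grid_points)
    # f has shape (n_ped, grid_points)
    f = _response_difference(grid[None, :], peds[:, None], arr, params) - params.k
    f = np.atleast_2d(f)
    above = f >= 0.0
    if np.any(above[:, 0]):
        raise SolverError(
            "criterion already exceeded at the lower bracket edge; widen the bracket"
        )
    if np.any(~above.max(axis=1)):
        bad = peds[~above.max(axis=1)]
        raise SolverError(f"no criterion crossing in bracket for pedestals {bad}")
    first = np.argmax(above, axis=1)  # first grid index at/above criterion
    lo = np.log10(grid[first - 1])
    hi = np.log10(grid[first])
    # bisection in log10 contrast, vectorized over pedestals
    n_iter = max(1, int(math.ceil(math.log2((hi - lo).max() / (tol / math.log(10.0))))))
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        fm = _response_difference(10.0**mid, peds, arr, params) - params.k
        below = np.atleast_1d(fm) < 0.0
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 10.0 ** (0.5 * (lo + hi))


def solve_threshold(
    pedestal: float,
    arr: OcularArrangement,
    params: GainParams,
    tol: float = 1e-6,
    bracket: tuple[float, float] = (1e-4, 1e4),
    grid_points: int = 64,
) -> float:
    """Smallest target contrast whose response difference reaches ``k``.

    Raises :class:`SolverError` when no crossing lies in the bracket.
    """
    return float(
        solve_thresholds([pedestal], arr, params, tol=tol, bracket=bracket,
                         grid_points=grid_points)[0]
    )


def dipper_curve(
    pedestals: Sequence[float], arr: OcularArrangement, params: GainParams, **kw
) -> DipperCurve:
    """Solve thresholds over a pedestal grid, returning a :class:`DipperCurve`."""
    peds = tuple(float(p) for p in pedestals)
    if not peds:
        return DipperCurve(arr, (), ())
    thr = solve_thresholds(peds, arr, params, **kw)
    return DipperCurve(arr, peds, tuple(float(t) for t in thr))


def summarize_dipper(curve: DipperCurve, ref_curve: DipperCurve | None = None) -> dict:
    """Summary statistics of a dipper function.

    Returns a dict with:

    - ``facilitation_factor``: zero-pedestal threshold divided by the
      minimum threshold across pedestals (> 1 indicates a dip).
    - ``handle_slope``: OLS slope of dB threshold against dB pedestal
      over the four highest nonzero pedestals (the masking "handle").
    - ``summation_ratio``: ``ref_curve`` zero-pedestal threshold divided
      by this curve's (e.g. monocular / binocular); None if no reference.
    """
    ped = np.asarray(curve.pedestals, dtype=float)
    thr = np.asarray(curve.thresholds, dtype=float)
    if ped.size == 0 or ped[0] != 0.0:
        raise ValueError("curve must include a zero-pedestal (detection) point")
    facilitation = float(thr[0] / thr.min())

    nz = ped > 0
    if nz.sum() < 4:
        raise ValueError("handle slope requires at least 4 nonzero pedestals")
    top = np.argsort(ped[nz])[-4:]
    x = 20.0 * np.log10(ped[nz][top])
    y = 20.0 * np.log10(thr[nz][top])
    slope = float(np.polyfit(x, y, 1)[0])

    summation = None
    if ref_curve is not None:
        if not ref_curve.pedestals or ref_curve.pedestals[0] != 0.0:
            raise ValueError("reference curve must include a zero-pedestal point")
        summation = float(ref_curve.thresholds[0] / thr[0])
    return {
        "summation_ratio": summation,
        "facilitation_factor": facilitation,
        "handle_slope": slope,
    }
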