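"""Cross-pathway extension of the two-stage gain control model.

Three parallel mechanisms — achromatic (AC), L-M red/green (RG) and
S-(L+M) blue/yellow (BY) — each run the two-stage model on their own
pathway's contrast, but the stage-1 denominator pools suppression from
the *other eye's* contrast in all three pathways, e.g. for the
achromatic mechanism's left-eye channel::

    AC_Stage1_L = AC_L**m / (S + AC_L + wAA*AC_R + wAR*RG_R + wAB*BY_R)

The 3x3 weight matrix ``W[target][mask]`` holds the within-pathway
weights on the diagonal and six cross-pathway weights off it.  Each
pathway's contrasts are in that pathway's own threshold-normalized
units.  Monocular (same-eye) cross-pathway suppression is deliberately
absent: cross-pathway masks act only through the opposite eye.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gain_model import GainParams, dprime_to_pc

__all__ = [
    "PATHWAYS",
    "CrossPathState",
    "MaskingCondition",
    "crosspath_stage1",
    "crosspath_response",
    "crosspath_dprime",
    "crosspath_dprime_batch",
    "predict_psychometric",
    "masked_threshold",
]

PATHWAYS = ("AC", "RG", "BY")
_PIDX = {name: i for i, name in enumerate(PATHWAYS)}
_EIDX = {"left": 0, "right": 1}


@dataclass(frozen=True)
class CrossPathState:
    """Parameters and stimulus of the three-pathway model.

    Parameters
    ----------
    mechs
        Per-mechanism :class:`GainParams` (AC, RG, BY).  p, q, m, S, k
        and the within-pathway omega are typically fixed from
        single-pathway fits; Z is free per mechanism.
    weights
        3x3 interocular suppression matrix ``W[target][mask]``; the
        diagonal is the within-pathway omega.  When omitted, built from
        ``mechs`` omegas with zero cross weights.
    contrasts
        3x2 array of normalized contrast, rows = pathway (AC, RG, BY),
        columns = (left, right) eye.  Defaults to all-zero (blank).
    """

    mechs: tuple[GainParams, GainParams, GainParams]
    weights: tuple = None  # type: ignore[assignment]
    contrasts: tuple = ((0.0, 0.0), (0.0, 0.0), (0.0, 0.0))

    def __post_init__(self) -> None:
        if len(self.mechs) != 3:
            raise ValueError("three mechanisms (AC, RG, BY) required")
        if self.weights is None:
            W = np.diag([mech.omega for mech in self.mechs])
            object.__setattr__(self, "weights", tuple(map(tuple, W)))
        W = np.asarray(self.weights, dtype=float)
        if W.shape != (3, 3) or np.any(W < 0) or not np.all(np.isfinite(W)):
            raise ValueError("weights must be a non-negative finite 3x3 matrix")
        C = np.asarray(self.contrasts, dtype=float)
        if C.shape != (3, 2) or np.any(C < 0) or not np.all(np.isfinite(C)):
            raise ValueError("contrasts must be a non-negative finite 3x2 array")
        object.__setattr__(self, "weights", tuple(map(tuple, W)))
        object.__setattr__(self, "contrasts", tuple(map(tuple, C)))

    def with_contrasts(self, contrasts) -> "CrossPathState":
        return CrossPathState(self.mechs, self.weights, contrasts)

    def weight_matrix(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


@dataclass(frozen=True)
class MaskingCondition:
    """A dichoptic masking condition: target pathway/eye vs mask pathway/eye.

    The mask, when present, is always in the eye opposite the target
    (dichoptic by construction).
    """

    target_pathway: str
    mask_pathway: str | None = None
    mask_contrast: float = 0.0
    target_eye: str = "left"

    def __post_init__(self) -> None:
        if self.target_pathway not in PATHWAYS:
            raise ValueError(f"unknown target pathway {self.target_pathway!r}")
        if self.mask_pathway is not None and self.mask_pathway not in PATHWAYS:
            raise ValueError(f"unknown mask pathway {self.mask_pathway!r}")
        if self.mask_contrast < 0:
            raise ValueError("mask contrast must be non-negative")
        if self.target_eye not in _EIDX:
            raise ValueError("target_eye must be 'left' or 'right'")

    @property
    def mask_eye(self) -> str:
        return "right" if self.target_eye == "left" else "left"


def crosspath_stage1(state: CrossPathState, pathway: str, eye: str) -> float:
    """Stage-1 response of one pathway's monocular channel.

    The denominator pools the same pathway's same-eye contrast plus
    weighted other-eye contrasts from all three pathways.
    """
    i = _PIDX[pathway]
    e = _EIDX[eye]
    C = np.asarray(state.contrasts, dtype=float)
    W = state.weight_matrix()
    mech = state.mechs[i]
    c = C[i, e]
    if c == 0.0:
        return 0.0
    suppression = float(W[i] @ C[:, 1 - e])
    return float(c**mech.m / (mech.S + c + suppression))


def crosspath_response(state: CrossPathState, pathway: str) -> float:
    """Stage-2 response of the mechanism tuned to ``pathway``."""
    i = _PIDX[pathway]
    mech = state.mechs[i]
    binsum = crosspath_stage1(state, pathway, "left") + crosspath_stage1(
        state, pathway, "right"
    )
    if binsum == 0.0:
        return 0.0
    return float(binsum**mech.p / (mech.Z + binsum**mech.q))


def _displays(cond: MaskingCondition, target: float, state: CrossPathState):
    """Contrast matrices for the target+mask and mask-only displays."""
    C1 = np.zeros((3, 2))
    C1[_PIDX[cond.target_pathway], _EIDX[cond.target_eye]] = target
    C0 = np.zeros((3, 2))
    if cond.mask_pathway is not None:
        C1[_PIDX[cond.mask_pathway], _EIDX[cond.mask_eye]] += cond.mask_contrast
        C0[_PIDX[cond.mask_pathway], _EIDX[cond.mask_eye]] += cond.mask_contrast
    return C1, C0


def crosspath_dprime(cond: MaskingCondition, target: float, state: CrossPathState) -> float:
    """d-prime for a masked detection trial, read out from the target's mechanism.

    A within-pathway dichoptic mask drives the target mechanism's
    other-eye excitatory channel (target and mask sum binocularly);
    cross-pathway masks contribute only suppressive denominator terms.
    The readout mechanism is always the one tuned to the target's
    chromaticity — the task leaves no uncertainty about target identity.
    """
    if target < 0:
        raise ValueError("target contrast must be non-negative")
    C1, C0 = _displays(cond, float(target), state)
    mech = state.mechs[_PIDX[cond.target_pathway]]
    r1 = crosspath_response(state.with_contrasts(C1), cond.target_pathway)
    r0 = crosspath_response(state.with_contrasts(C0), cond.target_pathway)
    return (r1 - r0) / (mech.k / mech.tau)


def predict_psychometric(
    cond: MaskingCondition, target_levels, state: CrossPathState, lapse: float = 0.01
) -> np.ndarray:
    """Model percent correct at each target level (proportions in [0, 1]).

    Uses the 2AFC link ``lapse/2 + (1-lapse)*Phi(d'/sqrt(2))``.  Values
    below 0.5 are possible in the swan region of within-pathway
    dichoptic masking.
    """
    levels = np.asarray(target_levels, dtype=float)
    if np.any(levels <= 0):
        raise ValueError("target levels must be positive")
    dp = np.array([crosspath_dprime(cond, t, state) for t in levels])
    return np.asarray(dprime_to_pc(dp, lapse=lapse))


def crosspath_dprime_batch(
    cond: MaskingCondition, targets, state: CrossPathState
) -> np.ndarray:
    """Vectorized :func:`crosspath_dprime` over an array of target levels.

    Exploits the display structure: with only a target and (at most) one
    dichoptic mask on screen, the target mechanism's response has a
    closed form in the target contrast, so no per-level state
    construction is needed.  Agrees with the scalar path to machine
    precision.
    """
    t = np.asarray(targets, dtype=float)
    i = _PIDX[cond.target_pathway]
    mech = state.mechs[i]
    W = state.weight_matrix()
    M = float(cond.mask_contrast) if cond.mask_pathway is not None else 0.0

    def stage2(binsum):
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(
                binsum > 0, binsum**mech.p / (mech.Z + binsum**mech.q), 0.0
            )

    if cond.mask_pathway is None or M == 0.0:
        s1 = np.where(t > 0, t**mech.m / (mech.S + t), 0.0)
        dp = stage2(s1) - 0.0
    elif cond.mask_pathway == cond.target_pathway:
        # within-pathway dichoptic mask: the mask drives the target
        # mechanism's other-eye channel and suppresses the target eye
        w = W[i, i]
        s1_t = np.where(t > 0, t**mech.m / (mech.S + t + w * M), 0.0)
        s1_m = M**mech.m / (mech.S + M + w * t)
        s1_m0 = M**mech.m / (mech.S + M)
        dp = stage2(s1_t + s1_m) - stage2(s1_m0)
    else:
        # cross-pathway mask: suppressive denominator term only
        w = W[i, _PIDX[cond.mask_pathway]]
        s1 = np.where(t > 0, t**mech.m / (mech.S + t + w * M), 0.0)
        dp = stage2(s1) - 0.0
    return dp / (mech.k / mech.tau)


def masked_threshold(
    cond: MaskingCondition,
    state: CrossPathState,
    bracket: tuple[float, float] = (1e-4, 1e4),
    grid_points: int = 256,
    tol: float = 1e-6,
) -> float:
    """Smallest target contrast with d-prime = tau (the 75% point).

    Grid scan for the first upward crossing, then log-contrast
    bisection; mirrors the single-pathway threshold solver.
    """
    mech = state.mechs[_PIDX[cond.target_pathway]]
    grid = np.logspace(np.log10(bracket[0]), np.log10(bracket[1]), grid_points)
    f = np.array([crosspath_dprime(cond, t, state) - mech.tau for t in grid])
    above = f >= 0
    if above[0] or not above.any():
        raise RuntimeError("no d-prime = tau crossing within the bracket")
    first = int(np.argmax(above))
    lo, hi = np.log10(grid[first - 1]), np.log10(grid[first])
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if crosspath_dprime(cond, 10.0**mid, state) < mech.tau:
            lo = mid
        else:
            hi = mid
    return float(10.0 ** (0.5 * (lo + hi)))
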