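"""Parameter estimation for the gain control models.

Two routes, mirroring standard practice for this model family:

1. Multi-start Nelder-Mead ("simplex") least squares on threshold data,
   minimizing the dB RMSE between model-predicted and observed dipper
   thresholds; 100 random starting vectors by default.
2. Hierarchical Bayesian fitting of trial-level binomial data by
   ensemble MCMC.  The likelihood is binomial with success probability
   given by the model's d-prime through the 2AFC link at each
   (arrangement, pedestal, target) cell.  Priors follow the model's
   conventions: Gaussian on p, q, m, omega centered on published
   values, uniform on S, Z, k.  Participant-level (m, omega, k) are
   partially pooled (log-normal) toward group means; (p, q, S, Z) are
   shared at group level.

The MCMC engine is emcee's affine-invariant ensemble sampler, with
walkers treated as chains for split-chain convergence diagnostics
(arviz ``rhat`` / ``ess``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr

from .gain_model import (
    DipperCurve,
    GainParams,
    SolverError,
    MEESE_2006,
    TAU,
    model_response,
    solve_thresholds,
)
from .crosspath import (
    PATHWAYS,
    CrossPathState,
    MaskingCondition,
    crosspath_dprime_batch,
)

__all__ = [
    "FitResult",
    "PosteriorSummary",
    "PARAM_BOUNDS",
    "rmse_dB",
    "simplex_fit",
    "bayes_fit",
    "bayes_fit_crosspath",
]

PARAM_NAMES = ("p", "q", "m", "S", "Z", "omega", "k")

#: Search/prior ranges per parameter (natural units).
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "p": (1.0, 20.0),
    "q": (1.0, 20.0),
    "m": (0.5, 3.0),
    "S": (0.02, 3.0),
    "Z": (1e-4, 1.0),
    "omega": (0.01, 2.5),
    "k": (0.01, 2.0),
}

#: Gaussian prior means/SDs for p, q, m, omega (published achromatic values).
GAUSSIAN_PRIORS: dict[str, tuple[float, float]] = {
    "p": (7.99, 2.0),
    "q": (6.59, 2.0),
    "m": (1.28, 0.3),
    "omega": (1.00, 0.3),
}


@dataclass(frozen=True)
class FitResult:
    """Outcome of a multi-start least-squares fit."""

    params: GainParams
    rmse_dB: float
    n_starts: int
    best_start_seed: int


@dataclass
class PosteriorSummary:
    """Retained posterior draws plus point and interval summaries."""

    samples: dict[str, np.ndarray]
    map_estimate: dict[str, float]
    intervals: dict[str, tuple[float, float]]
    diagnostics: dict[str, dict[str, float]]
    retained_fraction: float
    n_draws_total: int

    def converged(self, rhat_max: float = 1.05) -> bool:
        return all(d["rhat"] < rhat_max for d in self.diagnostics.values())


def rmse_dB(model_thresholds, data_thresholds) -> float:
    """Root mean squared error between threshold sets, in dB.

    Both inputs are positive linear contrasts; the error is taken on
    the 20*log10 scale.
    """
    m = np.asarray(model_thresholds, dtype=float)
    d = np.asarray(data_thresholds, dtype=float)
    if m.shape != d.shape:
        raise ValueError("threshold lists must have equal length")
    if np.any(m <= 0) or np.any(d <= 0):
        raise ValueError("thresholds must be positive")
    return float(np.sqrt(np.mean((20.0 * np.log10(m) - 20.0 * np.log10(d)) ** 2)))


def _predicted_thresholds(curves: Sequence[DipperCurve], params: GainParams) -> np.ndarray:
    out = []
    for c in curves:
        out.append(solve_thresholds(c.pedestals, c.arrangement, params))
    return np.concatenate(out) if out else np.array([])


def simplex_fit(
    curves: Sequence[DipperCurve],
    free: Sequence[str],
    fixed: GainParams = MEESE_2006,
    n_starts: int = 100,
    rng: np.random.Generator | int = 0,
    maxiter: int = 400,
) -> FitResult:
    """Fit the two-stage model to dipper thresholds by multi-start simplex.

    Parameters named in ``free`` are optimized (on log scale, keeping
    them positive); the rest stay at their values in ``fixed``.  Each
    start draws a log-uniform vector within :data:`PARAM_BOUNDS`; the
    best local optimum by dB RMSE wins, ties broken by lowest start
    index.  Deterministic for a given ``rng`` seed.
    """
    free = list(free)
    unknown = set(free) - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown free parameters: {sorted(unknown)}")
    if not curves:
        raise ValueError("at least one dipper curve is required")
    rng = np.random.default_rng(rng)
    data = np.concatenate([np.asarray(c.thresholds, dtype=float) for c in curves])

    def build(x_log: np.ndarray) -> GainParams:
        return fixed.replace(**{name: math.exp(v) for name, v in zip(free, x_log)})

    def objective(x_log: np.ndarray) -> float:
        try:
            params = build(x_log)
            pred = _predicted_thresholds(curves, params)
        except (SolverError, ValueError, OverflowError):
            return 1e6
        return rmse_dB(pred, data)

    best: tuple[float, int, np.ndarray] | None = None
    for start in range(n_starts):
        x0 = np.array(
            [
                rng.uniform(math.log(PARAM_BOUNDS[name][0]), math.log(PARAM_BOUNDS[name][1]))
                for name in free
            ]
        )
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-6, "fatol": 1e-8},
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best[0] - 0.0):
            if best is None or res.fun < best[0]:
                best = (float(res.fun), start, res.x.copy())
    if best is None or best[0] >= 1e6:
        raise RuntimeError("all simplex starts failed to produce a valid fit")
    # polish: restarting the simplex at the incumbent rebuilds a fresh
    # simplex and escapes premature collapse in higher dimensions
    fun, start, x = best
    for _ in range(3):
        res = minimize(
            objective,
            x,
            method="Nelder-Mead",
            options={"maxiter": 5 * maxiter, "xatol": 1e-8, "fatol": 1e-10},
        )
        if not np.isfinite(res.fun) or res.fun >= fun - 1e-9:
            break
        fun, x = float(res.fun), res.x.copy()
    best = (fun, start, x)
    return FitResult(
        params=build(best[2]),
        rmse_dB=best[0],
        n_starts=n_starts,
        best_start_seed=best[1],
    )


# ---------------------------------------------------------------------------
# Hierarchical Bayesian fit to trial-level dipper data
# ---------------------------------------------------------------------------

_ARR_TAGS = ("monocular", "binocular", "half_binocular", "dichoptic")


class _CellParams:
    """Parameter bundle whose fields may be per-cell arrays.

    Duck-types :class:`GainParams` for the vectorized response
    functions, letting participant-level (m, omega, k) broadcast
    elementwise over binomial cells.
    """

    __slots__ = PARAM_NAMES + ("tau",)

    def __init__(self, p, q, m, S, Z, omega, k, tau):
        self.p, self.q, self.m, self.S = p, q, m, S
        self.Z, self.omega, self.k, self.tau = Z, omega, k, tau


def _prepare_cells(trials: pd.DataFrame):
    """Aggregate trials into binomial cells with precomputed eye contrasts.

    Each cell is one (participant, arrangement, pedestal, target)
    combination; the four ocular arrangements reduce to per-cell eye
    contrasts for the target and null intervals, so the likelihood
    needs just two model-response evaluations over concatenated arrays.
    Returns (participant ids, cell arrays).
    """
    participants = sorted(trials["participant"].unique())
    pidx = {pid: i for i, pid in enumerate(participants)}
    g = (
        trials.groupby(["arrangement", "participant", "pedestal_norm", "target_norm"])[
            "correct"
        ]
        .agg(["sum", "size"])
        .reset_index()
    )
    P = g["pedestal_norm"].to_numpy(float)
    T = g["target_norm"].to_numpy(float)
    tag = g["arrangement"].to_numpy()
    tl = np.empty_like(P)
    tr = np.empty_like(P)
    nl = np.empty_like(P)
    nr = np.empty_like(P)
    for t, (f_tl, f_tr, f_nl, f_nr) in {
        "monocular": (lambda: P + T, lambda: 0 * P, lambda: P, lambda: 0 * P),
        "binocular": (lambda: P + T, lambda: P + T, lambda: P, lambda: P),
        "half_binocular": (lambda: P + T, lambda: P, lambda: P, lambda: P),
        "dichoptic": (lambda: T, lambda: P, lambda: 0 * P, lambda: P),
    }.items():
        sel = tag == t
        tl[sel], tr[sel] = f_tl()[sel], f_tr()[sel]
        nl[sel], nr[sel] = f_nl()[sel], f_nr()[sel]
    cells = {
        "target_interval": (tl, tr),
        "null_interval": (nl, nr),
        "n_correct": g["sum"].to_numpy(float),
        "n_total": g["size"].to_numpy(float),
        "participant": g["participant"].map(pidx).to_numpy(int),
    }
    return participants, cells


def _cells_loglik(cells, group, part_mok: np.ndarray, lapse: float) -> float:
    """Binomial log likelihood over all cells.

    ``group`` is (p, q, S, Z); ``part_mok`` is a (3, n_participants)
    array of participant-level (m, omega, k).
    """
    p_, q_, S_, Z_ = group
    pi = cells["participant"]
    params = _CellParams(
        p=p_, q=q_, m=part_mok[0, pi], S=S_, Z=Z_, omega=part_mok[1, pi],
        k=1.0, tau=1.0,
    )
    tl, tr = cells["target_interval"]
    nl, nr = cells["null_interval"]
    # extreme walker positions can overflow binsum**p to inf; the
    # resulting non-finite log likelihood is rejected by the caller
    with np.errstate(over="ignore", invalid="ignore"):
        diff = model_response(tl, tr, params) - model_response(nl, nr, params)
        dp = diff / (part_mok[2, pi] / TAU)
        pc = lapse / 2.0 + (1.0 - lapse) * ndtr(dp / math.sqrt(2.0))
        pc = np.clip(pc, 1e-9, 1 - 1e-9)
    kk, nn = cells["n_correct"], cells["n_total"]
    return float(np.sum(kk * np.log(pc) + (nn - kk) * np.log1p(-pc)))


def _summaries(
    chain: np.ndarray,  # (walkers, steps, dim)
    logprob: np.ndarray,  # (walkers, steps)
    names: Sequence[str],
    transform,
    retained_fraction: float,
) -> PosteriorSummary:
    nw, ns, ndim = chain.shape
    flat = chain.reshape(-1, ndim)
    values = transform(flat)  # dict name -> 1D array over all draws
    n_total = flat.shape[0]
    keep = max(1, int(round(1.0 / retained_fraction)))
    samples = {k: v[::keep].copy() for k, v in values.items()}
    imax = int(np.argmax(logprob))
    map_vec = chain.reshape(-1, ndim)[imax][None, :]
    map_vals = transform(map_vec)
    diagnostics = {}
    for j, name in enumerate(names):
        da = az.convert_to_dataset({"x": chain[:, :, j]})
        diagnostics[name] = {
            "rhat": float(az.rhat(da)["x"].values),
            "ess_bulk": float(az.ess(da)["x"].values),
        }
    intervals = {
        k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
        for k, v in values.items()
    }
    return PosteriorSummary(
        samples=samples,
        map_estimate={k: float(v[0]) for k, v in map_vals.items()},
        intervals=intervals,
        diagnostics=diagnostics,
        retained_fraction=1.0 / keep,
        n_draws_total=n_total,
    )


def bayes_fit(
    trials: pd.DataFrame,
    pooling_sd: float | None = None,
    pooling_sd_scale: float = 0.2,
    lapse: float = 0.01,
    n_walkers: int = 40,
    n_steps: int = 1200,
    n_burn: int = 400,
    retained_fraction: float = 0.1,
    rng: np.random.Generator | int = 0,
    progress: bool = False,
) -> PosteriorSummary:
    """Hierarchical Bayesian fit of the two-stage model to 2IFC trials.

    ``trials`` holds one experiment/pathway (dipper design).  Group
    parameters (p, q, S, Z) are shared; participant-level (m, omega, k)
    are log-normally pooled around group means.  The between-participant
    SD of each pooled parameter is itself estimated (half-normal prior
    with scale ``pooling_sd_scale``) unless ``pooling_sd`` fixes it;
    estimating it keeps the group-mean intervals honestly wide when only
    a few participants inform them.  Sampling is on log scale for all
    strictly positive parameters.

    Returns group-level posteriors under names p, q, m, S, Z, omega, k.
    Unconverged chains are flagged in ``diagnostics`` (rhat), never
    raised.
    """
    rng = np.random.default_rng(rng)
    participants, cells = _prepare_cells(trials)
    n_part = len(participants)
    if n_part == 0:
        raise ValueError("no trials supplied")

    group_names = ["p", "q", "S", "Z", "m", "omega", "k"]
    estimate_sd = pooling_sd is None
    sd_names = [f"log_sd_{n}" for n in ("m", "omega", "k")] if estimate_sd else []
    names = (
        [f"log_{n}" for n in group_names]
        + sd_names
        + [f"eta_{p}_{pid}" for p in ("m", "omega", "k") for pid in participants]
    )
    ndim = len(names)
    n_sd = len(sd_names)

    lb = np.log([PARAM_BOUNDS[n][0] for n in group_names])
    ub = np.log([PARAM_BOUNDS[n][1] for n in group_names])
    sd_lb, sd_ub = math.log(0.005), math.log(1.0)

    def unpack(x):
        g = np.exp(x[:7])
        if estimate_sd:
            sds = np.exp(x[7 : 7 + n_sd])
        else:
            sds = np.full(3, pooling_sd)
        eta = x[7 + n_sd :].reshape(3, n_part)
        return g, sds, eta

    def log_prior(x):
        if np.any(x[:7] < lb) or np.any(x[:7] > ub):
            return -np.inf
        if estimate_sd and (
            np.any(x[7 : 7 + n_sd] < sd_lb) or np.any(x[7 : 7 + n_sd] > sd_ub)
        ):
            return -np.inf
        g, sds, eta = unpack(x)
        p_, q_, S_, Z_, m_, w_, k_ = g
        lp = 0.0
        for val, name in ((p_, "p"), (q_, "q"), (m_, "m"), (w_, "omega")):
            mu, sd = GAUSSIAN_PRIORS[name]
            lp += -0.5 * ((val - mu) / sd) ** 2
        # uniform on natural scale for S, Z, k; include log-Jacobian of
        # the log-scale parameterization for every parameter
        lp += float(np.sum(x[:7]))
        if estimate_sd:
            # half-normal prior on the pooling SDs, log-scale Jacobian
            lp += float(
                np.sum(x[7 : 7 + n_sd]) - 0.5 * np.sum((sds / pooling_sd_scale) ** 2)
            )
        lp += float(-0.5 * np.sum(eta**2))
        return lp

    def log_prob(x):
        lp = log_prior(x)
        if not np.isfinite(lp):
            return -np.inf
        g, sds, eta = unpack(x)
        p_, q_, S_, Z_, m_, w_, k_ = g
        part_mok = np.array([m_, w_, k_])[:, None] * np.exp(sds[:, None] * eta)
        with np.errstate(over="ignore"):
            ll = _cells_loglik(cells, (p_, q_, S_, Z_), part_mok, lapse)
        if not np.isfinite(ll):
            return -np.inf
        return lp + ll

    x0 = np.empty((n_walkers, ndim))
    center = np.log(
        [
            GAUSSIAN_PRIORS["p"][0],
            GAUSSIAN_PRIORS["q"][0],
            0.8,
            0.1,
            GAUSSIAN_PRIORS["m"][0],
            GAUSSIAN_PRIORS["omega"][0],
            0.2,
        ]
    )
    x0[:, :7] = center[None, :] + 0.05 * rng.standard_normal((n_walkers, 7))
    if estimate_sd:
        x0[:, 7 : 7 + n_sd] = math.log(0.1) + 0.2 * rng.standard_normal((n_walkers, n_sd))
    x0[:, 7 + n_sd :] = 0.1 * rng.standard_normal((n_walkers, ndim - 7 - n_sd))

    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob, moves=moves)
    initial = emcee.State(
        x0, random_state=np.random.RandomState(int(rng.integers(2**31))).get_state()
    )
    sampler.run_mcmc(initial, n_steps, progress=progress, skip_initial_state_check=True)
    chain = sampler.get_chain(discard=n_burn)  # (steps, walkers, ndim)
    chain = np.moveaxis(chain, 0, 1)  # (walkers, steps, ndim)
    logprob = np.moveaxis(sampler.get_log_prob(discard=n_burn), 0, 1)

    def transform(flat):
        return {name: np.exp(flat[:, j]) for j, name in enumerate(group_names)}

    return _summaries(chain, logprob, names[:7], transform, retained_fraction)


def bayes_fit_crosspath(
    trials: pd.DataFrame,
    fixed_mechs: tuple[GainParams, GainParams, GainParams],
    within_weights: Sequence[float] | None = None,
    weight_max: float = 2.5,
    lapse: float = 0.01,
    n_walkers: int = 32,
    n_steps: int = 1200,
    n_burn: int = 400,
    retained_fraction: float = 0.1,
    rng: np.random.Generator | int = 0,
    progress: bool = False,
) -> PosteriorSummary:
    """Bayesian fit of the cross-pathway model to dichoptic masking trials.

    Exactly nine free parameters: one stage-2 saturation constant Z per
    mechanism (uniform prior on [0, 1]) and the six cross-pathway
    suppression weights (uniform prior on [0, weight_max]).  All other
    parameters — p, q, m, S, k and the within-pathway (diagonal)
    weights — are fixed from single-pathway fits, supplied via
    ``fixed_mechs`` (their ``omega`` is the diagonal unless
    ``within_weights`` overrides it).  The likelihood pools all
    participants' binomial counts.

    Returns posteriors under names Z_AC, Z_RG, Z_BY and
    w_<target><mask> for the six cross weights.
    """
    rng = np.random.default_rng(rng)
    if within_weights is None:
        within_weights = [m.omega for m in fixed_mechs]
    diag = np.asarray(within_weights, dtype=float)

    off_pairs = [(i, j) for i in range(3) for j in range(3) if i != j]
    names = [f"Z_{pw}" for pw in PATHWAYS] + [
        f"w_{PATHWAYS[i]}_{PATHWAYS[j]}" for i, j in off_pairs
    ]
    ndim = len(names)

    # binomial cells pooled over participants per (target, mask, level)
    g = trials.groupby(["pathway_target", "pathway_mask", "pedestal_norm", "target_norm"])[
        "correct"
    ].agg(["sum", "size"])
    cell_tgt = g.index.get_level_values(0).to_numpy()
    cell_msk = g.index.get_level_values(1).to_numpy()
    cell_mc = g.index.get_level_values(2).to_numpy(float)
    cell_lvl = g.index.get_level_values(3).to_numpy(float)
    cell_k = g["sum"].to_numpy(float)
    cell_n = g["size"].to_numpy(float)

    conds = []
    for tgt in PATHWAYS:
        for msk in list(PATHWAYS) + ["none"]:
            sel = (cell_tgt == tgt) & (cell_msk == msk)
            if not sel.any():
                continue
            mask_pathway = None if msk == "none" else msk
            mc = float(cell_mc[sel][0]) if mask_pathway else 0.0
            conds.append(
                (
                    MaskingCondition(tgt, mask_pathway, mc),
                    cell_lvl[sel],
                    cell_k[sel],
                    cell_n[sel],
                )
            )

    def build_state(x):
        W = np.diag(diag).astype(float)
        for idx, (i, j) in enumerate(off_pairs):
            W[i, j] = x[3 + idx]
        mechs = tuple(
            mech.replace(Z=float(x[i]), omega=float(diag[i]))
            for i, mech in enumerate(fixed_mechs)
        )
        return CrossPathState(mechs, tuple(map(tuple, W)))

    def log_prob(x):
        if np.any(x[:3] < 0) or np.any(x[:3] > 1) or np.any(x[3:] < 0) or np.any(
            x[3:] > weight_max
        ):
            return -np.inf
        state = build_state(x)
        ll = 0.0
        for cond, lvl, kk, nn in conds:
            dp = crosspath_dprime_batch(cond, lvl, state)
            pc = lapse / 2.0 + (1.0 - lapse) * ndtr(dp / math.sqrt(2.0))
            pc = np.clip(pc, 1e-9, 1 - 1e-9)
            ll += float(np.sum(kk * np.log(pc) + (nn - kk) * np.log1p(-pc)))
        return ll

    x0 = np.empty((n_walkers, ndim))
    x0[:, :3] = np.clip(0.1 + 0.05 * rng.standard_normal((n_walkers, 3)), 1e-3, 0.9)
    x0[:, 3:] = np.clip(
        0.5 + 0.2 * rng.standard_normal((n_walkers, ndim - 3)), 1e-3, weight_max - 0.1
    )
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob, moves=moves)
    initial = emcee.State(
        x0, random_state=np.random.RandomState(int(rng.integers(2**31))).get_state()
    )
    sampler.run_mcmc(initial, n_steps, progress=progress, skip_initial_state_check=True)
    chain = np.moveaxis(sampler.get_chain(discard=n_burn), 0, 1)
    logprob = np.moveaxis(sampler.get_log_prob(discard=n_burn), 0, 1)

    def transform(flat):
        return {name: flat[:, j].copy() for j, name in enumerate(names)}

    return _summaries(chain, logprob, names, transform, retained_fraction)
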