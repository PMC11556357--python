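"""End-to-end orchestration: simulate -> fit -> summarize.

Library functions behind the command-line interface.  Each stage reads
and writes plain-text artifacts (trial-table CSV, JSON reports) and
records provenance (seed, config hash, package version) so every
reported number traces back to an input file and a seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .gain_model import (
    GainParams,
    OcularArrangement,
    PUBLISHED_PARAMS,
    dipper_curve,
    summarize_dipper,
)
from .crosspath import CrossPathState, PATHWAYS
from .observer import (
    PEDESTALS_PCT,
    ParticipantSpec,
    StaircaseConfig,
    generate_experiment1,
    generate_experiment2,
    generate_experiment3,
    write_trials,
)
from .psychometric import LevelCounts, fit_psychometric, threshold_elevation
from .fitting import bayes_fit, bayes_fit_crosspath, simplex_fit

log = logging.getLogger("binocgain")

_EXP_KEYS = {
    "experiment",
    "seed",
    "participants",
    "jitter_sd",
    "pathways",
    "repetitions",
    "staircase_trials",
    "trials_per_block",
    "n_levels",
    "mask_contrast_norm",
    "params",
    "cross_weights",
}

_FIT_KEYS = {
    "seed",
    "psychometric",
    "simplex",
    "simplex_free",
    "simplex_starts",
    "bayes",
    "bayes_steps",
    "bayes_burn",
    "bayes_walkers",
    "crosspath",
    "fixed_params",
}


def _check_keys(config: dict, allowed: set, where: str) -> None:
    unknown = set(config) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:12]


def _provenance(config: dict, seed: int) -> dict:
    return {
        "seed": int(seed),
        "config_hash": _config_hash(config),
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }


def _params_from_config(spec) -> GainParams:
    if isinstance(spec, str):
        return PUBLISHED_PARAMS[spec]
    return GainParams(**spec)


def simulate(config: dict, seed: int, out_path) -> pd.DataFrame:
    """Generate a trial table per the config and write CSV + provenance."""
    _check_keys(config, _EXP_KEYS, "simulate")
    experiment = config.get("experiment", "exp1")
    participants = ParticipantSpec(
        n=int(config.get("participants", 3)),
        jitter_sd=float(config.get("jitter_sd", 0.1)),
    )
    rng = np.random.default_rng(seed)
    t0 = time.time()
    if experiment == "exp1":
        kwargs = {}
        if "pathways" in config:
            kwargs["pathways"] = tuple(config["pathways"])
            kwargs["pedestals_pct"] = {p: PEDESTALS_PCT[p] for p in kwargs["pathways"]}
        if "params" in config:
            kwargs["params_per_pathway"] = {
                pw: _params_from_config(s) for pw, s in config["params"].items()
            }
        trials = generate_experiment1(
            participants=participants,
            repetitions=int(config.get("repetitions", 3)),
            staircase=StaircaseConfig(n_trials=int(config.get("staircase_trials", 50))),
            rng=rng,
            **kwargs,
        )
    elif experiment == "exp2":
        state = None
        if "cross_weights" in config:
            mechs = tuple(
                _params_from_config(config.get("params", {}).get(pw, f"bayes_{suffix}"))
                for pw, suffix in zip(PATHWAYS, ("achromatic", "lm", "s"))
            )
            state = CrossPathState(mechs, tuple(map(tuple, config["cross_weights"])))
        trials = generate_experiment2(
            state=state,
            participants=participants,
            mask_contrast_norm=float(config.get("mask_contrast_norm", 16.0)),
            trials_per_block=int(config.get("trials_per_block", 200)),
            repetitions=int(config.get("repetitions", 10)),
            rng=rng,
        )
    elif experiment == "exp3":
        trials = generate_experiment3(
            participants=participants,
            repetitions=int(config.get("repetitions", 3)),
            staircase=StaircaseConfig(n_trials=int(config.get("staircase_trials", 50))),
            rng=rng,
        )
    else:
        raise ValueError(f"unknown experiment {experiment!r}")
    log.info("simulated %d trials in %.1fs (seed=%d)", len(trials), time.time() - t0, seed)
    if out_path is not None:
        write_trials(trials, out_path, seed=seed)
        meta = _provenance(config, seed)
        Path(str(out_path) + ".provenance.json").write_text(json.dumps(meta, indent=1))
    return trials


def _staircase_thresholds(trials: pd.DataFrame) -> pd.DataFrame:
    """Psychometric-fit thresholds per (pathway, arrangement, pedestal).

    Trials pool over participants, target eyes and repetitions; each
    cell is fit with the cumulative-Gaussian model on dB contrast.
    """
    rows = []
    for (pathway, arrangement, pedestal), sub in trials.groupby(
        ["pathway_target", "arrangement", "pedestal_norm"]
    ):
        counts = LevelCounts.from_trials(sub)
        if len(counts.levels_dB) < 2:
            continue
        fit = fit_psychometric(counts)
        rows.append(
            {
                "pathway": pathway,
                "arrangement": arrangement,
                "pedestal_norm": pedestal,
                "threshold_dB": fit.threshold_dB,
                "threshold_norm": 10.0 ** (fit.threshold_dB / 20.0),
                "sigma_dB": fit.sigma_dB,
                "beta": fit.beta,
                "ci_lo_dB": fit.threshold_ci[0],
                "ci_hi_dB": fit.threshold_ci[1],
                "identifiable": fit.identifiable,
                "n_trials": int(sum(counts.n_total)),
            }
        )
    return pd.DataFrame(rows)


def _elevation_matrix(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """3x3 threshold-elevation and psychometric-slope matrices for exp2."""
    fits = {}
    for (tgt, msk), sub in trials.groupby(["pathway_target", "pathway_mask"]):
        counts = LevelCounts.from_trials(sub)
        fits[(tgt, msk)] = fit_psychometric(counts)
    elev = pd.DataFrame(index=list(PATHWAYS), columns=list(PATHWAYS), dtype=float)
    slope = pd.DataFrame(index=list(PATHWAYS), columns=list(PATHWAYS), dtype=float)
    for tgt in PATHWAYS:
        base = fits.get((tgt, "none"))
        for msk in PATHWAYS:
            f = fits.get((tgt, msk))
            if f is None or base is None:
                continue
            elev.loc[tgt, msk] = threshold_elevation(f, base)
            slope.loc[tgt, msk] = f.beta
    return elev, slope


def fit(trials: pd.DataFrame, config: dict, seed: int) -> dict:
    """Run psychometric and model fits on a trial table; build a report."""
    _check_keys(config, _FIT_KEYS, "fit")
    if trials.empty:
        raise ValueError("empty trial table")
    report: dict = {"provenance": _provenance(config, seed), "experiments": {}}
    rng = np.random.default_rng(seed)
    for experiment, sub in trials.groupby("experiment"):
        entry: dict = {"n_trials": int(len(sub))}
        if experiment in ("exp1", "exp3"):
            thr = _staircase_thresholds(sub)
            entry["dipper_tables"] = thr.to_dict(orient="records")
            entry["summary"] = {}
            for pathway, tsub in thr.groupby("pathway"):
                mono = tsub[tsub.arrangement == "monocular"].sort_values("pedestal_norm")
                summ = {}
                for arrangement, asub in tsub.groupby("arrangement"):
                    asub = asub.sort_values("pedestal_norm")
                    peds = asub.pedestal_norm.to_numpy()
                    thrs = asub.threshold_norm.to_numpy()
                    if peds.size >= 5 and peds[0] == 0:
                        from .gain_model import DipperCurve

                        curve = DipperCurve(
                            OcularArrangement(arrangement), tuple(peds), tuple(thrs)
                        )
                        ref = None
                        if arrangement == "binocular" and len(mono):
                            ref = DipperCurve(
                                OcularArrangement("monocular"),
                                tuple(mono.pedestal_norm),
                                tuple(mono.threshold_norm),
                            )
                        summ[arrangement] = summarize_dipper(curve, ref)
                entry["summary"][pathway] = summ
            if config.get("simplex", False):
                entry["simplex_fits"] = {}
                for pathway, tsub in thr.groupby("pathway"):
                    curves = []
                    for arrangement, asub in tsub.groupby("arrangement"):
                        asub = asub.sort_values("pedestal_norm")
                        from .gain_model import DipperCurve

                        curves.append(
                            DipperCurve(
                                OcularArrangement(arrangement),
                                tuple(asub.pedestal_norm),
                                tuple(asub.threshold_norm),
                            )
                        )
                    res = simplex_fit(
                        curves,
                        config.get("simplex_free", ["p", "q", "m", "S", "Z", "omega", "k"]),
                        n_starts=int(config.get("simplex_starts", 100)),
                        rng=rng,
                    )
                    entry["simplex_fits"][pathway] = {
                        "params": {
                            n: getattr(res.params, n)
                            for n in ("p", "q", "m", "S", "Z", "omega", "k")
                        },
                        "rmse_dB": res.rmse_dB,
                        "n_starts": res.n_starts,
                    }
            if config.get("bayes", False):
                entry["bayes_fits"] = {}
                for pathway, psub in sub.groupby("pathway_target"):
                    post = bayes_fit(
                        psub,
                        n_walkers=int(config.get("bayes_walkers", 40)),
                        n_steps=int(config.get("bayes_steps", 800)),
                        n_burn=int(config.get("bayes_burn", 300)),
                        rng=rng,
                    )
                    entry["bayes_fits"][pathway] = {
                        "map": post.map_estimate,
                        "intervals": post.intervals,
                        "diagnostics": post.diagnostics,
                    }
        elif experiment == "exp2":
            elev, slope = _elevation_matrix(sub)
            entry["threshold_elevation_matrix"] = elev.to_dict()
            entry["beta_matrix"] = slope.to_dict()
            if config.get("crosspath", False):
                mechs = tuple(
                    _params_from_config(
                        config.get("fixed_params", {}).get(pw, f"bayes_{suffix}")
                    )
                    for pw, suffix in zip(PATHWAYS, ("achromatic", "lm", "s"))
                )
                post = bayes_fit_crosspath(
                    sub,
                    mechs,
                    n_walkers=int(config.get("bayes_walkers", 32)),
                    n_steps=int(config.get("bayes_steps", 800)),
                    n_burn=int(config.get("bayes_burn", 300)),
                    rng=rng,
                )
                entry["crosspath_fit"] = {
                    "map": post.map_estimate,
                    "intervals": post.intervals,
                    "diagnostics": post.diagnostics,
                }
        report["experiments"][str(experiment)] = entry
    return report


def reproduce(which: str = "table1_simplex", scale: str = "demo", seed: int = 0) -> dict:
    """Generate noiseless dippers from published parameter rows and refit.

    ``which`` selects the simplex or Bayesian parameter table;
    ``scale`` is ``demo`` (suppression weight free, everything else
    fixed at generating values) or ``full-desk`` (weight and stage-1
    exponent both free).  Reports recovered next to generating values.
    """
    if which not in ("table1_simplex", "table1_bayes"):
        raise ValueError("which must be 'table1_simplex' or 'table1_bayes'")
    if scale not in ("demo", "full-desk"):
        raise ValueError("scale must be 'demo' or 'full-desk'")
    prefix = "simplex_" if which == "table1_simplex" else "bayes_"
    rows = {k: v for k, v in PUBLISHED_PARAMS.items() if k.startswith(prefix)}
    free = ["omega"] if scale == "demo" else ["omega", "m"]
    n_starts = 20 if scale == "demo" else 50
    peds = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0)
    arrs = [OcularArrangement(t) for t in
            ("monocular", "binocular", "half_binocular", "dichoptic")]
    out: dict = {"which": which, "scale": scale, "rows": {}}
    rng = np.random.default_rng(seed)
    for name, gen in rows.items():
        curves = [dipper_curve(peds, a, gen) for a in arrs]
        res = simplex_fit(curves, free, fixed=gen, n_starts=n_starts, rng=rng)
        out["rows"][name] = {
            "generating": {n: getattr(gen, n) for n in ("p", "q", "m", "S", "Z", "omega", "k")},
            "recovered": {n: getattr(res.params, n) for n in free},
            "rmse_dB": res.rmse_dB,
        }
    return out


def report_to_text(report: dict) -> str:
    """Human-readable table dump of an analysis report."""
    lines = []
    for exp, entry in report.get("experiments", {}).items():
        lines.append(f"== {exp} ({entry.get('n_trials', '?')} trials) ==")
        for pathway, summ in entry.get("summary", {}).items():
            for arrangement, s in summ.items():
                lines.append(
                    f"  {pathway:3s} {arrangement:15s} facil={s['facilitation_factor']:.2f}"
                    f" slope={s['handle_slope']:.2f}"
                    + (
                        f" summation={s['summation_ratio']:.2f}"
                        if s.get("summation_ratio")
                        else ""
                    )
                )
        if "threshold_elevation_matrix" in entry:
            lines.append("  threshold elevation (rows=target, cols=mask):")
            elev = pd.DataFrame(entry["threshold_elevation_matrix"])
            lines.append("    " + elev.round(2).to_string().replace("\n", "\n    "))
    return "\n".join(lines)
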