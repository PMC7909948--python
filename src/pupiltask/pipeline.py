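"""End-to-end driver: simulate/load sessions -> fit -> attribute -> summarize.

Produces the tables the analysis scripts and the acceptance checks consume:
per-block behavior metrics, per-unit model evaluations with modulation
indices, and population-level statistics (category counts, hierarchical
bootstrap tests, sign-normalized MI reduction, independence permutation
test, d'-correlation).  All randomness flows from explicit seeds so a fixed
seed reproduces every table byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import score_session
from .modulation import sign_normalized_reduction, unit_modulation
from .popstats import (
    bootstrap_correlation,
    hierarchical_bootstrap,
    independence_permutation_test,
)
from .session import extract_reference_responses
from .statemodel import DEFAULT_CONSTANTS, evaluate_unit

FLOAT_FMT = "%.10g"


def analyze_population(sessions_truths: list, seed: int = 0, n_folds: int = 20,
                       alpha: float = 0.05, constants=DEFAULT_CONSTANTS,
                       n_iter: int = 2000) -> dict:
    """Run the full analysis over (Session, GroundTruth|None) pairs.

    Returns {'behavior': DataFrame, 'units': DataFrame, 'population': dict}.
    """
    beh_rows, unit_rows = [], []
    for si, (session, truth) in enumerate(sessions_truths):
        beh = score_session(session)
        beh.insert(0, "site", session.meta.get("site", f"site{si}"))
        beh_rows.append(beh)
        dprime = float(beh["dprime"].mean()) if len(beh) else np.nan
        refset = extract_reference_responses(session)
        for u in range(refset.n_units):
            ev = evaluate_unit(refset, unit=u, seed=seed + 97 * si + u,
                               n_folds=n_folds, alpha=alpha, constants=constants)
            mods = unit_modulation(refset, unit=u, evaluation=ev)
            row = dict(
                session=session.meta.get("session_id", ""),
                site=session.meta.get("site", f"site{si}"),
                unit=refset.unit_ids[u], area=session.meta.get("area", ""),
                dprime=dprime,
                r2_null=ev.r2_null, r2_full=ev.r2_full,
                r2_task_only=ev.r2_task_only, r2_pupil_only=ev.r2_pupil_only,
                r2_task_unique=ev.r2_task_unique, r2_pupil_unique=ev.r2_pupil_unique,
                p_state=ev.p_state, p_task_unique=ev.p_task_unique,
                p_pupil_unique=ev.p_pupil_unique, category=ev.category,
                mi_ap_full=mods["AP"].mi_full,
                mi_ap_task_only=mods["AP"].mi_task_only,
                mi_ap_pupil_only=mods["AP"].mi_pupil_only,
                mi_ap_task_unique=mods["AP"].mi_task_unique,
                mi_ls_full=mods["LS"].mi_full,
                mi_ls_task_only=mods["LS"].mi_task_only,
                mi_ls_pupil_unique=mods["LS"].mi_pupil_unique,
            )
            if truth is not None:
                tu = truth.units[u]
                row.update(effect=tu.effect, true_dp=tu.params.dp, true_db=tu.params.db,
                           true_gp=tu.params.gp, true_gb=tu.params.gb,
                           true_mi_ap=tu.mi_ap, true_mi_ls=tu.mi_ls)
            unit_rows.append(row)
    behavior = pd.concat(beh_rows, ignore_index=True) if beh_rows else pd.DataFrame()
    units = pd.DataFrame(unit_rows)
    population = summarize_population(units, seed=seed, n_iter=n_iter, alpha=alpha)
    return {"behavior": behavior, "units": units, "population": population}


def summarize_population(units: pd.DataFrame, seed: int = 0,
                         n_iter: int = 2000, alpha: float = 0.05) -> dict:
    """Population statistics over the per-unit results table."""
    sites = units["site"].to_numpy()
    out: dict = {
        "n_units": int(len(units)),
        "mean_r2_null": float(units["r2_null"].mean()),
        "mean_r2_full": float(units["r2_full"].mean()),
        "n_state_modulated": int((units["category"] != "none").sum()),
        "category_counts": units["category"].value_counts().to_dict(),
    }
    bs = hierarchical_bootstrap(units["r2_full"].to_numpy(), sites,
                                statistic="mean", n_iter=n_iter, seed=seed,
                                values2=units["r2_null"].to_numpy())
    out["full_vs_null_p"] = bs.p
    out["full_vs_null_p_text"] = bs.p_text()

    norm, reduction = sign_normalized_reduction(
        units["mi_ap_task_only"].to_numpy(), units["mi_ap_task_unique"].to_numpy())
    out["mi_ap_mean_task_only"] = float(norm[:, 0].mean())
    out["mi_ap_mean_task_unique"] = float(norm[:, 1].mean())
    out["mi_ap_reduction"] = float(reduction)
    bs2 = hierarchical_bootstrap(norm[:, 0] - norm[:, 1], sites,
                                 statistic="mean", n_iter=n_iter, seed=seed + 1)
    out["mi_ap_reduction_p"] = bs2.p
    out["mi_ap_reduction_p_text"] = bs2.p_text()

    sig_task = (units["p_task_unique"] < alpha).to_numpy()
    sig_pupil = (units["p_pupil_unique"] < alpha).to_numpy()
    out["independence_p"] = independence_permutation_test(
        sig_task, sig_pupil, n_iter=n_iter, seed=seed + 2)

    dp = units["dprime"].to_numpy()
    tu = units["r2_task_unique"].to_numpy()
    ok = np.isfinite(dp) & np.isfinite(tu)
    if ok.sum() >= 3 and len(np.unique(dp[ok])) >= 3 and tu[ok].std() > 0:
        r, bres = bootstrap_correlation(dp[ok], tu[ok], sites[ok],
                                        n_iter=n_iter, seed=seed + 3)
        out["dprime_task_unique_r"] = float(r)
        out["dprime_task_unique_p"] = bres.p
    return out


def write_results(results: dict, outdir) -> None:
    """Write the result tables with a fixed float format (byte-reproducible)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results["behavior"].to_csv(outdir / "behavior.csv", index=False,
                               float_format=FLOAT_FMT)
    results["units"].to_csv(outdir / "unit_results.csv", index=False,
                            float_format=FLOAT_FMT)
    with open(outdir / "population.json", "w") as f:
        json.dump(results["population"], f, indent=1, sort_keys=True, default=str)
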