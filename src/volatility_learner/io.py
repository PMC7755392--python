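"""CSV readers/writers and the staged pipeline runner.

Choice data schema (one row per trial):

    subject, task_version, trial, block_type, p_shape1_event, M1, M2,
    event_shape, choice, outcome_O, received_magnitude

``choice`` is 1/2 with 0 for a missed response; ``outcome_O`` must agree
with the schedule's event shape under the task version's valence map (it is
recomputed and checked on read).
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .models import ChoiceDataset, coded_outcome, get_model_spec
from .task import TrialSchedule

CHOICE_COLUMNS = [
    "subject", "task_version", "trial", "block_type", "p_shape1_event",
    "M1", "M2", "event_shape", "choice", "outcome_O", "received_magnitude",
]


def write_choice_data(datasets, path) -> None:
    frames = []
    for ds in datasets:
        f = ds.to_frame()
        f.insert(4, "p_shape1_event", ds.schedule.trials["p_shape1_event"].to_numpy())
        f.insert(7, "event_shape", ds.schedule.event_shape)
        frames.append(f[CHOICE_COLUMNS])
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_choice_data(path) -> list[ChoiceDataset]:
    """Read and validate a cohort of choice datasets.

    Schema violations and outcome-coding inconsistencies are reported with
    the offending CSV row numbers (1-based, counting the header as row 1).
    """
    df = pd.read_csv(path)
    missing = set(CHOICE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df["_row"] = np.arange(2, len(df) + 2)

    bad = df[~df["choice"].isin([0, 1, 2])]
    if len(bad):
        raise ValueError(
            f"invalid choice values at rows {bad['_row'].tolist()[:10]} "
            "(choice must be 0 [missed], 1 or 2)"
        )

    datasets = []
    for (subject, version), g in df.groupby(["subject", "task_version"],
                                            sort=True):
        g = g.sort_values("trial")
        block_order = ("stable_first" if g["block_type"].iloc[0] == "stable"
                       else "volatile_first")
        schedule = TrialSchedule(
            version, block_order, -1,
            g[["trial", "block_type", "p_shape1_event", "M1", "M2",
               "event_shape"]].reset_index(drop=True),
        )
        expected_O = coded_outcome(schedule)
        mism = g["_row"].to_numpy()[g["outcome_O"].to_numpy() != expected_O]
        if len(mism):
            raise ValueError(
                f"outcome_O coding disagrees with event_shape for subject "
                f"{subject} ({version}) at rows {mism.tolist()[:10]}"
            )
        datasets.append(
            ChoiceDataset(
                str(subject), schedule,
                g["choice"].to_numpy(), g["outcome_O"].to_numpy(),
                g["received_magnitude"].to_numpy(),
            )
        )
    return datasets


def write_scores(scores: pd.DataFrame, path) -> None:
    scores.rename_axis("subject").to_csv(path)


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject")


# ---------------------------------------------------------------------------
# Pipeline

STAGES = ("simulate", "fit", "compare", "recover", "ppc")


def run_pipeline(config: dict, out_dir) -> Path:
    """Execute pipeline stages in order and write artifacts + manifest.

    ``config`` keys: ``stages`` (ordered subset of {simulate, fit, compare,
    recover, ppc}), ``model`` (model id), ``seed``, cohort settings
    (``n_subjects``, ``task_versions``, ``missing_rate``), sampler settings
    (``chains``, ``tune``, ``draws``) and ``compare_models``.  All stage
    randomness derives from the top-level seed through a per-stage counter,
    so each stage is independently reproducible.
    """
    from .compare import compare as compare_tables
    from .hbayes import build_model, fit
    from .recovery import parameter_recovery, switch_count_ppc
    from .synth import CohortSpec, default_population, simulate_cohort

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", ("simulate", "fit")))
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown pipeline stages: {sorted(unknown)}")

    seed = int(config.get("seed", 0))
    stage_seeds = {s: seed + 1000 * (i + 1) for i, s in enumerate(STAGES)}
    model_id = config.get("model", "m11")
    spec = get_model_spec(model_id, three_way=config.get("three_way", False))
    sampler = {
        "chains": int(config.get("chains", 4)),
        "tune": int(config.get("tune", 200)),
        "draws": int(config.get("draws", 2000)),
    }

    manifest = {
        "package_version": __version__,
        "config": config,
        "stage_seeds": stage_seeds,
        "runtimes_s": {},
        "artifacts": {},
    }

    truth = None
    datasets = scores = None
    result = None
    for stage in stages:
        t0 = time.perf_counter()
        if stage == "simulate":
            cohort = CohortSpec(
                n_subjects=int(config.get("n_subjects", 20)),
                task_versions=tuple(config.get("task_versions",
                                               ("gain", "aversive"))),
                population=default_population(spec),
                seed=stage_seeds["simulate"],
                missing_rate=float(config.get("missing_rate", 0.0)),
            )
            truth = simulate_cohort(cohort)
            datasets, scores = truth.datasets, truth.scores
            write_choice_data(datasets, out / "choices.csv")
            write_scores(scores, out / "scores.csv")
            truth.parameters.rename_axis("subject").to_csv(
                out / "true_parameters.csv")
            manifest["artifacts"][stage] = [
                "choices.csv", "scores.csv", "true_parameters.csv"]
        elif stage in ("fit", "compare", "recover", "ppc"):
            if datasets is None:
                datasets = read_choice_data(config["choices"])
                scores = read_scores(config["scores"])
            if stage == "fit":
                model = build_model(spec, datasets, scores)
                result = fit(model, seed=stage_seeds["fit"], **sampler)
                result.summary("mu").to_csv(out / "population_mu.csv",
                                            index=False)
                result.summary("beta_g").to_csv(out / "population_beta_g.csv",
                                                index=False)
                result.posterior_mean_theta().rename_axis("subject").to_csv(
                    out / "subject_posterior_means.csv")
                manifest["artifacts"][stage] = [
                    "population_mu.csv", "population_beta_g.csv",
                    "subject_posterior_means.csv"]
            elif stage == "compare":
                lls = {}
                for mid in config.get("compare_models", ["m1", "m2"]):
                    mspec = get_model_spec(mid)
                    m = build_model(mspec, datasets, scores)
                    r = fit(m, seed=stage_seeds["compare"], **sampler)
                    lls[mid] = r.pointwise_loglik()
                table = compare_tables(lls)
                table.to_csv(out / "model_comparison.csv")
                manifest["artifacts"][stage] = ["model_comparison.csv"]
            elif stage == "recover":
                if truth is None:
                    raise ValueError(
                        "recover stage requires the simulate stage")
                report = parameter_recovery(
                    spec, truth,
                    n_datasets=int(config.get("n_datasets", 2)),
                    fit_config=sampler, seed=stage_seeds["recover"],
                )
                report.per_component.rename_axis("component").to_csv(
                    out / "recovery_correlations.csv")
                manifest["artifacts"][stage] = ["recovery_correlations.csv"]
            elif stage == "ppc":
                if result is None:
                    raise ValueError("ppc stage requires the fit stage")
                ppc = switch_count_ppc(result, datasets,
                                       seed=stage_seeds["ppc"])
                ppc["table"].to_csv(out / "switch_counts.csv")
                (out / "switch_ppc.json").write_text(json.dumps(
                    {"correlation": None if np.isnan(ppc["correlation"])
                     else ppc["correlation"], "note": ppc["note"]}, indent=2))
                manifest["artifacts"][stage] = [
                    "switch_counts.csv", "switch_ppc.json"]
        manifest["runtimes_s"][stage] = round(time.perf_counter() - t0, 3)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return out
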