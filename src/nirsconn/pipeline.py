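"""End-to-end orchestration of the synthetic cohort pipeline.

``run_pipeline`` simulates a cohort of participants (three groups,
three sessions), pushes every recording through preprocessing and
connectivity, fits the multilevel Poisson degree model, and applies the
ROPE/HDI decision layer, returning a report with per-stage logs and the
18 pairwise decisions.  All randomness descends from the single
top-level seed in the configuration.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .connectivity import compute_connectivity, degree_rows
from .errors import NirsConnError
from .glmm import GROUP_LEVELS, SESSION_LEVELS, check_convergence, fit_poisson_glmm
from .preprocess import BeerLambertConfig, preprocess_recording
from .rope import compare_all, comparisons_to_frame
from .synth import simulate_cluster_network, simulate_hemo, simulate_optical

logger = logging.getLogger(__name__)


def simulate_cohort(config: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate, preprocess and measure a full cohort.

    Returns the long-format degree table and a log dictionary with
    per-recording epoch/bad-channel counts.
    """
    cohort = config.cohort
    sim = config.simulation
    blc = BeerLambertConfig(ppf=config.ppf, wavelengths=sim.wavelengths)
    ep = config.epoching
    root = np.random.SeedSequence(config.seed)

    rows, log = [], []
    pid = 0
    for g, n_g in zip(GROUP_LEVELS, cohort.n_per_group):
        for _ in range(n_g):
            pname = f"P{pid:03d}"
            for s in SESSION_LEVELS:
                child = np.random.SeedSequence([config.seed, pid, SESSION_LEVELS.index(s)])
                seed = int(child.generate_state(1)[0] % (2**31 - 1))
                n_clusters = (
                    cohort.n_clusters_effect
                    if (g, s) in [tuple(c) for c in cohort.effect_cells]
                    else cohort.n_clusters_base
                )
                network = simulate_cluster_network(
                    sim.n_long_channels, n_clusters, seed=seed, coupling=cohort.coupling
                )
                rec_cfg = dataclasses.replace(sim, seed=seed)
                hemo_true = simulate_hemo(network, rec_cfg)
                optical, truth = simulate_optical(hemo_true, rec_cfg, blc, return_truth=True)
                # manual annotation stands in for visual inspection: the
                # injected artifact windows are the annotated segments
                annotations = [
                    (onset, max(duration, 1.0), "artifact")
                    for onset, duration, _ in truth["artifact_windows"]
                ]
                hemo, report = preprocess_recording(optical, blc, config.quality, annotations)
                try:
                    result = compute_connectivity(
                        hemo,
                        epoch_length=ep.epoch_length,
                        overlap=ep.overlap,
                        saturation_limit=ep.saturation_limit,
                        threshold=ep.threshold,
                        aggregate=ep.aggregate,
                    )
                except NirsConnError:
                    # recording lost entirely to artifacts: drop it, as a
                    # study would, and continue with the rest of the cohort
                    logger.warning("recording %s/%s dropped: no usable epochs", pname, s)
                    log.append(
                        {
                            "participant": pname,
                            "group": g,
                            "session": s,
                            "n_epochs_used": 0,
                            "n_bad_channels": report["n_bad"],
                        }
                    )
                    continue
                rows.append(degree_rows(result, pname, g, s))
                log.append(
                    {
                        "participant": pname,
                        "group": g,
                        "session": s,
                        "n_epochs_used": result.n_epochs_used,
                        "n_bad_channels": report["n_bad"],
                    }
                )
            pid += 1
    table = pd.concat(rows, ignore_index=True)
    return table, {"recordings": log}


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate -> preprocess -> connect -> fit -> compare.

    Returns a report with the degree table, posterior convergence
    summary, and the completed pairwise comparisons.  A stage failure
    aborts with the stage name and cause.
    """
    stage = "simulate/preprocess/connect"
    try:
        table, cohort_log = simulate_cohort(config)
        stage = "fit"
        sampler = config.sampler
        draws = fit_poisson_glmm(
            table,
            n_chains=sampler.n_chains,
            n_iter=sampler.n_iter,
            n_warmup=sampler.n_warmup,
            seed=config.seed,
            target_accept=sampler.target_accept,
            max_depth=sampler.max_depth,
        )
        convergence = check_convergence(draws)
        stage = "compare"
        inf = config.inference
        n_pred = min(inf.n_pred_draws, draws.n_chains * draws.n_draws)
        if n_pred < inf.n_pred_draws:
            logger.warning(
                "only %d retained draws; using them all for marginal predictions", n_pred
            )
        comps = compare_all(
            draws,
            table,
            n_draws=n_pred,
            seed=config.seed,
            response_sd=inf.response_sd,
            mass=inf.hdi_mass,
            rope_fraction=inf.rope_fraction,
        )
    except NirsConnError as err:
        raise NirsConnError(f"pipeline stage {stage!r} failed: {err}") from err

    report = {
        "seed": config.seed,
        "degree_table": table,
        "cohort_log": cohort_log,
        "convergence": convergence,
        "comparisons": comparisons_to_frame(comps),
        "response_sd": float(table["degree"].std(ddof=1)),
    }
    logger.info(
        "pipeline complete: %d rows, max rhat %.3f, %d comparisons",
        len(table), convergence["max_rhat"], len(comps),
    )
    return report
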