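"""End-to-end pipeline: flows -> catchments -> model fits -> comparison report.

One call reproduces the whole workflow on any dataset: build area flow
weights and discrete HSAs, fit the multiple-membership Poisson model on the
weighted hospital network, fit the corresponding HSA-clustered model, and
write variance metrics, rankings and a ranking comparison, with a
provenance record (config echo, seed, package version) so two runs with the
same inputs and seed are reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import catchments as ca
from . import io as hio
from . import metrics as me
from . import mm_model as mm
from . import synthetic as sy

log = logging.getLogger("hsanet")


@dataclass
class RunConfig:
    """Inputs and settings for a full pipeline run.

    Either point the path fields at CSV tables or leave them None and supply
    ``sim`` to generate a synthetic system.  ``fixed_effects`` are person
    columns entering the Poisson model; ``outcome`` is a count column and
    ``offset`` a positive follow-up column.
    """

    out_dir: str | Path = "hsanet_run"
    seed: int = 0
    admissions_path: str | None = None
    persons_path: str | None = None
    hospitals_path: str | None = None
    sim: sy.SimConfig | None = None
    attribute_episode: str = "first"
    outcome: str = "preventable_count"
    offset: str = "followup_years"
    fixed_effects: tuple = ("age_std", "sex", "health_score")
    occupancy_covariate: bool = False
    burnin: int = 1_000
    iterations: int = 4_000
    thin: int = 1
    make_plots: bool = True


def _fit_pair(config: RunConfig, persons_inc: pd.DataFrame,
              pw: ca.PersonWeights, partition: ca.HsaPartition,
              hospitals: pd.DataFrame | None):
    """Fit the weighted-network model and the discrete-HSA model."""
    hosp_cov = None
    if config.occupancy_covariate:
        if hospitals is None:
            raise ValueError("occupancy covariate requested without hospital table")
        hosp_cov = {"occupancy": hospitals.set_index("hospital_id")
                    ["occupancy_pct"].to_dict()}

    spec = mm.ModelSpec(burnin=config.burnin, iterations=config.iterations,
                        thin=config.thin, seed=config.seed)
    data_mm = mm.build_dataset(
        persons_inc, outcome=config.outcome, offset=config.offset,
        fixed_effects=config.fixed_effects,
        classifications=[mm.Classification.from_person_weights("hospital", pw)],
        hospital_covariates=hosp_cov, person_weights=pw,
    )
    fit_mm = mm.fit_mcmc(spec, data_mm)

    hsa_of_person = persons_inc["area_id"].astype(str).map(partition.assignment)
    data_hsa = mm.build_dataset(
        persons_inc, outcome=config.outcome, offset=config.offset,
        fixed_effects=config.fixed_effects,
        classifications=[mm.Classification.from_grouping("hsa", hsa_of_person)],
        hospital_covariates=hosp_cov, person_weights=pw,
    )
    fit_hsa = mm.fit_mcmc(
        mm.ModelSpec(burnin=config.burnin, iterations=config.iterations,
                     thin=config.thin, seed=config.seed + 1),
        data_hsa,
    )
    return fit_mm, fit_hsa


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write artifacts under ``config.out_dir``.

    Returns a dict with the in-memory objects (profiles, partition, fits,
    metrics) for interactive use.  Artifacts: weights.csv, hsa.csv,
    summary.json, exclusions.csv, chains_*.csv.gz, metrics.json,
    ranking_*.csv, provenance.json and optional plots.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        log.info("stage: %s", name)
        return name

    try:
        stage("inputs")
        if config.sim is not None:
            admissions, persons, hospitals, truth = sy.generate_system(
                config.sim, seed=config.seed
            )
            admissions.to_csv(out / "admissions.csv", index=False)
            persons.to_csv(out / "persons.csv", index=False)
            hospitals.to_csv(out / "hospitals.csv", index=False)
        else:
            if config.admissions_path is None or config.persons_path is None:
                raise ValueError("need admissions/persons paths or a SimConfig")
            admissions, persons, hospitals = hio.read_tables(
                config.admissions_path, config.persons_path,
                config.hospitals_path,
                require_hospital_attrs=config.occupancy_covariate,
            )
            truth = None
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'inputs' failed: {err}") from err

    try:
        stage("catchments")
        episodes = ca.merge_episodes(admissions, attribute=config.attribute_episode)
        log.info("episodes: %d rows from %d admission rows",
                 len(episodes), len(admissions))
        profiles, _ = ca.compute_area_weights(episodes)
        partition = ca.assign_hsa(profiles)
        pw = ca.person_weight_matrix(profiles, persons)
        summary = ca.catchment_summary(profiles, partition, persons, episodes)
        hio.write_weights(profiles, out / "weights.csv")
        hio.write_hsa(partition, out / "hsa.csv")
        hio.write_summary(summary.stats, out / "summary.json")
        hio.write_exclusions(pw.exclusions, out / "exclusions.csv")
        log.info("catchments: %d areas, %d hospitals, %d persons excluded",
                 len(profiles), len(pw.hospital_ids), len(pw.exclusions))
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'catchments' failed: {err}") from err

    try:
        stage("fit")
        persons_inc = persons[persons["person_id"].isin(pw.person_ids)]
        persons_inc = persons_inc.set_index("person_id").loc[pw.person_ids] \
            .reset_index()
        fit_mm_, fit_hsa_ = _fit_pair(config, persons_inc, pw, partition,
                                      hospitals)
        for label, fit in (("mm", fit_mm_), ("hsa", fit_hsa_)):
            long = pd.concat(
                [fit.beta.add_prefix("beta."),
                 fit.sigma2.add_prefix("sigma2."),
                 next(iter(fit.u.values())).add_prefix("u.")],
                axis=1,
            )
            long.insert(0, "iteration", np.arange(len(long)))
            long.to_csv(out / f"chains_{label}.csv.gz", index=False)
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'fit' failed: {err}") from err

    try:
        stage("report")
        rank_mm = me.rank_hospitals(fit_mm_, "hospital")
        rank_hsa = me.rank_hospitals(fit_hsa_, "hsa")
        comparison = me.compare_rankings(rank_mm, rank_hsa)
        s2_mm = me.mrr_summary(fit_mm_.sigma2["hospital"].to_numpy())
        s2_hsa = me.mrr_summary(fit_hsa_.sigma2["hsa"].to_numpy())
        dic_mm, pd_mm = me.dic(fit_mm_)
        dic_hsa, pd_hsa = me.dic(fit_hsa_)
        metrics = {
            "mm": {**s2_mm, "dic": dic_mm, "pD": pd_mm},
            "hsa": {**s2_hsa, "dic": dic_hsa, "pD": pd_hsa},
            "comparison": {
                **me.variance_comparison(s2_mm["sigma2_mean"],
                                         s2_hsa["sigma2_mean"]),
                "spearman_rho": comparison["spearman_rho"],
                "only_in_mm": comparison["only_in_mm"],
            },
        }
        with open(out / "metrics.json", "w") as f:
            json.dump(metrics, f, indent=2, default=hio._jsonify)
        rank_mm.to_csv(out / "ranking_mm.csv")
        rank_hsa.to_csv(out / "ranking_hsa.csv")
        if config.make_plots:
            me.caterpillar_plot(rank_mm, str(out / "caterpillar_mm.png"),
                                ranking_ref=None)
        provenance = {
            "package": "hsanet",
            "version": _pkg_version(),
            "seed": config.seed,
            "config": _config_echo(config),
        }
        with open(out / "provenance.json", "w") as f:
            json.dump(provenance, f, indent=2, default=hio._jsonify)
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'report' failed: {err}") from err

    return {
        "profiles": profiles, "partition": partition,
        "person_weights": pw, "summary": summary,
        "fit_mm": fit_mm_, "fit_hsa": fit_hsa_,
        "metrics": metrics, "ranking_mm": rank_mm, "ranking_hsa": rank_hsa,
        "truth": truth,
    }


def _pkg_version() -> str:
    from . import __version__
    return __version__


def _config_echo(config: RunConfig) -> dict:
    d = asdict(config)
    d["out_dir"] = str(d["out_dir"])
    return d
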