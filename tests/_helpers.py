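"""Shared test utilities: closed-loop generate/build/fit runs."""

import numpy as np

import hsanet as hn


def closed_loop(cfg, seed, burnin=1000, iterations=4000, fit_hsa=False,
                fixed_effects=("age_std", "sex", "health_score")):
    """Generate a synthetic system, build catchments, fit the MM model.

    Returns a dict with the truth, the weighted-network fit and (optionally)
    the HSA-clustered fit, plus the catchment objects.
    """
    adm, per, hos, truth = hn.generate_system(cfg, seed=seed)
    profiles, _ = hn.compute_area_weights(adm)
    partition = hn.assign_hsa(profiles)
    pw = hn.person_weight_matrix(profiles, per)
    per_inc = (per[per.person_id.isin(pw.person_ids)]
               .set_index("person_id").loc[pw.person_ids].reset_index())
    data = hn.build_dataset(
        per_inc, outcome="preventable_count", offset="followup_years",
        fixed_effects=fixed_effects,
        classifications=[hn.Classification.from_person_weights("hospital", pw)],
    )
    fit = hn.fit_mcmc(
        hn.ModelSpec(burnin=burnin, iterations=iterations, seed=seed + 1000),
        data,
    )
    out = {
        "admissions": adm, "persons": per_inc, "hospitals": hos,
        "truth": truth, "profiles": profiles, "partition": partition,
        "person_weights": pw, "data": data, "fit": fit,
        "sigma2": fit.sigma2["hospital"].to_numpy(),
    }
    if fit_hsa:
        hsa_groups = per_inc["area_id"].astype(str).map(partition.assignment)
        data_hsa = hn.build_dataset(
            per_inc, outcome="preventable_count", offset="followup_years",
            fixed_effects=fixed_effects,
            classifications=[hn.Classification.from_grouping("hsa", hsa_groups)],
        )
        fit_h = hn.fit_mcmc(
            hn.ModelSpec(burnin=burnin, iterations=iterations,
                         seed=seed + 2000),
            data_hsa,
        )
        out["fit_hsa"] = fit_h
        out["sigma2_hsa"] = fit_h.sigma2["hsa"].to_numpy()
    return out


def ci(draws, level=0.95):
    lo = (1 - level) / 2
    return tuple(np.quantile(np.asarray(draws), [lo, 1 - lo]))


def intervals_overlap(a, b):
    return a[0] <= b[1] and b[0] <= a[1]
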