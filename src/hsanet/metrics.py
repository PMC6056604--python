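"""Posterior summary metrics: MRR, PCV, DIC, and hospital rankings.

The median rate ratio (MRR) converts a between-cluster variance on the log
scale into the median rate increase a person would face moving from a
lower-rate to a higher-rate cluster:

    MRR = exp( sqrt(2 * sigma2) * Phi^{-1}(0.75) )

The proportional change in variance (PCV) measures how much of a variance
component a covariate explains, and DIC = mean deviance + pD compares model
fit, with pD the effective number of parameters.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .mm_model import FitResult, deviance

__all__ = [
    "mrr", "mrr_summary", "pcv", "dic", "rank_hospitals",
    "compare_rankings", "variance_comparison", "caterpillar_plot",
]

_PHI_INV_075 = stats.norm.ppf(0.75)


def mrr(sigma2):
    """Median rate ratio for a between-cluster variance (scalar or array).

    ``mrr(0) == 1`` (no between-cluster variation); strictly increasing in
    sigma2. Negative variances are rejected.
    """
    s2 = np.asarray(sigma2, dtype=float)
    if np.any(s2 < 0):
        raise ValueError("variance must be non-negative")
    out = np.exp(np.sqrt(2.0 * s2) * _PHI_INV_075)
    return float(out) if np.isscalar(sigma2) or out.ndim == 0 else out


def mrr_summary(sigma2_chain: np.ndarray, ci: float = 0.95) -> dict:
    """Point MRR and credible interval from a sigma2 posterior chain.

    The point estimate applies the transformation to the posterior *mean* of
    sigma2 (the conventional pairing of a reported variance with its MRR);
    the interval is the per-draw transformation's quantiles, which is
    order-preserving because the map is monotone.
    """
    s2 = np.asarray(sigma2_chain, dtype=float)
    if s2.ndim != 1 or len(s2) < 2:
        raise ValueError("need a 1-d chain of sigma2 draws")
    lo, hi = (1 - ci) / 2, 1 - (1 - ci) / 2
    draws = mrr(s2)
    return {
        "mrr": mrr(float(s2.mean())),
        "ci": (float(np.quantile(draws, lo)), float(np.quantile(draws, hi))),
        "sigma2_mean": float(s2.mean()),
        "sigma2_se": float(s2.std(ddof=1)),
    }


def pcv(v_before: float, v_after: float) -> float:
    """Proportional change in variance: (v_before - v_after) / v_before.

    Negative values are meaningful (a variance can rise after adjustment).
    """
    if v_before <= 0:
        raise ValueError("baseline variance must be positive")
    return (v_before - v_after) / v_before


def dic(fit: FitResult) -> tuple[float, float]:
    """Deviance information criterion and effective parameter count pD.

    pD = mean posterior deviance - deviance at the plug-in (posterior means
    of the fixed and random effects); DIC = mean deviance + pD.
    """
    dbar = float(np.mean(fit.deviance))
    beta_bar, u_bar = fit.posterior_mean_state()
    eta = fit.linear_predictor(beta_bar, u_bar)
    dhat = deviance(fit.data.y, np.exp(eta))
    pd_ = dbar - dhat
    return dbar + pd_, pd_


def rank_hospitals(
    fit: FitResult, classification: str | None = None, ci: float = 0.95
) -> pd.DataFrame:
    """Posterior medians, credible intervals and ranks of the unit effects.

    Rank 1 is the lowest (best, for an adverse outcome) posterior median.
    A unit is flagged ``significant`` when its interval excludes zero, i.e.
    its rate differs credibly from the average hospital; no multiplicity
    adjustment is applied.
    """
    if classification is None:
        classification = next(iter(fit.u))
    chains = fit.u[classification]
    lo, hi = (1 - ci) / 2, 1 - (1 - ci) / 2
    med = chains.median(axis=0)
    qlo = chains.quantile(lo, axis=0)
    qhi = chains.quantile(hi, axis=0)
    out = pd.DataFrame({
        "median": med, "lower": qlo, "upper": qhi,
        "significant": (qlo > 0) | (qhi < 0),
    })
    out["rank"] = out["median"].rank(method="first").astype(int)
    out.index.name = "unit"
    return out.sort_values("rank")


def compare_rankings(
    ranking_mm: pd.DataFrame, ranking_ref: pd.DataFrame
) -> dict:
    """Compare hospital rankings from two fits (e.g. weighted network vs HSA).

    Returns a paired table over shared units, the Spearman rank correlation
    of their posterior medians, and the units present only in the first
    (multiple-membership) ranking — e.g. hospitals that never form an HSA.
    """
    shared = ranking_mm.index.intersection(ranking_ref.index)
    if len(shared) == 0:
        raise ValueError("rankings share no units")
    only_mm = sorted(ranking_mm.index.difference(ranking_ref.index))
    paired = ranking_mm.loc[shared].join(
        ranking_ref.loc[shared], lsuffix="_mm", rsuffix="_ref"
    )
    if len(shared) > 1:
        rho = float(stats.spearmanr(
            paired["median_mm"], paired["median_ref"]
        ).statistic)
    else:
        rho = float("nan")
    return {"paired": paired, "spearman_rho": rho, "only_in_mm": only_mm}


def variance_comparison(v_network: float, v_hsa: float) -> dict:
    """Headline comparison of between-hospital variance under two structures.

    Reports the weighted-network : discrete-catchment variance ratio and the
    PCV from the network model to the catchment model.  A ratio above 1 means
    the discrete catchments attenuate between-hospital variation.
    """
    if v_hsa <= 0 or v_network < 0:
        raise ValueError("variances must be positive")
    return {
        "variance_network": v_network,
        "variance_hsa": v_hsa,
        "ratio": v_network / v_hsa,
        "pcv_network_to_hsa": pcv(v_network, v_hsa) if v_network > 0 else float("nan"),
    }


def caterpillar_plot(
    ranking: pd.DataFrame, path: str, ranking_ref: pd.DataFrame | None = None
) -> None:
    """Ranked unit effects with credible intervals (optionally two fits)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    r = ranking.sort_values("rank")
    x = np.arange(len(r))
    fig, ax = plt.subplots(figsize=(max(6, len(r) * 0.25), 4))
    ax.errorbar(x, r["median"],
                yerr=[r["median"] - r["lower"], r["upper"] - r["median"]],
                fmt="o", ms=3, lw=0.8, capsize=2, label="weighted network")
    if ranking_ref is not None:
        ref = ranking_ref.reindex(r.index)
        ok = ref["median"].notna()
        ax.errorbar(x[ok.to_numpy()], ref.loc[ok, "median"],
                    yerr=[ref.loc[ok, "median"] - ref.loc[ok, "lower"],
                          ref.loc[ok, "upper"] - ref.loc[ok, "median"]],
                    fmt="s", ms=3, lw=0.8, capsize=2, alpha=0.6,
                    label="discrete HSA")
        ax.legend(fontsize=8)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xticks(x)
    ax.set_xticklabels(r.index, rotation=90, fontsize=6)
    ax.set_ylabel("hospital effect u_j (log rate)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
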