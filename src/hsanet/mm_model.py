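"""Multilevel Poisson models with multiple-membership random classifications.

A person's outcome count Y_i over follow-up t_i is modelled as

    Y_i ~ Poisson(mu_i),
    log mu_i = log t_i + sum_p beta_p x_pi + sum_q beta_q (sum_j w_ij x_qj)
               + sum_c sum_j w_ij^(c) u_j^(c),
    u_j^(c) ~ N(0, sigma2_c),

where each classification *c* (hospital network, geographic area, ...) carries
a per-person weight row summing to one.  A single-membership (nested)
classification is the degenerate case of one unit carrying weight 1, and two
or more classifications give a cross-classified model.  Estimation is by
MCMC (Metropolis-within-Gibbs with adaptive scalar random walks and conjugate
variance draws), with flat-ish N(0, 1e6) priors on fixed effects and
Inverse-Gamma(0.001, 0.001) priors on variances by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import gammaln

from .catchments import PersonWeights, weighted_hospital_covariate
from . import _sampler

__all__ = [
    "Classification", "MmDataset", "ModelSpec", "FitResult",
    "build_dataset", "fit_mcmc", "deviance", "diagnostics",
    "conditional_sigma2_draws",
]

_WEIGHT_TOL = 1e-9


@dataclass
class Classification:
    """One random classification: a label, its units, and person weights.

    ``weights`` is a sparse n_persons x n_units matrix whose rows sum to one.
    Single membership is expressed by unit-vector rows.
    """

    label: str
    units: list
    weights: sp.csr_matrix
    fixed_variance: float | None = None  # pin sigma2 (e.g. 0) instead of sampling

    def __post_init__(self) -> None:
        self.weights = sp.csr_matrix(self.weights)
        if self.weights.shape[1] != len(self.units):
            raise ValueError(
                f"classification {self.label!r}: {self.weights.shape[1]} weight "
                f"columns but {len(self.units)} units"
            )
        rows = np.asarray(self.weights.sum(axis=1)).ravel()
        if np.any(np.abs(rows - 1.0) > 1e-6):
            bad = int(np.argmax(np.abs(rows - 1.0)))
            raise ValueError(
                f"classification {self.label!r}: weight row {bad} sums to {rows[bad]}"
            )

    @classmethod
    def from_person_weights(cls, label: str, pw: PersonWeights,
                            **kw) -> "Classification":
        return cls(label=label, units=list(pw.hospital_ids),
                   weights=pw.matrix, **kw)

    @classmethod
    def from_grouping(cls, label: str, groups: Sequence, **kw) -> "Classification":
        """Single-membership classification from a group label per person."""
        codes, units = pd.factorize(pd.Series(groups), sort=True)
        n = len(codes)
        mat = sp.csr_matrix(
            (np.ones(n), (np.arange(n), codes)), shape=(n, len(units))
        )
        return cls(label=label, units=list(units), weights=mat, **kw)


@dataclass
class MmDataset:
    """Assembled model inputs: counts, offset, fixed design, classifications."""

    y: np.ndarray
    offset_log: np.ndarray       # log follow-up time
    X: np.ndarray                # fixed-effect design incl. intercept
    x_names: list[str]
    classifications: list[Classification]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.offset_log = np.asarray(self.offset_log, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        n = len(self.y)
        if np.any(self.y < 0) or np.any(self.y != np.round(self.y)):
            raise ValueError("outcome counts must be non-negative integers")
        if not np.all(np.isfinite(self.offset_log)):
            raise ValueError("follow-up times must be positive and finite")
        if self.X.shape != (n, len(self.x_names)):
            raise ValueError("design matrix shape does not match x_names")
        for c in self.classifications:
            if c.weights.shape[0] != n:
                raise ValueError(
                    f"classification {c.label!r} has {c.weights.shape[0]} rows "
                    f"for {n} persons"
                )

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class ModelSpec:
    """Priors and MCMC settings.

    Defaults follow common practice for MCMC estimation of multilevel Poisson
    models: diffuse N(0, 1e6) fixed-effect priors, Inverse-Gamma(0.001, 0.001)
    variance priors, 20,000 stored samples after a burn-in of 5,000 with
    adaptation confined to burn-in.
    """

    beta_prior_var: float = 1e6
    sigma_prior_shape: float = 0.001
    sigma_prior_scale: float = 0.001
    burnin: int = 5_000
    iterations: int = 20_000
    thin: int = 1
    adapt_interval: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burnin < 0 or self.iterations <= 0 or self.thin <= 0:
            raise ValueError("burnin >= 0, iterations > 0, thin > 0 required")
        if self.beta_prior_var <= 0 or self.sigma_prior_shape <= 0 \
                or self.sigma_prior_scale <= 0:
            raise ValueError("priors must be proper")


@dataclass
class FitResult:
    """Posterior chains and bookkeeping for one fitted model."""

    beta: pd.DataFrame               # samples x fixed effects
    u: dict[str, pd.DataFrame]       # label -> samples x units
    sigma2: pd.DataFrame             # samples x classification labels
    deviance: np.ndarray
    acceptance: dict
    spec: ModelSpec
    data: MmDataset = field(repr=False)

    @property
    def n_samples(self) -> int:
        return len(self.beta)

    def posterior_mean_state(self) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        """Posterior means of (beta, u) — the DIC plug-in parameters."""
        return (
            self.beta.mean(axis=0).to_numpy(),
            {lab: ch.mean(axis=0).to_numpy() for lab, ch in self.u.items()},
        )

    def linear_predictor(self, beta: np.ndarray,
                         u: Mapping[str, np.ndarray]) -> np.ndarray:
        eta = self.data.offset_log + self.data.X @ beta
        for c in self.data.classifications:
            eta = eta + c.weights @ np.asarray(u[c.label])
        return eta


def build_dataset(
    persons: pd.DataFrame,
    outcome: str,
    offset: str,
    fixed_effects: Sequence[str] = (),
    classifications: Sequence[Classification] = (),
    hospital_covariates: Mapping[str, Mapping[str, float]] | None = None,
    person_weights: PersonWeights | None = None,
    center_scale: float | None = 10.0,
    add_intercept: bool = True,
) -> MmDataset:
    """Assemble an MmDataset from a person table and weight structures.

    ``hospital_covariates`` maps a covariate name to hospital-level values;
    each is expanded to a person-level weighted average over the person's
    network (requires ``person_weights``), then group-mean-centred and divided
    by ``center_scale`` so that, with the default 10, one unit is a 10-point
    change in e.g. percent bed occupancy.

    ``persons`` must be aligned with the weight rows (use the included-person
    subset produced by :func:`hsanet.person_weight_matrix`).
    """
    if outcome not in persons.columns:
        raise ValueError(f"outcome column {outcome!r} not in persons table")
    if offset not in persons.columns:
        raise ValueError(f"offset column {offset!r} not in persons table")
    t = persons[offset].to_numpy(dtype=float)
    if np.any(t <= 0) or np.any(~np.isfinite(t)):
        raise ValueError("follow-up (offset) must be positive")

    cols: list[np.ndarray] = []
    names: list[str] = []
    if add_intercept:
        cols.append(np.ones(len(persons)))
        names.append("intercept")
    for cname in fixed_effects:
        if cname not in persons.columns:
            raise ValueError(f"fixed-effect column {cname!r} not in persons table")
        cols.append(persons[cname].to_numpy(dtype=float))
        names.append(cname)

    if hospital_covariates:
        if person_weights is None:
            raise ValueError("hospital_covariates require person_weights")
        for cname, values in hospital_covariates.items():
            v = weighted_hospital_covariate(person_weights, values)
            if center_scale is not None:
                v = (v - v.mean()) / center_scale
            cols.append(np.asarray(v, dtype=float))
            names.append(f"whosp_{cname}")

    X = np.column_stack(cols) if cols else np.empty((len(persons), 0))
    return MmDataset(
        y=persons[outcome].to_numpy(dtype=float),
        offset_log=np.log(t),
        X=X,
        x_names=names,
        classifications=list(classifications),
    )


def _pack_classifications(classifications: Sequence[Classification]):
    """Concatenate all classifications' unit columns into flat CSC arrays."""
    n_units = np.array([len(c.units) for c in classifications], dtype=np.int64)
    unit_class, indptr, rows, vals = [], [0], [], []
    for ci, c in enumerate(classifications):
        csc = c.weights.tocsc()
        for j in range(csc.shape[1]):
            lo, hi = csc.indptr[j], csc.indptr[j + 1]
            rows.append(csc.indices[lo:hi].astype(np.int64))
            vals.append(csc.data[lo:hi].astype(np.float64))
            indptr.append(indptr[-1] + hi - lo)
            unit_class.append(ci)
    return (
        n_units,
        np.array(unit_class, dtype=np.int64),
        np.array(indptr, dtype=np.int64),
        np.concatenate(rows) if rows else np.empty(0, dtype=np.int64),
        np.concatenate(vals) if vals else np.empty(0, dtype=np.float64),
    )


def fit_mcmc(spec: ModelSpec, data: MmDataset) -> FitResult:
    """Sample the posterior of the multiple-membership Poisson model.

    Deterministic given ``spec.seed``.  Proposal-scale adaptation is confined
    to burn-in; if any block's post-burn-in acceptance rate falls outside
    [0.1, 0.8] a warning is recorded in the result (and emitted), not raised.
    """
    if not data.classifications and data.X.shape[1] == 0:
        raise ValueError("model has no fixed effects and no classifications")

    beta_init = np.zeros(data.X.shape[1])
    if "intercept" in data.x_names:
        k = data.x_names.index("intercept")
        rate = (data.y.sum() + 0.5) / np.exp(data.offset_log).sum()
        beta_init[k] = np.log(rate)

    n_units, unit_class, indptr, rows, vals = _pack_classifications(
        data.classifications
    )
    fixed_var = np.array(
        [np.nan if c.fixed_variance is None else float(c.fixed_variance)
         for c in data.classifications],
        dtype=np.float64,
    )
    eta0 = data.offset_log + data.X @ beta_init

    (beta_ch, u_ch, sig_ch, ll2_ch, acc_b, acc_u, sd_b, sd_u) = _sampler.run_chain(
        np.int64(spec.seed % (2**31)),
        data.y.astype(np.float64),
        np.ascontiguousarray(data.X, dtype=np.float64),
        eta0.astype(np.float64),
        beta_init,
        float(spec.beta_prior_var),
        n_units, unit_class, indptr, rows, vals,
        float(spec.sigma_prior_shape), float(spec.sigma_prior_scale),
        fixed_var,
        int(spec.burnin), int(spec.iterations), int(spec.thin),
        int(spec.adapt_interval),
    )
    # kernel tracks -2*(y*eta - mu); add the count normalising constant
    dev = ll2_ch + 2.0 * gammaln(data.y + 1.0).sum()

    labels = [c.label for c in data.classifications]
    u_frames: dict[str, pd.DataFrame] = {}
    acc_u_split: dict[str, np.ndarray] = {}
    start = 0
    for c in data.classifications:
        stop = start + len(c.units)
        u_frames[c.label] = pd.DataFrame(u_ch[:, start:stop], columns=c.units)
        acc_u_split[c.label] = acc_u[start:stop]
        start = stop

    acceptance = {"beta": acc_b, "u": acc_u_split,
                  "proposal_sd_beta": sd_b, "proposal_sd_u": sd_u}
    active = np.concatenate(
        [acc_b] + [acc_u_split[c.label] for c in data.classifications
                   if not (c.fixed_variance == 0)]
    ) if data.classifications else acc_b
    bad = (active < 0.1) | (active > 0.8)
    if bad.any():
        msg = (f"{int(bad.sum())} Metropolis block(s) with post-burn-in "
               f"acceptance outside [0.1, 0.8]; inspect diagnostics")
        acceptance["warning"] = msg
        warnings.warn(msg, RuntimeWarning, stacklevel=2)

    return FitResult(
        beta=pd.DataFrame(beta_ch, columns=data.x_names),
        u=u_frames,
        sigma2=pd.DataFrame(sig_ch, columns=labels),
        deviance=dev,
        acceptance=acceptance,
        spec=replace(spec),
        data=data,
    )


def deviance(y: np.ndarray, mu: np.ndarray) -> float:
    """Poisson deviance -2 sum_i [Y_i log mu_i - mu_i - log(Y_i!)].

    This is -2 times the exact Poisson log-likelihood (not the saturated-model
    deviance), the quantity entering DIC.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("Poisson means must be positive")
    return float(-2.0 * np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))


def conditional_sigma2_draws(
    u: np.ndarray,
    n_draws: int,
    shape: float = 0.001,
    scale: float = 0.001,
    seed: int = 0,
) -> np.ndarray:
    """Gibbs draws of sigma2 | u — the sampler's conjugate variance update.

    With u_j ~ N(0, sigma2) and an Inverse-Gamma(shape, scale) prior, the full
    conditional is Inverse-Gamma(shape + J/2, scale + sum(u^2)/2); draws are
    generated exactly as in the MCMC kernel (reciprocal of a Gamma draw).
    """
    u = np.asarray(u, dtype=float)
    rng = np.random.default_rng(seed)
    a = shape + 0.5 * u.size
    b = scale + 0.5 * float(u @ u)
    return 1.0 / rng.gamma(a, 1.0 / b, size=n_draws)


def _geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    import arviz as az

    n = len(x)
    a, b = x[: int(first * n)], x[int((1 - last) * n):]
    if a.std() == 0 and b.std() == 0:
        return 0.0

    def se(seg):
        ess = float(az.ess(np.asarray(seg)))
        ess = max(ess, 1.0)
        return seg.var(ddof=1) / ess

    return float((a.mean() - b.mean()) / np.sqrt(se(a) + se(b)))


def diagnostics(fit: FitResult) -> pd.DataFrame:
    """Per-parameter convergence report: ESS, Geweke z, degeneracy flag.

    Covers fixed effects, variance components and random effects.  A chain
    with zero variance is flagged degenerate (its ESS is meaningless).
    Acceptance rates live in ``fit.acceptance``.
    """
    import arviz as az

    rows = []
    named: list[tuple[str, np.ndarray]] = [
        (f"beta[{c}]", fit.beta[c].to_numpy()) for c in fit.beta.columns
    ]
    named += [(f"sigma2[{c}]", fit.sigma2[c].to_numpy())
              for c in fit.sigma2.columns]
    for lab, frame in fit.u.items():
        named += [(f"u[{lab}:{j}]", frame[j].to_numpy()) for j in frame.columns]
    for name, x in named:
        degenerate = bool(np.std(x) == 0)
        ess = float(az.ess(np.asarray(x))) if not degenerate else float("nan")
        rows.append({
            "parameter": name,
            "ess": ess,
            "geweke_z": _geweke_z(x) if not degenerate else float("nan"),
            "degenerate": degenerate,
        })
    return pd.DataFrame(rows).set_index("parameter")


def traceplots(fit: FitResult, path: str, max_u: int = 6) -> None:
    """Export trace plots for visual convergence checks (PNG or PDF)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    series: list[tuple[str, np.ndarray]] = [
        (f"beta[{c}]", fit.beta[c].to_numpy()) for c in fit.beta.columns
    ]
    series += [(f"sigma2[{c}]", fit.sigma2[c].to_numpy())
               for c in fit.sigma2.columns]
    for lab, frame in fit.u.items():
        for j in list(frame.columns)[:max_u]:
            series.append((f"u[{lab}:{j}]", frame[j].to_numpy()))
    fig, axes = plt.subplots(len(series), 1,
                             figsize=(8, 1.6 * len(series)), squeeze=False)
    for ax, (name, x) in zip(axes.ravel(), series):
        ax.plot(x, lw=0.4)
        ax.set_ylabel(name, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
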