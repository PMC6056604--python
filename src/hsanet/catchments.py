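"""Patient-flow-weighted hospital catchments.

Admission records are reduced to episodes of care, per-area flow profiles
(the multiple-membership weights) are the proportional distribution of an
area's all-cause admissions over hospitals, and discrete hospital service
areas (HSAs) assign every area to its plurality hospital.  The same flow
profiles supply person-level weight matrices and weighted hospital
covariates for the multilevel models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "AreaFlowProfile", "HsaPartition", "PersonWeights", "CatchmentSummary",
    "merge_episodes", "compute_area_weights", "assign_hsa",
    "market_share_index", "person_weight_matrix",
    "weighted_hospital_covariate", "catchment_summary",
]

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class AreaFlowProfile:
    """Probability distribution of one residence area's admissions over hospitals.

    ``weights[h]`` is the fraction of the area's all-cause admissions that went
    to hospital ``h``; weights are strictly positive and sum to one.
    """

    area_id: str
    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError(f"area {self.area_id!r}: profile has no hospitals")
        w = np.array(list(self.weights.values()), dtype=float)
        if np.any(w <= 0):
            raise ValueError(f"area {self.area_id!r}: non-positive weight")
        if abs(w.sum() - 1.0) > _WEIGHT_TOL:
            raise ValueError(
                f"area {self.area_id!r}: weights sum to {w.sum()!r}, not 1"
            )

    def top_hospital(self) -> str:
        """Plurality hospital; ties broken by lexicographically smallest id."""
        best = max(self.weights.items(), key=lambda kv: (kv[1], _neg_key(kv[0])))
        return best[0]

    def ordered_shares(self) -> list[float]:
        """Weights sorted descending (top-1, top-2, ... shares)."""
        return sorted(self.weights.values(), reverse=True)


class _neg_key:
    """Inverts string ordering so max() prefers the smallest id on weight ties."""

    __slots__ = ("s",)

    def __init__(self, s: str):
        self.s = s

    def __lt__(self, other: "_neg_key") -> bool:
        return self.s > other.s


@dataclass(frozen=True)
class HsaPartition:
    """Discrete area -> hospital plurality assignment and the induced HSAs.

    ``hsas`` is the exact inverse mapping and includes hospitals whose HSA is
    empty (hospitals that are nowhere the most common hospital of admission).
    """

    assignment: Mapping[str, str]
    hsas: Mapping[str, frozenset]

    @property
    def nonempty_hsas(self) -> dict[str, frozenset]:
        return {h: a for h, a in self.hsas.items() if a}


@dataclass
class PersonWeights:
    """Sparse person x hospital multiple-membership weight matrix.

    Row *i* is the flow profile of person *i*'s residence area, so every row
    sums to one.  Persons whose area has no flow profile (no admissions
    observed from that area) are excluded and listed in ``exclusions``.
    """

    matrix: sp.csr_matrix
    person_ids: list
    hospital_ids: list
    exclusions: pd.DataFrame  # columns: person_id, area_id, reason

    @property
    def weighted_catchment_sizes(self) -> pd.Series:
        """Per-hospital sum of person weights (weighted population base)."""
        sizes = np.asarray(self.matrix.sum(axis=0)).ravel()
        return pd.Series(sizes, index=self.hospital_ids, name="weighted_catchment")


@dataclass
class CatchmentSummary:
    """Descriptive statistics of the weighting structure.

    ``areas``/``hospitals``/``persons`` are row-per-unit tables; ``stats`` holds
    mean, interquartile range and min-max for each characteristic, in the style
    of catchment-description tables in the small-area-variation literature.
    """

    areas: pd.DataFrame
    hospitals: pd.DataFrame
    persons: pd.DataFrame
    stats: dict


_REQUIRED_ADMISSION_COLS = ("person_id", "area_id", "hospital_id")


def _check_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required column(s) {missing}")


def merge_episodes(records: pd.DataFrame, attribute: str = "first") -> pd.DataFrame:
    """Collapse rows sharing an episode into a single admission record.

    Transfers between hospitals and changes of care type within an episode are
    one episode of care.  Rows sharing a non-null ``episode_id`` (within a
    person) collapse to one record attributed to the episode's first hospital
    in row order (``attribute="last"`` attributes to the final hospital
    instead).  Rows without an episode id pass through unchanged.

    Parameters
    ----------
    records : DataFrame with person_id, area_id, hospital_id, optionally
        preventable and episode_id.
    attribute : "first" or "last" — which hospital receives the merged episode.

    Returns
    -------
    DataFrame of admission records, one row per episode, preserving first-row
    values of all other columns (``preventable`` is OR-ed over the episode).
    """
    if attribute not in ("first", "last"):
        raise ValueError(f"attribute must be 'first' or 'last', got {attribute!r}")
    _check_columns(records, _REQUIRED_ADMISSION_COLS, "admission records")
    df = records.copy()
    for col in _REQUIRED_ADMISSION_COLS:
        if df[col].isna().any() or (df[col].astype(str).str.len() == 0).any():
            raise ValueError(f"admission records: empty values in column {col!r}")

    if "episode_id" not in df.columns or df["episode_id"].isna().all():
        return df.reset_index(drop=True)

    has_ep = df["episode_id"].notna()
    loose = df[~has_ep]
    grouped = df[has_ep]

    keep = "first" if attribute == "first" else "last"
    agg: dict = {c: keep for c in df.columns}
    agg["hospital_id"] = keep
    if "preventable" in df.columns:
        agg["preventable"] = "max"
    merged = (
        grouped.groupby(["person_id", "episode_id"], sort=False, as_index=False)
        .agg(agg)
    )
    merged = merged[df.columns]
    out = pd.concat([merged, loose], ignore_index=True)
    return out


def compute_area_weights(
    admissions: pd.DataFrame,
) -> tuple[dict[str, AreaFlowProfile], pd.DataFrame]:
    """Per-area flow profiles: weight(h) = admissions to h / area's admissions.

    Weights are computed from all-cause admissions — callers wanting a subset
    (e.g. excluding particular episode types) filter before calling.  Areas
    appear only if they have at least one admission; the returned report lists
    areas present in the input but contributing zero usable rows (only
    possible when the caller pre-filters with a mask).

    Returns
    -------
    (profiles, report) where ``profiles`` maps area_id -> AreaFlowProfile and
    ``report`` is a DataFrame of omitted areas (empty in the ordinary case).
    """
    _check_columns(admissions, _REQUIRED_ADMISSION_COLS, "admissions")
    if len(admissions) == 0:
        raise ValueError("no admissions")
    counts = (
        admissions.groupby(["area_id", "hospital_id"], sort=True)
        .size()
        .rename("n")
        .reset_index()
    )
    profiles: dict[str, AreaFlowProfile] = {}
    for area, grp in counts.groupby("area_id", sort=True):
        total = grp["n"].sum()
        weights = {str(h): n / total for h, n in zip(grp["hospital_id"], grp["n"])}
        profiles[str(area)] = AreaFlowProfile(area_id=str(area), weights=weights)
    report = pd.DataFrame(columns=["area_id", "reason"])
    return profiles, report


def assign_hsa(
    profiles: Mapping[str, AreaFlowProfile],
    hospitals: Iterable[str] | None = None,
) -> HsaPartition:
    """Plurality rule: every area goes to its most common hospital of admission.

    Ties are broken by the lexicographically smallest hospital id so the
    partition is deterministic and independent of input ordering.  Hospitals
    listed in ``hospitals`` (default: all hospitals appearing in any profile)
    that never achieve plurality receive an empty HSA.
    """
    assignment = {a: p.top_hospital() for a, p in profiles.items()}
    if hospitals is None:
        hospitals = sorted({h for p in profiles.values() for h in p.weights})
    hsas: dict[str, set] = {str(h): set() for h in hospitals}
    for area, hosp in assignment.items():
        hsas.setdefault(hosp, set()).add(area)
    return HsaPartition(
        assignment=dict(sorted(assignment.items())),
        hsas={h: frozenset(a) for h, a in sorted(hsas.items())},
    )


def market_share_index(
    partition: HsaPartition, admissions: pd.DataFrame
) -> dict[str, float]:
    """Fraction of each hospital's admissions originating inside its own HSA.

    Hospitals with an empty HSA (never the plurality hospital anywhere) score
    zero by definition.  Hospitals with a non-empty HSA but no admissions in
    the supplied table also score zero.
    """
    _check_columns(admissions, ("area_id", "hospital_id"), "admissions")
    unknown = set(map(str, admissions["area_id"])) - set(partition.assignment)
    if unknown:
        raise ValueError(
            f"admissions reference areas outside the partition: {sorted(unknown)[:5]}"
        )
    msi: dict[str, float] = {}
    by_hosp = admissions.groupby(admissions["hospital_id"].astype(str))
    totals = by_hosp.size()
    for hosp, areas in partition.hsas.items():
        if not areas or hosp not in totals.index:
            msi[hosp] = 0.0
            continue
        rows = by_hosp.get_group(hosp)
        internal = rows["area_id"].astype(str).isin(areas).sum()
        msi[hosp] = internal / totals.loc[hosp]
    return msi


def person_weight_matrix(
    profiles: Mapping[str, AreaFlowProfile],
    persons: pd.DataFrame,
    hospitals: Iterable[str] | None = None,
) -> PersonWeights:
    """Expand area flow profiles to a sparse person x hospital weight matrix.

    Each person inherits the profile of their residence area, so people are
    proportionately structured within all hospitals their area uses.  Persons
    in areas without a profile are excluded and reported (mirroring the
    exclusion of residents of areas with no observed admissions), never
    silently dropped.
    """
    _check_columns(persons, ("person_id", "area_id"), "persons")
    if hospitals is None:
        hospitals = sorted({h for p in profiles.values() for h in p.weights})
    hospitals = [str(h) for h in hospitals]
    hosp_index = {h: j for j, h in enumerate(hospitals)}

    areas = persons["area_id"].astype(str)
    known = areas.isin(profiles.keys())
    excl = persons.loc[~known, ["person_id", "area_id"]].copy()
    excl["reason"] = "area has no admissions"
    included = persons.loc[known]

    rows, cols, vals = [], [], []
    for i, area in enumerate(included["area_id"].astype(str)):
        prof = profiles[area]
        for h, w in prof.weights.items():
            rows.append(i)
            cols.append(hosp_index[h])
            vals.append(w)
    mat = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(included), len(hospitals))
    )
    return PersonWeights(
        matrix=mat,
        person_ids=list(included["person_id"]),
        hospital_ids=hospitals,
        exclusions=excl.reset_index(drop=True),
    )


def weighted_hospital_covariate(
    weights: PersonWeights | np.ndarray,
    covariate: Mapping[str, float] | pd.Series,
) -> np.ndarray | float:
    """Weighted average of a hospital attribute over each person's network.

    For weight row *w_i* and hospital attribute *x*, returns sum_j w_ij x_j —
    e.g. average bed occupancy over all hospitals a person might attend.
    Raises if the attribute is missing for any hospital carrying weight.
    """
    cov = pd.Series(covariate, dtype=float)
    if isinstance(weights, PersonWeights):
        missing = [
            h
            for j, h in enumerate(weights.hospital_ids)
            if weights.matrix[:, j].nnz > 0
            and (h not in cov.index or pd.isna(cov.get(h)))
        ]
        if missing:
            raise ValueError(f"covariate missing for hospital(s): {missing}")
        x = cov.reindex(weights.hospital_ids).to_numpy()
        x = np.nan_to_num(x)
        return np.asarray(weights.matrix @ x).ravel()
    w = np.asarray(weights, dtype=float)
    x = cov.to_numpy()
    if np.any((w > 0) & pd.isna(cov).to_numpy()):
        raise ValueError("covariate missing for a weighted hospital")
    return float(w @ x)


def _dist_stats(x: pd.Series) -> dict:
    x = pd.Series(x, dtype=float)
    return {
        "mean": float(x.mean()),
        "iqr": (float(x.quantile(0.25)), float(x.quantile(0.75))),
        "range": (float(x.min()), float(x.max())),
    }


def catchment_summary(
    profiles: Mapping[str, AreaFlowProfile],
    partition: HsaPartition,
    persons: pd.DataFrame,
    admissions: pd.DataFrame,
    thresholds: tuple[float, ...] = (0.05, 0.10, 0.20, 0.50),
) -> CatchmentSummary:
    """Descriptives of the weighting structure: areas, HSAs, hospitals, persons.

    Produces, per area: participant and admission counts, number of hospitals,
    and top-1/2/3 admission shares; per hospital: weighted catchment size,
    areas serviced, areas above weight thresholds, HSA size and market share
    index; per person: network size and top shares inherited from their area.
    ``stats`` aggregates each column as mean / IQR / min-max.
    """
    pw = person_weight_matrix(profiles, persons)
    msi = market_share_index(partition, admissions)

    adm_areas = admissions.groupby(admissions["area_id"].astype(str))
    persons_by_area = persons.groupby(persons["area_id"].astype(str)).size()

    area_rows = []
    for area, prof in profiles.items():
        shares = prof.ordered_shares()
        area_rows.append(
            {
                "area_id": area,
                "n_participants": int(persons_by_area.get(area, 0)),
                "n_admissions": int(adm_areas.size().get(area, 0)),
                "n_hospitals": len(prof.weights),
                "share_top1": shares[0],
                "share_top2": shares[1] if len(shares) > 1 else 0.0,
                "share_top3": shares[2] if len(shares) > 2 else 0.0,
                "assigned_hospital": partition.assignment[area],
            }
        )
    areas_df = pd.DataFrame(area_rows).set_index("area_id")

    wcs = pw.weighted_catchment_sizes
    hosp_rows = []
    for j, h in enumerate(pw.hospital_ids):
        w_by_area = np.array(
            [profiles[a].weights.get(h, 0.0) for a in profiles], dtype=float
        )
        hsa_areas = partition.hsas.get(h, frozenset())
        hosp_rows.append(
            {
                "hospital_id": h,
                "weighted_catchment": float(wcs.loc[h]),
                "areas_serviced": int((w_by_area > 0).sum()),
                **{
                    f"areas_weight_gt_{int(t * 100)}pct": int((w_by_area > t).sum())
                    for t in thresholds
                },
                "hsa_n_areas": len(hsa_areas),
                "hsa_population": int(
                    sum(persons_by_area.get(a, 0) for a in hsa_areas)
                ),
                "market_share_index": msi.get(h, 0.0),
            }
        )
    hosp_df = pd.DataFrame(hosp_rows).set_index("hospital_id")

    areas_series = persons.loc[
        persons["person_id"].isin(pw.person_ids)
    ].set_index("person_id")["area_id"].astype(str)
    person_df = pd.DataFrame(
        {
            "person_id": pw.person_ids,
            "area_id": [areas_series.loc[p] for p in pw.person_ids],
        }
    )
    person_df = person_df.join(
        areas_df[["n_hospitals", "share_top1", "share_top2", "share_top3"]],
        on="area_id",
    ).set_index("person_id")

    stats = {
        "areas": {c: _dist_stats(areas_df[c]) for c in areas_df.columns
                  if c != "assigned_hospital"},
        "hospitals": {c: _dist_stats(hosp_df[c]) for c in hosp_df.columns},
        "hsas": {
            "population": _dist_stats(
                hosp_df.loc[hosp_df["hsa_n_areas"] > 0, "hsa_population"]
            ),
            "n_areas": _dist_stats(
                hosp_df.loc[hosp_df["hsa_n_areas"] > 0, "hsa_n_areas"]
            ),
            "n_nonempty": int((hosp_df["hsa_n_areas"] > 0).sum()),
        },
        "persons": {
            c: _dist_stats(person_df[c])
            for c in ("n_hospitals", "share_top1", "share_top2", "share_top3")
        },
        "n_persons_included": len(pw.person_ids),
        "n_persons_excluded": len(pw.exclusions),
    }
    return CatchmentSummary(
        areas=areas_df, hospitals=hosp_df, persons=person_df, stats=stats
    )
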