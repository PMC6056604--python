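"""CSV readers/writers with schema and referential-integrity validation.

All tabular I/O is plain CSV (gzip transparently accepted via the ``.gz``
suffix), the norm for health-services extracts.  Readers return typed
pandas DataFrames and fail loudly, naming offending columns or identifiers.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

log = logging.getLogger("hsanet")

ADMISSION_SCHEMA = {"person_id": str, "area_id": str, "hospital_id": str}
PERSON_SCHEMA = {"person_id": str, "area_id": str, "followup_years": float}
HOSPITAL_SCHEMA = {"hospital_id": str}


def _read_csv(path, schema: Mapping[str, type], what: str,
              optional: Mapping[str, object] | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{what} table not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise ValueError(f"{what} ({path.name}): missing column(s) {missing}")
    for c, typ in schema.items():
        if df[c].isna().any():
            bad = df.index[df[c].isna()][:5].tolist()
            raise ValueError(f"{what} ({path.name}): null {c!r} at rows {bad}")
        df[c] = df[c].astype(typ)
    for c, default in (optional or {}).items():
        if c not in df.columns or df[c].isna().all():
            log.warning("%s: optional column %r absent; defaulting to %r",
                        what, c, default)
            df[c] = default
    log.info("%s: read %d rows from %s", what, len(df), path)
    return df


def read_tables(
    admissions_path,
    persons_path,
    hospitals_path=None,
    require_hospital_attrs: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame | None]:
    """Read and cross-validate the admission, person and hospital tables.

    Checks: required columns present and non-null; every admission's person
    exists in the person table; when hospital attributes are required, every
    hospital referenced by an admission appears in the hospital table.
    """
    admissions = _read_csv(admissions_path, ADMISSION_SCHEMA, "admissions",
                           optional={"preventable": 0})
    persons = _read_csv(persons_path, PERSON_SCHEMA, "persons")

    if (persons["followup_years"] <= 0).any():
        bad = persons.loc[persons["followup_years"] <= 0, "person_id"]
        raise ValueError(
            f"persons: non-positive follow-up for {bad.head().tolist()}"
        )
    if persons["person_id"].duplicated().any():
        dup = persons.loc[persons["person_id"].duplicated(), "person_id"]
        raise ValueError(f"persons: duplicate person_id {dup.head().tolist()}")

    unknown = set(admissions["person_id"]) - set(persons["person_id"])
    if unknown:
        raise ValueError(
            f"admissions reference unknown person_id(s): {sorted(unknown)[:5]}"
        )

    hospitals = None
    if hospitals_path is not None:
        hospitals = _read_csv(hospitals_path, HOSPITAL_SCHEMA, "hospitals")
        if require_hospital_attrs:
            missing = set(admissions["hospital_id"]) - set(hospitals["hospital_id"])
            if missing:
                raise ValueError(
                    f"admissions reference hospital(s) absent from the hospital "
                    f"table: {sorted(missing)[:5]}"
                )
    return admissions, persons, hospitals


def write_weights(profiles, path) -> None:
    """Long-format area flow weights: area_id, hospital_id, weight."""
    rows = [
        {"area_id": a, "hospital_id": h, "weight": w}
        for a, prof in profiles.items()
        for h, w in sorted(prof.weights.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_hsa(partition, path) -> None:
    pd.DataFrame(
        [{"area_id": a, "hospital_id": h}
         for a, h in partition.assignment.items()]
    ).to_csv(path, index=False)


def write_summary(stats: dict, path) -> None:
    with open(path, "w") as f:
        json.dump(stats, f, indent=2, default=_jsonify)


def write_exclusions(exclusions: pd.DataFrame, path) -> None:
    exclusions.to_csv(path, index=False)


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.ndarray, tuple, set, frozenset)):
        return list(x)
    raise TypeError(f"not JSON-serialisable: {type(x)}")
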