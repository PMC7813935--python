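"""Cohort selection and exact 1:k matching on age group, sex and region.

Cases are patients with a clean washout window (no diagnosis from the analysis
universe, A00-N99 by default) and at least one case-defining code (E10-E14 by
default) during the observation window. Eligible controls are washout-clean
patients who never receive a case code during observation. Each retained case
is matched, without replacement and within its exact (age group, sex, region)
stratum, to ``ratio`` controls; cases whose stratum runs out of controls are
dropped and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blocks import code_in_range, parse_code_range
from .util import (
    AGE_GROUPS,
    PERIODS_PER_AGE_GROUP,
    HalfYearInterval,
    age_group_index,
    stratum_rng,
)

DEFAULT_CASE_CODES = "E10-E14"
DEFAULT_UNIVERSE = "A00-N99"


@dataclass
class CohortAssignment:
    case_ids: list[str]
    matching: dict[str, tuple[str, ...]]
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def control_ids(self) -> list[str]:
        return [c for ctrls in self.matching.values() for c in ctrls]

    def validate(self) -> None:
        controls = self.control_ids
        if len(set(controls)) != len(controls):
            raise ValueError("a control is matched to more than one case")
        if set(controls) & set(self.case_ids):
            raise ValueError("case and control sets overlap")

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for case, ctrls in sorted(self.matching.items()):
            rec = {"case_id": case}
            for i, c in enumerate(ctrls, 1):
                rec[f"control_id_{i}"] = c
            recs.append(rec)
        return pd.DataFrame(recs)

    def exclusions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.excluded.items()), columns=["patient_id", "reason"]
        )


def _exploded_codes(claims: pd.DataFrame) -> pd.DataFrame:
    """One row per (patient, half-year, code); empty code strings dropped."""
    sub = claims.loc[claims["icd10_codes"].astype(str).str.len() > 0,
                    ["patient_id", "half_year_index", "icd10_codes"]].copy()
    sub["icd10_codes"] = sub["icd10_codes"].str.split(";")
    sub = sub.explode("icd10_codes", ignore_index=True)
    return sub.rename(columns={"icd10_codes": "code"})


def _patients_with_code_in(
    codes: pd.DataFrame, window: HalfYearInterval, code_range: str
) -> set[str]:
    rng = parse_code_range(code_range)
    inwin = codes[
        (codes["half_year_index"] >= window.start)
        & (codes["half_year_index"] < window.stop)
    ]
    if inwin.empty:
        return set()
    hit = inwin["code"].map(lambda c: code_in_range(c, rng))
    return set(inwin.loc[hit, "patient_id"])


def select_cases(
    claims: pd.DataFrame,
    washout: HalfYearInterval,
    observation: HalfYearInterval,
    case_codes: str = DEFAULT_CASE_CODES,
    universe_codes: str = DEFAULT_UNIVERSE,
) -> set[str]:
    """Patients washout-clean (no universe code) with a case code in observation."""
    if washout.stop > observation.start:
        raise ValueError("washout must precede (and not overlap) observation")
    codes = _exploded_codes(claims)
    dirty = _patients_with_code_in(codes, washout, universe_codes)
    with_case = _patients_with_code_in(codes, observation, case_codes)
    return with_case - dirty


def select_control_pool(
    claims: pd.DataFrame,
    washout: HalfYearInterval,
    observation: HalfYearInterval,
    case_codes: str = DEFAULT_CASE_CODES,
    universe_codes: str = DEFAULT_UNIVERSE,
    patient_ids: set[str] | None = None,
) -> set[str]:
    """Washout-clean patients never receiving a case code during observation.

    ``patient_ids`` widens the candidate universe beyond patients appearing in
    the claims table (a patient with zero stays vacuously qualifies).
    """
    if washout.stop > observation.start:
        raise ValueError("washout must precede (and not overlap) observation")
    codes = _exploded_codes(claims)
    universe = set(claims["patient_id"]) if patient_ids is None else set(patient_ids)
    dirty = _patients_with_code_in(codes, washout, universe_codes)
    with_case = _patients_with_code_in(codes, observation, case_codes)
    return universe - dirty - with_case


def derive_demographics(
    claims: pd.DataFrame, observation: HalfYearInterval
) -> pd.DataFrame:
    """Per-patient sex, region and age group at observation start.

    The age group recorded on a stay advances one 5-year group every
    ``PERIODS_PER_AGE_GROUP`` half-years from the observation start, so the
    group at observation start is recovered from the patient's first observed
    stay as recorded_group - (t - start) // PERIODS_PER_AGE_GROUP. Rows before
    the observation window (none in generated data) are used unadjusted as a
    fallback.

    Returns a frame indexed by patient_id with columns sex, region, age_group.
    """
    first = (
        claims.sort_values(["patient_id", "half_year_index"], kind="stable")
        .groupby("patient_id", sort=True)
        .first()
    )
    out = first[["sex", "region"]].copy()
    t = first["half_year_index"].to_numpy()
    g = np.array([age_group_index(a) for a in first["age_group"]])
    adj = np.where(t >= observation.start, (t - observation.start) // PERIODS_PER_AGE_GROUP, 0)
    out["age_group"] = [AGE_GROUPS[i] for i in np.clip(g - adj, 0, len(AGE_GROUPS) - 1)]
    return out


def match_controls(
    cases: set[str],
    pool: set[str],
    demographics: pd.DataFrame,
    ratio: int = 2,
    seed: int = 0,
) -> CohortAssignment:
    """Exact-stratum matching without replacement, shuffled under ``seed``.

    Randomness is drawn from a per-stratum stream keyed on (seed, stratum), so
    the matching within one stratum is unaffected by patients in any other.
    Cases that cannot be served ``ratio`` fresh controls are dropped with
    reason ``insufficient_controls``; cases or pool members without
    demographics are dropped with reason ``missing_demographics``.
    """
    if ratio < 1:
        raise ValueError("matching ratio must be >= 1")
    excluded: dict[str, str] = {}
    known = set(demographics.index)
    usable_cases = sorted(cases & known)
    usable_pool = sorted((pool - cases) & known)
    for p in sorted((cases | pool) - known):
        excluded[p] = "missing_demographics"

    key_of = {
        p: f"{demographics.at[p, 'age_group']}|{demographics.at[p, 'sex']}|{demographics.at[p, 'region']}"
        for p in usable_cases + usable_pool
    }
    strata_cases: dict[str, list[str]] = {}
    strata_pool: dict[str, list[str]] = {}
    for p in usable_cases:
        strata_cases.setdefault(key_of[p], []).append(p)
    for p in usable_pool:
        strata_pool.setdefault(key_of[p], []).append(p)

    matching: dict[str, tuple[str, ...]] = {}
    for key in sorted(strata_cases):
        cs = strata_cases[key]
        ps = strata_pool.get(key, [])
        rng = stratum_rng(seed, key)
        cs = [cs[i] for i in rng.permutation(len(cs))]
        ps = [ps[i] for i in rng.permutation(len(ps))]
        n_served = min(len(cs), len(ps) // ratio)
        for i, case in enumerate(cs):
            if i < n_served:
                matching[case] = tuple(ps[i * ratio : (i + 1) * ratio])
            else:
                excluded[case] = "insufficient_controls"
    out = CohortAssignment(
        case_ids=sorted(matching), matching=matching, excluded=excluded
    )
    out.validate()
    return out
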