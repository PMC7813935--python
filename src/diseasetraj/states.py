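"""Cumulative binary health-state vectors per patient per half-year.

Each patient contributes, for every observed half-year t from the start of the
observation window until death or window end, a binary vector v in {0,1}^M
with v_d = 1 iff some diagnosis in disease block d occurred at or before the
end of t. Diagnoses before the observation window (but inside the data window)
also accumulate. The half-year of death is included as a terminal snapshot;
downstream transition estimation excludes it from exposure, making death
absorbing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blocks import BlockTable
from .util import AGE_GROUPS, PERIODS_PER_AGE_GROUP, HalfYearInterval, age_group_index


class DataIntegrityError(ValueError):
    """Claims rows that contradict the record structure (e.g. stays after death)."""


@dataclass
class StateMatrix:
    """Columnar container for per-(patient, half-year) binary health states.

    Per-patient arrays (length n_patients): ``patient_ids``, ``sex``,
    ``region``, ``death_t`` (-1 if no death), ``start_t``/``stop_t`` (observed
    span, half-open). Per-snapshot arrays (length n_snapshots, grouped by
    patient and consecutive in t): ``snap_patient`` (patient row index),
    ``snap_t``, ``snap_age`` (age-group index), and the dense boolean
    ``vectors`` of shape (n_snapshots, M).
    """

    table: BlockTable
    patient_ids: np.ndarray
    sex: np.ndarray
    region: np.ndarray
    death_t: np.ndarray
    start_t: np.ndarray
    stop_t: np.ndarray
    snap_patient: np.ndarray
    snap_t: np.ndarray
    snap_age: np.ndarray
    vectors: np.ndarray
    dropped_codes: int = 0

    @property
    def M(self) -> int:
        return self.table.M

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_snapshots(self) -> int:
        return len(self.snap_t)

    def patient_slice(self, i: int) -> slice:
        off = np.searchsorted(self.snap_patient, [i, i + 1])
        return slice(int(off[0]), int(off[1]))

    def final_vectors(self) -> np.ndarray:
        """One vector per patient: the last observed snapshot."""
        last = np.searchsorted(self.snap_patient, np.arange(self.n_patients) + 1) - 1
        return self.vectors[last]

    # ---- serialization (sparse triplets + demographics + snapshots) -------

    def to_frames(self) -> dict[str, pd.DataFrame]:
        pid = self.patient_ids
        events = []
        for i in range(self.n_patients):
            sl = self.patient_slice(i)
            vecs = self.vectors[sl]
            ts = self.snap_t[sl]
            if len(ts) == 0:
                continue
            prev = np.zeros(self.M, dtype=bool)
            for row, t in zip(vecs, ts):
                new = row & ~prev
                for d in np.flatnonzero(new):
                    events.append((pid[i], int(t), int(d)))
                prev = row
        triplets = pd.DataFrame(events, columns=["patient_id", "half_year", "block_index"])
        demo = pd.DataFrame(
            {
                "patient_id": pid,
                "sex": self.sex,
                "region": self.region,
                "death_t": self.death_t,
                "start_t": self.start_t,
                "stop_t": self.stop_t,
            }
        )
        snaps = pd.DataFrame(
            {
                "patient_id": pid[self.snap_patient],
                "half_year": self.snap_t,
                "age_index": self.snap_age,
            }
        )
        return {"triplets": triplets, "demographics": demo, "snapshots": snaps}

    @classmethod
    def from_frames(
        cls, frames: dict[str, pd.DataFrame], table: BlockTable
    ) -> "StateMatrix":
        demo = frames["demographics"].sort_values("patient_id", kind="stable")
        pid = demo["patient_id"].to_numpy(dtype=object)
        index = {p: i for i, p in enumerate(pid)}
        snaps = frames["snapshots"].copy()
        snaps["pi"] = snaps["patient_id"].map(index)
        snaps = snaps.sort_values(["pi", "half_year"], kind="stable")
        snap_patient = snaps["pi"].to_numpy(dtype=np.int64)
        snap_t = snaps["half_year"].to_numpy(dtype=np.int64)
        snap_age = snaps["age_index"].to_numpy(dtype=np.int64)
        start = np.searchsorted(snap_patient, np.arange(len(pid)))
        vectors = np.zeros((len(snap_t), table.M), dtype=bool)
        stops = demo["stop_t"].to_numpy()
        for p, t0, d in frames["triplets"].itertuples(index=False):
            i = index[p]
            sl = slice(int(start[i]) + max(0, int(t0) - int(snap_t[start[i]])),
                       int(start[i]) + int(stops[i] - snap_t[start[i]]))
            vectors[sl, int(d)] = True
        return cls(
            table=table,
            patient_ids=pid,
            sex=demo["sex"].to_numpy(dtype=object),
            region=demo["region"].to_numpy(dtype=object),
            death_t=demo["death_t"].to_numpy(dtype=np.int64),
            start_t=demo["start_t"].to_numpy(dtype=np.int64),
            stop_t=demo["stop_t"].to_numpy(dtype=np.int64),
            snap_patient=snap_patient,
            snap_t=snap_t,
            snap_age=snap_age,
            vectors=vectors,
        )


def build_state_matrix(
    claims: pd.DataFrame,
    patient_ids,
    table: BlockTable,
    observation: HalfYearInterval,
    demographics: pd.DataFrame | None = None,
) -> StateMatrix:
    """Build the cumulative state matrix for ``patient_ids`` from raw claims.

    Codes outside the block universe are silently dropped (their count is
    recorded on the result). The snapshot age group is carried forward from the
    most recent stay at or before t (backfilled from the first stay for
    snapshots preceding it). Claims rows after a recorded death raise
    :class:`DataIntegrityError`.

    Patients without any claims row are observable only if ``demographics``
    (columns: patient_id, sex, region, entry_age_index -- the age-group index
    at observation start) covers them; they contribute all-zero vectors over
    the full window, aging one group every ``PERIODS_PER_AGE_GROUP``
    half-years. Without that, absent patients raise ValueError.
    """
    wanted = sorted(set(patient_ids))
    index = {p: i for i, p in enumerate(wanted)}
    n_p = len(wanted)
    sub = claims[claims["patient_id"].isin(index)].sort_values(
        ["patient_id", "half_year_index"], kind="stable"
    )
    rowless: dict[str, tuple[str, str, int]] = {}
    if sub["patient_id"].nunique() != n_p:
        missing = sorted(set(wanted) - set(sub["patient_id"]))
        if demographics is None:
            raise ValueError(
                f"{len(missing)} requested patients have no claims rows "
                f"(first few: {missing[:5]}); demographics are unrecoverable"
            )
        demo = demographics.set_index("patient_id") if "patient_id" in demographics else demographics
        unknown = [p for p in missing if p not in demo.index]
        if unknown:
            raise ValueError(
                f"patients missing from both claims and demographics: {unknown[:5]}"
            )
        for p in missing:
            rowless[p] = (
                demo.at[p, "sex"],
                demo.at[p, "region"],
                int(demo.at[p, "entry_age_index"]),
            )

    sex = np.empty(n_p, dtype=object)
    region = np.empty(n_p, dtype=object)
    death_t = np.full(n_p, -1, dtype=np.int64)
    row_t: list[np.ndarray] = [None] * n_p
    row_age: list[np.ndarray] = [None] * n_p
    events: list[list[tuple[int, int]]] = [[] for _ in range(n_p)]  # (t, block)
    dropped = 0

    for p, (sx, rg, _g0) in rowless.items():
        sex[index[p]] = sx
        region[index[p]] = rg

    for p, g in sub.groupby("patient_id", sort=True):
        i = index[p]
        sex[i] = g["sex"].iloc[0]
        region[i] = g["region"].iloc[0]
        ts = g["half_year_index"].to_numpy(dtype=np.int64)
        row_t[i] = ts
        row_age[i] = np.array([age_group_index(a) for a in g["age_group"]])
        deaths = np.flatnonzero((g["discharge"] == "death").to_numpy())
        if len(deaths) > 0:
            if len(deaths) > 1 or deaths[0] != len(ts) - 1:
                raise DataIntegrityError(f"patient {p} has stays after recorded death")
            death_t[i] = ts[deaths[0]]
        for t, codes in zip(ts, g["icd10_codes"].astype(str)):
            if not codes:
                continue
            for code in codes.split(";"):
                d = table.map_code(code)
                if d is None:
                    dropped += 1
                else:
                    events[i].append((int(t), d))

    start_t = np.full(n_p, observation.start, dtype=np.int64)
    stop_t = np.where(
        (death_t >= 0) & (death_t < observation.stop - 1), death_t + 1, observation.stop
    ).astype(np.int64)
    for i in range(n_p):
        if death_t[i] >= 0 and death_t[i] < observation.start:
            stop_t[i] = observation.start  # died before the window: no snapshots
    lengths = stop_t - start_t
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    n_snap = int(offsets[-1])

    snap_patient = np.repeat(np.arange(n_p), lengths)
    snap_t = np.concatenate(
        [np.arange(start_t[i], stop_t[i]) for i in range(n_p)]
    ) if n_snap else np.array([], dtype=np.int64)
    vectors = np.zeros((n_snap, table.M), dtype=bool)
    snap_age = np.zeros(n_snap, dtype=np.int64)

    for i in range(n_p):
        if lengths[i] == 0:
            continue
        off, ln = int(offsets[i]), int(lengths[i])
        if row_t[i] is None:  # rowless patient: ages follow the convention
            g0 = rowless[wanted[i]][2]
            rel = np.arange(ln) // PERIODS_PER_AGE_GROUP
            snap_age[off : off + ln] = np.minimum(g0 + rel, len(AGE_GROUPS) - 1)
            continue
        for t0, d in events[i]:
            lo = max(t0 - int(start_t[i]), 0)
            if lo < ln:
                vectors[off + lo : off + ln, d] = True
        # carry-forward age from recorded stays
        ts, ags = row_t[i], row_age[i]
        pos = np.searchsorted(ts, np.arange(start_t[i], stop_t[i]), side="right") - 1
        snap_age[off : off + ln] = ags[np.clip(pos, 0, len(ts) - 1)]

    return StateMatrix(
        table=table,
        patient_ids=np.array(wanted, dtype=object),
        sex=sex,
        region=region,
        death_t=death_t,
        start_t=start_t,
        stop_t=stop_t,
        snap_patient=snap_patient,
        snap_t=snap_t,
        snap_age=snap_age,
        vectors=vectors,
        dropped_codes=dropped,
    )
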