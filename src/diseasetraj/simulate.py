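"""Seeded synthetic hospital-claims populations with a planted trajectory model.

The generator emulates the structure of claims registries used for disease
trajectory studies: a washout window free of any somatic (A00-N99) diagnosis,
an observation window of half-year periods, cumulative diagnosis accumulation
over disease blocks, a case arm carrying a case-defining diagnosis (diabetes,
E10-E14, by default), elevated progression hazards in the case arm and in one
sex, and state-dependent in-hospital death.

The planted model is a discrete-time absorbing Markov chain on a small latent
DAG. Each latent state, on entry, emits a fixed set of previously unseen
disease blocks, so diagnoses accumulate monotonically by construction and the
cluster-transition machinery downstream is upper triangular by construction.
Per half-year, a patient first makes at most one latent transition (categorical
over the state's successors, with the case/sex multipliers applied), then dies
in hospital with the post-transition state's hazard. Under this ordering the
per-pair transition probabilities and the per-state hazards are exactly the
quantities the downstream estimators target, which is what makes planted
recovery tests sharp.

The case-defining block can be delivered two ways: (a) an onset process that
gives every case-arm patient a truncated-geometric onset half-year within the
observation window (the default), which leaves the comorbidity dynamics of the
two arms identically distributed; or (b) a latent state flagged
``is_case_entry`` whose emission includes the case block, which control-arm
patients traverse without receiving the case block. With ``case_blocks`` empty
the arms are draws from the identical generating process (up to the configured
multipliers), the configuration used for null calibration experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .blocks import BlockTable, load_default_blocks
from .util import AGE_GROUPS, PERIODS_PER_AGE_GROUP, age_group_index

ARMS = ("case", "control")
SEXES = ("F", "M")

CLAIMS_COLUMNS = [
    "patient_id",
    "sex",
    "age_group",
    "region",
    "half_year_index",
    "icd10_codes",
    "discharge",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class LatentState:
    """A latent health state emitting a set of new disease blocks on entry."""

    state_id: int
    emitted_blocks: frozenset[int] = frozenset()
    is_case_entry: bool = False


@dataclass(frozen=True)
class SimulationConfig:
    n_cases: int
    latent_states: tuple[LatentState, ...]
    baseline_rates: dict[tuple[int, int], float]
    controls_per_case: int = 2
    n_blocks: int = 131
    n_half_years: int = 24
    washout_half_years: int = 12
    case_multiplier: float = 1.0
    boosted_transitions: frozenset[tuple[int, int]] = frozenset()
    sex_multiplier: float = 1.0
    sex_boosted_transitions: frozenset[tuple[int, int]] = frozenset()
    boosted_sex: str = "M"
    death_hazard: dict[int, float] = field(default_factory=dict)
    case_blocks: frozenset[int] = frozenset({32})  # E10-E14 in the default table
    onset_rate: float = 0.12
    male_fraction: float = 0.53
    age_group_distribution: dict[str, float] = field(
        default_factory=lambda: {
            "50-54": 0.18, "55-59": 0.20, "60-64": 0.20, "65-69": 0.16,
            "70-74": 0.12, "75-79": 0.08, "80-84": 0.06,
        }
    )
    region_distribution: dict[str, float] = field(
        default_factory=lambda: {"east": 0.38, "west": 0.34, "south": 0.28}
    )
    seed: int = 0

    @property
    def n_states(self) -> int:
        return len(self.latent_states)

    @property
    def observation_start(self) -> int:
        return self.washout_half_years

    @property
    def observation_stop(self) -> int:
        return self.washout_half_years + self.n_half_years

    def pair_probability(self, i: int, j: int, arm: str, sex: str) -> float:
        """Per-half-year probability of the latent transition i -> j after multipliers."""
        p = self.baseline_rates.get((i, j), 0.0)
        if arm == "case" and (i, j) in self.boosted_transitions:
            p *= self.case_multiplier
        if sex == self.boosted_sex and (i, j) in self.sex_boosted_transitions:
            p *= self.sex_multiplier
        return p


@dataclass(frozen=True)
class PlantedTruth:
    """Exact per-stratum latent transition law implied by a configuration.

    ``p[(arm, sex)]`` is the (S, S) one-step matrix over latent states with the
    stay probability on the diagonal; ``death`` holds the per-state hazard.
    """

    n_states: int
    p: dict[tuple[str, str], np.ndarray]
    death: np.ndarray

    def pair(self, i: int, j: int, arm: str, sex: str) -> float:
        return float(self.p[(arm, sex)][i, j])


def _ancestors(config: SimulationConfig) -> dict[int, set[int]]:
    """Ancestor sets of the latent DAG; raises ConfigError on a cycle."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(s.state_id for s in config.latent_states)
    g.add_edges_from(config.baseline_rates.keys())
    if not nx.is_directed_acyclic_graph(g):
        raise ConfigError("latent-state graph has a cycle")
    return {n: set(nx.ancestors(g, n)) for n in g.nodes}


def validate_config(config: SimulationConfig) -> None:
    """Check the structural and probabilistic invariants of a configuration."""
    states = {s.state_id: s for s in config.latent_states}
    if sorted(states) != list(range(config.n_states)):
        raise ConfigError("latent state ids must be 0..S-1 and unique")
    if config.n_cases < 1 or config.controls_per_case < 0:
        raise ConfigError("n_cases must be >= 1 and controls_per_case >= 0")
    if states[0].emitted_blocks:
        raise ConfigError(
            "state 0 (the pre-diagnosis root) must emit no blocks; "
            "washout purity would fail otherwise"
        )
    for (i, j) in config.baseline_rates:
        if i not in states or j not in states:
            raise ConfigError(f"transition ({i}, {j}) references an unknown state")
    anc = _ancestors(config)
    for s in config.latent_states:
        for a in anc[s.state_id]:
            overlap = s.emitted_blocks & states[a].emitted_blocks
            if overlap:
                raise ConfigError(
                    f"state {s.state_id} re-emits blocks {sorted(overlap)} "
                    f"already emitted by ancestor {a}"
                )
        flagged = bool(s.emitted_blocks & config.case_blocks)
        if flagged != s.is_case_entry:
            raise ConfigError(
                f"state {s.state_id}: is_case_entry must be set iff the emission "
                "includes a case-defining block"
            )
    for b in {b for s in config.latent_states for b in s.emitted_blocks} | set(
        config.case_blocks
    ):
        if not 0 <= b < config.n_blocks:
            raise ConfigError(f"emitted block index {b} outside 0..{config.n_blocks - 1}")
    for dist, name in (
        (config.age_group_distribution, "age_group_distribution"),
        (config.region_distribution, "region_distribution"),
    ):
        if not dist or abs(sum(dist.values()) - 1.0) > 1e-9 or min(dist.values()) < 0:
            raise ConfigError(f"{name} must be a probability distribution")
    for g in config.age_group_distribution:
        age_group_index(g)  # raises on unknown labels
    if not 0.0 <= config.onset_rate <= 1.0:
        raise ConfigError("onset_rate must lie in [0, 1]")
    if config.boosted_sex not in SEXES:
        raise ConfigError(f"boosted_sex must be one of {SEXES}")
    for k, h in config.death_hazard.items():
        if k not in states or not 0.0 <= h <= 1.0:
            raise ConfigError(f"death hazard for state {k} invalid")
    # Total exit probability (transitions + death) per state and stratum.
    for arm in ARMS:
        for sex in SEXES:
            for k in states:
                pairs = [(i, j) for (i, j) in config.baseline_rates if i == k]
                probs = {pr: config.pair_probability(*pr, arm, sex) for pr in pairs}
                bad = [pr for pr, p in probs.items() if not 0.0 <= p <= 1.0]
                total = sum(probs.values()) + config.death_hazard.get(k, 0.0)
                if bad or total > 1.0 + 1e-12:
                    raise ConfigError(
                        f"state {k} ({arm}, sex {sex}): total exit probability "
                        f"{total:.4f} invalid after multipliers; transition pairs "
                        f"{sorted(probs)} with probabilities "
                        f"{[round(probs[pr], 4) for pr in sorted(probs)]}"
                    )


def planted_truth(config: SimulationConfig) -> PlantedTruth:
    """The exact transition law (per arm and sex) the generator draws from."""
    validate_config(config)
    S = config.n_states
    death = np.zeros(S)
    for k, h in config.death_hazard.items():
        death[k] = h
    mats = {}
    for arm in ARMS:
        for sex in SEXES:
            P = np.zeros((S, S))
            for (i, j) in config.baseline_rates:
                P[i, j] = config.pair_probability(i, j, arm, sex)
            np.fill_diagonal(P, 0.0)
            P[np.arange(S), np.arange(S)] = 1.0 - P.sum(axis=1)
            mats[(arm, sex)] = P
    return PlantedTruth(n_states=S, p=mats, death=death)


def cumulative_emissions(config: SimulationConfig) -> dict[int, frozenset[int]]:
    """Cumulative block set of each latent state, for single-path (tree) DAGs.

    Raises ConfigError when a state is reachable along paths with different
    cumulative sets (multiple parents), in which case the state-to-block map is
    not well defined.
    """
    parents: dict[int, list[int]] = {s.state_id: [] for s in config.latent_states}
    for (i, j) in config.baseline_rates:
        parents[j].append(i)
    emitted = {s.state_id: s.emitted_blocks for s in config.latent_states}
    out: dict[int, frozenset[int]] = {}

    def resolve(k: int) -> frozenset[int]:
        if k in out:
            return out[k]
        ps = parents[k]
        if len(ps) > 1:
            raise ConfigError(f"state {k} has multiple parents; cumulative set ambiguous")
        base = resolve(ps[0]) if ps else frozenset()
        out[k] = base | emitted[k]
        return out[k]

    for s in config.latent_states:
        resolve(s.state_id)
    return out


# ---------------------------------------------------------------------------
# Simulation


@dataclass
class SimulationResult:
    """Claims table plus the planted per-patient ground truth used by tests."""

    claims: pd.DataFrame
    demographics: pd.DataFrame  # patient_id, arm, sex, entry_age_index, region, death_t, onset_t
    state_entries: pd.DataFrame  # patient_id, half_year_index, state


def _draw_categorical(rng: np.random.Generator, labels: list[str], probs: list[float], n: int) -> np.ndarray:
    idx = rng.choice(len(labels), size=n, p=np.asarray(probs) / np.sum(probs))
    return np.asarray(labels, dtype=object)[idx]


def _truncated_geometric(rng: np.random.Generator, rate: float, horizon: int, n: int) -> np.ndarray:
    """Onset half-years in {0..horizon-1}: geometric conditioned on < horizon."""
    u = rng.random(n)
    if rate >= 1.0:
        return np.zeros(n, dtype=np.int64)
    if rate <= 0.0:  # no preference; fall back to uniform over the window
        return np.floor(u * horizon).astype(np.int64)
    tail = (1.0 - rate) ** horizon
    t = np.floor(np.log1p(-u * (1.0 - tail)) / np.log1p(-rate)).astype(np.int64)
    return np.clip(t, 0, horizon - 1)


def simulate_population(
    config: SimulationConfig, table: BlockTable | None = None
) -> pd.DataFrame:
    """Generate a claims table (one row per patient-half-year with new events)."""
    return simulate_with_truth(config, table).claims


def simulate_with_truth(
    config: SimulationConfig, table: BlockTable | None = None
) -> SimulationResult:
    """As :func:`simulate_population`, but also return the planted paths."""
    validate_config(config)
    if table is None:
        table = load_default_blocks()
    rng = np.random.default_rng(config.seed)

    W = config.observation_start
    T = config.n_half_years
    S = config.n_states
    nc = config.n_cases
    ratio = config.controls_per_case
    nk = nc * ratio

    # Demographics: controls mirror their case's stratum so exact matching on
    # (age group, sex, region) is well populated by construction.
    case_sex = np.where(rng.random(nc) < config.male_fraction, "M", "F").astype(object)
    age_labels = list(config.age_group_distribution)
    case_age = rng.choice(
        len(age_labels), size=nc, p=list(config.age_group_distribution.values())
    )
    case_age_idx = np.array([age_group_index(age_labels[i]) for i in case_age])
    case_region = _draw_categorical(
        rng, list(config.region_distribution), list(config.region_distribution.values()), nc
    )

    sex = np.concatenate([case_sex, np.repeat(case_sex, ratio)])
    age_idx = np.concatenate([case_age_idx, np.repeat(case_age_idx, ratio)])
    region = np.concatenate([case_region, np.repeat(case_region, ratio)])
    arm = np.array(["case"] * nc + ["control"] * nk, dtype=object)
    pid = np.array(
        [f"D{i:07d}" for i in range(nc)] + [f"C{i:07d}" for i in range(nk)],
        dtype=object,
    )
    n = nc + nk

    # Case onset half-years (only used when delivery is via the onset process).
    has_entry_state = any(s.is_case_entry for s in config.latent_states)
    use_onset = bool(config.case_blocks) and not has_entry_state
    onset_t = np.full(n, -1, dtype=np.int64)
    if use_onset:
        onset_t[:nc] = W + _truncated_geometric(rng, config.onset_rate, T, nc)

    # Per-stratum transition structures: successors and cumulative probabilities.
    exits: dict[tuple[str, str, int], tuple[np.ndarray, np.ndarray]] = {}
    for a in ARMS:
        for sx in SEXES:
            for k in range(S):
                succ = sorted(j for (i, j) in config.baseline_rates if i == k)
                ps = np.array([config.pair_probability(k, j, a, sx) for j in succ])
                exits[(a, sx, k)] = (np.array(succ, dtype=np.int64), np.cumsum(ps))
    hazard = np.zeros(S)
    for k, h in config.death_hazard.items():
        hazard[k] = h

    # Dynamics: the chain is frozen during washout (patients are present but
    # diagnosis-free, matching the eligibility design) and evolves during the
    # observation window only.
    state = np.zeros(n, dtype=np.int64)
    alive = np.ones(n, dtype=bool)
    death_t = np.full(n, -1, dtype=np.int64)
    ev_patient: list[np.ndarray] = []
    ev_t: list[np.ndarray] = []
    ev_state: list[np.ndarray] = []
    for t in range(W, W + T):
        u = rng.random(n)
        nxt = state.copy()
        for a in ARMS:
            for sx in SEXES:
                stratum = alive & (arm == a) & (sex == sx)
                for k in np.unique(state[stratum]):
                    succ, cum = exits[(a, sx, int(k))]
                    if len(succ) == 0:
                        continue
                    mask = stratum & (state == k)
                    pos = np.searchsorted(cum, u[mask], side="right")
                    moved = pos < len(succ)
                    idx = np.flatnonzero(mask)[moved]
                    nxt[idx] = succ[pos[moved]]
        changed = alive & (nxt != state)
        if changed.any():
            ev_patient.append(np.flatnonzero(changed))
            ev_t.append(np.full(int(changed.sum()), t, dtype=np.int64))
            ev_state.append(nxt[changed])
        state = nxt
        ud = rng.random(n)
        dies = alive & (ud < hazard[state])
        death_t[dies] = t
        alive &= ~dies

    # Assemble stay rows: one per (patient, half-year) with new diagnoses or death.
    code_of_block = {b.index: b.start for b in table.blocks}
    case_codes = sorted(code_of_block[b] for b in sorted(config.case_blocks))
    emit_case: dict[int, list[str]] = {}
    emit_control: dict[int, list[str]] = {}
    for s in config.latent_states:
        bl = sorted(s.emitted_blocks)
        emit_case[s.state_id] = [code_of_block[b] for b in bl]
        emit_control[s.state_id] = [
            code_of_block[b] for b in bl if b not in config.case_blocks
        ]

    rows: dict[tuple[int, int], list[str]] = {}

    def add_codes(p: int, t: int, codes: list[str]) -> None:
        if codes:
            rows.setdefault((p, t), []).extend(codes)

    if ev_patient:
        all_p = np.concatenate(ev_patient)
        all_t = np.concatenate(ev_t)
        all_s = np.concatenate(ev_state)
    else:
        all_p = all_t = all_s = np.array([], dtype=np.int64)
    for p, t, st in zip(all_p, all_t, all_s):
        codes = emit_case[int(st)] if arm[p] == "case" else emit_control[int(st)]
        add_codes(int(p), int(t), list(codes))
    if use_onset:
        for p in range(nc):
            t_on = int(onset_t[p])
            if death_t[p] == -1 or t_on <= death_t[p]:
                add_codes(p, t_on, case_codes)
            else:
                onset_t[p] = -1  # died before onset; no case diagnosis recorded
    for p in np.flatnonzero(death_t >= 0):
        rows.setdefault((int(p), int(death_t[p])), [])

    keys = sorted(rows)
    rec = {c: [] for c in CLAIMS_COLUMNS}
    for p, t in keys:
        g = min(int(age_idx[p]) + max(0, t - W) // PERIODS_PER_AGE_GROUP, len(AGE_GROUPS) - 1)
        rec["patient_id"].append(pid[p])
        rec["sex"].append(sex[p])
        rec["age_group"].append(AGE_GROUPS[g])
        rec["region"].append(region[p])
        rec["half_year_index"].append(t)
        rec["icd10_codes"].append(";".join(rows[(p, t)]))
        rec["discharge"].append("death" if death_t[p] == t else "normal")
    claims = pd.DataFrame(rec, columns=CLAIMS_COLUMNS)
    claims = claims.sort_values(["patient_id", "half_year_index"], kind="stable").reset_index(drop=True)

    demo = pd.DataFrame(
        {
            "patient_id": pid,
            "arm": arm,
            "sex": sex,
            "entry_age_index": age_idx,
            "region": region,
            "death_t": death_t,
            "onset_t": onset_t,
        }
    )
    entries = pd.DataFrame(
        {
            "patient_id": pid[all_p],
            "half_year_index": all_t,
            "state": all_s,
        }
    )
    return SimulationResult(claims=claims, demographics=demo, state_entries=entries)


# ---------------------------------------------------------------------------
# Ready-made configurations


#: Disease blocks (by range start) used for the planted chain, ordered along a
#: plausible progression: dorsopathies, metabolic disorders, disorders of lens,
#: ischaemic/other heart disease, chronic lower respiratory disease, renal
#: failure, cerebrovascular disease, oesophagus/stomach/duodenum.
_CHAIN_BLOCK_CODES = ["M40", "E70", "H25", "I20", "J40", "N17", "I60", "K20", "F00", "L80"]


def demo_config(
    n_cases: int = 2000,
    seed: int = 0,
    rho: float = 2.0,
    sex_multiplier: float = 1.5,
    with_case_block: bool = True,
    controls_per_case: int = 2,
    table: BlockTable | None = None,
) -> SimulationConfig:
    """Default study-like configuration: a 7-state progression DAG.

    The heart-disease-involving transitions carry the case multiplier rho, the
    late transitions toward renal failure additionally carry the male sex
    multiplier. Death hazards rise along the progression.
    """
    if table is None:
        table = load_default_blocks()
    b = table.index_for_start
    states = (
        LatentState(0),
        LatentState(1, frozenset({b("M40")})),
        LatentState(2, frozenset({b("E70")})),
        LatentState(3, frozenset({b("H25")})),
        LatentState(4, frozenset({b("I20"), b("I30")})),
        LatentState(5, frozenset({b("J40")})),
        LatentState(6, frozenset({b("N17")})),
    )
    rates = {
        (0, 1): 0.25,
        (1, 2): 0.15,
        (2, 3): 0.12,
        (3, 4): 0.12,
        (4, 5): 0.08,
        (4, 6): 0.06,
        (5, 6): 0.08,
    }
    return SimulationConfig(
        n_cases=n_cases,
        controls_per_case=controls_per_case,
        n_blocks=table.M,
        latent_states=states,
        baseline_rates=rates,
        case_multiplier=rho,
        boosted_transitions=frozenset({(3, 4), (4, 5), (4, 6), (5, 6)}),
        sex_multiplier=sex_multiplier,
        sex_boosted_transitions=frozenset({(4, 6), (5, 6)}),
        death_hazard={0: 0.0005, 1: 0.001, 2: 0.002, 3: 0.004, 4: 0.01, 5: 0.02, 6: 0.04},
        case_blocks=frozenset({b("E10")}) if with_case_block else frozenset(),
        seed=seed,
    )


def chain_config(
    n_states: int = 5,
    n_cases: int = 2000,
    base_rate: float = 0.15,
    rho: float = 1.0,
    boosted: tuple[tuple[int, int], ...] = (),
    sex_multiplier: float = 1.0,
    sex_boosted: tuple[tuple[int, int], ...] = (),
    death_hazard: float | dict[int, float] = 0.002,
    with_case_block: bool = False,
    seed: int = 0,
    controls_per_case: int = 2,
    n_half_years: int = 24,
    washout_half_years: int = 12,
    table: BlockTable | None = None,
) -> SimulationConfig:
    """A pure latent chain 0 -> 1 -> ... -> S-1 with a single rate everywhere.

    Chains have unique paths, so each latent state maps to one cumulative block
    set and hence (noise-free emissions) to exactly one monothetic cluster;
    the configuration of choice for recovery and null experiments.
    """
    if n_states < 2 or n_states > len(_CHAIN_BLOCK_CODES) + 1:
        raise ConfigError(f"chain_config supports 2..{len(_CHAIN_BLOCK_CODES) + 1} states")
    if table is None:
        table = load_default_blocks()
    states = [LatentState(0)]
    for i in range(1, n_states):
        states.append(
            LatentState(i, frozenset({table.index_for_start(_CHAIN_BLOCK_CODES[i - 1])}))
        )
    rates = {(i, i + 1): base_rate for i in range(n_states - 1)}
    if isinstance(death_hazard, dict):
        hz = dict(death_hazard)
    else:
        hz = {i: float(death_hazard) for i in range(n_states)}
    return SimulationConfig(
        n_cases=n_cases,
        controls_per_case=controls_per_case,
        n_blocks=table.M,
        n_half_years=n_half_years,
        washout_half_years=washout_half_years,
        latent_states=tuple(states),
        baseline_rates=rates,
        case_multiplier=rho,
        boosted_transitions=frozenset(boosted),
        sex_multiplier=sex_multiplier,
        sex_boosted_transitions=frozenset(sex_boosted),
        death_hazard=hz,
        case_blocks=frozenset({table.index_for_start("E10")}) if with_case_block else frozenset(),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Config (de)serialization


def config_to_dict(config: SimulationConfig) -> dict:
    return {
        "n_cases": config.n_cases,
        "controls_per_case": config.controls_per_case,
        "n_blocks": config.n_blocks,
        "n_half_years": config.n_half_years,
        "washout_half_years": config.washout_half_years,
        "latent_states": [
            {
                "state_id": s.state_id,
                "emitted_blocks": sorted(s.emitted_blocks),
                "is_case_entry": s.is_case_entry,
            }
            for s in config.latent_states
        ],
        "baseline_rates": {f"{i},{j}": p for (i, j), p in sorted(config.baseline_rates.items())},
        "case_multiplier": config.case_multiplier,
        "boosted_transitions": [list(p) for p in sorted(config.boosted_transitions)],
        "sex_multiplier": config.sex_multiplier,
        "sex_boosted_transitions": [list(p) for p in sorted(config.sex_boosted_transitions)],
        "boosted_sex": config.boosted_sex,
        "death_hazard": {str(k): v for k, v in sorted(config.death_hazard.items())},
        "case_blocks": sorted(config.case_blocks),
        "onset_rate": config.onset_rate,
        "male_fraction": config.male_fraction,
        "age_group_distribution": dict(config.age_group_distribution),
        "region_distribution": dict(config.region_distribution),
        "seed": config.seed,
    }


def config_from_dict(d: dict) -> SimulationConfig:
    return SimulationConfig(
        n_cases=int(d["n_cases"]),
        controls_per_case=int(d.get("controls_per_case", 2)),
        n_blocks=int(d.get("n_blocks", 131)),
        n_half_years=int(d.get("n_half_years", 24)),
        washout_half_years=int(d.get("washout_half_years", 12)),
        latent_states=tuple(
            LatentState(
                int(s["state_id"]),
                frozenset(int(b) for b in s.get("emitted_blocks", [])),
                bool(s.get("is_case_entry", False)),
            )
            for s in d["latent_states"]
        ),
        baseline_rates={
            tuple(int(x) for x in k.split(",")): float(v)
            for k, v in d["baseline_rates"].items()
        },
        case_multiplier=float(d.get("case_multiplier", 1.0)),
        boosted_transitions=frozenset(tuple(p) for p in d.get("boosted_transitions", [])),
        sex_multiplier=float(d.get("sex_multiplier", 1.0)),
        sex_boosted_transitions=frozenset(
            tuple(p) for p in d.get("sex_boosted_transitions", [])
        ),
        boosted_sex=d.get("boosted_sex", "M"),
        death_hazard={int(k): float(v) for k, v in d.get("death_hazard", {}).items()},
        case_blocks=frozenset(int(b) for b in d.get("case_blocks", [])),
        onset_rate=float(d.get("onset_rate", 0.12)),
        male_fraction=float(d.get("male_fraction", 0.53)),
        age_group_distribution=dict(d.get("age_group_distribution", {"60-64": 1.0})),
        region_distribution=dict(d.get("region_distribution", {"east": 1.0})),
        seed=int(d.get("seed", 0)),
    )


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=int(seed))
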