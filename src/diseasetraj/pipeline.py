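"""End-to-end orchestration: simulate/ingest -> cohort -> states -> cluster ->
tensors -> comparisons -> network exports, with a manifest tying every
artifact to its seed and stage parameters.

The clustering is fit on the case-arm state vectors only and frozen before
control vectors are assigned to it; the control arm never influences the tree.
All randomness descends from a single root seed via named per-stage children.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cohort as cohort_mod
from . import io
from . import simulate as sim_mod
from .blocks import BlockTable, load_default_blocks
from .divclus import ClusterTree, assign_matrix, cut_tree, fit_divclus, select_k_elbow
from .states import StateMatrix, build_state_matrix
from .transitions import (
    ComparisonResult,
    NodeStats,
    TransitionTensor,
    average_strata,
    build_network,
    count_transitions,
    node_statistics,
    risk_difference,
    sex_risk_difference,
)
from .util import HalfYearInterval, derived_seed

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    simulation: sim_mod.SimulationConfig | None = None
    claims_path: str | None = None
    washout: HalfYearInterval | None = None
    observation: HalfYearInterval | None = None
    case_codes: str = cohort_mod.DEFAULT_CASE_CODES
    universe_codes: str = cohort_mod.DEFAULT_UNIVERSE
    ratio: int = 2
    block_table_path: str | None = None
    max_leaves: int = 32
    n_clusters: int | None = None  # elbow override
    n_macro: int = 11
    min_leaf_size: int = 1
    threshold: float = 0.007
    out_dir: str = "out"
    seed: int = 0

    def resolve_windows(self) -> tuple[HalfYearInterval, HalfYearInterval]:
        if self.washout is not None and self.observation is not None:
            return self.washout, self.observation
        if self.simulation is not None:
            c = self.simulation
            return (
                HalfYearInterval(0, c.observation_start),
                HalfYearInterval(c.observation_start, c.observation_stop),
            )
        raise StageError("config", "input_error", "windows unresolvable without a simulation config")

    def to_dict(self) -> dict:
        w, o = self.resolve_windows()
        return {
            "simulation": None
            if self.simulation is None
            else sim_mod.config_to_dict(self.simulation),
            "claims_path": self.claims_path,
            "washout": f"{w.start}-{w.stop}",
            "observation": f"{o.start}-{o.stop}",
            "case_codes": self.case_codes,
            "universe_codes": self.universe_codes,
            "ratio": self.ratio,
            "block_table_path": self.block_table_path,
            "max_leaves": self.max_leaves,
            "n_clusters": self.n_clusters,
            "n_macro": self.n_macro,
            "min_leaf_size": self.min_leaf_size,
            "threshold": self.threshold,
            "out_dir": self.out_dir,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            simulation=None
            if d.get("simulation") is None
            else sim_mod.config_from_dict(d["simulation"]),
            claims_path=d.get("claims_path"),
            washout=HalfYearInterval.parse(d["washout"]) if d.get("washout") else None,
            observation=HalfYearInterval.parse(d["observation"])
            if d.get("observation")
            else None,
            case_codes=d.get("case_codes", cohort_mod.DEFAULT_CASE_CODES),
            universe_codes=d.get("universe_codes", cohort_mod.DEFAULT_UNIVERSE),
            ratio=int(d.get("ratio", 2)),
            block_table_path=d.get("block_table_path"),
            max_leaves=int(d.get("max_leaves", 32)),
            n_clusters=d.get("n_clusters"),
            n_macro=int(d.get("n_macro", 11)),
            min_leaf_size=int(d.get("min_leaf_size", 1)),
            threshold=float(d.get("threshold", 0.007)),
            out_dir=d.get("out_dir", "out"),
            seed=int(d.get("seed", 0)),
        )


@dataclass
class PipelineResult:
    claims: "object"
    assignment: cohort_mod.CohortAssignment
    states_case: StateMatrix
    states_control: StateMatrix
    tree: ClusterTree
    n_clusters: int
    leaf_to_cluster: np.ndarray
    cluster_to_macro: np.ndarray
    tensor_case: TransitionTensor
    tensor_control: TransitionTensor
    rd: ComparisonResult
    srd: ComparisonResult
    node_stats: NodeStats
    manifest: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Execute all stages; write artifacts and a manifest under ``out_dir``."""
    t0 = time.time()
    out = Path(config.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "artifacts": {}}

    def record(stage: str, **info) -> None:
        # timings go to the log only, keeping the manifest reproducible
        manifest["stages"][stage] = info
        logger.info("stage %s (%.2fs): %s", stage, time.time() - t0, info)

    table = (
        load_default_blocks()
        if config.block_table_path is None
        else BlockTable.from_tsv(config.block_table_path)
    )
    washout, observation = config.resolve_windows()

    # -- simulate / ingest --------------------------------------------------
    if config.simulation is not None:
        sim_cfg = sim_mod.with_seed(
            config.simulation, derived_seed(config.seed, "simulate")
        )
        try:
            claims = sim_mod.simulate_population(sim_cfg, table)
        except sim_mod.ConfigError as e:
            raise StageError("simulate", "input_error", str(e)) from e
        record("simulate", n_rows=len(claims), seed=sim_cfg.seed)
    elif config.claims_path is not None:
        claims = io.read_claims(config.claims_path)
        record("ingest", n_rows=len(claims), path=config.claims_path)
    else:
        raise StageError("simulate", "input_error", "no simulation config or claims path")
    if write:
        io.write_claims(claims, out / "claims.csv")

    # -- cohort -------------------------------------------------------------
    try:
        cases = cohort_mod.select_cases(
            claims, washout, observation, config.case_codes, config.universe_codes
        )
        pool = cohort_mod.select_control_pool(
            claims, washout, observation, config.case_codes, config.universe_codes
        )
        demo = cohort_mod.derive_demographics(claims, observation)
        assignment = cohort_mod.match_controls(
            cases, pool, demo, ratio=config.ratio, seed=derived_seed(config.seed, "match")
        )
    except ValueError as e:
        raise StageError("cohort", "input_error", str(e)) from e
    record(
        "cohort",
        n_cases=len(cases),
        n_pool=len(pool),
        n_matched=len(assignment.case_ids),
        n_excluded=len(assignment.excluded),
    )
    if not assignment.case_ids:
        raise StageError("cohort", "empty_cohort", "no case could be matched")
    if write:
        assignment.to_frame().to_csv(out / "cohort.csv", index=False)
        assignment.exclusions_frame().to_csv(out / "exclusions.csv", index=False)

    # -- states -------------------------------------------------------------
    states_case = build_state_matrix(claims, assignment.case_ids, table, observation)
    states_ctrl = build_state_matrix(claims, assignment.control_ids, table, observation)
    record(
        "states",
        case_snapshots=states_case.n_snapshots,
        control_snapshots=states_ctrl.n_snapshots,
        dropped_codes=states_case.dropped_codes + states_ctrl.dropped_codes,
    )
    if write:
        io.write_states(states_case, out / "states_case")
        io.write_states(states_ctrl, out / "states_control")

    # -- cluster (cases only; controls assigned afterwards) ------------------
    tree = fit_divclus(
        states_case.vectors, max_leaves=config.max_leaves, min_leaf_size=config.min_leaf_size
    )
    k = select_k_elbow(tree.inertia_curve, override=config.n_clusters)
    leaf_to_cluster = cut_tree(tree, k).leaf_to_macro
    n_macro = min(config.n_macro, k)
    macro_of_leaf = cut_tree(tree, n_macro).leaf_to_macro
    # macro id of each cluster: all leaves of a cluster share one macro
    cluster_to_macro = np.zeros(k, dtype=np.int64)
    cluster_to_macro[leaf_to_cluster] = macro_of_leaf
    record("cluster", n_leaves=tree.n_leaves, n_clusters=k, n_macro=n_macro)
    if write:
        io.write_tree(tree, out / "tree.json")
        with open(out / "inertia_curve.csv", "w", encoding="utf-8") as fh:
            fh.write("n_leaves,inertia\n")
            for i, v in enumerate(tree.inertia_curve, 1):
                fh.write(f"{i},{v!r}\n")

    # -- tensors ------------------------------------------------------------
    assign_case = leaf_to_cluster[assign_matrix(tree, states_case.vectors)]
    assign_ctrl = leaf_to_cluster[assign_matrix(tree, states_ctrl.vectors)]
    tensor_case = count_transitions(states_case, assign_case, k)
    tensor_ctrl = count_transitions(states_ctrl, assign_ctrl, k)
    record(
        "transitions",
        case_steps=int(tensor_case.N.sum()),
        control_steps=int(tensor_ctrl.N.sum()),
    )
    if write:
        io.write_tensor(tensor_case, out / "tensor_case.csv")
        io.write_tensor(tensor_ctrl, out / "tensor_control.csv")

    # -- comparisons ----------------------------------------------------------
    rd = risk_difference(tensor_case, tensor_ctrl)
    srd = sex_risk_difference(tensor_case)
    if write:
        rd.to_frame().to_csv(out / "rd.csv", index=False)
        srd.to_frame().to_csv(out / "srd.csv", index=False)

    # -- networks -------------------------------------------------------------
    stats = node_statistics(states_case, assign_case, k, cluster_to_macro)
    q_pooled, q_def = average_strata(tensor_case, over=("s", "a"), weights="exposure")
    g_rate = build_network(q_pooled, q_def, stats, threshold=config.threshold, kind="rate")
    rd_avg = average_strata(rd, over=("s", "a"))
    g_rd = build_network(rd_avg.values, rd_avg.defined, stats, threshold=0.0, kind="RD")
    srd_avg = average_strata(srd, over=("a",))
    g_srd = build_network(srd_avg.values, srd_avg.defined, stats, threshold=0.0, kind="SRD")
    record(
        "network",
        rate_edges=g_rate.number_of_edges(),
        rd_edges=g_rd.number_of_edges(),
        srd_edges=g_srd.number_of_edges(),
    )
    if write:
        io.write_network(g_rate, out / "network_rate.graphml", out / "network_rate.json")
        io.write_network(g_rd, out / "network_rd.graphml", out / "network_rd.json")
        io.write_network(g_srd, out / "network_srd.graphml", out / "network_srd.json")
        for p in sorted(out.iterdir()):
            if p.is_file() and p.name != "manifest.json":
                manifest["artifacts"][p.name] = io.sha256_file(p)
        io.write_manifest(manifest, out / "manifest.json")

    return PipelineResult(
        claims=claims,
        assignment=assignment,
        states_case=states_case,
        states_control=states_ctrl,
        tree=tree,
        n_clusters=k,
        leaf_to_cluster=leaf_to_cluster,
        cluster_to_macro=cluster_to_macro,
        tensor_case=tensor_case,
        tensor_control=tensor_ctrl,
        rd=rd,
        srd=srd,
        node_stats=stats,
        manifest=manifest,
    )
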