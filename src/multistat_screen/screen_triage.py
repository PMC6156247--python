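"""Triage statistics for a comparative multi-target virtual screen.

The screening cascade selects candidate SH2-domain inhibitors from docked
pose sets in successive stages:

1. best-pose selection per compound × target (highest binding score, BS);
2. primary ranking: keep the top-k compounds by reference-target BS;
3. similarity / molecular-weight filter against validated reference hits;
4. comparative binding-affinity value (CBAV) filter: CBAV(ref, other) =
   best BS on the reference target minus best BS on the other target;
   CBAV ≥ 0 for every other target means the reference is bound at least
   as well as any off-target;
5. ligand binding-pose variation (LBPV): the fraction of a compound's
   top-ranked poses falling in a given pocket class (pY+0 only, pY-X only,
   both, neither).  High LBPV for the dual-pocket class (≥ 0.8) indicates
   low conformer diversity, i.e. specific dual-pocket binding.

A ΔΔG° comparator flags binding impairment after in-silico alanine
mutagenesis: ΔΔG° = ΔG°(mutant) − ΔG°(wild-type) > 0 means the mutant
complex is less stable, i.e. the residue contributes to binding.
"""

from __future__ import annotations

import enum
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .dock_model import (
    CompoundRecord,
    ConfigurationError,
    PocketDefinition,
    PoseRecord,
    StabilityRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PocketClass",
    "DockScoreSummary",
    "TriageConfig",
    "TriageStage",
    "TriageReport",
    "best_pose",
    "rank_top_k",
    "similarity_filter",
    "cbav",
    "cbav_filter",
    "classify_pocket_occupancy",
    "lbpv",
    "ddg0_impairment",
    "summarize_poses",
    "run_triage",
]


class PocketClass(enum.Enum):
    """Exhaustive, mutually exclusive pocket assignment of one pose."""

    PY0_ONLY = "PY0_ONLY"
    PYX_ONLY = "PYX_ONLY"
    BOTH = "BOTH"
    NEITHER = "NEITHER"


#: aggregate LBPV classes accepted alongside the exclusive PocketClass values:
#: "PY0_ANY" counts poses touching pY+0 (alone or with pY-X), likewise "PYX_ANY".
AGGREGATE_CLASSES = ("PY0_ANY", "PYX_ANY", "BOTH")


@dataclass
class DockScoreSummary:
    """Per-compound cross-target score summary feeding the filters."""

    compound_id: str
    best_bs: dict[str, float] = field(default_factory=dict)
    cbav: dict[tuple[str, str], float] = field(default_factory=dict)
    lbpv: dict[tuple[str, str], float] = field(default_factory=dict)


def best_pose(poses: list[PoseRecord]) -> PoseRecord:
    """Select the best of a compound×target pose set.

    Maximal BS wins; ties broken by larger (less negative) crash, then by
    lower pose rank.
    """
    if not poses:
        raise ValueError("best_pose: empty pose list")
    keys = {(p.compound_id, p.target_id) for p in poses}
    if len(keys) > 1:
        raise ValueError(f"best_pose: mixed compound×target sets {keys}")
    return max(poses, key=lambda p: (p.bs, p.crash, -p.pose_rank))


def rank_top_k(
    summaries: list[DockScoreSummary], target: str, k: int
) -> list[DockScoreSummary]:
    """Top-k compounds by best BS on ``target``, descending; ties by compound id."""
    if k < 1:
        raise ValueError("k must be ≥ 1")
    missing = [s.compound_id for s in summaries if target not in s.best_bs]
    if missing:
        raise ValueError(f"summaries lack best_bs[{target!r}]: {missing}")
    ranked = sorted(summaries, key=lambda s: (-s.best_bs[target], s.compound_id))
    if k > len(ranked):
        logger.info("rank_top_k: k=%d exceeds n=%d; returning all", k, len(ranked))
    return ranked[:k]


def similarity_filter(
    compounds: list[CompoundRecord],
    reference_ids: list[str],
    min_sim: float,
    min_mw: float | None = None,
) -> list[CompoundRecord]:
    """Keep compounds similar enough to at least one reference (and heavy enough).

    A compound passes when its maximal similarity over the given references
    is ≥ ``min_sim`` and, if ``min_mw`` is set, its molecular weight is
    ≥ ``min_mw`` g/mol.  Both thresholds inclusive.  Compounds lacking all
    similarity annotations are excluded with a warning.
    """
    kept = []
    for c in compounds:
        sims = [c.similarity_to_ref[r][0] for r in reference_ids
                if r in c.similarity_to_ref]
        if not sims:
            logger.warning(
                "similarity_filter: %s has no similarity to any of %s; excluded",
                c.compound_id, reference_ids)
            continue
        if max(sims) >= min_sim and (min_mw is None or c.mw >= min_mw):
            kept.append(c)
    return kept


def cbav(best_bs_ref: float, best_bs_other: float) -> float:
    """Comparative binding-affinity value: reference minus other best BS.

    Antisymmetric; zero iff the two targets are bound equally well.
    """
    if not (math.isfinite(best_bs_ref) and math.isfinite(best_bs_other)):
        raise ValueError("cbav: non-finite binding score")
    return best_bs_ref - best_bs_other


def cbav_filter(
    summaries: list[DockScoreSummary],
    reference_target: str,
    threshold: float = 0.0,
) -> list[DockScoreSummary]:
    """Keep compounds whose CBAV(ref, t) ≥ threshold for *every* other target."""
    kept = []
    for s in summaries:
        others = [t for t in s.best_bs if t != reference_target]
        try:
            vals = [s.cbav[(reference_target, t)] for t in others]
        except KeyError as e:
            logger.warning("cbav_filter: %s missing CBAV entry %s; excluded",
                           s.compound_id, e)
            continue
        if all(v >= threshold for v in vals):
            kept.append(s)
    return kept


def classify_pocket_occupancy(
    pose: PoseRecord, pockets: list[PocketDefinition] | None = None
) -> PocketClass:
    """Assign one pose to its pocket class.

    Flag-dialect poses are read directly.  Coordinate-dialect poses occupy a
    pocket iff at least one heavy atom lies within the pocket radius of its
    centroid (both pockets must then be defined).
    """
    if pose.flags is not None:
        py0, pyx = pose.flags
    else:
        if not pockets:
            raise ConfigurationError(
                "classify_pocket_occupancy: coordinate pose needs pocket definitions"
            )
        by_id = {p.pocket_id: p for p in pockets}
        if set(by_id) != {"pY0", "pYX"}:
            raise ConfigurationError("both pY0 and pYX pockets must be defined")
        occupied = {}
        for pid, pocket in by_id.items():
            d = np.linalg.norm(pose.coords - np.asarray(pocket.centroid), axis=1)
            occupied[pid] = bool((d <= pocket.radius).any())
        py0, pyx = occupied["pY0"], occupied["pYX"]
    if py0 and pyx:
        return PocketClass.BOTH
    if py0:
        return PocketClass.PY0_ONLY
    if pyx:
        return PocketClass.PYX_ONLY
    return PocketClass.NEITHER


def lbpv(
    poses: list[PoseRecord],
    cls: PocketClass | str,
    pockets: list[PocketDefinition] | None = None,
) -> float:
    """Ligand binding-pose variation: fraction of poses in a pocket class.

    ``cls`` is either an exclusive :class:`PocketClass` or one of the
    aggregates ``"PY0_ANY"`` / ``"PYX_ANY"`` / ``"BOTH"``.  The denominator
    is the number of poses provided (20 in a full dual-pocket re-screen run;
    fewer triggers a warning).
    """
    if not poses:
        raise ValueError("lbpv: empty pose set")
    if len(poses) < 20:
        logger.warning("lbpv: only %d poses; denominator = %d", len(poses), len(poses))
    classes = [classify_pocket_occupancy(p, pockets) for p in poses]
    if isinstance(cls, PocketClass):
        hits = sum(c is cls for c in classes)
    elif cls == "PY0_ANY":
        hits = sum(c in (PocketClass.PY0_ONLY, PocketClass.BOTH) for c in classes)
    elif cls == "PYX_ANY":
        hits = sum(c in (PocketClass.PYX_ONLY, PocketClass.BOTH) for c in classes)
    elif cls == "BOTH":
        hits = sum(c is PocketClass.BOTH for c in classes)
    else:
        raise ValueError(f"lbpv: unknown class {cls!r}")
    return hits / len(poses)


def ddg0_impairment(
    wt: StabilityRecord, mut: StabilityRecord
) -> tuple[float, bool]:
    """Mutant-minus-wild-type ΔG° difference and the binding-impairment flag.

    ΔΔG° > 0 (the mutant complex is less stable) is called impaired.
    """
    if wt.variant != "wt":
        raise ValueError("first record must be the wild type")
    if (wt.target_id, wt.ligand_id) != (mut.target_id, mut.ligand_id):
        raise ValueError(
            f"mismatched pair: {(wt.target_id, wt.ligand_id)} vs "
            f"{(mut.target_id, mut.ligand_id)}"
        )
    ddg0 = mut.dg0 - wt.dg0
    return ddg0, ddg0 > 0


# ---------------------------------------------------------------------------
# orchestrated cascade
# ---------------------------------------------------------------------------

@dataclass
class TriageConfig:
    """Thresholds of the screening cascade (defaults follow the study design)."""

    reference_target: str = "STAT1"
    top_k: int = 20
    reference_compounds: list[str] = field(default_factory=list)
    min_sim: float = 0.5
    min_mw: float | None = 300.0
    cbav_threshold: float = 0.0
    lbpv_both_min: float = 0.8
    pockets: list[PocketDefinition] | None = None


@dataclass
class TriageStage:
    name: str
    parameters: dict
    n_in: int
    n_out: int
    survivors: list[str]
    exclusions: list[str]


@dataclass
class TriageReport:
    stages: list[TriageStage]
    summaries: dict[str, DockScoreSummary]

    @property
    def final_survivors(self) -> list[str]:
        return self.stages[-1].survivors if self.stages else []

    def to_json(self, path=None) -> str:
        doc = {
            "stages": [
                {
                    "name": s.name,
                    "parameters": s.parameters,
                    "n_in": s.n_in,
                    "n_out": s.n_out,
                    "survivors": s.survivors,
                    "exclusions": s.exclusions,
                }
                for s in self.stages
            ],
            "summaries": {
                cid: {
                    "best_bs": s.best_bs,
                    "cbav": {f"{a}|{b}": v for (a, b), v in s.cbav.items()},
                    "lbpv": {f"{t}|{c}": v for (t, c), v in s.lbpv.items()},
                }
                for cid, s in self.summaries.items()
            },
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def summarize_poses(
    poses: list[PoseRecord],
    reference_target: str,
    pockets: list[PocketDefinition] | None = None,
) -> dict[str, DockScoreSummary]:
    """Best-pose BS, CBAV and four-class LBPV per compound from a mixed pose list."""
    by_key: dict[tuple[str, str], list[PoseRecord]] = {}
    for p in poses:
        by_key.setdefault((p.compound_id, p.target_id), []).append(p)

    summaries: dict[str, DockScoreSummary] = {}
    for (cid, tid), pose_set in sorted(by_key.items()):
        s = summaries.setdefault(cid, DockScoreSummary(cid))
        s.best_bs[tid] = best_pose(pose_set).bs
        for cls in PocketClass:
            s.lbpv[(tid, cls.value)] = lbpv(pose_set, cls, pockets)
    for s in summaries.values():
        if reference_target not in s.best_bs:
            continue
        for tid, bs_other in s.best_bs.items():
            if tid != reference_target:
                s.cbav[(reference_target, tid)] = cbav(
                    s.best_bs[reference_target], bs_other
                )
    return summaries


def run_triage(
    poses: list[PoseRecord],
    compounds: list[CompoundRecord],
    config: TriageConfig,
) -> TriageReport:
    """Run the full in-scope cascade and return a per-stage audit report.

    Stages: best-pose summary → top-k by reference BS → similarity/MW →
    CBAV ≥ threshold on every off-target → dual-pocket LBPV ≥ threshold.
    A stage that empties the candidate set leaves the downstream stages
    empty; the report still completes.
    """
    meta = {c.compound_id: c for c in compounds}
    summaries = summarize_poses(poses, config.reference_target, config.pockets)
    ref = config.reference_target

    stages: list[TriageStage] = []

    def record(name: str, params: dict, before: list[str], after: list[str]) -> None:
        stages.append(
            TriageStage(
                name=name,
                parameters=params,
                n_in=len(before),
                n_out=len(after),
                survivors=after,
                exclusions=sorted(set(before) - set(after)),
            )
        )
        if before and not after:
            logger.info("triage stage %s emptied the candidate set", name)

    all_ids = sorted(summaries)
    scored = [cid for cid in all_ids if ref in summaries[cid].best_bs]
    record("best_pose_summary", {"reference_target": ref}, all_ids, scored)

    ranked = rank_top_k([summaries[c] for c in scored], ref, config.top_k) if scored else []
    top_ids = [s.compound_id for s in ranked]
    record("bs_top_k", {"k": config.top_k}, scored, top_ids)

    if config.reference_compounds:
        candidates = [meta[c] for c in top_ids if c in meta]
        sim_ids = [
            c.compound_id
            for c in similarity_filter(
                candidates, config.reference_compounds, config.min_sim, config.min_mw
            )
        ]
    else:
        sim_ids = list(top_ids)
    record(
        "similarity_mw",
        {
            "references": config.reference_compounds,
            "min_sim": config.min_sim,
            "min_mw": config.min_mw,
        },
        top_ids,
        sim_ids,
    )

    cbav_ids = [
        s.compound_id
        for s in cbav_filter([summaries[c] for c in sim_ids], ref, config.cbav_threshold)
    ]
    record("cbav", {"reference_target": ref, "threshold": config.cbav_threshold},
           sim_ids, cbav_ids)

    final_ids = [
        cid for cid in cbav_ids
        if summaries[cid].lbpv.get((ref, PocketClass.BOTH.value), 0.0)
        >= config.lbpv_both_min
    ]
    record("lbpv_dual_pocket", {"target": ref, "min_lbpv_both": config.lbpv_both_min},
           cbav_ids, final_ids)

    return TriageReport(stages=stages, summaries=summaries)
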