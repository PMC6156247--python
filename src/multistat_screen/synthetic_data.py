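"""Seeded generators emulating the pipeline's three input kinds.

The generators stand in for the parts of the study that cannot run at desk
scale — the docking engine's pose tables, the two-replicate bead-array
expression matrices, and genomic promoter sequences — while preserving the
statistical structure each downstream stage assumes.  Every generator takes
an explicit integer seed and returns, besides the data, a *truth record*
sufficient to score downstream recovery without re-reading generator
internals.  Identical seeds give identical output (including written
files, byte for byte).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .dock_model import (
    CompoundRecord,
    ConfigurationError,
    PoseRecord,
    write_compound_table,
    write_pose_table,
)
from .expression_pipeline import ExpressionMatrix
from .promoter_scan import ALPHABET, PWMModel, matrix_similarity_score, reverse_complement

import pandas as pd

__all__ = [
    "PoseSimConfig",
    "ExpressionSimConfig",
    "PromoterSimConfig",
    "SimulationConfig",
    "PoseTruth",
    "ExpressionTruth",
    "PromoterTruth",
    "simulate_pose_table",
    "simulate_expression",
    "simulate_promoters",
    "sample_motif",
    "markov_resample",
]


# ---------------------------------------------------------------------------
# pose tables
# ---------------------------------------------------------------------------

@dataclass
class PoseSimConfig:
    """Pose-set generator emulating a dual-pocket re-screen run.

    Per compound × target the generator emits ``n_poses`` poses ranked by
    descending sampled binding score, with pocket-occupancy flags drawn from
    the configured multinomial (p_both, p_py0, p_pyx, remainder neither).
    ``n_winners`` compounds are planted to pass every cascade stage: top
    reference-target BS, high similarity and MW, non-negative CBAV against
    every off-target, and forced dual-pocket occupancy.  In that scenario
    every decoy carries at least one deterministic disqualifier so planted
    winners are exactly the cascade survivors.  With ``n_winners=0`` the
    generator is a plain occupancy/score sampler (no disqualifiers), the
    mode used for statistical recovery of the occupancy probability.
    """

    seed: int = 0
    n_compounds: int = 50
    targets: tuple[str, ...] = ("STAT1", "STAT2", "STAT3")
    reference_target: str = "STAT1"
    reference_compounds: tuple[str, ...] = ("C01", "E01", "F01")
    n_poses: int = 20
    p_py0: float = 0.2
    p_pyx: float = 0.2
    p_both: float = 0.25
    bs_mean: float = 6.5
    bs_sd: float = 0.8
    n_winners: int = 3

    def __post_init__(self) -> None:
        probs = (self.p_py0, self.p_pyx, self.p_both)
        if any(not 0.0 <= p <= 1.0 for p in probs) or sum(probs) > 1.0 + 1e-12:
            raise ConfigurationError(
                "occupancy probabilities must lie in [0,1] with p0+pX+pBoth ≤ 1"
            )
        if self.n_winners > self.n_compounds:
            raise ConfigurationError("more winners than compounds")


@dataclass
class PoseTruth:
    winners: list[str]
    occupancy_probs: dict[str, tuple[float, float, float]]  # (p_py0, p_pyx, p_both)
    failure_mode: dict[str, str]


_DECOY_MODES = ("low_sim", "low_mw", "neg_cbav", "low_lbpv")


def _pose_set(
    rng: np.random.Generator,
    cid: str,
    tid: str,
    n_poses: int,
    best_bs: float,
    bs_sd: float,
    probs: tuple[float, float, float],
) -> list[PoseRecord]:
    """Poses ranked by descending BS, shifted so the best pose scores best_bs."""
    draws = np.sort(rng.normal(0.0, bs_sd, n_poses))[::-1]
    bs = draws - draws[0] + best_bs
    p0, px, pb = probs
    classes = rng.choice(4, size=n_poses, p=[pb, p0, px, 1.0 - pb - p0 - px])
    flags = [( (1, 1), (1, 0), (0, 1), (0, 0) )[c] for c in classes]
    poses = []
    for i in range(n_poses):
        poses.append(
            PoseRecord(
                compound_id=cid,
                target_id=tid,
                pose_rank=i + 1,
                bs=round(float(bs[i]), 4),
                crash=round(-abs(float(rng.normal(1.2, 0.3))), 4),
                polar_score=round(abs(float(rng.normal(6.0, 1.0))), 4),
                flags=(bool(flags[i][0]), bool(flags[i][1])),
            )
        )
    return poses


def simulate_pose_table(
    config: PoseSimConfig,
) -> tuple[list[PoseRecord], list[CompoundRecord], PoseTruth]:
    rng = np.random.default_rng(config.seed)
    poses: list[PoseRecord] = []
    compounds: list[CompoundRecord] = []
    occupancy: dict[str, tuple[float, float, float]] = {}
    failure: dict[str, str] = {}
    winners: list[str] = []

    others = [t for t in config.targets if t != config.reference_target]
    for i in range(config.n_compounds):
        is_winner = i < config.n_winners
        cid = f"{'WIN' if is_winner else 'CPD'}{i:04d}"
        if is_winner:
            winners.append(cid)
            probs = (0.0, 0.0, 1.0)  # forced dual-pocket binding
            best_ref = float(rng.normal(9.5, 0.2))
            sim = float(rng.uniform(0.65, 0.9))
            mw = float(rng.uniform(310.0, 420.0))
            mode = "winner"
        elif config.n_winners == 0:
            mode = "none"
            probs = (config.p_py0, config.p_pyx, config.p_both)
            best_ref = float(rng.normal(config.bs_mean, config.bs_sd))
            sim = float(rng.uniform(0.55, 0.85))
            mw = float(rng.uniform(305.0, 400.0))
        else:
            mode = _DECOY_MODES[(i - config.n_winners) % len(_DECOY_MODES)]
            probs = (
                (config.p_py0, config.p_pyx, 0.05)
                if mode == "low_lbpv"
                else (config.p_py0, config.p_pyx, config.p_both)
            )
            best_ref = min(float(rng.normal(config.bs_mean, config.bs_sd)), 8.8)
            sim = 0.2 if mode == "low_sim" else float(rng.uniform(0.55, 0.85))
            mw = 250.0 if mode == "low_mw" else float(rng.uniform(305.0, 400.0))
        occupancy[cid] = probs
        failure[cid] = mode

        poses.extend(
            _pose_set(rng, cid, config.reference_target, config.n_poses,
                      best_ref, 0.4, probs)
        )
        for t in others:
            if mode == "neg_cbav":
                best_other = best_ref + float(rng.uniform(0.5, 1.5))
            else:
                best_other = best_ref - abs(float(rng.normal(1.0, 0.4)))
            poses.extend(
                _pose_set(rng, cid, t, config.n_poses, best_other, 0.4, probs)
            )
        compounds.append(
            CompoundRecord(
                compound_id=cid,
                name=f"ZINC{90000000 + i}",
                mw=round(mw, 2),
                source_library="CDL",
                similarity_to_ref={
                    ref: (round(sim, 3), round(float(rng.uniform(1.0, 3.0)), 2))
                    for ref in config.reference_compounds
                },
            )
        )
    truth = PoseTruth(winners=winners, occupancy_probs=occupancy, failure_mode=failure)
    return poses, compounds, truth


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSimConfig:
    """Two-replicate expression generator with planted induction/inhibition.

    Log2 signals are Gaussian around a per-gene baseline (raw signals
    log-normal); induced genes carry a planted log2 fold change (truncated
    so the linear FC is ≥ 2 by construction); a configured subset of the
    induced genes responds to each inhibitor with a planted FC ratio
    (stimulated FC over stimulated+inhibitor FC) applied on the mean.
    A small fraction of raw signals is flipped negative to emulate
    background-subtracted bead intensities and exercise the flooring rule.
    """

    seed: int = 0
    n_genes: int = 2000
    n_replicates: int = 2
    inhibitors: tuple[str, ...] = ("C01L_F03", "STATTIC", "STX-0119")
    # sparse induction, as on a genome-wide array (where a stimulus moves a few
    # percent of probes); quantile normalization presumes mostly-unchanged
    # distributions and compresses planted effects when this is violated
    fraction_induced: float = 0.03
    induced_log2fc_mean: float = 3.0
    induced_log2fc_sd: float = 1.0
    induced_log2fc_min: float = 1.0  # truncation floor; 1.0 ⇒ linear FC ≥ 2
    inhibited_fraction: float = 0.6
    inhibition_log2ratio: float = 4.0
    noise_sd: float = 0.25
    baseline_log2_mean: float = 7.5
    baseline_log2_sd: float = 1.2
    # fraction of cells reported as negative intensities; applied to the
    # dimmest cells, as background subtraction on a real array only drives
    # near-background probes below zero
    negative_fraction: float = 0.005

    def __post_init__(self) -> None:
        for name in ("fraction_induced", "inhibited_fraction", "negative_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd <= 0 or self.baseline_log2_sd <= 0:
            raise ConfigurationError("standard deviations must be > 0")
        if self.induced_log2fc_min < 1.0:
            raise ConfigurationError(
                "induced_log2fc_min below 1 breaks the FC ≥ 2 planting contract"
            )
        if self.n_replicates < 2:
            raise ConfigurationError("need ≥ 2 replicates per condition")


@dataclass
class ExpressionTruth:
    induced: list[tuple[str, str]]
    inhibited: dict[str, list[tuple[str, str]]]
    planted_log2fc: dict[str, float]


def simulate_expression(
    config: ExpressionSimConfig,
) -> tuple[ExpressionMatrix, dict, ExpressionTruth]:
    """Returns (matrix, design, truth); design maps roles to condition labels."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = [(f"P{i:05d}", f"GENE{i:05d}") for i in range(n)]

    n_induced = int(round(config.fraction_induced * n))
    induced_idx = np.sort(rng.choice(n, size=n_induced, replace=False))
    induced_mask = np.zeros(n, bool)
    induced_mask[induced_idx] = True

    log2fc = np.zeros(n)
    raw_fc = rng.normal(config.induced_log2fc_mean, config.induced_log2fc_sd, n_induced)
    log2fc[induced_idx] = np.maximum(raw_fc, config.induced_log2fc_min)

    responders: dict[str, np.ndarray] = {}
    for inh in config.inhibitors:
        k = int(round(config.inhibited_fraction * n_induced))
        chosen = rng.choice(induced_idx, size=k, replace=False)
        mask = np.zeros(n, bool)
        mask[chosen] = True
        responders[inh] = mask

    conditions = ["control", "stim"] + [f"stim+{inh}" for inh in config.inhibitors]
    effects = {"control": np.zeros(n), "stim": log2fc}
    for inh in config.inhibitors:
        arm = log2fc.copy()
        arm[responders[inh]] -= config.inhibition_log2ratio
        arm[~induced_mask] = 0.0
        effects[f"stim+{inh}"] = arm

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)
    columns = []
    data = np.empty((n, len(conditions) * config.n_replicates))
    j = 0
    for cond in conditions:
        for rep in range(1, config.n_replicates + 1):
            x = baseline + effects[cond] + rng.normal(0.0, config.noise_sd, n)
            data[:, j] = np.exp2(x)
            columns.append((cond, rep))
            j += 1
    if config.negative_fraction > 0:
        thr = np.quantile(data, config.negative_fraction)
        dim = data < thr
        data[dim] = -rng.uniform(0.0, 10.0, int(dim.sum()))

    df = pd.DataFrame(
        data,
        index=pd.MultiIndex.from_tuples(genes, names=["gene_id", "gene_name"]),
        columns=pd.MultiIndex.from_tuples(columns, names=["condition", "replicate"]),
    )
    matrix = ExpressionMatrix(df)
    design = {
        "control": "control",
        "stim": "stim",
        "inhibitors": {inh: f"stim+{inh}" for inh in config.inhibitors},
    }
    truth = ExpressionTruth(
        induced=[genes[i] for i in induced_idx],
        inhibited={
            inh: [genes[i] for i in np.flatnonzero(mask)]
            for inh, mask in responders.items()
        },
        planted_log2fc={genes[i][0]: float(log2fc[i]) for i in induced_idx},
    )
    return matrix, design, truth


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

#: default planted category composition of a synthetic cohort (ISRE/GAS/NFKB
#: presence combinations); roughly an inflammation-responsive promoter set in
#: which most genes carry at least one interferon-pathway site.
DEFAULT_CATEGORY_PROBS = {
    "none": 0.10,
    "ISRE": 0.13,
    "GAS": 0.16,
    "NFKB": 0.02,
    "ISRE+GAS": 0.17,
    "ISRE+NFKB": 0.05,
    "GAS+NFKB": 0.16,
    "ISRE+GAS+NFKB": 0.21,
}


@dataclass
class PromoterSimConfig:
    """Promoter generator: i.i.d. background at a set GC plus planted motifs.

    Each gene draws a site-combination category; one motif instance per
    planted class is sampled from a class PFM (columnwise, retained only if
    its matrix similarity score reaches the class threshold, i.e. the
    high-probability instance set) and written at a random non-overlapping
    offset on a random strand.
    """

    seed: int = 0
    n_promoters: int = 200
    length: int = 1000
    upstream: int = 950
    gc: float = 0.45
    category_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROBS)
    )
    sampler: str = "high_probability"  # or "pfm" (unconditional column sampling)

    def __post_init__(self) -> None:
        if not 0.0 < self.gc < 1.0:
            raise ConfigurationError("gc must be in (0, 1)")
        total = sum(self.category_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"category probabilities sum to {total}, not 1")
        if self.sampler not in ("high_probability", "pfm"):
            raise ConfigurationError(f"unknown sampler {self.sampler!r}")


@dataclass
class PlantedSite:
    class_id: str
    matrix_id: str
    offset: int  # TSS-relative start
    strand: str
    instance: str


@dataclass
class PromoterTruth:
    categories: dict[str, str]  # gene_id -> planted category label
    sites: dict[str, list[PlantedSite]]


def sample_motif(
    pwm: PWMModel,
    rng: np.random.Generator,
    threshold: float | None = None,
    max_tries: int = 200,
) -> str:
    """Sample one motif instance columnwise from the PFM probabilities.

    With a threshold, sampling is restricted to the high-probability
    instance set by rejection (accept only instances whose matrix similarity
    score is ≥ threshold); after ``max_tries`` rejections the consensus is
    returned.
    """
    probs = pwm.counts / pwm.counts.sum(axis=1, keepdims=True)
    for _ in range(max_tries):
        letters = [
            ALPHABET[rng.choice(4, p=probs[i])] for i in range(pwm.width)
        ]
        inst = "".join(letters)
        if threshold is None or matrix_similarity_score(pwm, inst) >= threshold:
            return inst
    return pwm.consensus


def markov_resample(seq: str, rng: np.random.Generator, order: int = 3) -> str:
    """Resample a sequence from its own order-``order`` Markov transition counts.

    Produces a background sequence of the same length preserving the
    source's k-mer composition statistically (k = order + 1); used to build
    motif-free backgrounds that retain local composition.
    """
    seq = seq.upper()
    if len(seq) <= order + 1:
        return seq
    trans: dict[str, list[str]] = {}
    for i in range(len(seq) - order):
        trans.setdefault(seq[i : i + order], []).append(seq[i + order])
    state = seq[:order]
    out = list(state)
    for _ in range(len(seq) - order):
        nxts = trans.get(state)
        if not nxts:  # dead end: restart from a random observed state
            state = list(trans)[rng.integers(len(trans))]
            nxts = trans[state]
        c = nxts[rng.integers(len(nxts))]
        out.append(c)
        state = state[1:] + c
    return "".join(out[: len(seq)])


def _random_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(4, size=length, p=p)


def simulate_promoters(
    config: PromoterSimConfig,
    classes,  # list[SiteClassConfig]
    pwms: dict[str, PWMModel],
) -> tuple[list[tuple[str, str]], PromoterTruth]:
    """Returns ([(gene_id, sequence), ...], truth)."""
    rng = np.random.default_rng(config.seed)
    class_by_id = {c.class_id: c for c in classes}
    max_width = max(p.width for p in pwms.values())
    if max_width > config.length:
        raise ConfigurationError("planted motif longer than the promoter sequence")

    labels = list(config.category_probs)
    probs = np.array([config.category_probs[k] for k in labels], float)
    probs = probs / probs.sum()

    records: list[tuple[str, str]] = []
    categories: dict[str, str] = {}
    sites: dict[str, list[PlantedSite]] = {}
    for g in range(config.n_promoters):
        gene_id = f"PRM{g:05d}"
        label = labels[rng.choice(len(labels), p=probs)]
        planted_classes = [] if label == "none" else label.split("+")

        arr = _random_background(rng, config.length, config.gc)
        occupied: list[tuple[int, int]] = []
        gene_sites: list[PlantedSite] = []
        for cls_name in planted_classes:
            cfg = class_by_id[cls_name]
            mid = cfg.matrix_ids[rng.integers(len(cfg.matrix_ids))]
            pwm = pwms[mid]
            thr = cfg.threshold if config.sampler == "high_probability" else None
            inst = sample_motif(pwm, rng, thr)
            strand = "+" if rng.random() < 0.5 else "-"
            for _ in range(1000):
                start = int(rng.integers(0, config.length - pwm.width + 1))
                span = (start, start + pwm.width)
                if all(span[1] <= a or span[0] >= b for a, b in occupied):
                    break
            else:  # pragma: no cover - pathological overcrowding
                raise ConfigurationError("could not place motif without overlap")
            occupied.append(span)
            written = inst if strand == "+" else reverse_complement(inst)
            arr[span[0] : span[1]] = [
                "ACGT".index(c) for c in written
            ]
            gene_sites.append(
                PlantedSite(
                    class_id=cls_name,
                    matrix_id=mid,
                    offset=start - config.upstream,
                    strand=strand,
                    instance=inst,
                )
            )
        seq = "".join(ALPHABET[i] for i in arr)
        records.append((gene_id, seq))
        categories[gene_id] = label
        sites[gene_id] = gene_sites
    return records, PromoterTruth(categories=categories, sites=sites)


# ---------------------------------------------------------------------------
# umbrella config + file emitters (CLI surface)
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    seed: int = 0
    pose: PoseSimConfig = field(default_factory=PoseSimConfig)
    expression: ExpressionSimConfig = field(default_factory=ExpressionSimConfig)
    promoter: PromoterSimConfig = field(default_factory=PromoterSimConfig)

    def __post_init__(self) -> None:
        # one top-level seed drives all three generators deterministically
        self.pose.seed = self.seed
        self.expression.seed = self.seed + 1
        self.promoter.seed = self.seed + 2


def write_pose_bundle(config: PoseSimConfig, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    poses, compounds, truth = simulate_pose_table(config)
    write_pose_table(poses, out / "poses.tsv")
    write_compound_table(compounds, out / "compounds.tsv")
    (out / "pose_truth.json").write_text(
        json.dumps(asdict(truth), indent=2, sort_keys=True) + "\n"
    )
    return {"poses": str(out / "poses.tsv"), "compounds": str(out / "compounds.tsv"),
            "truth": str(out / "pose_truth.json")}


def write_expression_bundle(config: ExpressionSimConfig, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, design, truth = simulate_expression(config)
    matrix.to_tsv(out / "expression.tsv")
    (out / "design.json").write_text(json.dumps(design, indent=2, sort_keys=True) + "\n")
    (out / "expression_truth.json").write_text(
        json.dumps(asdict(truth), indent=2, sort_keys=True) + "\n"
    )
    return {"matrix": str(out / "expression.tsv"), "design": str(out / "design.json"),
            "truth": str(out / "expression_truth.json")}


def write_promoter_bundle(config: PromoterSimConfig, classes, pwms, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, truth = simulate_promoters(config, classes, pwms)
    with open(out / "promoters.fasta", "w") as fh:
        for gene_id, seq in records:
            fh.write(f">{gene_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    (out / "promoter_truth.json").write_text(
        json.dumps(asdict(truth), indent=2, sort_keys=True) + "\n"
    )
    return {"fasta": str(out / "promoters.fasta"),
            "truth": str(out / "promoter_truth.json")}
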