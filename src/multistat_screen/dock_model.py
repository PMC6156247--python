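"""Data model and I/O for docking-engine output tables.

The triage statistics downstream (see :mod:`multistat_screen.screen_triage`)
operate on per-pose score records rather than on raw docking-engine output,
so that any engine producing a binding score (BS), a clash penalty (crash)
and a polar-interaction contribution can feed the pipeline.  Pose geometry
is carried either as precomputed pocket-occupancy flags (the canonical
dialect: occupancy of the phosphotyrosine pocket pY+0 and the hydrophobic
side-pocket pY-X of a STAT SH2 domain) or as explicit heavy-atom
coordinates, from which occupancy is derived geometrically.

Stability tables carry per-complex binding free-enthalpy estimates (ΔG°,
kcal/mol; more negative = more stable) for wild-type and point-mutant
targets, used for the alanine-scanning impairment comparison.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "IntegrityError",
    "ConfigurationError",
    "CompoundRecord",
    "PoseRecord",
    "PocketDefinition",
    "StabilityRecord",
    "read_pose_table",
    "write_pose_table",
    "read_stability_table",
    "stability_pairs",
    "read_compound_table",
    "write_compound_table",
]


class FormatError(ValueError):
    """A table does not conform to the declared column layout."""


class IntegrityError(ValueError):
    """A table parses but violates a semantic invariant (duplicates, bad signs)."""


class ConfigurationError(ValueError):
    """An operation was invoked with an inconsistent or unknown configuration."""


_VARIANT_RE = re.compile(r"^[A-Z]\d+[A-Z]$")

#: canonical column order of the flags-dialect pose table
POSE_FLAG_COLUMNS = (
    "compound_id",
    "target_id",
    "pose_rank",
    "bs",
    "crash",
    "polar_score",
    "occupies_py0",
    "occupies_pyx",
)
POSE_COORD_COLUMNS = (
    "compound_id",
    "target_id",
    "pose_rank",
    "bs",
    "crash",
    "polar_score",
    "atom_x",
    "atom_y",
    "atom_z",
)
STABILITY_COLUMNS = ("target_id", "variant", "ligand_id", "dg0_kcal_mol")
COMPOUND_COLUMNS = ("compound_id", "name", "mw", "source_library")

SOURCE_LIBRARIES = ("CL", "CDL", "external")


@dataclass(frozen=True)
class CompoundRecord:
    """One screened compound with metadata and optional similarity annotations.

    ``similarity_to_ref`` maps a reference compound id to a
    ``(sim, rmsd)`` pair: ``sim`` is a unitless shape/feature similarity in
    [0, 1] (1 = the reference itself) and ``rmsd`` the alignment RMSD in Å.
    Both are consumed as inputs; the package does not compute chemical
    similarity.
    """

    compound_id: str
    name: str
    mw: float
    source_library: str = "external"
    similarity_to_ref: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.mw > 0:
            raise IntegrityError(f"{self.compound_id}: mw must be > 0, got {self.mw}")
        if self.source_library not in SOURCE_LIBRARIES:
            raise IntegrityError(
                f"{self.compound_id}: unknown source_library {self.source_library!r}"
            )
        for ref, (sim, rmsd) in self.similarity_to_ref.items():
            if not 0.0 <= sim <= 1.0:
                raise IntegrityError(
                    f"{self.compound_id}: similarity to {ref} out of [0,1]: {sim}"
                )
            if rmsd < 0:
                raise IntegrityError(
                    f"{self.compound_id}: rmsd to {ref} negative: {rmsd}"
                )


@dataclass(frozen=True)
class PoseRecord:
    """One docked conformation of a compound in a target pocket region.

    ``bs`` is the engine's binding score (unitless, higher = stronger
    predicted affinity), ``crash`` the clash/error penalty (≤ 0) and
    ``polar_score`` (≥ 0) the polar-interaction contribution to ``bs``.
    Exactly one of ``flags`` / ``coords`` must be present.
    """

    compound_id: str
    target_id: str
    pose_rank: int
    bs: float
    crash: float
    polar_score: float
    flags: tuple[bool, bool] | None = None  # (occupies_py0, occupies_pyx)
    coords: np.ndarray | None = None  # (n_atoms, 3) heavy-atom coordinates, Å

    def __post_init__(self) -> None:
        if self.pose_rank < 1:
            raise IntegrityError(
                f"{self.compound_id}/{self.target_id}: pose_rank must be ≥ 1"
            )
        if self.crash > 0:
            raise IntegrityError(
                f"{self.compound_id}/{self.target_id} pose {self.pose_rank}: "
                f"crash must be ≤ 0, got {self.crash}"
            )
        if (self.flags is None) == (self.coords is None):
            raise IntegrityError(
                f"{self.compound_id}/{self.target_id} pose {self.pose_rank}: "
                "exactly one of flags/coords must be present"
            )
        if self.coords is not None:
            arr = np.asarray(self.coords, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 1:
                raise IntegrityError("coords must be a non-empty (n_atoms, 3) array")
            object.__setattr__(self, "coords", arr)


@dataclass(frozen=True)
class PocketDefinition:
    """Spherical proxy for an SH2 sub-pocket (pY+0 or pY-X)."""

    pocket_id: str
    centroid: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.pocket_id not in ("pY0", "pYX"):
            raise IntegrityError(f"unknown pocket_id {self.pocket_id!r}")
        if not self.radius > 0:
            raise IntegrityError("pocket radius must be > 0")


@dataclass(frozen=True)
class StabilityRecord:
    """ΔG° of one target(variant)–ligand complex, kcal/mol."""

    target_id: str
    variant: str  # "wt" or a point mutation like "R602A"
    ligand_id: str
    dg0: float

    def __post_init__(self) -> None:
        if self.variant != "wt" and not _VARIANT_RE.match(self.variant):
            raise IntegrityError(
                f"variant {self.variant!r} is neither 'wt' nor <AA><pos><AA>"
            )


# ---------------------------------------------------------------------------
# pose tables
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: tuple[str, ...], path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")


def read_pose_table(path, dialect: str = "flags") -> list[PoseRecord]:
    """Read a TSV pose table in the ``flags`` or ``coords`` dialect.

    In the coords dialect one row is emitted per atom with the pose key
    columns repeated; rows are regrouped into one :class:`PoseRecord` per
    (compound, target, rank).  Output is sorted by
    (compound_id, target_id, pose_rank).
    """
    if dialect not in ("flags", "coords"):
        raise ConfigurationError(f"unknown pose-table dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t")
    required = POSE_FLAG_COLUMNS if dialect == "flags" else POSE_COORD_COLUMNS
    _require_columns(df, required, path)

    records: list[PoseRecord] = []
    if dialect == "flags":
        keys = list(zip(df["compound_id"], df["target_id"], df["pose_rank"]))
        if len(set(keys)) != len(keys):
            dup = pd.Series(keys)[pd.Series(keys).duplicated()].iloc[0]
            raise IntegrityError(f"{path}: duplicate (compound,target,rank) {dup}")
        for row in df.itertuples(index=False):
            records.append(
                PoseRecord(
                    compound_id=str(row.compound_id),
                    target_id=str(row.target_id),
                    pose_rank=int(row.pose_rank),
                    bs=float(row.bs),
                    crash=float(row.crash),
                    polar_score=float(row.polar_score),
                    flags=(bool(int(row.occupies_py0)), bool(int(row.occupies_pyx))),
                )
            )
    else:
        grouped = df.groupby(["compound_id", "target_id", "pose_rank"], sort=False)
        for (cid, tid, rank), sub in grouped:
            scores = sub[["bs", "crash", "polar_score"]].drop_duplicates()
            if len(scores) != 1:
                raise IntegrityError(
                    f"{path}: inconsistent scores within pose {(cid, tid, rank)}"
                )
            records.append(
                PoseRecord(
                    compound_id=str(cid),
                    target_id=str(tid),
                    pose_rank=int(rank),
                    bs=float(sub["bs"].iloc[0]),
                    crash=float(sub["crash"].iloc[0]),
                    polar_score=float(sub["polar_score"].iloc[0]),
                    coords=sub[["atom_x", "atom_y", "atom_z"]].to_numpy(float),
                )
            )
    records.sort(key=lambda r: (r.compound_id, r.target_id, r.pose_rank))
    return records


def write_pose_table(records: list[PoseRecord], path) -> None:
    """Write pose records as TSV; dialect inferred from the records.

    Round-trips losslessly with :func:`read_pose_table`.
    """
    if records and records[0].coords is not None:
        rows = []
        for r in sorted(records, key=lambda r: (r.compound_id, r.target_id, r.pose_rank)):
            for x, y, z in r.coords:
                rows.append(
                    (r.compound_id, r.target_id, r.pose_rank, r.bs, r.crash,
                     r.polar_score, x, y, z)
                )
        df = pd.DataFrame(rows, columns=POSE_COORD_COLUMNS)
    else:
        rows = [
            (r.compound_id, r.target_id, r.pose_rank, r.bs, r.crash, r.polar_score,
             int(r.flags[0]), int(r.flags[1]))
            for r in sorted(records, key=lambda r: (r.compound_id, r.target_id, r.pose_rank))
        ]
        df = pd.DataFrame(rows, columns=POSE_FLAG_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# stability tables
# ---------------------------------------------------------------------------

def read_stability_table(path) -> list[StabilityRecord]:
    """Read a ΔG° TSV (target_id, variant, ligand_id, dg0_kcal_mol)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, STABILITY_COLUMNS, path)
    records = []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        try:
            dg0 = float(row.dg0_kcal_mol)
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}: row {i}: dg0_kcal_mol not numeric: {row.dg0_kcal_mol!r}"
            ) from None
        key = (row.target_id, row.variant, row.ligand_id)
        if key in seen:
            raise IntegrityError(f"{path}: duplicated (target,variant,ligand) {key}")
        seen.add(key)
        records.append(StabilityRecord(str(row.target_id), str(row.variant),
                                       str(row.ligand_id), dg0))
    return records


def stability_pairs(
    records: list[StabilityRecord],
) -> list[tuple[StabilityRecord, StabilityRecord]]:
    """Pair each mutant record with the wild-type row for the same (target, ligand).

    Mutants without a wild-type partner are skipped with a warning.
    """
    wt = {(r.target_id, r.ligand_id): r for r in records if r.variant == "wt"}
    pairs = []
    for r in records:
        if r.variant == "wt":
            continue
        partner = wt.get((r.target_id, r.ligand_id))
        if partner is None:
            warnings.warn(
                f"no wild-type row for mutant {r.variant} of "
                f"({r.target_id}, {r.ligand_id}); pair skipped",
                stacklevel=2,
            )
            continue
        pairs.append((partner, r))
    return pairs


# ---------------------------------------------------------------------------
# compound metadata
# ---------------------------------------------------------------------------

def read_compound_table(path) -> list[CompoundRecord]:
    """Read compound metadata TSV with optional ``sim_<ref>`` / ``rmsd_<ref>`` columns."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, COMPOUND_COLUMNS, path)
    sim_refs = [c[len("sim_"):] for c in df.columns if c.startswith("sim_")]
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        sims: dict[str, tuple[float, float]] = {}
        for ref in sim_refs:
            sim = d.get(f"sim_{ref}")
            if sim is None or (isinstance(sim, float) and np.isnan(sim)):
                continue
            rmsd = d.get(f"rmsd_{ref}", 0.0)
            if rmsd is None or (isinstance(rmsd, float) and np.isnan(rmsd)):
                rmsd = 0.0
            sims[ref] = (float(sim), float(rmsd))
        records.append(
            CompoundRecord(
                compound_id=str(d["compound_id"]),
                name=str(d["name"]),
                mw=float(d["mw"]),
                source_library=str(d["source_library"]),
                similarity_to_ref=sims,
            )
        )
    return records


def write_compound_table(records: list[CompoundRecord], path) -> None:
    refs = sorted({ref for r in records for ref in r.similarity_to_ref})
    rows = []
    for r in records:
        row: dict = {
            "compound_id": r.compound_id,
            "name": r.name,
            "mw": r.mw,
            "source_library": r.source_library,
        }
        for ref in refs:
            if ref in r.similarity_to_ref:
                row[f"sim_{ref}"], row[f"rmsd_{ref}"] = r.similarity_to_ref[ref]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
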