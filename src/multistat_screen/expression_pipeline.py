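"""Microarray-style expression processing and the inhibition-ratio analysis.

Signals are processed in the order: floor non-positive values to 1 →
log2 transform → per-sample background subtraction → quantile
normalization → replicate testing.  A gene is *induced* when its linear
fold change stimulated-vs-control is ≥ 2 with p ≤ 0.05; an induced gene is
*inhibited* by a compound when

    FC(stim) / FC(stim + inhibitor)  ≥  4

with fold changes computed against the untreated control on the normalized
scale.  Lists of inhibited genes are intersected (gene identity = (gene id,
gene name) pair) to find genes commonly inhibited by several compounds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dock_model import ConfigurationError, IntegrityError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneCall",
    "VennResult",
    "floor_negatives",
    "log_transform",
    "subtract_background",
    "quantile_normalize",
    "replicate_test",
    "induced_genes",
    "inhibition_call",
    "common_inhibited",
    "run_expression_pipeline",
]

Gene = tuple[str, str]  # (gene_id, gene_name)


class ExpressionMatrix:
    """Genes × samples signal matrix with replicate structure.

    Wraps a DataFrame whose row index is (gene_id, gene_name) and whose
    column index is (condition, replicate).  Values are signal intensities
    in arbitrary fluorescence units (raw scale on input, log2 scale after
    :func:`log_transform`).
    """

    def __init__(self, data: pd.DataFrame):
        if data.isna().any().any():
            raise IntegrityError("expression matrix contains missing cells")
        if data.index.nlevels != 2 or data.columns.nlevels != 2:
            raise IntegrityError(
                "expect (gene_id, gene_name) rows and (condition, replicate) columns"
            )
        self.data = data

    @property
    def genes(self) -> list[Gene]:
        return list(self.data.index)

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values(0)))

    def replicates(self, condition: str) -> pd.DataFrame:
        return self.data[condition]

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(
            pd.DataFrame(values, index=self.data.index, columns=self.data.columns)
        )

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        """Read a TSV with gene_id, gene_name, then ``<condition>.<replicate>`` columns."""
        df = pd.read_csv(path, sep="\t")
        for col in ("gene_id", "gene_name"):
            if col not in df.columns:
                raise IntegrityError(f"{path}: missing column {col!r}")
        df = df.set_index(["gene_id", "gene_name"])
        pairs = []
        for col in df.columns:
            cond, _, rep = col.rpartition(".")
            if not cond or not rep.isdigit():
                raise IntegrityError(
                    f"{path}: sample column {col!r} is not <condition>.<replicate>"
                )
            pairs.append((cond, int(rep)))
        df.columns = pd.MultiIndex.from_tuples(pairs, names=["condition", "replicate"])
        return cls(df.astype(float))

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.columns = [f"{c}.{r}" for c, r in out.columns]
        out.reset_index().to_csv(path, sep="\t", index=False)


def floor_negatives(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Replace every signal ≤ 0 by 1 (raw scale), leaving other values unchanged."""
    values = matrix.data.to_numpy(float).copy()
    values[values <= 0] = 1.0
    return matrix.with_values(values)


def log_transform(matrix: ExpressionMatrix, base: int = 2) -> ExpressionMatrix:
    """Elementwise log (base 2 by default); requires strictly positive signals."""
    values = matrix.data.to_numpy(float)
    if (values <= 0).any():
        raise ValueError(
            "log_transform: non-positive signal present; run floor_negatives first"
        )
    return matrix.with_values(np.log(values) / np.log(base))


def subtract_background(
    matrix: ExpressionMatrix,
    method: str = "percentile",
    percentile: float = 5.0,
) -> ExpressionMatrix:
    """Subtract a per-sample offset from a log-scale matrix, flooring at 0.

    ``method="percentile"`` uses the given per-sample signal percentile as
    the offset (a control-probe-free background proxy); ``method="none"``
    is the identity.
    """
    if method == "none":
        return matrix.with_values(matrix.data.to_numpy(float).copy())
    if method != "percentile":
        raise ConfigurationError(f"unknown background method {method!r}")
    values = matrix.data.to_numpy(float)
    offsets = np.percentile(values, percentile, axis=0, keepdims=True)
    return matrix.with_values(np.clip(values - offsets, 0.0, None))


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Classic rank-mean quantile normalization.

    Each sample is sorted, values at each rank are averaged across samples,
    and the averages are assigned back by rank; tied values receive the mean
    of their tied-rank averages.  Afterwards every sample carries the same
    sorted value vector, and the grand mean is preserved.
    """
    values = matrix.data.to_numpy(float)
    n, m = values.shape
    if m == 1:
        warnings.warn("quantile_normalize: single sample, identity", stacklevel=2)
        return matrix.with_values(values.copy())
    rank_means = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(m):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = rank_means
        # ties receive the mean of the rank means spanned by the tied block,
        # which also preserves the grand mean exactly
        out[:, j] = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
    return matrix.with_values(out)


def replicate_test(
    matrix: ExpressionMatrix,
    condition_a: str,
    condition_b: str,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-gene fold change and t-test p-value between two conditions.

    Operates on a log2-scale matrix: the linear fold change is
    2**(mean_b − mean_a).  The p-value comes from a two-sample t-test on the
    log2 replicate signals; with two replicates per condition the pooled
    variance test (default) retains usable power, while ``equal_var=False``
    switches to Welch.  Degenerate zero-variance genes get p = 1 when the
    means agree and p = 0 otherwise.
    """
    a = matrix.replicates(condition_a).to_numpy(float)
    b = matrix.replicates(condition_b).to_numpy(float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("replicate_test: need ≥ 2 replicates per condition")
    diff = b.mean(axis=1) - a.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # near-constant genes
        _, p = stats.ttest_ind(b, a, axis=1, equal_var=equal_var)
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate, np.where(diff == 0.0, 1.0, 0.0), p)
    return pd.DataFrame(
        {"fc": np.exp2(diff), "p": p}, index=matrix.data.index
    )


def induced_genes(
    calls: pd.DataFrame, fc_threshold: float = 2.0, p_threshold: float = 0.05
) -> set[Gene]:
    """Genes with fold change ≥ fc_threshold AND p ≤ p_threshold (inclusive)."""
    mask = (calls["fc"] >= fc_threshold) & (calls["p"] <= p_threshold)
    return set(calls.index[mask])


def inhibition_call(
    fc_stim: float, fc_stim_inh: float, ratio_threshold: float = 4.0
) -> tuple[float, bool]:
    """FC-ratio inhibition criterion for one gene and one inhibitor.

    ratio = FC(stim) / FC(stim + inhibitor); the gene is called inhibited
    when ratio ≥ ratio_threshold (inclusive).
    """
    if not fc_stim_inh > 0:
        raise ValueError("inhibition_call: fc_stim_inh must be > 0")
    ratio = fc_stim / fc_stim_inh
    return ratio, ratio >= ratio_threshold


@dataclass
class VennResult:
    """Region decomposition of several gene sets."""

    region_counts: dict[frozenset, int]
    intersection: set[Gene]

    def count(self, *names: str) -> int:
        """Count of the exclusive region belonging to exactly these sets."""
        return self.region_counts.get(frozenset(names), 0)


def common_inhibited(sets: dict[str, set[Gene]]) -> VennResult:
    """All 2^k − 1 exclusive Venn regions and the full intersection.

    Gene identity is the (gene_id, gene_name) pair; the same gene_id
    appearing with different names across sets is an integrity error.
    """
    if len(sets) < 2:
        raise ValueError("common_inhibited: need ≥ 2 sets")
    names_by_id: dict[str, set[str]] = {}
    for genes in sets.values():
        for gid, gname in genes:
            names_by_id.setdefault(gid, set()).add(gname)
    offenders = {gid: names for gid, names in names_by_id.items() if len(names) > 1}
    if offenders:
        raise IntegrityError(f"inconsistent gene id/name pairing: {offenders}")

    keys = sorted(sets)
    regions: dict[frozenset, int] = {}
    union = set().union(*sets.values())
    for gene in union:
        members = frozenset(k for k in keys if gene in sets[k])
        regions[members] = regions.get(members, 0) + 1
    intersection = set.intersection(*(sets[k] for k in keys))
    return VennResult(region_counts=regions, intersection=intersection)


@dataclass
class GeneCall:
    """Full per-gene verdict of the expression pipeline."""

    gene_id: str
    gene_name: str
    fc_stim: float
    p_value: float
    induced: bool
    inhibition_ratio: dict[str, float] = field(default_factory=dict)
    inhibited_by: set[str] = field(default_factory=set)


@dataclass
class ExpressionResult:
    calls: list[GeneCall]
    induced: set[Gene]
    inhibited: dict[str, set[Gene]]
    venn: VennResult | None
    common: set[Gene]


def run_expression_pipeline(
    matrix: ExpressionMatrix,
    control: str,
    stim: str,
    inhibitor_conditions: dict[str, str],
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    ratio_threshold: float = 4.0,
    background: str = "percentile",
    equal_var: bool = True,
) -> ExpressionResult:
    """Floor → log2 → background → quantile → induction filter → FC-ratio calls.

    ``inhibitor_conditions`` maps an inhibitor name to the condition label of
    its stim+inhibitor arm.  The ratio criterion is applied only to genes
    already passing the induction filter.
    """
    m = quantile_normalize(
        subtract_background(log_transform(floor_negatives(matrix)), method=background)
    )
    stim_stats = replicate_test(m, control, stim, equal_var=equal_var)
    induced = induced_genes(stim_stats, fc_threshold, p_threshold)

    inh_fc = {
        name: replicate_test(m, control, cond, equal_var=equal_var)["fc"]
        for name, cond in inhibitor_conditions.items()
    }
    inhibited: dict[str, set[Gene]] = {name: set() for name in inhibitor_conditions}
    calls: list[GeneCall] = []
    for gene in m.genes:
        fc_s = float(stim_stats.loc[gene, "fc"])
        call = GeneCall(
            gene_id=gene[0],
            gene_name=gene[1],
            fc_stim=fc_s,
            p_value=float(stim_stats.loc[gene, "p"]),
            induced=gene in induced,
        )
        if call.induced:
            for name in inhibitor_conditions:
                ratio, is_inh = inhibition_call(
                    fc_s, float(inh_fc[name].loc[gene]), ratio_threshold
                )
                call.inhibition_ratio[name] = ratio
                if is_inh:
                    call.inhibited_by.add(name)
                    inhibited[name].add(gene)
        calls.append(call)

    venn = common_inhibited(inhibited) if len(inhibited) >= 2 else None
    common = venn.intersection if venn else next(iter(inhibited.values()), set())
    return ExpressionResult(
        calls=calls, induced=induced, inhibited=inhibited, venn=venn, common=common
    )
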