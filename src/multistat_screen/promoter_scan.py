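"""PWM promoter scanning with a min–max normalized matrix similarity score.

A position frequency matrix (PFM) is turned into log2 odds weights against
a uniform background,

    w[i, b] = log2( (count[i, b] + q) / (total[i] + 4q) / 0.25 ),

with pseudocount q.  A window of the matrix width is scored by summing the
weights of its letters; the *matrix similarity score* rescales that sum to
[0, 1] by the minimal/maximal achievable window scores,

    MSS = (S − S_min) / (S_max − S_min),

so the consensus sequence scores exactly 1 and the per-position worst
sequence exactly 0.  Promoters (the window around the transcription start
site, by default 950 bp upstream and 50 bp downstream) are scanned on both
strands; a binding-site class (ISRE, GAS, NF-κB) is called present when any
of its matrices reaches the class threshold (0.85 for ISRE/GAS, 0.90 for
NF-κB), and each gene is assigned to one of the eight presence/absence
combination categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import motifs as bio_motifs

from .dock_model import FormatError, IntegrityError

logger = logging.getLogger(__name__)

__all__ = [
    "PWMModel",
    "SiteClassConfig",
    "ScanHit",
    "GeneSiteCall",
    "CategorySummary",
    "DEFAULT_CLASS_THRESHOLDS",
    "CATEGORIES",
    "read_pfm",
    "pwm_from_counts",
    "matrix_similarity_score",
    "scan_promoter",
    "site_class_call",
    "category_counts",
    "reverse_complement",
]

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DEFAULT_CLASS_THRESHOLDS = {"ISRE": 0.85, "GAS": 0.85, "NFKB": 0.90}

CATEGORIES = (
    "none",
    "ISRE only",
    "GAS only",
    "NFKB only",
    "ISRE+GAS",
    "ISRE+NFKB",
    "GAS+NFKB",
    "ISRE+GAS+NFKB",
)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWMModel:
    """A PFM with derived log2 weights and min/max achievable window scores."""

    matrix_id: str
    counts: np.ndarray  # (width, 4) nonnegative counts, columns = positions
    pseudocount: float | None = None  # default: 1% of the per-position total

    weights: np.ndarray = field(init=False, repr=False)
    s_min: float = field(init=False)
    s_max: float = field(init=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise FormatError("counts must be a (width, 4) array over ACGT")
        if counts.shape[0] < 4:
            raise IntegrityError(f"{self.matrix_id}: width must be ≥ 4")
        if (counts < 0).any():
            raise FormatError(f"{self.matrix_id}: negative counts")
        if (counts.sum(axis=1) <= 0).any():
            raise IntegrityError(f"{self.matrix_id}: a position has no positive count")
        self.counts = counts
        totals = counts.sum(axis=1, keepdims=True)
        if self.pseudocount is None:
            self.pseudocount = 0.01 * float(totals.mean())
        if not self.pseudocount > 0:
            raise IntegrityError("pseudocount must be > 0")
        q = self.pseudocount
        probs = (counts + q) / (totals + 4.0 * q)
        self.weights = np.log2(probs / 0.25)
        self.s_min = float(self.weights.min(axis=1).sum())
        self.s_max = float(self.weights.max(axis=1).sum())
        if not self.s_min < self.s_max:
            raise IntegrityError(
                f"{self.matrix_id}: degenerate matrix (s_min == s_max); "
                "an all-uniform PFM carries no information"
            )

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.weights.argmax(axis=1))

    @property
    def anticonsensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.weights.argmin(axis=1))

    def window_scores(self, seq: str) -> np.ndarray:
        """Raw summed-weight score of every window of ``seq`` (vectorized).

        Ambiguous letters (N or anything outside ACGT) score the column
        minimum at their position.
        """
        w = self.width
        if len(seq) < w:
            raise ValueError(f"sequence shorter than matrix width {w}")
        idx = np.fromiter(
            (_BASE_INDEX.get(c, 4) for c in seq.upper()), dtype=np.intp, count=len(seq)
        )
        ext = np.hstack([self.weights, self.weights.min(axis=1, keepdims=True)])
        windows = np.lib.stride_tricks.sliding_window_view(idx, w)
        return ext[np.arange(w), windows].sum(axis=1)


def pwm_from_counts(matrix_id: str, counts, pseudocount: float | None = None) -> PWMModel:
    """Build a model from a plain counts structure (rows = positions over ACGT)."""
    return PWMModel(matrix_id=matrix_id, counts=np.asarray(counts, float),
                    pseudocount=pseudocount)


def read_pfm(path, pseudocount: float | None = None) -> PWMModel:
    """Read a JASPAR-style PFM file (with or without base-row labels)."""
    with open(path) as fh:
        try:
            motif = bio_motifs.read(fh, "jaspar")
        except Exception:
            fh.seek(0)
            try:
                motif = bio_motifs.read(fh, "pfm")
            except Exception as e:
                raise FormatError(f"{path}: not a readable PFM: {e}") from None
    counts = np.array([[motif.counts[b][i] for b in ALPHABET]
                       for i in range(motif.length)], dtype=float)
    matrix_id = getattr(motif, "matrix_id", None) or motif.name or str(path)
    return PWMModel(matrix_id=str(matrix_id), counts=counts, pseudocount=pseudocount)


def matrix_similarity_score(pwm: PWMModel, window: str) -> float:
    """Min–max normalized window score in [0, 1]; 1 at the consensus."""
    if len(window) != pwm.width:
        raise ValueError(
            f"window length {len(window)} != matrix width {pwm.width}"
        )
    s = float(pwm.window_scores(window)[0])
    return (s - pwm.s_min) / (pwm.s_max - pwm.s_min)


@dataclass(frozen=True)
class ScanHit:
    """Best match of one matrix in one promoter."""

    score: float
    offset: int  # TSS-relative position of the window start (0 = TSS)
    strand: str  # "+" or "-"
    passed: bool


def scan_promoter(
    seq: str, pwm: PWMModel, threshold: float, upstream: int = 950
) -> ScanHit:
    """Best matrix-similarity hit over both strands of a promoter window.

    ``seq`` covers [−upstream, len(seq) − upstream) relative to the TSS
    (position 0).  The minus strand is scanned as the reverse complement;
    its hits are reported at the plus-strand start coordinate of the matched
    window.  Ties go to the leftmost offset, then to the plus strand.
    ``passed`` is score ≥ threshold (inclusive).
    """
    if len(seq) < pwm.width:
        raise ValueError("sequence shorter than matrix width")
    span = pwm.s_max - pwm.s_min
    fwd = (pwm.window_scores(seq) - pwm.s_min) / span
    rev_raw = (pwm.window_scores(reverse_complement(seq)) - pwm.s_min) / span
    rev = rev_raw[::-1]  # re-index so rev[i] scores the window starting at i

    best_score = float(max(fwd.max(), rev.max()))
    hits_f = np.flatnonzero(fwd == best_score)
    hits_r = np.flatnonzero(rev == best_score)
    first_f = hits_f[0] if hits_f.size else len(fwd)
    first_r = hits_r[0] if hits_r.size else len(rev)
    if first_f <= first_r:  # plus strand wins exact positional ties
        offset, strand = int(first_f), "+"
    else:
        offset, strand = int(first_r), "-"
    return ScanHit(
        score=float(best_score),
        offset=offset - upstream,
        strand=strand,
        passed=bool(best_score >= threshold),
    )


@dataclass
class SiteClassConfig:
    """One binding-site class: its matrices and its similarity threshold."""

    class_id: str  # ISRE, GAS or NFKB
    matrix_ids: list[str]
    threshold: float

    def __post_init__(self) -> None:
        if self.class_id not in ("ISRE", "GAS", "NFKB"):
            raise IntegrityError(f"unknown site class {self.class_id!r}")
        if not 0.0 < self.threshold <= 1.0:
            raise IntegrityError("class threshold must be in (0, 1]")


@dataclass
class GeneSiteCall:
    gene_id: str
    best: dict[str, ScanHit]  # per class
    has_isre: bool
    has_gas: bool
    has_nfkb: bool
    category: str

    @staticmethod
    def category_of(has_isre: bool, has_gas: bool, has_nfkb: bool) -> str:
        parts = [name for name, flag in
                 (("ISRE", has_isre), ("GAS", has_gas), ("NFKB", has_nfkb)) if flag]
        return "+".join(parts) + (" only" if len(parts) == 1 else "") if parts else "none"


def site_class_call(
    gene_id: str,
    seq: str,
    classes: list[SiteClassConfig],
    pwms: dict[str, PWMModel],
    upstream: int = 950,
) -> GeneSiteCall:
    """Scan one promoter with every class matrix; any-matrix rule per class."""
    best: dict[str, ScanHit] = {}
    present: dict[str, bool] = {}
    for cfg in classes:
        hits = [
            scan_promoter(seq, pwms[mid], cfg.threshold, upstream)
            for mid in cfg.matrix_ids
        ]
        top = max(hits, key=lambda h: h.score)
        best[cfg.class_id] = top
        present[cfg.class_id] = any(h.passed for h in hits)
    has_isre = present.get("ISRE", False)
    has_gas = present.get("GAS", False)
    has_nfkb = present.get("NFKB", False)
    return GeneSiteCall(
        gene_id=gene_id,
        best=best,
        has_isre=has_isre,
        has_gas=has_gas,
        has_nfkb=has_nfkb,
        category=GeneSiteCall.category_of(has_isre, has_gas, has_nfkb),
    )


@dataclass
class CategorySummary:
    """Dense eight-category census of a gene cohort plus class-set Venn regions."""

    counts: dict[str, int]
    pct_of_all: dict[str, float]
    pct_of_with_site: dict[str, float]
    n_genes: int
    n_with_site: int
    venn_regions: dict[frozenset, int]


def category_counts(calls: list[GeneSiteCall]) -> CategorySummary:
    """Counts and percentages per combination category.

    Percentages are reported both over all genes and over the genes carrying
    at least one site (the natural denominator when the siteless group is
    not displayed).
    """
    if not calls:
        raise ValueError("category_counts: no calls")
    counts = {cat: 0 for cat in CATEGORIES}
    for c in calls:
        counts[c.category] += 1
    n = len(calls)
    n_with = n - counts["none"]
    pct_all = {cat: 100.0 * k / n for cat, k in counts.items()}
    pct_with = {
        cat: (100.0 * k / n_with if n_with else 0.0)
        for cat, k in counts.items() if cat != "none"
    }
    venn: dict[frozenset, int] = {}
    for c in calls:
        members = frozenset(
            name for name, flag in
            (("ISRE", c.has_isre), ("GAS", c.has_gas), ("NFKB", c.has_nfkb)) if flag
        )
        if members:
            venn[members] = venn.get(members, 0) + 1
    return CategorySummary(
        counts=counts,
        pct_of_all=pct_all,
        pct_of_with_site=pct_with,
        n_genes=n,
        n_with_site=n_with,
        venn_regions=venn,
    )
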