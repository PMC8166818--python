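"""Developmental expression trend comparison.

Expression of duplicated Notch ligands is compared across ordered
developmental stages (zygote, cleavage, gastrula, trochophore, ...).
Because RPKM/FPKM values are only comparable as within-gene trends, all
comparisons are correlations of stage profiles — Spearman rank
correlation by default — and the verdicts are threshold calls:

* ``similar``        score >= similarity_threshold (default +0.5)
* ``complementary``  score <= complementarity_threshold (default -0.5)
* ``unrelated``      otherwise

"Complementary expression" of paralogs (the Delta1/Delta2 pattern, where
one paralog's high-expression stages are the other's low ones) has no
quantitative definition in the comparative literature; the rank-
correlation operationalisation and its threshold are surfaced in every
report rather than hidden.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .errors import ValidationError

MIN_STAGES = 4  # rank correlation on fewer stages is degenerate


@dataclasses.dataclass
class ExpressionMatrix:
    """Genes x ordered developmental stages, nonnegative RPKM/FPKM values."""

    values: pd.DataFrame  # index: gene ids; columns: stage labels in time order
    unit: str = "RPKM"  # RPKM | FPKM | other

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate stage labels in expression matrix")
        if (self.values.values < 0).any():
            raise ValidationError("negative expression values")
        if self.unit not in ("RPKM", "FPKM", "other"):
            raise ValidationError(f"unknown unit tag {self.unit!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def stages(self) -> list[str]:
        return list(self.values.columns)

    def profile(self, gene: str) -> np.ndarray:
        if gene not in self.values.index:
            raise ValidationError(f"gene {gene!r} not in expression matrix")
        return self.values.loc[gene].to_numpy(dtype=float)


@dataclasses.dataclass
class NormalizedMatrix:
    values: pd.DataFrame  # constant rows excluded
    method: str
    flagged_constant: list  # gene ids excluded as constant


def normalize_trend(matrix: ExpressionMatrix, method: str = "zscore") -> NormalizedMatrix:
    """Per-gene trend normalisation: zscore, minmax or rank.

    Constant rows are flagged and excluded (their trend is undefined),
    never silently zeroed.
    """
    if method not in ("zscore", "minmax", "rank"):
        raise ValidationError(f"unknown normalisation method {method!r}")
    df = matrix.values
    constant = [g for g in df.index if df.loc[g].nunique() <= 1]
    work = df.drop(index=constant)
    if method == "zscore":
        out = work.sub(work.mean(axis=1), axis=0).div(work.std(axis=1, ddof=0), axis=0)
    elif method == "minmax":
        lo, hi = work.min(axis=1), work.max(axis=1)
        out = work.sub(lo, axis=0).div(hi - lo, axis=0)
    else:
        out = work.rank(axis=1, method="average")
    return NormalizedMatrix(out, method, constant)


@dataclasses.dataclass
class ProfileComparison:
    gene_a: str
    gene_b: str
    method: str  # spearman | pearson
    score: float
    relation: str  # similar | complementary | unrelated
    n_stages: int


def _correlate(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if method == "spearman":
        rho = stats.spearmanr(a, b).statistic
    elif method == "pearson":
        rho = stats.pearsonr(a, b).statistic
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    return float(rho)


def _relation(score: float, cfg: RunConfig) -> str:
    if score >= cfg.similarity_threshold:
        return "similar"
    if score <= cfg.complementarity_threshold:
        return "complementary"
    return "unrelated"


def profile_similarity(
    a: Sequence[float],
    b: Sequence[float],
    method: str = "spearman",
    config: RunConfig | None = None,
    gene_a: str = "a",
    gene_b: str = "b",
) -> ProfileComparison:
    """Correlate two stage profiles and call their relation.

    Profiles must cover the same stages in the same order; at least four
    stages are required for a meaningful rank correlation.
    """
    cfg = config or RunConfig()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("profiles cover different stage sets")
    if a.size < MIN_STAGES:
        raise ValidationError(f"need >= {MIN_STAGES} stages, got {a.size}")
    if np.unique(a).size <= 1 or np.unique(b).size <= 1:
        raise ValidationError("constant profile: correlation undefined")
    score = _correlate(a, b, method)
    return ProfileComparison(gene_a, gene_b, method, score, _relation(score, cfg), a.size)


def nearest_profile(
    target: str,
    candidates: Sequence[str],
    matrix: ExpressionMatrix,
    method: str = "spearman",
    config: RunConfig | None = None,
) -> list[ProfileComparison]:
    """Rank candidate genes by descending similarity to the target profile.

    Constant-profile candidates are dropped with a diagnostic; exact score
    ties keep deterministic gene-id order.
    """
    cfg = config or RunConfig()
    if target in candidates:
        raise ValidationError("target gene must not be among the candidates")
    t = matrix.profile(target)
    if np.unique(t).size <= 1:
        raise ValidationError(f"target {target!r} has a constant profile")
    comparisons = []
    for gene in candidates:
        p = matrix.profile(gene)
        if np.unique(p).size <= 1:
            continue  # constant-flagged candidate
        comparisons.append(
            profile_similarity(t, p, method, cfg, gene_a=target, gene_b=gene)
        )
    comparisons.sort(key=lambda c: (-c.score, c.gene_b))
    return comparisons


def stage_peak_report(
    matrix: ExpressionMatrix,
    gene_set: Sequence[str] | None = None,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Per-gene peak stage and enrichment ratio.

    The ratio is (max + 1) / (median + 1) on raw values — the +1
    pseudocount avoids division by zero for silent genes and is noted in
    the column name.  Argmax ties list every tied stage.  Genes whose
    median raw value is below ``low_expression_floor`` carry a low-
    expression flag; no biological claim is attached to it.
    """
    cfg = config or RunConfig()
    genes = list(gene_set) if gene_set is not None else matrix.genes
    rows = []
    for gene in genes:
        p = matrix.profile(gene)
        peak = p.max()
        tied = [str(s) for s, v in zip(matrix.stages, p) if v == peak]
        median = float(np.median(p))
        rows.append(
            {
                "gene": gene,
                "peak_stage": ";".join(tied),
                "max_over_median_pseudo1": (peak + 1.0) / (median + 1.0),
                "low_expression": int(median < cfg.low_expression_floor),
            }
        )
    return pd.DataFrame(
        rows, columns=["gene", "peak_stage", "max_over_median_pseudo1", "low_expression"]
    )


def comparison_table(comparisons: Sequence[ProfileComparison], cfg: RunConfig) -> pd.DataFrame:
    """TSV-ready table of comparisons with the thresholds surfaced."""
    rows = [
        {
            "gene_a": c.gene_a,
            "gene_b": c.gene_b,
            "method": c.method,
            "score": round(c.score, 6),
            "relation": c.relation,
            "n_stages": c.n_stages,
            "similarity_threshold": cfg.similarity_threshold,
            "complementarity_threshold": cfg.complementarity_threshold,
        }
        for c in comparisons
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_a", "gene_b", "method", "score", "relation", "n_stages",
            "similarity_threshold", "complementarity_threshold",
        ],
    )
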