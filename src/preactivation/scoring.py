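"""Pathway-signature derivation, single-sample scoring and stratification.

A signature is derived as the top-N genes ranked by log2 fold change in a
contrast (typically: most down-regulated under pathway inhibition, so the
signature tracks pathway activity).  A sample's score is the plain sum of
its log2 expression over the signature genes present in the cohort; no
gene standardization is applied.  Cohorts are stratified into high / low
tails of the score distribution, and signature–signature association is
tested against a Monte Carlo null of size-matched random gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneSet

__all__ = [
    "ScoreTable",
    "derive_signature",
    "score_cohort",
    "stratify",
    "spearman_rho",
    "mc_correlation_pvalue",
]

logger = logging.getLogger(__name__)

COVERAGE_WARN_THRESHOLD = 0.8


@dataclass
class ScoreTable:
    """Per-sample signature scores with optional high/low/mid strata.

    ``coverage`` is the fraction of signature genes found in the cohort
    matrix.  After :func:`stratify`, ``strata`` maps every sample to one of
    {"high", "low", "mid"} with |high| = |low| = floor(fraction·n).
    """

    scores: pd.Series
    coverage: float = 1.0
    strata: pd.Series | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise ValueError("scores must be finite")

    @property
    def samples(self) -> list[str]:
        return list(self.scores.index)

    def samples_in(self, label: str) -> list[str]:
        if self.strata is None:
            raise ValueError("strata not assigned; call stratify() first")
        return list(self.strata.index[self.strata == label])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"score": self.scores})
        if self.strata is not None:
            df["stratum"] = self.strata
        df.index.name = "sample_id"
        return df


def derive_signature(
    mat: ExpressionMatrix,
    treated: Sequence[str],
    control: Sequence[str],
    direction: str = "down",
    top_n: int = 500,
    name: str = "signature",
) -> GeneSet:
    """Top-N genes by log2 fold change (treated − control).

    ``direction="down"`` ranks ascending (most down-regulated first);
    ``"up"`` descending.  Ties are broken by gene id lexicographically so
    the result is deterministic.
    """
    from .diffexp import ContrastSpec, log2_fold_changes

    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    if top_n > mat.n_genes:
        raise ValueError(f"top_n={top_n} exceeds number of genes {mat.n_genes}")
    if top_n < 1:
        raise ValueError("top_n must be positive")
    fc = log2_fold_changes(mat, ContrastSpec(tuple(treated), tuple(control)))
    df = pd.DataFrame({"fc": fc, "gene": fc.index.astype(str)})
    ascending = direction == "down"
    ranked = df.sort_values(["fc", "gene"], ascending=[ascending, True])
    members = frozenset(ranked.index[:top_n])
    return GeneSet(name=name, members=members)


def score_cohort(cohort: ExpressionMatrix, signature: GeneSet) -> ScoreTable:
    """Sum of log2 expression over the signature genes, per sample.

    Signature genes missing from the cohort are dropped; the retained
    fraction is reported as coverage and a warning is logged below
    :data:`COVERAGE_WARN_THRESHOLD`.
    """
    signature.require_nonempty()
    present = sorted(signature.members & set(cohort.values.index))
    coverage = len(present) / len(signature)
    if not present:
        raise ValueError(
            f"signature {signature.name!r} has zero coverage in the cohort"
        )
    if coverage < COVERAGE_WARN_THRESHOLD:
        logger.warning(
            "signature %r coverage %.2f below %.2f (%d of %d genes present)",
            signature.name, coverage, COVERAGE_WARN_THRESHOLD,
            len(present), len(signature),
        )
    scores = cohort.values.loc[present].sum(axis=0)
    return ScoreTable(scores=scores.astype(float), coverage=coverage)


def stratify(scores: ScoreTable, fraction: float = 0.15) -> ScoreTable:
    """Label the top/bottom ``fraction`` of samples "high"/"low", rest "mid".

    Both tails get exactly floor(fraction·n) samples.  Score ties at a
    boundary are broken by sample id lexicographically (ascending), making
    the labeling deterministic.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    n = len(scores.scores)
    if n < int(np.ceil(1 / fraction)):
        raise ValueError(
            f"too few samples ({n}) to take a {fraction:.0%} tail"
        )
    m = int(np.floor(fraction * n))
    df = pd.DataFrame(
        {"score": scores.scores, "sample": scores.scores.index.astype(str)}
    )
    ordered = df.sort_values(["score", "sample"], ascending=[True, True]).index
    strata = pd.Series("mid", index=scores.scores.index, dtype=object)
    strata.loc[ordered[:m]] = "low"
    strata.loc[ordered[n - m:]] = "high"
    return replace(scores, strata=strata)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of midranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


def _rank_rows(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=-1)


def mc_correlation_pvalue(
    cohort: ExpressionMatrix,
    signature_a: GeneSet,
    scores_b: ScoreTable,
    reps: int = 1000,
    seed: int = 0,
    chunk: int = 64,
) -> tuple[float, float]:
    """Spearman correlation of two signature scores with a Monte Carlo p.

    The observed statistic is ``spearman_rho(score(signature_a), scores_b)``.
    The null resamples ``reps`` gene sets of the same effective size
    (|signature_a ∩ cohort genes|) uniformly without replacement from the
    cohort's measured genes, scores each, and correlates it with
    ``scores_b``.  The two-sided empirical p uses the add-one rule:
    p = (1 + #{|rho_null| ≥ |rho_obs|}) / (reps + 1).

    Fully reproducible for a given ``seed``.
    """
    if reps < 100:
        raise ValueError("reps must be at least 100")
    table_a = score_cohort(cohort, signature_a)
    b = scores_b.scores.reindex(table_a.scores.index)
    if b.isna().any():
        missing = list(b.index[b.isna()])[:10]
        raise ValueError(f"scores_b missing cohort samples: {missing}")
    rho_obs = spearman_rho(table_a.scores.to_numpy(), b.to_numpy())

    rng = np.random.default_rng(seed)
    vals = cohort.values.to_numpy(dtype=float)
    g, s = vals.shape
    m = len(signature_a.members & set(cohort.values.index))
    b_rank = stats.rankdata(b.to_numpy())
    b_centered = b_rank - b_rank.mean()
    b_norm = np.linalg.norm(b_centered)

    null = np.empty(reps)
    done = 0
    while done < reps:
        take = min(chunk, reps - done)
        idx = np.empty((take, m), dtype=np.intp)
        for r in range(take):
            idx[r] = rng.choice(g, size=m, replace=False)
        null_scores = vals[idx.ravel()].reshape(take, m, s).sum(axis=1)
        ranks = _rank_rows(null_scores)
        centered = ranks - ranks.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centered, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            rhos = centered @ b_centered / (norms * b_norm)
        null[done:done + take] = np.nan_to_num(rhos, nan=0.0)
        done += take

    exceed = int(np.count_nonzero(np.abs(null) >= abs(rho_obs)))
    p = (1 + exceed) / (reps + 1)
    return rho_obs, p
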