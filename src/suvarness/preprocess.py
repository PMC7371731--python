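"""Matrix standardization, cohort merging, signature scoring and PCA.

The conventions here mirror common expression-analysis practice: gene-wise
z-scoring uses the n-1 (sample) standard deviation; cohorts are
standardized independently before being joined on their shared genes, so
that platform- and cohort-level location/scale differences cancel; extreme
z-scores are clipped only for heatmap-style export, never before any
clustering or scoring step.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet

log = logging.getLogger(__name__)

__all__ = [
    "row_standardize",
    "clip_z",
    "combine_cohorts",
    "signature_score",
    "median_split",
    "pca_project",
]


def row_standardize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Center each gene row to mean 0 and scale to unit (n-1) SD.

    Zero-variance genes carry no between-sample information and are dropped
    with a warning rather than producing non-finite z-scores.
    """
    if m.shape[1] < 2:
        raise ValueError("row standardization needs at least 2 samples")
    values = m.values
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(m.gene_ids, keep) if not k]
        log.warning("dropping %d constant gene rows: %s", len(dropped), dropped[:5])
    values = values[keep]
    centered = values - values.mean(axis=1, keepdims=True)
    z = centered / sd[keep][:, None]
    return ExpressionMatrix(
        pd.DataFrame(z, index=np.asarray(m.gene_ids)[keep], columns=m.sample_ids)
    )


def clip_z(m: ExpressionMatrix, lo: float = -5.0, hi: float = 5.0) -> ExpressionMatrix:
    """Clip values into [lo, hi] — presentation only, never before clustering."""
    if lo >= hi:
        raise ValueError(f"invalid clip interval [{lo}, {hi}]")
    return ExpressionMatrix(m.data.clip(lower=lo, upper=hi))


def combine_cohorts(
    ms: Sequence[ExpressionMatrix],
    cohort_names: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Standardize each cohort gene-wise, then join on the gene intersection.

    Sample IDs are prefixed with their cohort name so the combined matrix
    keeps unique columns. Gene order follows the first cohort.
    """
    if len(ms) < 2:
        raise ValueError("combining requires at least 2 cohorts")
    if cohort_names is None:
        cohort_names = [f"cohort{i + 1}" for i in range(len(ms))]
    if len(cohort_names) != len(ms):
        raise ValueError("one cohort name per matrix required")
    standardized = [row_standardize(m) for m in ms]
    shared = set(standardized[0].gene_ids)
    for m in standardized[1:]:
        shared &= set(m.gene_ids)
    if not shared:
        raise ValueError("cohorts share no genes after standardization")
    gene_order = [g for g in standardized[0].gene_ids if g in shared]
    blocks = []
    for name, m in zip(cohort_names, standardized):
        block = m.data.loc[gene_order]
        block.columns = [f"{name}:{s}" for s in block.columns]
        blocks.append(block)
    return ExpressionMatrix(pd.concat(blocks, axis=1))


def signature_score(m: ExpressionMatrix, gs: GeneSet | Iterable[str]) -> pd.Series:
    """Per-sample unweighted mean expression over the present set members."""
    members = gs.members if isinstance(gs, GeneSet) else frozenset(gs)
    present = [g for g in m.gene_ids if g in members]
    if not present:
        raise ValueError("no gene-set member present in the matrix")
    missing = members - set(present)
    if missing:
        log.warning("%d signature genes absent from matrix: %s",
                    len(missing), sorted(missing)[:5])
    scores = m.data.loc[present].mean(axis=0)
    scores.name = gs.name if isinstance(gs, GeneSet) else "signature_score"
    return scores


def median_split(scores: pd.Series) -> pd.Series:
    """Label samples 'above'/'below' the cohort median score.

    Scores exactly at the median go to 'below' so the rule is deterministic;
    an all-tied vector yields all-'below' with a warning.
    """
    if len(scores) < 2:
        raise ValueError("median split needs at least 2 samples")
    med = float(scores.median())
    labels = pd.Series(
        np.where(scores.to_numpy() > med, "above", "below"),
        index=scores.index,
        name="median_split",
    )
    if (labels == "below").all():
        log.warning("all scores at or below the median; no 'above' group")
    return labels


def pca_project(m: ExpressionMatrix, k: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples onto the first k principal axes of the gene space.

    Rows are expected to be standardized by the caller (gene means 0).
    Returns (coordinates: samples x k, explained-variance fractions). The
    sign of each component is fixed so its largest-magnitude gene loading is
    positive, making output independent of the linear-algebra backend.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > min(m.shape):
        raise ValueError(f"k={k} exceeds matrix rank bound {min(m.shape)}")
    X = m.values.T  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    for i in range(k):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]
    coords = U[:, :k] * S[:k]
    total = float((S**2).sum())
    explained = (S[:k] ** 2) / total if total > 0 else np.zeros(k)
    frame = pd.DataFrame(
        coords, index=m.sample_ids, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return frame, explained
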