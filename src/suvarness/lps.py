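"""Linear predictor score (LPS) classification with Bayesian posteriors.

The LPS of a sample is LPS(X) = sum_j a_j x_j over the classifier genes,
with weights a_j equal to the genes' two-group t-statistics estimated on
training data. Class-conditional Gaussians are fitted by method of moments
to the training LPS scores of each class, and a sample's class probability
follows from Bayes' rule:

    P(k | s) = pi_k phi(s; mu_k, sigma_k) / sum_l pi_l phi(s; mu_l, sigma_l)

Priors are equal by default. Samples whose maximum posterior falls below a
confidence cut are reported as unclassified, producing the familiar
confident-A / confident-B / intermediate three-band output of
cell-of-origin classification. The posterior of the senescent class,
interpreted as a "TIS score", is further banded at fixed cutoffs 0.8/0.2
into senescence responders, non-responders and unclassifiable samples.

A three-class extension fits one one-vs-rest LPS axis per class and
normalizes the per-axis two-class posteriors; it reduces to the two-class
rule when one class is absent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.model_selection import StratifiedKFold

from .diffexpr import two_sample_t
from .io import ExpressionMatrix

log = logging.getLogger(__name__)

__all__ = [
    "LPSModel",
    "MulticlassLPSModel",
    "fit_lps",
    "lps_score",
    "posterior",
    "fit_lps_multiclass",
    "classify",
    "tenfold_cv",
    "classify_tis_responders",
]

UNCLASSIFIED = "unclassified"
MODEL_FORMAT_VERSION = 1


@dataclass
class LPSModel:
    """Two-class LPS classifier: gene weights + class-conditional Gaussians."""

    classifier_genes: tuple[str, ...]
    weights: np.ndarray
    classes: tuple[str, str]
    means: dict[str, float]
    sds: dict[str, float]
    priors: dict[str, float]
    confidence_cut: float = 0.9
    gene_means: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.classifier_genes) != self.weights.size:
            raise ValueError("one weight per classifier gene required")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if len(self.classes) != 2:
            raise ValueError("LPSModel is two-class; use MulticlassLPSModel")
        for k in self.classes:
            if self.sds[k] <= 0:
                raise ValueError(f"class {k!r} has non-positive LPS score SD")
        total = sum(self.priors.values())
        if not np.isclose(total, 1.0):
            raise ValueError("priors must sum to 1")
        if not 0.5 < self.confidence_cut <= 1.0:
            raise ValueError("confidence_cut must lie in (0.5, 1]")

    def to_dict(self) -> dict:
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "kind": "two_class",
            "classifier_genes": list(self.classifier_genes),
            "weights": [float(w) for w in self.weights],
            "classes": list(self.classes),
            "means": {k: float(v) for k, v in self.means.items()},
            "sds": {k: float(v) for k, v in self.sds.items()},
            "priors": {k: float(v) for k, v in self.priors.items()},
            "confidence_cut": float(self.confidence_cut),
            "gene_means": {k: float(v) for k, v in self.gene_means.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LPSModel":
        return cls(
            classifier_genes=tuple(d["classifier_genes"]),
            weights=np.asarray(d["weights"], dtype=float),
            classes=tuple(d["classes"]),
            means=dict(d["means"]),
            sds=dict(d["sds"]),
            priors=dict(d["priors"]),
            confidence_cut=float(d["confidence_cut"]),
            gene_means=dict(d.get("gene_means", {})),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "LPSModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class MulticlassLPSModel:
    """Three-class LPS: one one-vs-rest axis per class, product-normalized.

    Each axis is a two-class LPSModel with classes (k, "rest"). The final
    posterior for class k is p_k / sum_l p_l where p_k is the two-class
    posterior of k on its own axis.
    """

    axes: dict[str, LPSModel]
    classes: tuple[str, ...]
    confidence_cut: float = 0.9

    def to_dict(self) -> dict:
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "kind": "one_vs_rest",
            "classes": list(self.classes),
            "confidence_cut": float(self.confidence_cut),
            "axes": {k: m.to_dict() for k, m in self.axes.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MulticlassLPSModel":
        return cls(
            axes={k: LPSModel.from_dict(v) for k, v in d["axes"].items()},
            classes=tuple(d["classes"]),
            confidence_cut=float(d["confidence_cut"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "MulticlassLPSModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_lps(
    m: ExpressionMatrix,
    labels: pd.Series | Mapping[str, str],
    n_genes: int = 20,
    priors: dict[str, float] | None = None,
    confidence_cut: float = 0.9,
    groups: tuple[str, str] | None = None,
) -> LPSModel:
    """Fit a two-class LPS model.

    The classifier genes are the top ``n_genes`` by |t| of the training
    comparison class-A vs class-B; their t-statistics become the weights,
    so positive weights mark class-A-high genes. Per-class Gaussians are
    fitted to the training LPS scores by sample mean and (n-1) SD.
    """
    labels = pd.Series(labels).reindex(m.sample_ids)
    de = two_sample_t(m, labels, groups=groups)
    a, b = de.attrs["groups"]
    for cls_name in (a, b):
        if int((labels == cls_name).sum()) < 3:
            raise ValueError(f"class {cls_name!r} needs at least 3 training samples")
    if n_genes > len(de):
        raise ValueError(f"n_genes={n_genes} exceeds {len(de)} testable genes")
    top = de.reindex(de["t_stat"].abs().sort_values(ascending=False, kind="mergesort").index)
    chosen = top.iloc[:n_genes]
    genes = tuple(chosen.index)
    weights = chosen["t_stat"].to_numpy()
    sub = m.data.loc[list(genes)]
    scores = weights @ sub.to_numpy()
    scores = pd.Series(scores, index=m.sample_ids)
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for cls_name in (a, b):
        cls_scores = scores[(labels == cls_name).to_numpy()]
        mu = float(cls_scores.mean())
        sd = float(cls_scores.std(ddof=1))
        if sd <= 0:
            raise ValueError(f"class {cls_name!r} has zero LPS score variance")
        means[cls_name], sds[cls_name] = mu, sd
    if priors is None:
        priors = {a: 0.5, b: 0.5}
    return LPSModel(
        classifier_genes=genes,
        weights=weights,
        classes=(a, b),
        means=means,
        sds=sds,
        priors=priors,
        confidence_cut=confidence_cut,
        gene_means={g: float(mu) for g, mu in sub.mean(axis=1).items()},
    )


def lps_score(
    model: LPSModel,
    m: ExpressionMatrix,
    impute_missing: bool = False,
) -> pd.Series:
    """LPS(X) = sum_j a_j x_j for every sample of ``m``.

    Classifier genes absent from the matrix are an error unless
    ``impute_missing`` substitutes the training mean of each missing gene.
    """
    data = m.data
    missing = [g for g in model.classifier_genes if g not in data.index]
    if missing and not impute_missing:
        raise KeyError(f"classifier genes missing from matrix: {missing[:5]}")
    rows = []
    for g in model.classifier_genes:
        if g in data.index:
            rows.append(data.loc[g].to_numpy())
        else:
            rows.append(np.full(data.shape[1], model.gene_means.get(g, 0.0)))
    X = np.vstack(rows)
    if missing:
        log.warning("imputed %d missing classifier genes with training means", len(missing))
    return pd.Series(model.weights @ X, index=m.sample_ids, name="lps_score")


def posterior(model: LPSModel, score: float | np.ndarray) -> pd.DataFrame | dict[str, float]:
    """Bayes-rule class posteriors for one score or an array of scores.

    Computed in log space for numerical stability far out in the tails.
    Scalar input returns a {class: probability} dict; array input returns a
    DataFrame with one column per class.
    """
    s = np.atleast_1d(np.asarray(score, dtype=float))
    logp = np.empty((s.size, 2))
    for i, k in enumerate(model.classes):
        logp[:, i] = norm.logpdf(s, model.means[k], model.sds[k]) + np.log(
            model.priors[k]
        )
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    p /= p.sum(axis=1, keepdims=True)
    frame = pd.DataFrame(p, columns=list(model.classes))
    if np.isscalar(score) or np.ndim(score) == 0:
        return {k: float(frame.iloc[0][k]) for k in model.classes}
    return frame


def _posterior_matrix(
    model: LPSModel | MulticlassLPSModel,
    m: ExpressionMatrix,
    impute_missing: bool = False,
) -> pd.DataFrame:
    if isinstance(model, LPSModel):
        scores = lps_score(model, m, impute_missing=impute_missing)
        frame = posterior(model, scores.to_numpy())
        frame.index = m.sample_ids
        return frame
    cols = {}
    for k in model.classes:
        axis = model.axes[k]
        scores = lps_score(axis, m, impute_missing=impute_missing)
        frame = posterior(axis, scores.to_numpy())
        cols[k] = frame[k].to_numpy()
    out = pd.DataFrame(cols, index=m.sample_ids)
    out = out.div(out.sum(axis=1), axis=0)
    return out


def fit_lps_multiclass(
    m: ExpressionMatrix,
    labels: pd.Series | Mapping[str, str],
    n_genes_per_class: int = 20,
    confidence_cut: float = 0.9,
) -> MulticlassLPSModel:
    """Fit the three-class one-vs-rest LPS extension.

    For each class k a binary LPS axis k-vs-rest is trained (weights from
    the class-k-vs-rest t-statistics); the in-class and pooled-rest
    Gaussians on that axis give a two-class posterior p_k, and the final
    sample posterior is p_k / sum_l p_l.
    """
    labels = pd.Series(labels).reindex(m.sample_ids)
    classes = tuple(dict.fromkeys(labels))
    if len(classes) != 3:
        raise ValueError(f"expected 3 classes, found {list(classes)}")
    axes: dict[str, LPSModel] = {}
    for k in classes:
        binary = labels.map(lambda lab, k=k: k if lab == k else "rest")
        if int((binary == k).sum()) < 3:
            raise ValueError(f"class {k!r} needs at least 3 samples")
        axes[k] = fit_lps(
            m,
            binary,
            n_genes=n_genes_per_class,
            confidence_cut=confidence_cut,
            groups=(k, "rest"),
        )
    return MulticlassLPSModel(axes=axes, classes=classes, confidence_cut=confidence_cut)


def classify(
    model: LPSModel | MulticlassLPSModel,
    m: ExpressionMatrix,
    confidence_cut: float | None = None,
    impute_missing: bool = False,
) -> pd.DataFrame:
    """Posterior probabilities plus an arg-max call with unclassified band.

    Samples whose maximum posterior is below the confidence cut are called
    ``unclassified``. Returns a frame with one posterior column per class
    and a ``call`` column.
    """
    cut = model.confidence_cut if confidence_cut is None else confidence_cut
    post = _posterior_matrix(model, m, impute_missing=impute_missing)
    best = post.idxmax(axis=1)
    confident = post.max(axis=1) >= cut
    calls = best.where(confident, UNCLASSIFIED)
    out = post.copy()
    out["call"] = calls
    return out


def tenfold_cv(
    m: ExpressionMatrix,
    labels: pd.Series | Mapping[str, str],
    n_genes: int = 20,
    folds: int = 10,
    seed: int = 1,
    confidence_cut: float = 0.5001,
) -> tuple[float, pd.DataFrame]:
    """Stratified k-fold cross-validated accuracy of the LPS classifier.

    Gene selection, weight estimation and Gaussian fitting are redone
    inside every training fold, so held-out accuracy carries no selection
    leakage. The default confidence cut is effectively the arg-max rule
    (no sample unclassified in the two-class case); with a stricter cut,
    unclassified held-out samples count as errors. Folds are fixed by
    ``seed``; a class smaller than the fold count shrinks the fold count
    with a warning.

    Returns (overall accuracy in [0, 1], per-fold table).
    """
    labels = pd.Series(labels).reindex(m.sample_ids)
    class_counts = labels.value_counts()
    n_splits = min(folds, int(class_counts.min()))
    if n_splits < folds:
        log.warning("smallest class has %d samples; using %d folds", class_counts.min(), n_splits)
    if n_splits < 2:
        raise ValueError("cross-validation needs the smallest class >= 2")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    sample_ids = np.asarray(m.sample_ids)
    y = labels.to_numpy()
    rows = []
    correct = total = 0
    for fold, (train_idx, test_idx) in enumerate(skf.split(sample_ids, y), start=1):
        train_m = m.subset_samples(sample_ids[train_idx])
        test_m = m.subset_samples(sample_ids[test_idx])
        model = fit_lps(
            train_m,
            labels.iloc[train_idx],
            n_genes=n_genes,
            confidence_cut=max(confidence_cut, 0.5001),
        )
        calls = classify(model, test_m)["call"]
        truth = labels.iloc[test_idx]
        n_ok = int((calls.to_numpy() == truth.to_numpy()).sum())
        rows.append(
            {
                "fold": fold,
                "n_test": len(test_idx),
                "n_correct": n_ok,
                "n_unclassified": int((calls == UNCLASSIFIED).sum()),
            }
        )
        correct += n_ok
        total += len(test_idx)
    table = pd.DataFrame(rows)
    return correct / total, table


def classify_tis_responders(
    model: LPSModel,
    m: ExpressionMatrix,
    upper: float = 0.8,
    lower: float = 0.2,
    tis_class: str | None = None,
) -> pd.DataFrame:
    """Band samples by their TIS-class posterior ("TIS score").

    A sample is a senescence ``responder`` when its TIS score exceeds
    ``upper`` (default 0.8), a ``non_responder`` below ``lower`` (default
    0.2), and ``unclassified`` in the closed band between, boundaries
    included. The TIS class defaults to the model's first class.
    """
    if tis_class is None:
        tis_class = model.classes[0]
    if tis_class not in model.classes:
        raise ValueError(f"{tis_class!r} is not a model class")
    post = _posterior_matrix(model, m)
    score = post[tis_class]
    return pd.DataFrame(
        {"tis_score": score, "call": band_tis_scores(score, upper, lower)},
        index=m.sample_ids,
    ).rename_axis("sample_id")


def band_tis_scores(
    scores: pd.Series | np.ndarray,
    upper: float = 0.8,
    lower: float = 0.2,
) -> np.ndarray:
    """Band TIS scores: > upper responder, < lower non-responder, else
    unclassified (band boundaries included in the unclassified band)."""
    s = np.asarray(scores, dtype=float)
    return np.where(
        s > upper, "responder", np.where(s < lower, "non_responder", UNCLASSIFIED)
    )
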