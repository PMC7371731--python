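"""Signature construction: cross-species common-DE genes, two-cluster
stratification, leading-edge core signatures, and gene-set stratifiers.

The cross-species step selects genes upregulated in the matching response
group of both species, linked through an ortholog map (a many-to-many
pair qualifies if any mapped partner passes). Two-cluster stratification
follows the heatmap convention: samples are clustered on their
z-scored signature-gene profiles with Pearson correlation distance and
complete linkage, and the tree is cut into two top clusters. The "core"
signature is the intersection of GSEA leading edges across comparisons,
translated into a common namespace first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist

from .diffexpr import select_de_genes
from .io import ExpressionMatrix, GeneSet, OrthologMap
from .preprocess import median_split, row_standardize, signature_score

log = logging.getLogger(__name__)

__all__ = [
    "CrossSpeciesSignature",
    "common_de_genes",
    "cluster_stratify",
    "core_signature",
    "go_set_stratify",
    "translate_signature",
]


@dataclass(frozen=True)
class CrossSpeciesSignature:
    """Genes up in the matching response group of both species."""

    source_genes: GeneSet
    target_genes: GeneSet
    pairs: frozenset[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.source_genes)


def common_de_genes(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    omap: OrthologMap,
    p_thresh: float = 0.01,
    lfc_thresh: float = 1.0,
) -> CrossSpeciesSignature:
    """Genes upregulated in both species' matching response groups.

    Both DE tables must be oriented so positive log-FC means up in the
    matching group. A species-A gene enters the signature when it passes
    the up-filter and at least one of its ortholog partners passes the
    up-filter in species B; the signature's target side collects exactly
    those qualifying partners.
    """
    up_a = select_de_genes(de_a, p_thresh, lfc_thresh, direction="up", name="speciesA")
    up_b = select_de_genes(de_b, p_thresh, lfc_thresh, direction="up", name="speciesB")
    pairs = set()
    for a in sorted(up_a.members):
        for b in sorted(omap.partners(a, "forward") & up_b.members):
            pairs.add((a, b))
    if not pairs:
        log.warning("no commonly upregulated ortholog pairs; empty signature")
    return CrossSpeciesSignature(
        source_genes=GeneSet("common_up_source", frozenset(a for a, _ in pairs)),
        target_genes=GeneSet("common_up_target", frozenset(b for _, b in pairs)),
        pairs=frozenset(pairs),
    )


def cluster_stratify(
    m: ExpressionMatrix,
    k: int = 2,
    standardize: bool = True,
) -> tuple[pd.Series, list[str]]:
    """Split samples into two top clusters on their signature profiles.

    The matrix should already be restricted to the signature genes. Gene
    rows are z-scored (unless ``standardize=False``), sample–sample
    distance is 1 - Pearson correlation of the profiles, agglomeration is
    complete linkage, and the dendrogram is cut at ``k`` clusters.
    Cluster labels are renumbered so cluster 1 is the larger one (ties
    resolved toward the cluster holding the lexicographically first
    sample). Returns (sample -> cluster Series, dendrogram leaf order).
    Any z-score clipping for heatmap export must happen after this step.
    """
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("clustering needs >=2 genes and >=2 samples")
    work = row_standardize(m) if standardize else m
    X = work.values.T  # samples x genes
    flat = X.std(axis=1) == 0
    if flat.any():
        bad = [s for s, f in zip(work.sample_ids, flat) if f]
        raise ValueError(f"constant signature profile for sample(s) {bad[:5]}")
    dist = pdist(X, metric="correlation")
    Z = linkage(dist, method="complete")
    raw = fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=work.sample_ids, name="cluster")
    order = [work.sample_ids[i] for i in leaves_list(Z)]
    sizes = labels.value_counts()
    ranked = sorted(
        sizes.index,
        key=lambda c: (
            -sizes[c],
            min(s for s in labels.index[labels == c]),
        ),
    )
    remap = {old: new for new, old in enumerate(ranked, start=1)}
    return labels.map(remap), order


def core_signature(
    leading_edges: Sequence[GeneSet],
    omap: OrthologMap | None = None,
) -> GeneSet:
    """Intersection of leading edges across comparisons, common namespace.

    With an ortholog map, any edge whose members live predominantly on the
    map's source side is translated to the target side before
    intersecting, so mouse- and human-derived edges meet in one
    namespace. An empty intersection is returned with a warning.
    """
    if len(leading_edges) < 2:
        raise ValueError("core signature needs at least 2 leading edges")
    translated: list[frozenset[str]] = []
    for gs in leading_edges:
        members = gs.members
        if omap is not None:
            src_overlap = len(members & omap.source_genes())
            tgt_overlap = len(members & omap.target_genes())
            if src_overlap > tgt_overlap:
                members = omap.image(members, "forward")
        translated.append(frozenset(members))
    core = frozenset.intersection(*translated)
    if not core:
        log.warning("leading edges share no genes; core signature is empty")
    return GeneSet(
        name="core_signature",
        members=core,
        description=f"intersection of {len(leading_edges)} leading edges",
    )


def go_set_stratify(m: ExpressionMatrix, gs: GeneSet) -> pd.Series:
    """Median split of samples by mean expression over a gene set."""
    scores = signature_score(m, gs)
    return median_split(scores)


def translate_signature(
    gs: GeneSet,
    omap: OrthologMap,
    direction: str = "forward",
) -> GeneSet:
    """Map a gene set through the ortholog relation (deduplicated image).

    Unmapped members are dropped with a warning; zero coverage is an
    error. Many-to-many orthologs expand, then deduplicate.
    """
    image = omap.image(gs.members, direction)
    covered = {
        g for g in gs.members if omap.partners(g, direction)
    }
    if not covered:
        raise ValueError(f"ortholog map covers no member of {gs.name!r}")
    dropped = gs.members - covered
    if dropped:
        log.warning(
            "%d members of %s unmapped and dropped: %s",
            len(dropped), gs.name, sorted(dropped)[:5],
        )
    return GeneSet(
        name=f"{gs.name}_{direction}",
        members=image,
        description=f"{gs.name} translated {direction}",
    )
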