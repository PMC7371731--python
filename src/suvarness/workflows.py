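"""End-to-end analysis workflows over synthetic cohorts.

Each workflow is a pure function of (config, seeds): rerunning with the
same configuration produces byte-identical artifacts (no timestamps or
environment state enter any output). All stage parameters and in/out
counts are recorded in a structured ``workflow_log.json`` next to the
result tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, gsea, lps, signatures, survival
from .io import GeneSet, write_gmt, write_expression_matrix, write_annotations
from .preprocess import median_split, signature_score
from .simulate import (
    CohortConfig,
    generate_paired_species_cohorts,
    generate_suvarness_study,
    generate_tis_study,
)

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "run_tis_workflow",
    "run_suvarness_workflow",
    "run_xspecies_workflow",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative configuration for the three named workflows."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_classifier_genes: int = 20
    cv_folds: int = 10
    cv_seed: int = 1
    de_p_threshold: float = 0.01
    de_lfc_threshold: float = 1.0
    gsea_permutations: int = 1000
    gsea_seed: int = 1
    tis_upper: float = 0.8
    tis_lower: float = 0.2
    confidence_cut: float = 0.9
    overlap_fraction: float = 1.0
    outdir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["n_samples_per_group"] = dict(self.cohort.n_samples_per_group)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_raw = raw.pop("cohort", {})
        if "baseline_mean_range" in cohort_raw:
            cohort_raw["baseline_mean_range"] = tuple(cohort_raw["baseline_mean_range"])
        return cls(cohort=CohortConfig(**cohort_raw), **raw)


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def _negate_de(de: pd.DataFrame) -> pd.DataFrame:
    """Flip the comparison orientation of a DE table (A-B -> B-A)."""
    flipped = de.copy()
    flipped["t_stat"] = -flipped["t_stat"]
    flipped["log_fc"] = -flipped["log_fc"]
    return flipped


def _maybe_outdir(config: PipelineConfig) -> Path | None:
    if config.outdir is None:
        return None
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _logrank_two_arm(ann: pd.DataFrame, labels: pd.Series, arm_a: str, arm_b: str):
    """Log-rank between two label arms; None when an arm is degenerate."""
    joined = ann.join(labels.rename("arm"))
    arms = []
    for arm in (arm_a, arm_b):
        sub = joined[joined["arm"] == arm].dropna(subset=["time", "event"])
        arms.append((sub["time"].to_numpy(), sub["event"].to_numpy()))
    if any(t.size < 2 for t, _ in arms) or sum(e.sum() for _, e in arms) == 0:
        log.warning("degenerate survival arms (%s vs %s); test skipped", arm_a, arm_b)
        return None
    return survival.logrank_test(arms)


def run_tis_workflow(config: PipelineConfig) -> dict:
    """Train the TIS classifier, score a treated cohort, stratify survival.

    Stages: simulate the in-vitro training comparison and the linked
    application cohort; differential expression TIS vs non-senescent;
    fit the two-class LPS model and cross-validate it; band the
    application samples into senescence responders / non-responders /
    unclassified by TIS score; log-rank test of responder vs
    non-responder survival.
    """
    out = _maybe_outdir(config)
    training, application = generate_tis_study(config.cohort)
    labels = training.annotation["outcome_group"]
    de = diffexpr.two_sample_t(training.expression, labels, groups=("TIS", "non_senescent"))
    model = lps.fit_lps(
        training.expression, labels,
        n_genes=config.n_classifier_genes,
        confidence_cut=config.confidence_cut,
        groups=("TIS", "non_senescent"),
    )
    cv_accuracy, cv_table = lps.tenfold_cv(
        training.expression, labels,
        n_genes=config.n_classifier_genes,
        folds=config.cv_folds,
        seed=config.cv_seed,
    )
    calls = lps.classify_tis_responders(
        model, application.expression,
        upper=config.tis_upper, lower=config.tis_lower,
    )
    test = _logrank_two_arm(
        application.annotation, calls["call"], "responder", "non_responder"
    )
    report = {
        "workflow": "tis",
        "config": config.to_dict(),
        "n_training_samples": training.expression.shape[1],
        "n_application_samples": application.expression.shape[1],
        "n_de_genes_tested": len(de),
        "cv_accuracy": float(cv_accuracy),
        "n_responder": int((calls["call"] == "responder").sum()),
        "n_non_responder": int((calls["call"] == "non_responder").sum()),
        "n_unclassified": int((calls["call"] == lps.UNCLASSIFIED).sum()),
        "logrank_statistic": None if test is None else test.statistic,
        "logrank_p": None if test is None else test.p_value,
    }
    if out is not None:
        write_expression_matrix(training.expression, out / "training_matrix.tsv")
        write_annotations(training.annotation, out / "training_annotation.csv")
        write_annotations(application.annotation, out / "application_annotation.csv")
        de.to_csv(out / "de_table.csv")
        model.save(out / "lps_model.json")
        cv_table.to_csv(out / "cv_folds.csv", index=False)
        calls.to_csv(out / "tis_calls.csv")
        _dump_json(report, out / "workflow_log.json")
    return report


def run_suvarness_workflow(config: PipelineConfig) -> dict:
    """Derive the senescence-up signature, its core, and survival splits.

    Stages: simulate four comparisons sharing a planted senescence-up
    block (mouse in-vitro and in-vivo, two human cohorts); select the
    TIS-upregulated DE genes of the in-vitro comparison as the signature;
    GSEA of that signature (humanized through the ortholog map where
    needed) in all four comparisons; intersect the leading edges into a
    core signature; median-split both human cohorts on core-signature
    average expression and log-rank the halves.
    """
    out = _maybe_outdir(config)
    invitro, invivo, human1, human2, omap = generate_suvarness_study(
        config.cohort, overlap_fraction=config.overlap_fraction
    )
    de_invitro = diffexpr.two_sample_t(
        invitro.expression, invitro.annotation["outcome_group"], groups=("TIS", "untreated")
    )
    suvarness = diffexpr.select_de_genes(
        de_invitro, config.de_p_threshold, config.de_lfc_threshold,
        direction="up", name="SUVARness",
    )
    suvarness = GeneSet("SUVARness", suvarness.members, "TIS-upregulated genes")
    human_set = signatures.translate_signature(suvarness, omap, "forward") if suvarness.members else suvarness

    comparisons = [
        ("mouse_invitro", invitro, ("TIS", "untreated"), suvarness),
        ("mouse_invivo", invivo, ("NR", "RP"), suvarness),
        ("human_cohort1", human1, ("cured", "relapsed"), human_set),
        ("human_cohort2", human2, ("cured", "relapsed"), human_set),
    ]
    edges: list[GeneSet] = []
    gsea_rows = []
    for label, cohort, group_pair, gene_set in comparisons:
        de = diffexpr.two_sample_t(
            cohort.expression, cohort.annotation["outcome_group"], groups=group_pair
        )
        ranked = gsea.rank_genes(de, metric="t_stat")
        res = gsea.permutation_test(
            ranked, gene_set,
            n_perm=config.gsea_permutations, seed=config.gsea_seed,
        )
        edge = GeneSet(f"{label}_leading_edge", res.leading_edge.members)
        edges.append(edge)
        gsea_rows.append(
            {"comparison": label, "es": res.es, "nes": res.nes,
             "p_perm": res.p_perm, "leading_edge_size": len(edge)}
        )
    core = signatures.core_signature(edges, omap)
    report = {
        "workflow": "suvarness",
        "config": config.to_dict(),
        "suvarness_size": len(suvarness),
        "gsea": gsea_rows,
        "core_size": len(core),
        "survival": {},
    }
    if core.members:
        for label, cohort in (("human_cohort1", human1), ("human_cohort2", human2)):
            scores = signature_score(cohort.expression, core)
            split = median_split(scores)
            test = _logrank_two_arm(cohort.annotation, split, "above", "below")
            report["survival"][label] = {
                "n_above": int((split == "above").sum()),
                "n_below": int((split == "below").sum()),
                "logrank_statistic": None if test is None else test.statistic,
                "logrank_p": None if test is None else test.p_value,
            }
            if out is not None:
                scores.rename("core_score").to_frame().join(split).to_csv(
                    out / f"{label}_core_scores.csv", index_label="sample_id"
                )
    else:
        log.warning("empty core signature; survival stratification skipped")
        report["survival"] = None
    if out is not None:
        write_gmt([suvarness, human_set], out / "suvarness.gmt")
        write_gmt(edges, out / "leading_edges.gmt")
        if core.members:
            write_gmt([core], out / "core_signature.gmt")
        pd.DataFrame(gsea_rows).to_csv(out / "gsea_results.csv", index=False)
        _dump_json(report, out / "workflow_log.json")
    return report


def run_xspecies_workflow(config: PipelineConfig) -> dict:
    """Cross-species common-DE signature, two-cluster split, survival tests.

    Stages: simulate paired mouse/human cohorts with ortholog-linked
    planted genes; per-species differential expression of the favorable
    vs relapsing group; select genes commonly upregulated in both species
    through the ortholog map; cluster each species' samples on its side
    of the signature (Pearson distance, complete linkage, two top
    clusters); log-rank survival between clusters and Fisher test of
    cluster vs outcome group.
    """
    out = _maybe_outdir(config)
    mouse, human, omap = generate_paired_species_cohorts(
        config.cohort, overlap_fraction=config.overlap_fraction, half_down=True
    )
    de_m = diffexpr.two_sample_t(mouse.expression, mouse.annotation["outcome_group"])
    de_h = diffexpr.two_sample_t(human.expression, human.annotation["outcome_group"])
    sig = signatures.common_de_genes(
        de_m, de_h, omap,
        p_thresh=config.de_p_threshold, lfc_thresh=config.de_lfc_threshold,
    )
    # the reversed orientation gives the commonly-DOWN arm; the union of
    # both arms carries the anticorrelated structure the Pearson-distance
    # clustering stratifies on
    sig_down = signatures.common_de_genes(
        _negate_de(de_m), _negate_de(de_h), omap,
        p_thresh=config.de_p_threshold, lfc_thresh=config.de_lfc_threshold,
    )
    mouse_sig = GeneSet(
        "mouse_signature", sig.source_genes.members | sig_down.source_genes.members
    )
    human_sig = GeneSet(
        "human_signature", sig.target_genes.members | sig_down.target_genes.members
    )
    report = {
        "workflow": "xspecies",
        "config": config.to_dict(),
        "signature_pairs_up": len(sig.pairs),
        "signature_pairs_down": len(sig_down.pairs),
        "species": {},
    }
    per_species = [
        ("mouse", mouse, mouse_sig),
        ("human", human, human_sig),
    ]
    cluster_tables = {}
    for label, cohort, gene_set in per_species:
        entry: dict = {"signature_size": len(gene_set)}
        present = [g for g in cohort.expression.gene_ids if g in gene_set.members]
        if len(present) >= 2:
            clusters, order = signatures.cluster_stratify(
                cohort.expression.subset_genes(present)
            )
            cluster_tables[label] = clusters
            entry["cluster_sizes"] = clusters.value_counts().sort_index().to_dict()
            test = _logrank_two_arm(
                cohort.annotation, clusters.map({1: "c1", 2: "c2"}), "c1", "c2"
            )
            entry["logrank_statistic"] = None if test is None else test.statistic
            entry["logrank_p"] = None if test is None else test.p_value
            groups = list(dict.fromkeys(cohort.annotation["outcome_group"]))[:2]
            table = [
                [
                    int(((clusters == c) & (cohort.annotation["outcome_group"] == g)).sum())
                    for g in groups
                ]
                for c in (1, 2)
            ]
            fisher = survival.contingency_test(table)
            entry["fisher_p"] = fisher.p_value
            entry["contingency"] = table
        else:
            log.warning("%s signature too small to cluster (%d genes)", label, len(present))
            entry["cluster_sizes"] = None
        report["species"][label] = entry
    if out is not None:
        write_gmt(
            [sig.source_genes, sig.target_genes,
             GeneSet("common_down_source", sig_down.source_genes.members),
             GeneSet("common_down_target", sig_down.target_genes.members)],
            out / "xspecies_signature.gmt",
        )
        for label, clusters in cluster_tables.items():
            clusters.to_frame().to_csv(out / f"{label}_clusters.csv", index_label="sample_id")
        _dump_json(report, out / "workflow_log.json")
    return report
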