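"""Synthetic expression cohorts with planted signal and linked survival.

The generators emulate the statistical structure of RMA-processed
log-scale microarray cohorts: gene-wise baseline means drawn uniformly on
a log-expression interval, i.i.d. Gaussian noise on the log scale, and a
block of "planted" signature genes shifted between outcome groups by a
stated effect size (in units of the within-group SD). Survival follows an
exponential model whose hazard is log-linear in the standardized planted
signature score of each sample,

    T_s ~ Exponential(rate = hazard_rate * exp(hazard_log_hr * z_s)),

right-censored at a fixed observation horizon (default 100 days, the
mouse-trial design). A negative ``hazard_log_hr`` therefore makes
high-signature samples survive longer. Paired cross-species cohorts share
a configurable fraction of their planted genes through an ortholog map.

Every generator is a pure function of its config (including the seed);
independent sub-streams are derived for baselines, noise, survival and
planted-gene choice so the pieces stay reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet, OrthologMap

__all__ = [
    "CohortConfig",
    "PlantedSignature",
    "Cohort",
    "generate_cohort",
    "generate_tis_training",
    "generate_paired_species_cohorts",
    "generate_tis_study",
    "generate_suvarness_study",
]


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    ``effect_size`` is the planted mean shift in within-group SD units;
    ``hazard_rate`` is the baseline event rate in events/day and
    ``hazard_log_hr`` the log hazard ratio per unit of standardized
    signature score. ``censor_horizon`` is the observation period in days.
    """

    n_genes: int = 200
    n_samples_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"NR": 20, "RP": 20}
    )
    n_signature_genes: int = 20
    effect_size: float = 1.5
    noise_sd: float = 1.0
    baseline_mean_range: tuple[float, float] = (4.0, 12.0)
    hazard_rate: float = 0.02
    hazard_log_hr: float = 0.0
    censor_horizon: float = 100.0
    seed: int = 1
    up_group: str | None = None

    def validate(self) -> None:
        if self.n_signature_genes > self.n_genes:
            raise ValueError("n_signature_genes exceeds n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.censor_horizon <= 0:
            raise ValueError("censor_horizon must be positive")
        if self.hazard_rate <= 0:
            raise ValueError("hazard_rate must be positive")
        if not self.n_samples_per_group:
            raise ValueError("at least one sample group required")
        if any(n < 1 for n in self.n_samples_per_group.values()):
            raise ValueError("every group needs at least one sample")


@dataclass(frozen=True)
class PlantedSignature:
    """Ground truth of a generated cohort: up- and down-planted genes."""

    up: GeneSet
    down: GeneSet

    @property
    def all_genes(self) -> frozenset[str]:
        return self.up.members | self.down.members


@dataclass(frozen=True)
class Cohort:
    expression: ExpressionMatrix
    annotation: pd.DataFrame
    planted: PlantedSignature


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("planted", "baseline", "noise", "survival")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _simulate(
    config: CohortConfig,
    gene_ids: list[str],
    up_idx: np.ndarray,
    down_idx: np.ndarray,
    groups: list[str],
    up_group: str,
    sample_prefix: str = "s",
    cohort: str = "synthetic",
    baseline_seed: int | None = None,
) -> Cohort:
    """Shared core: build the matrix, annotation and survival outcomes.

    ``baseline_seed`` reuses another cohort's gene-baseline stream so two
    cohorts share per-gene mean expression (same-platform emulation) while
    drawing independent noise and survival.
    """
    rng = _streams(config.seed)
    if baseline_seed is not None:
        rng["baseline"] = _streams(baseline_seed)["baseline"]
    sizes = dict(config.n_samples_per_group)
    sample_ids: list[str] = []
    sample_groups: list[str] = []
    for g in groups:
        for i in range(sizes[g]):
            sample_ids.append(f"{sample_prefix}{len(sample_ids) + 1:04d}")
            sample_groups.append(g)
    n_samples = len(sample_ids)
    mu = rng["baseline"].uniform(*config.baseline_mean_range, size=config.n_genes)
    values = mu[:, None] + rng["noise"].normal(
        0.0, config.noise_sd, size=(config.n_genes, n_samples)
    )
    in_up_group = np.array([g == up_group for g in sample_groups])
    delta = config.effect_size * config.noise_sd
    if up_idx.size:
        values[np.ix_(up_idx, np.flatnonzero(in_up_group))] += delta
    if down_idx.size:
        values[np.ix_(down_idx, np.flatnonzero(in_up_group))] -= delta
    matrix = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))

    planted_idx = np.concatenate([up_idx, down_idx]) if down_idx.size else up_idx
    if planted_idx.size:
        score = values[up_idx].mean(axis=0) if up_idx.size else np.zeros(n_samples)
        if down_idx.size:
            score = score - values[down_idx].mean(axis=0)
        sd = score.std(ddof=1)
        z = (score - score.mean()) / sd if sd > 0 else np.zeros(n_samples)
    else:
        z = np.zeros(n_samples)
    rate = config.hazard_rate * np.exp(config.hazard_log_hr * z)
    raw_times = rng["survival"].exponential(1.0 / rate)
    event = (raw_times <= config.censor_horizon).astype(int)
    times = np.minimum(raw_times, config.censor_horizon)

    annotation = pd.DataFrame(
        {
            "outcome_group": sample_groups,
            "time": times,
            "event": event,
            "condition": "untreated",
            "cohort": cohort,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    gene_arr = np.asarray(gene_ids)
    planted = PlantedSignature(
        up=GeneSet("planted_up", frozenset(gene_arr[up_idx])),
        down=GeneSet("planted_down", frozenset(gene_arr[down_idx])),
    )
    return Cohort(expression=matrix, annotation=annotation, planted=planted)


def _choose_planted(config: CohortConfig, n: int) -> np.ndarray:
    rng = _streams(config.seed)["planted"]
    return np.sort(rng.choice(config.n_genes, size=n, replace=False))


def generate_cohort(
    config: CohortConfig,
    gene_prefix: str = "gene",
    sample_prefix: str = "s",
    cohort: str = "synthetic",
) -> Cohort:
    """One cohort with an up-planted signature block in the 'up' group.

    Planted genes get a +effect_size*noise_sd mean shift in the designated
    up group (default: the first group of the config); survival times
    follow the exponential hazard tied to the standardized mean planted
    expression of each sample, censored at the horizon.
    """
    config.validate()
    groups = list(config.n_samples_per_group)
    up_group = config.up_group or groups[0]
    if up_group not in groups:
        raise ValueError(f"up_group {up_group!r} not among groups {groups}")
    gene_ids = [f"{gene_prefix}{i + 1:05d}" for i in range(config.n_genes)]
    up_idx = _choose_planted(config, config.n_signature_genes)
    return _simulate(
        config, gene_ids, up_idx, np.array([], dtype=int), groups, up_group,
        sample_prefix=sample_prefix, cohort=cohort,
    )


def generate_tis_training(
    config: CohortConfig,
    groups: tuple[str, str] = ("TIS", "non_senescent"),
    gene_prefix: str = "gene",
    cohort: str = "tis_invitro",
) -> Cohort:
    """Two-group senescent-vs-non-senescent cohort with up and down blocks.

    Half of the planted genes are shifted up in the senescent (TIS) group
    and half down, emulating a therapy-induced senescence program with
    induced and repressed arms. Group sizes reuse the config's first two
    entries (or the single entry for both).
    """
    config.validate()
    sizes = list(config.n_samples_per_group.values())
    if len(sizes) == 1:
        sizes = [sizes[0], sizes[0]]
    cfg = replace(
        config,
        n_samples_per_group={groups[0]: sizes[0], groups[1]: sizes[1]},
        up_group=groups[0],
    )
    gene_ids = [f"{gene_prefix}{i + 1:05d}" for i in range(cfg.n_genes)]
    planted = _choose_planted(cfg, cfg.n_signature_genes)
    half = cfg.n_signature_genes // 2
    up_idx, down_idx = planted[:half], planted[half:]
    return _simulate(
        cfg, gene_ids, up_idx, down_idx, list(cfg.n_samples_per_group), groups[0],
        sample_prefix="t", cohort=cohort,
    )


def generate_paired_species_cohorts(
    config: CohortConfig,
    overlap_fraction: float = 1.0,
    half_down: bool = False,
) -> tuple[Cohort, Cohort, OrthologMap]:
    """Mouse and human cohorts sharing planted genes through orthologs.

    Gene namespaces are disjoint (``mgene...`` vs ``HGENE...``) and linked
    one-to-one over all genes. A fraction ``overlap_fraction`` of each
    cohort's planted genes are orthologs of the other's planted genes;
    the remainder are planted at non-matching positions. With
    ``half_down`` the planted block splits into an up- and a down-arm in
    the favorable group (directions matched across shared orthologs),
    giving the anticorrelated two-block structure that correlation-based
    sample clustering needs.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    config.validate()
    s = config.n_signature_genes
    n_shared = int(round(overlap_fraction * s))
    if 2 * s - n_shared > config.n_genes:
        raise ValueError("n_genes too small for the requested planted overlap")
    mouse_planted = np.arange(s)
    human_planted = np.concatenate([np.arange(n_shared), np.arange(s, 2 * s - n_shared)])
    h = s // 2 if half_down else s
    mouse_up, mouse_down = mouse_planted[:h], mouse_planted[h:]
    if half_down:
        # shared orthologs keep the mouse direction; extras fill up to h 'up'
        up_list = [i for i in human_planted if i < h]
        down_list = [i for i in human_planted if h <= i < s]
        extras = [i for i in human_planted if i >= s]
        for i in extras:
            (up_list if len(up_list) < h else down_list).append(i)
        human_up = np.sort(np.array(up_list, dtype=int))
        human_down = np.sort(np.array(down_list, dtype=int))
    else:
        human_up = human_planted
        human_down = np.array([], dtype=int)
    mouse_genes = [f"mgene{i + 1:05d}" for i in range(config.n_genes)]
    human_genes = [f"HGENE{i + 1:05d}" for i in range(config.n_genes)]
    groups = list(config.n_samples_per_group)
    up_group = config.up_group or groups[0]
    mouse = _simulate(
        replace(config, seed=config.seed * 2 + 1),
        mouse_genes, mouse_up, mouse_down, groups, up_group,
        sample_prefix="m", cohort="mouse",
    )
    human = _simulate(
        replace(config, seed=config.seed * 2 + 2),
        human_genes, human_up, human_down, groups, up_group,
        sample_prefix="h", cohort="human",
    )
    omap = OrthologMap(zip(mouse_genes, human_genes))
    return mouse, human, omap


def generate_tis_study(
    config: CohortConfig,
    cohort_groups: tuple[str, str] = ("capable", "incapable"),
) -> tuple[Cohort, Cohort]:
    """Training cohort plus an application cohort sharing its planted genes.

    The training cohort is the in-vitro-style TIS vs non-senescent
    comparison; the application cohort contains senescence-capable and
    -incapable samples carrying the same planted expression pattern in the
    same gene namespace, with survival linked to the planted score. Both
    cohorts derive from the same config, so the study is a pure function
    of (config, seed).
    """
    training = generate_tis_training(config)
    app_cfg = replace(config, seed=config.seed + 104729)  # distinct sub-stream
    sizes = list(config.n_samples_per_group.values())
    if len(sizes) == 1:
        sizes = [sizes[0], sizes[0]]
    app_cfg = replace(
        app_cfg,
        n_samples_per_group={cohort_groups[0]: sizes[0], cohort_groups[1]: sizes[1]},
        up_group=cohort_groups[0],
    )
    gene_ids = training.expression.gene_ids
    gene_arr = np.asarray(gene_ids)
    up_idx = np.flatnonzero(np.isin(gene_arr, sorted(training.planted.up.members)))
    down_idx = np.flatnonzero(np.isin(gene_arr, sorted(training.planted.down.members)))
    application = _simulate(
        app_cfg, gene_ids, up_idx, down_idx,
        list(app_cfg.n_samples_per_group), cohort_groups[0],
        sample_prefix="a", cohort="tis_invivo",
        baseline_seed=config.seed,  # same platform: shared gene baselines
    )
    return training, application


def generate_suvarness_study(
    config: CohortConfig,
    overlap_fraction: float = 1.0,
) -> tuple[Cohort, Cohort, Cohort, Cohort, OrthologMap]:
    """Four comparison cohorts sharing one planted senescence-up block.

    Two mouse cohorts in a common namespace — an in-vitro senescent (TIS)
    vs untreated comparison and an in-vivo cured (NR) vs relapse-prone
    (RP) comparison — and two independent human cohorts (cured vs
    relapsed) whose planted genes overlap the mouse block through the
    ortholog map by ``overlap_fraction``. In every cohort the planted
    block is up in the favorable-outcome group, emulating a shared
    senescence-capacity signature with linked survival.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    config.validate()
    s = config.n_signature_genes
    n_shared = int(round(overlap_fraction * s))
    if 2 * s - n_shared > config.n_genes:
        raise ValueError("n_genes too small for the requested planted overlap")
    mouse_up = np.arange(s)
    human_up = np.concatenate([np.arange(n_shared), np.arange(s, 2 * s - n_shared)])
    mouse_genes = [f"mgene{i + 1:05d}" for i in range(config.n_genes)]
    human_genes = [f"HGENE{i + 1:05d}" for i in range(config.n_genes)]
    empty = np.array([], dtype=int)
    sizes = list(config.n_samples_per_group.values())
    if len(sizes) == 1:
        sizes = [sizes[0], sizes[0]]

    def cohort_for(seed_offset, genes, up_idx, group_pair, prefix, name):
        cfg = replace(
            config,
            seed=config.seed * 4 + seed_offset,
            n_samples_per_group={group_pair[0]: sizes[0], group_pair[1]: sizes[1]},
            up_group=group_pair[0],
        )
        return _simulate(
            cfg, genes, up_idx, empty, list(cfg.n_samples_per_group),
            group_pair[0], sample_prefix=prefix, cohort=name,
        )

    invitro = cohort_for(1, mouse_genes, mouse_up, ("TIS", "untreated"), "v", "mouse_invitro")
    invivo = cohort_for(2, mouse_genes, mouse_up, ("NR", "RP"), "m", "mouse_invivo")
    human1 = cohort_for(3, human_genes, human_up, ("cured", "relapsed"), "p", "human_cohort1")
    human2 = cohort_for(4, human_genes, human_up, ("cured", "relapsed"), "q", "human_cohort2")
    omap = OrthologMap(zip(mouse_genes, human_genes))
    return invitro, invivo, human1, human2, omap
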