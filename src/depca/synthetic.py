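"""Synthetic designed experiments with known ground truth.

Real validation data for this methodology are microarray series with
group-structured designs (a developmental time course; a toxicology panel
of repeated chemical treatments).  This module emulates that structure so
every claim about the method is testable without downloads:

    value[item, sample] = baseline_item
                          + loadings_item . latent[group(sample)]
                          + loadings_item . jitter_sample   (heterogeneous items)
                          + within-group noise                (variable group)
                          + spike                             (outlier samples)
                          + Normal(0, noise_sd)

Groups occupy positions on a small number of latent axes, so the true
component structure is low-rank and checkable; informative items carry
Gaussian loadings onto those axes, the rest only baseline plus noise.
Individual differences are modeled as Gaussian noise in many items (the
dominant noise mode in normalized expression data), with optional
outlier-sample spikes and a "within-group variable" regime in which chosen
items (or one whole group) fluctuate sample-to-sample around the group
position.

Everything is reproducible from the config seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CONTROL_GROUP, GRAND_MEAN, Design, ExpressionMatrix
from .errors import UsageError
from .filtering import ProbeLevelData


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated designed experiment.

    Defaults emulate a toxicology-style panel: 7 groups (one control) with
    5 replicates each, 200 items of which 150 respond to 2 latent axes,
    group displacements three times the individual noise sd.
    """

    n_groups: int = 7
    reps: int | Sequence[int] = 5
    n_items: int = 200
    n_informative: int = 150
    n_latent: int = 2
    #: sd of latent group coordinates when positions are drawn; ignored if
    #: ``latent_positions`` is given.  Default 1.5 = 3 x noise_sd.
    effect_size: float = 1.5
    latent_positions: tuple[tuple[float, ...], ...] | None = None
    noise_sd: float = 0.5
    outlier_fraction: float = 0.0
    outlier_magnitude: float = 4.0
    #: fraction of informative items whose latent coordinate jitters per
    #: sample (items with high within-group variance)
    heterogeneous_item_fraction: float = 0.0
    heterogeneous_item_sd: float = 1.0
    #: index of a group whose samples get extra item-space noise (a
    #: within-group-variable group); None for none
    heterogeneous_group: int | None = None
    within_group_sd: float = 1.5
    #: group index used as the control/reference; None -> grand-mean rule
    reference_group: int | None = 0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        reps = self.reps_list
        if self.n_groups < 1 or self.n_items < 1 or any(r < 1 for r in reps):
            raise UsageError("counts must be positive and reps >= 1 per group")
        if len(reps) != self.n_groups:
            raise UsageError("reps list length must equal n_groups")
        if self.n_informative > self.n_items:
            raise UsageError("n_informative exceeds n_items")
        for f in (self.outlier_fraction, self.heterogeneous_item_fraction):
            if not 0 <= f <= 1:
                raise UsageError("fractions must lie in [0, 1]")
        if self.latent_positions is not None:
            lp = np.asarray(self.latent_positions, dtype=float)
            if lp.shape != (self.n_groups, self.n_latent):
                raise UsageError(
                    f"latent_positions must be {self.n_groups} x {self.n_latent}")

    @property
    def reps_list(self) -> list[int]:
        if isinstance(self.reps, int):
            return [self.reps] * self.n_groups
        return list(self.reps)

    @property
    def n_samples(self) -> int:
        return sum(self.reps_list)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows: group geometry and which items carry it."""

    latent: np.ndarray                 # n_groups x n_latent
    loadings: np.ndarray               # n_items x n_latent
    informative_items: tuple[str, ...]
    heterogeneous_items: tuple[str, ...]
    outlier_samples: tuple[str, ...]
    group_labels: tuple[str, ...]


def group_label(i: int) -> str:
    return f"g{i}"


def simulate_experiment(config: SimulationConfig
                        ) -> tuple[ExpressionMatrix, Design, GroundTruth]:
    """Draw one experiment: expression matrix, design table, ground truth."""
    rng = np.random.default_rng(config.seed)
    reps = config.reps_list
    groups = [group_label(i) for i in range(config.n_groups)]
    item_ids = [f"item{i:04d}" for i in range(config.n_items)]
    sample_ids, group_of = [], {}
    for gi, g in enumerate(groups):
        for r in range(reps[gi]):
            sid = f"{g}_s{r}"
            sample_ids.append(sid)
            group_of[sid] = g
    n, m = len(sample_ids), config.n_items

    if config.latent_positions is not None:
        latent = np.asarray(config.latent_positions, dtype=float)
    else:
        latent = rng.normal(0.0, config.effect_size,
                            (config.n_groups, config.n_latent))
        if config.reference_group is not None:
            latent[config.reference_group] = 0.0  # control sits at the origin

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, m)
    loadings = np.zeros((m, config.n_latent))
    informative = rng.choice(m, size=config.n_informative, replace=False)
    informative.sort()
    loadings[informative] = rng.normal(0.0, 1.0,
                                       (config.n_informative, config.n_latent))

    n_het = int(round(config.heterogeneous_item_fraction * config.n_informative))
    het_items = informative[rng.choice(config.n_informative, size=n_het,
                                       replace=False)] if n_het else np.array([], int)
    het_items.sort()

    sample_group_idx = np.array(
        [groups.index(group_of[s]) for s in sample_ids])
    values = (baseline[:, None]
              + loadings @ latent[sample_group_idx].T
              + rng.normal(0.0, config.noise_sd, (m, n)))

    if n_het:
        jitter = rng.normal(0.0, config.heterogeneous_item_sd,
                            (config.n_latent, n))
        values[het_items] += loadings[het_items] @ jitter

    if config.heterogeneous_group is not None:
        g = group_label(config.heterogeneous_group)
        cols = [j for j, s in enumerate(sample_ids) if group_of[s] == g]
        values[np.ix_(informative, cols)] += rng.normal(
            0.0, config.within_group_sd, (len(informative), len(cols)))

    n_out = int(round(config.outlier_fraction * n))
    outlier_cols = rng.choice(n, size=n_out, replace=False) if n_out else np.array([], int)
    for j in outlier_cols:
        spiked = rng.choice(m, size=max(1, m // 10), replace=False)
        values[spiked, j] += config.outlier_magnitude * rng.choice([-1.0, 1.0],
                                                                   len(spiked))

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=item_ids, columns=sample_ids))
    if config.reference_group is None:
        design = Design(group_of=group_of, reference_rule=GRAND_MEAN)
    else:
        design = Design(group_of=group_of, reference_rule=CONTROL_GROUP,
                        control_label=group_label(config.reference_group))
    truth = GroundTruth(
        latent=latent,
        loadings=loadings,
        informative_items=tuple(item_ids[i] for i in informative),
        heterogeneous_items=tuple(item_ids[i] for i in het_items),
        outlier_samples=tuple(sample_ids[j] for j in sorted(outlier_cols)),
        group_labels=tuple(groups),
    )
    return matrix, design, truth


def toxicology_layout(effect: float = 1.5) -> tuple[tuple[float, ...], ...]:
    """Deterministic 7-group latent geometry mimicking a toxicology panel.

    g0 is the untreated control at the origin.  The toxic chemicals (g1,
    g3, g5) share a large displacement on latent axis 1 and spread along
    axis 2; the nontoxic chemicals (g2, g4, g6) sit near the control.
    ``effect`` is the toxic displacement in latent units (per unit item
    loading); the default is three times the default individual noise sd.
    """
    e = effect
    return (
        (0.0, 0.0),          # g0 control
        (e, -0.5 * e),       # g1 toxic
        (0.3 * e, 0.15 * e), # g2 nontoxic
        (e, 0.0),            # g3 toxic
        (-0.3 * e, 0.15 * e),# g4 nontoxic
        (e, 0.5 * e),        # g5 toxic
        (0.0, -0.3 * e),     # g6 nontoxic
    )


TOXIC_GROUPS = ("g1", "g3", "g5")
NONTOXIC_GROUPS = ("g2", "g4", "g6")


def toxicology_config(seed: int = 0, noise_sd: float = 0.5,
                      **overrides) -> SimulationConfig:
    """Config for the toxicology-panel scenario (7 groups x 5 repeats)."""
    effect = overrides.pop("effect", 3.0 * noise_sd)
    return SimulationConfig(
        n_groups=7, reps=5, noise_sd=noise_sd,
        latent_positions=toxicology_layout(effect),
        reference_group=0, seed=seed, **overrides)


def simulate_probe_level(config: SimulationConfig, probes_per_gene: int,
                         effect_genes: Sequence[str] = (),
                         effect_size: float = 1.0) -> ProbeLevelData:
    """Probe-level data for the ANOVA filter, additive by construction.

    value = gene baseline + probe sensitivity + group shift + Normal(0, sd).
    Genes in ``effect_genes`` shift every non-control group by
    ``effect_size``; all other genes are null.  Gene ids are ``item0000``..
    as in :func:`simulate_experiment`.
    """
    if probes_per_gene < 2:
        raise UsageError("probes_per_gene must be >= 2")
    rng = np.random.default_rng(config.seed)
    reps = config.reps_list
    groups = [group_label(i) for i in range(config.n_groups)]
    sample_ids = [f"{groups[gi]}_s{r}"
                  for gi in range(config.n_groups) for r in range(reps[gi])]
    sample_group_idx = np.repeat(np.arange(config.n_groups), reps)
    gene_ids = [f"item{i:04d}" for i in range(config.n_items)]
    effect_set = set(effect_genes)
    unknown = effect_set - set(gene_ids)
    if unknown:
        raise UsageError(f"effect genes outside the gene set: {sorted(unknown)}")

    n = len(sample_ids)
    p = probes_per_gene
    baselines = rng.normal(config.baseline_mean, config.baseline_sd,
                           config.n_items)
    sensitivities = rng.normal(0.0, 1.0, (config.n_items, p))
    noise = rng.normal(0.0, config.noise_sd, (config.n_items, p, n))
    group_shift = (sample_group_idx != 0).astype(float) * effect_size

    blocks = []
    for gi, gene in enumerate(gene_ids):
        block = (baselines[gi]
                 + sensitivities[gi][:, None]
                 + noise[gi])
        if gene in effect_set:
            block = block + group_shift[None, :]
        blocks.append(block)
    arr = np.concatenate(blocks, axis=0)
    index = pd.MultiIndex.from_tuples(
        [(g, f"p{j}") for g in gene_ids for j in range(p)],
        names=["gene_id", "probe_id"])
    return ProbeLevelData(values=pd.DataFrame(arr, index=index,
                                              columns=sample_ids))
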