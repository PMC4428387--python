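"""Synthetic two-platform expression data with pathway-structured signal.

The generator emulates the study design in which the same biological samples
are profiled on two platforms (an array-like and a sequencing-like one).  One
latent log10 expression value exists per gene and sample; each platform
observes it through its own gene-specific multiplicative bias, independent
per-measurement noise, and dropout:

    observed = 10 ** (latent + bias[gene, platform] + eps),   eps ~ N(0, sigma_platform)

then zeroed with probability ``dropout_rate``.  Control samples scatter around
a per-gene baseline with biological noise ``sigma_bio``; in case samples a
chosen fraction of pathways is perturbed, shifting every member gene by
``delta * sign(ARR) * direction`` on the log10 scale — so an up-perturbed
pathway has its activators up and its repressors down, and its true pathway
activation is positive.

Because the case-to-normal ratio divides a case value by the mean of control
values from the *same* platform, the gene x platform bias cancels exactly in
the noise-free limit; independent per-measurement noise does not cancel at
the gene level but is averaged down by the pathway sum.  The default
configuration is the ``heavy-noise regime`` preset: heavy per-measurement noise
(sd 1.0 / 0.8 log10 units), gene-platform bias sd 0.5, dropout 10% / 2%, and
a modest 0.5 log10 perturbation — the regime where gene-level cross-platform
correlation collapses while pathway-level correlation survives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .pathway_db import ArrRole, Pathway, PathwayDB
from .scoring import PASMatrix

__all__ = [
    "SimConfig",
    "SimOutput",
    "SimulationError",
    "heavy_noise_regime",
    "make_fixture_db",
    "simulate_two_platforms",
    "expected_pas_sign_check",
]


class SimulationError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass(frozen=True)
class SimConfig:
    """Synthetic study configuration.

    Defaults are the ``heavy-noise regime`` preset: 90 pathways of 30 genes (the
    scale of a curated signaling knowledge base), 4 case vs 4 control samples
    (a treated-vs-untreated cell-line design), and the platform error levels
    described in the module docstring.

    n_pathways, genes_per_pathway
        Knowledge-base size; member genes are unique to their pathway so the
        expected pathway score is analytically transparent.
    activator_fraction
        Probability a member is an activator (ARR +1) rather than a repressor
        (ARR -1); partial roles (+/-0.5, 0) can be mixed in via
        ``partial_role_fraction``.
    perturbed_fraction
        Fraction of pathways truly perturbed in case samples, each with a
        random up/down direction.
    delta
        Log10 effect size applied to members of perturbed pathways
        (sign follows ARR and the pathway direction).
    sigma_bio
        Biological sample-to-sample sd of latent log10 expression (shared by
        both platforms — it is real signal variation).
    sigma_platform, dropout_rate
        Per-platform measurement noise sd (log10) and zero-observation
        probability, one value per platform.
    bias_sd
        Sd of the fixed gene x platform log10 offset (probe affinity /
        mappability style bias).
    base_mean, base_sd
        Distribution of per-gene baseline log10 expression.
    """

    n_pathways: int = 90
    genes_per_pathway: int = 30
    activator_fraction: float = 0.7
    partial_role_fraction: float = 0.0
    n_case: int = 4
    n_control: int = 4
    perturbed_fraction: float = 0.3
    delta: float = 0.5
    sigma_bio: float = 0.3
    sigma_platform: Tuple[float, float] = (1.0, 0.8)
    bias_sd: float = 0.5
    dropout_rate: Tuple[float, float] = (0.1, 0.02)
    base_mean: float = 2.0
    base_sd: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pathways", "genes_per_pathway", "n_case", "n_control"):
            if getattr(self, name) < 1:
                raise SimulationError(f"{name} must be >= 1")
        for name in ("activator_fraction", "partial_role_fraction",
                     "perturbed_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1]")
        for name in ("sigma_bio", "bias_sd", "base_sd"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if len(self.sigma_platform) != 2 or any(s < 0 for s in self.sigma_platform):
            raise SimulationError("sigma_platform must be two sds >= 0")
        if len(self.dropout_rate) != 2 or any(not 0 <= d <= 1 for d in self.dropout_rate):
            raise SimulationError("dropout_rate must be two probabilities in [0, 1]")


def heavy_noise_regime(seed: int = 0, **overrides) -> SimConfig:
    """The default heavy-noise preset (see module docstring), seedable."""
    return replace(SimConfig(seed=seed), **overrides)


@dataclass
class SimOutput:
    """A simulated two-platform study.

    ``truth`` records the latent log10 matrix and, per perturbed pathway, its
    direction (+1 up, -1 down).  Both platforms share gene and sample ids.
    """

    config: SimConfig
    db: PathwayDB
    latent_log10: pd.DataFrame
    perturbed: Dict[str, int]
    platform_a: ExpressionMatrix
    platform_b: ExpressionMatrix

    @property
    def case_ids(self) -> Tuple[str, ...]:
        return self.platform_a.case_ids


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), stream])


_ROLE_CHOICES = (0.5, -0.5, 0.0)


def make_fixture_db(cfg: SimConfig) -> PathwayDB:
    """Synthetic pathway database: disjoint membership, random ARR roles.

    Each pathway gets ``genes_per_pathway`` unique genes; a member is an
    activator with probability ``activator_fraction`` and a repressor
    otherwise, except that with probability ``partial_role_fraction`` it is
    instead given one of the partial roles {+0.5, -0.5, 0}.  Deterministic
    under ``cfg.seed``.
    """
    rng = _rng(cfg, 0)
    pathways: List[Pathway] = []
    gene_no = 0
    for k in range(cfg.n_pathways):
        members: Dict[str, ArrRole] = {}
        for _ in range(cfg.genes_per_pathway):
            gene_no += 1
            gene = f"G{gene_no:05d}"
            if rng.random() < cfg.partial_role_fraction:
                role = ArrRole(_ROLE_CHOICES[rng.integers(len(_ROLE_CHOICES))])
            elif rng.random() < cfg.activator_fraction:
                role = ArrRole(1.0)
            else:
                role = ArrRole(-1.0)
            members[gene] = role
        pathways.append(
            Pathway(id=f"P{k + 1:03d}", name=f"Synthetic pathway {k + 1}", members=members)
        )
    return PathwayDB(pathways=pathways, version=f"synthetic-seed{cfg.seed}")


def simulate_two_platforms(cfg: SimConfig) -> SimOutput:
    """Draw a complete two-platform case/control study from the configuration.

    Randomness is split into fixed seeded streams (db, truth, platform A,
    platform B) so outputs are reproducible bit-for-bit from ``cfg``.
    """
    db = make_fixture_db(cfg)
    genes = [g for p in db for g in p.members]
    n_genes = len(genes)
    case_ids = [f"CASE{i + 1}" for i in range(cfg.n_case)]
    control_ids = [f"CTRL{i + 1}" for i in range(cfg.n_control)]
    samples = case_ids + control_ids

    rng = _rng(cfg, 1)
    base = rng.normal(cfg.base_mean, cfg.base_sd, size=n_genes)
    latent = base[:, None] + rng.normal(
        0.0, cfg.sigma_bio, size=(n_genes, len(samples))
    )

    n_perturbed = int(round(cfg.perturbed_fraction * cfg.n_pathways))
    chosen = rng.choice(cfg.n_pathways, size=n_perturbed, replace=False)
    directions = rng.choice([-1, 1], size=n_perturbed)
    perturbed = {
        db.pathways[int(k)].id: int(d) for k, d in zip(np.sort(chosen), directions)
    }
    # shift members of perturbed pathways in the case samples only
    gene_index = {g: i for i, g in enumerate(genes)}
    shift = np.zeros(n_genes)
    for pid, direction in perturbed.items():
        for gene, role in db[pid].members.items():
            shift[gene_index[gene]] = cfg.delta * direction * np.sign(float(role))
    latent[:, : cfg.n_case] += shift[:, None]

    latent_df = pd.DataFrame(latent, index=genes, columns=samples)

    platforms = []
    for k, label in enumerate(("platformA-array", "platformB-rnaseq")):
        prng = _rng(cfg, 2 + k)
        bias = prng.normal(0.0, cfg.bias_sd, size=n_genes)
        eps = prng.normal(0.0, cfg.sigma_platform[k], size=latent.shape)
        observed = 10.0 ** (latent + bias[:, None] + eps)
        if cfg.dropout_rate[k] > 0:
            observed = np.where(
                prng.random(size=latent.shape) < cfg.dropout_rate[k], 0.0, observed
            )
        platforms.append(
            ExpressionMatrix(
                data=pd.DataFrame(observed, index=genes, columns=samples),
                platform_label=label,
                control_ids=tuple(control_ids),
            )
        )

    return SimOutput(
        config=cfg,
        db=db,
        latent_log10=latent_df,
        perturbed=perturbed,
        platform_a=platforms[0],
        platform_b=platforms[1],
    )


def expected_pas_sign_check(out: SimOutput, pas: PASMatrix) -> float:
    """Fraction of truly perturbed pathways whose mean case PAS sign matches truth.

    A parameter-recovery harness: for each perturbed pathway, the PAS values
    of the case samples are averaged and the sign compared with the simulated
    direction.  A zero mean score counts as a miss.
    """
    if not out.perturbed:
        raise SimulationError("no pathways were perturbed in this simulation")
    hits = 0
    for pid, direction in out.perturbed.items():
        mean_pas = float(pas.pas.loc[pid].mean())
        if np.sign(mean_pas) == direction:
            hits += 1
    return hits / len(out.perturbed)
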