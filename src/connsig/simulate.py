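"""Synthetic cohorts, signatures, behavior scores and donor expression.

These generators produce data with the statistical structure the analysis
assumes — multi-site case/control z-connectome cohorts with planted
connection-level effects and covariate confounds, gene-dosage mirror pairs,
behavior scores tied to signature similarity, and donor-level expression
with spatial gradients — so every stage of the pipeline is testable without
any clinical or donor data. All generators are pure functions of their
configuration and seed.

By default connectomes are drawn directly in Fisher-z space (per-connection
Gaussians around a baseline), which matches the additive linear model the
association stage fits; a channel-time-series mode exercises the raw
correlation pathway for integration tests. Covariate defaults loosely mirror
developmental case/control cohorts: ages 6-45 years, balanced sex, 2 sites,
framewise displacement around 0.14-0.19 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import ATLAS_COLUMNS, RegionAtlas
from .connectome import ChannelTimeSeries, n_pairs
from .cwas import CohortDataset
from .exceptions import ConfigurationError
from .similarity import similarity_scores


@dataclass
class SimulationConfig:
    """Conditions for one synthetic case/control cohort.

    ``effect_map`` is the planted case-minus-control difference per
    connection, in control-SD units; ``global_shift`` adds a uniform
    displacement on top. ``dosage_ratio`` scales the duplication arm of a
    mirror pair (duplication effect = -dosage_ratio * deletion effect).
    Covariate slopes are drawn once per cohort with the given SDs, giving
    realistic site/sex/age/motion confounds that the models must absorb.
    """

    n_regions: int = 64
    n_networks: int = 12
    n_cases: int = 40
    n_controls: int = 40
    effect_map: np.ndarray | None = None
    global_shift: float = 0.0
    dosage_ratio: float = 1.0
    noise_sd: float = 1.0
    n_sites: int = 2
    site_offset_sd: float = 0.1
    sex_offset_sd: float = 0.05
    age_slope_sd: float = 0.005
    fd_slope_sd: float = 0.5
    age_range: tuple[float, float] = (6.0, 45.0)
    sex_p: float = 0.5
    fd_mean: float = 0.16
    fd_sd: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 2 or self.n_controls < 2 or self.n_sites < 1:
            raise ConfigurationError("counts must be >= 2 (sites >= 1)")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.effect_map is not None:
            self.effect_map = np.asarray(self.effect_map, dtype=float)
            if self.effect_map.size != n_pairs(self.n_regions):
                raise ConfigurationError("effect_map length must be R(R+1)/2")

    @property
    def n_connections(self) -> int:
        return n_pairs(self.n_regions)


def generate_atlas(n_regions: int = 64, n_networks: int = 12, seed: int = 0) -> RegionAtlas:
    """Atlas with contiguous region ids split into near-equal network blocks."""
    if n_networks > n_regions:
        raise ConfigurationError("n_networks cannot exceed n_regions")
    blocks = np.array_split(np.arange(n_regions), n_networks)
    rows = []
    for net_id, block in enumerate(blocks):
        for region in block:
            rows.append(
                {
                    "region_id": int(region),
                    "region_name": f"region_{region:02d}",
                    "network_id": net_id,
                    "network_name": f"network_{net_id:02d}",
                }
            )
    return RegionAtlas(pd.DataFrame(rows, columns=ATLAS_COLUMNS))


def _covariates(config: SimulationConfig, n: int, role: str, rng: np.random.Generator,
                prefix: str = "") -> pd.DataFrame:
    lo, hi = config.age_range
    return pd.DataFrame(
        {
            "subject_id": [f"{prefix}{role}_{i:04d}" for i in range(n)],
            "group": role,
            "role": role,
            "sex": rng.binomial(1, config.sex_p, size=n),
            "site": rng.integers(0, config.n_sites, size=n),
            "age": rng.uniform(lo, hi, size=n),
            "mean_fd": np.exp(
                rng.normal(np.log(config.fd_mean), config.fd_sd / config.fd_mean, size=n)
            ),
        }
    )


def generate_cohort(
    config: SimulationConfig,
    atlas: RegionAtlas | None = None,
    contrast_name: str = "synthetic",
) -> CohortDataset:
    """One case/control cohort of z-space connectomes.

    Controls: baseline 0 per connection plus site offsets, sex offsets,
    centered age and motion slopes, and Gaussian noise. Cases additionally
    receive ``effect_map + global_shift``. Bit-identical for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    L = config.n_connections
    effect = np.zeros(L) if config.effect_map is None else config.effect_map

    prefix = f"{contrast_name}_{config.seed}_"
    pheno = pd.concat(
        [
            _covariates(config, config.n_controls, "control", rng, prefix),
            _covariates(config, config.n_cases, "case", rng, prefix),
        ],
        ignore_index=True,
    )
    # per-connection confound structure, shared by cases and controls
    site_offsets = rng.normal(0, config.site_offset_sd, size=(config.n_sites, L))
    sex_offsets = rng.normal(0, config.sex_offset_sd, size=L)
    age_slopes = rng.normal(0, config.age_slope_sd, size=L)
    fd_slopes = rng.normal(0, config.fd_slope_sd, size=L)

    n = len(pheno)
    age_c = pheno["age"].to_numpy() - np.mean(config.age_range)
    fd_c = pheno["mean_fd"].to_numpy() - config.fd_mean
    conn = (
        site_offsets[pheno["site"].to_numpy()]
        + np.outer(pheno["sex"].to_numpy(), sex_offsets)
        + np.outer(age_c, age_slopes)
        + np.outer(fd_c, fd_slopes)
        + rng.normal(0, config.noise_sd, size=(n, L))
    )
    is_case = (pheno["role"] == "case").to_numpy()
    conn[is_case] += effect + config.global_shift
    return CohortDataset(phenotypes=pheno, connectomes=conn, contrast_name=contrast_name)


def sparse_effect_map(
    n_regions: int, n_affected: int, delta: float, seed: int = 0
) -> np.ndarray:
    """Effect map with ``delta`` planted on ``n_affected`` random connections."""
    rng = np.random.default_rng(seed)
    effect = np.zeros(n_pairs(n_regions))
    idx = rng.choice(effect.size, size=n_affected, replace=False)
    effect[idx] = delta
    return effect


def generate_mirror_pair(
    config: SimulationConfig, atlas: RegionAtlas | None = None
) -> tuple[CohortDataset, CohortDataset]:
    """Deletion/duplication cohorts with opposite planted effects.

    The duplication cohort's effect map is ``-dosage_ratio`` times the
    deletion's; controls and noise are resampled independently (distinct
    seeds derived from ``config.seed``).
    """
    if config.dosage_ratio < 0:
        raise ConfigurationError("dosage_ratio must be >= 0")
    from dataclasses import replace

    seeds = np.random.SeedSequence(config.seed).generate_state(2) % (2**31)
    effect = np.zeros(config.n_connections) if config.effect_map is None else config.effect_map
    del_cfg = replace(config, seed=int(seeds[0]), effect_map=effect)
    dup_cfg = replace(
        config,
        seed=int(seeds[1]),
        effect_map=-config.dosage_ratio * effect,
        global_shift=-config.dosage_ratio * config.global_shift,
    )
    deletion = generate_cohort(del_cfg, atlas, contrast_name="deletion")
    duplication = generate_cohort(dup_cfg, atlas, contrast_name="duplication")
    return deletion, duplication


def generate_behavior(
    dataset: CohortDataset,
    signature: np.ndarray,
    slope: float = 1.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    score_name: str = "score",
) -> pd.Series:
    """Behavior scores tied to each subject's signature similarity.

    ``score_i = slope * Pearson(signature, connectome_i) + N(0, noise_sd)``;
    the scores are also attached to the dataset's phenotype table.
    """
    rng = np.random.default_rng(seed)
    sims = similarity_scores(np.asarray(signature, dtype=float), dataset.connectomes)
    scores = slope * sims + rng.normal(0, noise_sd, size=sims.size)
    dataset.phenotypes[score_name] = scores
    return pd.Series(scores, name=score_name)


def smooth_gradient(n_regions: int, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency spatial gradient over region index, standardized."""
    idx = np.arange(n_regions)
    a, b, phase = rng.normal(size=3)
    g = a * np.sin(2 * np.pi * idx / n_regions + phase) + b * np.cos(
        4 * np.pi * idx / n_regions
    )
    g = g - g.mean()
    sd = g.std()
    return g / sd if sd > 0 else g


def generate_expression_dataset(
    atlas: RegionAtlas,
    n_genes: int = 200,
    n_donors: int = 6,
    samples_per_region: int = 2,
    signal_genes: dict[str, tuple[np.ndarray, float]] | None = None,
    noise_sd: float = 0.3,
    sample_noise_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Donor-level expression samples with planted spatial structure.

    Gene g's regional profile is ``w_g * target_g + (1 - w_g) * gradient +
    regional noise`` where the gradient is one smooth spatial pattern shared
    by all genes; decoy genes have w = 0. Donor samples add sample-level
    noise, and a per-gene affine distortion (scale/offset) emulates raw
    microarray units that the sigmoid normalization must remove.

    ``signal_genes`` maps a gene name to (target regional vector, mixing
    weight in [0, 1]). Returns a tidy sample table (one row per sample).
    """
    rng = np.random.default_rng(seed)
    r = atlas.n_regions
    signal_genes = signal_genes or {}
    for name, (target, w) in signal_genes.items():
        if not (0.0 <= w <= 1.0):
            raise ConfigurationError(f"mixing weight for {name} outside [0, 1]")
        if np.asarray(target).size != r:
            raise ConfigurationError(f"target vector for {name} must have length R")

    n_decoys = n_genes - len(signal_genes)
    if n_decoys < 0:
        raise ConfigurationError("more signal genes than n_genes")
    genes = list(signal_genes) + [f"decoy_{k:04d}" for k in range(n_decoys)]

    gradient = smooth_gradient(r, rng)
    profiles = np.empty((r, n_genes))
    for g, name in enumerate(genes):
        if name in signal_genes:
            target, w = signal_genes[name]
            target = np.asarray(target, dtype=float)
            tsd = target.std()
            target = (target - target.mean()) / (tsd if tsd > 0 else 1.0)
        else:
            target, w = np.zeros(r), 0.0
        profiles[:, g] = w * target + (1 - w) * gradient + rng.normal(0, noise_sd, size=r)

    gene_scale = np.exp(rng.normal(0.5, 0.3, size=n_genes))
    gene_offset = rng.normal(8.0, 1.0, size=n_genes)

    rows = []
    sample_counter = 0
    for donor in range(n_donors):
        for region in range(r):
            for _ in range(samples_per_region):
                expr = profiles[region] + rng.normal(0, sample_noise_sd, size=n_genes)
                expr = gene_offset + gene_scale * expr
                rows.append(
                    {
                        "donor_id": f"donor_{donor}",
                        "sample_id": f"sample_{sample_counter:05d}",
                        "region_id": region,
                        **{g: v for g, v in zip(genes, expr)},
                    }
                )
                sample_counter += 1
    return pd.DataFrame(rows)


def generate_time_series(
    atlas: RegionAtlas,
    n_timepoints: int = 100,
    channels_per_region: int = 3,
    coupling: np.ndarray | None = None,
    seed: int = 0,
) -> ChannelTimeSeries:
    """Channel-level signals whose region means have a known coupling.

    Each region owns a latent series; channels are the latent plus channel
    noise. ``coupling`` (R x R correlation-like mixing of the latents) lets
    integration tests exercise :func:`connsig.connectome.compute_connectome`.
    """
    rng = np.random.default_rng(seed)
    r = atlas.n_regions
    latents = rng.normal(size=(n_timepoints, r))
    if coupling is not None:
        chol = np.linalg.cholesky(np.asarray(coupling, dtype=float))
        latents = latents @ chol.T
    values = np.empty((n_timepoints, r * channels_per_region))
    channel_region = np.repeat(np.arange(r), channels_per_region)
    for c in range(values.shape[1]):
        values[:, c] = latents[:, channel_region[c]] + rng.normal(
            0, 0.5, size=n_timepoints
        )
    return ChannelTimeSeries(values=values, channel_region=channel_region)
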