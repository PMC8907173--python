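"""Synthetic twin cohorts with planted genotype-microbiome associations.

The generator emulates the structure of a twin-registry metagenome
study: female twin pairs (monozygotic pairs share identical genotypes;
dizygotic pairs inherit from explicitly simulated parental haplotypes,
sharing half their alleles identical-by-descent on average), biallelic
loci in Hardy-Weinberg equilibrium arranged in linkage-disequilibrium
blocks, covariates (shared twin age, individual BMI, shipment batch),
and Tweedie compound Poisson-gamma feature abundances.

A planted latent factor ties the two views together: the standardized
sum of the planted variants' dosages (plus noise) shifts the log-mean
of the planted features, so the true association is a single common
factor -- the data-generating model the sparse CCA is built to detect.
The cohort records its ground truth, giving every other module a
parameter-recovery target.

All randomness flows through one seeded generator: identical config and
seed give a bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .abundance import FeatureTable
from .genotype import GenotypeMatrix
from .tweedie import sample_tweedie

__all__ = ["SimulationConfig", "SyntheticCohort", "simulate_genotypes", "simulate_cohort"]


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the emulated study scale: 150 twin pairs (35:92
    MZ:DZ ratio), 2,000 loci with MAF uniform on [0.10, 0.50] in LD
    blocks of 10, 1,000 Tweedie features with power 1.6 and dispersion
    2, and a planted factor of 5 variants driving 20 features with an
    effect of 0.5 on the log-mean per latent SD.
    """

    n_pairs: int = 150
    mz_fraction: float = 35 / 127
    n_loci: int = 2000
    maf_range: tuple = (0.10, 0.50)
    ld_block_size: int = 10
    ld_block_rho: float = 0.85
    n_features: int = 1000
    tweedie_p: float = 1.6
    tweedie_phi: float = 2.0
    n_planted_snp_groups: int = 5
    n_planted_features: int = 20
    effect_size: float = 0.5
    latent_noise_sd: float = 0.2
    n_factors: int = 1
    factor_strengths: tuple = (1.0, 0.7)
    baseline_mu_range: tuple = (0.5, 50.0)
    planted_mu_range: tuple = (10.0, 50.0)
    gene_length_range: tuple = (300, 3000)
    library_scale_sd: float = 0.3
    n_shipments: int = 3
    shipment_effects: tuple = (0.0, 0.2, -0.1)
    age_range: tuple = (40.0, 75.0)
    age_effect: float = 0.005
    bmi_mean: float = 26.0
    bmi_sd: float = 4.0
    bmi_effect: float = 0.02
    seed: int = 20220309

    def __post_init__(self):
        if not (1.0 < self.tweedie_p < 2.0):
            raise ValueError("tweedie_p must lie in (1, 2)")
        if self.tweedie_phi <= 0:
            raise ValueError("tweedie_phi must be > 0")
        for name in ("n_pairs", "n_loci", "n_features", "ld_block_size", "n_shipments"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.mz_fraction <= 1.0):
            raise ValueError("mz_fraction must lie in [0, 1]")
        if self.n_planted_snp_groups > self.n_loci // self.ld_block_size:
            raise ValueError("more planted variant groups than LD blocks")
        if self.n_planted_features > self.n_features:
            raise ValueError("more planted features than features")
        if len(self.shipment_effects) < self.n_shipments:
            raise ValueError("one shipment effect per shipment level required")
        if not (1 <= self.n_factors <= min(self.n_planted_snp_groups, self.n_planted_features)):
            raise ValueError("n_factors must fit within the planted sets")
        if len(self.factor_strengths) < self.n_factors:
            raise ValueError("one strength per latent factor required")


@dataclass
class SyntheticCohort:
    """Generated data plus ground truth."""

    genotypes: GenotypeMatrix
    counts: FeatureTable
    covariates: pd.DataFrame
    truth: dict


def _haplotypes(rng, n_hap, mafs, block_size, rho):
    """Correlated 0/1 haplotypes via a per-block latent Gaussian factor."""
    n_loci = len(mafs)
    thresholds = _norm_ppf(mafs)
    haps = np.empty((n_hap, n_loci), dtype=np.int8)
    for start in range(0, n_loci, block_size):
        stop = min(start + block_size, n_loci)
        width = stop - start
        z = rng.standard_normal((n_hap, 1))
        eps = rng.standard_normal((n_hap, width))
        latent = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * eps
        haps[:, start:stop] = latent < thresholds[start:stop]
    return haps


def _norm_ppf(q):
    from scipy.stats import norm

    return norm.ppf(q)


def simulate_genotypes(config: SimulationConfig, rng: np.random.Generator):
    """Twin-structured genotype matrix in HWE with LD blocks.

    Each pair has two simulated parents (four founder haplotypes); a
    child inherits one haplotype per parent, re-drawn independently per
    LD block (recombination between blocks only, preserving within-block
    LD).  MZ pairs duplicate one child; DZ pairs are two independent
    children of the same parents, hence half-IBD on average.

    Returns ``(GenotypeMatrix, sample_ids, family_ids, zygosity)``.
    """
    n_pairs = config.n_pairs
    n_mz = int(round(config.mz_fraction * n_pairs))
    mafs = rng.uniform(*config.maf_range, size=config.n_loci)
    n_blocks = -(-config.n_loci // config.ld_block_size)
    # four founder haplotypes per pair: mother x2, father x2
    founders = _haplotypes(
        rng, 4 * n_pairs, mafs, config.ld_block_size, config.ld_block_rho
    ).reshape(n_pairs, 4, config.n_loci)

    def child(pair):
        mom, dad = founders[pair, :2], founders[pair, 2:]
        pick_m = rng.integers(0, 2, size=n_blocks)
        pick_d = rng.integers(0, 2, size=n_blocks)
        hap_m = np.empty(config.n_loci, dtype=np.int8)
        hap_d = np.empty(config.n_loci, dtype=np.int8)
        for b in range(n_blocks):
            s = b * config.ld_block_size
            e = min(s + config.ld_block_size, config.n_loci)
            hap_m[s:e] = mom[pick_m[b], s:e]
            hap_d[s:e] = dad[pick_d[b], s:e]
        return hap_m + hap_d

    calls = np.empty((2 * n_pairs, config.n_loci), dtype=np.int8)
    zygosity, family_ids = [], []
    for pair in range(n_pairs):
        zyg = "MZ" if pair < n_mz else "DZ"
        first = child(pair)
        second = first if zyg == "MZ" else child(pair)
        calls[2 * pair] = first
        calls[2 * pair + 1] = second
        zygosity += [zyg, zyg]
        family_ids += [f"F{pair:04d}"] * 2
    sample_ids = [f"S{i:04d}" for i in range(2 * n_pairs)]
    locus_ids = [f"rs{j:05d}" for j in range(config.n_loci)]
    g = GenotypeMatrix(
        pd.DataFrame(calls.astype(float), index=sample_ids, columns=locus_ids),
        pd.DataFrame(
            {"chrom": "1", "pos": np.arange(config.n_loci)}, index=locus_ids
        ),
    )
    return g, sample_ids, family_ids, zygosity


def simulate_cohort(config: SimulationConfig | None = None) -> SyntheticCohort:
    """Full synthetic cohort: genotypes, covariates, Tweedie abundances.

    The latent factor per sample is the standardized sum of the planted
    variants' additive dosages plus Gaussian noise (SD
    ``latent_noise_sd``), re-standardized.  Feature log-means are

        log mu = log(baseline) + effect * u * 1[planted]
                 + age and BMI terms + shipment offset,

    and abundances are compound Poisson-gamma draws at
    ``(tweedie_p, tweedie_phi)``, multiplied by a per-sample log-normal
    library factor and per-feature gene length (per kb) to emulate the
    raw-count scale the normalization step removes.  An effect size of 0
    yields a valid null cohort with truth still recorded.
    """
    config = config if config is not None else SimulationConfig()
    rng = np.random.default_rng(config.seed)
    g, sample_ids, family_ids, zygosity = simulate_genotypes(config, rng)
    n = len(sample_ids)

    # covariates: twins share age; BMI individual; shipment per sample
    age_pair = rng.uniform(*config.age_range, size=config.n_pairs)
    age = np.repeat(age_pair, 2)
    bmi = rng.normal(config.bmi_mean, config.bmi_sd, size=n)
    shipment = rng.integers(0, config.n_shipments, size=n)
    cov = pd.DataFrame(
        {
            "age": age,
            "bmi": bmi,
            "shipment": [f"ship{s}" for s in shipment],
            "family_id": family_ids,
            "zygosity": zygosity,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # planted variants: one locus in each of several distinct LD blocks
    n_blocks = config.n_loci // config.ld_block_size
    blocks = rng.choice(n_blocks, size=config.n_planted_snp_groups, replace=False)
    planted_loci_idx = np.sort(
        blocks * config.ld_block_size
        + rng.integers(0, config.ld_block_size, size=config.n_planted_snp_groups)
    )
    planted_loci = [g.calls.columns[j] for j in planted_loci_idx]

    # baselines first: planted features are drawn from the detectable
    # abundance range (an effect on a nearly-always-zero feature is an
    # unidentifiable truth no method could be scored against)
    feature_ids = [f"K{j:05d}" for j in range(config.n_features)]
    lo, hi = config.baseline_mu_range
    baseline = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_features))
    plo, phi_ = config.planted_mu_range
    eligible = np.flatnonzero((baseline >= plo) & (baseline <= phi_))
    if len(eligible) < config.n_planted_features:
        eligible = np.arange(config.n_features)
    planted_feat_idx = np.sort(
        rng.choice(eligible, size=config.n_planted_features, replace=False)
    )
    planted_features = [feature_ids[j] for j in planted_feat_idx]

    # one latent factor per planted-set partition: u_k is the
    # standardized dosage sum of the factor's variants plus noise
    snp_parts = np.array_split(np.arange(config.n_planted_snp_groups), config.n_factors)
    feat_parts = np.array_split(np.arange(config.n_planted_features), config.n_factors)
    dosage = g.calls.to_numpy(dtype=float)[:, planted_loci_idx]
    log_mu = np.tile(np.log(baseline)[:, None], (1, n))
    latents = []
    for k in range(config.n_factors):
        genetic = dosage[:, snp_parts[k]].sum(axis=1)
        genetic = (genetic - genetic.mean()) / (genetic.std() + 1e-12)
        u_k = genetic + config.latent_noise_sd * rng.standard_normal(n)
        u_k = (u_k - u_k.mean()) / u_k.std()
        latents.append(u_k)
        rows = planted_feat_idx[feat_parts[k]]
        strength = config.effect_size * config.factor_strengths[k]
        log_mu[rows, :] += strength * u_k[None, :]
    u = latents[0]
    ship_fx = np.asarray(config.shipment_effects)[shipment]
    log_mu += (
        config.age_effect * (age - age.mean())
        + config.bmi_effect * (bmi - bmi.mean())
        + ship_fx
    )[None, :]
    abundances = sample_tweedie(
        np.exp(log_mu), config.tweedie_phi, config.tweedie_p, rng
    )

    lengths = rng.integers(*config.gene_length_range, size=config.n_features)
    library = np.exp(rng.normal(0.0, config.library_scale_sd, size=n))
    counts = abundances * (lengths[:, None] / 1000.0) * library[None, :]
    table = FeatureTable(
        pd.DataFrame(counts, index=feature_ids, columns=sample_ids),
        lengths=pd.Series(lengths, index=feature_ids, name="length"),
    )
    block_of = {
        lid: j // config.ld_block_size for j, lid in enumerate(g.calls.columns)
    }
    planted_blocks = [
        [l for l, b in block_of.items() if b == block_of[p]] for p in planted_loci
    ]
    truth = {
        "planted_loci": planted_loci,
        "planted_features": planted_features,
        "planted_block_members": planted_blocks,
        "factor_loci": [[planted_loci[i] for i in part] for part in snp_parts],
        "factor_features": [[planted_features[i] for i in part] for part in feat_parts],
        "latent": u,
        "latents": latents,
        "config": asdict(config),
    }
    return SyntheticCohort(genotypes=g, counts=table, covariates=cov, truth=truth)
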