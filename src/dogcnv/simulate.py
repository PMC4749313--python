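"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here with
planted truth, so each stage is verifiable end to end:

* :func:`simulate_breed_cnv` — per-breed diploid copy-number calls under
  a stabilizing-selection regime (tight spread around an adaptive
  optimum) or a drift regime (wide spread around a lower mean), with
  ddPCR-style measurement noise and integer rounding.
* :func:`simulate_acgh` — two-breed per-site log2-ratio tables whose
  null sites lie on a known line, with a focal site planted off-line.
* :func:`simulate_genotypes` — dog and wolf genotype panels under a
  Balding–Nichols-style drift model, with an optional wolf-introgressed
  breed and planted high-|ΔDAF| ancestry-informative loci.
* :func:`simulate_latitude_dataset` — breed latitudes plus copy-number
  calls whose mean is latitude-independent but whose spread follows a
  configurable variance model.

Each generator is a pure function of its config (including the seed):
replaying the same config reproduces the data exactly, and changing
only the seed changes the draws but not the ground-truth parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError
from .io import BreedInfo, CnvCall, GeneRegion
from .datasets import REPORTED_AMY2B_BREED_STATS, study_breed_info

__all__ = [
    "BreedSim",
    "CnvSimConfig",
    "GenoSimConfig",
    "simulate_breed_cnv",
    "simulate_acgh",
    "simulate_genotypes",
    "simulate_latitude_dataset",
    "study_cnv_config",
    "study_scale_bundle",
]

_REGIMES = ("selection", "drift")


@dataclass(frozen=True)
class BreedSim:
    """One breed's generating regime: 'selection' centers a tight
    truncated normal on the adaptive optimum; 'drift' uses a wider one."""

    name: str
    regime: str
    n_samples: int
    center: float  # optimum (selection) or drift mean, diploid copies
    sd: float

    def __post_init__(self) -> None:
        if self.regime not in _REGIMES:
            raise ConfigError(f"unknown regime {self.regime!r}; use one of {_REGIMES}")
        if self.n_samples < 1:
            raise ConfigError(f"{self.name}: n_samples must be >= 1")
        if self.sd < 0:
            raise ConfigError(f"{self.name}: sd must be >= 0")


@dataclass(frozen=True)
class CnvSimConfig:
    breeds: tuple
    gene: str = "AMY2B"
    measurement_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.measurement_sd < 0:
            raise ConfigError("measurement_sd must be >= 0")


def study_cnv_config(seed: int = 0, measurement_sd: float = 0.3) -> CnvSimConfig:
    """Study-scale scenario: five breed labels at the published per-breed
    sample sizes, means and SDs, selection regime for the high-starch
    breeds and drift for the low-starch ones (80 calls in total)."""
    breeds = tuple(
        BreedSim(name=name, regime="selection" if starch == "high" else "drift",
                 n_samples=n, center=mean, sd=sd)
        for name, n, starch, mean, sd in REPORTED_AMY2B_BREED_STATS)
    return CnvSimConfig(breeds=breeds, seed=seed, measurement_sd=measurement_sd)


def _truncnorm_at_zero(rng, center: float, sd: float, size: int) -> np.ndarray:
    """Normal(center, sd) truncated below at 0 (copy numbers are counts)."""
    if sd == 0.0:
        return np.full(size, max(center, 0.0))
    a = (0.0 - center) / sd
    return sps.truncnorm.rvs(a, np.inf, loc=center, scale=sd, size=size,
                             random_state=rng)


def simulate_breed_cnv(config: CnvSimConfig) -> tuple[list[CnvCall], dict]:
    """Generate per-sample copy-number calls plus the ground truth.

    True copy numbers are drawn from each breed's truncated normal; the
    observed raw value adds measurement noise (truncated at 0) and the
    integer call rounds half away from zero, mirroring how ddPCR point
    estimates are reported.
    """
    rng = np.random.default_rng(config.seed)
    calls: list[CnvCall] = []
    for breed in config.breeds:
        true_cn = _truncnorm_at_zero(rng, breed.center, breed.sd, breed.n_samples)
        noise = (rng.normal(0.0, config.measurement_sd, breed.n_samples)
                 if config.measurement_sd > 0 else np.zeros(breed.n_samples))
        raw = np.maximum(true_cn + noise, 0.0)
        err = np.abs(rng.normal(config.measurement_sd, config.measurement_sd / 4,
                                breed.n_samples)) if config.measurement_sd > 0 \
            else np.zeros(breed.n_samples)
        slug = breed.name.lower().replace(" ", "_")
        for i in range(breed.n_samples):
            calls.append(CnvCall.from_raw(
                sample_id=f"{slug}_{i:03d}", breed=breed.name, gene=config.gene,
                raw=float(raw[i]), technical_error=float(err[i])))
    truth = {
        "gene": config.gene,
        "measurement_sd": config.measurement_sd,
        "seed": config.seed,
        "breeds": [{"name": b.name, "regime": b.regime, "n_samples": b.n_samples,
                    "center": b.center, "sd": b.sd} for b in config.breeds],
    }
    return calls, truth


def simulate_acgh(n_null_sites: int = 156, slope: float = 1.0,
                  intercept: float = 0.0, noise_sd: float = 0.15,
                  focal_offset: float = 0.9, samples_per_site: int = 4,
                  sample_jitter_sd: float = 0.05,
                  x_range: tuple = (-1.0, 1.0), focal_x: float = 0.5,
                  breed_x: str = "Alaskan Malamute", breed_y: str = "Shar Pei",
                  seed: int = 0) -> tuple[pd.DataFrame, tuple, dict]:
    """Two-breed aCGH site table with a planted off-line focal point.

    Null-site x means are uniform on ``x_range``; y means follow
    slope·x + intercept plus vertical normal noise. Per-sample values
    jitter around each site mean, with the jitter centered per site so
    the site mean is reproduced exactly (so zero noise and zero offset
    give a focal z of exactly 0). The focal point sits at ``focal_x``
    with ``focal_offset`` added to its on-line y value; it is returned
    separately and never appears among the null sites.
    """
    if n_null_sites < 3:
        raise ConfigError("need >= 3 null sites")
    if samples_per_site < 1:
        raise ConfigError("samples_per_site must be >= 1")
    rng = np.random.default_rng(seed)
    x_means = rng.uniform(x_range[0], x_range[1], n_null_sites)
    noise = rng.normal(0.0, noise_sd, n_null_sites) if noise_sd > 0 \
        else np.zeros(n_null_sites)
    y_means = slope * x_means + intercept + noise
    rows = []
    for i in range(n_null_sites):
        site_id = f"site_{i:04d}"
        start = 1_000_000 + i * 50_000
        for breed, mean in ((breed_x, x_means[i]), (breed_y, y_means[i])):
            jitter = rng.normal(0.0, sample_jitter_sd, samples_per_site)
            jitter -= jitter.mean()  # exact site mean by construction
            for j in range(samples_per_site):
                rows.append({"site_id": site_id, "chrom": "chr1", "start": start,
                             "end": start + 10_000, "breed": breed,
                             "sample_id": f"{breed}_{j}",
                             "log2": mean + jitter[j]})
    focal_y = slope * focal_x + intercept + focal_offset
    table = pd.DataFrame(rows)
    truth = {"slope": slope, "intercept": intercept, "noise_sd": noise_sd,
             "focal_offset": focal_offset, "focal_x": focal_x, "focal_y": focal_y,
             "n_null_sites": n_null_sites, "breed_x": breed_x, "breed_y": breed_y,
             "seed": seed}
    return table, (focal_x, focal_y), truth


@dataclass(frozen=True)
class GenoSimConfig:
    """Genotype-panel scenario: several dog breeds plus a wolf population.

    Background allele frequencies follow a Balding–Nichols-style model:
    a shared ancestral frequency q ~ Beta(ancestral_beta) per locus, and
    dog/wolf frequencies drawn from Beta(q·k, (1−q)·k) with k =
    ``drift_k`` (divergence F_ST ≈ 1/(k+1)). Planted ancestry-informative
    loci get dog and wolf frequencies (1±effect)/2 so their ΔDAF is the
    planted effect; they are placed inside ``planted_region`` (plus
    optionally ``n_planted_outside`` elsewhere). The introgressed breed
    draws each haplotype from the wolf frequency with probability
    ``introgression_fraction``, otherwise from the dog frequency.
    """

    n_loci: int = 1000
    populations: tuple = (("breed_a", 20), ("breed_b", 20), ("breed_c", 20),
                          ("breed_d", 20), ("wolf", 20))
    wolf_population: str = "wolf"
    ancestral_beta: tuple = (0.7, 0.7)
    drift_k: float = 10.0
    introgressed_breed: str | None = "breed_a"
    introgression_fraction: float = 0.5
    n_planted_aisnps: int = 3
    n_planted_outside: int = 0
    planted_effect: float = 0.8
    planted_region: GeneRegion | None = field(
        default_factory=lambda: GeneRegion(gene="AMY2B", chrom="chr6",
                                           window_start=1_000_000,
                                           window_end=1_500_000))
    chroms: tuple = ("chr1", "chr6")
    locus_spacing: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.introgression_fraction <= 1.0):
            raise ConfigError("introgression_fraction must be in [0, 1]")
        if self.n_planted_aisnps + self.n_planted_outside > self.n_loci:
            raise ConfigError("more planted loci than loci")
        names = [p[0] for p in self.populations]
        if self.wolf_population not in names:
            raise ConfigError(f"no population named {self.wolf_population!r}")
        if (self.introgressed_breed is not None
                and self.introgressed_breed not in names):
            raise ConfigError(
                f"introgressed breed {self.introgressed_breed!r} not in populations")


def _locus_positions(config: GenoSimConfig):
    """Cycle loci across chromosomes at fixed spacing."""
    chroms, positions = [], []
    counters = dict.fromkeys(config.chroms, 0)
    for i in range(config.n_loci):
        chrom = config.chroms[i % len(config.chroms)]
        counters[chrom] += 1
        chroms.append(chrom)
        positions.append(counters[chrom] * config.locus_spacing)
    return chroms, positions


def simulate_genotypes(config: GenoSimConfig):
    """Generate loci, a derived-dosage matrix, a population map and truth.

    Returns ``(loci, dosages, pop_map, truth)`` where ``dosages`` has
    loci as rows and samples as columns, ``pop_map`` maps sample id to
    population, and ``truth`` records the planted locus indices, the
    introgressed breed, and the generating frequencies.
    """
    from .introgression import Locus

    rng = np.random.default_rng(config.seed)
    chroms, positions = _locus_positions(config)
    loci = [Locus(chrom=c, pos=p, ancestral_allele="A", derived_allele="G")
            for c, p in zip(chroms, positions)]

    a, b = config.ancestral_beta
    q = rng.beta(a, b, config.n_loci)
    q = np.clip(q, 1e-3, 1 - 1e-3)
    k = config.drift_k
    p_wolf = rng.beta(q * k, (1 - q) * k)
    p_dog = rng.beta(q * k, (1 - q) * k)

    region = config.planted_region
    in_region = [i for i, loc in enumerate(loci)
                 if region is not None and region.contains(loc.chrom, loc.pos)]
    if region is not None and len(in_region) < config.n_planted_aisnps:
        raise ConfigError(
            f"planted region holds only {len(in_region)} loci; "
            f"cannot plant {config.n_planted_aisnps}")
    planted_in = in_region[:config.n_planted_aisnps] if region is not None \
        else list(range(config.n_planted_aisnps))
    outside_pool = [i for i in range(config.n_loci) if i not in set(planted_in)
                    and (region is None or not region.contains(loci[i].chrom,
                                                               loci[i].pos))]
    planted_out = outside_pool[:config.n_planted_outside]
    planted = planted_in + planted_out
    hi = (1.0 + config.planted_effect) / 2.0
    lo = (1.0 - config.planted_effect) / 2.0
    p_dog[planted] = hi
    p_wolf[planted] = lo

    columns: dict[str, np.ndarray] = {}
    pop_map: dict[str, str] = {}
    for pop, n_ind in config.populations:
        if pop == config.wolf_population:
            p = p_wolf
            mixture = None
        elif pop == config.introgressed_breed:
            p = p_dog
            mixture = config.introgression_fraction
        else:
            p = p_dog
            mixture = None
        for j in range(n_ind):
            sid = f"{pop}_{j:03d}"
            pop_map[sid] = pop
            if mixture is None:
                dos = rng.binomial(2, p).astype(float)
            else:
                # two haplotypes, each wolf-derived with prob = fraction
                from_wolf = rng.random((config.n_loci, 2)) < mixture
                freqs = np.where(from_wolf, p_wolf[:, None], p_dog[:, None])
                dos = (rng.random((config.n_loci, 2)) < freqs).sum(axis=1) \
                    .astype(float)
            columns[sid] = dos
    dosages = pd.DataFrame(columns)
    truth = {
        "planted_indices": planted,
        "planted_in_region": planted_in,
        "planted_outside": planted_out,
        "planted_effect": config.planted_effect,
        "introgressed_breed": config.introgressed_breed,
        "introgression_fraction": config.introgression_fraction,
        "wolf_population": config.wolf_population,
        "seed": config.seed,
    }
    return loci, dosages, pop_map, truth


def simulate_latitude_dataset(n_below: int = 75, n_above: int = 177,
                              split_degrees: float = 40.0,
                              latitude_range: tuple = (5.0, 68.0),
                              mean_cn: float = 11.8,
                              variance_model=None,
                              calls_per_breed: int = 4,
                              seed: int = 0):
    """Breed latitudes plus calls with latitude-independent mean.

    ``variance_model`` maps absolute latitude to the copy-number SD
    (default: SD 4.4 below the split and 5.3 at or above it, the spreads
    seen at study scale). Returns (calls, breeds, truth).
    """
    if variance_model is None:
        def variance_model(lat):  # noqa: ANN001 - simple default model
            return 4.4 if lat < split_degrees else 5.3
    rng = np.random.default_rng(seed)
    calls: list[CnvCall] = []
    breeds: list[BreedInfo] = []
    truth_breeds = []
    counter = 0
    for side, n_calls, lat_lo, lat_hi in (
            ("below", n_below, latitude_range[0], split_degrees),
            ("above", n_above, split_degrees, latitude_range[1])):
        remaining = n_calls
        while remaining > 0:
            size = min(calls_per_breed, remaining)
            lat = float(rng.uniform(lat_lo, lat_hi))
            # keep strictly on the intended side of the split
            if side == "below":
                lat = min(lat, np.nextafter(split_degrees, -np.inf))
            name = f"breed_{counter:03d}"
            counter += 1
            sd = float(variance_model(abs(lat)))
            breeds.append(BreedInfo(breed=name, latitude_origin=lat,
                                    diet_labels={}))
            truth_breeds.append({"breed": name, "latitude": lat, "sd": sd})
            values = _truncnorm_at_zero(rng, mean_cn, sd, size)
            for i in range(size):
                calls.append(CnvCall.from_raw(sample_id=f"{name}_{i:02d}",
                                              breed=name, gene="AMY2B",
                                              raw=float(values[i]),
                                              source="aggregated"))
            remaining -= size
    truth = {"mean_cn": mean_cn, "split_degrees": split_degrees,
             "n_below": n_below, "n_above": n_above, "seed": seed,
             "breeds": truth_breeds}
    return calls, breeds, truth


def study_scale_bundle(seed: int = 0):
    """Convenience: study-scale CNV calls plus the matching breed metadata."""
    calls, truth = simulate_breed_cnv(study_cnv_config(seed=seed))
    return calls, study_breed_info(), truth
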