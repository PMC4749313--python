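"""ΔDAF introgression scan: ancestry-informative SNPs and wolf-allele frequencies.

For every biallelic locus with an ancestral-allele designation, the
derived allele frequency (DAF) is computed in a pooled dog panel and a
wolf panel; ΔDAF = DAF_dogs − DAF_wolves. Loci whose ΔDAF lies more
than two genome-wide standard deviations from the genome-wide mean are
ancestry-informative SNPs (aiSNPs). Within a gene window — the span
between the transcription start sites of the flanking genes, padded by
500 kb on either side — aiSNPs are extracted and each breed's frequency
of the "wolf allele" (the allele at higher frequency in wolves) is
ranked; wolf introgression into a breed would put that breed at the top.

Genotypes are derived-allele dosages (0/1/2, NaN missing) in a pandas
DataFrame with one row per locus and one column per sample, built either
directly or from a VCF with an ancestral-allele INFO field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, InputError, ValidationError
from .io import GeneRegion
from .stats import TestResult, welch_t_test

__all__ = [
    "Locus",
    "AiSnpScan",
    "BreedAlleleFreq",
    "derived_allele_freq",
    "delta_daf_scan",
    "threshold_moments",
    "chromosome_control",
    "gene_region",
    "aisnps_in_region",
    "wolf_allele_freq_by_breed",
    "load_genotypes_vcf",
    "load_dosage_table",
    "load_population_map",
]


@dataclass(frozen=True)
class Locus:
    """A biallelic site with ancestral/derived designation.

    ``pos`` is 0-based internally; VCF-style 1-based positions are
    converted at the boundary (`from_vcf_pos`).
    """

    chrom: str
    pos: int
    ancestral_allele: str
    derived_allele: str

    def __post_init__(self) -> None:
        if self.ancestral_allele == self.derived_allele:
            raise ValidationError(
                f"{self.chrom}:{self.pos}: ancestral and derived alleles identical")

    @classmethod
    def from_vcf_pos(cls, chrom: str, pos1: int, ancestral: str,
                     derived: str) -> "Locus":
        return cls(chrom=chrom, pos=pos1 - 1, ancestral_allele=ancestral,
                   derived_allele=derived)


@dataclass(frozen=True)
class AiSnpScan:
    """Genome-wide ΔDAF moments, aiSNP thresholds, and per-locus flags."""

    genome_mean: float
    genome_sd: float
    multiplier: float
    upper_threshold: float
    lower_threshold: float
    flags: np.ndarray
    degenerate: bool = False

    @property
    def n_flagged(self) -> int:
        return int(np.nansum(self.flags))


@dataclass(frozen=True)
class BreedAlleleFreq:
    """A breed's frequency of the wolf allele at one aiSNP."""

    breed: str
    locus: Locus
    wolf_allele: str
    wolf_allele_freq: float
    tie_flag: bool


def derived_allele_freq(dosages: pd.DataFrame, samples) -> pd.DataFrame:
    """Per-locus derived allele frequency over a set of samples.

    ``dosages`` holds derived-allele dosages 0/1/2 (NaN = missing) with
    loci as rows and samples as columns. Frequency is derived count over
    2 × non-missing individuals; loci with no non-missing individual get
    NaN frequency and n_chrom 0.
    """
    samples = list(samples)
    missing = [s for s in samples if s not in dosages.columns]
    if missing:
        raise ValidationError(f"samples absent from genotype panel: {missing}")
    sub = dosages[samples].to_numpy(dtype=float)
    n_obs = np.sum(~np.isnan(sub), axis=1)
    n_chrom = 2 * n_obs
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_chrom > 0, np.nansum(sub, axis=1) / n_chrom, np.nan)
    return pd.DataFrame({"daf": freq, "n_chrom": n_chrom}, index=dosages.index)


def delta_daf_scan(dogs: pd.DataFrame, wolves: pd.DataFrame,
                   multiplier: float = 2.0) -> tuple[pd.DataFrame, AiSnpScan]:
    """Per-locus ΔDAF with genome-wide moments and aiSNP flags.

    ``dogs`` and ``wolves`` are `derived_allele_freq` outputs over the
    same loci in the same order. The genome-wide mean and SD (n−1) of
    ΔDAF over loci with both frequencies non-missing set the thresholds
    mean ± multiplier·SD; a locus is flagged when its ΔDAF exceeds the
    upper or falls below the lower threshold (strict inequalities on
    both sides). A zero SD yields a degenerate scan with no flags.
    """
    if not dogs.index.equals(wolves.index):
        raise InputError("dog and wolf frequency tables cover different loci")
    delta = dogs["daf"].to_numpy() - wolves["daf"].to_numpy()
    usable = ~np.isnan(delta)
    if usable.sum() < 2:
        raise InputError("need >= 2 loci with non-missing ΔDAF")
    mean = float(np.mean(delta[usable]))
    sd = float(np.std(delta[usable], ddof=1))
    upper = mean + multiplier * sd
    lower = mean - multiplier * sd
    degenerate = sd == 0.0
    if degenerate:
        flags = np.zeros(delta.shape, dtype=bool)
    else:
        with np.errstate(invalid="ignore"):
            flags = (delta > upper) | (delta < lower)
        flags &= usable
    table = pd.DataFrame({
        "daf_dogs": dogs["daf"].to_numpy(),
        "daf_wolves": wolves["daf"].to_numpy(),
        "delta_daf": delta,
        "n_chrom_dogs": dogs["n_chrom"].to_numpy(),
        "n_chrom_wolves": wolves["n_chrom"].to_numpy(),
        "aisnp": flags,
    }, index=dogs.index)
    return table, AiSnpScan(genome_mean=mean, genome_sd=sd, multiplier=multiplier,
                            upper_threshold=upper, lower_threshold=lower,
                            flags=flags, degenerate=degenerate)


def threshold_moments(upper: float, lower: float,
                      multiplier: float = 2.0) -> tuple[float, float]:
    """Invert mean ± multiplier·SD thresholds back to the genome moments.

    mean = (upper + lower) / 2 and SD = (upper − lower) / (2·multiplier);
    the exact inverse of the threshold construction in
    :func:`delta_daf_scan`.
    """
    if upper < lower:
        raise InputError("upper threshold below lower threshold")
    return (upper + lower) / 2.0, (upper - lower) / (2.0 * multiplier)


def chromosome_control(scan: pd.DataFrame, loci, chrom: str) -> TestResult:
    """Welch t-test of one chromosome's ΔDAF against the genome-wide set.

    A sanity check that no single chromosome's ΔDAF distribution departs
    from the genome-wide one; the chromosome's loci remain part of the
    genome-wide sample, so comparing a chromosome that IS the whole
    genome gives t = 0, p = 1.
    """
    chroms = np.array([loc.chrom for loc in loci])
    if len(chroms) != len(scan):
        raise InputError("loci list and scan table differ in length")
    on_chrom = chroms == chrom
    if on_chrom.sum() == 0:
        raise InputError(f"no loci on chromosome {chrom!r}")
    delta = scan["delta_daf"].to_numpy()
    usable = ~np.isnan(delta)
    chrom_vals = delta[on_chrom & usable]
    genome_vals = delta[usable]
    if chrom_vals.size < 2:
        raise InputError(f"chromosome {chrom!r} has < 2 usable loci")
    return welch_t_test(chrom_vals, genome_vals)


def gene_region(gene: str, chrom: str, flank_upstream_tss: int,
                flank_downstream_tss: int, pad: int = 500_000) -> GeneRegion:
    """Window between the flanking genes' TSSs, padded on either side.

    The default 500 kb pad matches the typical length of wolf-introgressed
    haplotypes in dogs. The window start clamps at 0; coordinates are
    0-based half-open.
    """
    if flank_upstream_tss >= flank_downstream_tss:
        raise InputError(
            f"upstream TSS {flank_upstream_tss} must be < downstream TSS "
            f"{flank_downstream_tss}")
    return GeneRegion(gene=gene, chrom=chrom,
                      window_start=max(0, flank_upstream_tss - pad),
                      window_end=flank_downstream_tss + pad)


def aisnps_in_region(scan: pd.DataFrame, loci, region: GeneRegion) -> list[int]:
    """Indices of flagged loci inside the region (half-open on the right)."""
    flags = scan["aisnp"].to_numpy()
    return [i for i, loc in enumerate(loci)
            if flags[i] and region.contains(loc.chrom, loc.pos)]


def wolf_allele_freq_by_breed(dosages: pd.DataFrame, pop_map: dict,
                              wolves: pd.DataFrame, loci, indices,
                              breeds=None, wolf_population: str = "wolf"
                              ) -> tuple[list[BreedAlleleFreq], list[str]]:
    """Per-breed wolf-allele frequencies at selected loci, with a ranking.

    The wolf allele at a locus is the allele at higher frequency in
    wolves: derived when the wolves' DAF exceeds ½, ancestral when below,
    and — by deterministic convention — derived with ``tie_flag`` set at
    exactly ½. Returns the per-breed per-locus frequencies and the breed
    labels ranked by descending mean wolf-allele frequency across the
    selected loci.
    """
    by_pop: dict[str, list[str]] = {}
    for sample, pop in pop_map.items():
        by_pop.setdefault(pop, []).append(sample)
    if breeds is None:
        breeds = sorted(p for p in by_pop if p != wolf_population)
    absent = [b for b in breeds if b not in by_pop]
    if absent:
        raise ValidationError(f"breeds absent from genotype panel: {absent}")
    results: list[BreedAlleleFreq] = []
    means: dict[str, list[float]] = {b: [] for b in breeds}
    wolf_daf = wolves["daf"].to_numpy()
    for breed in breeds:
        freq = derived_allele_freq(dosages, by_pop[breed])
        daf = freq["daf"].to_numpy()
        for i in indices:
            w = wolf_daf[i]
            if math.isnan(w) or math.isnan(daf[i]):
                continue
            tie = bool(w == 0.5)
            wolf_is_derived = bool(w >= 0.5)
            loc = loci[i]
            allele = loc.derived_allele if wolf_is_derived else loc.ancestral_allele
            f = daf[i] if wolf_is_derived else 1.0 - daf[i]
            results.append(BreedAlleleFreq(breed=breed, locus=loc, wolf_allele=allele,
                                           wolf_allele_freq=float(f), tie_flag=tie))
            means[breed].append(float(f))
    ranking = sorted((b for b in breeds if means[b]),
                     key=lambda b: (-float(np.mean(means[b])), b))
    return results, ranking


def load_population_map(path) -> dict:
    """Read a two-column sample→population map (TSV or whitespace)."""
    out = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise FormatError(f"population map line {i}: need sample and population")
            out[parts[0]] = parts[1]
    return out


def load_genotypes_vcf(path, aa_field: str = "AA"
                       ) -> tuple[list[Locus], pd.DataFrame]:
    """Load biallelic SNPs from a VCF into loci + derived-dosage matrix.

    The ancestral allele comes from the INFO field named ``aa_field`` and
    must equal REF or ALT; records that are multiallelic, lack the field,
    or carry a third allele are skipped. Genotype dosages count copies
    of the derived (non-ancestral) allele; missing genotypes become NaN.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise FormatError(f"could not open VCF {path}: {exc}") from None
    samples = list(vcf.samples)
    loci: list[Locus] = []
    rows: list[np.ndarray] = []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        ancestral = var.INFO.get(aa_field)
        if ancestral is None:
            skipped += 1
            continue
        ancestral = str(ancestral).upper()
        ref, alt = var.REF.upper(), var.ALT[0].upper()
        if ancestral == ref:
            derived = alt
            flip = False
        elif ancestral == alt:
            derived = ref
            flip = True
        else:
            skipped += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types
        dos = np.full(len(samples), np.nan)
        dos[gt == 0] = 0.0
        dos[gt == 1] = 1.0
        dos[gt == 3] = 2.0
        if flip:
            dos = 2.0 - dos
        loci.append(Locus.from_vcf_pos(var.CHROM, var.POS, ancestral, derived))
        rows.append(dos)
    if not loci:
        raise FormatError(f"no usable biallelic records in {path} "
                          f"({skipped} skipped)")
    matrix = pd.DataFrame(np.vstack(rows), columns=samples)
    return loci, matrix


def load_dosage_table(path) -> tuple[list[Locus], pd.DataFrame]:
    """Load a flat dosage table: chrom, pos (1-based), ancestral, derived,
    then one column of 0/1/2 derived dosages per sample (empty = missing)."""
    df = pd.read_csv(path, sep=None, engine="python")
    meta = ["chrom", "pos", "ancestral", "derived"]
    missing = [c for c in meta if c not in df.columns]
    if missing:
        raise FormatError(f"dosage table missing columns: {missing}")
    loci = [Locus.from_vcf_pos(str(r.chrom), int(r.pos), str(r.ancestral),
                               str(r.derived))
            for r in df[meta].itertuples(index=False)]
    samples = [c for c in df.columns if c not in meta]
    matrix = df[samples].apply(pd.to_numeric, errors="coerce")
    matrix.index = pd.RangeIndex(len(matrix))
    return loci, matrix
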