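"""Domain types and readers/writers for the tabular inputs.

Copy-number calls arrive as delimited tables of per-sample diploid copy
numbers from droplet digital PCR (ddPCR) or aggregated from published
studies; breed metadata carries diet-category labels per nutrient and the
latitude of breed origin; cladograms arrive as newick. Comma and tab
delimiters are auto-detected from the header line. All genomic
coordinates are 0-based half-open internally; 1-based inputs are
converted at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import dendropy
import pandas as pd

from .errors import FormatError, SchemaError, ValidationError

__all__ = [
    "CnvCall",
    "BreedInfo",
    "GeneRegion",
    "round_half_away",
    "load_cnv_calls",
    "write_cnv_calls",
    "assemble_dataset",
    "load_breed_info",
    "load_cladogram",
    "missing_breeds",
    "load_regions_bed",
    "write_regions_bed",
    "NUTRIENTS",
    "DIET_CATEGORIES",
]

GENES = ("AMY2B", "GCKR", "PHYH")
NUTRIENTS = ("starch", "sugar", "phytanic_acid")
DIET_CATEGORIES = ("high", "moderate", "low")


def round_half_away(x: float) -> int:
    """Round to the nearest integer with ties going away from zero.

    ddPCR raw diploid copy numbers are rounded to whole copies; 7.5
    rounds to 8, −7.5 would round to −8 (negative copies never occur in
    valid data but the rule is total).
    """
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class CnvCall:
    """One sample's diploid copy-number measurement for one gene.

    ``raw_copy_number`` is the ddPCR point estimate in diploid copies and
    ``technical_error`` its per-reaction error estimate; both are None
    for calls aggregated from published studies that report only the
    integer copy number. ``copy_number`` is always the rounded integer
    used in the analyses.
    """

    sample_id: str
    breed: str
    gene: str
    copy_number: int
    raw_copy_number: float | None = None
    technical_error: float | None = None
    source: str = "collected"
    dna_concentration: float | None = None

    def __post_init__(self) -> None:
        if self.source not in ("collected", "aggregated"):
            raise ValidationError(f"unknown source {self.source!r}")
        if self.copy_number < 0:
            raise ValidationError(
                f"sample {self.sample_id}: negative copy number {self.copy_number}")
        if self.raw_copy_number is not None:
            if self.raw_copy_number < 0:
                raise ValidationError(
                    f"sample {self.sample_id}: negative raw copy number")
            if self.copy_number != round_half_away(self.raw_copy_number):
                raise ValidationError(
                    f"sample {self.sample_id}: copy_number {self.copy_number} is not "
                    f"raw {self.raw_copy_number} rounded half-away-from-zero")
        if self.technical_error is not None and self.technical_error < 0:
            raise ValidationError(
                f"sample {self.sample_id}: negative technical error")

    @classmethod
    def from_raw(cls, sample_id: str, breed: str, gene: str, raw: float,
                 technical_error: float | None = None, source: str = "collected",
                 dna_concentration: float | None = None) -> "CnvCall":
        return cls(sample_id=sample_id, breed=breed, gene=gene,
                   copy_number=round_half_away(raw), raw_copy_number=raw,
                   technical_error=technical_error, source=source,
                   dna_concentration=dna_concentration)


@dataclass(frozen=True)
class BreedInfo:
    """Per-breed metadata: latitude of origin and diet category per nutrient."""

    breed: str
    latitude_origin: float
    diet_labels: dict = field(default_factory=dict)
    clade: str | None = None

    def __post_init__(self) -> None:
        if not (-90.0 <= self.latitude_origin <= 90.0):
            raise ValidationError(
                f"breed {self.breed}: latitude {self.latitude_origin} outside [-90, 90]")
        for nutrient, category in self.diet_labels.items():
            if nutrient not in NUTRIENTS:
                raise SchemaError(f"unknown nutrient {nutrient!r}")
            if category is not None and category not in DIET_CATEGORIES:
                raise ValidationError(
                    f"breed {self.breed}: unknown diet category {category!r} "
                    f"for {nutrient}")


@dataclass(frozen=True)
class GeneRegion:
    """A genomic window around a gene, 0-based half-open."""

    gene: str
    chrom: str
    window_start: int
    window_end: int

    def __post_init__(self) -> None:
        if self.window_start < 0:
            raise ValidationError(f"{self.gene}: negative window start")
        if not self.window_start < self.window_end:
            raise ValidationError(
                f"{self.gene}: window_start {self.window_start} must be < "
                f"window_end {self.window_end}")

    def contains(self, chrom: str, pos0: int) -> bool:
        """Membership of a 0-based position, half-open on the right."""
        return chrom == self.chrom and self.window_start <= pos0 < self.window_end


def _read_table(path) -> pd.DataFrame:
    """Read a comma- or tab-delimited UTF-8 table, sniffing the header line."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _opt_float(text: str, what: str, row: int) -> float | None:
    if text.strip() == "":
        return None
    try:
        return float(text)
    except ValueError:
        raise ValidationError(f"row {row}: non-numeric {what}: {text!r}") from None


def load_cnv_calls(path, schema: dict | None = None,
                   breed_aliases: dict | None = None) -> list[CnvCall]:
    """Load per-sample copy-number calls from a delimited table.

    ``schema`` maps canonical column names (sample_id, breed, gene,
    raw_copy_number, copy_number, technical_error, source,
    dna_concentration) to the file's column names; unmapped names are
    looked up directly. ``breed_aliases`` maps file breed labels onto
    analysis labels (e.g. pooling Akita and Shiba Inu as Japanese dogs).
    Raw values are rounded half-away-from-zero; duplicate
    (sample_id, gene) pairs are rejected.
    """
    schema = schema or {}
    aliases = {k.lower(): v for k, v in (breed_aliases or {}).items()}
    df = _read_table(path)

    def col(name: str) -> str:
        return schema.get(name, name)

    for required in ("sample_id", "breed", "gene"):
        if col(required) not in df.columns:
            raise SchemaError(f"missing required column {col(required)!r}")
    has_raw = col("raw_copy_number") in df.columns
    has_cn = col("copy_number") in df.columns
    if not (has_raw or has_cn):
        raise SchemaError(
            "need at least one of columns "
            f"{col('raw_copy_number')!r} / {col('copy_number')!r}")

    calls: list[CnvCall] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        sample_id = rec[col("sample_id")].strip()
        breed = rec[col("breed")].strip()
        breed = aliases.get(breed.lower(), breed)
        gene = rec[col("gene")].strip()
        raw = _opt_float(rec.get(col("raw_copy_number"), ""), "raw_copy_number", i) \
            if has_raw else None
        err = _opt_float(rec.get(col("technical_error"), ""), "technical_error", i)
        conc = _opt_float(rec.get(col("dna_concentration"), ""), "dna_concentration", i)
        source = (rec.get(col("source"), "") or "collected").strip() or "collected"
        key = (sample_id, gene)
        if key in seen:
            raise ValidationError(f"row {i}: duplicate sample_id+gene pair {key}")
        seen.add(key)
        try:
            if raw is not None:
                if raw < 0:
                    raise ValidationError(f"negative raw copy number {raw}")
                call = CnvCall.from_raw(sample_id, breed, gene, raw,
                                        technical_error=err, source=source,
                                        dna_concentration=conc)
            else:
                cn_text = rec.get(col("copy_number"), "").strip()
                if cn_text == "":
                    raise ValidationError("no raw_copy_number and no copy_number")
                cn = int(round(float(cn_text)))
                call = CnvCall(sample_id=sample_id, breed=breed, gene=gene,
                               copy_number=cn, technical_error=err, source=source,
                               dna_concentration=conc)
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
        calls.append(call)
    return calls


def write_cnv_calls(calls, path) -> None:
    """Write calls with the canonical header; floats keep full precision."""
    rows = [{
        "sample_id": c.sample_id, "breed": c.breed, "gene": c.gene,
        "raw_copy_number": "" if c.raw_copy_number is None else repr(c.raw_copy_number),
        "copy_number": c.copy_number,
        "technical_error": "" if c.technical_error is None else repr(c.technical_error),
        "source": c.source,
        "dna_concentration": ("" if c.dna_concentration is None
                              else repr(c.dna_concentration)),
    } for c in calls]
    pd.DataFrame(rows, columns=["sample_id", "breed", "gene", "raw_copy_number",
                                "copy_number", "technical_error", "source",
                                "dna_concentration"]).to_csv(path, index=False)


def assemble_dataset(collected, aggregated) -> list[CnvCall]:
    """Union of collected and aggregated calls, preserving source tags.

    Rejects sample_id collisions for the same gene across the two lists,
    since a collision would double-count an individual.
    """
    keys_collected = {(c.sample_id, c.gene) for c in collected}
    collisions = sorted(k for k in ((a.sample_id, a.gene) for a in aggregated)
                        if k in keys_collected)
    if collisions:
        raise ValidationError(
            f"sample_id collisions across collected/aggregated: {collisions}")
    out = list(collected)
    out.extend(replace(a, source="aggregated") if a.source != "aggregated" else a
               for a in aggregated)
    return out


def load_breed_info(path) -> list[BreedInfo]:
    """Load breed metadata: breed, latitude, one column per nutrient, clade."""
    df = _read_table(path)
    for required in ("breed", "latitude"):
        if required not in df.columns:
            raise SchemaError(f"missing required column {required!r}")
    nutrient_cols = [c for c in df.columns if c in NUTRIENTS]
    infos = []
    for i, rec in enumerate(df.to_dict("records")):
        try:
            lat = float(rec["latitude"])
        except ValueError:
            raise ValidationError(f"row {i}: non-numeric latitude") from None
        labels = {}
        for nutrient in nutrient_cols:
            cat = rec[nutrient].strip().lower()
            if cat:
                labels[nutrient] = cat
        clade = rec.get("clade", "").strip() or None
        try:
            infos.append(BreedInfo(breed=rec["breed"].strip(), latitude_origin=lat,
                                   diet_labels=labels, clade=clade))
        except (ValidationError, SchemaError) as exc:
            raise type(exc)(f"row {i}: {exc}") from None
    return infos


def load_cladogram(path) -> dendropy.Tree:
    """Parse a newick cladogram whose leaves are breed labels."""
    try:
        return dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"could not parse newick file {path}: {exc}") from None


def missing_breeds(tree: dendropy.Tree, breeds) -> list[str]:
    """Breeds in the analysis set absent from the tree's leaf labels."""
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon}
    return sorted(b for b in breeds if b not in leaves)


def load_regions_bed(path) -> list[GeneRegion]:
    """Read gene windows from BED (3+ columns, 0-based half-open).

    Column 4, when present, names the gene; otherwise chrom:start-end.
    """
    regions = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise FormatError(f"BED line {i}: fewer than 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            regions.append(GeneRegion(gene=name, chrom=chrom,
                                      window_start=start, window_end=end))
    return regions


def write_regions_bed(regions, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.window_start}\t{r.window_end}\t{r.gene}\n")
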