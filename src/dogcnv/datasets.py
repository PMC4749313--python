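"""Published per-breed summaries and study-condition metadata.

The per-breed diploid AMY2B copy-number summaries reported for the six
study breeds (the two Japanese breeds, Akita and Shiba Inu, are pooled
under one label), together with breed metadata — approximate latitude of
breed origin and diet-category labels per nutrient — matching the
study's groupings. These printed summaries are inputs: they seed the
synthetic generator's study-scale scenario and let pooled group
statistics be recomputed without the per-sample tables.
"""

from __future__ import annotations

from .io import BreedInfo

__all__ = [
    "REPORTED_AMY2B_BREED_STATS",
    "study_breed_info",
    "pooled_mean",
    "HIGH_STARCH_BREEDS",
    "LOW_STARCH_BREEDS",
]

# breed, n, starch intake, reported mean, reported SD (diploid AMY2B copies)
REPORTED_AMY2B_BREED_STATS = (
    ("Chinese Shar Pei", 16, "high", 11.1, 2.7),
    ("Pekingese", 18, "high", 10.7, 1.7),
    ("Japanese Dogs", 14, "low", 8.3, 3.4),
    ("Siberian Husky", 17, "low", 7.8, 3.9),
    ("Alaskan Malamute", 15, "low", 6.1, 5.0),
)

HIGH_STARCH_BREEDS = tuple(r[0] for r in REPORTED_AMY2B_BREED_STATS if r[2] == "high")
LOW_STARCH_BREEDS = tuple(r[0] for r in REPORTED_AMY2B_BREED_STATS if r[2] == "low")

# Latitude of the breed's historical region of origin (degrees north) and
# diet categories per nutrient, following the study's groupings: starch
# high for the Chinese breeds; sugar moderate for Shar Pei, Pekingese and
# the Japanese dogs, low for the sled breeds; phytanic acid (ruminant
# meat / seafood) high for the sled and Japanese breeds.
_STUDY_BREEDS = (
    # breed, latitude, starch, sugar, phytanic_acid
    ("Chinese Shar Pei", 23.1, "high", "moderate", "low"),
    ("Pekingese", 39.9, "high", "moderate", "low"),
    ("Japanese Dogs", 36.2, "low", "moderate", "high"),
    ("Siberian Husky", 63.0, "low", "low", "high"),
    ("Alaskan Malamute", 64.1, "low", "low", "high"),
)


def study_breed_info() -> list[BreedInfo]:
    """Breed metadata for the six study breeds (Japanese breeds pooled)."""
    return [
        BreedInfo(breed=name, latitude_origin=lat,
                  diet_labels={"starch": starch, "sugar": sugar,
                               "phytanic_acid": phytanic})
        for name, lat, starch, sugar, phytanic in _STUDY_BREEDS
    ]


def pooled_mean(stats=REPORTED_AMY2B_BREED_STATS, starch: str | None = None
                ) -> tuple[int, float]:
    """Sample-size-weighted pooled mean from per-breed summaries.

    Returns (total n, pooled mean); restrict to one starch category with
    ``starch='high'`` or ``'low'``.
    """
    rows = [r for r in stats if starch is None or r[2] == starch]
    n = sum(r[1] for r in rows)
    total = sum(r[1] * r[3] for r in rows)
    return n, total / n
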