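"""ALT-ratio genotype binning.

The panel SNPs all have allele frequencies near 0.5, so in a single-genotype
sample the ALT ratio at each SNP sits near 0 (hom-ref, AA), 0.5 (het, AB) or
1 (hom-alt, BB). Binning the observed ratios recovers the recipient genotype
class without any external genotyping. Heterozygous SNPs show much larger
ALT-ratio variability than homozygous ones and are excluded from estimation;
ratios falling in the gaps between bins are treated as outliers and excluded
as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .panel import AltRatioProfile

# Closed ALT-ratio bins; values in the gaps (0.1, 0.4) and (0.6, 0.9) are excluded.
AA_BIN = (0.0, 0.1)
AB_BIN = (0.4, 0.6)
BB_BIN = (0.9, 1.0)


class GenotypeClass(str, Enum):
    AA = "AA"
    AB = "AB"
    BB = "BB"
    EXCLUDED = "EXCLUDED"


@dataclass
class ClassifiedProfile:
    """An ALT-ratio profile together with its per-SNP genotype class."""

    profile: AltRatioProfile
    classes: dict[str, GenotypeClass] = field(default_factory=dict)

    def snps_in_class(self, cls: GenotypeClass) -> list[str]:
        return [s for s, c in self.classes.items() if c is cls]

    def class_counts(self) -> dict[GenotypeClass, int]:
        counts = {c: 0 for c in GenotypeClass}
        for c in self.classes.values():
            counts[c] += 1
        return counts


def classify_ratio(ratio: float | None) -> GenotypeClass:
    """Bin one ALT ratio; bin edges are inclusive, undefined ratios excluded."""
    if ratio is None:
        return GenotypeClass.EXCLUDED
    if AA_BIN[0] <= ratio <= AA_BIN[1]:
        return GenotypeClass.AA
    if AB_BIN[0] <= ratio <= AB_BIN[1]:
        return GenotypeClass.AB
    if BB_BIN[0] <= ratio <= BB_BIN[1]:
        return GenotypeClass.BB
    return GenotypeClass.EXCLUDED


def classify(profile: AltRatioProfile) -> ClassifiedProfile:
    """Assign every SNP of the profile to AA / AB / BB / EXCLUDED.

    In baseline (pre-transplant) mode this is run on the pre sample, so the
    bins reflect the recipient genotype; in reference-free mode it is run on
    the post sample itself and the bins absorb the (small) donor-induced
    shift.
    """
    classes = {snp_id: classify_ratio(ratio) for snp_id, (ratio, _) in profile.rows.items()}
    return ClassifiedProfile(profile=profile, classes=classes)
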