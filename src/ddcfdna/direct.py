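"""Genotype-informed reference calculation of the dd-cfDNA fraction.

When recipient and donor SNP genotypes are both known, the mixture fraction
can be read off directly, without clustering: at an informative SNP — one
where the recipient is homozygous and the donor carries at least one
differing allele — a donor fraction f shifts the ALT ratio by f (donor
opposite-homozygous) or f/2 (donor heterozygous, hence the ×2 factor).
The per-SNP contributions are averaged into the reference estimate used for
clinical validation of the clustering-based method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .panel import AltRatioProfile

logger = logging.getLogger(__name__)

VALID_DOSAGES = (0, 1, 2)


class DirectEstimationError(RuntimeError):
    """Raised when no informative SNP is available."""


@dataclass
class GenotypeTable:
    """Per-SNP alternative-allele dosage (0/1/2) for one individual."""

    role: str  # "recipient" | "donor"
    rows: dict[str, int]

    def __post_init__(self) -> None:
        bad = {s: d for s, d in self.rows.items() if d not in VALID_DOSAGES}
        if bad:
            raise ValueError(f"dosages must be 0, 1 or 2; offending entries: {bad}")


@dataclass
class DirectResult:
    fraction: float
    n_informative: int
    n_skipped: int
    contributions: dict[str, float] = field(default_factory=dict)


def direct_dd(
    recipient: GenotypeTable,
    donor: GenotypeTable,
    post: AltRatioProfile,
    pre: AltRatioProfile | None = None,
) -> DirectResult:
    """Average per-SNP dd-cfDNA contributions over informative SNPs.

    recipient hom-ref (dosage 0): contribution = post − baseline ALT ratio;
    recipient hom-alt (dosage 2): contribution = baseline − post;
    doubled when the donor is heterozygous. The baseline is the measured
    pre-transplant ratio when a pre profile is supplied, otherwise the ideal
    homozygous value (0 or 1). Negative contributions (noise around f = 0)
    are kept unclipped so the mean stays unbiased. SNPs with missing
    genotypes or undefined ratios are skipped and logged.
    """
    contributions: dict[str, float] = {}
    n_skipped = 0
    for snp_id, r_dos in recipient.rows.items():
        if r_dos == 1:
            continue  # recipient heterozygous: not informative
        d_dos = donor.rows.get(snp_id)
        if d_dos is None:
            logger.debug("SNP %s skipped: no donor genotype", snp_id)
            n_skipped += 1
            continue
        if d_dos == r_dos:
            continue  # donor indistinguishable from recipient: not informative
        if snp_id not in post.rows or post.ratio(snp_id) is None:
            logger.debug("SNP %s skipped: no usable post-transplant ratio", snp_id)
            n_skipped += 1
            continue
        post_ratio = post.ratio(snp_id)
        if pre is not None and snp_id in pre.rows and pre.ratio(snp_id) is not None:
            baseline = pre.ratio(snp_id)
        else:
            baseline = 0.0 if r_dos == 0 else 1.0
        delta = post_ratio - baseline if r_dos == 0 else baseline - post_ratio
        if d_dos == 1:
            delta *= 2.0
        contributions[snp_id] = delta

    if not contributions:
        raise DirectEstimationError("no informative SNP (recipient homozygous, donor differing)")
    return DirectResult(
        fraction=float(np.mean(list(contributions.values()))),
        n_informative=len(contributions),
        n_skipped=n_skipped,
        contributions=contributions,
    )
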