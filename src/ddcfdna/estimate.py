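"""Clustering-based estimation of the donor-derived cfDNA fraction.

After transplantation, plasma cfDNA is a two-person mixture: a fraction f of
donor molecules on a background of recipient molecules. At a SNP where the
recipient is homozygous (say BB), the post-transplant ALT ratio depends on
the donor genotype:

    donor bb : shift 0          (BB/bb — recipient-like)
    donor ab : shift f/2        (BB/ab — heterozygous donor)
    donor aa : shift f          (BB/aa — fully mismatched donor)

so the per-SNP ALT-ratio shifts within the recipient-homozygous groups fall
into (up to) three components whose spacing encodes f. Clustering the shifts
with k = 3 (k = 2 for parent–child pairs, where a fully mismatched donor
genotype is Mendelian-impossible) and reading off the cluster means gives two
estimates per group — the span between the recipient-like and fully
mismatched clusters, and twice the gap to the heterozygous-donor cluster —
which are averaged into the final estimate.

With a pre-transplant baseline the shift is (post − pre) per SNP; without
one, the raw post ALT ratios are clustered instead, shifted by the ideal
homozygous baseline (0 for AA, 1 for BB) so both groups live on a common
scale. Cluster→genotype labels are assigned by magnitude of mean shift:
near-zero = recipient-like, largest = fully mismatched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .classify import ClassifiedProfile, GenotypeClass, classify
from .cluster import DEFAULT_MIN_CLUSTER_SIZE, ClusteringError, ClusterSet, prune_and_recluster
from .panel import AltRatioProfile

logger = logging.getLogger(__name__)

Relatedness = Literal["unrelated", "sibling", "parent_child"]

#: without a baseline, estimates above this level sit where the heterozygous
#: and fully-mismatched clusters start to overlap; flagged low-confidence
LOW_CONFIDENCE_THRESHOLD = 0.10


class EstimationError(RuntimeError):
    """Raised when neither SNP group supports a cluster-based estimate."""


@dataclass
class GroupResult:
    """Per-genotype-group (AA-side or BB-side) clustering outcome."""

    group: GenotypeClass
    clusters: ClusterSet | None
    component: float | None  # group dd-cfDNA estimate (fraction), None if unusable
    n_snps: int
    n_excluded: int
    flags: list[str] = field(default_factory=list)


@dataclass
class DdEstimate:
    """A dd-cfDNA fraction estimate with per-group diagnostics."""

    sample_id: str
    mode: Literal["with_pre", "without_pre"]
    relatedness: Relatedness
    combined: float
    aa: GroupResult | None
    bb: GroupResult | None
    flags: list[str] = field(default_factory=list)

    @property
    def aa_component(self) -> float | None:
        return self.aa.component if self.aa else None

    @property
    def bb_component(self) -> float | None:
        return self.bb.component if self.bb else None

    def to_dict(self) -> dict:
        def group(g: GroupResult | None) -> dict | None:
            if g is None:
                return None
            return {
                "component": g.component,
                "n_snps": g.n_snps,
                "n_excluded_outliers": g.n_excluded,
                "cluster_means": None if g.clusters is None else g.clusters.means.tolist(),
                "cluster_sizes": None if g.clusters is None else g.clusters.sizes.tolist(),
                "flags": g.flags,
            }

        return {
            "sample_id": self.sample_id,
            "mode": self.mode,
            "relatedness": self.relatedness,
            "combined": self.combined,
            "aa_group": group(self.aa),
            "bb_group": group(self.bb),
            "flags": self.flags,
        }


def k_for_relatedness(relatedness: Relatedness) -> int:
    """Three shift components in general; two for parent–child pairs, where
    opposite-homozygous donor genotypes cannot occur."""
    if relatedness not in ("unrelated", "sibling", "parent_child"):
        raise ValueError(f"unknown relatedness {relatedness!r}")
    return 2 if relatedness == "parent_child" else 3


def _component_from_clusters(cs: ClusterSet) -> float:
    """Group estimate from cluster mean shifts, labelled by |mean|.

    k=3: mean of (|mismatched − recipient-like|, 2·|het − recipient-like|);
    k=2: 2·|het − recipient-like| only.
    """
    order = np.argsort(np.abs(cs.means), kind="stable")
    rec = cs.means[order[0]]
    if cs.k == 2:
        het = cs.means[order[1]]
        return 2.0 * abs(het - rec)
    het = cs.means[order[1]]
    extreme = cs.means[order[2]]
    return float(np.mean([abs(extreme - rec), 2.0 * abs(het - rec)]))


def _estimate_group(
    shifts: np.ndarray,
    group: GenotypeClass,
    k: int,
    seed: int | None,
    min_cluster_size: int,
    method: str,
) -> GroupResult:
    n = len(shifts)
    if n < k:
        return GroupResult(
            group, None, None, n, 0, flags=[f"unusable: {n} SNPs < k={k}"]
        )
    if n > 0 and np.ptp(shifts) == 0.0:
        # all shifts identical (noise-free f=0): nothing to separate
        return GroupResult(group, None, 0.0, n, 0, flags=["no-donor-signal"])
    try:
        cs = prune_and_recluster(
            shifts, k, seed, min_cluster_size=min_cluster_size, method=method
        )
    except ClusteringError as exc:
        return GroupResult(group, None, None, n, 0, flags=[f"unusable: {exc}"])
    flags = []
    if cs.degenerate:
        flags.append("no-donor-signal")
        component = 0.0
    else:
        component = _component_from_clusters(cs)
    return GroupResult(group, cs, component, n - cs.n_excluded, cs.n_excluded, flags=flags)


def _combine(
    sample_id: str,
    mode: Literal["with_pre", "without_pre"],
    relatedness: Relatedness,
    aa: GroupResult,
    bb: GroupResult,
) -> DdEstimate:
    components = [g.component for g in (aa, bb) if g.component is not None]
    flags: list[str] = []
    if not components:
        raise EstimationError(
            f"{sample_id}: both SNP groups unusable "
            f"(AA: {aa.flags}, BB: {bb.flags})"
        )
    if len(components) == 1:
        flags.append("single-group-estimate")
    combined = float(np.mean(components))
    if mode == "without_pre" and combined > LOW_CONFIDENCE_THRESHOLD:
        flags.append("low-confidence->10%")
    if all("no-donor-signal" in g.flags for g in (aa, bb) if g.component is not None):
        flags.append("no-donor-signal")
    return DdEstimate(
        sample_id=sample_id,
        mode=mode,
        relatedness=relatedness,
        combined=combined,
        aa=aa,
        bb=bb,
        flags=flags,
    )


def estimate_with_pre(
    pre: ClassifiedProfile | AltRatioProfile,
    post: AltRatioProfile,
    relatedness: Relatedness = "unrelated",
    seed: int | None = None,
    *,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    k_override: int | None = None,
    method: str = "exact",
) -> DdEstimate:
    """Estimate the dd-cfDNA fraction using a pre-transplant baseline.

    SNPs are classed AA/AB/BB on the *pre* profile; for every AA- or BB-class
    SNP with a defined ratio in both samples, the shift post − pre is
    computed, the per-group shifts are clustered with outlier pruning, and
    the cluster-mean formulas give one component per group. The combined
    estimate is the mean of the usable group components.
    """
    if isinstance(pre, AltRatioProfile):
        pre = classify(pre)
    k = k_override if k_override is not None else k_for_relatedness(relatedness)

    groups: dict[GenotypeClass, GroupResult] = {}
    for cls in (GenotypeClass.AA, GenotypeClass.BB):
        snps = [
            s
            for s in pre.snps_in_class(cls)
            if pre.profile.ratio(s) is not None and s in post.rows and post.ratio(s) is not None
        ]
        shifts = np.array([post.ratio(s) - pre.profile.ratio(s) for s in snps], dtype=float)
        groups[cls] = _estimate_group(shifts, cls, k, seed, min_cluster_size, method)

    return _combine(post.sample_id, "with_pre", relatedness,
                    groups[GenotypeClass.AA], groups[GenotypeClass.BB])


def estimate_without_pre(
    post: AltRatioProfile,
    relatedness: Relatedness = "unrelated",
    seed: int | None = None,
    *,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    k_override: int | None = None,
    method: str = "exact",
) -> DdEstimate:
    """Estimate the dd-cfDNA fraction without a pre-transplant baseline.

    The post profile is classified on itself; within the AA and BB bins the
    raw ALT ratios are clustered directly (expressed as shifts from the
    ideal homozygous baseline, 0 for AA and 1 for BB — a common offset that
    leaves all cluster-mean differences unchanged). Estimates above ~10%
    are flagged low-confidence: without a baseline the heterozygous-donor
    and fully mismatched clusters start to overlap there.
    """
    classified = classify(post)
    k = k_override if k_override is not None else k_for_relatedness(relatedness)

    groups: dict[GenotypeClass, GroupResult] = {}
    for cls, baseline in ((GenotypeClass.AA, 0.0), (GenotypeClass.BB, 1.0)):
        snps = [s for s in classified.snps_in_class(cls) if post.ratio(s) is not None]
        shifts = np.array([post.ratio(s) - baseline for s in snps], dtype=float)
        groups[cls] = _estimate_group(shifts, cls, k, seed, min_cluster_size, method)

    result = _combine(post.sample_id, "without_pre", relatedness,
                      groups[GenotypeClass.AA], groups[GenotypeClass.BB])
    # a large donor fraction pushes het/mismatched SNPs out of the genotype
    # bins entirely; a high excluded share means the bins no longer reflect
    # the recipient genotype and the estimate cannot be trusted
    n_defined = len(post.defined_snps())
    n_excluded_bin = classified.class_counts()[GenotypeClass.EXCLUDED]
    undefined = len(post.rows) - n_defined
    if n_defined and (n_excluded_bin - undefined) / n_defined > 0.10:
        if "low-confidence->10%" not in result.flags:
            result.flags.append("low-confidence->10%")
    return result
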