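"""Synthetic data emulating the spike-in validation design.

Generates everything the pipeline consumes, from genotypes down to FASTQ
reads, so every stage can be exercised end to end without external data:

* recipient/donor genotype pairs at a panel of biallelic SNPs with allele
  frequencies near 0.5 (Hardy–Weinberg), under unrelated, full-sibling or
  parent→child relatedness;
* two-person mixture read counts at a given donor fraction f, with Poisson
  (or fixed) per-SNP depth and a symmetric per-read allele-flip error;
* binomial read downsampling, mimicking reduced cfDNA input;
* FASTQ reads with planted allele k-mers, for round-trip tests of the
  alignment-free counter.

All randomness flows from the single config seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .panel import (
    AlleleCountTable,
    AlleleKmerPair,
    SnpLocus,
    SnpPanel,
    reverse_complement,
)

BASES = "ACGT"

#: mixture grid of the spike-in experiment (donor fractions)
DEFAULT_MIXTURE_FRACTIONS = (0.0, 0.005, 0.01, 0.03, 0.05, 0.10, 0.50, 1.0)


@dataclass
class SimulationConfig:
    """Study conditions of the spike-in design.

    300 SNPs with minor allele frequency 0.45–0.5; mean depth 3000 reads/SNP
    (high enough that 0.5% mixtures are resolvable); allele-flip error rate
    0.001 approximating post-filter substitution error.
    """

    n_snps: int = 300
    maf_range: tuple[float, float] = (0.45, 0.5)
    relatedness: Literal["unrelated", "sibling", "parent_child"] = "unrelated"
    mixture_fractions: Sequence[float] = field(default_factory=lambda: DEFAULT_MIXTURE_FRACTIONS)
    mean_depth: float = 3000.0
    depth_model: Literal["poisson", "fixed"] = "poisson"
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")
        if any(not 0.0 <= f <= 1.0 for f in self.mixture_fractions):
            raise ValueError("mixture fractions must be in [0, 1]")
        if self.depth_model not in ("poisson", "fixed"):
            raise ValueError(f"unknown depth model {self.depth_model!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _hwe_alleles(q: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one haploid allele per SNP: 1 = alt with probability q."""
    return (rng.random(len(q)) < q).astype(int)


def simulate_pair_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
):
    """Draw a recipient/donor genotype pair under the configured relatedness.

    Per SNP the alternative-allele frequency is uniform in ``maf_range``.
    Unrelated: both dosages i.i.d. Hardy–Weinberg. Parent→child: the donor
    (parent) is HWE; the recipient (child) inherits one random parental
    allele plus one population allele, so an opposite-homozygous donor is
    impossible at any recipient-homozygous SNP. Sibling: both individuals
    drawn as full sibs of the same two HWE parents.

    Returns ``(recipient, donor)`` :class:`~ddcfdna.direct.GenotypeTable`\\ s.
    """
    from .direct import GenotypeTable

    rng = config.rng() if rng is None else rng
    n = config.n_snps
    q = rng.uniform(config.maf_range[0], config.maf_range[1], size=n)
    snp_ids = [f"snp{i:04d}" for i in range(n)]

    if config.relatedness == "unrelated":
        rec = _hwe_alleles(q, rng) + _hwe_alleles(q, rng)
        don = _hwe_alleles(q, rng) + _hwe_alleles(q, rng)
    elif config.relatedness == "parent_child":
        parent = np.stack([_hwe_alleles(q, rng), _hwe_alleles(q, rng)])
        transmitted = parent[rng.integers(0, 2, size=n), np.arange(n)]
        rec = transmitted + _hwe_alleles(q, rng)
        don = parent.sum(axis=0)
    elif config.relatedness == "sibling":
        p1 = np.stack([_hwe_alleles(q, rng), _hwe_alleles(q, rng)])
        p2 = np.stack([_hwe_alleles(q, rng), _hwe_alleles(q, rng)])
        def child() -> np.ndarray:
            a1 = p1[rng.integers(0, 2, size=n), np.arange(n)]
            a2 = p2[rng.integers(0, 2, size=n), np.arange(n)]
            return a1 + a2
        rec, don = child(), child()
    else:  # pragma: no cover - guarded by config validation
        raise ValueError(config.relatedness)

    recipient = GenotypeTable("recipient", dict(zip(snp_ids, map(int, rec))))
    donor = GenotypeTable("donor", dict(zip(snp_ids, map(int, don))))
    return recipient, donor


def simulate_counts(
    recipient,
    donor,
    f: float,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    sample_id: str | None = None,
) -> AlleleCountTable:
    """Mixture read counts at donor fraction ``f``.

    Per SNP: the alt-read probability is the dosage-weighted mixture
    p = (1−f)·d_r/2 + f·d_d/2, perturbed by the symmetric error rate ε to
    p' = p(1−ε) + (1−p)ε; depth is Poisson(mean_depth) or fixed; the alt
    count is Binomial(depth, p').
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("mixture fraction must be in [0, 1]")
    rng = config.rng() if rng is None else rng
    snp_ids = list(recipient.rows)
    d_r = np.array([recipient.rows[s] for s in snp_ids], dtype=float)
    d_d = np.array([donor.rows[s] for s in snp_ids], dtype=float)
    p_alt = (1.0 - f) * d_r / 2.0 + f * d_d / 2.0
    eps = config.error_rate
    p_obs = p_alt * (1.0 - eps) + (1.0 - p_alt) * eps
    if config.depth_model == "poisson":
        depth = rng.poisson(config.mean_depth, size=len(snp_ids))
    else:
        depth = np.full(len(snp_ids), int(round(config.mean_depth)))
    alt = rng.binomial(depth, p_obs)
    ref = depth - alt
    rows = {s: (int(r), int(a)) for s, r, a in zip(snp_ids, ref, alt)}
    return AlleleCountTable(sample_id or f"mix_{f:g}", rows)


def binomial_downsample(
    counts: AlleleCountTable, fraction: float, seed: int | np.random.Generator = 0
) -> AlleleCountTable:
    """Thin every read count c to Binomial(c, fraction), independently."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("downsampling fraction must be in (0, 1]")
    if fraction == 1.0:
        return AlleleCountTable(counts.sample_id, dict(counts.rows), counts.ambiguous)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = {
        s: (int(rng.binomial(r, fraction)), int(rng.binomial(a, fraction)))
        for s, (r, a) in counts.rows.items()
    }
    return AlleleCountTable(counts.sample_id, rows, counts.ambiguous)


def random_panel(
    n_snps: int = 300,
    k: int = 31,
    context_length: int = 61,
    seed: int | np.random.Generator = 0,
) -> SnpPanel:
    """A synthetic SNP panel with random variant-centered contexts."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if context_length < k or context_length % 2 == 0:
        raise ValueError("context_length must be odd and >= k")
    entries = []
    for i in range(n_snps):
        context = "".join(rng.choice(list(BASES), size=context_length))
        center = context_length // 2
        ref = context[center]
        alt = rng.choice([b for b in BASES if b != ref])
        entries.append(
            SnpLocus(
                id=f"snp{i:04d}",
                chrom=f"chr{1 + i % 22}",
                pos=1000 + i,
                ref=ref,
                alt=str(alt),
                context=context,
            )
        )
    return SnpPanel(entries=entries, k=k)


def simulate_fastq(
    counts: AlleleCountTable,
    kmers: Sequence[AlleleKmerPair],
    read_length: int = 150,
    seed: int | np.random.Generator = 0,
):
    """Emit reads realising a count table: per SNP, exactly ref_count reads
    carrying the ref k-mer and alt_count carrying the alt k-mer, planted at a
    random offset in random background sequence, on a random strand, in
    shuffled order. Yields ``(read_id, sequence, quality)`` tuples.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_id = {p.snp_id: p for p in kmers}
    k = len(next(iter(by_id.values())).ref_kmer) if by_id else 0
    if by_id and read_length < k:
        raise ValueError(f"read_length {read_length} shorter than k={k}")

    reads: list[tuple[str, str]] = []
    for snp_id, (ref_count, alt_count) in counts.rows.items():
        pair = by_id.get(snp_id)
        if pair is None:
            if ref_count or alt_count:
                raise ValueError(f"no k-mer pair for SNP {snp_id} with non-zero counts")
            continue
        for kmer, count, allele in ((pair.ref_kmer, ref_count, "ref"), (pair.alt_kmer, alt_count, "alt")):
            for j in range(count):
                offset = int(rng.integers(0, read_length - k + 1))
                bg = "".join(rng.choice(list(BASES), size=read_length - k))
                seq = bg[:offset] + kmer + bg[offset:]
                if rng.random() < 0.5:
                    seq = reverse_complement(seq)
                reads.append((f"{snp_id}_{allele}_{j}", seq))

    rng.shuffle(reads)
    for read_id, seq in reads:
        yield read_id, seq, "I" * len(seq)


def write_fastq(reads, path) -> int:
    """Write ``(id, seq, qual)`` tuples as FASTQ text; returns read count."""
    n = 0
    with open(path, "w") as fh:
        for read_id, seq, qual in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


@dataclass
class SpikeInDataset:
    """A simulated spike-in series: one count table per mixture fraction."""

    config: SimulationConfig
    recipient: "object"
    donor: "object"
    counts: dict[float, AlleleCountTable]

    @property
    def baseline(self) -> AlleleCountTable:
        """The 0% mixture, standing in for the pre-transplant sample."""
        if 0.0 not in self.counts:
            raise KeyError("dataset has no 0% mixture")
        return self.counts[0.0]


def simulate_spikein(config: SimulationConfig) -> SpikeInDataset:
    """Simulate the whole mixing experiment: a genotype pair plus one count
    table per configured mixture fraction, all driven by the config seed."""
    rng = config.rng()
    recipient, donor = simulate_pair_genotypes(config, rng)
    counts = {
        float(f): simulate_counts(recipient, donor, float(f), config, rng)
        for f in config.mixture_fractions
    }
    return SpikeInDataset(config=config, recipient=recipient, donor=donor, counts=counts)
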