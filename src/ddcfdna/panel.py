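"""SNP panel handling and alignment-free allele counting.

A capture panel targets a few hundred biallelic SNPs. Instead of aligning
reads to a reference genome, each SNP is represented by a pair of
allele-discriminating k-mers: the k-mer of the probe context centered on the
variant position, carrying either the reference or the alternative base.
A read supports an allele iff it contains the corresponding k-mer (or its
reverse complement) as an exact substring. Because the panel SNPs are sparse
in the genome and the k-mers are long (k = 31 by default), exact matching is
both specific and fast, and ref/alt attribution is unambiguous.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
VALID_BASES = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class PanelError(ValueError):
    """Raised for malformed panel entries (bad context, bad alleles)."""


@dataclass(frozen=True)
class SnpLocus:
    """One biallelic SNP with its probe context.

    ``context`` is the flanking sequence carrying the *reference* base at
    ``var_index`` (defaults to the center of the string). Positions are
    1-based, VCF-style.
    """

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    context: str
    var_index: int | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise PanelError(f"{self.id}: ref and alt alleles are identical")
        for allele in (self.ref, self.alt):
            if len(allele) != 1 or allele not in VALID_BASES:
                raise PanelError(f"{self.id}: allele {allele!r} is not a single ACGT base")
        idx = self.center
        if not 0 <= idx < len(self.context):
            raise PanelError(f"{self.id}: variant index {idx} outside context")
        if self.context[idx].upper() != self.ref:
            raise PanelError(
                f"{self.id}: context base {self.context[idx]!r} at variant position "
                f"does not match ref allele {self.ref!r}"
            )

    @property
    def center(self) -> int:
        return len(self.context) // 2 if self.var_index is None else self.var_index


@dataclass
class SnpPanel:
    """An ordered collection of panel SNPs plus the k-mer length used."""

    entries: list[SnpLocus]
    k: int = 31

    def __post_init__(self) -> None:
        ids = [e.id for e in self.entries]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelError(f"duplicate SNP ids in panel: {dup}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[SnpLocus]:
        return iter(self.entries)

    @property
    def snp_ids(self) -> list[str]:
        return [e.id for e in self.entries]


@dataclass(frozen=True)
class AlleleKmerPair:
    """Ref/alt k-mer pair for one SNP; the two differ only at the variant site."""

    snp_id: str
    ref_kmer: str
    alt_kmer: str

    def __post_init__(self) -> None:
        if len(self.ref_kmer) != len(self.alt_kmer):
            raise PanelError(f"{self.snp_id}: k-mer length mismatch")
        diff = [i for i, (a, b) in enumerate(zip(self.ref_kmer, self.alt_kmer)) if a != b]
        if len(diff) != 1:
            raise PanelError(
                f"{self.snp_id}: ref/alt k-mers differ at {len(diff)} positions, expected 1"
            )


@dataclass
class KmerBuildResult:
    """Usable k-mer pairs plus per-locus exclusion reasons (collisions, bad contexts)."""

    pairs: list[AlleleKmerPair]
    excluded: dict[str, str] = field(default_factory=dict)

    def __iter__(self) -> Iterator[AlleleKmerPair]:
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def build_allele_kmers(panel: SnpPanel, k: int | None = None) -> KmerBuildResult:
    """Derive one ref/alt k-mer pair per panel SNP.

    The k-mer is the window of the probe context centered on the variant; the
    alt k-mer substitutes the alternative base at the center. Pairs whose
    k-mers (or reverse complements) collide with a previously accepted panel
    entry are excluded and reported, since a colliding k-mer cannot attribute
    a read to a single SNP/allele.
    """
    k = panel.k if k is None else k
    if k % 2 == 0:
        raise PanelError(f"k must be odd, got {k}")
    half = k // 2

    pairs: list[AlleleKmerPair] = []
    excluded: dict[str, str] = {}
    seen: dict[str, str] = {}  # kmer (either strand) -> snp_id that claimed it

    for locus in panel:
        c = locus.center
        if c - half < 0 or c + half >= len(locus.context):
            excluded[locus.id] = (
                f"context too short for k={k}: needs {half} flanking bases on each side"
            )
            continue
        window = locus.context[c - half : c + half + 1].upper()
        if not set(window) <= VALID_BASES:
            excluded[locus.id] = f"non-ACGT base in k-mer window {window!r}"
            continue
        ref_kmer = window
        alt_kmer = window[:half] + locus.alt + window[half + 1 :]
        candidates = {ref_kmer, alt_kmer, reverse_complement(ref_kmer), reverse_complement(alt_kmer)}
        owner = next((seen[km] for km in candidates if km in seen), None)
        if owner is not None:
            excluded[locus.id] = f"k-mer collision with SNP {owner}"
            continue
        for km in candidates:
            seen[km] = locus.id
        pairs.append(AlleleKmerPair(locus.id, ref_kmer, alt_kmer))

    for snp_id, reason in excluded.items():
        logger.warning("panel SNP %s excluded: %s", snp_id, reason)
    return KmerBuildResult(pairs=pairs, excluded=excluded)


@dataclass
class AlleleCountTable:
    """Per-SNP reference / alternative read counts for one sample."""

    sample_id: str
    rows: dict[str, tuple[int, int]]
    ambiguous: int = 0  # reads carrying both alleles of the same SNP (chimeras)

    def __post_init__(self) -> None:
        for snp_id, (ref, alt) in self.rows.items():
            if ref < 0 or alt < 0 or ref != int(ref) or alt != int(alt):
                raise ValueError(f"{snp_id}: counts must be non-negative integers")

    def depth(self, snp_id: str) -> int:
        ref, alt = self.rows[snp_id]
        return ref + alt

    def total_reads(self) -> int:
        return sum(r + a for r, a in self.rows.values())

    def __add__(self, other: "AlleleCountTable") -> "AlleleCountTable":
        if set(self.rows) != set(other.rows):
            raise ValueError("cannot sum count tables over different SNP sets")
        rows = {
            s: (self.rows[s][0] + other.rows[s][0], self.rows[s][1] + other.rows[s][1])
            for s in self.rows
        }
        return AlleleCountTable(self.sample_id, rows, self.ambiguous + other.ambiguous)


class FastqError(ValueError):
    """Raised for malformed FASTQ records, carrying the record index."""


def _iter_fastq_sequences(handle: IO[str]) -> Iterator[str]:
    """Yield read sequences from a FASTQ text stream.

    Minimal four-line-record reader: counting only needs the sequence line,
    and avoiding per-record object construction matters when streaming
    millions of reads.
    """
    record = 0
    while True:
        header = handle.readline()
        if not header:
            return
        if header.strip() == "":
            continue
        seq = handle.readline()
        plus = handle.readline()
        qual = handle.readline()
        if not header.startswith("@") or not plus.startswith("+") or not qual:
            raise FastqError(f"malformed FASTQ record at record index {record}")
        seq = seq.strip()
        if len(qual.strip()) != len(seq):
            raise FastqError(
                f"quality/sequence length mismatch at record index {record}"
            )
        yield seq
        record += 1


def _open_maybe_gzip(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def count_alleles(
    reads: Iterable[str] | str | Path | Sequence[str | Path],
    kmers: KmerBuildResult | Sequence[AlleleKmerPair],
    *,
    match_reverse_complement: bool = True,
) -> AlleleCountTable:
    """Count ref/alt allele support per SNP by exact k-mer matching.

    ``reads`` may be FASTQ path(s) (optionally .gz; paired files are treated
    as one stream) or an iterable of sequence strings. A read increments the
    ref (alt) counter of a SNP iff it contains that SNP's ref (alt) k-mer —
    or, by default, its reverse complement — as an exact substring. A read
    carrying both alleles of the same SNP is ambiguous (chimeric) and
    increments neither counter; reads matching no panel k-mer are ignored.
    """
    pairs = list(kmers)
    if not pairs:
        raise ValueError("no usable k-mer pairs")
    k = len(pairs[0].ref_kmer)

    # kmer -> (snp_id, allele index 0=ref 1=alt)
    lookup: dict[str, tuple[str, int]] = {}
    for p in pairs:
        targets = [(p.ref_kmer, 0), (p.alt_kmer, 1)]
        if match_reverse_complement:
            targets += [(reverse_complement(p.ref_kmer), 0), (reverse_complement(p.alt_kmer), 1)]
        for km, allele in targets:
            lookup[km] = (p.snp_id, allele)

    counts = {p.snp_id: [0, 0] for p in pairs}
    ambiguous = 0

    if isinstance(reads, (str, Path)):
        paths: list[str | Path] | None = [reads]
    elif isinstance(reads, Sequence) and reads and all(
        isinstance(r, Path)
        or (isinstance(r, str) and r.lower().endswith((".fastq", ".fq", ".fastq.gz", ".fq.gz")))
        for r in reads
    ):
        paths = list(reads)  # type: ignore[arg-type]
    else:
        paths = None

    if paths is not None:
        def stream() -> Iterator[str]:
            for path in paths:
                with _open_maybe_gzip(path) as fh:
                    yield from _iter_fastq_sequences(fh)
        seq_iter: Iterable[str] = stream()
    else:
        seq_iter = reads  # type: ignore[assignment]

    for seq in seq_iter:
        seq = seq.upper()
        hits: dict[str, set[int]] = {}
        for i in range(len(seq) - k + 1):
            hit = lookup.get(seq[i : i + k])
            if hit is not None:
                hits.setdefault(hit[0], set()).add(hit[1])
        for snp_id, alleles in hits.items():
            if len(alleles) == 2:
                ambiguous += 1
            else:
                counts[snp_id][alleles.pop()] += 1

    return AlleleCountTable(
        sample_id="sample",
        rows={p.snp_id: (counts[p.snp_id][0], counts[p.snp_id][1]) for p in pairs},
        ambiguous=ambiguous,
    )


@dataclass
class AltRatioProfile:
    """Per-SNP alternative-allele ratio with its supporting depth.

    ``rows`` maps snp_id -> (alt_ratio, depth); the ratio is None when depth
    is below the minimum required depth, and such SNPs are excluded from all
    downstream estimation.
    """

    sample_id: str
    rows: dict[str, tuple[float | None, int]]
    min_depth: int = 1

    def ratio(self, snp_id: str) -> float | None:
        return self.rows[snp_id][0]

    def defined_snps(self) -> list[str]:
        return [s for s, (r, _) in self.rows.items() if r is not None]


def alt_ratio_profile(counts: AlleleCountTable, min_depth: int = 1) -> AltRatioProfile:
    """ALT ratio = alt_count / (ref_count + alt_count), per SNP.

    SNPs with depth below ``min_depth`` get an undefined ratio.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    rows: dict[str, tuple[float | None, int]] = {}
    for snp_id, (ref, alt) in counts.rows.items():
        depth = ref + alt
        ratio = alt / depth if depth >= min_depth else None
        rows[snp_id] = (ratio, depth)
    return AltRatioProfile(sample_id=counts.sample_id, rows=rows, min_depth=min_depth)
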