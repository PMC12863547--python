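"""File formats and evaluation harnesses.

Readers/writers for the plain-text exchange formats (panel TSV/FASTA, count
TSV, genotype TSV), the spike-in workbook evaluator (per-SNP read counts per
mixing rate in an XLSX, run through the estimator and scored against the
true rates), and the clinical concordance harness over the bundled
validation series.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .clinical_data import (
    CLINICAL_SERIES,
    EXCLUSION_THRESHOLD_PERCENT,
    PUBLISHED_CCC,
)
from .direct import GenotypeTable
from .estimate import estimate_with_pre, estimate_without_pre
from .metrics import ccc_with_exclusion, lin_ccc, mae, ols_fit, rmse
from .panel import AlleleCountTable, AltRatioProfile, SnpLocus, SnpPanel, alt_ratio_profile

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised for malformed input files, carrying the offending line number."""


# ---------------------------------------------------------------- panel I/O

PANEL_COLUMNS = ["id", "chrom", "pos", "ref", "alt", "context"]


def read_panel(path: str | Path, k: int = 31) -> SnpPanel:
    """Load a SNP panel from TSV (columns id, chrom, pos, ref, alt, context)
    or FASTA (header ``>id|ref|alt|offset``, sequence = context)."""
    path = Path(path)
    if path.suffix.lower() in (".fa", ".fasta", ".fna"):
        entries = []
        for rec in SeqIO.parse(str(path), "fasta"):
            try:
                snp_id, ref, alt, offset = rec.id.split("|")
            except ValueError as exc:
                raise ParseError(
                    f"{path}: FASTA header {rec.id!r} is not id|ref|alt|offset"
                ) from exc
            entries.append(
                SnpLocus(
                    id=snp_id, chrom=".", pos=0, ref=ref, alt=alt,
                    context=str(rec.seq).upper(), var_index=int(offset),
                )
            )
        return SnpPanel(entries=entries, k=k)

    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing panel columns {missing}")
    entries = [
        SnpLocus(
            id=row["id"], chrom=row["chrom"], pos=int(row["pos"]),
            ref=row["ref"], alt=row["alt"], context=row["context"].upper(),
        )
        for _, row in df.iterrows()
    ]
    return SnpPanel(entries=entries, k=k)


def write_panel(panel: SnpPanel, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {"id": e.id, "chrom": e.chrom, "pos": e.pos, "ref": e.ref,
             "alt": e.alt, "context": e.context}
            for e in panel
        ],
        columns=PANEL_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- count I/O

COUNT_COLUMNS = ["snp_id", "ref_count", "alt_count"]


def read_count_table(
    path: str | Path, panel: SnpPanel | None = None, sample_id: str | None = None
) -> AlleleCountTable:
    """Read a TSV count table; with a panel, unknown snp_ids are rejected and
    panel SNPs absent from the file get zero counts."""
    path = Path(path)
    rows: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != COUNT_COLUMNS:
            raise ParseError(f"{path}:1: expected columns {COUNT_COLUMNS}, got {header[:3]}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            snp_id = fields[0]
            try:
                ref_count, alt_count = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer count") from exc
            if ref_count < 0 or alt_count < 0:
                raise ParseError(f"{path}:{lineno}: negative count")
            if snp_id in rows:
                raise ParseError(f"{path}:{lineno}: duplicate snp_id {snp_id!r}")
            rows[snp_id] = (ref_count, alt_count)

    if panel is not None:
        unknown = set(rows) - set(panel.snp_ids)
        if unknown:
            raise ParseError(f"{path}: snp_ids not in panel: {sorted(unknown)[:5]}")
        rows = {s: rows.get(s, (0, 0)) for s in panel.snp_ids}
    return AlleleCountTable(sample_id=sample_id or path.stem, rows=rows)


def write_count_table(table: AlleleCountTable, path: str | Path) -> None:
    """Write a count table as TSV in stable (insertion/panel) row order."""
    with open(path, "w") as fh:
        fh.write("\t".join(COUNT_COLUMNS) + "\n")
        for snp_id, (ref, alt) in table.rows.items():
            fh.write(f"{snp_id}\t{ref}\t{alt}\n")


# -------------------------------------------------------------- genotype I/O

def read_genotype_table(path: str | Path, role: str) -> GenotypeTable:
    """Read a genotype TSV with columns snp_id, dosage (0/1/2)."""
    df = pd.read_csv(path, sep="\t")
    if not {"snp_id", "dosage"} <= set(df.columns):
        raise ParseError(f"{path}: expected columns snp_id, dosage")
    return GenotypeTable(role=role, rows=dict(zip(df["snp_id"].astype(str), df["dosage"].astype(int))))


def write_genotype_table(table: GenotypeTable, path: str | Path) -> None:
    pd.DataFrame(
        {"snp_id": list(table.rows), "dosage": list(table.rows.values())}
    ).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------- provenance

def provenance_record(config: dict) -> dict:
    """Machine-readable run record: software version plus the full config."""
    return {"software": "ddcfdna", "version": __version__, "config": config}


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ------------------------------------------------- spike-in workbook harness

_SAMPLE_COL = re.compile(r"^(?P<label>.+)_(?P<allele>ref|alt)$")


def _label_to_fraction(label: str) -> float:
    """Parse a sample label like '1.0%' or '0.05' into a fraction."""
    label = label.strip()
    if label.endswith("%"):
        return float(label[:-1]) / 100.0
    return float(label)


def load_workbook_counts(
    path: str | Path,
    sheet: str | int = 0,
    mapping: dict | None = None,
) -> dict[float, AlleleCountTable]:
    """Load per-SNP read counts for a spike-in series from an XLSX sheet.

    Default layout: one ``snp_id`` column plus ``<label>_ref`` /
    ``<label>_alt`` column pairs, the label naming the mixing rate (e.g.
    ``1.0%``). A mapping dict overrides this for workbooks with other
    layouts: ``{"snp_id": col, "samples": {fraction: [ref_col, alt_col]}}``.
    """
    path = Path(path)
    try:
        df = pd.read_excel(path, sheet_name=sheet)
    except ValueError as exc:
        import openpyxl

        names = openpyxl.load_workbook(path, read_only=True).sheetnames
        raise ParseError(f"{path}: sheet {sheet!r} not found; available: {names}") from exc

    if mapping is None:
        snp_col = df.columns[0]
        samples: dict[float, list[str | None]] = {}
        for col in df.columns[1:]:
            m = _SAMPLE_COL.match(str(col))
            if not m:
                continue
            frac = _label_to_fraction(m.group("label"))
            pair = samples.setdefault(frac, [None, None])
            pair[0 if m.group("allele") == "ref" else 1] = col
    else:
        snp_col = mapping["snp_id"]
        samples = {float(f): list(cols) for f, cols in mapping["samples"].items()}

    if not samples:
        raise ParseError(f"{path}: no '<label>_ref'/'<label>_alt' column pairs found")
    out: dict[float, AlleleCountTable] = {}
    for frac, (ref_col, alt_col) in sorted(samples.items()):
        if ref_col is None or alt_col is None:
            raise ParseError(f"{path}: incomplete ref/alt column pair for rate {frac}")
        rows = {
            str(s): (int(r), int(a))
            for s, r, a in zip(df[snp_col], df[ref_col], df[alt_col])
        }
        out[frac] = AlleleCountTable(sample_id=f"mix_{frac:g}", rows=rows)
    return out


@dataclass
class SpikeInReport:
    """Estimates and error statistics for one spike-in series."""

    mode: Literal["with_pre", "without_pre"]
    estimates: dict[float, float]  # true fraction -> estimated fraction
    r_squared: float | None = None
    slope: float | None = None
    intercept: float | None = None
    mae_full: float | None = None  # over every evaluated fraction
    mae_low: float | None = None  # over the 0-10% range
    rmse_low: float | None = None
    flags: dict[float, list[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "estimates_percent": {f"{k:g}": v * 100.0 for k, v in self.estimates.items()},
            "r_squared": self.r_squared,
            "slope": self.slope,
            "intercept": self.intercept,
            "mae_full_percent": None if self.mae_full is None else self.mae_full * 100.0,
            "mae_0_10_percent": None if self.mae_low is None else self.mae_low * 100.0,
            "rmse_0_10_percent": None if self.rmse_low is None else self.rmse_low * 100.0,
            "flags": {f"{k:g}": v for k, v in self.flags.items()},
        }


def evaluate_spikein(
    counts_by_fraction: dict[float, AlleleCountTable],
    mode: Literal["with_pre", "without_pre"],
    relatedness: str = "unrelated",
    seed: int | None = None,
    baseline_fraction: float = 0.0,
    min_depth: int = 1,
    low_range: float = 0.10,
    without_pre_max: float = 0.10,
) -> SpikeInReport:
    """Run the cluster estimator across a spike-in series and score it.

    In ``with_pre`` mode the 0% mixture acts as the pre-transplant baseline.
    Reference-free (``without_pre``) estimation is only attempted for
    fractions up to ``without_pre_max``: above that the heterozygous-donor
    and fully mismatched clusters overlap the classification bins and the
    method is not used without a baseline.
    """
    profiles = {f: alt_ratio_profile(t, min_depth) for f, t in counts_by_fraction.items()}
    estimates: dict[float, float] = {}
    flags: dict[float, list[str]] = {}

    if mode == "with_pre":
        if baseline_fraction not in profiles:
            raise ValueError(f"no {baseline_fraction:g} mixture to use as baseline")
        pre = profiles[baseline_fraction]
        for f, post in profiles.items():
            est = estimate_with_pre(pre, post, relatedness=relatedness, seed=seed)
            estimates[f] = est.combined
            flags[f] = est.flags
    else:
        for f, post in profiles.items():
            if f > without_pre_max:
                continue  # reference-free mode breaks down as clusters merge
            est = estimate_without_pre(post, relatedness=relatedness, seed=seed)
            estimates[f] = est.combined
            flags[f] = est.flags

    truths = np.array(sorted(estimates))
    ests = np.array([estimates[f] for f in truths])
    report = SpikeInReport(mode=mode, estimates=dict(zip(truths, ests)), flags=flags)
    if len(truths) >= 3 and np.ptp(truths) > 0:
        fit = ols_fit(truths, ests)
        report.slope, report.intercept, report.r_squared = fit.slope, fit.intercept, fit.r_squared
        report.mae_full = mae(truths, ests)
    low = truths <= low_range
    if low.sum() >= 1:
        report.mae_low = mae(truths[low], ests[low])
        report.rmse_low = rmse(truths[low], ests[low])
    return report


def evaluate_workbook(
    path: str | Path,
    mode: Literal["with_pre", "without_pre"],
    sheet: str | int = 0,
    mapping: dict | None = None,
    seed: int | None = None,
) -> SpikeInReport:
    """Load a spike-in workbook sheet and evaluate the estimator on it."""
    counts = load_workbook_counts(path, sheet=sheet, mapping=mapping)
    return evaluate_spikein(counts, mode=mode, seed=seed)


# --------------------------------------------- clinical concordance harness

def clinical_concordance(threshold_percent: float = EXCLUSION_THRESHOLD_PERCENT) -> dict:
    """Concordance (Lin's CCC) between the direct genotype-based values and
    the clustering estimates over the bundled clinical validation series.

    With-pre coefficients use all seven time points; without-pre
    coefficients exclude time points whose direct value is at or above the
    threshold (reference-free estimates are unreliable there) and are
    reported as not-calculable (None) when fewer than four points survive.
    """
    report: dict[str, dict] = {}
    for rel, series in CLINICAL_SERIES.items():
        direct = series["direct"]
        with_pre = lin_ccc(direct, series["clustering_with_pre"])
        without_pre = ccc_with_exclusion(
            direct, series["clustering_without_pre"], threshold=threshold_percent
        )
        report[rel] = {
            "ccc_with_pre": round(with_pre, 4),
            "ccc_without_pre": None if without_pre is None else round(without_pre, 4),
            "published_with_pre": PUBLISHED_CCC[rel]["with_pre"],
            "published_without_pre": PUBLISHED_CCC[rel]["without_pre"],
            "n_points": len(direct),
            "n_after_exclusion": int(sum(d < threshold_percent for d in direct)),
        }
    return report
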