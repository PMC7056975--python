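"""Readers and writers for the pipeline's tabular formats.

Variant-frequency tables and gene annotations are tab-separated; phenotype
tables are CSV.  Internal coordinates are 1-based inclusive (FlyBase
convention); the BED exporter converts to 0-based half-open.  Chromosome-arm
ordering is the order of first appearance in the input, then position.
"""

from __future__ import annotations

import logging
import re
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .scan import DivergenceInterval

logger = logging.getLogger(__name__)

__all__ = [
    "TableFormatError",
    "read_variants",
    "write_variants",
    "read_annotations",
    "write_annotations",
    "read_lifespan",
    "write_lifespan",
    "read_productivity",
    "write_productivity",
    "read_qpcr",
    "write_qpcr",
    "write_intervals_bed",
    "write_intervals",
    "read_intervals",
]


class TableFormatError(ValueError):
    """A table violated its schema; the message names the offending line."""


def _line_no(df_index: int) -> int:
    # +1 header, +1 one-based
    return int(df_index) + 2


def sort_variants(df: pd.DataFrame) -> pd.DataFrame:
    """Stable sort by (arm in order of first appearance, pos)."""
    arm_order = pd.unique(df["arm"])
    key = df["arm"].map({a: i for i, a in enumerate(arm_order)})
    return (
        df.assign(_armkey=key)
        .sort_values(["_armkey", "pos"], kind="stable")
        .drop(columns="_armkey")
        .reset_index(drop=True)
    )


def _freq_columns(df: pd.DataFrame) -> tuple[list[str], list[str]]:
    sel = sorted(
        (c for c in df.columns if re.fullmatch(r"freq_sel_\d+", c)),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    ctl = sorted(
        (c for c in df.columns if re.fullmatch(r"freq_ctl_\d+", c)),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    if not sel or not ctl:
        raise TableFormatError("variant table needs freq_sel_* and freq_ctl_* columns")
    return sel, ctl


def _validate_variants(df: pd.DataFrame, min_lines: int | None) -> pd.DataFrame:
    for col in ("arm", "pos"):
        if col not in df.columns:
            raise TableFormatError(f"variant table is missing required column {col!r}")
    sel, ctl = _freq_columns(df)
    pos = pd.to_numeric(df["pos"], errors="coerce")
    bad = pos.isna() | (pos < 1) | (pos != pos.round())
    if bad.any():
        raise TableFormatError(f"line {_line_no(df.index[bad][0])}: malformed position {df.loc[bad, 'pos'].iloc[0]!r}")
    df = df.assign(pos=pos.astype(int))
    freqs = df[sel + ctl].apply(pd.to_numeric, errors="coerce")
    raw_missing = df[sel + ctl].isna()
    malformed = freqs.isna() & ~raw_missing
    if malformed.any().any():
        idx = df.index[malformed.any(axis=1)][0]
        raise TableFormatError(f"line {_line_no(idx)}: malformed frequency value")
    out_of_range = (freqs < 0) | (freqs > 1)
    if out_of_range.any().any():
        idx = df.index[out_of_range.any(axis=1)][0]
        raise TableFormatError(f"line {_line_no(idx)}: frequency outside [0, 1]")
    df[sel + ctl] = freqs

    dup = df.duplicated(subset=["arm", "pos"], keep=False)
    if dup.any():
        idx = df.index[dup][0]
        raise TableFormatError(f"line {_line_no(idx)}: duplicate (arm, pos) entry")

    n_sel = freqs[sel].notna().sum(axis=1)
    n_ctl = freqs[ctl].notna().sum(axis=1)
    if min_lines is None:
        keep = df[sel + ctl].notna().all(axis=1)
    else:
        keep = (n_sel >= min_lines) & (n_ctl >= min_lines)
    if not keep.all():
        logger.warning("dropping %d variant(s) with missing line frequencies", int((~keep).sum()))
        df = df[keep]

    if "delta_p" not in df.columns or df["delta_p"].isna().all():
        df = df.assign(delta_p=(df[sel].mean(axis=1) - df[ctl].mean(axis=1)).abs())
    if "p_divergence" in df.columns:
        p = pd.to_numeric(df["p_divergence"], errors="coerce")
        if ((p <= 0) | (p > 1)).any():
            idx = df.index[(p <= 0) | (p > 1)][0]
            raise TableFormatError(f"line {_line_no(idx)}: p_divergence outside (0, 1]")
    return sort_variants(df)


def read_variants(
    path,
    dialect: str = "tsv",
    min_lines: int | None = None,
    sel_samples: list[str] | None = None,
    ctl_samples: list[str] | None = None,
) -> pd.DataFrame:
    """Read a variant-frequency table, validate it and sort by (arm, pos).

    ``dialect`` is ``"tsv"`` (the documented column schema) or ``"vcf"``
    (per-sample ``AF`` FORMAT field; ``sel_samples``/``ctl_samples`` name the
    O- and B-line samples).  ``delta_p`` is computed when absent.  Variants
    with missing line frequencies are dropped with a warning unless
    ``min_lines`` allows partial rows.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
    elif dialect == "vcf":
        df = _read_variants_vcf(path, sel_samples, ctl_samples)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return _validate_variants(df, min_lines)


def _read_variants_vcf(path, sel_samples, ctl_samples) -> pd.DataFrame:
    from cyvcf2 import VCF

    if not sel_samples or not ctl_samples:
        raise ValueError("VCF input requires sel_samples and ctl_samples")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for s in list(sel_samples) + list(ctl_samples):
        if s not in samples:
            raise TableFormatError(f"sample {s!r} not present in VCF")
    sel_idx = [samples.index(s) for s in sel_samples]
    ctl_idx = [samples.index(s) for s in ctl_samples]
    rows = []
    for var in vcf:
        af = np.asarray(var.format("AF"), dtype=float).reshape(len(samples))
        row = {"arm": var.CHROM, "pos": var.POS}
        for i, j in enumerate(sel_idx):
            row[f"freq_sel_{i + 1}"] = af[j]
        for i, j in enumerate(ctl_idx):
            row[f"freq_ctl_{i + 1}"] = af[j]
        rows.append(row)
    return pd.DataFrame(rows)


def write_variants(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


_ANNOTATION_COLS = [
    "gene_id",
    "symbol",
    "arm",
    "start",
    "end",
    "expressed_ovary",
    "expressed_accessory_gland",
    "rnai_available",
    "min_snp_p",
]
_FLAG_COLS = ["expressed_ovary", "expressed_accessory_gland", "rnai_available"]


def read_annotations(path) -> pd.DataFrame:
    """Read the gene-annotation table (1-based inclusive coordinates)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _ANNOTATION_COLS if c not in df.columns and c != "min_snp_p"]
    if missing:
        raise TableFormatError(f"annotation table is missing columns: {missing}")
    if "min_snp_p" not in df.columns:
        df["min_snp_p"] = np.nan
    bad = df["start"] > df["end"]
    if bad.any():
        raise TableFormatError(f"line {_line_no(df.index[bad][0])}: start > end")
    for c in _FLAG_COLS:
        # permit True/False strings and 0/1 but come out boolean (NaN = unknown)
        df[c] = df[c].map(
            {True: True, False: False, "True": True, "False": False, 1: True, 0: False}
        )
    return df[_ANNOTATION_COLS].reset_index(drop=True)


def write_annotations(df: pd.DataFrame, path) -> None:
    df[_ANNOTATION_COLS].to_csv(path, sep="\t", index=False)


def _read_phenotype(path, required: list[str], name: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{name} table is missing columns: {missing}")
    return df


def read_lifespan(path) -> pd.DataFrame:
    df = _read_phenotype(
        path, ["genotype", "control_pairing", "block", "sex", "vial", "lifespan"], "lifespan"
    )
    bad = ~df["sex"].isin(["F", "M"])
    if bad.any():
        raise TableFormatError(f"line {_line_no(df.index[bad][0])}: sex must be F or M")
    y = pd.to_numeric(df["lifespan"], errors="coerce")
    bad = y.isna() | ~np.isfinite(y) | (y < 0)
    if bad.any():
        raise TableFormatError(f"line {_line_no(df.index[bad][0])}: lifespan must be finite and >= 0")
    return df.assign(lifespan=y)


def write_lifespan(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_productivity(path) -> pd.DataFrame:
    """Weekly productivity; either a ``genotype`` column (screen) or
    ``gm``/``gf`` columns (O/B reciprocal crosses)."""
    df = pd.read_csv(path)
    if "genotype" not in df.columns and not {"gm", "gf"} <= set(df.columns):
        raise TableFormatError("productivity table needs 'genotype' or 'gm'+'gf' columns")
    for c in ("vial", "week", "offspring_per_female"):
        if c not in df.columns:
            raise TableFormatError(f"productivity table is missing column {c!r}")
    wk = pd.to_numeric(df["week"], errors="coerce")
    bad = wk.isna() | (wk < 1) | (wk != wk.round())
    if bad.any():
        raise TableFormatError(f"line {_line_no(df.index[bad][0])}: week must be a positive integer")
    y = pd.to_numeric(df["offspring_per_female"], errors="coerce")
    bad = y.notna() & (y < 0)
    if bad.any():
        raise TableFormatError(f"line {_line_no(df.index[bad][0])}: offspring_per_female must be >= 0")
    return df.assign(week=wk.astype(int), offspring_per_female=y)


def write_productivity(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_qpcr(path) -> pd.DataFrame:
    df = _read_phenotype(
        path,
        ["line", "gene", "tissue", "biological_rep", "technical_rep", "ct_target", "ct_reference"],
        "qpcr",
    )
    ct = pd.to_numeric(df["ct_target"], errors="coerce")
    bad = ct.notna() & (ct <= 0)
    if bad.any():
        raise TableFormatError(f"line {_line_no(df.index[bad][0])}: Ct values must be positive")
    return df
def write_qpcr(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_intervals_bed(intervals: Iterable["DivergenceInterval"], path) -> None:
    """Write intervals as BED (0-based half-open): chromStart = start_pos - 1,
    chromEnd = end_pos; name = "arm:start-end"; score = variant count capped
    at 1000."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = f"{iv.arm}:{iv.start_pos}-{iv.end_pos}"
            score = min(iv.n_variants, 1000)
            fh.write(f"{iv.arm}\t{iv.start_pos - 1}\t{iv.end_pos}\t{name}\t{score}\n")


def write_intervals(intervals: Iterable["DivergenceInterval"], path) -> None:
    """Interval table as TSV with all fields; gene lists joined with ','."""
    rows = [
        {
            "arm": iv.arm,
            "start_pos": iv.start_pos,
            "end_pos": iv.end_pos,
            "n_variants": iv.n_variants,
            "span_bp": iv.span_bp,
            "min_delta_p": iv.min_delta_p,
            "mean_delta_p": iv.mean_delta_p,
            "genes": ",".join(iv.genes),
        }
        for iv in intervals
    ]
    cols = ["arm", "start_pos", "end_pos", "n_variants", "span_bp", "min_delta_p", "mean_delta_p", "genes"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_intervals(path) -> list["DivergenceInterval"]:
    from .scan import DivergenceInterval

    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples(index=False):
        genes = [] if pd.isna(r.genes) or r.genes == "" else str(r.genes).split(",")
        out.append(
            DivergenceInterval(
                arm=r.arm,
                start_pos=int(r.start_pos),
                end_pos=int(r.end_pos),
                n_variants=int(r.n_variants),
                min_delta_p=float(r.min_delta_p),
                mean_delta_p=float(r.mean_delta_p),
                genes=genes,
            )
        )
    return out
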