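"""Detection of high-divergence genomic intervals between selected and
control replicate lines.

A variant qualifies when its absolute O-vs-B mean allele-frequency
difference |dp| exceeds ``high_threshold`` (default 0.8).  Maximal runs of
consecutive qualifying variants seed intervals; two neighbouring seed
intervals are merged, together with the interrupting run between them,
when that run holds at most ``max_interruption`` variants (default 2,
i.e. fewer than three) all with |dp| above ``interruption_threshold``
(default 0.5).  Adjacency is counted in variant-table order, not bp,
since interruptions are measured in variant counts.  Merging is iterated
to a fixpoint with a left-to-right sweep; because an interruption's
qualification does not depend on the extent of its flanking intervals,
the fixpoint is independent of merge order.  Single qualifying variants
are emitted as one-variant, zero-span intervals.  Interval span is the
distance between the first and last member variant, an underestimate of
the swept region when variants are sparse.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ScanParams", "DivergenceInterval", "scan_intervals", "assign_genes", "scan_summary"]


@dataclass(frozen=True)
class ScanParams:
    high_threshold: float = 0.8
    interruption_threshold: float = 0.5
    max_interruption: int = 2

    def validate(self) -> None:
        if not (0.0 < self.interruption_threshold < self.high_threshold <= 1.0):
            raise ValueError("need 0 < interruption_threshold < high_threshold <= 1")
        if self.max_interruption < 0:
            raise ValueError("max_interruption must be >= 0")


@dataclass
class DivergenceInterval:
    """A merged run of divergent variants on one chromosome arm.

    ``n_variants`` counts qualifying variants plus merged interruptions;
    positions are 1-based bp of the first and last member variant.
    """

    arm: str
    start_pos: int
    end_pos: int
    n_variants: int
    min_delta_p: float
    mean_delta_p: float
    genes: list[str] = field(default_factory=list)

    @property
    def span_bp(self) -> int:
        return self.end_pos - self.start_pos


def _check_sorted(variants: pd.DataFrame) -> None:
    arms = variants["arm"].to_numpy()
    pos = variants["pos"].to_numpy()
    seen: dict[str, int] = {}
    last_arm = None
    for i, a in enumerate(arms):
        if a != last_arm:
            if a in seen:
                raise ValueError("variant table is not sorted: arm blocks are interleaved")
            seen[a] = i
            last_arm = a
        elif pos[i] <= pos[i - 1]:
            raise ValueError(f"variant table is not sorted at row {i} ({a}:{pos[i]})")


def scan_intervals(variants: pd.DataFrame, params: ScanParams = ScanParams()) -> list[DivergenceInterval]:
    """Run the threshold/seed/merge scan over a sorted variant table.

    Requires columns ``arm``, ``pos``, ``delta_p``, sorted by (arm, pos).
    Returns disjoint intervals sorted in table order, never spanning arms.
    """
    params.validate()
    if len(variants) == 0:
        return []
    if "delta_p" not in variants.columns:
        raise ValueError("variant table has no delta_p column")
    _check_sorted(variants)

    out: list[DivergenceInterval] = []
    for arm, sub in variants.groupby("arm", sort=False):
        pos = sub["pos"].to_numpy()
        dp = sub["delta_p"].to_numpy(dtype=float)
        marked = dp > params.high_threshold
        runs = _marked_runs(marked)
        merged = _merge_runs(runs, dp, params)
        for s, e in merged:
            members = dp[s : e + 1]
            out.append(
                DivergenceInterval(
                    arm=str(arm),
                    start_pos=int(pos[s]),
                    end_pos=int(pos[e]),
                    n_variants=int(e - s + 1),
                    min_delta_p=float(members.min()),
                    mean_delta_p=float(members.mean()),
                )
            )
    return out


def _marked_runs(marked: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutively indexed True entries, as (start, end) inclusive."""
    runs = []
    idx = np.flatnonzero(marked)
    if idx.size == 0:
        return runs
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def _gap_mergeable(dp: np.ndarray, left_end: int, right_start: int, params: ScanParams) -> bool:
    gap = dp[left_end + 1 : right_start]
    return len(gap) <= params.max_interruption and bool((gap > params.interruption_threshold).all())


def _merge_runs(runs: list[tuple[int, int]], dp: np.ndarray, params: ScanParams) -> list[tuple[int, int]]:
    """Left-to-right merge of seed runs across qualifying interruptions.

    A single pass reaches the fixpoint: whether a gap qualifies depends only
    on the gap itself, so no later merge can enable an earlier one.
    Interruption runs at arm ends have only one flanking interval and are
    never merged.
    """
    if not runs:
        return []
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if _gap_mergeable(dp, pe, s, params):
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    return merged


def assign_genes(
    intervals: list[DivergenceInterval],
    annotations: pd.DataFrame,
    flank_bp: int = 0,
    known_arms: set[str] | None = None,
) -> list[DivergenceInterval]:
    """Fill each interval's gene list with overlapping annotated genes.

    A gene is listed iff [start - flank_bp, end + flank_bp] overlaps the
    interval by at least 1 bp (both 1-based inclusive).  Genes on arms not
    in ``known_arms`` (when given) are skipped with a warning.  Modifies and
    returns the interval list.
    """
    if known_arms is not None:
        unknown = set(annotations["arm"]) - set(known_arms)
        if unknown:
            warnings.warn(f"skipping genes on unknown arm(s): {sorted(unknown)}", stacklevel=2)
            annotations = annotations[annotations["arm"].isin(known_arms)]
    by_arm = dict(tuple(annotations.groupby("arm", sort=False)))
    for iv in intervals:
        genes = []
        sub = by_arm.get(iv.arm)
        if sub is not None:
            hit = (sub["start"] - flank_bp <= iv.end_pos) & (sub["end"] + flank_bp >= iv.start_pos)
            genes = list(sub.loc[hit, "gene_id"])
        iv.genes = genes
    return intervals


def scan_summary(intervals: list[DivergenceInterval]) -> pd.DataFrame:
    """Per-arm interval count, variant count and bp covered (report content)."""
    rows: dict[str, dict[str, float]] = {}
    for iv in intervals:
        r = rows.setdefault(iv.arm, {"n_intervals": 0, "n_variants": 0, "bp_covered": 0})
        r["n_intervals"] += 1
        r["n_variants"] += iv.n_variants
        r["bp_covered"] += iv.span_bp
    df = pd.DataFrame.from_dict(rows, orient="index").rename_axis("arm").reset_index()
    if df.empty:
        df = pd.DataFrame(columns=["arm", "n_intervals", "n_variants", "bp_covered"])
    return df
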