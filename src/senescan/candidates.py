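"""Three-criterion candidate-gene selection.

A gene qualifies genomically either by lying in a high-divergence interval
with a per-SNP divergence P-value below ``p_cutoff`` (default 1e-5), or by
carrying a nominally significant SNP (P below ``nominal_p_cutoff``,
default 1e-3) even when its allele-frequency divergence never reaches the
interval threshold.  A qualifying gene is selected only if it is also
expressed in both ovaries and accessory glands and a viable RNAi stock is
available.  Rejected genes carry audit codes naming the failed criterion.

Expression and stock availability are input flags rather than database
lookups; a loader for FlyAtlas/VDRC-style resources would populate the
same columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scan import DivergenceInterval

__all__ = ["FilterParams", "select_candidates", "annotate_min_snp_p"]

_RULES = ("either", "interval", "nominal")


@dataclass(frozen=True)
class FilterParams:
    p_cutoff: float = 1e-5
    nominal_p_cutoff: float = 1e-3
    rule: str = "either"  # which genomic route(s) admit a gene

    def validate(self) -> None:
        if not 0.0 < self.p_cutoff < 1.0:
            raise ValueError("p_cutoff must be in (0, 1)")
        if not 0.0 < self.nominal_p_cutoff < 1.0:
            raise ValueError("nominal_p_cutoff must be in (0, 1)")
        if self.rule not in _RULES:
            raise ValueError(f"rule must be one of {_RULES}")


def annotate_min_snp_p(annotations: pd.DataFrame, variants: pd.DataFrame) -> pd.DataFrame:
    """Fill ``min_snp_p`` with the smallest ``p_divergence`` among each gene's
    variants (variants within [start, end] on the gene's arm)."""
    if "p_divergence" not in variants.columns:
        raise ValueError("variant table has no p_divergence column")
    out = annotations.copy()
    mins = np.full(len(out), np.nan)
    by_arm = dict(tuple(variants.groupby("arm", sort=False)))
    for i, gene in enumerate(out.itertuples(index=False)):
        sub = by_arm.get(gene.arm)
        if sub is None:
            continue
        hit = (sub["pos"] >= gene.start) & (sub["pos"] <= gene.end)
        if hit.any():
            mins[i] = sub.loc[hit, "p_divergence"].min()
    out["min_snp_p"] = mins
    return out


def select_candidates(
    annotations: pd.DataFrame,
    intervals: list[DivergenceInterval],
    params: FilterParams = FilterParams(),
) -> pd.DataFrame:
    """Apply the candidate-gene criteria; expects :func:`assign_genes` run.

    Returns one row per gene with ``selected``, per-route flags
    (``via_interval``, ``via_nominal``) and an ``audit`` column listing the
    failed criteria for rejected genes (empty when selected).  Audit codes:
    ``genomic``, ``expression``, ``unknown-expression``, ``rnai``.
    """
    params.validate()
    in_interval_ids = set()
    for iv in intervals:
        in_interval_ids.update(iv.genes)

    rows = []
    for gene in annotations.itertuples(index=False):
        min_p = gene.min_snp_p
        has_p = min_p is not None and np.isfinite(min_p)
        in_interval = gene.gene_id in in_interval_ids
        via_interval = in_interval and has_p and min_p < params.p_cutoff
        via_nominal = has_p and min_p < params.nominal_p_cutoff
        if params.rule == "interval":
            genomic = via_interval
        elif params.rule == "nominal":
            genomic = via_nominal
        else:
            genomic = via_interval or via_nominal

        audit = []
        if not genomic:
            audit.append("genomic")
        expr_flags = (gene.expressed_ovary, gene.expressed_accessory_gland)
        if any(pd.isna(f) for f in expr_flags):
            audit.append("unknown-expression")
        elif not (bool(expr_flags[0]) and bool(expr_flags[1])):
            audit.append("expression")
        if pd.isna(gene.rnai_available) or not bool(gene.rnai_available):
            audit.append("rnai")

        rows.append(
            {
                "gene_id": gene.gene_id,
                "symbol": gene.symbol,
                "in_interval": in_interval,
                "min_snp_p": min_p,
                "via_interval": via_interval,
                "via_nominal": via_nominal,
                "selected": not audit,
                "audit": ";".join(audit),
            }
        )
    return pd.DataFrame(rows)
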