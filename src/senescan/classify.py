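"""Antagonistic-pleiotropy classification of per-gene effect calls.

Senescence theory predicts that alleles extending lifespan can persist in
populations when they carry costs on other fitness components.  Each
gene's set of effect calls (lifespan per sex, lifetime productivity,
weekly productivity) is mapped onto the possible antagonism axes:

* ``sex`` — lifespan effects of opposite direction in females and males;
* ``early_vs_late_reproduction`` — significant weekly productivity calls
  of opposite direction between the early weeks (default 1-2) and the
  late weeks (default 4 onward; the boundary is a parameter because
  "early" and "late" have no canonical cutoff);
* ``lifespan_vs_reproduction`` — any significant lifespan call opposing
  any significant productivity call in fitness sign (longer life with
  lower reproduction, or the converse).

A gene with at least one axis is ``antagonistic_pleiotropy``; otherwise it
falls into one of the concordant categories.  Lifespan decrease and
productivity decrease are both costs; antagonism requires one significant
cost and one significant benefit.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "PleiotropyProfile",
    "classify",
    "classify_all",
    "category_counts",
    "screen_tallies",
]

LIFESPAN_PATTERNS = ("both_up", "both_down", "one_sex_up", "one_sex_down", "sex_antagonistic", "none")
CATEGORIES = (
    "no_effect",
    "lifespan_only_benefit",
    "lifespan_only_cost",
    "productivity_only",
    "concordant_beneficial",
    "concordant_deleterious",
    "antagonistic_pleiotropy",
)
AXES = ("sex", "lifespan_vs_reproduction", "early_vs_late_reproduction")


@dataclass(frozen=True)
class PleiotropyProfile:
    gene: str
    lifespan_pattern: str
    productivity_pattern: str
    category: str
    antagonism_axes: frozenset


def _lifespan_pattern(dir_f: str, dir_m: str) -> str:
    dirs = {dir_f, dir_m}
    if dirs == {"ns"}:
        return "none"
    if dirs == {"increase"}:
        return "both_up"
    if dirs == {"decrease"}:
        return "both_down"
    if dirs == {"increase", "decrease"}:
        return "sex_antagonistic"
    return "one_sex_up" if "increase" in dirs else "one_sex_down"


def _productivity_pattern(
    lifetime_dir: str, week_dirs: dict[int, str], early: set[int], late: set[int]
) -> str:
    sig = {w: d for w, d in week_dirs.items() if d != "ns"}
    early_dirs = {d for w, d in sig.items() if w in early}
    late_dirs = {d for w, d in sig.items() if w in late}
    if "increase" in early_dirs and "decrease" in late_dirs:
        return "early_up_late_down"
    if "decrease" in early_dirs and "increase" in late_dirs:
        return "early_down_late_up"
    if lifetime_dir == "increase":
        return "lifetime_up"
    if lifetime_dir == "decrease":
        return "lifetime_down"
    if "decrease" in sig.values():
        return "some_week_down"
    if "increase" in sig.values():
        return "some_week_up"
    return "none"


def classify(
    gene: str,
    calls: pd.DataFrame,
    early_weeks: set[int] | None = None,
    late_weeks: set[int] | None = None,
) -> PleiotropyProfile:
    """Map one gene's EffectCall rows to a :class:`PleiotropyProfile`.

    ``calls`` must cover both sexes' lifespan and at least one productivity
    trait (lifetime or weekly), all for the same gene.
    """
    genes = set(calls["gene"])
    if len(genes) > 1:
        raise ValueError(f"calls span multiple genes: {sorted(genes)}")
    if genes and genes != {gene}:
        raise ValueError(f"calls are for {genes.pop()!r}, not {gene!r}")
    early = {1, 2} if early_weeks is None else set(early_weeks)

    by_trait = {t: sub for t, sub in calls.groupby("trait", sort=False)}
    for t in ("lifespan_F", "lifespan_M"):
        if t not in by_trait:
            raise ValueError(f"calls lack the {t} trait")
    dir_f = by_trait["lifespan_F"]["direction"].iloc[0]
    dir_m = by_trait["lifespan_M"]["direction"].iloc[0]

    lifetime_dir = "ns"
    if "lifetime_productivity" in by_trait:
        lifetime_dir = by_trait["lifetime_productivity"]["direction"].iloc[0]
    week_dirs: dict[int, str] = {}
    if "weekly_productivity" in by_trait:
        wk = by_trait["weekly_productivity"]
        week_dirs = {int(w): d for w, d in zip(wk["week"], wk["direction"])}
    if "lifetime_productivity" not in by_trait and not week_dirs:
        raise ValueError("calls lack any productivity trait")
    if late_weeks is None:
        late = {w for w in week_dirs if w >= 4}
    else:
        late = set(late_weeks)

    sig_life = {d for d in (dir_f, dir_m) if d != "ns"}
    sig_prod = {d for d in [lifetime_dir, *week_dirs.values()] if d != "ns"}

    axes = set()
    if {"increase", "decrease"} <= {dir_f, dir_m}:
        axes.add("sex")
    early_dirs = {d for w, d in week_dirs.items() if w in early and d != "ns"}
    late_dirs = {d for w, d in week_dirs.items() if w in late and d != "ns"}
    if ("increase" in early_dirs and "decrease" in late_dirs) or (
        "decrease" in early_dirs and "increase" in late_dirs
    ):
        axes.add("early_vs_late_reproduction")
    if ("increase" in sig_life and "decrease" in sig_prod) or (
        "decrease" in sig_life and "increase" in sig_prod
    ):
        axes.add("lifespan_vs_reproduction")

    if axes:
        category = "antagonistic_pleiotropy"
    elif not sig_life and not sig_prod:
        category = "no_effect"
    elif sig_life and not sig_prod:
        category = "lifespan_only_benefit" if sig_life == {"increase"} else "lifespan_only_cost"
    elif sig_prod and not sig_life:
        category = "productivity_only"
    else:
        # both significant, no axis -> directions concordant in fitness sign
        category = "concordant_beneficial" if sig_life == {"increase"} else "concordant_deleterious"

    return PleiotropyProfile(
        gene=gene,
        lifespan_pattern=_lifespan_pattern(dir_f, dir_m),
        productivity_pattern=_productivity_pattern(lifetime_dir, week_dirs, early, late),
        category=category,
        antagonism_axes=frozenset(axes),
    )


def classify_all(
    calls: pd.DataFrame,
    early_weeks: set[int] | None = None,
    late_weeks: set[int] | None = None,
) -> pd.DataFrame:
    """Classify every gene in an EffectCall table; one profile row per gene."""
    rows = []
    for gene, sub in calls.groupby("gene", sort=False):
        prof = classify(gene, sub, early_weeks=early_weeks, late_weeks=late_weeks)
        rows.append(
            {
                "gene": prof.gene,
                "lifespan_pattern": prof.lifespan_pattern,
                "productivity_pattern": prof.productivity_pattern,
                "category": prof.category,
                "antagonism_axes": ";".join(sorted(prof.antagonism_axes)),
            }
        )
    return pd.DataFrame(rows)


def category_counts(profiles: pd.DataFrame) -> pd.Series:
    counts = profiles["category"].value_counts()
    return counts.reindex(CATEGORIES, fill_value=0)


def screen_tallies(calls: pd.DataFrame, profiles: pd.DataFrame) -> dict:
    """Headline screen tallies: genes affecting lifespan, increases and
    decreases by sex, sexually antagonistic genes, category counts."""
    life = calls[calls["trait"].isin(["lifespan_F", "lifespan_M"])]
    by_gene = life.groupby("gene")["direction"]
    affected = by_gene.apply(lambda d: (d != "ns").any())
    increased = by_gene.apply(lambda d: (d == "increase").any())
    decreased = by_gene.apply(lambda d: (d == "decrease").any())
    antagonistic = by_gene.apply(lambda d: {"increase", "decrease"} <= set(d))
    n_genes = life["gene"].nunique()
    return {
        "n_genes": int(n_genes),
        "lifespan_affected": int(affected.sum()),
        "lifespan_increased_any_sex": int(increased.sum()),
        "lifespan_decreased_any_sex": int(decreased.sum()),
        "lifespan_sex_antagonistic": int(antagonistic.sum()),
        "categories": {k: int(v) for k, v in category_counts(profiles).items()},
    }
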