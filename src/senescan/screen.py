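"""Effect calling for the RNAi life-history screen.

Each RNAi genotype is compared with its background-matched control within
its experimental block.  Lifespan uses the mixed factorial model
``lifespan ~ S + G + S*G + Rep(G) + S*Rep(G)`` for the sex-by-genotype
interaction and per-sex reduced models ``lifespan ~ G + Rep(G)`` for the
sex-specific calls.  Lifetime productivity (the per-vial sum of weekly
offspring per female; weeks after a vial's extinction genuinely contribute
zero) uses ``Y ~ G``; weekly productivity uses the full ``Y ~ W + G + W*G``
over weeks observed in both genotypes and per-week reduced ``Y ~ G``
models, skipping weeks a genotype never reached.  qPCR Ct values are
normalized to the reference gene (log2 expression = -(Ct_target -
Ct_reference)) and analyzed with biological replicate as the random
stratum.  Significance is per-test at alpha with no multiple-testing
correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anova import AnovaModel, AnovaResults, TukeyResult

logger = logging.getLogger(__name__)

__all__ = [
    "EffectCall",
    "PairingError",
    "call_lifespan_effects",
    "call_productivity_effects",
    "analyze_ob_productivity",
    "call_knockdown",
    "lifespan_sex_contrast",
    "ObProductivityResult",
]

CONTROL_TRAITS = {
    "lifespan_F",
    "lifespan_M",
    "lifetime_productivity",
    "weekly_productivity",
    "expression_ovary",
    "expression_AG",
}


class PairingError(ValueError):
    """An RNAi genotype has no matching control in the data."""


@dataclass(frozen=True)
class EffectCall:
    """One gene x trait contrast versus control.

    ``estimate`` is RNAi minus control on the trait's scale; ``direction``
    is ``ns`` iff ``p_value >= alpha`` and otherwise follows the estimate's
    sign.
    """

    gene: str
    trait: str
    estimate: float
    se: float
    p_value: float
    direction: str
    week: int | None = None


def _direction(estimate: float, p: float, alpha: float) -> str:
    if p >= alpha:
        return "ns"
    return "increase" if estimate > 0 else "decrease"


def _calls_frame(calls: list[dict]) -> pd.DataFrame:
    cols = ["gene", "trait", "week", "estimate", "se", "p_value", "direction"]
    extra = sorted({k for c in calls for k in c} - set(cols))
    df = pd.DataFrame(calls, columns=cols + extra)
    df["week"] = pd.to_numeric(df["week"])  # float with NaN for week-less traits
    return df


def _pairs(df: pd.DataFrame) -> list[tuple[str, str, object]]:
    """Unique (gene, control, block) comparisons; genotypes paired with
    themselves are controls and produce no call."""
    seen = []
    for g, c, b in df[["genotype", "control_pairing", "block"]].drop_duplicates().itertuples(index=False):
        if g == c:
            continue
        seen.append((g, c, b))
    return seen


def lifespan_sex_contrast(df_sex: pd.DataFrame, gene: str, control: str) -> tuple[float, float, float]:
    """Per-sex reduced model ``lifespan ~ G + Rep(G)``; returns
    (estimate, se, p) for gene minus control.  This is the call path the
    screen uses for each sex."""
    res = AnovaModel.from_formula("lifespan ~ G + Rep(G)", df_sex, rep_col="vial").fit()
    c = res.contrast("G", gene, control)
    p = float(res.anova_table.loc["G", "p"])
    return c.estimate, c.se, p


def call_lifespan_effects(lifespan: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene, per-sex lifespan EffectCalls against block-matched controls.

    Returns one row per gene per sex (traits ``lifespan_F``/``lifespan_M``)
    with the full-model sex-by-genotype interaction P attached as
    ``p_sex_interaction``.
    """
    calls: list[dict] = []
    genotypes = set(lifespan["genotype"])
    for gene, control, block in _pairs(lifespan):
        if control not in genotypes:
            raise PairingError(f"control {control!r} for {gene!r} not present in the data")
        sub = lifespan[
            (lifespan["block"] == block) & (lifespan["genotype"].isin([gene, control]))
        ].copy()
        sub["G"] = sub["genotype"]
        sub["S"] = sub["sex"]
        full = AnovaModel.from_formula(
            "lifespan ~ S + G + S*G + Rep(G) + S*Rep(G)", sub, rep_col="vial"
        ).fit()
        p_sxg = float(full.anova_table.loc["S*G", "p"])
        for sex in ("F", "M"):
            est, se, p = lifespan_sex_contrast(sub[sub["S"] == sex], gene, control)
            calls.append(
                {
                    "gene": gene,
                    "trait": f"lifespan_{sex}",
                    "week": None,
                    "estimate": est,
                    "se": se,
                    "p_value": p,
                    "direction": _direction(est, p, alpha),
                    "p_sex_interaction": p_sxg,
                }
            )
    return _calls_frame(calls)


def lifetime_productivity(weekly: pd.DataFrame) -> pd.DataFrame:
    """Per-vial lifetime productivity: the sum of observed weekly values
    (weeks after extinction contribute zero)."""
    out = (
        weekly.groupby(["genotype", "vial"], sort=False)["offspring_per_female"]
        .sum()
        .reset_index(name="lifetime")
    )
    return out


def call_productivity_effects(
    weekly: pd.DataFrame, pairing: dict[str, str], alpha: float = 0.05
) -> pd.DataFrame:
    """Lifetime and per-week productivity EffectCalls.

    ``pairing`` maps each RNAi genotype to its control genotype.  The
    weekly full model's week-by-genotype interaction P is attached to the
    weekly rows as ``p_week_interaction``; weeks in which either genotype
    has no surviving vials are skipped (no call).
    """
    calls: list[dict] = []
    genotypes = set(weekly["genotype"])
    life = lifetime_productivity(weekly)
    for gene, control in sorted(pairing.items()):
        if gene == control:
            continue
        if control not in genotypes:
            raise PairingError(f"control {control!r} for {gene!r} not present in the data")
        sub_life = life[life["genotype"].isin([gene, control])].copy()
        sub_life["G"] = sub_life["genotype"]
        res = AnovaModel.from_formula("lifetime ~ G", sub_life).fit()
        c = res.contrast("G", gene, control)
        p = float(res.anova_table.loc["G", "p"])
        calls.append(
            {
                "gene": gene,
                "trait": "lifetime_productivity",
                "week": None,
                "estimate": c.estimate,
                "se": c.se,
                "p_value": p,
                "direction": _direction(c.estimate, p, alpha),
            }
        )

        sub = weekly[weekly["genotype"].isin([gene, control])].copy()
        sub["G"] = sub["genotype"]
        sub["W"] = sub["week"]
        weeks_gene = set(sub.loc[sub["G"] == gene, "week"])
        weeks_ctl = set(sub.loc[sub["G"] == control, "week"])
        common = sorted(weeks_gene & weeks_ctl)
        if not common:
            raise ValueError(f"no overlapping weeks between {gene!r} and {control!r}")
        p_wxg = np.nan
        if len(common) >= 2:
            full_sub = sub[sub["week"].isin(common)]
            wres = AnovaModel.from_formula("offspring_per_female ~ W + G + W*G", full_sub).fit()
            p_wxg = float(wres.anova_table.loc["W*G", "p"])
        skipped = sorted((weeks_gene | weeks_ctl) - set(common))
        if skipped:
            logger.info("%s vs %s: skipping week(s) %s with one-sided data", gene, control, skipped)
        for w in common:
            wk = sub[sub["week"] == w]
            res_w = AnovaModel.from_formula("offspring_per_female ~ G", wk).fit()
            cw = res_w.contrast("G", gene, control)
            pw = float(res_w.anova_table.loc["G", "p"])
            calls.append(
                {
                    "gene": gene,
                    "trait": "weekly_productivity",
                    "week": int(w),
                    "estimate": cw.estimate,
                    "se": cw.se,
                    "p_value": pw,
                    "direction": _direction(cw.estimate, pw, alpha),
                    "p_week_interaction": p_wxg,
                }
            )
    return _calls_frame(calls)


@dataclass
class ObProductivityResult:
    """Full-factorial results plus per-week reduced models and Tukey letters
    for the O/B reciprocal-cross productivity assay."""

    full: AnovaResults
    weekly: dict[int, tuple[AnovaResults, TukeyResult]] = field(default_factory=dict)


def analyze_ob_productivity(ob: pd.DataFrame, alpha: float = 0.05) -> ObProductivityResult:
    """Maternal/paternal-regime factorial ANOVA of weekly productivity.

    Full model ``Y ~ Gm + Gf + W + Gm*W + Gf*W + Gm*Gf + Gm*Gf*W``; per week
    the reduced ``Y ~ Gm + Gf + Gm*Gf`` with Tukey-Kramer letters over the
    four crosses.  Weeks missing a regime are skipped with a warning.
    """
    d = ob.copy()
    d["Gm"] = d["gm"]
    d["Gf"] = d["gf"]
    d["W"] = d["week"]
    full = AnovaModel.from_formula(
        "offspring_per_female ~ Gm + Gf + W + Gm*W + Gf*W + Gm*Gf + Gm*Gf*W", d
    ).fit()
    weekly: dict[int, tuple[AnovaResults, TukeyResult]] = {}
    for w in sorted(d["week"].unique()):
        sub = d[d["week"] == w]
        if sub["Gm"].nunique() < 2 or sub["Gf"].nunique() < 2:
            warnings.warn(f"week {w}: a regime is missing; reduced model skipped", stacklevel=2)
            continue
        res = AnovaModel.from_formula("offspring_per_female ~ Gm + Gf + Gm*Gf", sub).fit()
        weekly[int(w)] = (res, res.tukey(("Gm", "Gf"), alpha=alpha))
    return ObProductivityResult(full, weekly)


def normalized_expression(qpcr: pd.DataFrame) -> pd.DataFrame:
    """Per-technical-replicate log2 expression normalized to the reference
    gene: log2(2^-(Ct_target - Ct_reference)) = Ct_reference - Ct_target.
    Replicates missing the reference Ct are dropped with a warning."""
    d = qpcr.copy()
    missing = d["ct_reference"].isna() | d["ct_target"].isna()
    if missing.any():
        warnings.warn(f"dropping {int(missing.sum())} qPCR replicate(s) missing a Ct value", stacklevel=2)
        d = d[~missing]
    d["log2_expr"] = d["ct_reference"] - d["ct_target"]
    return d


_TISSUE_TRAIT = {"ovary": "expression_ovary", "accessory_gland": "expression_AG"}


def call_knockdown(qpcr: pd.DataFrame, alpha: float = 0.05) -> tuple[pd.DataFrame, dict[str, AnovaResults]]:
    """Knockdown EffectCalls per gene x tissue on the log2 expression scale.

    Per tissue: a combined model ``Y ~ L + G + L*G + Rep(L*G)`` across genes
    (biological replicate as the random stratum), then per-gene reduced
    models ``Y ~ L + Rep(L)`` giving the estimate (RNAi minus control,
    log2) and P-value.  Returns (calls, combined results per tissue).
    """
    d = normalized_expression(qpcr)
    calls: list[dict] = []
    combined: dict[str, AnovaResults] = {}
    for tissue, sub_t in d.groupby("tissue", sort=False):
        sub_t = sub_t.copy()
        sub_t["L"] = sub_t["line"]
        sub_t["G"] = sub_t["gene"]
        if sub_t["G"].nunique() >= 2:
            combined[tissue] = AnovaModel.from_formula(
                "log2_expr ~ L + G + L*G + Rep(L*G)", sub_t, rep_col="biological_rep"
            ).fit()
        for gene, sub in sub_t.groupby("G", sort=False):
            res = AnovaModel.from_formula("log2_expr ~ L + Rep(L)", sub, rep_col="biological_rep").fit()
            c = res.contrast("L", "rnai", "control")
            p = float(res.anova_table.loc["L", "p"])
            calls.append(
                {
                    "gene": gene,
                    "trait": _TISSUE_TRAIT.get(tissue, f"expression_{tissue}"),
                    "week": None,
                    "estimate": c.estimate,
                    "se": c.se,
                    "p_value": p,
                    "direction": _direction(c.estimate, p, alpha),
                }
            )
    return _calls_frame(calls), combined
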