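"""Golden effect-direction fixtures for the pleiotropy classifier.

Each entry encodes one verbally described screen outcome as a direction
vector — female lifespan, male lifespan, lifetime productivity and weekly
productivity directions (weeks 1..5; early = {1, 2}, late = {4, 5}) —
with the category and antagonism axes it must map to.
"""

from __future__ import annotations

import pandas as pd

NS = "ns"
UP = "increase"
DN = "decrease"

# gene -> (dir_F, dir_M, dir_lifetime, {week: dir}, expected_category, expected_axes)
GOLDEN: dict[str, tuple] = {
    # lifespan up in one sex, productivity untouched
    "Lztr1": (UP, NS, NS, {}, "lifespan_only_benefit", set()),
    "pcx": (UP, NS, NS, {}, "lifespan_only_benefit", set()),
    # lifespan down in one sex only
    "CG18273": (NS, DN, NS, {}, "lifespan_only_cost", set()),
    "TRAM": (NS, DN, NS, {}, "lifespan_only_cost", set()),
    # productivity without lifespan effects
    "CG7970": (NS, NS, NS, {2: DN}, "productivity_only", set()),
    "Hsp22": (NS, NS, DN, {}, "productivity_only", set()),
    "piwi": (NS, NS, NS, {1: UP}, "productivity_only", set()),
    # early/late reproduction trade-off, lifespan untouched
    "babos": (NS, NS, NS, {1: UP, 4: DN}, "antagonistic_pleiotropy", {"early_vs_late_reproduction"}),
    "sov": (NS, NS, NS, {2: UP, 5: DN}, "antagonistic_pleiotropy", {"early_vs_late_reproduction"}),
    # concordant costs
    "blw": (DN, NS, DN, {3: DN}, "concordant_deleterious", set()),
    "CycE": (DN, DN, DN, {}, "concordant_deleterious", set()),
    # concordant benefits
    "CG3071": (UP, NS, NS, {2: UP}, "concordant_beneficial", set()),
    "sgg": (UP, UP, NS, {1: UP}, "concordant_beneficial", set()),
    "zf30c": (UP, NS, UP, {}, "concordant_beneficial", set()),
    # no effect at all
    "dnc": (NS, NS, NS, {}, "no_effect", set()),
    # longer life bought with lower early reproduction
    "abo": (UP, NS, NS, {1: DN}, "antagonistic_pleiotropy", {"lifespan_vs_reproduction"}),
    "Klp67A": (UP, NS, NS, {1: DN}, "antagonistic_pleiotropy", {"lifespan_vs_reproduction"}),
    # shorter life with higher early reproduction
    "CG3704": (NS, DN, NS, {1: UP}, "antagonistic_pleiotropy", {"lifespan_vs_reproduction"}),
    "sra": (DN, NS, NS, {2: UP}, "antagonistic_pleiotropy", {"lifespan_vs_reproduction"}),
    # sexually antagonistic lifespan with a productivity cost
    "Cdc7": (UP, DN, NS, {2: DN}, "antagonistic_pleiotropy", {"sex", "lifespan_vs_reproduction"}),
    "Dredd": (DN, UP, DN, {}, "antagonistic_pleiotropy", {"sex", "lifespan_vs_reproduction"}),
    # longer life, early loss / late gain in reproduction
    "CG32809": (
        UP, NS, NS, {1: DN, 4: UP},
        "antagonistic_pleiotropy", {"early_vs_late_reproduction", "lifespan_vs_reproduction"},
    ),
    "wds": (
        UP, NS, NS, {1: DN, 5: UP},
        "antagonistic_pleiotropy", {"early_vs_late_reproduction", "lifespan_vs_reproduction"},
    ),
    # shorter female life, early gain / late loss
    "Eip75B": (
        DN, NS, NS, {1: UP, 4: DN},
        "antagonistic_pleiotropy", {"early_vs_late_reproduction", "lifespan_vs_reproduction"},
    ),
    # triple antagonism
    "capu": (
        DN, UP, NS, {1: UP, 4: DN},
        "antagonistic_pleiotropy",
        {"sex", "early_vs_late_reproduction", "lifespan_vs_reproduction"},
    ),
    "MED22": (
        DN, UP, NS, {1: UP, 4: DN},
        "antagonistic_pleiotropy",
        {"sex", "early_vs_late_reproduction", "lifespan_vs_reproduction"},
    ),
    "CG13369": (
        UP, DN, NS, {1: DN, 4: UP},
        "antagonistic_pleiotropy",
        {"sex", "early_vs_late_reproduction", "lifespan_vs_reproduction"},
    ),
}


def calls_for(gene: str, dir_f: str, dir_m: str, dir_lifetime: str, week_dirs: dict[int, str]) -> pd.DataFrame:
    """Build an EffectCall frame from a direction vector (P-values are set
    consistently with the directions at alpha = 0.05)."""
    rows = [
        {"gene": gene, "trait": "lifespan_F", "week": None, "direction": dir_f},
        {"gene": gene, "trait": "lifespan_M", "week": None, "direction": dir_m},
        {"gene": gene, "trait": "lifetime_productivity", "week": None, "direction": dir_lifetime},
    ]
    for w in range(1, 6):
        rows.append(
            {"gene": gene, "trait": "weekly_productivity", "week": w, "direction": week_dirs.get(w, NS)}
        )
    df = pd.DataFrame(rows)
    df["estimate"] = df["direction"].map({UP: 1.0, DN: -1.0, NS: 0.1})
    df["p_value"] = df["direction"].map({UP: 0.01, DN: 0.01, NS: 0.5})
    return df
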