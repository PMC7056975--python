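"""Classical factorial ANOVA with nested random effects (EMS F-ratios).

The life-history models here are fixed or mixed factorial designs that are
balanced or nearly balanced, analyzed the classical way: least-squares
fits, partial (Type III-style, full-vs-reduced) sums of squares computed
with sum-to-zero effect coding — these reduce to the sequential
decomposition when the design is balanced — and F denominators chosen by
expected-mean-squares rules.  A term containing no random factor is tested
against the lowest random term whose factor set contains it (e.g. G
against Rep(G); S and S*G against S*Rep(G)); purely fixed models test
against the residual.  Random terms are tested against the smallest random
term strictly containing them, falling back to the residual.

Formulas use a small grammar mirroring the field's model notation::

    lifespan ~ S + G + S*G + Rep(G) + S*Rep(G)

``Rep(G)`` denotes the random replicate factor nested within genotype; the
data column holding replicate labels is named by ``rep_col`` (labels only
need to be unique within their nesting cell).  ``*`` (or the multiplication
sign) builds interactions.  Every fixed interaction must have its parent
main effects in the model.

This is not REML: with attrition the design becomes mildly unbalanced and
a likelihood-based mixed model could differ slightly; the classical EMS
construction is used because the designs are near-balanced and the
published tables are classical ANOVA tables.

Example
-------
>>> model = AnovaModel.from_formula("lifespan ~ G + Rep(G)", data, rep_col="vial")
>>> res = model.fit()
>>> res.anova_table          # df, sum_sq, mean_sq, denom, F, p per term
>>> res.contrast("G", "rnai", "control")
>>> print(res.summary())
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Term",
    "parse_formula",
    "AnovaModel",
    "AnovaResults",
    "TukeyResult",
    "Contrast",
    "FormulaError",
    "AliasedTermError",
]

REP = "Rep"


class FormulaError(ValueError):
    pass


class AliasedTermError(ValueError):
    pass


@dataclass(frozen=True)
class Term:
    """One model term: crossed fixed factors, optionally times a nested
    random replicate factor ``Rep(<nest factors>)``."""

    crossed: tuple[str, ...] = ()
    rep_within: tuple[str, ...] | None = None

    @property
    def is_random(self) -> bool:
        return self.rep_within is not None

    @property
    def factor_set(self) -> frozenset:
        s = set(self.crossed)
        if self.is_random:
            s |= set(self.rep_within)
            s.add(REP)
        return frozenset(s)

    @property
    def name(self) -> str:
        parts = list(self.crossed)
        if self.is_random:
            parts.append(f"{REP}({','.join(self.rep_within)})")
        return "*".join(parts)

    def __str__(self) -> str:  # pragma: no cover
        return self.name


_REP_RE = re.compile(r"Rep\(([^)]*)\)")


def parse_formula(formula: str) -> tuple[str | None, list[Term]]:
    """Parse ``response ~ terms`` (or just the term list) into Terms."""
    response = None
    rhs = formula
    if "~" in formula:
        response, rhs = (s.strip() for s in formula.split("~", 1))
    rhs = rhs.replace("×", "*")
    terms: list[Term] = []
    for tok in rhs.split("+"):
        tok = tok.strip()
        if not tok or tok in ("1", "mu", "µ"):
            continue
        rep: tuple[str, ...] | None = None
        matches = list(_REP_RE.finditer(tok))
        if len(matches) > 1:
            raise FormulaError(f"term {tok!r} has more than one Rep(...) factor")
        if matches:
            # nesting factors may be separated by ',' or '*'
            rep = tuple(
                x.strip() for x in re.split(r"[,*]", matches[0].group(1)) if x.strip()
            )
            if not rep:
                raise FormulaError("Rep(...) must name its nesting factors")
            tok_rest = tok[: matches[0].start()] + tok[matches[0].end() :]
        else:
            tok_rest = tok
        crossed: list[str] = []
        for part in (p.strip() for p in tok_rest.split("*")):
            if part == REP:
                raise FormulaError("Rep must be written nested, e.g. Rep(G)")
            if part:
                crossed.append(part)
        terms.append(Term(tuple(crossed), rep))
    _check_hierarchy(terms)
    return response, terms


def _check_hierarchy(terms: list[Term]) -> None:
    mains = {t.crossed[0] for t in terms if len(t.crossed) == 1 and not t.is_random}
    declared = set().union(*(set(t.crossed) for t in terms)) if terms else set()
    for t in terms:
        if not t.is_random and len(t.crossed) >= 2:
            missing = [f for f in t.crossed if f not in mains]
            if missing:
                raise FormulaError(f"interaction {t.name!r} lacks main effect(s) for {missing}")
        if t.is_random:
            unknown = [f for f in t.rep_within if f not in declared]
            if unknown:
                raise FormulaError(f"{t.name!r} nests within undeclared factor(s) {unknown}")


# ---------------------------------------------------------------------------
# design-matrix construction (sum-to-zero effect coding)


def _effect_codes(values: pd.Series) -> np.ndarray:
    levels = list(pd.unique(values))
    n, k = len(values), len(levels)
    if k < 2:
        return np.zeros((n, 0))
    idx = values.map({lv: i for i, lv in enumerate(levels)}).to_numpy()
    X = np.zeros((n, k - 1))
    inner = idx < k - 1
    X[np.flatnonzero(inner), idx[inner]] = 1.0
    X[idx == k - 1, :] = -1.0
    return X


def _nested_rep_codes(data: pd.DataFrame, nest: tuple[str, ...], rep_col: str) -> np.ndarray:
    """Effect-code replicate levels within each nesting cell."""
    n = len(data)
    if nest:
        cells = pd.Series(list(zip(*(data[f] for f in nest))), index=data.index)
    else:
        cells = pd.Series([()] * n, index=data.index)
    blocks = []
    for cell in pd.unique(cells):
        mask = (cells == cell).to_numpy()
        reps = list(pd.unique(data.loc[mask, rep_col]))
        r = len(reps)
        if r < 2:
            continue
        sub = np.zeros((n, r - 1))
        ridx = data.loc[mask, rep_col].map({rv: i for i, rv in enumerate(reps)}).to_numpy()
        rows = np.flatnonzero(mask)
        inner = ridx < r - 1
        sub[rows[inner], ridx[inner]] = 1.0
        sub[rows[~inner], :] = -1.0
        blocks.append(sub)
    if not blocks:
        return np.zeros((n, 0))
    return np.hstack(blocks)


def _rowwise_kron(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (a[:, :, None] * b[:, None, :]).reshape(a.shape[0], -1)


def _term_columns(data: pd.DataFrame, term: Term, rep_col: str) -> np.ndarray:
    X = np.ones((len(data), 1))
    for f in term.crossed:
        X = _rowwise_kron(X, _effect_codes(data[f]))
    if term.is_random:
        X = _rowwise_kron(X, _nested_rep_codes(data, term.rep_within, rep_col))
    return X


def _ols_sse(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


# ---------------------------------------------------------------------------


class AnovaModel:
    """Factorial (possibly mixed) ANOVA model for a tidy data frame.

    Parameters
    ----------
    data : DataFrame with one column per factor plus the response.
    formula : ``"response ~ term + ..."`` in the grammar above.
    rep_col : name of the column holding replicate labels for ``Rep(...)``
        terms (default ``"Rep"``).
    """

    def __init__(self, data: pd.DataFrame, formula: str, rep_col: str = REP):
        response, terms = parse_formula(formula)
        if response is None:
            raise FormulaError("formula must name the response: 'y ~ ...'")
        if response not in data.columns:
            raise KeyError(f"response column {response!r} not in data")
        self.data = data.reset_index(drop=True)
        self.response = response
        self.terms = terms
        self.rep_col = rep_col
        self.formula = formula

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame, rep_col: str = REP) -> "AnovaModel":
        return cls(data, formula, rep_col=rep_col)

    # -- checks ------------------------------------------------------------

    def _check_design(self) -> None:
        factors = set(itertools.chain.from_iterable(t.crossed for t in self.terms))
        for t in self.terms:
            if t.is_random:
                factors |= set(t.rep_within)
                if self.rep_col not in self.data.columns:
                    raise KeyError(f"replicate column {self.rep_col!r} not in data")
        for f in factors:
            if f not in self.data.columns:
                raise KeyError(f"factor column {f!r} not in data")
            if self.data[f].nunique() < 2:
                raise ValueError(f"factor {f!r} has fewer than 2 levels")
        for t in self.terms:
            if t.is_random or len(t.crossed) < 2:
                continue
            counts = self.data.groupby(list(t.crossed), observed=False).size()
            full = np.prod([self.data[f].nunique() for f in t.crossed])
            if len(counts) < full or (counts == 0).any():
                raise ValueError(f"empty cell(s) in fixed-effect term {t.name!r}")

    def _denominator(self, term: Term) -> Term | None:
        """EMS denominator: smallest random term whose factors contain this
        term's (strictly, for random terms); None means residual."""
        if term.is_random:
            candidates = [
                r
                for r in self.terms
                if r.is_random and r != term and term.factor_set < r.factor_set
            ]
        else:
            candidates = [r for r in self.terms if r.is_random and term.factor_set <= r.factor_set]
        if not candidates:
            return None
        return min(candidates, key=lambda r: len(r.factor_set))

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "AnovaResults":
        self._check_design()
        y = self.data[self.response].to_numpy(dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValueError("response contains non-finite values")
        n = len(y)
        blocks = {t: _term_columns(self.data, t, self.rep_col) for t in self.terms}
        X_full = np.hstack([np.ones((n, 1))] + [blocks[t] for t in self.terms])
        sse_full, rank_full = _ols_sse(X_full, y)
        df_resid = n - rank_full
        if df_resid <= 0:
            raise ValueError("zero residual degrees of freedom")

        ss: dict[Term, float] = {}
        df: dict[Term, int] = {}
        for t in self.terms:
            X_minus = np.hstack(
                [np.ones((n, 1))] + [blocks[u] for u in self.terms if u != t]
            )
            sse_m, rank_m = _ols_sse(X_minus, y)
            d = rank_full - rank_m
            if d == 0:
                raise AliasedTermError(f"term {t.name!r} is aliased with the rest of the design")
            ss[t] = max(sse_m - sse_full, 0.0)
            df[t] = d

        ms = {t: ss[t] / df[t] for t in self.terms}
        ms_resid = sse_full / df_resid
        rows = []
        denom_map: dict[str, tuple[float, int, str]] = {}
        for t in self.terms:
            d = self._denominator(t)
            if d is None:
                denom_name, ms_d, df_d = "Residual", ms_resid, df_resid
            else:
                denom_name, ms_d, df_d = d.name, ms[d], df[d]
            if ms_d > 0:
                F = ms[t] / ms_d
                p = float(stats.f.sf(F, df[t], df_d))
            elif ss[t] == 0.0:
                F, p = 0.0, 1.0
            else:
                F, p = np.inf, 0.0
            denom_map[t.name] = (ms_d, df_d, denom_name)
            rows.append((t.name, df[t], ss[t], ms[t], denom_name, F, p))
        rows.append(("Residual", df_resid, sse_full, ms_resid, "", np.nan, np.nan))
        table = pd.DataFrame(
            rows, columns=["term", "df", "sum_sq", "mean_sq", "denom", "F", "p"]
        ).set_index("term")
        return AnovaResults(self, table, denom_map)


@dataclass(frozen=True)
class Contrast:
    estimate: float
    se: float
    df: int
    t: float
    p: float


@dataclass(frozen=True)
class TukeyResult:
    """All-pairwise Tukey-Kramer comparisons plus a compact letter display
    (levels sharing a letter are not significantly different)."""

    table: pd.DataFrame
    letters: dict


class AnovaResults:
    """Fit results: the ANOVA table, cell means, contrasts and Tukey tests."""

    def __init__(self, model: AnovaModel, table: pd.DataFrame, denom_map: dict):
        self.model = model
        self.anova_table = table
        self._denoms = denom_map
        self.nobs = len(model.data)

    @property
    def residual_df(self) -> int:
        return int(self.anova_table.loc["Residual", "df"])

    @property
    def residual_ss(self) -> float:
        return float(self.anova_table.loc["Residual", "sum_sq"])

    def _as_factors(self, factor) -> tuple[str, ...]:
        return (factor,) if isinstance(factor, str) else tuple(factor)

    def _error_for(self, factors: tuple[str, ...]) -> tuple[float, int]:
        """Error MS/df appropriate to a fixed term over these factors: the
        denominator used for its F-test when the term is in the model, else
        the residual."""
        for t in self.model.terms:
            if not t.is_random and set(t.crossed) == set(factors):
                ms, dfd, _ = self._denoms[t.name]
                return ms, dfd
        return (
            float(self.anova_table.loc["Residual", "mean_sq"]),
            self.residual_df,
        )

    def cell_means(self, factor) -> pd.DataFrame:
        factors = self._as_factors(factor)
        g = self.model.data.groupby(list(factors), sort=False, observed=False)[self.model.response]
        ms, _ = self._error_for(factors)
        out = g.agg(mean="mean", n="size").reset_index()
        out["se"] = np.sqrt(ms / out["n"])
        return out

    def contrast(self, factor: str, a, b) -> Contrast:
        """Difference of level means (a minus b) with its EMS-based standard
        error and a t-test on the denominator's degrees of freedom."""
        cm = self.cell_means(factor).set_index(factor)
        ms, dfd = self._error_for((factor,))
        est = float(cm.loc[a, "mean"] - cm.loc[b, "mean"])
        se = float(np.sqrt(ms * (1.0 / cm.loc[a, "n"] + 1.0 / cm.loc[b, "n"])))
        t = est / se if se > 0 else (0.0 if est == 0 else np.inf)
        p = float(2.0 * stats.t.sf(abs(t), dfd)) if np.isfinite(t) else 0.0
        return Contrast(est, se, int(dfd), float(t), min(p, 1.0))

    def tukey(self, factor, alpha: float = 0.05) -> TukeyResult:
        """Tukey-Kramer studentized-range comparisons over the factor's cell
        means (``factor`` may be a tuple of factors for cross combinations),
        against the model's appropriate error MS."""
        factors = self._as_factors(factor)
        cm = self.cell_means(factors)
        if len(factors) == 1:
            labels = list(cm[factors[0]])
        else:
            labels = [tuple(r) for r in cm[list(factors)].itertuples(index=False)]
        k = len(labels)
        if k < 2:
            raise ValueError("Tukey test needs a factor with at least 2 levels")
        ms, dfe = self._error_for(factors)
        means = cm["mean"].to_numpy()
        ns = cm["n"].to_numpy()
        rows = []
        sig_pairs = []
        for i in range(k):
            for j in range(i + 1, k):
                diff = means[i] - means[j]
                se = np.sqrt(ms / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
                q = abs(diff) / se if se > 0 else (0.0 if diff == 0 else np.inf)
                p = float(stats.studentized_range.sf(q, k, dfe)) if np.isfinite(q) else 0.0
                p = min(max(p, 0.0), 1.0)
                reject = p < alpha
                if reject:
                    sig_pairs.append((labels[i], labels[j]))
                rows.append((labels[i], labels[j], diff, q, p, reject))
        table = pd.DataFrame(rows, columns=["level_a", "level_b", "diff", "q", "p", "reject"])
        order = [labels[i] for i in np.argsort(-means, kind="stable")]
        letters = _letter_display(order, sig_pairs)
        return TukeyResult(table, letters)

    def summary(self) -> str:
        lines = [
            f"ANOVA: {self.model.formula}",
            f"n = {self.nobs}",
            "",
            self.anova_table.to_string(
                float_format=lambda v: f"{v:.6g}", na_rep=""
            ),
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<AnovaResults: {self.model.formula}, n={self.nobs}>"


def _letter_display(order: list, sig_pairs: list[tuple]) -> dict:
    """Insert-and-absorb compact letter display.

    ``order`` lists the levels (highest mean first); ``sig_pairs`` the pairs
    judged different.  Levels sharing any letter are not significantly
    different.
    """
    cols: list[set] = [set(order)]
    for a, b in sig_pairs:
        for col in [c for c in cols if a in c and b in c]:
            cols.remove(col)
            for new in (col - {a}, col - {b}):
                if new and not any(new <= other for other in cols):
                    cols.append(new)
    cols = [c for c in cols if not any(c < other for other in cols)]
    rank = {lv: i for i, lv in enumerate(order)}
    cols.sort(key=lambda c: min(rank[lv] for lv in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict = {lv: "" for lv in order}
    for i, col in enumerate(cols):
        for lv in order:
            if lv in col:
                letters[lv] += alphabet[i % len(alphabet)]
    return letters
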