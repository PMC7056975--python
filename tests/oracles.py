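"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive results by enumeration/direct computation,
sharing no code with the implementation they check.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def brute_force_intervals(
    dp: list[float],
    high: float = 0.8,
    interruption: float = 0.5,
    max_interruption: int = 2,
    order_rng: np.random.Generator | None = None,
) -> list[tuple[int, int]]:
    """Merge-to-fixpoint by repeatedly applying one legal merge at a time.

    Intervals are (start_index, end_index) inclusive over the variant list.
    Seed intervals are runs of consecutive values above ``high``; a merge of
    two neighbouring intervals is legal when the run between them has at
    most ``max_interruption`` values, all above ``interruption``.  When
    ``order_rng`` is given, the merge applied at each step is chosen at
    random among the currently legal ones (to probe order-independence);
    otherwise the first is taken.
    """
    intervals: list[tuple[int, int]] = []
    i = 0
    n = len(dp)
    while i < n:
        if dp[i] > high:
            j = i
            while j + 1 < n and dp[j + 1] > high:
                j += 1
            intervals.append((i, j))
            i = j + 1
        else:
            i += 1

    def legal_merges() -> list[int]:
        out = []
        for k in range(len(intervals) - 1):
            gap = dp[intervals[k][1] + 1 : intervals[k + 1][0]]
            if len(gap) <= max_interruption and all(g > interruption for g in gap):
                out.append(k)
        return out

    while True:
        merges = legal_merges()
        if not merges:
            return intervals
        k = merges[0] if order_rng is None else merges[int(order_rng.integers(len(merges)))]
        a, b = intervals[k], intervals[k + 1]
        intervals[k : k + 2] = [(a[0], b[1])]


def random_dp_table(rng: np.random.Generator, max_len: int = 30) -> list[float]:
    """A random delta-p sequence concentrated around the decision thresholds."""
    n = int(rng.integers(0, max_len + 1))
    pool = np.array([0.05, 0.3, 0.45, 0.5, 0.55, 0.75, 0.8, 0.85, 0.95, 1.0])
    return list(rng.choice(pool, size=n))


def tukey_q_matrix(means: np.ndarray, ns: np.ndarray, ms_error: float) -> np.ndarray:
    """All pairwise Tukey-Kramer q statistics computed directly from cell
    means and the pooled error mean square."""
    k = len(means)
    q = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i != j:
                se = np.sqrt(ms_error / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
                q[i, j] = abs(means[i] - means[j]) / se
    return q


def balanced_two_way_ss(y: np.ndarray) -> dict[str, float]:
    """Sequential sums of squares for a balanced two-way layout from cell
    means; ``y`` has shape (a, b, n)."""
    a, b, n = y.shape
    grand = y.mean()
    mean_a = y.mean(axis=(1, 2))
    mean_b = y.mean(axis=(0, 2))
    mean_ab = y.mean(axis=2)
    ss_a = b * n * float(((mean_a - grand) ** 2).sum())
    ss_b = a * n * float(((mean_b - grand) ** 2).sum())
    ss_ab = n * float(
        ((mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2).sum()
    )
    ss_resid = float(((y - mean_ab[:, :, None]) ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    return {"A": ss_a, "B": ss_b, "A*B": ss_ab, "Residual": ss_resid, "Total": ss_total}


def nested_mixed_f(y: np.ndarray) -> dict[str, float]:
    """Classical EMS F-ratios for the balanced design
    sex x genotype with replicate vials nested in genotype;
    ``y`` has shape (genotypes, vials, sexes, flies)."""
    g, v, s, n = y.shape
    grand = y.mean()
    m_g = y.mean(axis=(1, 2, 3))
    m_s = y.mean(axis=(0, 1, 3))
    m_gs = y.mean(axis=(1, 3))
    m_gv = y.mean(axis=(2, 3))
    m_gvs = y.mean(axis=3)
    ss_g = v * s * n * float(((m_g - grand) ** 2).sum())
    ss_s = g * v * n * float(((m_s - grand) ** 2).sum())
    ss_gs = v * n * float(((m_gs - m_g[:, None] - m_s[None, :] + grand) ** 2).sum())
    ss_rep = s * n * float(((m_gv - m_g[:, None]) ** 2).sum())
    ss_srep = n * float(
        ((m_gvs - m_gv[:, :, None] - m_gs[:, None, :] + m_g[:, None, None]) ** 2).sum()
    )
    ss_resid = float(((y - m_gvs[:, :, :, None]) ** 2).sum())
    ms = {
        "G": ss_g / (g - 1),
        "S": ss_s / (s - 1),
        "S*G": ss_gs / ((g - 1) * (s - 1)),
        "Rep(G)": ss_rep / (g * (v - 1)),
        "S*Rep(G)": ss_srep / (g * (v - 1) * (s - 1)),
        "Residual": ss_resid / (g * v * s * (n - 1)),
    }
    F = {
        "G": ms["G"] / ms["Rep(G)"],
        "S": ms["S"] / ms["S*Rep(G)"],
        "S*G": ms["S*G"] / ms["S*Rep(G)"],
        "Rep(G)": ms["Rep(G)"] / ms["S*Rep(G)"],
        "S*Rep(G)": ms["S*Rep(G)"] / ms["Residual"],
    }
    return {"ss": {k: v_ for k, v_ in ms.items()}, "ms": ms, "F": F}


def pooled_t_squared(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    t, p = stats.ttest_ind(a, b)
    return float(t**2), float(p)
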