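"""Synthetic data generation for the divergence scan and the RNAi screen.

Emulates the structure of a postponed-senescence evolve-and-resequence
study in *Drosophila melanogaster*: five replicate selected (O) lines and
five unselected control (B) lines are scored for reference-allele
frequencies at variants along the major chromosome arms.  Line-to-line
drift around the ancestral frequency is modelled with a Beta distribution;
selective sweeps are planted as intervals in which the O-line frequencies
are driven toward the chromosome boundary opposite the B-line mean so that
the expected absolute frequency difference |dp| equals a target value.
Sequencing noise is binomial at a configurable mean depth.

The screen generator produces the three phenotype tables downstream models
consume: per-fly lifespans (genotype, sex, genotype-by-sex and shared vial
effects), per-vial weekly offspring per female (declining with age,
truncated at zero, vials ceasing to report once all their females have
died), and qPCR Ct values with biological and technical replication
against a constant housekeeping reference.

All randomness flows from a single seed through named substreams, so the
genome simulation is unaffected by adding or removing screen genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PlantedSweep",
    "SimConfig",
    "simulate_frequencies",
    "simulate_screen",
    "simulate_ob_productivity",
    "simulate_annotations",
]

#: chromosome arm name, length in bp, number of variants simulated on it
DEFAULT_ARMS: list[tuple[str, int, int]] = [
    ("X", 23_500_000, 2000),
    ("2L", 23_000_000, 1500),
    ("2R", 25_300_000, 1500),
    ("3L", 28_100_000, 1500),
    ("3R", 32_100_000, 1500),
]

CONTROL_LABEL = "control"


@dataclass(frozen=True)
class PlantedSweep:
    """A genomic interval in which O lines diverge from B lines.

    ``target_divergence`` is the expected |dp| (absolute difference of the
    O-line and B-line mean frequencies) for variants inside the interval,
    in (0, 1].
    """

    arm: str
    start: int
    end: int
    target_divergence: float

    def validate(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"sweep on {self.arm}: start must be < end")
        if not 0.0 < self.target_divergence <= 1.0:
            raise ValueError("target_divergence must be in (0, 1]")


@dataclass
class SimConfig:
    """Study-design and noise parameters for the synthetic data generator.

    Design constants default to the screen's layout: 48 lifespan vials per
    genotype with 3 flies of each sex per vial, 13 weekly-productivity
    vials per genotype, 15 vials per cross in the O/B productivity assay,
    and 2 biological x 3 technical qPCR replicates.
    """

    seed: int = 0
    n_sel_lines: int = 5
    n_ctl_lines: int = 5
    arms: list[tuple[str, int, int]] = field(default_factory=lambda: list(DEFAULT_ARMS))
    sweeps: list[PlantedSweep] = field(default_factory=list)
    #: Beta concentration for line-to-line drift around the ancestral frequency
    drift_concentration: float = 50.0
    #: mean read depth for binomial frequency noise (math.inf = noise free)
    coverage: float = 50.0

    # screen design constants
    n_lifespan_vials: int = 48
    flies_per_sex_per_vial: int = 3
    n_productivity_vials: int = 13
    n_ob_vials: int = 15
    qpcr_bio_reps: int = 2
    qpcr_tech_reps: int = 3

    # planted effects, keyed by gene symbol
    lifespan_effects: dict[str, tuple[float, float]] = field(default_factory=dict)  # (female, male) days
    productivity_effects: dict[str, dict[int, float]] = field(default_factory=dict)  # {week: offspring/female}
    qpcr_knockdown: dict[str, float] = field(default_factory=dict)  # fraction of control expression retained

    # phenotype baselines
    lifespan_mean: dict[str, float] = field(default_factory=lambda: {"F": 60.0, "M": 55.0})
    vial_sd: float = 3.0
    lifespan_resid_sd: float = 10.0
    weekly_means: tuple[float, ...] = (25.0, 20.0, 12.0, 6.0, 3.0)
    productivity_sd: float = 5.0
    qpcr_bio_sd: float = 0.3
    qpcr_tech_sd: float = 0.15
    ct_reference_mean: float = 16.0
    ct_target_mean: float = 22.0

    # synthetic annotation layout
    genes_per_arm: int = 40
    gene_length: int = 8_000

    def validate(self) -> None:
        for name, v in [
            ("n_sel_lines", self.n_sel_lines),
            ("n_ctl_lines", self.n_ctl_lines),
            ("n_lifespan_vials", self.n_lifespan_vials),
            ("flies_per_sex_per_vial", self.flies_per_sex_per_vial),
            ("n_productivity_vials", self.n_productivity_vials),
            ("n_ob_vials", self.n_ob_vials),
            ("qpcr_bio_reps", self.qpcr_bio_reps),
            ("qpcr_tech_reps", self.qpcr_tech_reps),
        ]:
            if v <= 0:
                raise ValueError(f"{name} must be > 0")
        if not self.drift_concentration > 0:
            raise ValueError("drift_concentration must be > 0")
        if not (self.coverage >= 1):
            raise ValueError("coverage must be >= 1")
        for gene, k in self.qpcr_knockdown.items():
            if not 0.0 <= k <= 1.0:
                raise ValueError(f"qpcr_knockdown[{gene!r}] must be in [0, 1]")
        arm_lengths = {name: length for name, length, _ in self.arms}
        by_arm: dict[str, list[PlantedSweep]] = {}
        for sw in self.sweeps:
            sw.validate()
            if sw.arm not in arm_lengths:
                raise ValueError(f"sweep arm {sw.arm!r} not among configured arms")
            if sw.end > arm_lengths[sw.arm]:
                raise ValueError(f"sweep on {sw.arm} extends past the arm end")
            by_arm.setdefault(sw.arm, []).append(sw)
        for arm, sws in by_arm.items():
            sws = sorted(sws, key=lambda s: s.start)
            for a, b in zip(sws, sws[1:]):
                if b.start <= a.end:
                    raise ValueError(f"overlapping sweeps on arm {arm}")

    def screen_genotypes(self) -> list[str]:
        genes = set(self.lifespan_effects) | set(self.productivity_effects) | set(self.qpcr_knockdown)
        return sorted(genes)


_STREAMS = ("genome", "lifespan", "productivity", "qpcr", "ob", "annotation")


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(child) for name, child in zip(_STREAMS, children)}


def _beta_lines(rng: np.random.Generator, mean: np.ndarray, conc: float, n_lines: int) -> np.ndarray:
    """Per-line true frequencies drawn Beta(mean*c, (1-mean)*c), shape (n, n_lines).

    Degenerate means (0 or 1) and infinite concentration collapse to the mean.
    """
    mean = np.asarray(mean, dtype=float)
    n = mean.shape[0]
    if math.isinf(conc):
        return np.broadcast_to(mean[:, None], (n, n_lines)).copy()
    out = np.broadcast_to(mean[:, None], (n, n_lines)).copy()
    interior = (mean > 0.0) & (mean < 1.0)
    if interior.any():
        m = mean[interior]
        draws = rng.beta(m * conc, (1.0 - m) * conc, size=(n_lines, m.shape[0])).T
        out[interior, :] = draws
    return out


def _sequencing_noise(rng: np.random.Generator, true: np.ndarray, coverage: float) -> np.ndarray:
    if math.isinf(coverage):
        return true
    depth = int(round(coverage))
    return rng.binomial(depth, true) / depth


def _divergence_pvalues(sel: np.ndarray, ctl: np.ndarray) -> np.ndarray:
    """5-vs-5 t-test on arcsine-sqrt transformed line frequencies, per variant."""
    import warnings

    t_sel = np.arcsin(np.sqrt(np.clip(sel, 0.0, 1.0)))
    t_ctl = np.arcsin(np.sqrt(np.clip(ctl, 0.0, 1.0)))
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-identical groups trigger a scipy precision warning; those
        # variants get p = 1 below anyway
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(t_sel, t_ctl, axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    # zero within-group variance with equal means -> undefined statistic -> no evidence
    p[~np.isfinite(p)] = 1.0
    return np.clip(p, np.finfo(float).tiny, 1.0)


def _unique_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    if n > length:
        raise ValueError("more variants requested than bp on the arm")
    pos = np.unique(rng.integers(1, length + 1, size=2 * n))
    while pos.shape[0] < n:
        pos = np.unique(np.concatenate([pos, rng.integers(1, length + 1, size=n)]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def simulate_frequencies(config: SimConfig) -> pd.DataFrame:
    """Simulate the per-variant allele-frequency table for the O vs B design.

    Returns a DataFrame with columns ``arm``, ``pos``,
    ``freq_sel_1..n``, ``freq_ctl_1..n``, ``delta_p``, ``p_divergence``,
    sorted by (arm, pos) with unique positions per arm.
    """
    config.validate()
    rng = _rngs(config.seed)["genome"]
    frames = []
    sweeps_by_arm: dict[str, list[PlantedSweep]] = {}
    for sw in config.sweeps:
        sweeps_by_arm.setdefault(sw.arm, []).append(sw)

    for arm, length, n_var in config.arms:
        pos = _unique_positions(rng, length, n_var)
        p0 = rng.uniform(0.05, 0.95, size=n_var)
        target = np.zeros(n_var)
        for sw in sweeps_by_arm.get(arm, []):
            mask = (pos >= sw.start) & (pos <= sw.end)
            d = sw.target_divergence
            # ancestral frequency low enough that the +d shift stays in [0, 1]
            hi = 1.0 - d
            p0[mask] = rng.uniform(0.0, hi, size=mask.sum()) if hi > 0 else 0.0
            target[mask] = d
        mean_ctl = p0
        mean_sel = p0 + target
        true_ctl = _beta_lines(rng, mean_ctl, config.drift_concentration, config.n_ctl_lines)
        true_sel = _beta_lines(rng, mean_sel, config.drift_concentration, config.n_sel_lines)
        obs_ctl = _sequencing_noise(rng, true_ctl, config.coverage)
        obs_sel = _sequencing_noise(rng, true_sel, config.coverage)
        delta_p = np.abs(obs_sel.mean(axis=1) - obs_ctl.mean(axis=1))
        p_div = _divergence_pvalues(obs_sel, obs_ctl)
        cols: dict[str, np.ndarray | str] = {"arm": arm, "pos": pos}
        for i in range(config.n_sel_lines):
            cols[f"freq_sel_{i + 1}"] = obs_sel[:, i]
        for i in range(config.n_ctl_lines):
            cols[f"freq_ctl_{i + 1}"] = obs_ctl[:, i]
        cols["delta_p"] = delta_p
        cols["p_divergence"] = p_div
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


def _lifespan_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    n_vials = config.n_lifespan_vials
    n_flies = config.flies_per_sex_per_vial
    for g in [CONTROL_LABEL] + config.screen_genotypes():
        eff_f, eff_m = config.lifespan_effects.get(g, (0.0, 0.0))
        vial_eff = rng.normal(0.0, config.vial_sd, size=n_vials)
        resid = rng.normal(0.0, config.lifespan_resid_sd, size=(n_vials, 2, n_flies))
        for v in range(n_vials):
            for s, (sex, shift) in enumerate([("F", eff_f), ("M", eff_m)]):
                base = config.lifespan_mean[sex]
                for i in range(n_flies):
                    y = max(base + shift + vial_eff[v] + resid[v, s, i], 0.0)
                    rows.append((g, CONTROL_LABEL, 1, sex, f"{g}_L{v + 1}", y))
    return pd.DataFrame(
        rows, columns=["genotype", "control_pairing", "block", "sex", "vial", "lifespan"]
    )


def _productivity_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    n_weeks = len(config.weekly_means)
    for g in [CONTROL_LABEL] + config.screen_genotypes():
        eff_f, _ = config.lifespan_effects.get(g, (0.0, 0.0))
        week_eff = config.productivity_effects.get(g, {})
        for v in range(config.n_productivity_vials):
            vial_eff = rng.normal(0.0, config.vial_sd)
            female_life = (
                config.lifespan_mean["F"]
                + eff_f
                + vial_eff
                + rng.normal(0.0, config.lifespan_resid_sd, size=config.flies_per_sex_per_vial)
            )
            last_alive = max(female_life.max(), 0.0)
            noise = rng.normal(0.0, config.productivity_sd, size=n_weeks)
            for w in range(1, n_weeks + 1):
                if (w - 1) * 7.0 >= last_alive:
                    continue  # vial extinct: week is missing, not zero
                y = config.weekly_means[w - 1] + week_eff.get(w, 0.0) + noise[w - 1]
                rows.append((g, f"{g}_P{v + 1}", w, max(y, 0.0)))
    return pd.DataFrame(rows, columns=["genotype", "vial", "week", "offspring_per_female"])


#: floor on relative expression so a complete knockdown keeps Ct finite
_EXPR_FLOOR = 2.0 ** -12


def _qpcr_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for g in sorted(config.qpcr_knockdown):
        k = max(config.qpcr_knockdown[g], _EXPR_FLOOR)
        for tissue in ("ovary", "accessory_gland"):
            for line, expr in (("control", 1.0), ("rnai", k)):
                for b in range(1, config.qpcr_bio_reps + 1):
                    bio = rng.normal(0.0, config.qpcr_bio_sd)
                    for t in range(1, config.qpcr_tech_reps + 1):
                        ct_ref = config.ct_reference_mean + rng.normal(0.0, config.qpcr_tech_sd)
                        ct_tar = (
                            config.ct_target_mean
                            - math.log2(expr)
                            + bio
                            + rng.normal(0.0, config.qpcr_tech_sd)
                        )
                        rows.append((line, g, tissue, b, t, ct_tar, ct_ref))
    return pd.DataFrame(
        rows,
        columns=["line", "gene", "tissue", "biological_rep", "technical_rep", "ct_target", "ct_reference"],
    )


def simulate_screen(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the RNAi screen: lifespan, weekly productivity and qPCR tables.

    Each table includes the control genotype; RNAi genotypes are the keys of
    the planted-effect dicts.  Lifespan draws share a vial effect across all
    six flies of a vial; productivity vials stop contributing once all their
    females are dead; qPCR Ct values reflect the planted knockdown fraction
    relative to the control line with a constant-expression reference gene.
    """
    config.validate()
    rngs = _rngs(config.seed)
    lifespan = _lifespan_table(config, rngs["lifespan"])
    productivity = _productivity_table(config, rngs["productivity"])
    qpcr = _qpcr_table(config, rngs["qpcr"])
    return lifespan, productivity, qpcr


def simulate_ob_productivity(
    config: SimConfig,
    maternal_week_effects: dict[int, float] | None = None,
    paternal_week_effects: dict[int, float] | None = None,
    interaction_week_effects: dict[int, float] | None = None,
    n_weeks: int = 4,
) -> pd.DataFrame:
    """Simulate the O/B reciprocal-cross productivity assay at the regime level.

    The four crosses (maternal x paternal regime in {B, O} x {B, O}) each get
    ``config.n_ob_vials`` vials scored weekly for ``n_weeks`` weeks.  Effects
    are additive shifts (offspring/female) applied when the maternal regime,
    paternal regime, or both are "O".
    """
    config.validate()
    rng = _rngs(config.seed)["ob"]
    mat = maternal_week_effects or {}
    pat = paternal_week_effects or {}
    inter = interaction_week_effects or {}
    rows = []
    for gm in ("B", "O"):
        for gf in ("B", "O"):
            for v in range(config.n_ob_vials):
                vial = f"{gm}x{gf}_{v + 1}"
                for w in range(1, n_weeks + 1):
                    y = config.weekly_means[w - 1]
                    if gm == "O":
                        y += mat.get(w, 0.0)
                    if gf == "O":
                        y += pat.get(w, 0.0)
                    if gm == "O" and gf == "O":
                        y += inter.get(w, 0.0)
                    y += rng.normal(0.0, config.productivity_sd)
                    rows.append((gm, gf, vial, w, max(y, 0.0)))
    return pd.DataFrame(rows, columns=["gm", "gf", "vial", "week", "offspring_per_female"])


def simulate_annotations(config: SimConfig) -> pd.DataFrame:
    """Generate a gene-annotation table consistent with the genome simulation.

    Screen genes (any gene with a planted effect) are placed inside planted
    sweeps, round-robin across sweeps, and flagged as expressed in both
    tissues with RNAi stocks available.  Background genes tile each arm at
    random positions with random flags.  ``min_snp_p`` is left unset; join it
    from a variant table with :func:`senescan.candidates.annotate_min_snp_p`.
    """
    config.validate()
    rng = _rngs(config.seed)["annotation"]
    rows = []
    for arm, length, _ in config.arms:
        starts = np.sort(rng.integers(1, max(length - config.gene_length, 2), size=config.genes_per_arm))
        for i, s in enumerate(starts):
            rows.append(
                (
                    f"GS_{arm}_{i + 1:03d}",
                    f"gs-{arm}-{i + 1}",
                    arm,
                    int(s),
                    int(s) + config.gene_length - 1,
                    bool(rng.random() < 0.6),
                    bool(rng.random() < 0.6),
                    bool(rng.random() < 0.8),
                    float("nan"),
                )
            )
    genes = config.screen_genotypes()
    sweeps = list(config.sweeps)
    for i, g in enumerate(genes):
        if sweeps:
            sw = sweeps[i % len(sweeps)]
            offset = (i // len(sweeps)) * config.gene_length
            start = min(sw.start + offset, max(sw.end - config.gene_length, sw.start))
            end = min(start + config.gene_length - 1, sw.end)
        else:
            arm, length, _ = config.arms[0]
            sw = None
            start = int(rng.integers(1, max(length - config.gene_length, 2)))
            end = start + config.gene_length - 1
        rows.append(
            (f"FBgn_{g}", g, sw.arm if sw else config.arms[0][0], int(start), int(end), True, True, True, float("nan"))
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "symbol",
            "arm",
            "start",
            "end",
            "expressed_ovary",
            "expressed_accessory_gland",
            "rnai_available",
            "min_snp_p",
        ],
    )
    return df.sort_values(["arm", "start"], kind="stable").reset_index(drop=True)
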