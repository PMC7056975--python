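"""Effect callers: planted-effect recovery, null behaviour, identity and
symmetry properties, O/B maternal-effect analysis, knockdown calls."""

import numpy as np
import pandas as pd
import pytest

from senescan import (
    SimConfig,
    analyze_ob_productivity,
    call_knockdown,
    call_lifespan_effects,
    call_productivity_effects,
    simulate_ob_productivity,
    simulate_screen,
)
from senescan.screen import PairingError, lifetime_productivity


def screen_cfg(seed=1, **effects):
    return SimConfig(seed=seed, arms=[], **effects)


class TestLifespanCalls:
    def test_sex_specific_planted_effect_recovered(self):
        """A +10-day female-only effect is flagged in females every time and
        in males at no more than the nominal false-positive rate."""
        male_ns = 0
        for seed in range(5):
            life, _, _ = simulate_screen(screen_cfg(seed=seed, lifespan_effects={"g1": (10.0, 0.0)}))
            calls = call_lifespan_effects(life).set_index("trait")
            assert calls.loc["lifespan_F", "direction"] == "increase"
            assert calls.loc["lifespan_F", "estimate"] == pytest.approx(10.0, abs=4.0)
            assert calls.loc["lifespan_F", "p_sex_interaction"] < 0.05
            male_ns += calls.loc["lifespan_M", "direction"] == "ns"
        assert male_ns >= 4

    def test_sexually_antagonistic_effect_recovered(self):
        life, _, _ = simulate_screen(screen_cfg(lifespan_effects={"g1": (8.0, -8.0)}))
        calls = call_lifespan_effects(life).set_index("trait")
        assert calls.loc["lifespan_F", "direction"] == "increase"
        assert calls.loc["lifespan_M", "direction"] == "decrease"

    def test_null_gene_not_called(self):
        life, _, _ = simulate_screen(screen_cfg(seed=42, lifespan_effects={"g1": (0.0, 0.0)}))
        calls = call_lifespan_effects(life)
        assert (calls["direction"] == "ns").all()

    def test_control_copy_gives_exactly_zero(self):
        """A genotype that is literally a relabelled copy of its control
        yields estimate 0 and P = 1."""
        life, _, _ = simulate_screen(screen_cfg(lifespan_effects={"g1": (5.0, 5.0)}))
        ctl = life[life["genotype"] == "control"]
        mock = ctl.assign(genotype="mock", vial=ctl["vial"].str.replace("control", "mock"))
        calls = call_lifespan_effects(pd.concat([ctl, mock], ignore_index=True))
        assert (calls["estimate"] == 0.0).all()
        assert np.allclose(calls["p_value"], 1.0)
        assert (calls["direction"] == "ns").all()

    def test_missing_control_raises(self):
        life, _, _ = simulate_screen(screen_cfg(lifespan_effects={"g1": (0.0, 0.0)}))
        with pytest.raises(PairingError, match="control"):
            call_lifespan_effects(life[life["genotype"] != "control"])

    def test_label_swap_negates_estimates_and_keeps_p(self):
        """Treating the control as the RNAi line (and vice versa) negates
        every estimate and preserves every P-value exactly."""
        life, _, _ = simulate_screen(screen_cfg(lifespan_effects={"g1": (6.0, -2.0)}))
        calls = call_lifespan_effects(life).set_index("trait")
        # same data, roles swapped: 'control' is now the tested genotype, paired to g1
        swapped = life.assign(control_pairing="g1")
        calls_s = call_lifespan_effects(swapped).set_index("trait")
        for trait in ("lifespan_F", "lifespan_M"):
            assert calls_s.loc[trait, "estimate"] == pytest.approx(-calls.loc[trait, "estimate"], rel=1e-9)
            assert calls_s.loc[trait, "p_value"] == pytest.approx(calls.loc[trait, "p_value"], rel=1e-9)


class TestProductivityCalls:
    def test_early_up_late_down_pattern_recovered(self):
        """An early increase + late decrease shows up as at least one
        significant increase in weeks 1-2 and one decrease in weeks 4-5, in
        at least 4 of 5 replicates; no call ever points the wrong way."""
        hits = 0
        for seed in range(5):
            cfg = screen_cfg(seed=seed, productivity_effects={"g1": {1: 8.0, 2: 8.0, 4: -6.0, 5: -6.0}})
            _, weekly, _ = simulate_screen(cfg)
            calls = call_productivity_effects(weekly, {"g1": "control"})
            wk = calls[calls["trait"] == "weekly_productivity"].set_index("week")["direction"]
            assert wk.get(1) != "decrease" and wk.get(2) != "decrease"
            assert wk.get(4) != "increase" and wk.get(5) != "increase"
            early_up = "increase" in {wk.get(1), wk.get(2)}
            late_down = "decrease" in {wk.get(4), wk.get(5)}
            hits += early_up and late_down
        assert hits >= 4

    def test_uniform_increase_lifts_lifetime_productivity(self):
        cfg = screen_cfg(productivity_effects={"g1": {w: 5.0 for w in range(1, 6)}})
        _, weekly, _ = simulate_screen(cfg)
        calls = call_productivity_effects(weekly, {"g1": "control"})
        lt = calls[calls["trait"] == "lifetime_productivity"].iloc[0]
        assert lt["direction"] == "increase"
        assert lt["estimate"] == pytest.approx(25.0, abs=12.0)

    def test_all_zero_productivity_is_ns_everywhere(self):
        cfg = screen_cfg(productivity_effects={"g1": {}}, weekly_means=(0.0,) * 5, productivity_sd=1e-9)
        _, weekly, _ = simulate_screen(cfg)
        weekly["offspring_per_female"] = 0.0
        calls = call_productivity_effects(weekly, {"g1": "control"})
        assert (calls["direction"] == "ns").all()

    def test_lifetime_sums_observed_weeks(self):
        weekly = pd.DataFrame(
            {
                "genotype": ["a"] * 3 + ["a"],
                "vial": ["v1"] * 3 + ["v2"],
                "week": [1, 2, 3, 1],
                "offspring_per_female": [10.0, 5.0, 1.0, 7.0],
            }
        )
        lt = lifetime_productivity(weekly).set_index("vial")["lifetime"]
        assert lt["v1"] == 16.0
        assert lt["v2"] == 7.0  # extinct after week 1: later weeks add nothing

    def test_weeks_missing_in_one_genotype_are_skipped(self):
        cfg = screen_cfg(
            lifespan_effects={"dead": (-50.0, 0.0)},
            productivity_effects={"dead": {}},
            lifespan_resid_sd=1.0,
            vial_sd=0.5,
        )
        _, weekly, _ = simulate_screen(cfg)
        calls = call_productivity_effects(weekly, {"dead": "control"})
        called_weeks = set(calls.loc[calls["trait"] == "weekly_productivity", "week"])
        assert max(called_weeks) <= 2  # the short-lived genotype never reaches late weeks


class TestObProductivity:
    def test_maternal_late_week_effect(self):
        cfg = SimConfig(seed=21, arms=[])
        ob = simulate_ob_productivity(cfg, maternal_week_effects={3: 5.0, 4: 8.0})
        res = analyze_ob_productivity(ob)
        w4 = res.weekly[4][0].anova_table
        assert w4.loc["Gm", "p"] < 0.05
        assert w4.loc["Gf", "p"] >= 0.05
        assert res.full.anova_table.loc["Gm*W", "p"] < 0.05

    def test_interaction_effect_detected(self):
        cfg = SimConfig(seed=22, arms=[])
        ob = simulate_ob_productivity(cfg, interaction_week_effects={w: 8.0 for w in range(1, 5)})
        res = analyze_ob_productivity(ob)
        assert res.full.anova_table.loc["Gm*Gf", "p"] < 0.05

    def test_identical_means_single_tukey_letter(self):
        cfg = SimConfig(seed=23, arms=[])
        ob = simulate_ob_productivity(cfg)
        res = analyze_ob_productivity(ob)
        for w, (tab, tukey) in res.weekly.items():
            assert set(tukey.letters.values()) == {"a"}, w
        assert (res.full.anova_table.loc[["Gm", "Gf", "Gm*Gf"], "p"] >= 0.05).all()


class TestKnockdown:
    def test_planted_quarter_expression_estimated_near_minus_two(self):
        """A 4-fold knockdown is estimated near -2 log2 units; with only two
        biological replicates the call is significant most but not all of
        the time."""
        sig = 0
        for seed in range(5):
            _, _, qpcr = simulate_screen(screen_cfg(seed=seed, qpcr_knockdown={"g1": 0.25}))
            calls, combined = call_knockdown(qpcr)
            calls = calls.set_index("trait")
            for trait in ("expression_ovary", "expression_AG"):
                assert calls.loc[trait, "estimate"] == pytest.approx(-2.0, abs=0.7)
                sig += calls.loc[trait, "direction"] == "decrease"
            assert combined == {}  # single gene: no combined model
        assert sig >= 6  # of 10 gene x tissue calls

    def test_combined_model_runs_across_genes(self):
        _, _, qpcr = simulate_screen(screen_cfg(qpcr_knockdown={"g1": 0.25, "g2": 0.8}))
        _, combined = call_knockdown(qpcr)
        tab = combined["ovary"].anova_table
        assert tab.loc["L", "denom"] == "Rep(L,G)"
        assert tab.loc["L", "p"] < 0.05

    def test_identical_expression_is_ns(self):
        _, _, qpcr = simulate_screen(screen_cfg(seed=30, qpcr_knockdown={"g1": 1.0}))
        calls, _ = call_knockdown(qpcr)
        assert (calls["direction"] == "ns").all()

    def test_large_biological_variance_widens_se_and_blocks_call(self):
        """With few biological replicates and large between-replicate
        variance the point estimate stays low but the call is ns."""
        cfg = screen_cfg(seed=31, qpcr_knockdown={"g1": 0.5}, qpcr_bio_sd=2.5)
        _, _, qpcr = simulate_screen(cfg)
        calls, _ = call_knockdown(qpcr)
        tight = call_knockdown(simulate_screen(screen_cfg(seed=31, qpcr_knockdown={"g1": 0.5}))[2])[0]
        assert calls["se"].mean() > 3 * tight["se"].mean()
        assert (calls["direction"] == "ns").all()

    def test_missing_reference_ct_dropped_with_warning(self):
        _, _, qpcr = simulate_screen(screen_cfg(qpcr_knockdown={"g1": 0.25}))
        qpcr.loc[0, "ct_reference"] = np.nan
        with pytest.warns(UserWarning, match="missing a Ct"):
            calls, _ = call_knockdown(qpcr)
        assert len(calls) == 2
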