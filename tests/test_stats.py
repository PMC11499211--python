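"""Response tables, mixed RM ANOVA, Sidak post hoc and summaries."""

import numpy as np
import pandas as pd
import pytest

from maternet.ethogram import Dataset, ObservationSession
from maternet.stats import (
    ResponseTable,
    mixed_anova,
    response_table,
    sidak_posthoc,
    summarize,
)
from maternet.transitions import transition_count


def make_table(values, groups, response="transitions", phase="DARK"):
    """values: dict dam -> list over days; groups: dict dam -> group."""
    frame = pd.DataFrame(values).T
    frame.columns = pd.Index(range(2, 2 + frame.shape[1]), name="ppd")
    frame.index.name = "dam_id"
    return ResponseTable(
        values=frame, groups=pd.Series(groups), response=response, phase=phase
    )


def random_table(rng, n_per_group=4, n_days=5, shift=0.0):
    values, groups = {}, {}
    for g, label in enumerate(("CTRL", "LBN")):
        for i in range(n_per_group):
            dam = f"{label}{i}"
            values[dam] = rng.normal(shift * g, 1.0, size=n_days)
            groups[dam] = label
    return make_table(values, groups)


def _uniform_session(dam, group, ppd, period, codes):
    return ObservationSession(dam, group, ppd, period, tuple(codes))


class TestResponseTable:
    def _tiny_dataset(self):
        sessions = []
        for dam, group in (("c1", "CTRL"), ("c2", "CTRL"), ("l1", "LBN"), ("l2", "LBN")):
            for ppd in (2, 3):
                am = ["HG"] * 10 + ["DN"] * 15
                pm = ["HG"] * 14 + ["DN"] * 11
                dark = ["OFF"] * 25
                sessions += [
                    _uniform_session(dam, group, ppd, "AM", am),
                    _uniform_session(dam, group, ppd, "PM", pm),
                    _uniform_session(dam, group, ppd, "DARK", dark),
                ]
        return Dataset(sessions)

    def test_light_value_is_am_pm_mean(self):
        ds = self._tiny_dataset()
        table = response_table(ds, "HG", "LIGHT")
        assert table.values.at["c1", 2] == 12.0  # mean of 10 and 14

    def test_dark_value_is_single_period(self):
        ds = self._tiny_dataset()
        table = response_table(ds, "OFF", "DARK")
        assert np.all(table.values.to_numpy() == 25.0)

    def test_all_hg_dataset_constant_responses(self):
        sessions = [
            _uniform_session(dam, grp, ppd, period, ["HG"] * 25)
            for dam, grp in (("a", "CTRL"), ("b", "LBN"))
            for ppd in (2, 3)
            for period in ("AM", "PM", "DARK")
        ]
        ds = Dataset(sessions)
        assert np.all(response_table(ds, "HG", "LIGHT").values.to_numpy() == 25.0)
        assert np.all(response_table(ds, "LW", "LIGHT").values.to_numpy() == 0.0)
        assert np.all(response_table(ds, "transitions", "DARK").values.to_numpy() == 0.0)

    def test_transitions_response_matches_session_counts(self, small_dataset):
        table = response_table(small_dataset, "transitions", "LIGHT")
        dam = small_dataset.dam_ids()[0]
        expected = np.mean(
            [
                transition_count(small_dataset.session(dam, 4, p).codes)
                for p in ("AM", "PM")
            ]
        )
        assert table.values.at[dam, 4] == pytest.approx(expected)

    def test_missing_sessions_listed(self, small_dataset):
        broken = Dataset([s for s in small_dataset if s.key[1:] != (5, "PM")])
        with pytest.raises(ValueError, match="missing sessions.*5, 'PM'"):
            response_table(broken, "HG", "LIGHT")


class TestMixedAnova:
    def test_study_design_degrees_of_freedom(self, default_dataset):
        """2 groups x 9 dams x 8 days: housing df (1,16); day/interaction (7,112)."""
        table = response_table(default_dataset, "transitions", "DARK")
        anova = mixed_anova(table)
        assert (anova["housing"]["df1"], anova["housing"]["df2"]) == (1, 16)
        assert (anova["day"]["df1"], anova["day"]["df2"]) == (7, 112)
        assert (anova["interaction"]["df1"], anova["interaction"]["df2"]) == (7, 112)

    def test_degenerate_constant_table(self):
        table = make_table(
            {"a": [3.0] * 4, "b": [3.0] * 4, "c": [3.0] * 4, "d": [3.0] * 4},
            {"a": "CTRL", "b": "CTRL", "c": "LBN", "d": "LBN"},
        )
        anova = mixed_anova(table)
        assert np.all(anova.effects["F"] == 0.0)
        assert np.all(anova.effects["p"] == 1.0)

    def test_ss_decomposition_is_exact(self, rng):
        for _ in range(50):
            table = random_table(rng)
            anova = mixed_anova(table)
            parts = (
                anova.ss["housing"]
                + anova.ss["subjects_within_groups"]
                + anova.ss["day"]
                + anova.ss["interaction"]
                + anova.ss["day_x_subjects_within_groups"]
            )
            assert parts == pytest.approx(anova.ss["total"], rel=1e-9)

    def test_matches_pingouin_on_random_designs(self, rng):
        """Cross-check against an independent mixed-ANOVA implementation."""
        import pingouin as pg

        for _ in range(30):
            table = random_table(rng, n_per_group=3, n_days=4, shift=0.5)
            anova = mixed_anova(table)
            long = (
                table.values.stack()
                .rename("y")
                .reset_index()
                .merge(table.groups.rename("group"), left_on="dam_id", right_index=True)
            )
            ref = pg.mixed_anova(
                data=long, dv="y", within="ppd", subject="dam_id",
                between="group", correction=False,
            ).set_index("Source")
            assert anova["housing"]["F"] == pytest.approx(ref.at["group", "F"], rel=1e-10)
            assert anova["day"]["F"] == pytest.approx(ref.at["ppd", "F"], rel=1e-10)
            assert anova["interaction"]["F"] == pytest.approx(
                ref.at["Interaction", "F"], rel=1e-10
            )
            assert anova["housing"]["p"] == pytest.approx(ref.at["group", "p_unc"], rel=1e-8)
            assert anova["day"]["p"] == pytest.approx(ref.at["ppd", "p_unc"], rel=1e-8)

    def test_unbalanced_groups_rejected(self, rng):
        table = random_table(rng)
        dropped = ResponseTable(
            values=table.values.iloc[1:],
            groups=table.groups,
            response="transitions",
            phase="DARK",
        )
        with pytest.raises(ValueError, match="balanced"):
            mixed_anova(dropped)

    def test_single_dam_group_rejected(self):
        table = make_table(
            {"a": [1, 2], "b": [2, 1], "c": [3, 4]},
            {"a": "CTRL", "b": "CTRL", "c": "LBN"},
        )
        with pytest.raises(ValueError):
            mixed_anova(table)

    def test_power_under_default_presets(self, rng):
        """The dark-phase fragmentation contrast is detectable at the simulated
        effect size: housing power > 0.8 over simulated experiments."""
        from maternet.simulate import default_profiles, simulate_codes

        profiles = {
            "CTRL": default_profiles()[("CTRL", "DARK")],
            "LBN": default_profiles()[("LBN", "DARK")],
        }
        n_exp, n_per_group = 200, 9
        counts = {}
        for group, profile in profiles.items():
            per_day = []
            for ppd in range(2, 10):
                sims = simulate_codes(profile, ppd, n_exp * n_per_group, rng)
                per_day.append(
                    (np.diff(sims, axis=1) != 0).sum(axis=1).reshape(n_exp, n_per_group)
                )
            counts[group] = np.stack(per_day, axis=2)  # (exp, dam, day)
        dams = [f"c{i}" for i in range(n_per_group)] + [
            f"l{i}" for i in range(n_per_group)
        ]
        groups = pd.Series(["CTRL"] * n_per_group + ["LBN"] * n_per_group, index=dams)
        cols = pd.Index(range(2, 10), name="ppd")
        hits = 0
        for e in range(n_exp):
            stacked = np.vstack([counts["CTRL"][e], counts["LBN"][e]])
            table = ResponseTable(
                pd.DataFrame(stacked, index=pd.Index(dams, name="dam_id"), columns=cols),
                groups,
                "transitions",
                "DARK",
            )
            if mixed_anova(table)["housing"]["p"] < 0.05:
                hits += 1
        assert hits / n_exp > 0.8

    def test_null_type_one_error_calibrated(self, rng):
        """Housing rejections at alpha=0.05 near nominal under the null (quick check)."""
        hits = 0
        n_sim = 300
        for _ in range(n_sim):
            table = random_table(rng, n_per_group=5, n_days=4, shift=0.0)
            if mixed_anova(table)["housing"]["p"] < 0.05:
                hits += 1
        assert 0.02 <= hits / n_sim <= 0.09


class TestSidak:
    def test_adjustment_bounds_and_identity(self, rng):
        table = random_table(rng, shift=1.0)
        result = sidak_posthoc(table)
        assert np.all(result["p_adj"] >= result["p_raw"] - 1e-15)
        assert np.all((result["p_adj"] >= 0) & (result["p_adj"] <= 1))
        # Sidak formula on a p grid: monotone, fixed points at 0 and 1
        m = table.n_days
        grid = np.linspace(0, 1, 101)
        adj = 1 - (1 - grid) ** m
        assert adj[0] == 0.0 and adj[-1] == 1.0
        assert np.all(np.diff(adj) >= 0)
        assert np.all(adj >= grid)

    def test_monotone_in_raw_p(self, rng):
        table = random_table(rng, shift=0.7)
        result = sidak_posthoc(table).sort_values("p_raw")
        assert np.all(np.diff(result["p_adj"]) >= -1e-15)

    def test_detects_large_shift(self, rng):
        table = random_table(rng, n_per_group=8, shift=3.0)
        result = sidak_posthoc(table)
        assert (result["p_adj"] < 0.05).any()
        assert np.all(result["diff"] > 0)  # LBN - CTRL


class TestSummarize:
    def test_closed_form(self):
        table = make_table(
            {"a": [2.0], "b": [4.0], "c": [1.0], "d": [1.0]},
            {"a": "CTRL", "b": "CTRL", "c": "LBN", "d": "LBN"},
        )
        out = summarize(table).set_index(["group", "ppd"])
        assert out.at[("CTRL", 2), "mean"] == 3.0
        assert out.at[("CTRL", 2), "sem"] == 1.0
        assert out.at[("LBN", 2), "sem"] == 0.0

    def test_matches_textbook_formulas(self, rng):
        table = random_table(rng)
        out = summarize(table).set_index(["group", "ppd"])
        by_group = table.by_group()
        for group, frame in by_group.items():
            for ppd in frame.columns:
                vals = frame[ppd].to_numpy()
                assert out.at[(group, int(ppd)), "mean"] == pytest.approx(vals.mean())
                assert out.at[(group, int(ppd)), "sem"] == pytest.approx(
                    vals.std(ddof=1) / np.sqrt(len(vals))
                )
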