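import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pulmotile.statistics import (
    aggregate,
    correlate,
    dose_response,
    percent_change,
    stars,
)
from pulmotile.tiling import DensityIndexes


def idx(dm, hdfm=0.1, n_tiles=1000):
    return DensityIndexes(Dm=dm, HDFm=hdfm, threshold_class=12, n_tiles=n_tiles)


def study_table(rng, means, n=12, sd=0.01, control_mean=None):
    """Gaussian study table: control plus one group per entry of `means`."""
    rows = []
    cm = means[0] if control_mean is None else control_mean
    for g, (name, mu) in enumerate([("control", cm)] + [(f"d{i}", m) for i, m in enumerate(means[1:])]):
        for k in range(n):
            rows.append({"animal_id": f"{name}-{k}", "group": name,
                         "value": rng.normal(mu, sd)})
    return pd.DataFrame(rows)


class TestAggregate:
    def test_two_section_mean(self):
        out = aggregate([("m1", idx(0.30)), ("m1", idx(0.34))])
        assert out.loc[0, "Dm"] == pytest.approx(0.32)
        assert out.loc[0, "n_sections"] == 2

    def test_single_section_identity(self):
        out = aggregate([("m1", idx(0.27, hdfm=0.05))])
        assert out.loc[0, "Dm"] == 0.27 and out.loc[0, "HDFm"] == 0.05

    def test_matches_loop_oracle(self, rng):
        pairs = [(f"m{a}", idx(rng.random(), hdfm=rng.random()))
                 for a in range(3) for _ in range(3)]
        out = aggregate(pairs).set_index("animal_id")
        for animal in ("m0", "m1", "m2"):
            vals = [ix.Dm for aid, ix in pairs if aid == animal]
            assert out.loc[animal, "Dm"] == pytest.approx(sum(vals) / len(vals))

    def test_pooled_weights_by_tiles(self):
        pairs = [("m1", idx(0.2, n_tiles=100)), ("m1", idx(0.4, n_tiles=300))]
        out = aggregate(pairs, how="pool")
        assert out.loc[0, "Dm"] == pytest.approx(0.35)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate([])


class TestDoseResponse:
    def test_identical_groups_null(self, rng):
        table = study_table(rng, [0.25, 0.25, 0.25], n=12, sd=0.01)
        res = dose_response(table, "value")
        assert (res.contrasts["p"] > 0.2).all()
        assert (res.contrasts["stars"] == "").all()

    def test_overwhelming_effect_four_stars(self, rng):
        table = study_table(rng, [0.25, 0.40], n=12, sd=0.01)
        res = dose_response(table, "value")
        assert res.test == "anova+dunnett"
        p = res.contrasts.loc[0, "p"]
        assert p < 0.0001 and res.contrasts.loc[0, "stars"] == "****"
        # permutation oracle: shuffling labels essentially never reproduces the gap
        ctrl = table.loc[table.group == "control", "value"].to_numpy()
        trt = table.loc[table.group == "d0", "value"].to_numpy()
        observed = abs(trt.mean() - ctrl.mean())
        pooled = np.concatenate([ctrl, trt])
        perm_rng = np.random.default_rng(0)
        hits = 0
        for _ in range(2000):
            perm = perm_rng.permutation(pooled)
            hits += abs(perm[:12].mean() - perm[12:].mean()) >= observed
        assert (hits + 1) / 2001 < 0.01

    def test_constant_column_degenerate(self):
        table = pd.DataFrame({
            "group": ["control"] * 3 + ["d0"] * 3,
            "value": [0.3] * 6,
        })
        with pytest.warns(UserWarning, match="constant"):
            res = dose_response(table, "value")
        assert res.omnibus_p == 1.0 and (res.contrasts["p"] == 1.0).all()

    def test_nonparametric_dunn(self, rng):
        table = study_table(rng, [1.0, 1.0, 4.0], n=10, sd=0.5)
        res = dose_response(table, "value", parametric=False)
        assert res.test == "kruskal+dunn"
        assert res.contrasts.set_index("group").loc["d1", "p"] < 0.001
        assert res.contrasts.set_index("group").loc["d0", "p"] > 0.05

    def test_dunnett_p_at_least_unadjusted(self, rng):
        """Multiplicity-adjusted p-values can only exceed the pairwise ones."""
        table = study_table(rng, [0.25, 0.27, 0.29, 0.31], n=8, sd=0.03)
        res = dose_response(table, "value")
        ctrl = table.loc[table.group == "control", "value"].to_numpy()
        for _, row in res.contrasts.iterrows():
            grp = table.loc[table.group == row["group"], "value"].to_numpy()
            raw = sps.ttest_ind(grp, ctrl).pvalue
            assert row["p"] >= raw - 1e-12

    def test_dunn_p_at_least_unadjusted_z(self, rng):
        table = study_table(rng, [1.0, 1.5, 2.0], n=10, sd=0.8)
        res = dose_response(table, "value", parametric=False)
        sub = table[table.group.isin(["control", "d1"])]
        ranks = sps.rankdata(sub["value"])
        n_tot = len(sub)
        s2 = n_tot * (n_tot + 1) / 12.0
        mr = {g: ranks[(sub.group == g).to_numpy()].mean() for g in ("control", "d1")}
        z = (mr["d1"] - mr["control"]) / np.sqrt(s2 * (2 / 10))
        raw = 2 * sps.norm.sf(abs(z))
        assert res.contrasts.set_index("group").loc["d1", "p"] >= raw - 0.05

    def test_missing_control_rejected(self, rng):
        table = study_table(rng, [0.2, 0.3])
        with pytest.raises(ValueError, match="control"):
            dose_response(table, "value", control="saline")

    def test_small_group_rejected(self, rng):
        table = study_table(rng, [0.2, 0.3], n=12)
        table = table.drop(table[table.group == "d0"].index[1:])
        with pytest.raises(ValueError, match="fewer than 2"):
            dose_response(table, "value")

    def test_familywise_error_controlled_under_null(self, rng):
        """~5% of null studies show any Dunnett hit; Monte-Carlo bound 0.07."""
        n_studies, hits = 1000, 0
        for _ in range(n_studies):
            groups = [rng.normal(0.3, 0.02, 12) for _ in range(5)]
            res = sps.dunnett(*groups[1:], control=groups[0])
            hits += (res.pvalue < 0.05).any()
        assert hits / n_studies <= 0.07


class TestCorrelate:
    def test_perfect_monotone(self):
        df = pd.DataFrame({"x": np.arange(10.0), "y": np.arange(10.0) * 2 + 1})
        res = correlate(df, "x", "y")
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0) and res.intercept == pytest.approx(1.0)

    def test_perfect_antitone(self):
        df = pd.DataFrame({"x": np.arange(10.0), "y": -np.arange(10.0)})
        assert correlate(df, "x", "y").r == pytest.approx(-1.0)

    def test_matches_rank_formula_oracle(self):
        """r = 1 - 6*sum(d^2)/(n(n^2-1)) for tie-free data, to 1e-12."""
        rng = np.random.default_rng(7)
        n = 54
        x = rng.permutation(n).astype(float)
        y = rng.permutation(n).astype(float)
        res = correlate(pd.DataFrame({"x": x, "y": y}), "x", "y")
        d = sps.rankdata(x) - sps.rankdata(y)
        oracle = 1 - 6 * (d**2).sum() / (n * (n**2 - 1))
        assert res.r == pytest.approx(oracle, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.random(30)
        y = rng.random(30)
        df = pd.DataFrame({"x": x, "y": y, "ex": np.exp(5 * x), "ly": np.log(y + 1)})
        assert correlate(df, "x", "y").r == pytest.approx(correlate(df, "ex", "ly").r, abs=1e-12)

    def test_pairwise_missing_dropped(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, np.nan, 5], "y": [1.0, 2, np.nan, 4, 5]})
        assert correlate(df, "x", "y").n == 3

    def test_too_few_pairs_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2], "y": [3.0, 4]})
        with pytest.raises(ValueError, match="at least 3"):
            correlate(df, "x", "y")

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"x": [1.0, 1, 1, 1], "y": [1.0, 2, 3, 4]})
        with pytest.raises(ValueError, match="zero-variance"):
            correlate(df, "x", "y")


class TestPercentChangeAndStars:
    @pytest.mark.parametrize("control,treated,expected", [
        (0.25, 0.25, 0.0),
        (0.20, 0.28, 40.0),
        (0.04, 0.48, 1100.0),
    ])
    def test_percent_change(self, control, treated, expected):
        assert percent_change(control, treated) == pytest.approx(expected)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 0.5)

    @pytest.mark.parametrize("p,expected", [
        (0.2, ""), (0.049, "*"), (0.009, "**"), (0.0009, "***"), (0.00009, "****"),
    ])
    def test_star_encoding(self, p, expected):
        assert stars(p) == expected
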