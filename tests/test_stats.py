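"""Analysis stage: ratios, filtering, gamma GLMM, ratio LMM, comparisons."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h
from scipy import stats as sps

import ferncover as fc
from ferncover import stats as st
from ferncover import synthgen as sg


class TestTheoreticalArea:
    @pytest.mark.parametrize(
        "total,n,expected", [(10.0, 5, 2.5), (10.0, 20, 10.0), (8.0, 15, 6.0)]
    )
    def test_formula(self, total, n, expected):
        assert st.theoretical_area(total, n) == pytest.approx(expected)

    def test_fifteen_five_split_is_three_to_one(self):
        t15 = st.theoretical_area(12.0, 15)
        t5 = st.theoretical_area(12.0, 5)
        assert t15 / t5 == pytest.approx(3.0)

    @given(st_h.floats(0.1, 1e3), st_h.integers(1, 15))
    @settings(max_examples=50, deadline=None)
    def test_two_species_shares_sum_to_total(self, total, n1):
        assert st.theoretical_area(total, n1) + st.theoretical_area(
            total, 20 - n1
        ) == pytest.approx(total, rel=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            st.theoretical_area(10.0, 25)


def _ratio_frame(raw_by_n, species="A", plate=1):
    rows = []
    for i, (n, raw) in enumerate(raw_by_n):
        rows.append(
            {
                "plate_id": plate,
                "well": f"{i + 1}A",
                "species": species,
                "n_spores_of_species": n,
                "raw_ratio": raw,
            }
        )
    return pd.DataFrame(rows)


class TestStandardizeRatios:
    def test_mean_one_mixtures_already_centered(self):
        df = _ratio_frame([(5, 0.5), (10, 1.0), (15, 1.5)])
        out = st.standardize_ratios(df)
        assert out["standardized_ratio"].tolist() == pytest.approx([0.5, 1.0, 1.5])

    def test_division_by_mixture_mean(self):
        df = _ratio_frame([(5, 0.8), (10, 0.8), (15, 0.8), (20, 1.0)])
        out = st.standardize_ratios(df)
        assert out["standardized_ratio"].tolist() == pytest.approx(
            [1.0, 1.0, 1.0, 1.25]
        )

    def test_mixture_mean_exactly_one(self, cover_tables):
        _, week5 = cover_tables
        out = st.standardize_ratios(st.build_ratio_records(week5))
        mix = out[out["n_spores_of_species"] < 20]
        for _, grp in mix.groupby("species"):
            assert abs(grp["standardized_ratio"].mean() - 1.0) < 1e-12

    def test_no_mixtures_rejected(self):
        df = _ratio_frame([(20, 1.0)])
        with pytest.raises(ValueError, match="mixture"):
            st.standardize_ratios(df)


class TestBuildRatioRecords:
    def test_monoculture_raw_ratio_exactly_one(self, cover_tables):
        _, week5 = cover_tables
        out = st.build_ratio_records(week5)
        mono = out[out["n_spores_of_species"] == 20]
        assert len(mono) > 0
        assert (mono["raw_ratio"] == 1.0).all() or np.allclose(
            mono["raw_ratio"], 1.0, rtol=1e-14, atol=0
        )

    def test_monoculture_mean_variant_uses_per_spore_baseline(self, cover_tables):
        _, week5 = cover_tables
        out = st.build_ratio_records(week5, method="monoculture-mean")
        mono = out[out["n_spores_of_species"] == 20]
        # under this reading monocultures are no longer pinned at 1
        assert mono["raw_ratio"].std() > 0


class TestFilterWells:
    def test_mirrors_study_loss_rate(self, cover_tables):
        cover, _ = cover_tables
        filtered, report = st.filter_wells(cover)
        assert report["n_wells"] == 120
        assert report["n_excluded"] == 5
        assert report["percent_excluded"] == 4
        assert (filtered["n_spores_sown"] == 20).all()

    def test_no_deficient_is_identity(self, cover_tables):
        cover, _ = cover_tables
        complete = cover[cover["n_spores_sown"] == 20].reset_index(drop=True)
        filtered, report = st.filter_wells(complete)
        assert len(filtered) == len(complete)
        assert report["n_excluded"] == 0

    def test_all_deficient_warns_and_empties(self):
        df = pd.DataFrame(
            {"plate_id": [1, 1], "well": ["1A", "2A"], "n_spores_sown": [19, 18]}
        )
        with pytest.warns(UserWarning, match="all wells"):
            filtered, report = st.filter_wells(df)
        assert len(filtered) == 0 and report["percent_excluded"] == 100


def _simulate_glmm(rng, n_plates=10, n_per=12, effect=0.0, sigma=0.2, nu=8.0):
    plate = np.repeat(np.arange(n_plates), n_per)
    grp = np.tile(np.array([0, 1] * (n_per // 2)), n_plates)
    b = rng.normal(0, sigma, n_plates)[plate]
    y = rng.gamma(nu, np.exp(1.0 + effect * grp + b) / nu)
    X = np.column_stack([np.ones(len(plate)), grp.astype(float)])
    return y, X, plate


class TestGammaGLMM:
    def test_degenerate_variance_matches_plain_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        y, X, plate = _simulate_glmm(rng, sigma=0.0, effect=0.5)
        fit = st.fit_gamma_glmm(y, X, plate, fix_sigma=0.0)
        glm = sm.GLM(
            y, X, family=sm.families.Gamma(link=sm.families.links.Log())
        ).fit()
        assert np.max(np.abs(fit.beta - glm.params)) < 1e-3

    def test_positive_response_required(self):
        with pytest.raises(ValueError, match="positive"):
            st.fit_gamma_glmm(
                np.array([1.0, 0.0, 2.0]), np.ones((3, 1)), np.array([0, 0, 1])
            )

    def test_agrees_with_glmmtmb(self, tmp_path):
        """Independent oracle: glmmTMB (Laplace ML) on the same data."""
        rng = np.random.default_rng(42)
        y, X, plate = _simulate_glmm(rng, effect=0.6, sigma=0.3)
        fit = st.fit_gamma_glmm(y, X, plate)
        df = pd.DataFrame({"y": y, "g": X[:, 1].astype(int), "plate": plate})
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = (
            "suppressMessages(library(glmmTMB));"
            f"d <- read.csv('{csv}');"
            "m <- glmmTMB(y ~ g + (1|plate), data=d, family=Gamma(link='log'));"
            "cat(fixef(m)$cond, sqrt(unlist(VarCorr(m)$cond)), as.numeric(logLik(m)), sep=',')"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        vals = [float(v) for v in out.stdout.strip().splitlines()[-1].split(",")]
        b0, b1, sigma_r, ll_r = vals
        assert fit.beta[0] == pytest.approx(b0, abs=0.01)
        assert fit.beta[1] == pytest.approx(b1, abs=0.01)
        assert fit.sigma == pytest.approx(sigma_r, abs=0.02)
        # adaptive quadrature should not fall below the Laplace likelihood
        assert fit.loglik >= ll_r - 0.05

    def test_sequential_lrt_invariant_to_response_rescaling(self, cover_tables):
        cover, _ = cover_tables
        df = st.add_analysis_columns(cover)
        df = df[df["is_monoculture"] & (df["week"] <= 6)].reset_index(drop=True)
        res1, _ = st.fit_cover_glmm(df, ["week", "C(species_1)"])
        df2 = df.copy()
        df2["total_area_mm2"] *= 37.5
        res2, _ = st.fit_cover_glmm(df2, ["week", "C(species_1)"])
        for a, b in zip(res1, res2):
            assert a.chi_square == pytest.approx(b.chi_square, abs=0.02)

    def test_terms_tested_in_declared_order(self, cover_tables):
        cover, _ = cover_tables
        df = st.add_analysis_columns(cover)
        df = df[df["is_monoculture"] & (df["week"] <= 6)].reset_index(drop=True)
        res, fits = st.fit_cover_glmm(df, ["week", "C(species_1)"])
        assert [r.order for r in res] == [1, 2]
        assert [r.term for r in res] == ["week", "C(species_1)"]
        assert res[1].df == 2
        # nested fits gain likelihood monotonically
        lls = [f.loglik for f in fits]
        assert all(b >= a - 1e-6 for a, b in zip(lls, lls[1:]))


class TestRatioLMM:
    def test_two_groups_tukey_equals_unadjusted(self):
        rng = np.random.default_rng(3)
        rows = []
        for plate in range(8):
            for n, mu in ((5, 1.0), (15, 1.2)):
                for _ in range(2):
                    rows.append(
                        {
                            "plate_id": plate,
                            "species": "A",
                            "n_spores_of_species": n,
                            "standardized_ratio": rng.normal(mu, 0.1),
                        }
                    )
        df = pd.DataFrame(rows)
        res = st.fit_ratio_lmm(df, "A")
        (c,) = res.contrasts
        ddf = res.n_obs - 3
        p_t = 2 * sps.t.sf(abs(c.t_value), ddf)
        assert c.p_tukey == pytest.approx(p_t, rel=1e-6)

    def test_insufficient_groups_rejected(self):
        df = _ratio_frame([(5, 1.0), (5, 1.1)])
        df["standardized_ratio"] = df["raw_ratio"]
        with pytest.raises(ValueError, match="groups"):
            st.fit_ratio_lmm(df, "A")

    def test_null_simulations_hold_size(self):
        """With identical group means, each Tukey contrast stays above 0.05
        in at least 90% of null replicates."""
        rng = np.random.default_rng(17)
        keep = np.zeros(3)
        reps = 200
        for _ in range(reps):
            rows = []
            for plate in range(10):
                for n in (5, 10, 15):
                    rows.append(
                        {
                            "plate_id": plate,
                            "species": "A",
                            "n_spores_of_species": n,
                            "standardized_ratio": rng.normal(1.0, 0.15)
                            + rng.normal(0, 0.05),
                        }
                    )
            res = st.fit_ratio_lmm(pd.DataFrame(rows), "A")
            keep += np.array([c.p_tukey > 0.05 for c in res.contrasts])
        assert np.all(keep / reps >= 0.90)

    def test_power_against_shifted_group(self):
        """A 3-residual-SD shift in one group is detected almost always."""
        rng = np.random.default_rng(23)
        hits = 0
        reps = 200
        for _ in range(reps):
            rows = []
            for plate in range(5):
                for n, mu in ((5, 1.0), (10, 1.0), (15, 1.45)):
                    for _ in range(2):
                        rows.append(
                            {
                                "plate_id": plate,
                                "species": "A",
                                "n_spores_of_species": n,
                                "standardized_ratio": rng.normal(mu, 0.15),
                            }
                        )
            res = st.fit_ratio_lmm(pd.DataFrame(rows), "A")
            hits += res.p_value < 0.05
        assert hits / reps >= 0.95


class TestCompareMeasurers:
    def test_identical_vectors(self):
        out = st.compare_measurers([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["mean_ratio"] == 1.0
        assert out["mean_pct_difference"] == 0.0

    def test_constant_offset_recovered(self):
        b = np.linspace(1, 10, 30)
        out = st.compare_measurers(1.039 * b, b)
        assert out["mean_pct_difference"] == pytest.approx(3.9, abs=1e-9)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError, match="denominator"):
            st.compare_measurers([1.0], [0.0])


class TestPresets:
    def test_combinations_preset_term_structure(self, cover_tables):
        """All-wells analysis: categorical week (6 df), combination (11 df)
        and their interaction (66 df), entered sequentially."""
        cover, _ = cover_tables
        cover_f, _ = st.filter_wells(cover)
        res, _ = st.run_preset(cover_f, "combinations")
        assert [(r.term, r.df) for r in res] == [
            ("C(week)", 6),
            ("C(combination)", 11),
            ("C(week):C(combination)", 66),
        ]
        assert all(r.chi_square >= 0 and r.converged for r in res)
        # the generator builds in strong week and combination effects
        assert res[0].p_value < 1e-6 and res[1].p_value < 1e-6

    def test_monoculture_traits_preset(self, cover_tables):
        """Reproduction type and ploidy each enter with 1 df after week."""
        cover, _ = cover_tables
        cover_f, _ = st.filter_wells(cover)
        res, _ = st.run_preset(cover_f, "monoculture_traits")
        assert [r.df for r in res] == [1, 1, 1, 1, 1]
        # sexual reproduction and higher ploidy both raise cover by design
        assert res[1].p_value < 0.01 and res[2].p_value < 0.05

    def test_unknown_preset_rejected(self, cover_tables):
        cover, _ = cover_tables
        with pytest.raises(ValueError, match="unknown preset"):
            st.run_preset(cover, "nope")


def test_model_results_frame_schema(cover_tables):
    cover, _ = cover_tables
    df = st.add_analysis_columns(cover)
    df = df[df["is_monoculture"] & (df["week"] == 5)].reset_index(drop=True)
    res, _ = st.fit_cover_glmm(df, ["C(species_1)"])
    frame = st.model_results_to_frame(res)
    assert list(frame.columns) == ["order", "term", "chisq", "df", "p", "converged"]
    assert (frame["chisq"] >= 0).all()
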