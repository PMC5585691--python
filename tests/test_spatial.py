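import subprocess
import textwrap

import numpy as np
import pytest
from scipy.stats import binomtest, linregress

from gutlink.io import SITES, CountTable
from gutlink.simulate import SimulationConfig, simulate_spatial
from gutlink.spatial import (
    SiteProfile,
    _exact_nb_p,
    classify_breakpoint,
    classify_gradient,
    classify_specialist,
    classify_spatial_patterns,
    fit_breakpoint_model,
    fit_monotonic_trend,
    nb_exact_test,
    site_profiles,
)

OBS_SITES = [s for s in SITES for _ in range(3)]


def profile_from_site_means(means, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    vals = np.repeat(np.asarray(means, float), 3)
    if jitter:
        vals = vals + rng.normal(0, jitter, vals.size)
    return SiteProfile("x", list(OBS_SITES), vals)


class TestMonotonicTrend:
    def test_perfect_linear_ramp(self):
        prof = profile_from_site_means(np.linspace(0.01, 0.07, 7))
        fit = fit_monotonic_trend(prof, "ordinal")
        assert fit["slope"] > 0
        assert fit["p"] < 1e-10

    def test_constant_profile_flagged_degenerate(self):
        prof = profile_from_site_means(np.full(7, 0.02))
        fit = fit_monotonic_trend(prof, "ordinal")
        assert fit["degenerate"] and fit["p"] == 1.0 and fit["slope"] == 0.0

    def test_matches_independent_ols(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            prof = profile_from_site_means(rng.uniform(0, 0.1, 7), jitter=0.01,
                                           seed=int(rng.integers(1e6)))
            fit = fit_monotonic_trend(prof, "ordinal")
            ref = linregress(prof.positions("ordinal"), prof.abundance)
            assert fit["slope"] == pytest.approx(ref.slope, abs=1e-10)
            assert fit["p"] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_rectumward_rise_is_mga_under_both_conventions(self):
        prof = profile_from_site_means(np.linspace(0.01, 0.07, 7), jitter=1e-4)
        for conv in ("ordinal", "distance_cm"):
            fit = fit_monotonic_trend(prof, conv)
            assert classify_gradient(fit, 0.05) == "MGA", conv

    def test_rectumward_fall_is_mgd(self):
        prof = profile_from_site_means(np.linspace(0.07, 0.01, 7), jitter=1e-4)
        assert classify_gradient(fit_monotonic_trend(prof, "ordinal"), 0.05) == "MGD"


class TestBreakpoint:
    def test_v_shape_at_ac_is_gab(self):
        means = [0.06, 0.04, 0.02, 0.03, 0.04, 0.05, 0.06]  # trough at AC
        fit = fit_breakpoint_model(profile_from_site_means(means, 1e-4), "AC")
        assert fit["p_break"] < 1e-6
        assert fit["slope_left"] < 0 < fit["slope_right"]
        assert classify_breakpoint(fit, 0.05) == "GAB"

    def test_peak_is_gdb(self):
        means = [0.01, 0.03, 0.05, 0.04, 0.03, 0.02, 0.01]
        fit = fit_breakpoint_model(profile_from_site_means(means, 1e-4), "AC")
        assert classify_breakpoint(fit, 0.05) == "GDB"

    def test_exactly_straight_line_has_zero_hinge(self):
        fit = fit_breakpoint_model(
            profile_from_site_means(np.linspace(0.01, 0.07, 7)), "TC"
        )
        assert abs(fit["slope_right"] - fit["slope_left"]) < 1e-10
        assert fit["p_break"] == pytest.approx(1.0)

    def test_hinge_equals_segmentwise_slopes_on_noise_free_data(self):
        # continuous piecewise-linear profile: segments fitted separately
        # must agree with the hinge parametrization exactly
        bp = 3  # ordinal of AC
        x = np.arange(1, 8, dtype=float)
        y = 0.1 - 0.02 * x + 0.03 * np.maximum(0.0, x - bp)
        fit = fit_breakpoint_model(profile_from_site_means(y), "AC")
        left = np.polyfit(x[x <= bp], y[x <= bp], 1)[0]
        right = np.polyfit(x[x >= bp], y[x >= bp], 1)[0]
        assert fit["slope_left"] == pytest.approx(left, abs=1e-10)
        assert fit["slope_right"] == pytest.approx(right, abs=1e-10)

    def test_same_sign_segments_are_not_classified(self):
        fit = {"degenerate": False, "p_break": 0.001, "slope_left": 0.01,
               "slope_right": 0.03, "site": "AC"}
        assert classify_breakpoint(fit, 0.05) is None

    def test_noninterior_site_rejected(self):
        with pytest.raises(ValueError):
            fit_breakpoint_model(profile_from_site_means(np.ones(7)), "TI")


class TestNBExactTest:
    def test_poisson_limit_equals_conditional_binomial(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            s1, s2 = int(rng.integers(0, 51)), int(rng.integers(0, 51))
            if s1 + s2 == 0:
                continue
            p_nb = _exact_nb_p(s1, s2, 3, 18, 1e-8)
            p_bin = binomtest(s1, s1 + s2, 3 / 21).pvalue
            assert p_nb == pytest.approx(p_bin, abs=1e-3)

    def test_equal_means_large_counts_not_significant(self):
        assert _exact_nb_p(300, 1800, 3, 18, 0.2) > 0.5

    def test_all_zero_otu_gets_p_one(self):
        assert _exact_nb_p(0, 0, 3, 18, 0.2) == 1.0

    def test_recovers_enriched_otu_and_estimates_dispersion(self, biopsy_metadata):
        rng = np.random.default_rng(1)
        n_otus, phi = 30, 0.2
        mu = np.full((n_otus, 21), 400.0)
        mu[0, :3] *= 8.0  # 8-fold enrichment in the three TI samples
        r = 1 / phi
        counts = rng.negative_binomial(r, r / (r + mu))
        table = CountTable(
            counts, [f"O{i}" for i in range(n_otus)],
            list(biopsy_metadata.frame["sample_id"]),
        )
        res = nb_exact_test(table, biopsy_metadata, "TI")
        assert res.at["O0", "p"] < 0.01 and res.at["O0", "fdr"] < 0.05
        assert res.at["O0", "direction"] == 1
        assert res["dispersion"].iloc[0] == pytest.approx(phi, rel=0.5)

    def test_agrees_with_edger_oracle(self, tmp_path, biopsy_metadata):
        """Independent cross-check against the reference exact-test code in R."""
        cfg = SimulationConfig(n_taxa=25, seed=3)
        labels = ["HS@TI", "HA@TI", "MGA"] + ["flat"] * 22
        table, meta, _ = simulate_spatial(cfg, labels=labels)
        np.savetxt(tmp_path / "counts.tsv", table.values, delimiter="\t", fmt="%d")
        layout = meta.biopsy_layout()
        groups = ["TI" if layout.at[s, "site"] == "TI" else "other"
                  for s in table.sample_ids]
        (tmp_path / "groups.txt").write_text("\n".join(groups) + "\n")
        script = textwrap.dedent(
            """
            suppressMessages(library(edgeR))
            args <- commandArgs(trailingOnly=TRUE)
            counts <- as.matrix(read.table(args[1], sep="\\t"))
            groups <- factor(readLines(args[2]), levels=c("other","TI"))
            y <- estimateCommonDisp(DGEList(counts=counts, group=groups))
            et <- exactTest(y, pair=c("other","TI"))
            write.table(data.frame(p=et$table$PValue, disp=y$common.dispersion),
                        args[3], sep="\\t", quote=FALSE, row.names=FALSE)
            """
        )
        (tmp_path / "et.R").write_text(script)
        subprocess.run(
            ["Rscript", str(tmp_path / "et.R"), str(tmp_path / "counts.tsv"),
             str(tmp_path / "groups.txt"), str(tmp_path / "out.tsv")],
            check=True, capture_output=True,
        )
        import pandas as pd

        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        res = nb_exact_test(table, meta, "TI")
        assert res["dispersion"].iloc[0] == pytest.approx(ref["disp"][0], rel=0.02)
        from scipy.stats import spearmanr

        assert spearmanr(res["p"], ref["p"]).statistic > 0.95
        # calls may differ only where both implementations sit at the
        # significance boundary (their two-sided tail conventions differ)
        ours = res["p"].to_numpy()
        theirs = ref["p"].to_numpy()
        disagree = (ours < 0.01) != (theirs < 0.01)
        assert (ours[disagree] < 0.05).all() and (theirs[disagree] < 0.05).all()
        assert (ours[disagree] > 0.002).all() and (theirs[disagree] > 0.002).all()


class TestSpecialistClassification:
    def _frame(self, p, fdr, direction):
        import pandas as pd

        return pd.DataFrame(
            {"p": [p], "fdr": [fdr], "direction": [direction]}, index=["O1"]
        )

    def test_enriched_passing_both_thresholds_is_hs(self):
        assert classify_specialist(self._frame(0.001, 0.01, 1))["O1"] == "HS"

    def test_depleted_passing_both_is_ha(self):
        assert classify_specialist(self._frame(0.001, 0.01, -1))["O1"] == "HA"

    def test_joint_threshold_required(self):
        calls = classify_specialist(self._frame(0.005, 0.2, 1))
        assert calls.isna().all()


class TestOrchestrator:
    def test_multiple_categories_per_otu_allowed(self, biopsy_metadata):
        # an OTU that both descends monotonically and spikes at TI can be
        # MGD and HS simultaneously
        rng = np.random.default_rng(2)
        n = 25
        mu = np.full((n, 21), 300.0)
        ramp = np.repeat(np.linspace(8, 1, 7), 3)
        mu[0] = 300.0 * ramp
        r = 1 / 0.05
        counts = rng.negative_binomial(r, r / (r + mu))
        table = CountTable(
            counts, [f"O{i}" for i in range(n)],
            list(biopsy_metadata.frame["sample_id"]),
        )
        calls = classify_spatial_patterns(
            table, biopsy_metadata, specialist_sites=("TI",)
        )
        cats = set(calls.loc[calls.otu_id == "O0", "category"])
        assert "MGD" in cats and "HS" in cats


def test_site_profiles_are_relative_abundances(biopsy_metadata):
    rng = np.random.default_rng(0)
    table = CountTable(
        rng.integers(1, 100, size=(5, 21)),
        [f"O{i}" for i in range(5)],
        list(biopsy_metadata.frame["sample_id"]),
    )
    profs = site_profiles(table, biopsy_metadata)
    total = np.zeros(21)
    for p in profs:
        total += p.abundance
    np.testing.assert_allclose(total, 1.0)
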