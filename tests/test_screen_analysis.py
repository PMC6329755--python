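"""Screen quantification: counting, normalization, moderated t, gene level."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist

from splicetox import screen_analysis as sa
from splicetox.synthetic_data import PlantedEffect, SimScreenConfig, simulate_screen


# ---------------------------------------------------------------------------
# barcode counting
# ---------------------------------------------------------------------------


def _fastq_bytes(seqs):
    return io.StringIO("".join(f"@r{i}\n{s}\n+\n{'I' * len(s)}\n" for i, s in enumerate(seqs)))


class TestCountBarcodes:
    def test_empty_stream_gives_zero_table(self, tiny_library):
        counts, stats = sa.count_barcodes([], tiny_library)
        assert (counts == 0).all()
        assert stats == {"assigned": 0, "unassigned": 0, "too_short": 0, "ambiguous": 0}

    def test_counts_match_brute_force(self, tiny_library):
        # reads carrying AAAA twice and CCCC once; GGGG never seen but zero-filled
        reads = ["AAAA", "AAAA", "CCCC", "TTTT"]
        counts, stats = sa.count_barcodes(reads, tiny_library)
        brute = {bc: sum(r[:4] == bc for r in reads) for bc in tiny_library.table["barcode"]}
        assert counts.to_dict() == brute
        assert stats["unassigned"] == 1

    def test_fastq_parsing_with_offset(self, tiny_library):
        reads = _fastq_bytes(["TTAAAAGG", "TTCCCCGG"])
        counts, _ = sa.count_barcodes(reads, tiny_library, offset=2)
        assert counts["AAAA"] == 1 and counts["CCCC"] == 1

    def test_hamming1_rescue_and_ambiguity(self):
        lib = sa.BarcodeLibrary(
            pd.DataFrame(
                {
                    "barcode": ["AAAAA", "AAAAT", "GGGGG"],
                    "shRNA_id": ["sh1", "sh2", "sh3"],
                    "gene": ["G1", "G1", "G2"],
                }
            )
        )
        # GGGGC is uniquely Hamming-1 from GGGGG; AAAAC is distance 1 from
        # both AAAAA and AAAAT -> ambiguous, discarded
        counts, stats = sa.count_barcodes(["GGGGC", "AAAAC"], lib, max_mismatch=1)
        assert counts["GGGGG"] == 1
        assert stats["ambiguous"] == 1
        counts0, stats0 = sa.count_barcodes(["GGGGC"], lib, max_mismatch=0)
        assert counts0["GGGGG"] == 0 and stats0["unassigned"] == 1

    def test_short_reads_skipped(self, tiny_library):
        counts, stats = sa.count_barcodes(["AA"], tiny_library)
        assert stats["too_short"] == 1 and counts.sum() == 0

    def test_duplicate_barcodes_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            sa.BarcodeLibrary(
                pd.DataFrame(
                    {"barcode": ["AAAA", "AAAA"], "shRNA_id": ["a", "b"], "gene": ["G", "G"]}
                )
            )

    def test_paper_scale_library_has_6500_rows(self):
        counts, library, _ = simulate_screen(SimScreenConfig(seed=0))
        assert len(counts) == 6500
        assert library.table["gene"].nunique() == 841


# ---------------------------------------------------------------------------
# CPTM normalization and log ratios
# ---------------------------------------------------------------------------


class TestCptm:
    def test_formula_forced(self):
        df = pd.DataFrame({"barcode": ["A", "B"], "s": [50, 10**6 - 50]})
        norm = sa.cptm_normalize(df, ["s"])
        assert norm["s"].iloc[0] == pytest.approx(50.0)

    def test_uniform_counts_symmetry(self):
        m = 8
        df = pd.DataFrame({"barcode": list("ABCDEFGH"), "s": [7] * m})
        norm = sa.cptm_normalize(df, ["s"])
        assert np.allclose(norm["s"], 1e6 / m)

    def test_conservation_on_random_fixture(self, rng):
        df = pd.DataFrame({"s1": rng.integers(0, 1000, 500), "s2": rng.integers(0, 1000, 500)})
        norm = sa.cptm_normalize(df, ["s1", "s2"])
        assert norm["s1"].sum() == pytest.approx(1e6, abs=1e-6)
        assert norm["s2"].sum() == pytest.approx(1e6, abs=1e-6)

    def test_all_zero_sample_names_the_sample(self):
        df = pd.DataFrame({"bad_sample": [0, 0, 0]})
        with pytest.raises(ValueError, match="bad_sample"):
            sa.cptm_normalize(df, ["bad_sample"])


class TestLogRatios:
    def test_identical_columns_give_zero(self):
        df = pd.DataFrame({"t": [10.0, 20.0], "d": [10.0, 20.0]})
        out = sa.screen_log_ratios(df, [("t", "d")])
        assert np.allclose(out["ratio_1"], 0.0)

    def test_direct_arithmetic(self):
        df = pd.DataFrame({"t": [300.0], "d": [75.0]})
        out = sa.screen_log_ratios(df, [("t", "d")])
        assert out["ratio_1"].iloc[0] == pytest.approx(np.log2(301 / 76))

    def test_unpaired_sample_errors(self):
        df = pd.DataFrame({"t": [1.0]})
        with pytest.raises(ValueError, match="unpaired"):
            sa.screen_log_ratios(df, [("t", "missing")])

    def test_planted_effect_recovered_in_median(self):
        cfg = SimScreenConfig(
            n_genes=50,
            total_barcodes=None,
            seed=11,
            sensitizer_genes=[PlantedEffect("GENE0003", -2.0)],
        )
        counts, _, truth = simulate_screen(cfg)
        norm = sa.cptm_normalize(counts)
        ratios = sa.screen_log_ratios(norm, [tuple(p) for p in truth["pairing"]])
        planted = ratios[ratios["gene"] == "GENE0003"]
        med = planted[["ratio_1", "ratio_2"]].to_numpy().flatten()
        assert np.median(med) == pytest.approx(-2.0, abs=0.4)


# ---------------------------------------------------------------------------
# moderated t: brute-force oracle
# ---------------------------------------------------------------------------


def _reference_moderated_t(data: np.ndarray):
    """Step-by-step reference of the moment-matched moderated t.

    Independent of the package implementation: solves the trigamma
    equation with Brent's method and computes every quantity explicitly.
    """
    n = data.shape[1]
    mean = data.mean(axis=1)
    s2 = data.var(axis=1, ddof=1)
    dg = n - 1
    e = np.log(s2) - digamma(dg / 2) + np.log(dg / 2)
    target = e.var(ddof=1) - polygamma(1, dg / 2)
    if target <= polygamma(1, 1e6 / 2):
        d0 = np.inf
        s0_2 = np.exp(e.mean())
    else:
        d0 = brentq(lambda d: polygamma(1, d / 2) - target, 0.1, 1e6, xtol=1e-12)
        s0_2 = np.exp(e.mean() + digamma(d0 / 2) - np.log(d0 / 2))
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
    else:
        s2_post = (d0 * s0_2 + dg * s2) / (d0 + dg)
    t = mean / np.sqrt(s2_post / n)
    p = 2 * t_dist.sf(np.abs(t), d0 + dg)
    return d0, s0_2, t, p


class TestModeratedT:
    def test_matches_independent_reference_to_6_decimals(self, rng):
        # heterogeneous variances so the prior df is finite and shrinkage real
        sd = np.exp(rng.normal(-1, 0.6, size=200))
        data = rng.normal(0, sd[:, None], size=(200, 3))
        df = pd.DataFrame(data, columns=["ratio_1", "ratio_2", "ratio_3"])
        res = sa.moderated_t_test(df)
        d0, s0_2, t_ref, p_ref = _reference_moderated_t(data)
        prior = res.attrs["prior"]
        assert prior.df_prior == pytest.approx(d0, abs=1e-6)
        assert prior.var_prior == pytest.approx(s0_2, rel=1e-6)
        np.testing.assert_allclose(res["t"].to_numpy(), t_ref, atol=1e-6)
        np.testing.assert_allclose(res["p"].to_numpy(), p_ref, atol=1e-6)

    def test_zero_prior_df_recovers_ordinary_t(self, rng):
        data = rng.normal(0, 1, size=(50, 4))
        df = pd.DataFrame(data, columns=[f"ratio_{i}" for i in range(1, 5)])
        res = sa.moderated_t_test(df, prior_df=0)
        t_ord = data.mean(axis=1) / np.sqrt(data.var(axis=1, ddof=1) / 4)
        np.testing.assert_allclose(res["t"].to_numpy(), t_ord, atol=1e-10)

    def test_posterior_variance_between_sample_and_prior(self, rng):
        sd = np.exp(rng.normal(0, 0.8, size=100))
        data = rng.normal(0, sd[:, None], size=(100, 2))
        res = sa.moderated_t_test(pd.DataFrame(data, columns=["ratio_1", "ratio_2"]))
        prior = res.attrs["prior"]
        lo = np.minimum(res["s2"], prior.var_prior)
        hi = np.maximum(res["s2"], prior.var_prior)
        assert ((res["s2_post"] >= lo - 1e-12) & (res["s2_post"] <= hi + 1e-12)).all()

    def test_scale_equivariance_of_t(self, rng):
        data = rng.normal(0.2, np.exp(rng.normal(0, 0.5, 80))[:, None], size=(80, 3))
        cols = ["ratio_1", "ratio_2", "ratio_3"]
        res1 = sa.moderated_t_test(pd.DataFrame(data, columns=cols))
        res2 = sa.moderated_t_test(pd.DataFrame(data * 7.5, columns=cols))
        np.testing.assert_allclose(res1["t"], res2["t"], rtol=1e-8)

    def test_bh_monotone_in_raw_p_order(self, rng):
        data = rng.normal(0, 1, size=(300, 2))
        res = sa.moderated_t_test(pd.DataFrame(data, columns=["ratio_1", "ratio_2"]))
        order = np.argsort(res["p"].to_numpy())
        adj = res["adj_p"].to_numpy()[order]
        assert (np.diff(adj) >= -1e-12).all()
        assert (res["adj_p"] >= res["p"] - 1e-12).all()
        assert res["adj_p"].between(0, 1).all()

    def test_single_feature_errors(self):
        with pytest.raises(ValueError, match="moderate"):
            sa.moderated_t_test(pd.DataFrame({"ratio_1": [1.0], "ratio_2": [1.0]}))

    def test_zero_variance_ensemble_falls_back_with_warning(self):
        df = pd.DataFrame({"ratio_1": [1.0, 2.0], "ratio_2": [1.0, 2.0]})
        with pytest.warns(RuntimeWarning, match="ordinary t"):
            res = sa.moderated_t_test(df)
        assert np.isinf(res["t"]).all()


# ---------------------------------------------------------------------------
# gene level + GFP validation
# ---------------------------------------------------------------------------


class TestGeneAggregate:
    def test_mean_of_member_shrnas(self):
        res = pd.DataFrame({"gene": ["G1"] * 3, "logFC": [-1.0, -2.0, -3.0]})
        out = sa.gene_aggregate(res)
        assert out["mean_logFC"].iloc[0] == pytest.approx(-2.0)
        assert out["n_shRNAs"].iloc[0] == 3

    def test_rank_deterministic_with_ties(self):
        res = pd.DataFrame({"gene": ["B", "A", "C"], "logFC": [-1.0, -1.0, 0.0]})
        out = sa.gene_aggregate(res)
        assert list(out["gene"]) == ["A", "B", "C"]
        assert list(out["rank"]) == [1, 2, 3]

    def test_planted_sensitizer_ranks_first(self):
        wins = 0
        for seed in range(25):
            cfg = SimScreenConfig(
                n_genes=60,
                total_barcodes=None,
                seed=seed,
                sensitizer_genes=[PlantedEffect("GENE0030", -2.0)],
            )
            counts, _, truth = simulate_screen(cfg)
            norm = sa.cptm_normalize(counts)
            ratios = sa.screen_log_ratios(norm, [tuple(p) for p in truth["pairing"]])
            res = sa.moderated_t_test(ratios)
            genes = sa.gene_aggregate(res)
            wins += genes["gene"].iloc[0] == "GENE0030"
        assert wins >= 24  # >= 95% of seeds

    def test_all_null_extreme_gene_near_zero(self):
        cfg = SimScreenConfig(n_genes=60, total_barcodes=None, seed=5)
        counts, _, truth = simulate_screen(cfg)
        norm = sa.cptm_normalize(counts)
        ratios = sa.screen_log_ratios(norm, [tuple(p) for p in truth["pairing"]])
        res = sa.moderated_t_test(ratios)
        genes = sa.gene_aggregate(res)
        # SE of a gene mean: shRNA ratio sd / sqrt(8 shRNAs * 2 reps)
        sd = res["logFC"].std()
        assert np.abs(genes["mean_logFC"]).max() <= 3 * sd


class TestGfpDepletion:
    def test_identical_arms_not_significant(self):
        p, sig = sa.gfp_depletion_test([50.0, 50.0], [50.0, 50.0])
        assert p == 1.0 and not sig

    def test_clear_depletion_significant(self):
        p, sig = sa.gfp_depletion_test([50.0, 50.1], [25.0, 24.9])
        assert p < 0.05 and sig

    def test_no_depletion_control_flagged_ns(self, rng):
        # luciferase-like hairpin: both arms hover at the infection rate
        dmso = 48 + rng.normal(0, 1.5, 3)
        drug = 48 + rng.normal(0, 1.5, 3)
        p, sig = sa.gfp_depletion_test(dmso, drug)
        assert not sig


# ---------------------------------------------------------------------------
# end-to-end recovery through FASTQ
# ---------------------------------------------------------------------------


def test_fastq_round_trip_recovers_planted_gene(tmp_path):
    from splicetox.synthetic_data import write_screen_fastq

    cfg = SimScreenConfig(
        n_genes=30,
        total_barcodes=None,
        library_size_per_sample=60_000,
        seed=3,
        sensitizer_genes=[PlantedEffect("GENE0010", -2.5)],
    )
    counts, library, truth = simulate_screen(cfg)
    sample_cols = [c for c in counts.columns if c.startswith(("vehicle_", "treated_"))]
    paths = {}
    for col in sample_cols:
        path = tmp_path / f"{col}.fastq"
        write_screen_fastq(counts, col, path, seed=cfg.seed)
        paths[col] = str(path)
    recounted, _ = sa.count_barcode_samples(paths, library, offset=4)
    for col in sample_cols:  # lossless round trip
        np.testing.assert_array_equal(recounted[col].to_numpy(), counts[col].to_numpy())
    norm = sa.cptm_normalize(recounted, sample_cols)
    ratios = sa.screen_log_ratios(norm, [tuple(p) for p in truth["pairing"]])
    res = sa.moderated_t_test(ratios)
    hits = sa.call_gene_hits(res)
    called = set(hits.loc[hits["hit"], "gene"])
    planted = set(truth["planted_genes"])
    assert planted <= called  # sensitivity 1.0 on the planted set
    fdr = len(called - planted) / max(len(called), 1)
    assert fdr <= 0.1
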