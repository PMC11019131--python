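"""PWM parsing, scanning against a naive oracle, threshold calibration, FE_adj."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from agesplit import tfbs
from agesplit.synthetic import PromoterSet

UNIFORM_BG = np.full(4, 0.25)


def naive_site_counts(pwm, sequences, threshold, background):
    """Brute-force per-position rescoring on both strands."""
    loms = [pwm.log_odds(background), pwm.reverse_complement().log_odds(background)]
    out = {}
    for gene, seq in sequences.items():
        n = 0
        for lom in loms:
            for i in range(len(seq) - pwm.width + 1):
                score = 0.0
                for j, ch in enumerate(seq[i:i + pwm.width]):
                    if ch not in "ACGT":
                        score = -np.inf
                        break
                    score += lom[j, "ACGT".index(ch)]
                if score >= threshold:
                    n += 1
        out[gene] = n
    return out


class TestTransfacIO:
    def test_parse_counts_block(self, tmp_path):
        path = tmp_path / "pwm.txt"
        path.write_text(
            "AC  M00001\nXX\nID  M00001\nXX\nDE  ZFP64\nXX\n"
            "P0      A      C      G      T\n"
            "01      10      0      0      0\n"
            "02      0      10      0      0\n"
            "03      0      0      10      0\n"
            "04      0      0      0      10\nXX\n//\n"
        )
        pwms = tfbs.read_transfac(path)
        assert len(pwms) == 1
        p = pwms["M00001"]
        assert p.tf_name == "ZFP64"
        assert p.width == 4
        assert np.allclose(p.probs.sum(axis=1), 1.0)
        assert p.consensus() == "ACGT"

    def test_roundtrip_preserves_matrices(self, tmp_path):
        rng = np.random.default_rng(0)
        pwms = tfbs.PWMSet(
            [tfbs.random_pwm(f"M{i}", f"TF{i}", 8, rng) for i in range(3)]
        )
        tfbs.write_transfac(pwms, tmp_path / "set.txt")
        back = tfbs.read_transfac(tmp_path / "set.txt")
        assert len(back) == 3
        for p in pwms:
            q = back[p.matrix_id]
            assert q.tf_name == p.tf_name
            assert np.allclose(q.counts, p.counts, atol=1e-9)

    def test_duplicate_ids_rejected(self):
        p = tfbs.consensus_pwm("M1", "TF1", "ACGT")
        with pytest.raises(ValueError, match="duplicate"):
            tfbs.PWMSet([p, p])

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError, match="width"):
            tfbs.PWM("M", "T", np.ones((3, 4)))
        bad = np.ones((5, 4))
        bad[2] = 0.0
        with pytest.raises(ValueError, match="all-zero"):
            tfbs.PWM("M", "T", bad)


class TestScanning:
    def test_consensus_forward_match(self):
        pwm = tfbs.consensus_pwm("M", "T", "ACGG", strength=1000)
        thr = pwm.max_score(UNIFORM_BG) - 1e-9
        prom = PromoterSet({"g": "AACGGT"})
        res = tfbs.scan_promoters(pwm, prom, thr, UNIFORM_BG)
        assert res.loc["g", "fwd_sites"] == 1
        assert res.loc["g", "sites"] == 1

    def test_palindromic_consensus_counted_on_both_strands(self):
        pwm = tfbs.consensus_pwm("M", "T", "ACGT", strength=1000)
        thr = pwm.max_score(UNIFORM_BG) - 1e-9
        res = tfbs.scan_promoters(pwm, PromoterSet({"g": "AACGTT"}), thr,
                                  UNIFORM_BG)
        assert res.loc["g", "fwd_sites"] == 1
        assert res.loc["g", "rev_sites"] == 1

    def test_minus_strand_detection(self):
        pwm = tfbs.consensus_pwm("M", "T", "ACCCGT", strength=1000)
        # reverse complement of ACCCGT is ACGGGT
        prom = PromoterSet({"g": "TTACGGGTTT"})
        thr = pwm.max_score(UNIFORM_BG) - 1e-9
        res = tfbs.scan_promoters(pwm, prom, thr, UNIFORM_BG)
        assert res.loc["g", "rev_sites"] == 1
        assert res.loc["g", "fwd_sites"] == 0

    def test_n_bases_yield_no_sites(self):
        pwm = tfbs.consensus_pwm("M", "T", "ACGT")
        prom = PromoterSet({"g": "N" * 50})
        res = tfbs.scan_promoters(pwm, prom, -100.0, UNIFORM_BG)
        assert res.loc["g", "sites"] == 0

    def test_sequence_shorter_than_pwm(self):
        pwm = tfbs.consensus_pwm("M", "T", "ACGTACGT")
        res = tfbs.scan_promoters(pwm, PromoterSet({"g": "ACG"}), -10.0, UNIFORM_BG)
        assert res.loc["g", "sites"] == 0
        assert res.loc["g", "scanned_positions"] == 0

    def test_matches_naive_oracle_on_random_set(self):
        rng = np.random.default_rng(1)
        seqs = {
            f"g{i}": "".join(rng.choice(list("ACGT"), 300))
            for i in range(30)
        }
        seqs["g0"] = seqs["g0"][:100] + "NNNN" + seqs["g0"][104:]
        prom = PromoterSet(seqs)
        pwm = tfbs.random_pwm("M", "T", 7, rng)
        bg = tfbs.background_composition(prom)
        scores = tfbs._all_scores(pwm, prom, bg)
        thr = float(np.quantile(scores[np.isfinite(scores)], 0.999))
        fast = tfbs.scan_promoters(pwm, prom, thr, bg)["sites"].to_dict()
        assert fast == naive_site_counts(pwm, seqs, thr, bg)


class TestCalibration:
    def _pool(self, n=200, length=1000, seed=0):
        rng = np.random.default_rng(seed)
        return PromoterSet(
            {f"b{i}": "".join(rng.choice(list("ACGT"), length)) for i in range(n)},
            role="background_pool",
        )

    def test_background_frequency_under_cap(self):
        pool = self._pool()
        pwm = tfbs.consensus_pwm("M", "T", "TGACGTCA", strength=50)
        bg = tfbs.background_composition(pool)
        thr = tfbs.calibrate_threshold(pwm, pool, bg)
        assert thr <= pwm.max_score(bg)
        res = tfbs.scan_promoters(pwm, pool, thr, bg)
        freq = res["sites"].sum() / res["scanned_positions"].sum()
        assert freq <= 1.0 / 2000.0

    def test_uniform_pwm_unscannable(self):
        """An information-free PWM scores every position identically, so no
        threshold can bring the site frequency under the cap."""
        pool = self._pool(50)
        pwm = tfbs.PWM("M", "T", np.full((6, 4), 25.0))
        with pytest.raises(tfbs.UnscannablePWM):
            tfbs.calibrate_threshold(pwm, pool, UNIFORM_BG)

    def test_threshold_is_minimal_over_observed_scores(self):
        """Chosen threshold equals the exhaustive sweep over the score set."""
        pool = self._pool(60, 500, seed=2)
        pwm = tfbs.random_pwm("M", "T", 8, np.random.default_rng(3))
        bg = tfbs.background_composition(pool)
        thr = tfbs.calibrate_threshold(pwm, pool, bg)
        scores = tfbs._all_scores(pwm, pool, bg)
        scores = scores[np.isfinite(scores)]
        cap = int(np.floor(scores.size / 2000.0))
        candidates = [
            t for t in np.unique(scores) if np.sum(scores >= t) <= cap
        ]
        assert thr == pytest.approx(min(candidates), abs=0.0)

    def test_small_pool_rejected(self):
        pool = PromoterSet({"b": "ACGT" * 100})
        pwm = tfbs.consensus_pwm("M", "T", "ACGTAC")
        with pytest.raises(ValueError, match="too small"):
            tfbs.calibrate_threshold(pwm, pool, UNIFORM_BG)


class TestBackgroundSampling:
    def test_pool_of_exactly_n_returned_whole(self):
        pool = PromoterSet({f"g{i}": "ACGT" * 10 for i in range(100)})
        out = tfbs.sample_background(pool, 100, seed=1)
        assert set(out.sequences) == set(pool.sequences)

    def test_seed_reproducible_and_subset(self):
        pool = PromoterSet({f"g{i}": "ACGT" * 10 for i in range(500)})
        s1 = tfbs.sample_background(pool, 50, seed=7)
        s2 = tfbs.sample_background(pool, 50, seed=7)
        assert list(s1.sequences) == list(s2.sequences)
        assert set(s1.sequences) <= set(pool.sequences)
        assert len(s1) == 50

    def test_short_pool_warns_and_returns_all(self):
        pool = PromoterSet({f"g{i}": "ACGT" for i in range(5)})
        with pytest.warns(UserWarning, match="background pool"):
            out = tfbs.sample_background(pool, 10, seed=0)
        assert len(out) == 5

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tfbs.sample_background(PromoterSet({}), 10, seed=0)


class TestEnrichmentStats:
    def test_equal_rates_give_unit_or_and_subunit_feadj(self):
        rec = tfbs.compute_enrichment("M", "T", 50, 10_000, 500, 100_000,
                                      30, 100, 300, 1000)
        assert rec["or_freq"] == pytest.approx(1.0, rel=1e-6)
        assert rec["FE_adj_freq"] < 1.0

    def test_promoter_table_woolf_lower_bound(self):
        """30/100 vs 500/5000 promoters: OR 3.857, 99% lower bound 2.17."""
        rec = tfbs.compute_enrichment("M", "T", 0, 1000, 0, 1000,
                                      30, 100, 500, 5000)
        assert rec["or_prom"] == pytest.approx(3.857, abs=0.001)
        se = np.sqrt(1 / 30 + 1 / 70 + 1 / 500 + 1 / 4500)
        expected = np.exp(np.log(rec["or_prom"]) - 2.5758293 * se)
        assert rec["FE_adj_prom"] == pytest.approx(expected, rel=1e-6)
        assert rec["FE_adj_prom"] == pytest.approx(2.17, abs=0.01)

    def test_fisher_five_vs_five(self):
        rec = tfbs.compute_enrichment("M", "T", 0, 100, 0, 100, 5, 5, 0, 5)
        assert rec["fisher_p"] == pytest.approx(1.0 / comb(10, 5), rel=1e-12)

    def test_feadj_below_raw_or_and_converges(self):
        """The corrected bound stays under the raw OR and approaches it as
        the table scales up."""
        gaps = []
        for scale in (1, 10, 100):
            rec = tfbs.compute_enrichment(
                "M", "T", 30 * scale, 10_000 * scale, 100 * scale,
                100_000 * scale, 20 * scale, 50 * scale, 100 * scale,
                1000 * scale,
            )
            assert rec["FE_adj_freq"] < rec["or_freq"]
            gaps.append(rec["or_freq"] - rec["FE_adj_freq"])
        assert gaps[0] > gaps[1] > gaps[2]

    def test_zero_background_bp_rejected(self):
        with pytest.raises(ValueError, match="background bp"):
            tfbs.compute_enrichment("M", "T", 1, 10, 0, 0, 1, 5, 0, 5)


class TestCollapseAndFilter:
    def _records(self):
        base = dict(fg_sites=10, fg_bp=1000, bg_sites=50, bg_bp=100_000,
                    fg_promoters_with_site=5, fg_promoters=10,
                    bg_promoters_with_site=50, bg_promoters=1000)
        return pd.DataFrame([
            {"matrix_id": "M1", "tf_name": "TFA", "FE_adj_freq": 2.1,
             "FE_adj_prom": 1.5, "binom_p": 1e-6, "fisher_p": 1e-4, **base},
            {"matrix_id": "M2", "tf_name": "TFA", "FE_adj_freq": 3.0,
             "FE_adj_prom": 1.8, "binom_p": 1e-8, "fisher_p": 1e-5, **base},
            {"matrix_id": "M3", "tf_name": "TFB", "FE_adj_freq": 0.5,
             "FE_adj_prom": 0.4, "binom_p": 0.9, "fisher_p": 0.8, **base},
        ])

    def test_most_enriched_pwm_kept_per_tf(self):
        out = tfbs.collapse_and_filter(self._records())
        tfa = out[out["tf_name"] == "TFA"]
        assert len(tfa) == 1
        assert tfa["matrix_id"].iloc[0] == "M2"

    def test_unexpressed_tf_dropped(self):
        tpm = pd.Series({"TFA": 0.5, "TFB": 10.0})
        out = tfbs.collapse_and_filter(self._records(), tpm)
        assert "TFA" not in set(out["tf_name"])
        assert "TFB" in set(out["tf_name"])

    def test_missing_tf_dropped_with_warning(self):
        tpm = pd.Series({"TFA": 10.0})
        with pytest.warns(UserWarning, match="missing from expression"):
            out = tfbs.collapse_and_filter(self._records(), tpm)
        assert set(out["tf_name"]) == {"TFA"}

    def test_tie_broken_by_fisher_then_id(self):
        rec = self._records()
        rec.loc[rec["matrix_id"] == "M1", "FE_adj_freq"] = 3.0
        rec.loc[rec["matrix_id"] == "M1", "fisher_p"] = 1e-5
        out = tfbs.collapse_and_filter(rec)
        assert out[out["tf_name"] == "TFA"]["matrix_id"].iloc[0] == "M1"

    def test_fdr_not_below_binomial_p(self):
        out = tfbs.collapse_and_filter(self._records())
        assert (out["fdr"] >= out["binom_p"] - 1e-15).all()
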