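"""Simulator: transcriptome invariants, truth construction, read artifacts."""

import numpy as np
import pandas as pd
import pytest

import supersage as ss
from supersage.synthetic import CLASS_BOUNDS, _largest_remainder


class TestGenerateTranscriptome:
    def test_invariants_hold_for_every_transcript(self):
        txs = ss.generate_transcriptome(40, (100, 300), seed=7)
        assert len(txs) == 40
        for tx in txs:
            assert len(tx.sequence) >= 60
            assert tx.has_anchor
            pos = tx.sequence.rfind("CATG")
            # the 3'-most anchor leaves room for a full 26-nt tag
            assert pos + 26 <= len(tx.sequence)
            assert tx.true_tag == tx.sequence[pos : pos + 26]
            assert tx.true_tag.startswith("CATG")

    def test_single_transcript_fixed_length(self):
        (tx,) = ss.generate_transcriptome(1, (100, 100), seed=7)
        assert len(tx.sequence) == 100
        assert tx.has_anchor and len(tx.true_tag) == 26

    def test_deterministic_given_seed(self):
        a = ss.generate_transcriptome(60, (200, 1500), seed=1)
        b = ss.generate_transcriptome(60, (200, 1500), seed=1)
        assert [t.sequence for t in a] == [t.sequence for t in b]
        c = ss.generate_transcriptome(60, (200, 1500), seed=2)
        assert [t.sequence for t in a] != [t.sequence for t in c]

    def test_tags_unique_by_exhaustive_pairwise_comparison(self):
        txs = ss.generate_transcriptome(500, (200, 1500), seed=1)
        tags = [t.true_tag for t in txs]
        for i in range(len(tags)):
            for j in range(i + 1, len(tags)):
                assert tags[i] != tags[j]

    @pytest.mark.parametrize(
        "n, length_range",
        [(0, (100, 200)), (5, (40, 200)), (5, (300, 200))],
    )
    def test_invalid_parameters_rejected(self, n, length_range):
        with pytest.raises(ValueError):
            ss.generate_transcriptome(n, length_range, seed=0)


class TestAssignExpression:
    def test_no_de_means_all_fold_changes_one(self, clean_sim_config):
        cfg = ss.SimConfig(
            **{**clean_sim_config.__dict__, "de_fraction": 0.0}
        )
        txs = ss.generate_transcriptome(cfg.n_transcripts, (100, 300), seed=3)
        truth = ss.assign_expression(txs, cfg)
        assert (truth["true_fc"] == 1.0).all()
        assert (truth["de_status"] == "null").all()

    def test_truth_normalized_to_one_million(self, clean_sim_config):
        txs = ss.generate_transcriptome(
            clean_sim_config.n_transcripts, (100, 300), seed=3
        )
        truth = ss.assign_expression(txs, clean_sim_config)
        assert truth["mean_W"].sum() == pytest.approx(1e6, rel=1e-9)
        assert truth["mean_F"].sum() == pytest.approx(1e6, rel=1e-9)
        assert (truth["true_fc"] > 0).all()

    def test_all_low_mixture_caps_every_mean(self):
        # 10^6 copies spread over n transcripts at <= 100 each needs n >= 10^4
        cfg = ss.SimConfig(
            n_transcripts=10_000,
            abundance_mixture=(1.0, 0.0, 0.0, 0.0),
            de_fraction=0.0,
            seed=2,
        )
        txs = ss.generate_transcriptome(10_000, (60, 120), seed=2)
        truth = ss.assign_expression(txs, cfg)
        assert (truth["mean_W"] <= 100.0).all()
        assert truth["mean_W"].sum() == pytest.approx(1e6, rel=1e-9)

    def test_class_proportions_match_configured_mixture(self):
        cfg = ss.SimConfig(
            n_transcripts=2000,
            abundance_mixture=(0.5, 0.4, 0.08, 0.02),
            de_fraction=0.0,
            seed=9,
        )
        txs = ss.generate_transcriptome(2000, (60, 120), seed=9)
        truth = ss.assign_expression(txs, cfg)
        classes = ss.abundance_class(truth["mean_W"].to_numpy())
        for label, expected in zip(
            ("low", "mid", "high", "very_high"), cfg.abundance_mixture
        ):
            observed = (classes == label).mean()
            assert observed == pytest.approx(expected, abs=1.0 / 2000)

    def test_de_statuses_respect_thresholds(self, clean_sim_config):
        txs = ss.generate_transcriptome(
            clean_sim_config.n_transcripts, (100, 300), seed=3
        )
        truth = ss.assign_expression(txs, clean_sim_config)
        up = truth[truth["de_status"] == "up"]
        down = truth[truth["de_status"] == "down"]
        assert (up["true_fc"] >= clean_sim_config.de_up_min).all()
        assert (down["true_fc"] <= clean_sim_config.de_down_max).all()
        assert len(up) > 0 and len(down) > 0

    def test_ambiguous_fc_range_rejected(self):
        with pytest.raises(ValueError, match="fc_range"):
            ss.SimConfig(de_fraction=0.1, fc_range=(1.5, 70.0))
        with pytest.raises(ValueError, match="fc_range"):
            ss.SimConfig(de_fraction=0.1, fc_range=(0.1, 0.9))

    def test_empty_transcriptome_rejected(self, clean_sim_config):
        with pytest.raises(ValueError, match="empty"):
            ss.assign_expression([], clean_sim_config)

    def test_infeasible_abundance_assignment_fails_loudly(self):
        # 50 mostly-low transcripts cannot carry 10^6 copies per million
        cfg = ss.SimConfig(
            n_transcripts=50, abundance_mixture=(0.9, 0.1, 0, 0), de_fraction=0
        )
        txs = ss.generate_transcriptome(50, (60, 120), seed=0)
        with pytest.raises(ValueError, match="feasible|budget"):
            ss.assign_expression(txs, cfg)

    def test_largest_remainder_allocates_exactly(self):
        counts = _largest_remainder((0.884, 0.102, 0.012, 0.002), 12774)
        assert counts.sum() == 12774
        assert counts[0] == pytest.approx(0.884 * 12774, abs=1)


class TestSimulateReads:
    def _setup(self, cfg):
        txs = ss.generate_transcriptome(cfg.n_transcripts, (100, 300), seed=cfg.seed)
        truth = ss.assign_expression(txs, cfg)
        return ss.simulate_reads(truth, cfg)

    def test_clean_reads_all_parse_into_two_valid_tags(self, clean_sim_config):
        sim = self._setup(clean_sim_config)
        for lib in ("W", "F"):
            for read in sim.reads[lib][:200]:
                ditag = ss.locate_ditag(read)
                assert isinstance(ditag, ss.Ditag)
                assert ditag.library == lib

    def test_clean_draw_totals_equal_configured_depths(self, clean_sim_config):
        sim = self._setup(clean_sim_config)
        assert sim.draw_totals() == {"W": 4000, "F": 2240}

    def test_zero_depth_gives_empty_stream(self, clean_sim_config):
        cfg = ss.SimConfig(
            **{**clean_sim_config.__dict__, "depth_W": 0}
        )
        sim = self._setup(cfg)
        assert sim.reads["W"] == []
        assert len(sim.reads["F"]) > 0

    def test_deterministic_given_config(self, noisy_sim_config):
        a = self._setup(noisy_sim_config)
        b = self._setup(noisy_sim_config)
        for lib in ("W", "F"):
            assert [r.bases for r in a.reads[lib]] == [r.bases for r in b.reads[lib]]

    def test_incomplete_read_fraction_matches_binomial_rate(self, clean_sim_config):
        rate = 0.1
        cfg = ss.SimConfig(
            **{
                **clean_sim_config.__dict__,
                "incomplete_read_rate": rate,
                "depth_W": 20_000,
                "depth_F": 0,
            }
        )
        sim = self._setup(cfg)
        n = len(sim.reads["W"])
        short = sum(len(r.bases) < 68 for r in sim.reads["W"])
        sd = np.sqrt(rate * (1 - rate) / n)
        assert short / n == pytest.approx(rate, abs=3 * sd)


class TestTruthEval:
    def _truth(self):
        return pd.DataFrame(
            {
                "true_tag": ["t1", "t2", "t3", "t4"],
                "de_status": ["up", "down", "null", "null"],
            }
        )

    def test_perfect_calls(self):
        results = pd.DataFrame(
            {
                "tag": ["t1", "t2", "t3", "t4"],
                "direction": ["up", "down", "unchanged", "unchanged"],
            }
        )
        metrics = ss.truth_eval(results, self._truth())
        assert metrics["sensitivity"] == 1.0
        assert metrics["fp_rate"] == 0.0

    def test_all_unchanged_calls(self):
        results = pd.DataFrame(
            {"tag": ["t1", "t2"], "direction": ["unchanged", "unchanged"]}
        )
        metrics = ss.truth_eval(results, self._truth())
        assert metrics["sensitivity"] == 0.0

    def test_absent_tags_count_as_non_calls(self):
        results = pd.DataFrame({"tag": ["t1"], "direction": ["up"]})
        metrics = ss.truth_eval(results, self._truth())
        assert metrics["sensitivity_up"] == 1.0
        assert metrics["sensitivity_down"] == 0.0

    def test_orphan_tags_rejected(self):
        results = pd.DataFrame({"tag": ["ghost"], "direction": ["up"]})
        with pytest.raises(ValueError, match="ghost"):
            ss.truth_eval(results, self._truth())
        metrics = ss.truth_eval(results, self._truth(), ignore_unknown=True)
        assert metrics["sensitivity"] == 0.0

    def test_randomized_labels_give_fp_near_call_rate(self, rng):
        # permutation oracle: with truth labels shuffled, the FP proportion
        # among nulls approximates the overall up/down call rate
        n = 2000
        tags = [f"t{i}" for i in range(n)]
        directions = rng.choice(
            ["up", "down", "unchanged"], size=n, p=[0.1, 0.05, 0.85]
        )
        truth = pd.DataFrame(
            {
                "true_tag": tags,
                "de_status": rng.permutation(
                    ["up"] * 100 + ["down"] * 100 + ["null"] * (n - 200)
                ),
            }
        )
        results = pd.DataFrame({"tag": tags, "direction": directions})
        metrics = ss.truth_eval(results, truth)
        call_rate = float(np.isin(directions, ["up", "down"]).mean())
        sd = np.sqrt(call_rate * (1 - call_rate) / (n - 200))
        assert metrics["fp_rate"] == pytest.approx(call_rate, abs=4 * sd)


class TestIO:
    def test_fasta_fastq_roundtrip(self, tmp_path, clean_sim_config):
        txs = ss.generate_transcriptome(40, (100, 200), seed=1)
        cfg = ss.SimConfig(
            **{
                **clean_sim_config.__dict__,
                "n_transcripts": 40,
                "depth_W": 100,
                "depth_F": 100,
                "abundance_mixture": (0.0, 0.0, 0.5, 0.5),
                "de_fraction": 0.0,
            }
        )
        truth = ss.assign_expression(txs, cfg)
        sim = ss.simulate_reads(truth, cfg)
        for fmt, suffix in (("fasta", "fa"), ("fastq", "fq")):
            path = tmp_path / f"reads.{suffix}"
            ss.synthetic.write_reads(sim.reads["W"], path, fmt)
            back = list(ss.parse_reads(path))
            assert [r.bases for r in back] == [r.bases for r in sim.reads["W"]]

    def test_truth_tsv_roundtrip(self, tmp_path, clean_sim_config):
        txs = ss.generate_transcriptome(
            clean_sim_config.n_transcripts, (100, 300), seed=5
        )
        truth = ss.assign_expression(txs, clean_sim_config)
        path = tmp_path / "truth.tsv"
        ss.synthetic.write_truth(truth, path)
        back = ss.synthetic.read_truth(path)
        assert list(back.columns) == list(truth.columns)
        assert back["mean_W"].sum() == pytest.approx(1e6, rel=1e-6)
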