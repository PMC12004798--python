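"""Caller tests: PFB compilation, GC-wave correction, and Viterbi decoding
checked against exhaustive path enumeration."""

import numpy as np
import pandas as pd
import pytest

import cnvrkit as ck
from cnvrkit.hmm import HmmModel, _viterbi_path, STATES

from oracles import exhaustive_best_path


def make_track(lrr, baf, positions=None, chrom="1"):
    n = len(lrr)
    if positions is None:
        positions = np.arange(1, n + 1) * 5_000
    return pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(n)],
        "chrom": chrom, "position": positions,
        "lrr": lrr, "baf": baf,
    })


def flat_pfb(track, value=0.5):
    return pd.Series(value, index=track["snp_id"].to_numpy(), name="pfb")


class TestCompilePfb:
    @pytest.mark.parametrize("baf_values, expected", [
        ([0.5, 0.5, 0.5], 0.5),       # mean of constants
        ([0.0, 0.0, 0.0], 0.01),      # clamped to the floor
        ([1.0, 1.0, 1.0], 0.99),      # clamped to the ceiling
        ([0.0, 0.5, 1.0], 0.5),       # arithmetic mean
    ])
    def test_mean_and_clamping(self, baf_values, expected):
        baf = pd.DataFrame({"snpA": baf_values})
        assert ck.compile_pfb(baf)["snpA"] == pytest.approx(expected)

    def test_all_missing_snp_excluded_with_warning(self):
        baf = pd.DataFrame({"snpA": [0.5, 0.5], "snpB": [np.nan, np.nan]})
        with pytest.warns(UserWarning, match="all-missing"):
            pfb = ck.compile_pfb(baf)
        assert list(pfb.index) == ["snpA"]


class TestGcCorrect:
    def test_constant_gc_is_identity(self):
        track = make_track(np.linspace(-1, 1, 100), np.zeros(100))
        track["gc"] = 40.0
        out = ck.gc_correct(track)
        np.testing.assert_array_equal(out["lrr"], track["lrr"])

    def test_perfectly_linear_wave_flattens_to_median(self):
        rng = np.random.default_rng(1)
        gc = rng.uniform(30, 60, 500)
        track = make_track(0.01 * (gc - 40), np.zeros(500))
        track["gc"] = gc
        out = ck.gc_correct(track)
        med = np.median(track["lrr"])
        np.testing.assert_allclose(out["lrr"], med, atol=1e-10)

    def test_noisy_wave_slope_removed(self):
        rng = np.random.default_rng(2)
        n = 10_000
        gc = rng.uniform(30, 60, n)
        noise = rng.normal(0, 0.1, n)
        track = make_track(0.01 * (gc - 40) + noise, np.zeros(n))
        track["gc"] = gc
        # least-squares sanity: the wave is recoverable from the data
        slope_before = np.polyfit(gc, track["lrr"], 1)[0]
        se = 0.1 / (np.std(gc) * np.sqrt(n))
        assert abs(slope_before - 0.01) <= 3 * se
        out = ck.gc_correct(track)
        slope_after = np.polyfit(gc, out["lrr"], 1)[0]
        assert abs(slope_after) <= 3 * se
        # median re-centred
        assert np.median(out["lrr"]) == pytest.approx(
            np.median(track["lrr"]), abs=1e-9)

    def test_mostly_missing_gc_rejected(self):
        track = make_track(np.zeros(10), np.zeros(10))
        track["gc"] = [40.0] * 5 + [np.nan] * 5
        with pytest.raises(ValueError, match="GC"):
            ck.gc_correct(track)


class TestViterbiCall:
    def test_noiseless_diploid_track_yields_no_calls(self):
        rng = np.random.default_rng(3)
        baf = rng.choice([0.0, 0.5, 1.0], size=200)
        track = make_track(np.zeros(200), baf)
        calls = ck.viterbi_call(track, flat_pfb(track), HmmModel())
        assert calls.empty

    def test_planted_deletion_recovered_exactly(self):
        rng = np.random.default_rng(4)
        n = 60
        lrr = np.zeros(n)
        baf = rng.choice([0.0, 0.5, 1.0], size=n).astype(float)
        lrr[20:40] = -0.66
        baf[20:40] = rng.choice([0.0, 1.0], size=20)
        track = make_track(lrr, baf)
        calls = ck.viterbi_call(track, flat_pfb(track), HmmModel())
        assert len(calls) == 1
        call = calls.iloc[0]
        assert call["state"] == 1
        assert call["numsnp"] == 20
        assert call["start"] == track["position"].iloc[20]
        assert call["end"] == track["position"].iloc[39]

    def test_single_snp_chromosome_skipped(self):
        track = make_track([0.0], [0.5])
        calls = ck.viterbi_call(track, flat_pfb(track), HmmModel())
        assert calls.empty

    def test_calls_disjoint_and_well_formed(self):
        rng = np.random.default_rng(5)
        lrr = rng.normal(0, 0.4, 500)
        baf = np.clip(rng.choice([0.0, 0.5, 1.0], 500)
                      + rng.normal(0, 0.05, 500), 0, 1)
        track = make_track(lrr, baf)
        calls = ck.viterbi_call(track, flat_pfb(track), HmmModel())
        assert (calls["numsnp"] >= 1).all()
        assert (calls["start"] <= calls["end"]).all()
        calls = calls.sort_values("start")
        assert (calls["start"].to_numpy()[1:] > calls["end"].to_numpy()[:-1]).all()

    def test_decoding_invariant_to_emission_scaling(self):
        rng = np.random.default_rng(6)
        model = HmmModel()
        track = make_track(rng.normal(0, 0.5, 30),
                           np.clip(rng.random(30), 0, 1))
        emis = model.log_emissions(track, flat_pfb(track))
        trans = [model.log_transition(d)
                 for d in np.diff(track["position"].to_numpy())]
        path1 = _viterbi_path(emis, model.log_initial(), trans)
        # multiplying every emission density by a positive constant
        path2 = _viterbi_path(emis + np.log(7.3), model.log_initial(), trans)
        np.testing.assert_array_equal(path1, path2)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_enumeration_on_short_tracks(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        model = HmmModel()
        track = make_track(rng.normal(0, 1.0, n), rng.random(n),
                           positions=np.cumsum(rng.integers(1_000, 200_000, n)))
        pfb = pd.Series(rng.uniform(0.05, 0.95, n),
                        index=track["snp_id"].to_numpy())
        emis = model.log_emissions(track, pfb)
        trans = [model.log_transition(d)
                 for d in np.diff(track["position"].to_numpy())]
        path = _viterbi_path(emis, model.log_initial(), trans)
        best_score, best_paths = exhaustive_best_path(
            emis, model.log_initial(), trans)
        score = model.log_initial()[path[0]] + emis[0, path[0]]
        for t in range(1, n):
            score += trans[t - 1][path[t - 1], path[t]] + emis[t, path[t]]
        assert score == pytest.approx(best_score, abs=1e-9)
        assert tuple(path) in best_paths

    def test_breakpoint_recovery_on_easy_signals(self):
        """>=95% of 20+-SNP events with a 0.4+ LRR shift are recovered
        within +-2 SNPs under moderate noise."""
        rng = np.random.default_rng(7)
        model = HmmModel()
        recovered = 0
        n_events = 40
        for i in range(n_events):
            n = 120
            i0 = int(rng.integers(30, 60))
            width = int(rng.integers(20, 35))
            is_del = rng.random() < 0.5
            shift = -0.66 if is_del else 0.40
            lrr = rng.normal(0, 0.15, n)
            baf = np.clip(rng.choice([0.0, 0.5, 1.0], n)
                          + rng.normal(0, 0.03, n), 0, 1)
            lrr[i0:i0 + width] += shift
            inside = (rng.choice([0.0, 1.0], width) if is_del
                      else rng.choice([0.0, 1 / 3, 2 / 3, 1.0], width))
            baf[i0:i0 + width] = np.clip(inside + rng.normal(0, 0.03, width), 0, 1)
            track = make_track(lrr, baf)
            calls = ck.viterbi_call(track, flat_pfb(track), model)
            want_state_low = is_del
            for c in calls.itertuples(index=False):
                if (c.state < 2) != want_state_low:
                    continue
                s_idx = track.index[track["position"] == c.start][0]
                e_idx = track.index[track["position"] == c.end][0]
                if abs(s_idx - i0) <= 2 and abs(e_idx - (i0 + width - 1)) <= 2:
                    recovered += 1
                    break
        assert recovered / n_events >= 0.95
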