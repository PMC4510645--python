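"""Profile construction, Viterbi scoring, calibration and domain search."""

import math

import numpy as np
import pytest
from scipy import stats

from sialoscreen.profile_hmm import (
    AMINO_ACIDS,
    AlignmentError,
    CalibrationError,
    ProfileHMM,
    ProfileHMMError,
    build_profile,
    calibrate,
    fit_gumbel,
    read_hmmer3,
    search_domains,
    viterbi_score,
)
from sialoscreen import synthetic_data as synth

from conftest import brute_force_viterbi, random_small_model, CAL_N, CAL_SEED


# ---------------------------------------------------------------------------
# build_profile
# ---------------------------------------------------------------------------

class TestBuildProfile:
    def test_identical_ungapped_rows(self):
        model = build_profile(["ACDEF"] * 3)
        assert model.length == 5
        assert AMINO_ACIDS[model.match_emissions[0].argmax()] == "A"
        assert AMINO_ACIDS[model.match_emissions[4].argmax()] == "F"

    def test_gap_majority_column_not_match(self):
        rows = ["A-C"] * 6 + ["AAC"] * 4  # middle column: 6/10 gaps
        model = build_profile(rows, gap_threshold=0.5)
        assert model.length == 2

    def test_gap_exactly_at_threshold_is_match(self):
        rows = ["A-C"] * 5 + ["AAC"] * 5  # gap fraction exactly 0.5
        assert build_profile(rows, gap_threshold=0.5).length == 3

    def test_emissions_match_independent_counting(self):
        # 36 rows emitted from a known profile; compare against brute counts
        src = synth.make_profile("src", 12, seed=5)
        rng = np.random.default_rng(9)
        rows = ["".join(AMINO_ACIDS[rng.choice(20, p=src.match_emissions[k])]
                        for k in range(12)) for _ in range(36)]
        mass = 1.0
        model = build_profile(rows, pseudocount_mass=mass)
        bg = np.full(20, 1 / 20)
        for k in range(12):
            counts = np.zeros(20)
            for r in rows:
                counts[AMINO_ACIDS.index(r[k])] += 1
            expected = (counts + mass * bg) / (counts.sum() + mass)
            np.testing.assert_allclose(model.match_emissions[k], expected, atol=1e-12)

    @pytest.mark.parametrize("rows", [[], ["ACD"], ["---", "---"], ["AXD", "ACD"]])
    def test_rejects_bad_alignments(self, rows):
        with pytest.raises(AlignmentError):
            build_profile(rows)

    def test_distributions_normalised(self):
        rows = ["AC-DE", "A-CDE", "ACCDE", "AC-D-"]
        model = build_profile(rows)
        assert np.allclose(model.match_emissions.sum(axis=1), 1.0)
        assert np.allclose(model.insert_emissions.sum(axis=1), 1.0)
        L = model.length
        for group in (("MM", "MI", "MD"), ("IM", "II"), ("DM", "DD")):
            tot = sum(model.transitions[g][: L - 1] for g in group)
            assert np.allclose(tot, 1.0)


# ---------------------------------------------------------------------------
# Viterbi
# ---------------------------------------------------------------------------

class TestViterbi:
    def test_matches_exhaustive_enumeration(self):
        # random small models x random sequences; DP must equal brute force
        rng = np.random.default_rng(0)
        for _ in range(250):
            L = int(rng.integers(1, 5))
            n = int(rng.integers(1, 6))
            model = random_small_model(rng, L)
            x = rng.integers(0, 20, size=n)
            got, _ = viterbi_score(model, x)
            want = brute_force_viterbi(model, x)
            assert got == pytest.approx(want, abs=1e-8)

    def test_consensus_dominates_single_mutants(self):
        model = synth.make_profile("m", 10, seed=2)
        cons = model.consensus
        base, _ = viterbi_score(model, cons)
        for i in range(len(cons)):
            for aa in AMINO_ACIDS:
                if aa == cons[i]:
                    continue
                mut = cons[:i] + aa + cons[i + 1:]
                score, _ = viterbi_score(model, mut)
                assert score <= base + 1e-9

    def test_zero_information_model_scores_near_zero(self):
        # emissions equal to background: only entry/exit terms remain
        bg = np.full(20, 1 / 20)
        L = 6
        model = ProfileHMM(
            name="flat", match_emissions=np.tile(bg, (L, 1)),
            insert_emissions=np.tile(bg, (L, 1)),
            transitions={"MM": np.full(L, 0.9), "MI": np.full(L, 0.05),
                         "MD": np.full(L, 0.05), "IM": np.full(L, 0.5),
                         "II": np.full(L, 0.5), "DM": np.full(L, 0.5),
                         "DD": np.full(L, 0.5)},
            background=bg)
        rng = np.random.default_rng(4)
        for _ in range(20):
            seq = synth.random_background(rng, 30)
            score, _ = viterbi_score(model, seq)
            assert score <= 1.0  # entry term is -log2(L) < 0; no information gain

    def test_empty_sequence_rejected(self):
        model = synth.make_profile("m", 5, seed=1)
        with pytest.raises(ProfileHMMError):
            viterbi_score(model, "")

    def test_path_is_optimal_scoring(self):
        # replaying the reported path must reproduce the reported score
        rng = np.random.default_rng(3)
        model = random_small_model(rng, 4)
        lt = {k: np.log2(v) for k, v in model.transitions.items()}
        lodM = np.log2(model.match_emissions) - np.log2(model.background)
        lodI = np.log2(model.insert_emissions) - np.log2(model.background)
        for _ in range(30):
            x = rng.integers(0, 20, size=5)
            score, path = viterbi_score(model, x)
            replay = -math.log2(model.length)
            prev = None
            for st, k, pos in path:
                if prev is not None:
                    ps, pk = prev
                    replay += lt[ps + st][pk - 1]
                if st == "M":
                    replay += lodM[k - 1, x[pos - 1]]
                elif st == "I":
                    replay += lodI[k - 1, x[pos - 1]]
                prev = (st, k)
            assert replay == pytest.approx(score, abs=1e-8)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

class TestCalibration:
    def test_gumbel_refit_recovers_known_parameters(self):
        rng = np.random.default_rng(12)
        scores = stats.gumbel_r.rvs(loc=5.0, scale=1 / 0.7, size=1000, random_state=rng)
        mu, lam = fit_gumbel(scores)
        assert mu == pytest.approx(5.0, abs=0.3)
        assert lam == pytest.approx(0.7, abs=0.1)

    def test_same_seed_identical_params(self):
        m1 = synth.make_profile("m", 20, seed=6)
        m2 = synth.make_profile("m", 20, seed=6)
        p1 = calibrate(m1, n_random=200, seed=33)
        p2 = calibrate(m2, n_random=200, seed=33)
        assert p1 == p2

    def test_degenerate_scores_rejected(self):
        with pytest.raises(CalibrationError):
            fit_gumbel(np.full(500, 3.2))

    def test_minimum_sample_size_enforced(self):
        model = synth.make_profile("m", 10, seed=1)
        with pytest.raises(CalibrationError):
            calibrate(model, n_random=50)

    def test_empirical_exceedance_matches_fitted_survival(self):
        # weakly conserved profile: smooth null score distribution
        model = synth.make_profile("m", 25, seed=8, conservation=0.35)
        params = calibrate(model, n_random=CAL_N, seed=CAL_SEED)
        # re-draw the calibration scores with the same seed
        rng = np.random.default_rng(CAL_SEED)
        draws = rng.choice(20, size=(CAL_N, params.random_length), p=model.background)
        scores = np.sort([viterbi_score(model, row, with_path=False)[0] for row in draws])
        k = int(0.95 * CAL_N)
        thr = (scores[k - 1] + scores[k]) / 2  # between order statistics: no ties
        emp = (scores > thr).mean()
        fitted = params.survival(thr)
        ci = 2.576 * math.sqrt(fitted * (1 - fitted) / CAL_N)
        assert abs(emp - fitted) <= ci + 1e-9


# ---------------------------------------------------------------------------
# Domain search
# ---------------------------------------------------------------------------

class TestSearch:
    def test_planted_domains_recovered_no_decoy_hits(self, models):
        sial = models["sialidase"]
        rng = np.random.default_rng(17)
        targets = []
        for i in range(10):
            seq, span = synth.sample_sequence_from_profile(sial, rng)
            targets.append((f"pos{i}", seq))
        for i in range(50):
            targets.append((f"neg{i}", synth.random_background(rng, 300)))
        hits = search_domains(sial, targets, max_evalue=1e-4)
        hit_ids = {h.target_id for h in hits}
        assert hit_ids == {f"pos{i}" for i in range(10)}

    def test_evalue_threshold_is_strict(self, models):
        # discard rule is "E-value > threshold": a hit with E exactly at the
        # threshold is retained, a hit 1% over is not
        sial = models["sialidase"]
        seq, _ = synth.sample_sequence_from_profile(sial, 23)
        hit = search_domains(sial, [("t", seq)], max_evalue=1.0)[0]  # best by E-value
        assert search_domains(sial, [("t", seq)], max_evalue=hit.evalue)
        assert not search_domains(sial, [("t", seq)], max_evalue=hit.evalue / 1.01)

    def test_tandem_copies_yield_disjoint_hits(self, models):
        sial = models["sialidase"]
        rng = np.random.default_rng(5)
        a, _ = synth.sample_sequence_from_profile(sial, rng, flank_range=(15, 25))
        b, _ = synth.sample_sequence_from_profile(sial, rng, flank_range=(15, 25))
        hits = search_domains(sial, [("tandem", a + b)], max_evalue=1e-4)
        assert len(hits) == 2
        h1, h2 = sorted(hits, key=lambda h: h.target_start)
        assert h1.target_end < h2.target_start  # disjoint envelopes

    def test_masking_monotone_bit_scores(self, models):
        sial = models["sialidase"]
        rng = np.random.default_rng(6)
        seq = "".join(synth.sample_sequence_from_profile(sial, rng)[0] for _ in range(3))
        hits = search_domains(sial, [("t", seq)], max_evalue=1e-4)
        assert len(hits) >= 2
        ordered = sorted(hits, key=lambda h: -h.bit_score)
        by_eval = sorted(hits, key=lambda h: h.evalue)
        assert [h.bit_score for h in by_eval] == [h.bit_score for h in ordered]

    def test_doubling_search_space_doubles_evalues(self, models):
        sial = models["sialidase"]
        seq, _ = synth.sample_sequence_from_profile(sial, 31)
        h1 = search_domains(sial, [("t", seq)], max_evalue=1.0, search_space=100)
        h2 = search_domains(sial, [("t", seq)], max_evalue=1.0, search_space=200)
        assert len(h1) == len(h2) >= 1
        for a, b in zip(h1, h2):
            assert b.evalue == pytest.approx(2 * a.evalue, rel=1e-12)

    def test_uncalibrated_model_rejected(self):
        model = synth.make_profile("m", 10, seed=1)
        with pytest.raises(CalibrationError):
            search_domains(model, [("t", "ACDEFGHIK")])


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

class TestIO:
    def test_json_roundtrip(self, tmp_path, models):
        sial = models["sialidase"]
        path = tmp_path / "sial.json"
        sial.to_json(path)
        back = ProfileHMM.from_json(path)
        np.testing.assert_allclose(back.match_emissions, sial.match_emissions)
        np.testing.assert_allclose(back.transitions["MM"], sial.transitions["MM"])
        assert back.calibration == sial.calibration
        s1, _ = viterbi_score(sial, sial.consensus)
        s2, _ = viterbi_score(back, back.consensus)
        assert s1 == pytest.approx(s2)

    def test_hmmer3_ascii_import(self, tmp_path):
        text = _HMMER3_MINI
        p = tmp_path / "mini.hmm"
        p.write_text(text)
        model = read_hmmer3(p)
        assert model.length == 2
        assert model.name == "mini"
        # first match state heavily favours A (-ln p = 0.1 vs 5.0 elsewhere)
        assert AMINO_ACIDS[model.match_emissions[0].argmax()] == "A"
        assert AMINO_ACIDS[model.match_emissions[1].argmax()] == "C"
        assert model.calibration is not None
        assert model.calibration.lam == pytest.approx(0.7)
        # scoring works end to end
        score, _ = viterbi_score(model, "AC")
        assert np.isfinite(score)


_AA_HMMER_ORDER = "A C D E F G H I K L M N P Q R S T V W Y".split()


def _emission_line(fav_idx):
    vals = ["5.00000"] * 20
    vals[fav_idx] = "0.10000"
    return "  ".join(vals)


_HMMER3_MINI = "\n".join([
    "HMMER3/f [3.1b2 | February 2015]",
    "NAME  mini",
    "LENG  2",
    "ALPH  amino",
    "STATS LOCAL MSV       -8.0  0.7",
    "STATS LOCAL VITERBI   -8.5  0.7",
    "STATS LOCAL FORWARD   -2.0  0.7",
    "HMM          " + "        ".join(_AA_HMMER_ORDER),
    "            m->m     m->i     m->d     i->m     i->i     d->m     d->d",
    "  COMPO   " + "  ".join(["2.99573"] * 20),
    "          " + "  ".join(["2.99573"] * 20),
    "          0.01  4.62  4.62  0.69  0.69  0.00  *",
    "      1   " + _emission_line(0) + "      1 - - -",
    "          " + "  ".join(["2.99573"] * 20),
    "          0.01  4.62  4.62  0.69  0.69  0.69  0.69",
    "      2   " + _emission_line(1) + "      2 - - -",
    "          " + "  ".join(["2.99573"] * 20),
    "          0.01  4.62  *  0.69  0.69  0.00  *",
    "//",
]) + "\n"
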