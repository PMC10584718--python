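"""Normalization, rescaling, summaries, and Euclidean similarity."""

import numpy as np
import pytest

from vowelmap import (
    ValidationError,
    VowelToken,
    distance_ranking,
    euclidean_distance,
    lobanov_normalize,
    rescale_to_hz,
    round_half_up,
    summarize_inventory,
)
from vowelmap.acoustics import NormalizationState
from vowelmap.synthetic import (
    CG_SUMMARY,
    NL_SUMMARY,
    GeneratorSpec,
    default_spec,
    generate_tokens,
)


def _tok(speaker, f1, f2, f3, duration=100.0, normalized=False, vowel="i"):
    return VowelToken(speaker=speaker, language="CG", vowel=vowel,
                      f1=f1, f2=f2, f3=f3, duration=duration,
                      normalized=normalized)


class TestLobanov:
    def test_two_value_hand_computation(self):
        # values {400, 600}: mean 500, sample SD 141.42 -> z = -/+ 0.7071
        toks = [_tok("s1", 400.0, 2000.0, 2900.0),
                _tok("s1", 600.0, 2100.0, 3000.0)]
        z, _ = lobanov_normalize(toks)
        assert z[0].f1 == pytest.approx(-0.70710678, abs=1e-6)
        assert z[1].f1 == pytest.approx(+0.70710678, abs=1e-6)

    def test_per_speaker_mean_zero_sd_one(self, cg_tokens):
        z, _ = lobanov_normalize(cg_tokens)
        by_speaker = {}
        for t in z:
            by_speaker.setdefault(t.speaker, []).append(t)
        for toks in by_speaker.values():
            for fmt in ("f1", "f2", "f3"):
                vals = np.array([getattr(t, fmt) for t in toks])
                assert abs(vals.mean()) < 1e-9
                assert abs(vals.std(ddof=1) - 1.0) < 1e-9

    def test_duration_passes_through(self, cg_tokens):
        z, _ = lobanov_normalize(cg_tokens)
        assert [t.duration for t in z] == [t.duration for t in cg_tokens]

    def test_standardized_input_unchanged(self):
        vals = np.array([-1.2, -0.3, 0.5, 1.0])
        vals = (vals - vals.mean()) / vals.std(ddof=1)
        toks = [_tok("s1", v, v + 0.1, v + 0.2, normalized=True)
                for v in vals]
        # shift f2/f3 to be standardized too
        toks = [
            VowelToken(speaker="s1", language="CG", vowel="i",
                       f1=v, f2=v, f3=v, duration=100.0, normalized=True)
            for v in vals]
        z, _ = lobanov_normalize(toks)
        for a, b in zip(z, toks):
            assert a.f1 == pytest.approx(b.f1, abs=1e-12)

    def test_affine_invariance_per_speaker(self, cg_tokens):
        z_ref, _ = lobanov_normalize(cg_tokens)
        shifted = [
            VowelToken(speaker=t.speaker, language=t.language,
                       vowel=t.vowel, f1=3.0 * t.f1 + 100.0,
                       f2=3.0 * t.f2 + 100.0, f3=3.0 * t.f3 + 100.0,
                       duration=t.duration)
            for t in cg_tokens]
        z_shift, _ = lobanov_normalize(shifted)
        for a, b in zip(z_ref, z_shift):
            for fmt in ("f1", "f2", "f3"):
                assert getattr(a, fmt) == pytest.approx(
                    getattr(b, fmt), abs=1e-9)

    def test_single_token_speaker_named_in_error(self):
        toks = [_tok("s1", 400.0, 2000.0, 2900.0),
                _tok("s1", 600.0, 2100.0, 3000.0),
                _tok("lonely", 500.0, 2050.0, 2950.0)]
        with pytest.raises(ValidationError, match="lonely"):
            lobanov_normalize(toks)

    def test_zero_spread_speaker_rejected(self):
        toks = [_tok("s1", 400.0, 2000.0, 2900.0)] * 3
        with pytest.raises(ValidationError, match="zero"):
            lobanov_normalize(toks)


class TestRescale:
    def _state(self):
        return NormalizationState(
            speaker_stats={("s1", f): (0.0, 1.0)
                           for f in ("f1", "f2", "f3")},
            z_range={f: (-2.0, 2.0) for f in ("f1", "f2", "f3")})

    @pytest.mark.parametrize(("z", "expected"),
                             [(-2.0, 250.0), (2.0, 750.0), (0.0, 500.0)])
    def test_affine_endpoints_and_midpoint(self, z, expected):
        state = self._state()
        tok = _tok("s1", z, z, z, normalized=True)
        out = rescale_to_hz([tok], state)[0]
        assert out.f1 == pytest.approx(expected)

    def test_out_of_range_clamped_with_warning(self):
        state = self._state()
        tok = _tok("s1", 5.0, 0.0, 0.0, normalized=True)
        with pytest.warns(UserWarning, match="clamped"):
            out = rescale_to_hz([tok], state)[0]
        assert out.f1 == pytest.approx(750.0)

    def test_pipeline_preserves_within_speaker_rank_order(self, cg_tokens):
        z, state = lobanov_normalize(cg_tokens)
        scaled = rescale_to_hz(z, state)
        by_speaker = {}
        for raw, s in zip(cg_tokens, scaled):
            by_speaker.setdefault(raw.speaker, []).append((raw, s))
        for pairs in by_speaker.values():
            for fmt in ("f1", "f2", "f3"):
                raw_order = np.argsort([getattr(r, fmt) for r, _ in pairs])
                scl_order = np.argsort([getattr(s, fmt) for _, s in pairs])
                assert (raw_order == scl_order).all()


class TestSummaries:
    def test_zero_noise_generator_recovers_the_table_exactly(self):
        table = {v: tuple((CG_SUMMARY.mean(v, f), 0.0)
                          for f in ("f1", "f2", "f3", "duration"))
                 for v in CG_SUMMARY.vowels}
        from vowelmap.acoustics import VowelSummary
        degenerate = VowelSummary.from_table("CG", table)
        spec = GeneratorSpec(seed=0, acoustic={"CG": degenerate})
        toks = generate_tokens(spec, "CG")
        summ = summarize_inventory(toks)
        for v in degenerate.vowels:
            for f in ("f1", "f2", "f3", "duration"):
                assert summ.mean(v, f) == pytest.approx(
                    CG_SUMMARY.mean(v, f))
                assert summ.sd(v, f) == pytest.approx(0.0, abs=1e-9)

    def test_large_sample_mean_within_three_se(self):
        # NL /a/: F1 mean 862, SD 113
        spec = default_spec(seed=1)
        spec.n_speakers["NL"] = 100
        spec.repetitions["NL"] = 4
        toks = [t for t in generate_tokens(spec, "NL") if t.vowel == "a"]
        assert len(toks) == 400
        se = 113 / np.sqrt(len(toks))
        mean = np.mean([t.f1 for t in toks])
        assert abs(mean - 862) < 3 * se

    def test_single_token_vowel_rejected(self):
        toks = [_tok("s1", 400.0, 2000.0, 2900.0, vowel="i"),
                _tok("s1", 600.0, 2100.0, 3000.0, vowel="i"),
                _tok("s1", 500.0, 1000.0, 2900.0, vowel="u")]
        with pytest.raises(ValidationError, match="u"):
            summarize_inventory(toks)


class TestEuclidean:
    def test_three_four_five_triangle(self):
        assert euclidean_distance(
            np.array([0.0, 0.0]), np.array([3.0, 4.0])) == pytest.approx(5.0)

    def test_identity(self):
        a = {"f1": 410.0, "f2": 2589.0}
        assert euclidean_distance(a, dict(a)) == 0.0

    def test_mismatched_feature_sets_rejected(self):
        with pytest.raises(ValidationError):
            euclidean_distance({"f1": 1.0}, {"f2": 1.0}, features=("f1",))

    def test_published_nearest_neighbour_distance(self):
        d = euclidean_distance(
            CG_SUMMARY.mean_vector("i", ("f1", "f2")),
            NL_SUMMARY.mean_vector("e", ("f1", "f2")))
        assert round_half_up(d) == 66


class TestDistanceRanking:
    def test_cg_u_nearest_neighbours(self):
        table = distance_ranking(CG_SUMMARY, NL_SUMMARY)
        nearest = table.nearest("u")
        assert [v for v, _ in nearest[:2]] == ["ɔ", "o"]
        assert table.rounded("u", "ɔ") == 48
        assert table.rounded("u", "o") == 99

    def test_cg_open_mid_back_ordering(self):
        table = distance_ranking(CG_SUMMARY, NL_SUMMARY)
        nearest = table.nearest("ɔ")
        assert [v for v, _ in nearest[:3]] == ["ɑ", "ɔ", "o"]
        assert [table.rounded("ɔ", v) for v in ("ɑ", "ɔ", "o")] \
            == [188, 216, 270]

    def test_singleton_l2_inventory_is_trivially_nearest(self):
        from vowelmap.acoustics import VowelSummary
        l2 = VowelSummary.from_table(
            "X", {"o": ((500, 10), (1000, 10), (2500, 10), (100, 10))})
        table = distance_ranking(CG_SUMMARY, l2)
        for v in CG_SUMMARY.vowels:
            assert table.nearest(v)[0][0] == "o"
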