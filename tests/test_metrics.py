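"""The five effect measures: IPC, WCM, PCC, LVN, pMLU/PWP."""

import random

import pytest

from phonosim import (
    EditRecord,
    apply_pattern,
    generate_lexicon,
    ipc_score,
    levenshtein,
    lvn,
    parse_transcription,
    pcc,
    pmlu,
    pwp,
    score_word,
    structural_diff,
    wcm_score,
    worked_example,
)
from phonosim.errors import Edit
from phonosim.metrics import ZeroConsonantWord
from phonosim.synth import FixtureSpec


def _dp_levenshtein(a: str, b: str) -> int:
    """Textbook dynamic-programming oracle."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            )
        prev = cur
    return prev[-1]


class TestStructuralMeasures:
    def test_ipc_fronting_removes_dorsal_point(self, sv):
        orig = parse_transcription('""g0$bar', sv.inventory)
        fronted = parse_transcription('""d0$bar', sv.inventory)
        assert ipc_score(orig, sv.scoring) == 1
        assert ipc_score(fronted, sv.scoring) == 0

    def test_ipc_cluster_and_heterorganic_points(self, sv):
        orig = parse_transcription('""sp2:$ket', sv.inventory)
        stopped = parse_transcription('""p2:$ket', sv.inventory)
        assert ipc_score(orig, sv.scoring) == 3
        assert ipc_score(stopped, sv.scoring) == 1
        assert structural_diff(orig, stopped, sv.scoring) == (-2, -2)

    def test_ipc_homorganic_cluster_scores_no_bonus(self, sv):
        # /tr/ is coronal+coronal: cluster point only
        assert ipc_score(parse_transcription('"tre:', sv.inventory), sv.scoring) == 1

    def test_ipc_zero_for_vowel_only_word(self, sv):
        assert ipc_score(parse_transcription("a", sv.inventory), sv.scoring) == 0

    def test_r_weakening_never_moves_ipc(self, sv):
        """Neither /r/ nor /j/ scores, and /r/ -> /j/ keeps clusters'
        place profile, so the IPC effect is exactly zero."""
        for raw in ('"tre:', '"br}:n', '""ra$ram', '"d9r'):
            t = parse_transcription(raw, sv.inventory)
            err, _ = apply_pattern(t, "r_weakening", sv)
            assert structural_diff(t, err, sv.scoring)[0] == 0

    def test_wcm_r_to_j_direction_differs_by_language(self, sv, en):
        # Swedish /j/ is a voiced fricative (2 points) vs liquid /r/ (1)
        sv_r = parse_transcription('"ra', sv.inventory)
        sv_j = parse_transcription('"ja', sv.inventory)
        assert wcm_score(sv_j, sv.scoring) - wcm_score(sv_r, sv.scoring) == 1
        # English /j/ is an approximant (0 points)
        en_r = parse_transcription('"rA', en.inventory)
        en_j = parse_transcription('"jA', en.inventory)
        assert wcm_score(en_j, en.scoring) - wcm_score(en_r, en.scoring) == -1

    def test_wcm_backing_increases_complexity(self, en):
        t = parse_transcription('"tu', en.inventory)
        err, _ = apply_pattern(t, "backing", en)
        assert structural_diff(t, err, en.scoring)[1] > 0

    def test_wcm_word_pattern_points(self, sv):
        # 3 syllables (+1), non-initial stress (+1), final C (+1),
        # fricative /s/ (+1) => 4
        t = parse_transcription('pU$"tA:$tIs', sv.inventory)
        assert wcm_score(t, sv.scoring) == 4
        initial = parse_transcription('"tA:$tIs', sv.inventory)
        assert wcm_score(initial, sv.scoring) == 2  # final C + fricative


class TestRelationalMeasures:
    def test_pcc_of_worked_example(self, sv):
        t = parse_transcription('""sp2:$ket', sv.inventory)
        _, edits = apply_pattern(t, "stopping", sv)
        assert pcc(t, edits) == 75.0

    def test_pcc_bounds(self, sv):
        t = parse_transcription('"ka$ka', sv.inventory)
        assert pcc(t, EditRecord()) == 100.0
        _, edits = apply_pattern(t, "fronting", sv)  # both /k/ touched
        assert pcc(t, edits) == 0.0

    def test_pcc_undefined_without_consonants(self, sv):
        t = parse_transcription("a", sv.inventory)
        with pytest.raises(ZeroConsonantWord):
            pcc(t, EditRecord())

    def test_pcc_rejects_foreign_edits(self, sv):
        t = parse_transcription('"ka', sv.inventory)
        bad = EditRecord((Edit("substitute", "k", "t", consonant_index=5),))
        with pytest.raises(ValueError, match="nonexistent"):
            pcc(t, bad)

    def test_levenshtein_agrees_with_dp_oracle(self):
        rng = random.Random(11)
        alphabet = 'abkst"$:%'
        for _ in range(500):
            a = "".join(rng.choice(alphabet) for _ in range(rng.randint(0, 8)))
            b = "".join(rng.choice(alphabet) for _ in range(rng.randint(0, 8)))
            assert levenshtein(a, b) == _dp_levenshtein(a, b)

    def test_levenshtein_triangle_inequality(self):
        rng = random.Random(5)
        alphabet = "abkst"
        for _ in range(100):
            a, b, c = (
                "".join(rng.choice(alphabet) for _ in range(rng.randint(0, 6)))
                for _ in range(3)
            )
            assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)

    def test_lvn_worked_example_and_symmetry(self):
        a, b = '""sp2:$ket', '""p2:$ket'
        assert levenshtein(a, b) == 1
        assert lvn(a, b) == pytest.approx(1 / 19)
        assert lvn(a, b) == lvn(b, a)
        assert lvn(a, a) == 0.0
        with pytest.raises(ValueError):
            lvn("", "")


class TestWholeWordMeasures:
    def test_pmlu_counts_segments_plus_correct_consonants(self, sv):
        t = parse_transcription('""sp2:$ket', sv.inventory)
        assert pmlu(t, len(t.consonants)) == 10
        single = parse_transcription("a", sv.inventory)
        assert pmlu(single, 0) == 1
        with pytest.raises(ValueError):
            pmlu(single, 2)
        with pytest.raises(ValueError):
            pmlu(single, -1)

    def test_pwp_examples(self, en):
        # /nana/ for 'banana' scores 6/9; the same form for 'nanny' is exact
        banana = parse_transcription('b@$"n{$n@', en.inventory)
        nanny = parse_transcription('"n{$ni', en.inventory)
        production = parse_transcription('"n{$n@', en.inventory)
        assert pmlu(banana, 3) == 9
        assert pmlu(production, 2) == 6
        assert pmlu(production, 2) / pmlu(banana, 3) == pytest.approx(2 / 3)
        assert pmlu(nanny, 2) == 6

    def test_pwp_via_simulation(self, sv):
        t = parse_transcription('""sp2:$ket', sv.inventory)
        err, edits = apply_pattern(t, "stopping", sv)
        assert pwp(t, err, edits) == pytest.approx(0.8)
        assert pwp(t, t, EditRecord()) == 1.0


class TestScoreWord:
    def test_worked_example_bundle_round_trips(self, sv):
        ex = worked_example()
        t = parse_transcription(ex.sampa_orig, sv.inventory)
        r = score_word(ex.word, t, ex.pattern, sv)
        assert r.raw_err == ex.sampa_err
        assert r.ipc_diff == ex.expected["ipc_diff"]
        assert r.wcm_diff == ex.expected["wcm_diff"]
        assert r.pcc == ex.expected["pcc"]
        assert r.lvn == pytest.approx(ex.expected["lvn"])
        assert r.pwp == pytest.approx(ex.expected["pwp"])
        assert (r.pmlu_orig, r.pmlu_err) == (10, 8)

    def test_unknown_pattern_propagates(self, sv):
        t = parse_transcription("a", sv.inventory)
        with pytest.raises(ValueError):
            score_word("a", t, "lateralization", sv)

    def test_neutrality_is_equivalent_across_measures(self, sv):
        """PCC 100 <=> LVN 0 <=> PWP 1 <=> zero structural diffs."""
        corpus = generate_lexicon(FixtureSpec(n_types=50, seed=13))
        for word, raw in corpus.lexicon.items():
            t = parse_transcription(raw, sv.inventory)
            for pattern in ("fronting", "stopping", "cluster_reduction"):
                r = score_word(word, t, pattern, sv)
                if r.pcc is None:
                    continue
                neutral = not r.applicable
                assert (r.pcc == 100.0) == neutral
                assert (r.lvn == 0.0) == neutral
                assert (r.pwp == 1.0) == neutral
                if neutral:
                    assert r.ipc_diff == 0 and r.wcm_diff == 0

    def test_delete_only_patterns_shrink_strings_by_deleted_chars(self, sv):
        corpus = generate_lexicon(FixtureSpec(n_types=40, seed=3))
        for word, raw in corpus.lexicon.items():
            t = parse_transcription(raw, sv.inventory)
            err, edits = apply_pattern(t, "cluster_reduction", sv)
            if edits.is_empty:
                continue
            deleted_chars = len(t.raw) - len(err.raw)
            assert levenshtein(t.raw, err.raw) == deleted_chars

    def test_pwp_bounded_for_non_inserting_patterns(self, sv):
        corpus = generate_lexicon(FixtureSpec(n_types=40, seed=23))
        for word, raw in corpus.lexicon.items():
            t = parse_transcription(raw, sv.inventory)
            for pattern in (
                "backing",
                "stopping",
                "weak_syllable_deletion",
                "cluster_reduction",
            ):
                r = score_word(word, t, pattern, sv)
                assert 0 < r.pwp <= 1
                assert r.pmlu_err <= r.pmlu_orig
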