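import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import log_odds_oracle
from speechphen.lexical import (
    GroupCounts,
    accumulate_counts,
    lexical_profile,
    weighted_log_odds,
)
from speechphen.transcript_io import parse_transcript


def _tr(text, group="HC", pid="p"):
    return parse_transcript(
        {
            "participant_id": pid,
            "group": group,
            "turns": [{"speaker": "I", "text": "Q?"}, {"speaker": "P", "text": text}],
        }
    )


class TestAccumulateCounts:
    def test_pronoun_pseudo_words(self):
        gc = accumulate_counts(
            [_tr("I am here.", "SSD", "a"), _tr("We are here.", "HC", "b")],
            ["SSD", "HC"],
        )
        d = dict(zip(gc.vocabulary, zip(gc.counts_a, gc.counts_b)))
        assert d["<PRON_1SG>"] == (1, 0)
        assert d["<PRON_1PL>"] == (0, 1)
        assert gc.n_a == 3 and gc.n_b == 3

    def test_incomplete_aggregated(self):
        gc = accumulate_counts(
            [_tr("sto- sto- stopped.", "SSD", "a"), _tr("fine.", "HC", "b")],
            ["SSD", "HC"],
        )
        d = dict(zip(gc.vocabulary, zip(gc.counts_a, gc.counts_b)))
        assert d["<INCOMPLETE>"] == (2, 0)
        assert "sto-" not in gc.vocabulary

    def test_disjoint_vocabularies_share_vocab(self):
        gc = accumulate_counts(
            [_tr("apple apple.", "SSD", "a"), _tr("banana.", "HC", "b")],
            ["SSD", "HC"],
        )
        d = dict(zip(gc.vocabulary, zip(gc.counts_a, gc.counts_b)))
        assert d["apple"] == (2, 0)
        assert d["banana"] == (0, 1)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="HC"):
            accumulate_counts([_tr("hi.", "SSD", "a")], ["SSD"])

    def test_interviewer_speech_not_counted(self):
        tr = parse_transcript(
            {
                "participant_id": "a",
                "group": "SSD",
                "turns": [
                    {"speaker": "I", "text": "zebra zebra zebra?"},
                    {"speaker": "P", "text": "yes."},
                ],
            }
        )
        gc = accumulate_counts([tr, _tr("no.", "HC", "b")], ["SSD", "HC"])
        assert "zebra" not in gc.vocabulary


class TestWeightedLogOdds:
    def test_symmetric_counts_zero_z(self):
        gc = GroupCounts(["a", "b"], [5, 7], [5, 7], 100, 100)
        for s in weighted_log_odds(gc, alpha0=50.0):
            assert s.delta == pytest.approx(0.0, abs=1e-15)
            assert s.z == pytest.approx(0.0, abs=1e-15)

    def test_one_sided_word_positive_z(self):
        gc = GroupCounts(["only_a", "both"], [10, 90], [0, 90], 100, 90)
        scores = {s.word: s for s in weighted_log_odds(gc, alpha0=10.0)}
        assert scores["only_a"].z > 0

    def test_against_high_precision_oracle(self):
        gc = GroupCounts(["w1", "w2"], [10, 990], [2, 998], 1000, 1000)
        scores = {s.word: s for s in weighted_log_odds(gc, alpha0=100.0)}
        oracle = log_odds_oracle([10, 990], [2, 998], 1000, 1000, 100.0)
        for (d_exp, z_exp), w in zip(oracle, ["w1", "w2"]):
            assert scores[w].delta == pytest.approx(d_exp, abs=1e-9)
            assert scores[w].z == pytest.approx(z_exp, abs=1e-9)

    def test_invalid_alpha0(self):
        gc = GroupCounts(["a"], [1], [1], 1, 1)
        with pytest.raises(ValueError):
            weighted_log_odds(gc, alpha0=0.0)

    def test_sorted_by_z_descending(self):
        gc = GroupCounts(["a", "b", "c"], [9, 1, 5], [1, 9, 5], 15, 15)
        zs = [s.z for s in weighted_log_odds(gc, alpha0=5.0)]
        assert zs == sorted(zs, reverse=True)

    def test_min_count_filter(self):
        gc = GroupCounts(["rare", "common"], [2, 50], [1, 50], 53, 51)
        words = {s.word for s in weighted_log_odds(gc, alpha0=5.0, min_count=5)}
        assert words == {"common"}

    def test_z_delta_variance_identity(self):
        gc = GroupCounts(["a", "b"], [3, 9], [7, 2], 12, 9)
        for s in weighted_log_odds(gc, alpha0=7.5):
            assert s.z == pytest.approx(s.delta / np.sqrt(s.variance), abs=1e-12)

    def test_antisymmetry_fixture(self):
        gc = GroupCounts(["a", "b", "c"], [4, 0, 9], [1, 6, 9], 13, 16)
        fwd = {s.word: s for s in weighted_log_odds(gc, alpha0=20.0)}
        rev = {s.word: s for s in weighted_log_odds(gc.swapped(), alpha0=20.0)}
        for w in gc.vocabulary:
            assert fwd[w].delta == -rev[w].delta
            assert fwd[w].z == -rev[w].z

    def test_regularization_shrinks_z(self):
        # adding a constant to every count (alpha0 fixed) shrinks |z| for a
        # moderately imbalanced word
        base = GroupCounts(["w", "x"], [12, 30], [4, 30], 42, 34)
        bumped = GroupCounts(["w", "x"], [112, 130], [104, 130], 242, 234)
        z0 = {s.word: abs(s.z) for s in weighted_log_odds(base, alpha0=10.0)}
        z1 = {s.word: abs(s.z) for s in weighted_log_odds(bumped, alpha0=10.0)}
        assert z1["w"] < z0["w"]


@settings(max_examples=200, deadline=None)
@given(
    counts=st.lists(
        st.tuples(st.integers(0, 50), st.integers(0, 50)), min_size=1, max_size=6
    ).filter(lambda c: sum(a + b for a, b in c) > 0),
    extra_a=st.integers(1, 100),
    extra_b=st.integers(1, 100),
    alpha0=st.floats(0.5, 500.0),
)
def test_oracle_equivalence_property(counts, extra_a, extra_b, alpha0):
    y_a = [a for a, _ in counts]
    y_b = [b for _, b in counts]
    n_a = sum(y_a) + extra_a
    n_b = sum(y_b) + extra_b
    vocab = [f"w{i}" for i in range(len(counts))]
    scores = {
        s.word: s for s in weighted_log_odds(GroupCounts(vocab, y_a, y_b, n_a, n_b), alpha0)
    }
    oracle = log_odds_oracle(y_a, y_b, n_a, n_b, alpha0)
    for w, expected in zip(vocab, oracle):
        if expected is None:
            assert w not in scores  # pooled-zero words are not scored
            continue
        d_exp, z_exp = expected
        assert scores[w].delta == pytest.approx(d_exp, abs=1e-9)
        assert scores[w].z == pytest.approx(z_exp, abs=1e-9)


@settings(max_examples=100, deadline=None)
@given(
    counts=st.lists(
        st.tuples(st.integers(0, 30), st.integers(0, 30)), min_size=1, max_size=5
    ).filter(lambda c: sum(a + b for a, b in c) > 0),
    alpha0=st.floats(1.0, 100.0),
)
def test_antisymmetry_property(counts, alpha0):
    y_a = [a for a, _ in counts]
    y_b = [b for _, b in counts]
    n_a, n_b = sum(y_a) + 5, sum(y_b) + 5
    vocab = [f"w{i}" for i in range(len(counts))]
    fwd = {s.word: s for s in weighted_log_odds(GroupCounts(vocab, y_a, y_b, n_a, n_b), alpha0)}
    rev = {s.word: s for s in weighted_log_odds(GroupCounts(vocab, y_b, y_a, n_b, n_a), alpha0)}
    for w in fwd:
        assert fwd[w].delta == pytest.approx(-rev[w].delta, abs=1e-12)
        assert fwd[w].z == pytest.approx(-rev[w].z, abs=1e-12)


class TestLexicalProfile:
    def test_rates_arithmetic(self):
        words = ["word"] * 197 + ["sto-", "bro-", "cra-"]
        tr = _tr(" ".join(words) + ".")
        prof = lexical_profile(tr)
        assert prof.token_total == 200
        assert prof.incomplete_rate == pytest.approx(1.5)
        assert prof.incomplete_count == 3

    def test_uh_um_ratio(self):
        tr = _tr("uh uh uh uh um filler words here.")
        assert lexical_profile(tr).uh_um_ratio == pytest.approx(0.8)

    def test_no_fillers_ratio_undefined(self):
        prof = lexical_profile(_tr("no fillers here."))
        assert prof.uh_um_ratio is None

    def test_laughter_excluded_from_denominator(self):
        prof = lexical_profile(_tr("one two three four. [laughter]"))
        assert prof.token_total == 4
        assert prof.laughter_rate == pytest.approx(25.0)

    def test_zero_tokens_errors(self):
        tr = parse_transcript(
            {"participant_id": "p", "turns": [{"speaker": "I", "text": "Q?"}]}
        )
        with pytest.raises(ValueError):
            lexical_profile(tr)

    def test_pronoun_rates(self):
        prof = lexical_profile(_tr("I we you he said ten word fill pad out."))
        assert prof.first_sg_rate == pytest.approx(10.0)
        assert prof.first_pl_rate == pytest.approx(10.0)
        assert prof.second_rate == pytest.approx(10.0)
        assert prof.third_rate == pytest.approx(10.0)


class TestRecovery:
    def test_pronoun_class_direction_recovered(self, preset_bundle):
        scores = preset_bundle.word_scores
        top10 = [s.word for s in scores[:10]]
        bottom10 = [s.word for s in scores[-10:]]
        assert "<PRON_1SG>" in top10  # group-A (SSD-like) side
        assert "<PRON_1PL>" in bottom10  # group-B (HC-like) side
        assert "<INCOMPLETE>" in top10
        by_word = {s.word: s.z for s in scores}
        assert by_word["uh"] > 0 > by_word["um"]
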