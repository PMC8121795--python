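import numpy as np
import pytest

from conftest import ols_closed_form
from speechphen.coherence import (
    TrajectoryPoint,
    fit_trajectory,
    mean_nsp,
    prompt_embedding,
    sentence_embedding,
    sentence_pairs,
    trajectory_points,
)
from speechphen.synthetic import TopicSpace, ToyEmbeddingBackend
from speechphen.transcript_io import (
    Sentence,
    Speaker,
    Turn,
    extract_exchanges,
    parse_transcript,
    tokenize,
)


def _sentence(text, speaker=Speaker.PARTICIPANT):
    return Sentence(tokens=tokenize(text), speaker=speaker)


class StubBackend:
    """Fixed word vectors + scripted pair probabilities."""

    def __init__(self, vectors, probs=None):
        self.vectors = vectors
        self.probs = probs or {}

    def embed_words(self, words):
        return np.vstack([self.vectors[w] for w in words])

    def next_sentence_probability(self, first, second):
        return self.probs[(tuple(first), tuple(second))]


class TestSentencePairs:
    def _tr(self, seq):
        return parse_transcript(
            {
                "participant_id": "p",
                "turns": [{"speaker": s, "text": t} for s, t in seq],
            }
        )

    def test_pairs_across_speakers(self):
        tr = self._tr([("I", "How are you?"), ("P", "Fine. Really fine.")])
        pairs = sentence_pairs(tr)
        assert len(pairs) == 2
        assert pairs[0][0].speaker is Speaker.INTERVIEWER
        assert pairs[1][0].text == "Fine"

    def test_interviewer_only_no_pairs(self):
        tr = self._tr([("I", "One. Two. Three.")])
        assert sentence_pairs(tr) == []

    def test_participant_initial_sentence_unpaired(self):
        tr = self._tr([("P", "Unprompted."), ("I", "Q?"), ("P", "A.")])
        pairs = sentence_pairs(tr)
        assert len(pairs) == 1
        assert pairs[0][1].text == "A"

    def test_pair_count_alternating(self):
        seq = [("I", "Q?"), ("P", "A.")] * 10
        assert len(sentence_pairs(self._tr(seq))) == 10


class TestMeanNSP:
    def test_unit_probabilities(self):
        s = _sentence("one two three four five six")
        backend = StubBackend({}, {(tuple(w.norm for w in s.tokens),) * 2: 1.0})
        pairs = [(s, s)] * 3
        prof = mean_nsp(pairs, backend)
        assert prof.mean_nsp == pytest.approx(1.0)

    def test_min_words_filter(self):
        long = _sentence("one two three four five six")
        short = _sentence("one two three")
        probs = {
            (tuple(t.norm for t in long.tokens), tuple(t.norm for t in long.tokens)): 1.0,
            (tuple(t.norm for t in long.tokens), tuple(t.norm for t in short.tokens)): 0.0,
        }
        backend = StubBackend({}, probs)
        prof = mean_nsp([(long, long), (long, short)], backend, min_words=5)
        assert prof.mean_nsp == pytest.approx(1.0)
        assert len(prof.pair_probabilities) == 1

    def test_length_weighted_mean(self):
        # probabilities [0.9, 0.6, 0.3] with second-sentence lengths [5,10,15]
        # -> weights [0.5, 1.0, 1.5] -> weighted mean exactly 0.5
        sents = [
            _sentence(" ".join(f"w{i}{j}" for j in range(n)))
            for i, n in enumerate([5, 10, 15])
        ]
        prev = _sentence("prompt words")
        probs = {}
        for s, p in zip(sents, [0.9, 0.6, 0.3]):
            probs[(tuple(t.norm for t in prev.tokens), tuple(t.norm for t in s.tokens))] = p
        backend = StubBackend({}, probs)
        prof = mean_nsp([(prev, s) for s in sents], backend, length_weighting=True)
        assert prof.mean_nsp == pytest.approx(0.5)

    def test_all_filtered_missing(self):
        short = _sentence("tiny")
        backend = StubBackend({}, {})
        prof = mean_nsp([(short, short)], backend, min_words=5)
        assert prof.mean_nsp is None

    def test_probability_bounds_enforced(self):
        s = _sentence("one two")
        backend = StubBackend({}, {(tuple(t.norm for t in s.tokens),) * 2: 1.5})
        with pytest.raises(ValueError):
            mean_nsp([(s, s)], backend)


class TestEmbeddings:
    def test_one_word_turn(self):
        v = np.array([1.0, 2.0, 3.0])
        turn = Turn(Speaker.INTERVIEWER, [_sentence("hello", Speaker.INTERVIEWER)])
        e = prompt_embedding(turn, StubBackend({"hello": v}))
        assert np.allclose(e, v)

    def test_opposite_vectors_cancel(self):
        v = np.array([1.0, -1.0])
        turn = Turn(
            Speaker.INTERVIEWER, [_sentence("up down", Speaker.INTERVIEWER)]
        )
        e = prompt_embedding(turn, StubBackend({"up": v, "down": -v}))
        assert np.allclose(e, 0.0)

    def test_three_word_mean(self):
        vs = {
            "a": np.array([1.0, 0.0]),
            "b": np.array([0.0, 3.0]),
            "c": np.array([2.0, 0.0]),
        }
        e = sentence_embedding(_sentence("a b c"), StubBackend(vs))
        assert np.allclose(e, [1.0, 1.0])

    def test_empty_turn_errors(self):
        turn = Turn(Speaker.INTERVIEWER, [_sentence("[name]", Speaker.INTERVIEWER)])
        with pytest.raises(ValueError):
            prompt_embedding(turn, StubBackend({}))


class TestTrajectoryPoints:
    def _exchange(self, prompt_text, responses):
        tr = parse_transcript(
            {
                "participant_id": "p",
                "turns": [
                    {"speaker": "I", "text": prompt_text},
                    {"speaker": "P", "text": " ".join(responses)},
                ],
            }
        )
        return extract_exchanges(tr)[0]

    def test_identical_response_zero_distance(self):
        v = {"alpha": np.array([1.0, 1.0]), "beta": np.array([2.0, 0.0])}
        ex = self._exchange("alpha beta?", ["alpha beta."])
        pts = trajectory_points(ex, StubBackend(v), metric="cosine")
        assert len(pts) == 1
        assert pts[0].position == 1
        assert pts[0].distance == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_response_distance_one(self):
        v = {"alpha": np.array([1.0, 0.0]), "omega": np.array([0.0, 1.0])}
        ex = self._exchange("alpha?", ["omega."])
        pts = trajectory_points(ex, StubBackend(v))
        assert pts[0].distance == pytest.approx(1.0)

    def test_unembeddable_sentence_skipped(self):
        v = {"alpha": np.array([1.0, 0.0])}
        ex = self._exchange("alpha?", ["alpha.", "[name].", "alpha."])
        pts = trajectory_points(ex, StubBackend(v))
        assert [p.position for p in pts] == [1, 3]

    def test_drifting_topics_increase_distance(self):
        # drift constructed from known topic mixtures, no jitter
        space = TopicSpace(topics=("A", "B"), word_topic={"aa": "A", "bb": "B"}, dim=2)
        backend = ToyEmbeddingBackend(space, jitter=0.0)
        ex = self._exchange(
            "aa aa aa?",
            ["aa aa aa aa.", "aa aa bb bb.", "aa bb bb bb.", "bb bb bb bb."],
        )
        pts = trajectory_points(ex, backend)
        dists = [p.distance for p in pts]
        assert dists == sorted(dists)
        assert dists[0] == pytest.approx(0.0, abs=1e-12)
        assert dists[-1] == pytest.approx(1.0, abs=1e-12)

    def test_metric_axioms(self):
        space = TopicSpace(topics=("A", "B"), word_topic={"aa": "A", "bb": "B"}, dim=2)
        backend = ToyEmbeddingBackend(space, jitter=0.02)
        x = sentence_embedding(_sentence("aa bb aa"), backend)
        from speechphen.coherence import _distance

        for metric in ("cosine", "euclidean", "mean_abs"):
            assert _distance(x, x, metric) == pytest.approx(0.0, abs=1e-12)
            y = sentence_embedding(_sentence("bb bb"), backend)
            assert _distance(x, y, metric) == pytest.approx(_distance(y, x, metric))


class TestFitTrajectory:
    def _pts(self, xy):
        return [TrajectoryPoint(0, x, y) for x, y in xy]

    def test_exact_collinear(self):
        fit = fit_trajectory(self._pts([(1, 0.2), (2, 0.3), (3, 0.4)]))
        assert fit.slope == pytest.approx(0.1, abs=1e-12)
        assert fit.intercept == pytest.approx(0.1, abs=1e-12)

    def test_constant_distances(self):
        fit = fit_trajectory(self._pts([(1, 0.5), (2, 0.5), (3, 0.5), (4, 0.5)]))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.5, abs=1e-12)

    def test_matches_closed_form(self):
        rng = np.random.default_rng(5)
        x = rng.integers(1, 8, size=40)
        y = 0.3 + 0.02 * x + rng.normal(0, 0.01, size=40)
        fit = fit_trajectory(self._pts(list(zip(x, y))))
        b0, b1 = ols_closed_form(x, y)
        assert fit.intercept == pytest.approx(b0, abs=1e-10)
        assert fit.slope == pytest.approx(b1, abs=1e-10)

    def test_ci_covers_generating_slope(self):
        rng = np.random.default_rng(42)
        x = np.tile(np.arange(1, 11), 5)  # 50 points
        y = 0.25 + 0.01 * x + rng.normal(0, 0.005, size=50)
        fit = fit_trajectory(self._pts(list(zip(x, y))))
        lo, hi = fit.ci95_slope
        assert lo < 0.01 < hi
        assert lo < fit.slope < hi
        assert fit.ci95_intercept[0] < fit.intercept < fit.ci95_intercept[1]

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_trajectory(self._pts([(1, 0.1), (2, 0.2)]))

    def test_degenerate_positions(self):
        with pytest.raises(ValueError):
            fit_trajectory(self._pts([(2, 0.1), (2, 0.2), (2, 0.3)]))


class TestGroupRecovery:
    def test_drift_group_slope_ci(self, preset_bundle):
        pooled = {"SSD": [], "HC": []}
        for pid, pts in preset_bundle.trajectory_points.items():
            pooled[preset_bundle.labels[pid]].extend(pts)
        fit_a = fit_trajectory(pooled["SSD"])
        fit_b = fit_trajectory(pooled["HC"])
        assert fit_a.ci95_slope[0] > 0  # drifting group: slope CI excludes 0
        assert fit_b.ci95_slope[0] < 0 < fit_b.ci95_slope[1]  # stationary
        assert fit_a.intercept > fit_b.intercept
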