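"""End-to-end orchestration: featurize -> analyze -> classify -> report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__, classify, coherence, lexical, pos, stats
from .synthetic import (
    GeneratorConfig,
    generate_corpus,
    null_preset,
    clinical_effects_preset,
    toy_backend,
)
from .transcript_io import Transcript, extract_exchanges, load_transcript

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "FeatureBundle",
    "StudyReport",
    "featurize_corpus",
    "word_aggregate_scores",
    "run",
]

PRESETS = {"clinical_effects": clinical_effects_preset, "null": null_preset}
DEFAULT_COVARIATES = ("age", "sex", "race", "education_years", "cohort")


@dataclass
class RunConfig:
    """Resolved run options; every field has a recorded default."""

    input_dir: str | None = None
    ratings_csv: str | None = None
    preset: str = "clinical_effects"
    n_per_group: int = 15
    backend: str = "toy"  # "toy" | "transformer:<model-name>"
    metric: str = "cosine"
    alpha0: float = 100.0
    min_word_count: int = 5
    nsp_min_words: int = 0
    nsp_length_weighting: bool = False
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    feature_sets: tuple[str, ...] = ("clinical", "nlp", "combined")
    cv_scheme: str = "loo"
    kfold_k: int = 5
    seed: int = 0
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        for k in ("covariates", "feature_sets"):
            if k in kwargs and isinstance(kwargs[k], list):
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)

    def validate(self) -> None:
        if self.preset not in PRESETS and self.input_dir is None:
            raise ValueError(f"unknown preset {self.preset!r} and no input_dir")
        needs_ratings = any(fs.startswith(("clinical", "combined")) for fs in self.feature_sets)
        if self.input_dir is not None and needs_ratings and self.ratings_csv is None:
            raise ValueError(
                "clinical/combined feature sets requested but no ratings_csv given"
            )
        if not self.backend.startswith(("toy", "transformer:")):
            raise ValueError(f"unknown backend {self.backend!r}")


def _make_backend(config: RunConfig):
    if config.backend == "toy":
        return toy_backend(seed=config.seed)
    if config.backend.startswith("transformer:"):  # pragma: no cover - optional
        from .transformer_backend import TransformerBackend

        return TransformerBackend(config.backend.split(":", 1)[1])
    raise ValueError(f"unknown backend {config.backend!r}")


@dataclass
class FeatureBundle:
    """Per-participant profiles from every analysis level."""

    labels: dict[str, str]
    lexical: dict[str, lexical.LexicalProfile]
    pos: dict[str, pos.POSProfile]
    coherence: dict[str, coherence.CoherenceProfile]
    trajectories: dict[str, coherence.TrajectoryFit | None]
    trajectory_points: dict[str, list[coherence.TrajectoryPoint]]
    word_scores: list[lexical.WordScore]
    word_aggregate: dict[str, float]
    covariates: pd.DataFrame  # index = participant_id
    ratings: dict[str, stats.ClinicalRatings]


def word_aggregate_scores(
    transcripts: Sequence[Transcript], scores: Sequence[lexical.WordScore]
) -> dict[str, float]:
    """Per-participant aggregate of word-level z-scores.

    Sum over scored words of z_w times the participant's relative usage of
    the word — a single-number reconstruction of "how SSD-flavoured" a
    participant's vocabulary is.
    """
    z = {s.word: s.z for s in scores}
    out = {}
    for tr in transcripts:
        words = lexical._token_words(tr.participant_tokens())
        total = tr.participant_word_count
        acc = 0.0
        for w in words:
            if w in z:
                acc += z[w]
        out[tr.participant_id] = acc / total if total else 0.0
    return out


def featurize_corpus(
    transcripts: Sequence[Transcript],
    ratings: Sequence[stats.ClinicalRatings] | None,
    config: RunConfig,
    backend=None,
    tagger: pos.TaggerBackend | None = None,
) -> FeatureBundle:
    """Compute every per-participant profile for a corpus."""
    backend = backend if backend is not None else _make_backend(config)
    tagger = tagger if tagger is not None else pos.LexiconTagger()

    labels = {t.participant_id: t.group for t in transcripts}
    lex_profiles = {t.participant_id: lexical.lexical_profile(t) for t in transcripts}
    pos_profiles = {t.participant_id: pos.pos_profile(t, tagger) for t in transcripts}

    coh_profiles = {}
    traj_fits: dict[str, coherence.TrajectoryFit | None] = {}
    traj_points = {}
    for t in transcripts:
        pairs = coherence.sentence_pairs(t)
        coh_profiles[t.participant_id] = coherence.mean_nsp(
            pairs,
            backend,
            min_words=config.nsp_min_words,
            length_weighting=config.nsp_length_weighting,
            participant_id=t.participant_id,
        )
        pts = coherence.participant_trajectory_points(
            extract_exchanges(t), backend, metric=config.metric
        )
        traj_points[t.participant_id] = pts
        positions = {p.position for p in pts}
        if len(pts) >= 3 and len(positions) >= 2:
            traj_fits[t.participant_id] = coherence.fit_trajectory(pts)
        else:
            traj_fits[t.participant_id] = None

    gc = lexical.accumulate_counts(
        transcripts, [labels[t.participant_id] for t in transcripts]
    )
    scores = lexical.weighted_log_odds(
        gc, alpha0=config.alpha0, min_count=config.min_word_count
    )
    aggregate = word_aggregate_scores(transcripts, scores)

    cov = pd.DataFrame.from_dict(
        {
            t.participant_id: {
                "age": t.metadata.get("age"),
                "sex": t.metadata.get("sex"),
                "race": t.metadata.get("race"),
                "education_years": t.metadata.get("education_years"),
                "cohort": t.cohort,
            }
            for t in transcripts
        },
        orient="index",
    )
    return FeatureBundle(
        labels=labels,
        lexical=lex_profiles,
        pos=pos_profiles,
        coherence=coh_profiles,
        trajectories=traj_fits,
        trajectory_points=traj_points,
        word_scores=scores,
        word_aggregate=aggregate,
        covariates=cov,
        ratings={r.participant_id: r for r in (ratings or [])},
    )


@dataclass
class StudyReport:
    descriptives: dict
    pos_comparison: list[dict]
    lexical_comparison: list[dict]
    word_scores: list[dict]
    nsp_model: dict | None
    trajectory_fits: dict
    classification: list[dict]
    stage_errors: dict[str, str]
    manifest: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=1)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _group_values(bundle: FeatureBundle, getter) -> tuple[list[float], list[str]]:
    pids = sorted(bundle.labels)
    return [getter(pid) for pid in pids], [bundle.labels[pid] for pid in pids]


def _result_dict(r: stats.GroupTestResult) -> dict:
    return {
        "feature": r.feature,
        "test": r.test,
        "statistic": r.statistic,
        "p": r.p_value,
        "d": r.cohens_d,
        "covariates": list(r.covariates),
    }


def _load_corpus(config: RunConfig):
    if config.input_dir is not None:
        paths = sorted(Path(config.input_dir).glob("*.json"))
        if not paths:
            raise ValueError(f"no transcript JSON files in {config.input_dir}")
        transcripts = [load_transcript(p) for p in paths]
        ratings = (
            stats.read_ratings_csv(config.ratings_csv) if config.ratings_csv else []
        )
        return transcripts, ratings
    gen: GeneratorConfig = PRESETS[config.preset](
        seed=config.seed, n_per_group=config.n_per_group
    )
    return generate_corpus(gen)


def run(config: RunConfig) -> StudyReport:
    """Execute all pipeline stages; independent stage failures are recorded
    per stage in the report instead of aborting the run."""
    config.validate()
    transcripts, ratings = _load_corpus(config)
    bundle = featurize_corpus(transcripts, ratings, config)
    pids = sorted(bundle.labels)
    groups = [bundle.labels[p] for p in pids]
    cov = bundle.covariates.loc[pids][list(config.covariates)]
    errors: dict[str, str] = {}

    # descriptives -----------------------------------------------------------
    desc: dict = {}
    for grp in sorted(set(groups)):
        sel = [p for p in pids if bundle.labels[p] == grp]
        words = [bundle.lexical[p].token_total for p in sel]
        desc[grp] = {
            "n": len(sel),
            "word_count_mean": float(pd.Series(words).mean()),
            "education_mean": float(cov.loc[sel, "education_years"].mean()),
            "age_mean": float(cov.loc[sel, "age"].mean()),
        }
        if bundle.ratings:
            desc[grp]["tlc_total_mean"] = float(
                pd.Series([bundle.ratings[p].total for p in sel]).mean()
            )
            desc[grp]["tlc_global_mean"] = float(
                pd.Series([bundle.ratings[p].global_score for p in sel]).mean()
            )
    if bundle.ratings and len(set(groups)) == 2:
        g_a, g_b = "SSD", "HC"
        a = [bundle.ratings[p].total for p in pids if bundle.labels[p] == g_a]
        b = [bundle.ratings[p].total for p in pids if bundle.labels[p] == g_b]
        try:
            stat, p_val = stats.wilcoxon_rank_sum(a, b)
            desc["tlc_total_wilcoxon"] = {"statistic": stat, "p": p_val}
        except ValueError as exc:
            errors["descriptives.wilcoxon"] = str(exc)

    # POS + lexical comparisons ---------------------------------------------
    pos_rows, lex_rows = [], []
    try:
        for cat in pos.POS_CATEGORIES:
            vals, grp = _group_values(bundle, lambda p, c=cat: bundle.pos[p].rates[c])
            pos_rows.append(
                _result_dict(
                    stats.ancova_group_effect(vals, grp, cov, feature=f"pos_{cat}")
                )
            )
        for name, getter in (
            ("incomplete_rate", lambda p: bundle.lexical[p].incomplete_rate),
            ("first_sg_rate", lambda p: bundle.lexical[p].first_sg_rate),
            ("first_pl_rate", lambda p: bundle.lexical[p].first_pl_rate),
            (
                "uh_um_ratio",
                lambda p: (
                    bundle.lexical[p].uh_um_ratio
                    if bundle.lexical[p].uh_um_ratio is not None
                    else float("nan")
                ),
            ),
        ):
            vals, grp = _group_values(bundle, getter)
            lex_rows.append(
                _result_dict(stats.ancova_group_effect(vals, grp, cov, feature=name))
            )
    except ValueError as exc:
        errors["group_comparisons"] = str(exc)

    # sentence level ---------------------------------------------------------
    nsp_model = None
    try:
        vals, grp = _group_values(
            bundle,
            lambda p: (
                bundle.coherence[p].mean_nsp
                if bundle.coherence[p].mean_nsp is not None
                else float("nan")
            ),
        )
        nsp_model = _result_dict(
            stats.group_linear_model(vals, grp, cov, feature="mean_nsp")
        )
    except ValueError as exc:
        errors["nsp_model"] = str(exc)

    traj = {}
    try:
        for grp_name in sorted(set(groups)):
            pooled = [
                pt
                for p in pids
                if bundle.labels[p] == grp_name
                for pt in bundle.trajectory_points[p]
            ]
            fit = coherence.fit_trajectory(pooled)
            traj[grp_name] = {
                "intercept": fit.intercept,
                "slope": fit.slope,
                "ci95_intercept": list(fit.ci95_intercept),
                "ci95_slope": list(fit.ci95_slope),
                "n_points": fit.n_points,
            }
    except ValueError as exc:
        errors["trajectory"] = str(exc)

    # classification ---------------------------------------------------------
    cls_rows = []
    for fs in config.feature_sets:
        try:
            matrix = classify.build_features(
                labels=bundle.labels,
                feature_set=fs,
                ratings=bundle.ratings or None,
                lexical=bundle.lexical,
                pos=bundle.pos,
                coherence=bundle.coherence,
                trajectories=bundle.trajectories,
                word_aggregate=bundle.word_aggregate,
                education=cov["education_years"].to_dict(),
            )
            res = classify.cross_validate_nb(
                matrix, scheme=config.cv_scheme, k=config.kfold_k, seed=config.seed
            )
            cls_rows.append(
                {
                    "feature_set": fs,
                    "cv_scheme": res.cv_scheme,
                    "auc": res.auc,
                    "accuracy": res.accuracy,
                }
            )
        except ValueError as exc:
            errors[f"classify.{fs}"] = str(exc)

    config_dict = config.to_dict()
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config_dict,
        "config_hash": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
    }
    report = StudyReport(
        descriptives=desc,
        pos_comparison=pos_rows,
        lexical_comparison=lex_rows,
        word_scores=[
            {"word": s.word, "count_a": s.count_a, "count_b": s.count_b, "z": s.z}
            for s in bundle.word_scores[:25] + bundle.word_scores[-25:]
        ],
        nsp_model=nsp_model,
        trajectory_fits=traj,
        classification=cls_rows,
        stage_errors=errors,
        manifest=manifest,
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.save(out / "report.json")
        lexical.write_word_scores(bundle.word_scores, out / "word_scores.csv")
        pos.write_pos_profiles(
            [bundle.pos[p] for p in pids], out / "pos_profiles.csv"
        )
    return report
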