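# speechphen

Linguistic phenotyping of diarized clinical interview speech, on three
levels:

- **Words** — group word-usage comparison with a weighted log-odds statistic
  under an informative Dirichlet prior (pronoun classes and incomplete words
  additionally pooled into pseudo-words), plus per-participant disfluency
  and pronoun rates.
- **Parts of speech** — per-100-word rates for ten coarse POS categories
  through a pluggable tagger backend (hermetic closed-lexicon rule tagger
  built in; spaCy optional).
- **Sentences** — next-sentence probabilities aggregated per participant,
  and prompt-anchored embedding-distance trajectories (distance of each
  response sentence from the interviewer prompt, by position) with OLS
  intercept/slope fits and 95% CIs. Backends are pluggable: a seeded
  deterministic topic-space toy embedder ships with the package; a
  pretrained transformer backend is an optional plug-in.

On top of those sit a group-statistics harness (Shapiro–Wilk, Wilcoxon
rank-sum, boxplot outlier flagging, ANCOVA with demographic covariates,
Cohen's d, TLC score arithmetic) and a Gaussian naive Bayes discrimination
harness with leave-one-out / stratified k-fold cross-validation reporting
AUC and accuracy.

Because no clinical recordings ship with the package, `speechphen.synthetic`
generates fully deterministic two-group corpora with controllable effects
(pronoun-class mix, POS mix, uh:um ratio, incomplete-word rate, response
topic drift, TLC-like zero-inflated ratings). Every test runs hermetically
on this generator — no downloads, no external data.

## CLI

```bash
# synthesize a corpus (transcript JSONs + ratings CSV)
speechphen simulate --preset clinical_effects --seed 1 --n 15 -o corpus/

# per-participant features, group statistics, classification
speechphen featurize corpus/ --ratings corpus/ratings.csv -o features/
speechphen analyze   corpus/ --ratings corpus/ratings.csv -o analysis/
speechphen classify  corpus/ --ratings corpus/ratings.csv -o cls/

# everything in one go (also accepts --config run.yaml)
speechphen run-all --preset clinical_effects --seed 1 --n 15 -o run/
```

Transcripts use a simple JSON schema (`{participant_id, group, cohort,
metadata, turns: [{speaker: "I"|"P", text}]}`); a reader for
Transcriber-style XML is included (`speechphen.transcript_io.read_transcriber_xml`).

## Layout

| module | contents |
| --- | --- |
| `speechphen.transcript_io` | transcript data model, tokenizer (fillers, incomplete words, laughter, redactions), sentence splitting, dialogue-exchange extraction, JSON/XML readers |
| `speechphen.lexical` | group counts, Dirichlet-prior weighted log-odds, lexical profiles |
| `speechphen.pos` | tagger backends and POS rate profiles |
| `speechphen.coherence` | NSP aggregation, trajectory points and OLS fits |
| `speechphen.stats` | normality/rank tests, outliers, ANCOVA, effect sizes, TLC totals |
| `speechphen.classify` | feature assembly, fold-safe preprocessing, cross-validated naive Bayes, AUC |
| `speechphen.synthetic` | corpus generator, topic space, toy embedding backend, presets |
| `speechphen.pipeline` | orchestration, run manifest, study report |
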