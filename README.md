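# lesionspeech

A tested, reusable pipeline for lesion–behaviour analysis of challenging
speech comprehension, covering two listening challenges:

1. **Acoustic degradation** — noise-vocoded sentence perception and
   adaptation, measured by order-sensitive word report and summarised as the
   channel threshold of a logistic psychometric function (guess rate fixed
   at 0, lapse rate fixed per participant from clear-speech accuracy).
2. **Semantic ambiguity** — sentence coherence judgements (d′ with boundary
   corrections, deviation-coded accuracy and log10-RT models, per-participant
   residual ambiguity effects) and word-meaning priming in a subsequent word
   association task (priming × dominance logistic model, residual priming
   effects).

Behavioural measures are correlated with lesion volumes inside two
functionally defined brain networks (probabilistic activation maps
thresholded at 5%), with one-tailed Pearson tests and two-tailed Meng's z
comparisons of dependent correlations. A synthetic-data module generates
cohorts, trial tables, toy audio and toy imaging volumes with the full
statistical structure the analysis assumes, so every stage is testable
without any external data.

## Layout

| module | role |
|---|---|
| `lesionspeech.synth` | synthetic cohorts, trial tables, toy audio/volumes |
| `lesionspeech.vocoder` | noise vocoding (log-spaced channels, 30 Hz envelopes) |
| `lesionspeech.scoring` | order-sensitive word-report scoring (LCS) |
| `lesionspeech.psychometrics` | logistic psychometric fits, channel thresholds |
| `lesionspeech.coherence` | exclusions, d′, condition models, residual effects |
| `lesionspeech.priming` | priming exclusions, priming × dominance model |
| `lesionspeech.lesion` | lesion volume within thresholded network maps |
| `lesionspeech.stats` | one-tailed Pearson r, Fisher z, Meng's z |
| `lesionspeech.pipeline` | end-to-end orchestration and reporting |

## CLI

```bash
# generate a synthetic cohort plus all trial tables (CSV)
lesionspeech synth --seed 1 --n-participants 19 --out data/

# noise-vocode a mono WAV into 8 channels
lesionspeech vocode --channels 8 --lo 50 --hi 8000 --cutoff 30 --seed 1 in.wav out.wav

# score word reports (CSV with target_text,response_text columns)
lesionspeech score reports.csv scored.csv

# fit psychometric curves (CSV: participant,phase,channels,k_correct,n_words)
lesionspeech fit-psych word_report.csv fits.csv

# coherence-judgement and priming analyses
lesionspeech coherence data/coherence.csv out/
lesionspeech priming data/association.csv data/coherence.csv out/

# lesion volume within thresholded probabilistic maps (NIfTI)
lesionspeech lesion-overlap --map lang.nii --map md.nii --threshold 0.05 lesions/*.nii

# full synthetic pipeline with a JSON report
lesionspeech run-all --seed 1 --n-participants 200 --out report.json
```

## Notes

- All generators are deterministic given a seed; every module draws from a
  named substream so tables can be regenerated independently.
- The mixed-effects models are approximated by fixed-intercept G/LMs behind
  a pluggable engine boundary; the design matrix, deviation coding
  (±1/2 contrasts), exclusion rules and residual-effect definitions — the
  substantively meaningful parts — are owned by this package.
- No multiple-testing correction is applied to the correlation tables; this
  is flagged in the report metadata.
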