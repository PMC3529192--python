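# closecall

Synthesis and statistical analysis of short two-segment ("close") calls:
an initial broadband **noisy segment** carrying a stable per-individual
spectral signature, followed by a tonal **harmonic segment** whose
duration and fundamental frequency grade with the caller's behavioral
context (digging / searching / moving).

The package covers the full workflow:

1. **`closecall.synth`** — synthetic WAV generator (PCM 16-bit, 44.1 kHz)
   with controllable individual, group, context, and (null) sex
   structure, plus an exact segment-annotation table.
2. **`closecall.acoustics`** — 1,024-point Hamming spectrograms
   (96.87 % overlap, 43 Hz bins) and the 14 per-segment parameters:
   duration, −20 dB bandwidth / min / max frequency, mean F0 and the
   onset/offset F0 transitions, mean-spectrum peak frequency, and the
   25/50/75 % energy quartiles from both the mean spectrum and the
   maximum-amplitude frame.
3. **`closecall.collinearity`** — variance inflation factors computed
   under the mixed-model structure (random intercepts for group and
   individual-within-group) with greedy elimination at VIF ≤ 2.5.
4. **`closecall.dfa`** — linear discriminant analysis, leave-one-out
   cross-validation, and best-first stepwise variable selection with an
   absolute 5 %-improvement stopping rule.
5. **`closecall.inference`** — bootstrap chance correction for CV-values
   and the crossed permuted DFA (pDFA) whose test statistic, *ncce*
   (number of correctly cross-classified elements, reported as a
   percentage of cross-set elements), is averaged over balanced
   training/cross-set selections; permutations respect the repeated
   sampling of individuals nested in groups.
6. **`closecall.pipeline`** — end-to-end orchestration
   (simulate/ingest → extract → VIF → stepwise DFA →
   bootstrap/pDFA) with inclusion rules (≥ 5 calls in ≥ 2 contexts,
   down-sampling to 5 calls per cell) and text + JSON reports.

## CLI

```bash
closecall simulate --out data/ --seed 1              # WAVs + annotations.csv
closecall extract  --annotations data/annotations.csv --out features.csv
closecall vif      --features features.csv --segment noisy --out vif.txt
closecall dfa      --features features.csv --segment noisy \
                   --classify-by individual_id --out dfa.txt
closecall pdfa     --features features.csv --segment harmonic \
                   --test-factor context --out pdfa.txt
closecall run      --out run/ --seed 1               # full pipeline
```

`simulate` and `run` accept a YAML config (`--config`) overriding any
field of `SyntheticConfig` / `PipelineConfig`; see the dataclasses for
the schema.

## Notes

- The default synthetic calibration reproduces the qualitative
  dissociation the analysis is designed to detect: individual identity
  classifiable from the noisy segment (all groups significant), context
  classifiable from the harmonic segment but not from the noisy one, and
  mean harmonic duration strictly ordered digging < searching < moving.
- Everything is deterministic given a seed; the pipeline derives
  per-stage generators from the master seed.
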