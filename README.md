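# vigilfc

Vigilance-state-conditioned seed-based functional connectivity (FC)
analysis, exercised end-to-end on synthetic multi-subject studies with
planted effects and known ground truth.

The pipeline covers:

- **Synthetic studies** (`vigilfc.synthetic`): a latent alert/drowsy
  two-state Markov chain (1-s steps) jointly drives EEG band powers
  (occipital alpha when alert, delta/theta when drowsy), BOLD parcel
  time series with a state-switched loading on a shared global factor
  (planting a known drowsy-minus-alert Fisher-z shift on a support
  mask), a respiratory waveform with NaN dropout segments, a pulse
  train with IBI jitter/outliers, and a pupil trace with zero-valued
  closures.
- **Physio features** (`vigilfc.physio`): respiratory volume (6-s
  sliding-window SD, missing when ≥ 20% of in-window samples are
  missing), beat detection, single-pass IBI outlier interpolation
  (2.5 SD cutoff), heart rate (1/median in-window IBI), and per-window
  percent eye closure (4-s forward shift, logit transform).
- **Vigilance staging** (`vigilfc.staging`): per-second band-power
  staging into five ordered stages (5 = most alert … 1 = most drowsy),
  then epoch labeling: Wilcoxon signed-rank z of the stage integers
  against a center of 2.75 per 30-volume epoch, ±1.5 threshold,
  same-state concatenation, 5-s forward shift.
- **Signal conditioning** (`vigilfc.conditioning`): Legendre detrending
  (order 4), zero-phase 0.01–0.15 Hz Butterworth band-pass, and three
  confound pipelines (mCSF/WM tissue means; aCompCor principal
  components; RV/HR convolved with 5-function response bases).
- **Connectivity** (`vigilfc.connectivity`): seed extraction, static /
  per-epoch / sliding-window (4-min, 50% overlap) seed-to-target
  correlation maps with Fisher r-to-z.
- **Group inference** (`vigilfc.inference`): random-intercept linear
  mixed-effects models fitted by profiled REML (group-mean, two-state
  with epoch-length covariate, single-state with centered covariate),
  BH-FDR, and dual thresholding (top 40% of |t| in GM ∩ FDR p < 0.05)
  into signed maps.
- **Map comparison** (`vigilfc.comparison`): multiclass (signed) Dice
  with poor/moderate/good banding and the signed Szymkiewicz–Simpson
  template overlap.
- **State clustering** (`vigilfc.clustering`): city-block k-medians over
  windowed FC maps, silhouette-based k selection, canonical state
  numbering (state 2 = drowsier), and the LME state-vs-vigilance test.
- **Orchestration** (`vigilfc.pipeline`, `vigilfc.cli`, `vigilfc.io`,
  `vigilfc.config`): in-memory stage runners, TSV/JSON/NIfTI I/O, and a
  YAML-configured CLI.

## CLI

```bash
vigilfc simulate --out study/ --seed 1            # synthetic study on disk
vigilfc run-static  --study study/ --out out/     # group-mean signed map
vigilfc run-state   --study study/ --out out/     # alert/drowsy epoch maps
vigilfc run-cluster --study study/ --out out/     # windowed-FC k-medians states
vigilfc compare out/a_signed.tsv out/b_signed.tsv --out cmp.tsv
vigilfc report out/
```

All commands accept `--config config.yaml` (see
`vigilfc.config.PipelineConfig` for the keys); every run freezes the
resolved config and tool version next to its outputs.

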