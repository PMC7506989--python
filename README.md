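# imbef

Automatic sleep-stage classification from a single EEG channel, built on
*model-based essence features*: wavelet-packet sub-band energies fused with
the parameters of dual state-space models.

## Who this is for

Sleep researchers and biomedical-signal engineers who score polysomnography
epochs (20–30 s windows of one EEG derivation, e.g. Pz–Oz or Cz–A1) into the
R&K stages (Awa, REM, S1–S4) or the AASM stages (Awa, REM, N1–N3), and who
want a transparent, fully classical feature pipeline rather than a deep
network.

## The method

For an epoch `X_i` of `j = Te × Fs` samples (0–35 Hz low-passed, zero
phase):

1. **Locality energies (LE).** A full wavelet-packet tree (periodized,
   orthonormal wavelet `ω_LE`) expands the epoch to level `l_LE`, giving
   `2^l_LE` sub-bands `C_{l,m}` of length `j / 2^l_LE`. The feature is the
   per-node energy `E_m = Σ_d |p_{l,m}(d)|²`.
2. **Dual state-space models (DSSM).** The two *first-level* packet
   coefficient series (wavelet `ω_DSSM`) are each fitted with an order-`n`
   innovation-form model

       u_{k+1} = A u_k + K e_k,      y_k = B u_k + e_k,

   by an output-only subspace algorithm (block-Hankel projection, CVA-weighted
   SVD, shift-invariance). The entries of `(Â, B̂, K̂)` — canonicalized so the
   same series always yields the same matrices — are the features:
   `s_m = [vec(Â) ‖ B̂ ‖ K̂]`, length `n² + 2n` per sub-band.
3. **Fusion.** The epoch's feature vector is `[E_1 … E_{2^l_LE} ‖ s_1 ‖ s_2]`
   with dimension `2^l_LE + 2(n² + 2n)` — 128 at the selected operating point
   (`ω_DSSM = db1`, `n = 6`, `ω_LE = db4`, `l_LE = 5`).
4. **Classification.** Bagged decision trees (30 bootstrap trees), evaluated
   by 10-fold cross-validation; accuracy is the pooled out-of-fold
   `trace/total`, agreement is Cohen's kappa `(p_o − p_e)/(1 − p_e)`.

Parameter selection is a two-step exhaustive grid (15 orthogonal wavelet
candidates; orders 5–10; levels 3–7), first over the model block alone, then
over the energy block with the model block frozen (`imbef.search_*`).

## Worked example

```sh
python examples/synthetic_pipeline.py
```

```
epochs            : 300 x 3840 samples (30 s at 128 Hz)
feature table     : 300 x 128 (dimension = 2^5 + 2*(6^2+2*6) = 128)
pooled CV accuracy: 100.00%
Cohen's kappa     : 1.0000
per-class recall  : Awa=100.0%  REM=100.0%  N1=100.0%  N2=100.0%  N3=100.0%
```

The 300 epochs come from the built-in five-stage synthetic generator, whose
stage profiles (alpha/beta-rich wake down to high-amplitude delta deep
sleep) are deliberately well separated — the perfect score certifies the
pipeline's plumbing, not real-world performance. On real recordings the hard
class is N1/S1; `examples/metrics_from_confusion.py` recomputes the metrics
of a published five-class evaluation (8889 epochs):

```
overall accuracy  : 81.65%   (diagonal / total)
Cohen's kappa     : 0.7629  (chance-corrected agreement)
sensitivity N1    : 57.70%
```

Other examples: `sysid_recovery.py` (subspace estimation recovers the poles
of a known generator) and `grid_search.py` (the two-step parameter search on
synthetic data). A thin CLI wraps the same library:

```sh
imbef synth --out rec.edf --n-per-stage 20
imbef extract-features --edf rec.edf --hypnogram rec.hyp.txt --out feat.csv
imbef evaluate --features feat.csv --report report.json
imbef metrics --confusion confusion.csv
```

## Layout

```
src/imbef/          signal_io, preprocess, wpd, sysid, features,
                    classify, search, synth, config, cli, datasets
examples/           one short narrative script per capability
tests/              pytest suite (unit, property and acceptance tests)
scripts/acceptance.py
docs/methods.md     model, assumptions, numerical choices, limitations
```
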