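# meg-seqmem

Synthetic-MEG analysis of auditory sequence recognition: who recognizes a
melody, with which brain regions, in which frequency band — and how do you
test that properly with mass-univariate statistics?

The package is an end-to-end, fully offline re-implementation of a
recognition-memory MEG pipeline for researchers who want to exercise,
validate, or teach the statistical machinery of such studies without any
data download. It simulates an old/new paradigm — subjects memorize a tonal
musical piece and an atonal counterpart, then classify five-tone excerpts
(250 ms/tone) as memorized or novel — and analyzes the simulated cohort
exactly the way a real one would be analyzed.

Core components:

* **Stimuli** — tonal→atonal pitch-class remapping (±1–2 semitones,
  uniform across octaves) and an order-n additive-smoothed n-gram model of
  melodic expectation: per-tone information content
  `IC = log₂ 1/p(e|context)` and entropy `H = Σ p·IC` in bits.
* **Simulator** — spherical head, analytic single-sphere current-dipole
  forward model (306-channel planar-gradiometer + magnetometer array),
  condition- and band-specific regional effects, 1/f + white sensor noise,
  behavioral accuracy/RT and familiarity ratings for a full cohort.
* **Preprocessing** — zero-phase Butterworth band-pass (0.1–1, 2–8, 1–4,
  5–8 Hz), −100…+1250 ms epochs with baseline correction, correct-trials-
  only selection, condition averaging, root-sum-square planar combination.
* **Cluster statistics** — the binarize → connected-components →
  permutation-of-the-binarized-map → maximum-cluster-size Monte-Carlo
  procedure (p = (1+#{null≥k})/(1+n_perm), strict-quantile significance),
  verified against exhaustive enumeration on small lattices.
* **Sensor & source level** — pointwise paired t-maps on the 2D layout;
  unit-gain scalar LCMV beamformer (`w = C⁻¹l/(lᵀC⁻¹l)`), two-level GLM,
  per-tone-window 3D cluster correction at α = 0.01/10 = 0.001, piece and
  band contrasts, familiarity Pearson maps.
* **Behavior** — one-way ANOVAs across the four conditions and Bonferroni
  post-hocs at adjusted α = 0.0125.

See `docs/methods.md` for the model, parameter defaults, and limitations.

## Worked example

Run the numbered analyses (each is a thin driver over the library and
writes TSV/JSON tables under `results/`):

```bash
python analysis/01_stimulus_complexity.py
python analysis/02_run_pipeline.py       # full desk-scale cohort, ~40 s
python analysis/03_behavioral_summary.py
python analysis/04_sensor_clusters.py
python analysis/05_source_dissociation.py
```

`01` trains the n-gram on the built-in diatonic corpus and compares the 40
tonal excerpts with their atonal remappings:

```
IC (bits): tonal 3.08 vs atonal 4.68  (paired t=-11.43, df=199, p=1.3e-23)
H  (bits): tonal 3.42 vs atonal 3.74  (paired t=-10.19, df=199, p=6.8e-20)
```

Atonal excerpts are less predictable (higher IC and H): the remapping moves
tones off the learned diatonic transition structure.

`05` runs the slow-band (0.1–1 Hz) memorized-vs-novel source analysis on a
simulated 12-subject cohort and checks the built-in ground truth — a
hippocampus/cingulate effect at tone windows 3–5 for the tonal piece and a
right-auditory effect at all windows for the atonal piece:

```
=== tonal: significant memorized>novel clusters ===
 window  size  roi_majority  p_value
      3    41     cingulate 0.000999
      3    37 hippocampus_L 0.000999
      4    49     cingulate 0.000999
      4    41 hippocampus_L 0.000999
      5    42     cingulate 0.000999
      5    16 hippocampus_L 0.000999
...
=== atonal: significant memorized>novel clusters ===
 window  size roi_majority  p_value
      1   113   auditory_R 0.000999
      ...
      5    54   auditory_R 0.000999

dissociation recovered: True
```

Memory-region clusters appear only late in the tonal sequences while the
auditory effect spans all atonal windows — the simulated dissociation comes
back out of the full pipeline (filters → beamformer → GLM → cluster
correction), with cluster p-values at the permutation floor 1/1001.

A `meg-seqmem` CLI wraps the same functionality
(`meg-seqmem run-all --seed 1 --out results/run`,
`meg-seqmem simulate …`, `meg-seqmem stimuli ic …`).

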