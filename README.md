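# dichopt

Analysis pipelines for studying how amblyopia ("lazy eye") degrades
monocular and binocular vision at two complementary scales:

* **Laminar fMRI** — depth-resolved BOLD responses on a submillimeter
  cortical ribbon: equivolume cortical depth, equal-volume layer
  compartments, large-vein exclusion, block-design GLM in percent signal
  change, and the **amblyopic deficit index** per layer, plus an
  **inverted encoding model** (IEM) that unmixes the two eyes' signals in
  each voxel and yields a laminar **binocular suppression index**.
* **SSVEP EEG** — dichoptic frequency tagging at 7.2 and 8 Hz: zero-phase
  filtering, surface-Laplacian referencing, amplitude spectra with
  harmonic summation, intermodulation amplitude, least-squares phase and
  latency, and the group statistics the design needs (Mahalanobis
  outliers, bootstrap CIs, circular tests, correlations).

No patient data ship with the package.  A first-class synthetic-data
generator (`dichopt.synth`) produces ground-truthed BOLD sessions and EEG
cohorts with the statistical structure the analyses assume, so **every
stage is verified by parameter recovery**: the pipeline must read back
the numbers the simulator planted.

## The indices

For responses `R_AE` (amblyopic eye), `R_FE` (fellow eye):

* **ADI** (amblyopic deficit index): `ADI = (R_FE − R_AE) / R_FE` — the
  proportional response loss of the amblyopic eye.  Under a purely
  feedforward (monocular) deficit, a linear-systems argument predicts the
  same ADI at every cortical depth.
* **BSI** (binocular suppression index): `BSI_eye = 1 − binocular/monocular`
  — the fraction of an eye's response suppressed under binocular viewing.
* **fMRI BSI via the IEM**: each voxel's response is modeled as
  `Y = W C` with non-negative monocular mixing weights `W` (fit by NNLS on
  the monocular conditions, where `C_mono = I`); inverting on the
  binocular condition by OLS gives the channel responses `C_bino`, and
  `BSI = 1 − C_bino`.  The inversion undoes the partial-volume mixing
  that makes raw voxel contrasts underestimate suppression.
* **Intermodulation (IM)**: the spectral amplitude at `f1 + f2`
  (7.2 + 8 = 15.2 Hz), producible only by nonlinear binocular
  combination — a direct marker of binocular integration.
* **Equivolume depth**: with pial/white neighborhood areas `A_p`, `A_w`,
  the surface enclosing volume fraction `α` of a column sits at Euclidean
  fraction `x(α) = (A_p − sqrt((1−α)A_p² + αA_w²)) / (A_p − A_w)`;
  depth tertiles then give equal-volume superficial/middle/deep layers
  regardless of curvature.

## Worked example

The numbered scripts under `analysis/` run the two arms end to end and
write their tables under `results/`:

```bash
python analysis/01_simulate_fmri.py 1
python analysis/02_laminar_adi.py
python analysis/03_iem_bsi.py
python analysis/04_simulate_eeg.py 1
python analysis/05_ssvep_indices.py
python analysis/06_group_stats.py
```

With seed 1, `03_iem_bsi.py` prints (abridged):

```
     depth_center  bsi_AE  bsi_FE
0          0.1667  0.4203  0.0576
1          0.5000  0.3629  0.0748
2          0.8333  0.2945  0.0907
planted BSI_AE per layer: [0.4167, 0.35, 0.2833]
max |BSI_AE error| = 0.0129
```

i.e. the IEM reads back the planted superficial-to-deep suppression
gradient of the amblyopic eye to ~0.01 despite voxel-level mixing and
noise.  `06_group_stats.py` prints for the EEG cohort:

```
AE-FE phase delay @ 7.2 Hz: 12.76 ms, reject H0(no delay): True
Pearson r between (ADI_bino - ADI_mono) and (BSI_AE - BSI_FE): r = 0.961
```

recovering the planted 12.81-ms amblyopic-eye latency and the planted
coupling between the extra binocular deficit and the suppression
asymmetry.

## Layout

```
src/dichopt/        library: synth/, laminar, iem, ssvep, stats, hrf,
                    containers, io, pipeline
analysis/           numbered narrative drivers (see worked example)
scripts/            acceptance.py
tests/              pytest suite (unit, property, acceptance)
docs/methods.md     models, assumptions, parameter choices, limitations
```
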