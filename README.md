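# oligoquant

Absolute quantification of fluorescently labelled antisense oligonucleotides
(LNA-ASO gapmers) from confocal microscopy, for cell biologists and
oligonucleotide-therapeutics researchers who need to answer a deceptively
simple question: **how many molecules are actually in each cellular
compartment?**

The package implements, as a tested and reusable pipeline, the quantitative
imaging analyses used to count oligonucleotide molecules in single cells:

* **Photon-count calibration** — hybrid detectors in photon-counting mode
  return counts linear in fluorophore concentration; an affine fit
  `counts = slope · c + intercept` to a dilution series (0.1–1 µM standards)
  translates whole images into absolute concentration maps.
* **Single-cell segmentation and knockdown quantification** — nuclei are
  found in the DAPI channel by three-class Otsu thresholding (middle class
  assigned to background), declumped by watershed dividing lines, and
  size-gated at 20–150 px equivalent diameter; microinjected cells are
  classified by a tracer-intensity threshold and target knockdown is the
  ratio of mean target intensity in injected vs non-injected cells.
* **FRAP** — recovery after photobleaching a 4 µm (nuclear) or 10 µm
  (solution) diameter spot, double-normalized against a reference ROI and
  fitted with `F(t) = a(1 − e^{−t/τ}) + c`, giving `t½ = τ ln 2`,
  `D = 0.88 r²/(4 t½)` and the immobile fraction
  `1 − (a + c − c)/(1 − c)`.
* **FCS** — intensity-fluctuation autocorrelation (multi-tau, m = 16),
  fitted with the 2D diffusion model with a triplet term at fixed
  τ_T = 4 µs: `G(τ) = N⁻¹ (1 + τ/τ_D)⁻¹ (1 + T/(1−T) e^{−τ/τ_T})`; the
  particle number N converts to a molar concentration through an effective
  volume calibrated with reference dyes of known D (400 / 330 µm²/s).
* **Copy-number budgets** — `copies = c · V · N_A` with compartment volumes
  of 2000 fl (cell), 1180 fl (nucleus) and 1.014 fl (vesicle), and 52
  vesicles per cell.

Because the original microscopy data are not deposited, the package ships a
first-class synthetic-data generator (`oligoquant.simulate`) producing
images, FRAP traces and FCS traces with fully known ground truth, so every
stage is testable end to end.

## Worked example

Copy-number budgets from measured concentrations:

```python
>>> import oligoquant as oq
>>> oq.copies(19.8e-6, 1.014e-15)       # 19.8 uM in one 1.014 fl vesicle
(12090.772446667199, 12000.0)
>>> oq.vesicle_budget(19.8e-6, 1.014e-15, 52)
(12000.0, 620000.0)
>>> oq.copies(296e-9, 1180e-15)         # 296 nM in a 1180 fl nucleus
(210341.33246528002, 210000.0)
```

A single vesicle at 19.8 µM holds ~12 000 molecules; 52 vesicles make an
endosomal compartment of ~620 000 molecules per cell, while the nucleus at
296 nM holds ~210 000 — the same order as the ~10⁵ molecules that must be
injected for >50 % target knockdown.

FRAP analysis of a synthetic nuclear recovery trace:

```python
>>> trace = oq.generate_frap_trace(oq.FrapGroundTruth(noise_sd=0.0))
>>> fit = oq.analyze_trace(trace)
>>> round(fit.tau, 4), round(fit.D, 4), round(fit.immobile_fraction, 3)
(1.8137, 0.7, 0.29)
```

i.e. a recovery time of 1.81 s in a 2 µm-radius spot corresponds to an
effective diffusion coefficient of 0.7 µm²/s with 29 % of molecules
immobile — restricted nuclear diffusion, two orders of magnitude below free
solution.

The same analyses are available from the shell:

```bash
oligoquant budget --conc 296nM --volume 1180fl
oligoquant simulate frap --seed 3 --out out/ && oligoquant frap --trace out/frap_trace.csv
oligoquant pipeline gymnosis --seed 11 --out out/gym
```

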