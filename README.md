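# endotrace

Quantitative analysis of myosin-1 and calmodulin dynamics at sites of
clathrin-mediated endocytosis in fission yeast, together with the
in-vitro biochemistry of the myosin-1 neck: single-molecule TIRF trace
analysis, particle tracking, calmodulin–IQ equilibrium binding, and
stopped-flow transient kinetics. A bundled synthetic-data generator with
exported ground truth makes every stage testable without any microscopy
data.

## Who this is for

Groups doing live-cell TIRF imaging of endocytic patch proteins
(myosin-1, calmodulin light chains, coat/actin machinery) who need
reproducible event-level quantification — event timing, assembly and
disassembly rates, per-spot fluorophore counts, vesicle-scission times,
single-molecule residency and mobility — plus the standard equilibrium
and transient fits used to characterise light-chain binding in vitro.

## The analysis in brief

**Event timing (ramp intercepts).** Candidate endocytic sites are bright
spots in the per-pixel temporal standard-deviation projection of the
movie. Each site gets a 5×5-pixel (0.5 µm) measurement core and a
1.5-µm-diameter background region excluding the core; the corrected
trace is `core − 25 × mean(background)`. The rising and falling flanks
are fitted with straight lines in the 60-point (3 s at 20 fps) window of
maximum (minimum) gradient; their zero-intensity intercepts define
`T_start` and `T_end`, the duration `T_dur = T_end − T_start`, and the
plateau amplitude `A_av` averages the samples 5–8 s after `T_start`.
An abrupt (< 0.5 s) collapse from above 50% to below 20% of the plateau
marks the vesicle-scission time `T_scis`.

**Fluorophore counting.** Single molecules are detected per frame
(matched filter at the PSF scale, robust threshold), localised by centre
of mass, and linked by mutual-nearest-neighbour association. The median
per-track intensity calibrates the single-fluorophore brightness, and
`molecules = A_av / (I₁ × excitation_scale)` converts event amplitudes
imaged at reduced laser power. Track durations give the unbinding rate
via the left-truncated exponential MLE (frame-quantisation corrected),
and the ensemble MSD over the first 4 lags gives `D = slope/4` with a
free intercept absorbing localisation noise.

**Binding models.** Calmodulin binding to the tandem IQ motifs is a
sequential (ordered) two-site scheme — no IQ2-only species — with step
dissociation constants `K1` (reported only as an upper bound when
tighter than the reporter concentration) and `K2`, per-step signal
amplitudes, and explicit free-ligand depletion solved from mass
conservation. Calcium titrations use a Hill description
`Y(pCa) = Ymin + (Ymax−Ymin)/(1+10^(n(pCa50−pCa)))`, and FRET
efficiencies map to distances through `R = R0 (1/E − 1)^{1/6}`
(CyPet–YPet `R0` = 5.301 nm).

**Transients.** Stopped-flow records are fitted with
`y(t) = offset + Σ Aᵢ e^{−kᵢt}` by variable projection with multistart;
the number of phases is chosen by sequential F-tests with AIC reported.

## Worked example

Simulate 50 endocytic events with the default Myo1 preset and measure
them:

```bash
endotrace simulate --preset myo1 --n 50 --seed 1 --out run/sim
endotrace analyze --traces run/sim --calibration-au 263.5 --out run/out
```

which prints

```
wrote 50 file(s) to run/sim
50 event(s); mean T_dur 13.33 s -> run/out/summary.json
```

`run/out/summary.json` then contains (abridged)

```json
{
  "n_events": 50,
  "t_dur_mean_s": 13.33,
  "t_dur_sem_s": 0.41,
  "a_av_mean_au": 2285.2,
  "molecules_mean": 43.4
}
```

The mean event duration (here 13.33 ± 0.41 s over 50 simulated events)
is the membrane residency of myosin-1 at one endocytic patch, and
`molecules_mean` says the plateau amplitude corresponds to ~43 myosin-1
molecules at the patch — both recovered by the full ramp-intercept
analysis, not read from the generator. The same CLI exposes `detect`,
`track` (off-rate and diffusion coefficient from a movie), `fit`
(titration / pCa / transient CSVs) and `report`.

Python API equivalents live in `endotrace.pipelines` (e.g.
`event_duration_stats`, `single_molecule_scene`,
`event_movie_molecule_count`, `titration_recovery`).

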