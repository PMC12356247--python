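# srnmr

Super-resolution (SR) pseudo-homodecoupling for the indirect ¹³C
dimension of protein NMR experiments: scan-number schedule generation,
interferogram/spectrum simulation, synthetic triple-resonance peak
lists, and a transparent sequential-assignment benchmark.

## The problem

In HSQC and HNCA-type experiments the one-bond carbon–carbon coupling
(¹J_CαCβ ≈ 35 Hz, methyl ¹J_CC ≈ 38 Hz) modulates the indirect-dimension
signal by `cos(π J t_eff)` with `t_eff = t1 + 2δ` (the coupling also
evolves during a fixed sequence delay `δ`). The cosine splits every ¹³C
peak into a doublet and forces evolution times to stop near
`1/(2J) ≈ 8 ms`, capping the resolution of exactly the dimension that
sequential backbone assignment depends on.

The SR scheme removes the modulation *experimentally*: the number of
scans at increment `i` is raised to the integer closest to
`base / |cos(π J t_eff[i])|`, a ±2 ms window around the cosine zero
crossing at `t_eff = 1/(2J)` is jumped over by switching the sequence
delay `δ_A → δ_B`, and the pulse phase is inverted past the crossing
(`φ_B = φ_A + π`) to absorb the cosine's sign. The accumulated signal
then decays only with T2: the coupling is pseudo-decoupled, evolution
can run 4–5× longer, and the ¹³C linewidth drops by the same factor. A
per-increment residual factor `base·weight/n_scans` corrects the
integer-rounding staircase in post-processing.

`srnmr` is aimed at spectroscopists and methods developers who want to
generate such schedules, predict their cost and artifacts (e.g. the
glycine Cα doublet-with-sinc-wiggles artifact), and quantify how the
narrower lines propagate into Cα-linking accuracy — without touching a
spectrometer.

## Worked example

```python
from srnmr import (get_preset, scan_budget, switch_time, SpinGroup,
                   simulate_interferogram, process, ProcessingParams,
                   measure_fwhm)

preset = get_preset("hnca-sr")          # J=35 Hz, dA=10 us, dB=2 ms, t1max=38 ms
print(f"switch at t1 = {switch_time(preset.acq)*1e3:.2f} ms")
sched = preset.build()
print(scan_budget(sched))

spin = SpinGroup("ca", offset_hz=0.0, couplings_hz=(35.0,), t2_s=0.1)
sr   = process(simulate_interferogram([spin], sched), ProcessingParams())
conv = process(simulate_interferogram([spin], get_preset("hnca-conv-8ms").build()),
               ProcessingParams())
print(f"FWHM: conventional {measure_fwhm(conv):.1f} Hz, SR {measure_fwhm(sr):.1f} Hz")
```

prints

```
switch at t1 = 12.27 ms
ScanBudget(total_scans=1122, mean_scans=5.61, time_ratio_vs_conventional=1.4025)
FWHM: conventional 132.5 Hz, SR 28.2 Hz
```

The delay switch lands at 12.27 ms (the zero crossing 1/(2·35 Hz) =
14.29 ms minus 2δ_A and the 2-ms margin); the SR schedule costs 1.4×
the conventional measurement time under the default boost convention
(convention-dependent — see `docs/methods.md`); and the simulated Cα
line narrows from 132 Hz (unresolved 35-Hz doublet at 8 ms of
evolution) to 28 Hz (decoupled singlet at 38 ms), a 4.7-fold
resolution gain.

The same machinery runs from the shell:

```bash
srnmr schedule -p hnca-sr --out schedule.tsv
srnmr simulate-fid -p hsqc-sr --spin "0,38,0.1" --out fid.tsv --schedule-out s.json
srnmr process --fid fid.tsv --schedule-json s.json --out spectrum.tsv
srnmr benchmark --n-residues 100 --replicates 20 --seed 1 --out bench.tsv
srnmr demo --out-dir demo --fast
```

`srnmr benchmark` simulates standard and SR HNCA peak lists from the
same synthetic shift table, adds linewidth-scaled coordinate jitter,
links strips by globally optimal Cα matching, and reports mean ± sd
linking accuracy per condition — the SR lists link markedly better
because both the jitter and the matching tolerance shrink with the
linewidth.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch: the cosine zero-crossing times for J = 38 and
35 Hz and the delay-switch times of the HSQC and HNCA presets (in ms),
and the conventional-to-SR FWHM ratio of a simulated methyl ¹³C doublet
(J = 38 Hz, T2 = 100 ms, noiseless, squared-cosine apodization, ×2 zero
fill; 8 ms versus the 33-ms SR schedule). Results are written as JSON
keyed by target id.

## Layout

- `src/srnmr/schedule.py` — scan schedules: weights, delay/phase switch, rounding, residuals
- `src/srnmr/spinsim.py` — interferogram simulation under a schedule, noise accumulation
- `src/srnmr/specproc.py` — apodization/zero-fill/DFT, FWHM and multiplet measurement
- `src/srnmr/shifts.py` — synthetic backbone shifts, peak-list simulation, ambiguity metric
- `src/srnmr/assign.py` — strips, global Cα linking, paired SR benchmark
- `src/srnmr/io.py`, `presets.py`, `cli.py` — formats, published presets, command line
- `docs/methods.md` — model assumptions, parameter rationale, known limitations
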