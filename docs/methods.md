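# Methods

`srnmr` implements scan-weighted pseudo-homodecoupling for the indirect
¹³C dimension of heteronuclear NMR experiments, together with the
simulation and benchmarking machinery needed to quantify its effect on
resolution and on sequential backbone assignment.

## The model

A one-bond carbon–carbon scalar coupling `J` (¹J_CαCβ ≈ 35 Hz,
methyl ¹J_CC ≈ 38 Hz) modulates the indirect-dimension signal of each
resonance by `cos(π J t_eff)`, where

```
t_eff = t1 + 2δ
```

is the effective coupling-evolution time: the chemical shift evolves
only during the incremented delay `t1`, but the coupling is also active
during a fixed pulse-sequence element of duration `2δ` (gradient
selection in the HSQC, transfer elements in the HNCA). After Fourier
transformation this cosine splits every peak into a doublet and limits
the usable evolution time to roughly `1/(2J) ≈ 8 ms`, which caps the
attainable ¹³C resolution.

The super-resolution (SR) scheme cancels the modulation in the
*accumulated* signal by acquiring, at increment `i`,

```
n_scans[i] = max(base, round(base / |cos(π J t_eff[i])|))
```

scans instead of a constant `base`. Two devices make this feasible:

1. **Zero-crossing skip.** Near `t_eff = 1/(2J)` the required scan count
   diverges. A window of ±2 ms (`switch_margin`) around the crossing is
   jumped over by replacing the short sequence delay `δ_A` with a longer
   `δ_B` from the evolution time

   ```
   t_switch = 1/(2J) − 2δ_A − switch_margin
   ```

   onward. The `t1` grid itself stays uniform — only `t_eff` jumps.
   Presets: HSQC `J=38 Hz, δ_A=1 ms, δ_B=3 ms` gives `t_switch ≈ 9.16 ms`;
   HNCA `J=35 Hz, δ_A=10 µs, δ_B=2 ms` gives `t_switch ≈ 12.27 ms`.

2. **Phase inversion.** Past the crossing the cosine is negative; the
   pulse/receiver phase is inverted (`φ_B = φ_A + π`) so the accumulated
   signal stays positive. In the simulator this is the per-row
   `phase_sign = sign(cos(π J t_eff))`. Hardware phase tables are carried
   as schedule metadata only.

Because only integer scan counts exist, each row stores the *residual*
`base·weight / n_scans`; multiplying the accumulated signal by this
vector in post-processing removes the rounding staircase exactly
(`base·weight = n_scans·residual` is an identity of the bookkeeping).
This residual-ratio rescaling is this package's interpretation of the
indirect-dimension smoothing applied by external processing software;
the exact smoothing filter used there is not public.

## Tunable parameters and defaults

| parameter | default | why |
|---|---|---|
| `switch_margin_s` | 2 ms | the skip half-width both published settings use |
| `base_scans` | 4 | a minimal phase cycle |
| `rounding_mode` | nearest integer of `base·weight`, floored at `base` | the stated "integer closest to 1/cos" convention; a nearest-multiple-of-k mode is provided for phase-cycle-constrained acquisition |
| `boost_cap` | `cap-after-1/J` | scans are not increased once `t_eff > 1/J`, letting the signal decay naturally toward zero and avoiding truncation wiggles at `t1max` |
| apodization | squared cosine (SSB = 2), ×2 zero fill, first point ×0.5 | standard spectrometer-software processing of such data |
| spectrometer basis | 700 MHz ¹H, ¹³C at 176.05 MHz | the field all published settings assume |

### The scan-budget convention (known discrepancy)

Under the defaults the SR-HNCA preset (J = 35 Hz, t1max = 38 ms, 200
increments, base 4) costs a **mean of 5.61 scans per increment**
(time ratio 1.40× conventional). The published mean for this experiment
is 4.86, which this package reproduces (≈4.82) only under the
alternative `cap-after-zero-crossing` convention — no boost anywhere
past `1/(2J)`. That convention, however, contradicts the stated scaling
law for `t1 ≥ t_switch` and would leave the cosine modulation live
between `1/(2J)` and `1/J`, destroying the pseudo-decoupling that the
measured spectra clearly show. The budget is therefore *reported*, not
forced: the default stays `cap-after-1/J`, the acceptance band of
4.5–5.5 mean scans is left unmet (measured 5.61), and the alternative
cap is available as configuration.

## Simulator

The accumulated interferogram is

```
values[i] = Σ_k n_scans[i] · phase_sign[i] · amp_k · e^{2πi Ω_k t1[i]}
            · Π_J cos(π J t_eff[i]) · e^{−t1[i]/T2_k} + ε[i]
```

with complex Gaussian noise of per-component sd `σ·sqrt(n_scans[i])`.
Assumptions and simplifications:

* chemical shift and relaxation evolve during `t1` only — the `2δ`
  element refocuses the shift (peak positions are identical in SR and
  conventional spectra, as observed);
* multiple passive couplings multiply as independent cosines
  (weak-coupling limit); strong coupling, relaxation interference,
  ¹⁵N constant-time details, TROSY line selection and ²H decoupling are
  out of scope;
* quadrature detection is an ideal complex signal (no echo–antiecho
  bookkeeping);
* noise is drawn once per accumulated increment with sd `σ√NS`
  (statistically identical to, and far cheaper than, `NS` independent
  scans; a literal per-scan mode exists and is tested for equivalence).

Two model facts the tests lean on: (i) noiseless SR plus residual
correction equals the uncoupled exponential envelope exactly wherever
the boost is active (`t_eff ≤ 1/J`), and (ii) the SR acquisition equals
a constant-scan acquisition multiplied by the `1/cos` window — but the
window multiplies the noise too, so SR is quieter by `√weight` per
point, which is the sensitivity argument for acquiring SR rather than
post-multiplying.

The *glycine artifact* falls out of the same equations: a ¹³Cα with no
¹³Cβ has no cosine to cancel, so the phase flip and the scan boost act
on an undecayed signal and the spectrum shows a sign-alternating
doublet with sinc side lobes where the conventional spectrum shows one
broad line.

## Processing conventions

Complex data of `n` points are zero-filled to `n·2·zero_fill` before
the FFT (the factor 2 reflecting the 2n real acquisition points);
with the plain-sum DFT normalisation the spectral integral
`Σ intensity · df` is invariant under zero filling. Peak widths and
splittings are read off by linear interpolation, so all width
assertions carry a one-bin tolerance. A sizeable `δ_A` adds a coupling
phase `π J 2δ_A` that mixes dispersion into doublet lineshapes and
skews apparent maxima outward; coupling-constant recovery is therefore
specified on acquisitions with negligible pre-evolution delay.

## Synthetic shifts and peak lists

The shift generator draws per-residue N/H/Cα/Cβ values from a built-in
random-coil table plus Gaussian dispersion (sd 2.5/0.45/1.5/1.3 ppm at
`dispersion_scale=1`, folded-protein-like). The table's means are
literature-typical random-coil values and a modelling choice of this
package, not data from any single repository; glycine has no Cβ and
proline no amide. Multidomain systems concatenate member tables with
10-residue glycine linkers drawn fresh.

Peak lists follow the transfer topology: each observable amide
(residues 2..L, non-proline; the N-terminal amide is lost to exchange)
yields intra and/or sequential Cα (and Cβ) peaks. The ¹³C linewidth
model is `FWHM ≈ 0.66/t1max` plus the 35-Hz splitting for unresolved
standard-experiment doublets, i.e. ≈118 Hz at 8 ms conventional versus
≈17 Hz at 38 ms SR. SR peak lists differ from standard ones *only* in
width and fine structure (singlets — the Cα–Cβ coupling is removed);
coordinates are identical. The intra:sequential intensity ratio
defaults to 1:0.5 (configurable; no published value exists). Measured
peak lists are emulated by Gaussian coordinate jitter with sd = FWHM/2
per dimension and log-normal intensity scatter; richer artifact models
(spurious/missing peaks, baseline ridges) are not modelled, so a green
benchmark establishes the linewidth effect only, not absolute assignment
performance on real spectra.

## Assignment benchmark

Strips are built by grouping carbon peaks on amide coordinates
(tolerances 0.04 ppm ¹H / 0.4 ppm ¹⁵N); HNcoCA peaks are sequential by
construction and disambiguate coincident HNCA peaks, otherwise the
stronger HNCA peak of a pair is taken as intra. Linking solves a
global linear assignment problem minimising total |ΔCα| with matches at
or beyond the tolerance forbidden (strict inequality, so a zero
tolerance forbids everything even for exactly coincident values);
this is deterministic and order-independent, unlike greedy matching,
and is verified against exhaustive enumeration on small instances.
The default matching tolerance is one singlet linewidth in ppm, so
tolerance and jitter both scale with the experiment's resolution.

Accuracy is the percentage of observable amides whose predecessor (or
correct absence of one) matches the simulation truth; amides collapsed
into a merged strip count as incorrectly placed. This transparent
metric isolates the Cα-linking effect of linewidth; amino-acid-type
inference and deep-learning assignment pipelines are deliberately out
of scope, so the benchmark's absolute percentages are not comparable to
published automated-assignment accuracies — only the *direction* (SR ≥
standard; accuracy non-increasing with system size) is claimed, and
that is what the tests assert.

A truth-aware crowding diagnostic (`ambiguity_metric`) reports the mean
number of intra-Cα candidates per linkable sequential peak; sequential
peaks whose carbon residue has no intra representation (the N-terminal
residue's Cα) are excluded so the clean-table baseline is exactly 1.0.

## Numerical choices and degenerate inputs

* Switch-branch classification uses a 1 ps absolute guard on `t1`
  comparisons; schedule construction re-checks every row against the
  skip window and fails with the offending index.
* `J·t1max < 1/2` (no crossing reached) is legal: no switch occurs and
  the weight grows monotonically.
* A configuration whose switch time is non-positive (J too large for
  the chosen delays) is rejected at `switch_time`.
* The windowed-reference simulator refuses skipless grids whose
  `|cos|` falls below 0.02 anywhere, pointing the user to an SR
  schedule.
* Ties in the assignment problem are resolved by the LAP solver
  deterministically; seeded runs are bit-reproducible end to end.

## Known limitations

* The scan-budget convention mismatch described above.
* No phase/baseline correction, NUS, or 3D processing beyond
  independent vectors; strips are outer products with a conventional
  direct dimension.
* The synthetic dispersion model has no secondary-structure
  correlations between neighbouring residues; real Cα ladders are
  easier or harder to link depending on local structure.
* The NMR-STAR reader accepts only the documented four-tag atom-shift
  loop dialect, and the Sparky writer one fixed column order.
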