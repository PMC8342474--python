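# Methods

## Physical model

The object is a complex transmission raster `O(r) = A(r) e^{iφ(r)}` on a
square grid whose side is a power of two (default 256, the superpixel
count of the reference instrument). The forward model captures the
signal chain of a heterodyne single-pixel holographic microscope:

1. **Patterned illumination.** A binary 0/1 pattern `H̃_n` multiplies the
   object field. The patterns are the binary forms of sequency-ordered
   Walsh-Hadamard bases; the 2-D basis of order `n` is the outer product
   of the 1-D Walsh rows selected by the sequency pair `(u, v)`.
2. **Bucket detection.** The detector integrates the transmitted field,
   giving the coefficient `ã_n = (1/√N) Σ_r O(r) H̃_n(r)`.
3. **Heterodyne beat.** Interference with a reference beam offset by the
   beat frequency Δf turns the complex coefficient into a real
   oscillation. One digitized record per pattern is synthesized as

       V(t) = dc_reference + dc_signal_n + 2·gain·|ã_n|·cos(2πΔf t + arg ã_n) + ε(t),

   with `dc_signal_n` the pattern's transmitted intensity
   `(1/√N) Σ_r |O(r) H̃_n(r)|²` (it varies with `n`, so demodulation must
   genuinely reject per-pattern DC) and `ε` zero-mean Gaussian noise with
   standard deviation `noise_rel` times the noiseless sample. Only the
   difference frequency is modelled — the two ~50 MHz acousto-optic
   shifts are invisible to the detector bandwidth. The carrier phase is
   referenced to the global clock `t = 0`; records are laid gap-free at
   `t_start = (k−1)·refresh_time`, so with an integer number of beat
   cycles per pattern every record sees the same carrier-phase grid.

Recovery inverts the chain: a three-parameter linear least-squares fit
(`c₀ + c_c cos + c_s sin` at the known Δf, absolute times) yields
`ã_n = (c_c − i c_s)/(2·gain)` — this is the single place the
`e^{+iωt}` sign convention is fixed; the DC correction
`a_n = 2ã_n − ã_1` maps onto the orthogonal basis; and the zero-filled
inverse fast Walsh-Hadamard transform produces the image, phase wrapped
to (−π, π] (never unwrapped). No global-phase calibration is applied:
the reconstruction carries an arbitrary global phase from the reference
arm, so all phase metrics use differences only.

## Default parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| `beat_freq` | 62 500 | Hz | AOM difference frequency (16 µs period) |
| `sample_rate` | 1.25×10⁶ | S/s | digitizer rate → 20 samples per beat cycle |
| `refresh_time` | 48×10⁻⁶ | s | DMD pattern period → 3 cycles, 60 samples |
| `noise_rel` | 0.001 | – | relative noise std (0.1 % of the measured value) |
| `dc_reference` | 1 | arb. | reference-beam DC on the detector |
| `gain` | 1 | arb. | interference scaling; cancels in reconstruction up to a global factor |
| `mirror_pitch` | 13.68 | µm | DMD mirror pitch |
| `binning` | 3 | – | mirrors per superpixel edge |
| `n_super` | 256 | – | superpixels per image edge |
| `f_front`, `f_rear` | 125, 125 | mm | 4f lens pair (magnification `f_rear/f_front`) |
| `diag_factor` | √2 | – | 45°-tilted DMD mounting |
| `anisotropy` | 43.1/58.0 | – | y-to-x resolution ratio |

The geometry calculator composes these:
`res_x = diag_factor · binning · mirror_pitch · f_rear/f_front`,
`res_y = anisotropy · res_x`, `fov = n_super · res`, and
`sbp_t = 2/refresh_time` (the factor 2 because amplitude and phase both
carry information; it is independent of optics and binning). The
anisotropy is treated as a configuration constant fitted to the printed
resolution pair; it is numerically close to cos 41.92°, the diffracted-
beam angle of the tilted DMD, but the underlying diffraction geometry is
deliberately out of scope. Note the printed mode table is internally
rounded: 256 × 43.1 µm = 11.03 mm prints as 11.1 mm; stored values are
full precision and rounding happens only at display time (three
significant figures).

## Design choices

- **Sequency ordering and the square path.** The linear order `n`
  enumerates sequency pairs along expanding shells of `max(u, v)`,
  boustrophedon within each shell: `(0,k)…(k,k)` then `(k,k−1)…(k,0)`.
  Any shell-complete traversal yields identical reconstructions at
  shell-aligned sampling ratios; the within-shell direction is a free
  choice. Truncating at ratio SR keeps pairs with
  `max(u,v) ≲ side·√SR`, which is why resolution degrades with √SR.
  A Sylvester ("natural") ordering is available behind a flag for
  testing.
- **Symmetric transform normalisation** (`1/√N` in each direction) so
  that forward/inverse are mutual inverses and Parseval holds; this
  makes the truncation error identity exact: the squared L2
  reconstruction error equals the energy of the unmeasured coefficients,
  which is what makes the nested-SR monotonicity a theorem rather than
  an observation.
- **Least-squares demodulation, not an FFT bin.** With integer cycles
  per record the fit is exact; with fractional cycles (e.g. the 45 µs
  refresh giving 56.8 samples per pattern) the absolute-time design
  matrix stays correct where a windowed FFT readout would bias. When all
  records share the carrier-phase grid one pseudoinverse is applied to
  the whole batch.
- **Zero-filling rather than iterative compressive solvers.** The
  reconstruction is the direct inverse transform of the measured prefix;
  ℓ1/TV solvers are an explicit non-goal.
- **Gaussian multiplicative noise.** Only the relative noise level is
  specified physically; a Gaussian law with std proportional to the
  instantaneous signal is the conventional detector model. Shot-noise
  statistics, bandwidth roll-off and partial light collection are not
  modelled (the holographic signal only lives in the zero-spatial-
  frequency interference term, so partial collection would not affect it
  anyway).

## Phantoms: what they emulate and what they do not

- `bar_target` builds positive three-bar elements (bar width w, length
  5w, gap w) on a layout aligned to multiples of the bar width. Because
  the first `k` Walsh sequencies (k a power of two) span exactly the
  piecewise-constant functions on `side/k` dyadic blocks, such a target
  has *zero* coefficients beyond the shell `side/w` — its information is
  genuinely confined to low sequencies, mirroring a resolution target
  imaged near the diffraction limit where higher-order coefficients
  carry only noise. This is the regime in which a moderate sampling
  ratio (12.5 %) yields a higher contrast-to-noise ratio than a large
  one (50 %): the extra measured orders add noise but no signal.
- `phase_step_target` places a known phase step (default 1.795 rad, the
  nominal step of a quantitative phase target) on unit amplitude.
- `tissue_phantom` is a seeded, low-pass-filtered Gaussian random field
  pair; with small amplitude contrast and a generous phase range it
  emulates unstained tissue (informative phase, flat amplitude). It is
  *not* a scattering model: no speckle, no thickness-dependent
  absorption, no spatial correlation between amplitude and phase.

Consequently, passing tests demonstrate correctness of the measurement
and reconstruction chain and its noise behaviour — not that the system
would resolve any particular biological structure; experimental factors
(alignment drift, DMD timing jitter, laser power) are outside the model,
which is why the real instrument's phase error (≈0.1 rad) is far above
the simulation's.

## Numerical notes

- Problem sizes: unit tests run at sides 2–64; the full-scale check runs
  one side-256 acquisition (65,536 patterns × 60 samples), a few seconds
  of compute via the fast-transform path and a shared demodulation
  pseudoinverse.
- Degenerate inputs: Δf = 0 or rank-deficient designs raise a
  `DegenerateFitError`; records need ≥ 3 samples; a zero-spread
  background makes CNR an `UndefinedMetricError` rather than ±inf;
  circular means are used for phase ROIs so steps straddling ±π do not
  cancel.
- Noise realisations are driven by a single `numpy` Generator seeded per
  acquisition; fixed seed ⇒ bitwise-identical pipeline output.
- Amplitude/phase TIFF pairs are 32-bit float; amplitudes outside [0, 1]
  are rejected when reading *objects* (tolerance 10⁻⁶ for float32
  round-off) but allowed when reading reconstructions, which may
  legitimately overshoot under noise. Phase files are wrapped on read
  with a logged warning.

## Known limitations

- The within-shell order of the square path is a convention; at
  non-shell-aligned sampling ratios two shell-complete paths can differ
  in which partial-shell coefficients are kept.
- The forward model is scalar and paraxial: no diffraction between DMD,
  sample and detector (the 4f relay is assumed ideal), no polarisation.
- `dc_reference` and `gain` are arbitrary units; absolute radiometry is
  not modelled.
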