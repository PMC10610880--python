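# epiopt

Protocol optimization for gradient-echo echo-planar imaging (GRE-EPI) at
mid-field MRI (0.3–1 T), built around the **T₂\* contrast efficiency**
metric, together with the measurement machinery needed to validate it:
mono-exponential T₂\* relaxometry, pseudo-multiple-replica SNR, temporal
SNR, the physiological-to-thermal noise decomposition, and a digital brain
phantom that stands in for in-vivo data.

**Who it is for.** MR physicists designing fMRI / SWI / thermometry
protocols on mid-field systems, where gray-matter T₁ is short
(≈ 717 ms at 0.5–0.55 T) and T₂\* is long (≈ 86 ms), so conventional
"set TE = T₂\*" advice produces echo trains dwarfed by sequence dead time.

## The metric

The BOLD-weighted SNR of a spoiled GRE-EPI acquisition is

```
SNR_BOLD ∝ Δx·Δy·Δz · TE · √TAD · (1 − E)·sin α / (1 − E·cos α) · exp(−TE/T₂*),   E = e^(−TR/T₁)
```

with TAD the readout duration and α the flip angle (Ernst angle
`arccos(E)` for maximum steady-state signal).  Acquiring N images in a
fixed total scan time TS = N·TR multiplies SNR by √N = √(TS/TR), so the
quantity to maximize at fixed scan time is the **contrast efficiency**

```
η_T₂* = SNR_BOLD / √TR .
```

If TR were free, η peaks at TE = T₂\*.  But multi-slice coverage couples
TR to TE (TR = n_slices · (TE + c), with c a per-slice overhead the
package calibrates from TE/TR tables), and the 1/√TR penalty pulls the
optimum to **TE < T₂\***.  On the built-in 3.4 mm reference family
(38 slices, ETL 70) with gray matter at 0.5 T the optimum is TE = 55 ms —
31 ms below T₂\* — which also removes dead time and shortens TR.

The SNR side is validated on a synthetic multi-coil phantom:
pseudo-replica SNR (add correlated noise drawn from the coil covariance Ψ
to one k-space acquisition, reconstruct many replicas, take voxel-wise
mean/SD) isolates thermal noise; temporal SNR over repeated acquisitions
adds physiological fluctuations; their combination
`σP/σT = √((pSNR/tSNR)² − 1)` quantifies the noise regime (< 1 means
thermal-noise dominance).

## Worked example

```python
from epiopt.report import compare_protocols
out = compare_protocols({"relaxation": {"t1": 717.2, "t2star": 86.0}})
print(out["curves"]["3.4mm"].round(3).to_string(index=False))
```

```
 te_ms  tr_ms  flip_deg  snr_bold     eta
  25.0 1738.0      85.0  3846.831  92.274
  35.0 2119.0      87.0  4973.655 108.046
  45.0 2499.0      88.0  5816.209 116.347
  55.0 2879.0      89.0  6408.802 119.442
  65.0 3259.0      89.0  6792.729 118.988
  75.0 3639.0      90.0  7007.988 116.172
  85.0 4019.0      90.0  7088.839 111.819
  95.0 4399.0      90.0  7063.833 106.503
 105.0 4779.0      90.0  6956.565 100.630
```

`snr_bold` (arbitrary units) keeps rising toward TE ≈ T₂\* = 86 ms, but
the efficiency `eta = snr_bold/√TR` peaks at **TE = 55 ms**: each extra
10 ms of TE costs 380 ms of TR across the 38-slice stack.  The comparison
table adds the derived timing consequences:

```
        te_opt_ms  te_opt_minus_t2star_ms  dead_time_at_te_opt_ms  tr_saved_vs_t2star_ms  pe_bandwidth_hz_per_px
3.4mm        55.0                   -31.0                   36.17                1177.89                   31.58
4.0mm        65.0                   -21.0                   50.37                 672.00                   42.98
```

(The 4.0 mm grid is a near-tie between 55 and 65 ms; η differs by 0.05%.)
Running at 55 ms instead of 86 ms saves ~1.2 s of TR per volume at 3.4 mm.
The alternative route to TE = T₂\* — stretching the echo spacing until the
dead time vanishes — would drop the phase-encode bandwidth to
`1/(2·T₂*)` ≈ 5.8 Hz/pixel and inflate geometric distortion several-fold
(`distortion_factor_vs_zero_dead_time` column).

The same numbers are available from the CLI:

```bash
epiopt optimize --config configs/reference.yaml --out-dir out/
epiopt report   --config configs/reference.yaml --seed 1 --out-dir out/
```

`epiopt report` additionally runs the synthetic validation loop: simulate
multi-coil EPI k-space time series on the phantom over a TE grid,
reconstruct, measure pSNR/tSNR per tissue ROI, and check the estimated
σP/σT and the pSNR-derived efficiency curve against the generator's
analytic ground truth.  Other subcommands: `timing`, `t2star-fit`, `snr`,
`simulate` (see `epiopt --help`).

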