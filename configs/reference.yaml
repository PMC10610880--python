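# Reference configuration: the two built-in 0.5 T EPI protocol families
# plus a phantom validation loop.  `epiopt optimize --config` uses the
# top-level keys; `epiopt report --config` additionally runs `validation`.

# "reference" expands to the built-in 3.4 mm and 4.0 mm families below;
# spell them out explicitly to modify either one.
families:
  - name: "3.4mm"
    voxel_size: 3.4          # mm, isotropic
    fov_inplane: 240.0       # mm
    matrix: 70               # in-plane matrix (square)
    etl: 70                  # phase-encode lines per shot
    n_slices: 38
    acq_bandwidth: 160.0e3   # Hz, total readout bandwidth
    te_grid:   [25, 35, 45, 55, 65, 75, 85, 95, 105]          # ms
    tr_grid:   [1738, 2119, 2499, 2879, 3259, 3639, 4019, 4399, 4779]  # ms
    flip_grid: [85, 87, 88, 89, 89, 90, 90, 90, 90]           # deg (Ernst)
  - name: "4.0mm"
    voxel_size: 4.0
    fov_inplane: 240.0
    matrix: 60
    etl: 60
    n_slices: 32
    acq_bandwidth: 160.0e3
    te_grid:   [25, 35, 45, 55, 65, 75, 85, 95, 105]
    tr_grid:   [1386, 1706, 2026, 2346, 2666, 2986, 3306, 3626, 3946]
    flip_grid: [82, 85, 87, 88, 89, 89, 89, 90, 90]

# tissue used for the efficiency optimization (0.5 T gray matter; T2*
# rounded to the nominal 86 ms)
relaxation:
  t1: 717.2        # ms
  t2star: 86.0     # ms
  tissue_label: gray matter

# synthetic validation loop (epiopt report / validate_pipeline)
validation:
  te_grid: [25, 55, 85]      # ms
  n_repeats: 64              # EPI time-series length
  n_replicas: 128            # pseudo-replica count
  per_slice_overhead: 18.3   # ms, per-slice timing constant
  target_ratio: 0.5          # injected GM sigma_P/sigma_T
  ratio_mode: bold           # 'bold' (TE-weighted) or 'const'
  phantom:
    shape: [32, 32, 8]
    voxel_size: 4.0          # mm
    n_coils: 16
    coil_coupling: 0.1       # off-diagonal of the coil noise covariance
    target_psnr: 50.0        # GM-mean thermal-only SNR
    seed: 20230
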