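# mesotof

Quantitative modelling and analysis tools for time-of-flight MR
angiography (TOF-MRA) of mesoscopic (50–300 µm) vessels such as pial
arteries:

- **`signal_model`** — spoiled gradient-echo steady-state and inflow
  magnetization, relative flow-related enhancement (FRE), blood dwell
  time, Ernst angle, and exhaustive grid-search optimization of the
  excitation flip angle for a given blood delivery time.
- **`partial_volume`** — cylinder-in-voxel geometry: exact
  circle/square overlap area, blood volume fraction, two-compartment
  partial-volume FRE, and predicted FRE gains from voxel-size reduction.
- **`displacement`** — velocity- and TE-dependent vessel displacement
  in the phase-encoding directions.
- **`phantom`** — synthetic 3D angiogram generator: branching vessel
  trees with near-right-angle side branches, supersampled rasterization
  to blood-fraction/delivery/label maps, two-echo T2*-weighted image
  simulation, Rician noise and smooth multiplicative bias fields. All
  ground truth (fraction, delivery, labels, vessel mask) is emitted
  alongside the images; everything is reproducible under a fixed seed.
- **`segmentation`** — homomorphic bias normalization, global
  thresholding with small-cluster removal, iterative region growing,
  rim-based FRE measurement, skeleton-length quantification and maximum
  intensity projections.
- **`vein_removal`** — two-echo T2* mapping and per-component vein
  classification/removal (90th-percentile T2* below threshold).
- **`io` / `cli`** — NIfTI-1 volume container and the `mesotof`
  command-line interface.

## Test

```sh
python -m pytest -q tests/
```

The suite is fully self-contained: every image it analyses is generated
by the phantom module at test time. `tests/test_acceptance.py` holds
the acceptance criteria (protocol optima, partial-volume gains,
displacement values, and property-based phantom experiments).

## Command line

```sh
mesotof fre --tr 20 --flip 18 --delivery 300            # FRE + optima
mesotof fre --surface --out fre_table.csv               # delivery x flip table
mesotof pvfre --vessel-diameter 0.3 --voxel 0.3 --gain-from 0.8
mesotof shift --velocity 200 --te 10 --voxel 0.4
mesotof --seed 7 simulate --out-prefix out/phantom --voxel 0.3
mesotof segment --in out/phantom_echo1.nii.gz --primary 0.2 \
    --secondary 0.18 --min-cluster 5 --out-prefix out/seg
mesotof veinfilter --echo1 out/phantom_echo1.nii.gz \
    --echo2 out/phantom_echo2.nii.gz --dte 6.95 \
    --seg out/seg_mask.nii.gz --out-prefix out/vf
```

Global flags `--config` (YAML/JSON mirroring the flag names), `--seed`
and `--log-level` precede the subcommand. Each pipeline command writes
a JSON provenance sidecar (config, seed, versions) next to its outputs.

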