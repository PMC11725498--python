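# tetherlab

Simulator and analysis toolkit for single-tether, multi-device neural
acquisition systems and the behavior they enable. Everything runs in
simulated time on a desk — no hardware required.

Subsystems (one module each under `src/tetherlab/`):

| module | what it does |
| --- | --- |
| `protocol` | device/frame data model and the byte-level codec that multiplexes heterogeneous device streams into one ordered channel (14-byte little-endian header + payload; `ONIS` stream files) |
| `link` | block-transfer channel model: latency in sample periods vs. block size, effective bandwidth under per-transfer overhead, channel-capacity arithmetic, greedy block packing of frame streams |
| `simulate` | seeded device simulators: multichannel ephys with ground-truth spikes, absolute-orientation sensor scripts, lighthouse sweep-event forward model, stimulator commands |
| `pose` | sweep-timing to angles, two-station ray triangulation, optical+IMU pose fusion onto a uniform 100 Hz grid |
| `commutator` | torque-free tether commutation: heading unwrapping, twist bookkeeping (exact conservation identity), thresholded/quantized motor policy |
| `loop` | closed-loop harness: threshold spike detection, stimulator command emission, additive end-to-end latency accounting with nearest-rank percentiles |
| `behavior` | speed distributions, 20x20 spatial-occupancy and 40x40 heading histograms, Shannon entropy (raw and normalized), ~1-minute block bootstrap CIs, band power and activity level, plus the synthetic hexagonal-arena trajectory generator |
| `config`, `io`, `cli` | TOML run configuration, stream/CSV/flat-binary persistence, manifests, and the `tetherlab` command-line interface |

## CLI

```sh
tetherlab simulate --duration 10 --seed 1 --out-dir out/          # session stream + ground truth
tetherlab benchmark-link --block-sizes 512,8192,65536             # latency/bandwidth sweep CSV
tetherlab closed-loop --duration 10 --seed 1 --out-dir out/       # latency summary JSON + per-event CSV
tetherlab track --duration 30 --seed 1 --out pose.csv             # lighthouse+IMU fused pose CSV
tetherlab commutate pose.csv --out commands.csv                   # commutator command log
tetherlab behavior pose.csv --out-dir out/                        # entropy/speed report JSON
```

Each run writes a `manifest.json` (seed, config hash, versions, input
digests). Configuration is TOML; see `tetherlab.config.RunConfig` for the
schema and defaults (unknown keys are rejected by name).

## Conventions

- World frame right-handed, z up, meters; arena origin at the arena center.
- Euler angles intrinsic yaw-pitch-roll (Z-Y'-X''); quaternions scalar-last.
- Yaw is stored in [-180, 180) for commutation and [0, 360) for heading
  histograms; `tetherlab.commutator.wrap_to_180/wrap_to_360` convert.
- Shared clock: 64-bit tick counter, default 30 kHz (one tick per spike-band
  sample period).
- Latency is reported in sample periods and converted to seconds only via an
  explicit sample rate.
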