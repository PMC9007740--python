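# multipose

Non-neural computational core of a multi-animal pose-tracking pipeline:

- **`multipose.model`** — skeleton/instance/frame data model, validation, a
  portable HDF5 container (`.poses.h5`), train/val/test splits, and dense
  array / CSV export.
- **`multipose.encode`** — training-target generation: per-part confidence
  maps (max-combined Gaussians), part affinity fields (distance-weighted
  edge unit vectors, summed over instances), per-identity class maps, and
  fixed-size anchor-centered crops.
- **`multipose.peaks`** — global/local peak finding with dilation-based NMS
  and integral-regression subpixel refinement (5×5 weighted mean).
- **`multipose.group`** — bottom-up assembly (line-integral connection
  scoring, per-edge Hungarian matching, greedy edge-wise growth over a
  directed tree skeleton), top-down centered-crop decoding, and
  appearance-based identity assignment (class maps or probability matrix).
- **`multipose.track`** — flow-shift tracking: sparse pyramidal
  Lucas–Kanade advection of past poses plus min-cost assignment over a
  sliding window.
- **`multipose.evaluate`** — OKS, greedy instance matching, VOC/PoseTrack
  mAP/mAR over 10 OKS thresholds and 101 recall points, localization-error
  percentiles, and identity-switch counting.
- **`multipose.netconfig`** — receptive-field closed form (both stride
  conventions) and the JSON run-configuration schema.
- **`multipose.behavior`** — pose-pair social features and the approach
  trigger predicate.
- **`multipose.synth`** — seeded synthetic scene/session generator used as
  the "oracle network" in tests.

## CLI

```sh
multipose synth scene --out scene.poses.h5 --n-instances 3 --seed 1
multipose synth session --out session.poses.h5 --images-out session.tif --n-frames 100
multipose track --predictions session.poses.h5 --images session.tif --out tracked.poses.h5
multipose evaluate --gt gt.poses.h5 --predictions tracked.poses.h5 --report metrics.json
multipose config rf --layers 3:1,3:2,3:1
multipose config validate config.json
multipose trigger --tracked tracked.poses.h5 --out trigger.csv --px-per-mm 15.5
```

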