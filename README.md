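# vesselreg

Rigid registration of cross-source vascular point clouds — aligning a liver
vessel tree reconstructed from intraoperative 3-D **ultrasound** with the
same tree reconstructed from preoperative **CT**, so that real-time US
images can be fused with the CT volume during radiofrequency ablation.

Cross-source clouds sample the same anatomy with very different density,
noise and coverage (the US sweep sees only part of the organ), which makes
direct surface registration unreliable. `vesselreg` instead reduces each
cloud to homologous **skeleton feature curves** and registers those:

1. **Laplacian contraction** shrinks the cloud toward its curve skeleton by
   iterating the least-squares system `[w_L L; W_H] X' = [0; W_H X]` on a
   k-nearest-neighbour umbrella Laplacian `L`, with the contraction weight
   `w_L` doubled per iteration and per-point attraction `W_H` grown as
   neighbourhoods collapse.
2. A **minimum spanning tree** over the contracted points, with
   degree-based node classification (degree 1 = endpoint, ≥ 3 = junction),
   junction-cluster simplification and shortest-path splitting, yields
   centerline segments.
3. Per segment, vessel points within 15 mm of each skeleton point are
   claimed (nearest-skeleton-point rule), cross-section centres `C_i` are
   refined from the wall geometry (nearest wall points `A_i`, `B_i` along
   the local vertical give a diameter `d_i`; the points within `d_i/2`
   recentre `C_i'`), and the ordered `C_i'` are fitted by a **quadratic
   feature curve**.
4. The US feature curves are registered onto the CT curves by a **globally
   optimal branch-and-bound search** over SE(3) (trimmed MSE bounds,
   axis-angle rotation cube, inner ICP polishing) followed by **fine ICP**;
   the CT frame is then mapped onto the fixed US frame by the inverse.

Evaluation uses skeleton RMSE, tumor-centre target registration error
(TRE), Dice, volume similarity and surface Dice at 5 mm. Because clinical
scan pairs cannot be redistributed, the package ships a seeded synthetic
phantom generator (branching tubes rendered twice with CT-like/US-like
asymmetry and known ground-truth transform) that drives all tests; see
`docs/methods.md` for the model, parameters and limitations.

## Worked example

Generate a synthetic case (fixed US-like cloud, moving CT-like cloud, known
truth), register it, and score the result:

```sh
vesselreg synth --out-dir case0 --n-branches 5 --seed 3
vesselreg register --moving case0/moving.ply --fixed case0/fixed.ply \
    --config examples/synthetic.yaml --out-transform case0/T.json \
    --report case0/report.json
vesselreg eval --moving case0/moving.ply --fixed case0/fixed.ply \
    --transform case0/T.json --tumors case0/tumors.json \
    --report case0/eval.json
```

which prints

```
case written to case0 (fixed 706 pts, moving 2303 pts)
rmse_mm=1.1863 converged=True
rmse_mm=10.9027 tre_mm=['0.192', '0.409', '0.547', '0.146']
```

The cloud sizes show the cross-source asymmetry: the US-like cloud is
sparse and truncated (706 points) while the CT-like cloud covers the whole
tree (2303 points). The first `rmse_mm` (1.19 mm) is the residual between
the registered feature curves — the skeletons agree to well under a vessel
diameter. In the `eval` line, the raw whole-cloud RMSE (10.9 mm) is
dominated by CT regions the US sweep never imaged and is *not* a
registration error; the tumor-centre errors are: all four land within
0.55 mm of their true positions, far inside the 5 mm ablation margin that
makes a fusion clinically usable. `examples/synthetic.yaml` holds the one
parameter adapted to the synthetic sampling density (`k_neighbors: 16`;
see `docs/methods.md`).

`synth --masks` additionally writes `masks.json`, one entry per tumor with
the voxel volume run-length encoded: `shape`, `origin` (mm), `spacing`
(mm), `first_value`, and `run_lengths` — alternating run lengths of the
flattened (C-order) boolean volume starting from `first_value`.

The same flow in Python:

```python
from vesselreg import extract_features, register_features
from vesselreg.study import study_config

cfg = study_config()
curves_us = extract_features(us_cloud, cfg.contraction, cfg.segmentation)
curves_ct = extract_features(ct_cloud, cfg.contraction, cfg.segmentation)
result = register_features(curves_us, curves_ct, cfg.goicp, cfg.icp)
# result.transform maps the US frame onto the CT frame; invert for CT->US
```

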