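# jkte — joint k-TE space reconstruction for T2 mapping

`jkte` reconstructs multi-echo T2-weighted MR magnitude images and the
pixelwise T2 relaxation map **simultaneously** from (possibly undersampled)
k-space data, instead of the conventional two-step pipeline (inverse FFT per
echo, then pixel-by-pixel exponential fitting).  It is aimed at quantitative
MRI / relaxometry work: phantom QA, protocol simulation, and method
comparison on synthetic data with known ground truth.

## The model

Per echo time TE_i, the measurement model is

    g(z, TE_i) = S F A(x, TE_i) f(x, TE_i) + n

with `F` the unitary 2D Fourier transform, `A` a fixed unit-modulus phase
image (estimated once from the zero-filled reconstruction), `S` a 0/1
sampling operator on phase-encode lines, and `n` complex Gaussian noise.
Echoes are tied together by mono-exponential decay,

    f(x, TE_i) = f(x, TE_0) · exp(−(TE_i − TE_0)/T2(x)).

The joint estimate solves

    min_{f, T2, v}  ½ Σ_i ‖S F A_i f_i − g_i‖² + R(v_i)
    s.t.  f_i = f_0 e^{−(TE_i−TE_0)/T2},   v_i = f_i,

by ADMM with penalty ρ (default 0.5).  The image subproblems are quadratic
and solved exactly; the T2 subproblem is a pixelwise weighted least-squares
fit of the log-linear decay; the regularizer R is a plug-and-play denoising
step (non-local means by default, with a registry of alternatives) whose
strength σ is estimated from the data by a 5×5-patch mode estimator.
Iterations stop when the mean relative intensity change (MRC) between
successive image iterates drops below ε = 1%, checked from the 4th
iteration.

Included for comparison: the conventional two-step method, per-echo
compressed sensing with a 1D total-variation penalty along the phase-encode
direction, and a k-space-only ablation (same ADMM/PnP machinery without the
decay constraint).

## Worked example

Simulate a 14-vial digital relaxometry phantom (T2 from 8.75 to 853 ms,
11 echoes from 11 to 176 ms, 2% complex Gaussian k-space noise), run the
joint reconstruction, and score it per vial:

```sh
jkte simulate --preset vials14 --grid 128 --noise-sd 2.0 --seed 1 --output data.h5
jkte recon    --input data.h5 --output-dir out
jkte evaluate --t2 out/t2_map.nii.gz --rois data.rois.json \
              --truth data.truth.nii.gz --out report.csv
```

The recon step prints

```
converged=True after 6 iterations (sigma=1.81)
```

— the solver met the 1% MRC stopping rule after 6 ADMM sweeps, with the
noise level estimated at 1.81 (true simulated value 2.0).  `report.csv`
then lists per-vial statistics, e.g.

```
label,mean_ms,std_ms,n,truth_ms,rel_error
vial06,53.2881,0.603332,119,53.0,0.005435942998680198
vial07,82.6564,1.23725,120,82.19999694824219,0.005552056944862451
vial10,193.786,4.08657,120,194.0,0.0011043804208027363
```

Vials in the protocol's well-conditioned range recover their T2 within
~1%, and the pixelwise standard deviation is a fraction of what the
two-step method yields on the same data (compare with
`jkte baseline --method two_step ...`).  Vials with T2 below a few echo
spacings are biased upward by the magnitude noise floor — an inherent limit
of magnitude-domain exponential fitting, discussed in `docs/methods.md`.

The same works from Python:

```python
import jkte

ph = jkte.make_vial_phantom((128, 128))
g = jkte.simulate_acquisition(ph, jkte.AcquisitionConfig(noise_sd=2.0, seed=1))
images, t2, log = jkte.joint_reconstruct(g, jkte.ReconConfig())
report = jkte.roi_stats(t2, ph.roi_masks, truth=jkte.T2Map(data=ph.t2_truth))
```

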