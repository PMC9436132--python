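# gipct

Desk-scale reconstruction stack for grating-interferometry differential
phase-contrast CT (GI DPC-CT), aimed at people studying iterative
reconstruction for X-ray phase-contrast breast imaging: it simulates
Talbot-Lau phase-stepping acquisitions of synthetic breast-like phantoms,
retrieves the wrapped differential-phase sinogram by Fourier analysis, and
reconstructs the refractive-index decrement δ with a Plug-and-Play
quasi-Newton scheme whose learned prior is certified non-expansive.

## The problem and the method

A Talbot-Lau interferometer measures, per detector element, the sinusoidal
phase-stepping curve

    I_k = I0 · T · (1 + V0 · D · cos(k + Φ0 − φ)),

whose first-harmonic phase shift φ = (2π d₂/g₂) · ∂/∂x ∫ δ dl is the
*derivative* of the δ line integral. Reconstruction solves

    δ* = argmin_δ ½‖Aδ − φ‖²₂

where the linear operator A is built from Kaiser-Bessel blobs: the image is
expanded in circularly symmetric windows w_kb whose analytic derivative is
tabulated once, and the ray-driven forward operator samples that derivative
at the signed voxel-to-ray distance — no numerical differentiation of the
sinogram ever happens. This operator's normal matrix AᵀA has a more slowly
decaying singular-value spectrum than the classical ray-sum +
finite-difference pair, and it propagates less noise per gradient step.

Because the problem remains severely ill-conditioned and the retrieved φ is
wrapped to (−π, π] (strong edges produce 2π wrap artifacts), data updates
alternate with a learned denoiser in a Plug-and-Play scheme: k_max L-BFGS
updates of the data term, then one application of a bias-free ReLU network
f(x) = W_N R(W_{N−1} … R(W_1 x)). The network is trained with

    L = mean ‖f(δ_noisy) − δ_clean‖² + λ · ReLU(Π_l L(W_l) − (1 − ε)),

where L(W_l) is layer l's spectral norm (power method) and λ = 1e-4,
ε = 1e-8. The penalty drives the product of layer norms to just below 1,
which certifies the whole network non-expansive via the composition bound —
individual layers may remain expansive. Training pairs are "noisy
iterates": a few unregularized data-term updates started at the clean
phantom against a Poisson-noisy wrapped sinogram, so the network sees
exactly the artifact structure the iterations produce.

Baselines included: Hilbert-filter filtered backprojection (the DPC
analogue of ramp-filter FBP), an iterative TV baseline whose proximal step
uses Chambolle's dual algorithm on finite-difference operators, plain PnP
gradient descent, and FBP followed by denoiser post-processing.

## Worked example

```python
import gipct as g

study = g.default_study(32)                      # geometry, interferometer, operators
phantom = g.make_breast_phantom((32, 32), 4, seed=42, delta_range=(0, 1))

# train the certified denoiser on noisy-iterate pairs
pairs = g.make_training_set(study, 50, seed=11)
net, state, log = g.train_denoiser(pairs, g.TrainingConfig(seed=5))
print(net.certified_bound(state.norms))          # 0.9915  (<= 1: non-expansive)

# end-to-end comparison on one noisy simulated scan
out = g.table_comparison(phantom, study, lambda x: net(x), seed=49)
print({k: round(v, 2) for k, v in out.items()})
# {'pnp_lbfgs': 29.67, 'tv': 25.14, 'fbp': 23.1, 'fbp_dl': 21.95}
```

The certified bound is the product of the per-layer spectral norms computed
with a 1000-iteration power method on the shipped weights: 0.9915 ≤ 1 means
the denoiser is provably 1-Lipschitz. The comparison numbers are PSNR in dB
against the ground-truth phantom: the Plug-and-Play L-BFGS reconstruction
(29.7 dB) beats the TV baseline (25.1 dB), which beats filtered
backprojection (23.1 dB) — the same ordering and magnitudes the method is
designed to deliver on simulated data.

A `gipct` console script exposes the pipeline
(`simulate`, `retrieve`, `train-denoiser`, `reconstruct`, `evaluate`,
`spectrum`, `one-step`); every command writes a JSON reproducibility bundle
next to its output.

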