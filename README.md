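# voxelrep

Self-supervised voxel-level representation learning and unsupervised
segmentation for 3D grayscale microscopy volumes (e.g. FIB-SEM whole-cell
stacks).

Large volume-EM datasets resist manual annotation, but at small scale the
textures of subcellular structures — mitochondrial cristae stripes, dark
granule cores, speckled nucleoplasm, smooth cytosol — are stereotypical.
`voxelrep` exploits this: it attaches a latent vector to *every voxel* by
encoding the small patch centred on it, with no labels involved, and
clusters these vectors into an unsupervised segmentation.

**Method.** A 3D patch VAE is trained jointly with a metric-learning
objective. Anchors are random 16³-lattice patches of physical size
a ∈ [4, 12]; each anchor is accompanied by n_pos positives sampled in a
small ball around it, freely rotated, sheared, resized and
photometrically augmented. The batch loss is

    L = 1/(b·a³) ‖x − µ_x‖²  +  θ_KL · 1/(b·d) KL(N(µ_z, σ_z²) ‖ N(0,1))
        +  θ_MS · L_MS(S; α, β, λ)

where the multi-similarity term L_MS acts only on the cosine similarities
S of the first d_MS latent dimensions of µ_z. This splits the latent
space into a *semantic* subspace, trained to be invariant to the
augmentation transforms, and a free remainder that serves reconstruction.
At inference every voxel's fixed a = 8 patch is encoded, the semantic
µ_z[0:d_MS] is kept, and mini-batch k-means produces the segmentation,
scored against a reference labelling by Hungarian-matched mean Dice
(minimum-weight assignment on the negated Dice matrix
D_ij = 2·C_ij / (Σ_k C_ik + Σ_l C_lj) of the confusion matrix C).

The package is pure NumPy/SciPy/scikit-learn (the VAE runs on a small
bundled reverse-mode autodiff engine) and ships a synthetic phantom
generator so the whole pipeline is testable without external data.
See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
import voxelrep as vr

# a 64^3 four-texture phantom: cytosol, nucleus, mitochondrion, granules
volume, labels = vr.generate_phantom(vr.default_phantom_spec(seed=2))

est = vr.VoxelRepresentation(latent_dim=16, semantic_dim=8,
                             anchors_per_stack=20_000, random_state=2)
est.fit(volume)                       # ~3 min on one CPU core
latent = est.transform(volume)        # (8, 64, 64, 64) semantic means

seg = vr.LatentKMeans(k=4, random_state=2).fit_predict(latent)
report = vr.evaluate_segmentation(seg, labels)
print(f"final recon loss {est.log_[-1]['recon']:.3f}")
print(f"matching {report['pairs']}  mean Dice {report['mean_dice']:.3f}")
```

prints

```
final recon loss 0.781
matching [(0, 1), (1, 0), (2, 2), (3, 3)]  mean Dice 0.709
```

The matching pairs each k-means cluster with a ground-truth class
(cluster 0 ↔ nucleus, cluster 2 ↔ mitochondria, …) and the mean of the
matched Dice entries summarizes the segmentation. Across seeds 1–3 the
same protocol yields mean Dice between 0.62 and 0.72: three of the four
classes are typically recovered with Dice ≈ 0.85–0.93, while at k = 4
one cluster tends to collect boundary-shell voxels at the expense of the
weakest foreground class — the least favourable k for this method
family.

The same pipeline is scriptable from the shell:

```bash
voxelrep simulate --out phantom.h5 --seed 2
voxelrep train    --volumes phantom.h5 --out model.npz --seed 2
voxelrep infer    --checkpoint model.npz --volume phantom.h5 --out latent.h5
voxelrep cluster  --latent latent.h5 --k 4 --out seg.h5 --seed 2
voxelrep evaluate --pred seg.h5 --ref phantom.h5 --report report.json
# or everything at once from one YAML config:
voxelrep pipeline --config pipeline.yaml --out-dir run/
```

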