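# fibray — 3D fiber orientation analysis by ray-casting

`fibray` estimates the local 3D orientation of straight fibrous structures
in volumetric grayscale images — electrospun scaffold fibers in μCT
reconstructions, reinforcing fibers in composites, and similar materials
where fiber alignment governs mechanical and biological behavior.  It is
aimed at people who have a stack of reconstructed slices and want per-fiber
azimuth/elevation statistics without hand-tuned segmentation pipelines.

## Method

An orientation is an angle pair (θ, φ): elevation φ ∈ [0°, 90°] measured
from the stack (Z) axis and azimuth θ ∈ [−90°, 90°) in the XY plane, with
(0°, 0°) meaning a fiber along Z.  At a medial-axis voxel p the package
computes the discretized bidirectional ray-sum

    R(p, θ, φ) = Σ_{l=−⌊L/2⌋}^{⌊L/2⌋} V(nearest voxel of p + l·d(θ, φ)),
    d(θ, φ) = (sin φ cos θ,  sin φ sin θ,  cos φ),

and reports the direction maximizing R over a discrete angular grid
(default 1° steps; the ray length L spans the diagonal of the local
analysis window, L = round(√2·N_W)).  A ray aligned with the fiber axis
accumulates skeleton voxels along its whole length, so the argmax is sharp
for straight, separable fibers.  A windowed second-order structure tensor
(Σ ∇V∇Vᵀ over the N_W³ cube; smallest-eigenvalue eigenvector) is included
as the standard comparison baseline.

The full workflow is: 3×3×3 median filter → Otsu segmentation → 3D
topology-preserving thinning → orientation estimation at every skeleton
voxel → error statistics / histograms / polar error heatmaps.  A synthetic
phantom generator (rasterized straight cylinders with exact ground-truth
angles, plus an additive-Gaussian-noise + Gaussian-smoothing contamination
model) makes the entire chain testable end to end.  See
[docs/methods.md](docs/methods.md) for conventions, parameters and known
limitations.

## Worked example

```python
from fibray import PhantomSpec, AngularGrid, generate_phantom
from fibray.evaluate import run_workflow

spec = PhantomSpec(volume_size=128, n_fibers=8, radius_range=(3, 8),
                   gap_range=(3, 10), seed=7)
phantom, fibers = generate_phantom(spec)
print(f"placed {len(fibers)} fibers, {int(phantom.data.sum())} foreground voxels")

res = run_workflow(phantom, fibers, window=21,
                   grid=AngularGrid(azimuth_step=2, elevation_step=2))
for method, rep in res["reports"].items():
    print(f"{method:8s} mean|az err| = {rep.mean_azimuth:5.2f} deg   "
          f"mean|el err| = {rep.mean_elevation:5.2f} deg   "
          f"sites = {rep.n_sites}")
```

prints

```
placed 8 fibers, 71051 foreground voxels
raycast  mean|az err| =  2.03 deg   mean|el err| =  1.35 deg   sites = 578
tensor   mean|az err| =  0.77 deg   mean|el err| =  0.99 deg   sites = 578
```

i.e. on a clean 128³ phantom of 8 fibers, both estimators recover the
ground-truth axes to within a couple of degrees averaged over all 578
skeleton voxels; the ray-casting error here is dominated by the 2° scan
quantization and by near-Z fibers whose azimuth is intrinsically poorly
resolved.

The same pipeline is available from the shell:

```
fibray generate --size 128 --n-fibers 8 --seed 7 -o phantom.tiff --truth truth.h5
fibray estimate -i phantom.tiff --method raycast --window 21 \
       --truth truth.h5 -o field.csv
fibray evaluate --field field.csv -o report.json
fibray report --field field.csv --out-prefix results/phantom --png
```

Volumes are multipage TIFF stacks (or raw + YAML sidecar), orientation
fields plain CSV (`x,y,z,azimuth_deg,elevation_deg[,true_*]`), reports
JSON.

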