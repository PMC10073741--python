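# aortaflow

Whole-aorta 4D flow MRI analysis: vessel tortuosity, local normalized
helicity, turbulent kinetic energy (TKE) from the motion-encoded magnitude
signal, regional flow velocity and Reynolds number — together with a
synthetic flow-phantom generator and the cohort-level statistics needed to
compare groups (e.g. young vs. old subjects).

## The problem

Aortas elongate and become more tortuous with age, and tortuous vessels tend
to carry more helical ("corkscrew") flow, which in turn is thought to
suppress turbulent velocity fluctuations. Quantifying that chain requires
extracting, from time-resolved 3D phase-contrast MRI (4D flow MRI), both
geometric and hemodynamic descriptors per aortic region — ascending (AAo),
descending (DAo), suprarenal (SAA) and infrarenal (IAA) abdominal aorta —
and relating them across a cohort. No public datasets accompany this kind of
acquisition, so the package ships a phantom generator that emulates the
motion-encoded signal model with exactly known ground truth, making every
stage of the pipeline testable against closed forms.

## The quantities

- **Tortuosity** `T = (L/D − 1)·100` [%], with `L` the centerline arc length
  of a segment and `D` the Euclidean distance between its end points.
- **Helicity** (absolute local normalized helicity)
  `LNH = |V·ω| / (|V||ω|)` with vorticity `ω = ∇×V`; 0 = no helical flow,
  1 = velocity and vorticity aligned.
- **Turbulence**: the intravoxel velocity fluctuation σᵢ is decoded from the
  four-point motion-encoded magnitudes, `σᵢ² = (2/k_v²)·ln(|S|/|Sᵢ|)` with
  `k_v = π/VENC`, and `TKE = ½ρ Σᵢ σᵢ²` [J/m³] (ρ = 1060 kg/m³). σ² is kept
  signed, so a TKE estimate buried in noise can average slightly negative.
- **Velocity**: spatial mean speed per region over a ±5%-of-cycle window
  around regional peak systole.
- **Reynolds number** `Re = ρ·V·D/μ` (μ = 3.5·10⁻³ Pa·s).

The pipeline stages are: phantom simulation (or NIfTI ingestion) →
phase-unwrap and weighted 4th-order polynomial background-offset correction →
PC-MRA synthesis, lumen segmentation, skeleton-based centerline, landmark
mapping, four-region partition → voxel-wise and regional hemodynamics →
normality-gated group comparisons, Spearman correlations, and TKE
regressions.

## Worked example

```python
import aortaflow as af

spec = af.PhantomSpec(n_timeframes=20, snr=30.0, velocity_noise=True, seed=1)
data, gt = af.generate_phantom(spec)
metrics = af.analyze_subject(data, gt.landmarks_xyz, do_preprocess=False)
print(metrics[["region", "tortuosity", "diameter", "helicity",
               "tke", "velocity", "reynolds"]].round(3).to_string(index=False))
```

prints

```
region  tortuosity  diameter  helicity    tke  velocity  reynolds
 Whole      72.674    14.150     0.808 16.213     0.440  1884.093
   AAo      14.993    14.004     0.798 14.969     0.445  1885.490
   DAo      16.005    14.115     0.804 16.460     0.443  1892.340
   SAA       1.357    14.175     0.817 17.250     0.433  1856.844
   IAA       1.957    14.361     0.815 15.798     0.437  1898.621
```

This phantom prescribes a candy-cane aorta with whole-aorta tortuosity
76.2% (72.7% is recovered through segmentation and skeletonization), swirl
ratio 0.30, and a uniform fluctuation intensity σ = 0.1 m/s, whose exact TKE
is ½·1060·3·0.1² = 15.9 J/m³; the per-region values around 15–17 J/m³ show
the decode under Rician noise at SNR 30. The helicity column is the regional
mean LNH, and Reynolds numbers follow from the recovered mean speed and
equivalent-circle diameter.

Cohort-level use goes through `CohortSpec` / `run_cohort_analysis`, or the
CLI:

```bash
aortaflow run --out run/ --seed 7          # simulate + analyze + statistics
aortaflow simulate --out subj/ --seed 3    # one NIfTI dataset with sidecar
aortaflow metrics --in subj/ --out m.csv
```

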