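# bctsim

Simulation and calibration of breast shape after breast-conserving
therapy (BCT: lumpectomy followed by whole-breast radiotherapy), in a 2D
sagittal slice. The cosmetic outcome of BCT emerges from the interplay of
gravity acting on soft hyperelastic tissue, the pressure of seroma
filling the surgical cavity, the stiffening of inflamed and irradiated
tissue, and the slow filling of the wound by scar tissue. `bctsim`
couples three models to capture this and fits their patient-specific
parameters to breast-profile contours:

* **Tissue mechanics** — quasi-incompressible Neo-Hookean plane-strain
  finite elements (quadratic triangles) with strain energy
  `W = μ/2 (J^(-2/3) I₁ − 3) + K/2 (J − 1)²`, gravity as a body force,
  seroma as a follower pressure on the cavity wall, and fixed-point
  estimation of the unloaded (stress-free) configuration.
* **Wound healing** — a hexagonal cellular automaton on the unloaded
  geometry: empty wound-edge sites are colonised with probability
  `p = F(c)(α₀ + α₁·Ê)`, where the growth factor `c` obeys
  `∂c/∂t − DΔc + Λc = χ_a.l.` with a unit source in an active layer
  around the wound edge, and `Ê` is the normalised mechanical stimulus
  mapped from the loaded configuration. Mechanics and healing alternate
  on a weekly clock, remeshing the breast around the shrinking wound.
* **Calibration** — each healing phase (0: pre-surgery; I: inflammation,
  weeks 1–6; II: healing, weeks 7–20; III: radiotherapy, weeks 21–35)
  exposes 2–3 unknowns `α` that are fitted by exhaustive surface-response
  search of `f(α, s) = Σᵢⱼ |C^model − s·C^obs|`, the mismatched-cell
  count of the model and observed contours rasterised at the MRI pixel
  pitch (0.7031 mm); `s` is a nuisance aspect ratio absorbing the
  unknown photograph scale.

Because clinical images from such studies are not released, the package
ships a first-class synthetic-phantom generator (label maps, MRI-like
images, noisy observed contours produced by the forward model at known
parameters), so the entire pipeline — fuzzy C-means segmentation,
Tikhonov skin smoothing, meshing, virtual lumpectomy, healing, fitting —
runs and is tested end to end without patient data.

Intended users: researchers in surgical-outcome modelling and
computational biomechanics who want a small, fully testable reference
implementation of a multiphase BCT outcome model.

## Worked example

Fit the inflammation phase (Phase I) on the default phantom. The
synthetic observation is generated by the forward model at
λ₁ = 2.0, P = 120 Pa; the grid search recovers it exactly with a zero
objective:

```python
import numpy as np
from bctsim import PhantomSpec, generate_phantom, generate_observation
from bctsim.calibration import FixedParams, fit_phase

spec = PhantomSpec(rng_seed=0)
label_map = generate_phantom(spec)
prior = {"E_fat": 3.7, "E_glandular": 9.5, "E_skin": 25.0}  # Phase-0 moduli
obs = generate_observation(label_map, "I", {"lambda1": 2.0, "P": 120.0},
                           seed=3, spec=spec, fixed=FixedParams(),
                           prior=prior)
fit = fit_phase("I", obs, {"lambda1": np.arange(1.0, 3.01, 0.5),
                           "P": np.arange(0.0, 361.0, 60.0)},
                label_map=label_map, spec=spec, prior=prior)
print(fit.argmin, fit.f_min, fit.s_hat)
```

```
{'lambda1': 2.0, 'P': 120.0} 0.0 1.0
```

`fit.argmin` is the fitted parameter vector (stiffness scaling 2.0,
seroma pressure 120 Pa — the planted truth), `fit.f_min = 0` means the
simulated and observed contours rasterise identically, and
`fit.s_hat = 1` is the recovered photograph scale. `fit.f` holds the
full objective surface; on this grid its range is ~30× larger along λ₁
than along P — the sensitivity anisotropy a seroma pressure of this
size implies.

The same study runs from the shell:

```bash
bctsim run-all --seed 0 --out study_out     # all four phases + report
bctsim fit --phase I --seed 0               # one phase
bctsim phantom --seed 0 --out phantom_out   # label map, MRI image, contour
```

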