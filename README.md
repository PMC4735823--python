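# invadopotts

Hybrid cellular Potts simulations of cancer-cell invasion through
fibrillar extracellular matrix (ECM), for computational biologists
studying how cell–cell adhesion, protease secretion, and matrix density
and organization select between single-cell and collective invasion.

A tumour aggregate of 69 motile cells sits at the centre of a 1 mm²
lattice meshed with straight collagen-like fibres.  Cells evolve by
Graner–Glazier–Hogeweg (CPM) dynamics under the Hamiltonian

```
E = Σ_edges J(τ_i, τ_j) + Σ_c λ_a (a(c) − a0)² + Σ_c λ_p (p(c) − p0)²
```

with Metropolis acceptance `min(1, exp(−ΔE/T_m))`, plus an active
self-propulsion bias `−μ0 p̂(c)·Δx_copy` per copy attempt, where the
polarity `p̂(c)` is the normalized sum of the cell's last 10 centroid
displacements (a velocity-aligned persistent random walk).  Cells touching
fibres secrete matrix metalloproteinases (MMPs) at rate λ into a
continuous field obeying

```
∂[MMP]/∂t = D ∇²[MMP] − δ_MMP [MMP]
```

solved by forward Euler in 36 one-second substeps per Monte Carlo step
(1 MCS = 36 s); any fibre pixel whose MMP count reaches 1 is degraded to
fluid, opening migration tracks.  Scenario presets sweep cell–cell
adhesion (J_cc = 1, 16, 40: epithelial → mesenchymal), secretion rate
(λ = 0.01–0.1 s⁻¹), fibre count (ξ = 400–1000) and fibre orientation
(random vs aligned), and the metrics module quantifies invasion: total
distance, net translocation, radius of gyration, % ECM degradation and
cluster statistics.  See `docs/methods.md` for the full model description.

## Worked example

Run a desk-scale adhesion contrast (250 × 250 lattice, 900 MCS ≈ 9 h of
biological time, proteolysis at λ = 0.05):

```python
from invadopotts import ScenarioConfig, run_scenario

cfg = ScenarioConfig(
    j_cc=(1.0, 40.0), secretion=(0.05,), xi=(150,),
    n_mcs=900, n_replicates=3, lattice_px=250, base_seed=0,
)
res = run_scenario(cfg)
print(res.table.groupby("j_cc")[
    ["d_total_um", "d_net_um", "pct_degradation", "n_clusters"]
].mean().round(2))
```

```
      d_total_um  d_net_um  pct_degradation  n_clusters
j_cc
1.0       405.93     92.07             6.47        1.00
40.0      274.12     86.74             9.10        1.33
```

At strong cell–cell adhesion (J_cc = 1) the population invades as one
cohesive cluster, moving much further in total (dynamic rearrangements
inside the moving group) and translocating at least as far — while
degrading *less* matrix.  At weak adhesion (J_cc = 40) the aggregate
begins to shed cells into separate clusters (EMT-like scattering) whose
greater exposed surface contacts more fibres, secretes more MMP and
degrades more ECM for no extra net displacement.  This is the model's
central observation: collective invasion is the more ECM-efficient mode.

The same objects drive the command line:

```bash
invadopotts ecmgen --xi 600 --mode aligned --seed 7 --out mesh.piff
invadopotts run --preset fig2 --desk --seed 42 --out results/fig2
```

`ecmgen` writes CompuCell3D-style PIFF layouts; `run` writes a metrics CSV,
the resolved config and a hashed run manifest.

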