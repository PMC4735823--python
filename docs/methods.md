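# Methods

## Model overview

`invadopotts` simulates the dissemination of a tumour-cell aggregate
through a fibrillar extracellular matrix with a two-dimensional hybrid
cellular Potts model (CPM / Graner–Glazier–Hogeweg model) coupled to a
reaction–diffusion field of soluble matrix metalloproteinases (MMPs).

The domain is a 1 mm × 1 mm lattice of 2 µm pixels (500 × 500).  Each
pixel belongs to one of three entity classes: a **cell** (multi-pixel
deformable domain with its own integer id), an **ECM fibre** (rigid,
immobile, degradable), or **interstitial fluid** (a single unconstrained
background domain).  The initial condition is a disk-shaped aggregate of
69 square cells (20 µm side, 400 µm² area) at the lattice centre — leaving
a 400 µm margin of matrix in every direction — embedded in a mesh of `xi`
straight fibres, each one pixel (2 µm) thick and 30–40 µm long, oriented
either uniformly at random on [0, π) or all horizontally ("aligned").

## Lattice dynamics

The static Hamiltonian is

```
E = Σ_edges J(τ_i, τ_j)  +  Σ_cells λ_a (a(c) − a0)²  +  Σ_cells λ_p (p(c) − p0)²
```

with contact energies `J` charged on 4-neighbour lattice edges whose
pixels belong to *different* domains, an area constraint (inverse
compressibility) and a perimeter constraint (cortical tension).  One Monte
Carlo step (MCS) performs `N` copy attempts, `N` being the number of
evolvable (cell + fluid) pixels: a random evolvable source pixel attempts
to copy its id onto a random 4-neighbour target.  Fibre pixels never
participate; same-domain pairs are skipped (both count towards `N`).  A
move is accepted if ΔE < 0 and with probability `exp(−ΔE/T_m)` otherwise.

### Active motility

Cells are self-propelled.  Each cell carries a unit polarity vector
`p̂(c)`, recomputed once per MCS as the normalized sum of its last
τ = 10 centroid displacements, so polarity aligns with recent velocity (a
persistent random walk that, under confinement, produces the collective
rotation used to calibrate the motility strength).  Every copy attempt is
biased by the self-propulsion work

```
w = − μ0 Σ_{affected cells} p̂(c) · (x_target − x_source)
```

i.e. ±μ0 per copy aligned with / against the polarity, the same order of
magnitude as the contact energies (μ0 carries units of k_BT per pixel
length L, and the copy vector has length L).  This term is an active,
non-variational force, not the gradient of a lattice energy: the
acceptance ΔE equals the static-Hamiltonian difference *plus* `w`, and the
oracle tests verify the two parts independently.  We deliberately did not
implement motility as a centroid-displacement work (−μ0 p̂·Δr_c): with
these parameter magnitudes that form contributes at most
μ0/a ≈ 0.5 k_BT per copy against interface quanta of 30–60 k_BT, which
freezes the dynamics entirely in the low-noise regime.

Two bootstrap choices follow from the same low-noise regime
(T_m = 0.01 k_BT means no purely thermal move is ever accepted, so an
unpolarized cell is a fixed point): cells start with a randomly oriented
unit polarity, and a cell whose whole displacement window is exactly zero
retains its previous polarity instead of de-polarizing.  A window of
nonzero displacements that cancels exactly still yields the zero vector.

## Units and parameter values

Energies are in k_BT; lengths internally in pixels (1 px = 2 µm), with
µm/µm² conversions only at I/O.  Reference values:

| parameter | value | meaning |
|---|---|---|
| lattice | 500 × 500 px (1 mm²) | 2 µm pixels |
| (J_cc, J_ce, J_cf, J_ef, J_ee, J_ff) | (1–40, 16, 32, 35, 5, 35) | contact energy per edge; low J = strong adhesion |
| λ_a | 1.0 | area constraint |
| a0 | 100 px² (400 µm²) | target cell area |
| λ_p | 0.5 | perimeter constraint |
| p0 | 35 edges | target cell perimeter |
| T_m | 0.01 k_BT | noise strength (membrane fluctuation amplitude) |
| μ0 | 50 k_BT/L | motility strength |
| τ | 10 MCS | polarity memory |
| 1 MCS | 36 s | set by the speed calibration |
| D | 0.1 µm²/s | MMP diffusion coefficient |
| δ_MMP | 0.002 s⁻¹ | MMP decay rate |
| λ | 0.01–0.1 s⁻¹ | MMP secretion rate (swept) |

The perimeter target is read in **lattice edge units**, not micrometres.
A 400 µm² cell has at least 80 µm (40 edges) of physical perimeter, so a
literal 35 µm target would be geometrically unreachable and would sit as a
frozen ~45 k_BT-per-edge penalty on every boundary rearrangement —
blocking, in particular, the cell–cell peeling that produces single-cell
scattering at weak adhesion.  At p0 = 35 edges a cell–cell peel costs
about +24 k_BT in contact energy at J_cc = 40 (accepted against the ~50
k_BT motility bias) but +63 k_BT at J_cc = 1 (rejected), which is exactly
the adhesion-controlled switch between single-cell and collective
invasion.  J_cc = 1 models the epithelial (high-adhesion) phenotype,
J_cc = 16 an intermediate one and J_cc = 40 the mesenchymal
(post-EMT) phenotype; because J_cc = 40 < 2·J_cf = 64, scattering is
kinetic (motility-driven) rather than an equilibrium dewetting.

## MMP dynamics and proteolysis

A cell in contact with a fibre secretes MMPs *at the fibre pixel* at rate
λ per second — one deposit per contacted fibre pixel per 1-s substep,
regardless of how many cell pixels touch it (contact = any cell pixel in
the fibre pixel's Moore neighbourhood).  Denser meshes expose more
contact pixels, so secretion is ECM-density-dependent without any extra
rule.  The field then evolves by

```
∂[MMP]/∂t = D ∇²[MMP] − δ_MMP [MMP]
```

integrated with forward Euler (5-point Laplacian, Δt = 1 s, zero-flux
boundaries).  Since one MCS is 36 s and all rates are per second, the
solver runs 36 substeps per MCS (secrete, then diffuse/decay, each
substep).  The stability number r = DΔt/Δx² = 0.025 is far below the 2D
bound of 0.25; positivity is preserved exactly (all stencil weights are
non-negative), with a hard clamp at 0 as a guard.  Once per MCS, after
the substeps, every fibre pixel whose MMP count has reached 1 is degraded:
the pixel becomes fluid and the local count drops by 1.  Degradation is
the only process that changes the fibre population, and fibres do not
obstruct diffusion.

For performance the engine integrates the PDE on a padded bounding box of
the non-negligible field (values ≥ 1e−9 against a degradation threshold of
1; the box is re-derived every MCS with a 10 px pad, well beyond the
~1.4 px/MCS diffusive spread).  The box edge reflects like the lattice
edge; the approximation error is bounded by the sub-1e−9 amplitudes at
the box rim.

## Quantification of invasion

Per replicate, over the 69-cell population:

- **d_total** — mean per-cell path length, summing centroid moves between
  successive MCS (mobility / dynamicity);
- **d_net** — mean |final − initial| displacement (effective invasion);
  d_net ≤ d_total is asserted on every run;
- **RoG** — root-mean-square distance of final positions from the initial
  population centroid (scattering);
- **% ECM degradation** — percentage of the initial fibre pixels removed;
- **cluster statistics** — connected components of the cell-contact graph
  (two cells adjacent iff any of their pixels are 4-neighbours; the
  4-connectivity choice matches the contact-energy neighbourhood).

## Calibrations

**Speed.**  `calibrate_speed` measures the mean per-MCS centroid
displacement (×100 MCS/h) of isolated cells migrating in fibre-free
channels between full-width horizontal fibre lines (a stand-in geometry
for a sparse ECM with pre-existing paths; channel pitch 20 px, cells well
separated, proteolysis off, 150 MCS with a 30-MCS burn-in, ≥3 seeds).
With the reference parameters this yields ≈23 µm/h, the experimental
value that fixed the 36 s/MCS conversion.

**Rotation.**  `build_confined_aggregate` encloses the aggregate in a
non-degradable circular fibre ring; the velocity-aligned polarity rule
then produces persistent collective rotation, detected as a time-averaged
angular momentum exceeding a shuffled-velocity-history null (p < 0.01).
This is the qualitative behaviour that motivated the choice of μ0.

## Scenario presets and problem sizes

Full-scale presets reproduce the reference experiment grids: 500 × 500 lattice,
1800 MCS (18 h), 10 replicates; `fig2` sweeps J_cc ∈ {1, 16, 40} at
λ = 0.05, `fig3` adds λ ∈ {0.01, 0.05, 0.1}, `fig4` sweeps
ξ ∈ {400, 600, 1000} (`fig4_high_lambda` at λ = 0.1), and `fig5` disables
proteolysis and contrasts random with aligned meshes.  The fibre count for
the fig2/fig3 presets defaults to ξ = 600, the middle of the density grid.

The stochastic regression suite runs in *desk-scale* mode: 250 × 250
lattice, fibre counts scaled by the area ratio (100/150/250), 5 replicates
per condition, and run lengths chosen for the observable at hand — the
adhesion/secretion grids run the full 1800 MCS (the collective-to-single
breakup at J_cc = 40 only begins around MCS 600, so shorter runs cannot
express the cluster and degradation contrasts), the density grids 900 MCS,
and the proteolysis-off contact-guidance grid 600 MCS, where the
aligned-versus-random contrast develops early.  Replicate `r` of every
condition draws its mesh and
dynamics seeds from the same `SeedSequence(base_seed + r)`, pairing the
comparisons across conditions.  Orderings are tested with one-sided
Mann–Whitney rank tests at α = 0.05 (the reference results report
mean ± SEM without naming a test; a rank test is the conservative choice
at n = 5).

## What the generator does and does not emulate

The synthetic ECM reproduces fibre density, length, thickness and
orientation statistics, but not fibre mechanics (bending, displacement,
strain stiffening), crosslink density as an explicit variable, 3D pore
topology, or matrix heterogeneity.  Cells are mechanically identical (no
heterogeneity, division, death or supply from a primary site), and MMPs
are purely soluble — no membrane-tethered proteases or activation
cascades.  Passing the regression suite therefore shows that the *model's*
documented behaviours are reproduced, not that real tissue would behave
identically.

## Numerical choices

- First-order (4-neighbour) adjacency everywhere a neighbourhood is
  needed for energetics: contact edges, copy attempts, perimeter counting
  (each edge is 2 µm of boundary).  Secretion contact uses the Moore
  (8-)neighbourhood, reflecting the looser notion of "touching" a fibre.
- Lattice-boundary edges carry no contact energy and do not count toward
  perimeters; cells start 200 px from the boundary and the full-scale
  geometry guarantees ≥400 µm of clearance.
- Fibres overlap by sharing pixels (no stacking); fibres crossing the
  domain edge are clipped, preserving the exact count ξ.
- Fibre pixels under the initial aggregate are deleted at t = 0, so no
  illegal cell-on-fibre state ever exists.
- The aggregate packing rule: cells occupy 10 × 10 px blocks on a grid
  centred on the lattice; a block is a cell iff its centre lies within the
  aggregate disk.  The default radius is the smallest 1-px-step radius
  that yields the reference 69-cell population (90 µm, i.e. a ~180 µm
  aggregate, consistent with the nominal 200 µm initial population).
- Metropolis acceptance draws are pre-generated per MCS from a PCG64
  stream; each replicate owns one seeded generator, so every run is
  exactly reproducible from (base_seed, replicate).
- Cell fragmentation is allowed (no connectivity constraint); fragment
  loss of the last pixel removes the cell from the records and is logged.
  Under the reference area constraint this does not occur in practice.
- CSV output is written at 6 significant digits for cross-platform
  byte-reproducibility.

## Known limitations

- Absolute energy scales depend on the neighbourhood-order and perimeter
  conventions above; orderings across conditions are the robust
  observables, and absolute invasion distances should be compared only
  within a convention.
- For cohesive populations (J_cc ≤ 16) the net-translocation metric is
  floored by intra-cluster circulation: cells continuously exchange
  positions inside the moving cluster, so each cell's |final − initial|
  displacement is at least of order the cluster radius (~90 µm) regardless
  of how far the cluster itself invades.  Condition effects smaller than
  this floor (notably the ECM-density dependence of d_net, which is strong
  and monotone for isolated cells) are not resolvable at the population
  level in this implementation; the radius of gyration and the
  single-cell regime are the sharper readouts.
- With J_cc = J_ce = 16 cells trade cell–cell for cell–fibre contact at
  zero adhesive cost and stream along fibres; this makes the
  intermediate-adhesion condition the most invasive and the heaviest MMP
  secretor here, whereas the degradation and MMP totals of the reference
  results vary monotonically with J_cc.  The discrepancy traces to the
  convention-dependent balance between contact energies and the motility
  bias, not to the secretion or degradation rules.
- Under the motility bias, cell areas equilibrate where the quadratic
  area gradient (2 λ_a |a − a0|) balances the ±μ0 per-copy work, giving a
  steady state around 90 ± 15 px rather than a tight band at a0 = 100 px;
  occasional cells transiently sit more than 20% below target.  Raising
  λ_a would tighten the band at the cost of stiffer, slower cells.
- The desk-scale suite detects orderings at n = 5 replicates; marginal
  effects (e.g. the cluster-count contrast, which needs the slow breakup
  kinetics) carry the usual rank-test granularity at this sample size.
- The 2D lattice treats a mid-plane slice of a spheroid; out-of-plane
  fibre geometry and cell escape are absent by construction.
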