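# hydrashell

Hydration-shell dynamics analysis for molecular-dynamics trajectories.

Water at a protein surface behaves differently from bulk water: it diffuses
and reorients more slowly, exchanges in and out of the first hydration layer
on two distinct time scales, and its hydrogen bonds to the protein relax
through both sub-picosecond partner exchange and slow, diffusion-controlled
escape. `hydrashell` computes the standard observables of this protein–water
coupling from MD trajectories (PDB/GRO structures with optional XTC/DCD
trajectories, GROMACS units: nm, ps):

- **Structure** — per-atom/per-residue RMSF, RMSD against a reference frame
  with least-squares (Kabsch) superposition, and Shrake–Rupley-style
  solvent-accessible surface area.
- **Transport** — multi-time-origin mean square displacement
  MSD(t) = ⟨|r_i(t₀+t) − r_i(t₀)|²⟩ with the Einstein-relation diffusion
  coefficient D = slope/6, windowed MSD summaries, radial distribution
  functions g(r) with first-peak statistics and the de-packing ratio
  g(r)_min/g(r)_max, and two-segment breakpoint detection for the protein
  dynamical transition in MSD-vs-temperature curves.
- **Hydration dynamics** — shell membership (water oxygen within a cutoff,
  0.6 nm by default, of any reference atom), the residence correlation
  C_r(t) = ⟨N_t(t₀ → t₀+t)/N_t₀⟩ fitted by the biphasic stretched-exponential
  model C_r(t) = n_s·exp(−(t/τ_s)^γ) + n₁·exp(−t/τ₁), and the rank-1 water
  dipole autocorrelation C_μ(t) = ⟨μ̂(0)·μ̂(t)⟩ fitted by A_μ·exp(−t/t_μ).
- **Hydrogen-bond kinetics** — geometric detection (D–A distance < 0.35 nm
  and H–D–A angle < 30°), per-frame bond counts, the continuous lifetime
  τ_HB (mean unbroken bonded interval), the intermittent population
  correlation c(t) = ⟨h(0)h(t)⟩/⟨h⟩, and the relaxation time τ_R at which
  c(t) first decays to 1/e.
- **Synthetic generators** — Brownian walkers with known D, rigid SPC/E-
  geometry waters under isotropic rotational diffusion with known D_rot,
  two-state Markov on/off indicator series with known k_on/k_off, a shell
  system whose occupancy is recoverable exactly by construction, and
  piecewise-linear temperature curves with a planted breakpoint. Every
  estimator in the package is validated against these ground truths.

## Worked example

```python
import hydrashell as hs

# hydration-water reorientation: rotors with D_rot = 0.1 / ps
rotors = hs.gen_rotors(n_molecules=1000, D_rot=0.1, dt=0.05, n_frames=201, seed=42)
c_mu = hs.dipole_autocorrelation(rotors, max_lag=10.0, origin_stride=20)
fit = hs.fit_reorientation(c_mu)
print(f"t_mu = {fit.params['t_mu']:.3f} +/- {fit.param_uncertainty['t_mu']:.3f} ps")

# hydrogen-bond population kinetics on a two-state Markov model
h = hs.gen_two_state_series(n_series=2000, k_on=0.1, k_off=1.0, dt=0.01,
                            n_frames=10_000, seed=42)
series = hs.HBondSeries.from_matrix(h, dt=0.01)
tau_hb = hs.continuous_lifetime(series)
c = hs.intermittent_correlation(series, max_lag=3.0, origin_stride=20)
tau_r, _ = hs.relaxation_time(c)
print(f"tau_HB = {tau_hb:.3f} ps, tau_R = {tau_r:.3f} ps")
```

prints

```
t_mu = 4.918 +/- 0.010 ps
tau_HB = 0.996 ps, tau_R = 1.073 ps
```

`t_mu` is the characteristic water reorientation time; for l=1 rotational
diffusion the exact value is 1/(2·D_rot) = 5 ps. `tau_HB` is the mean
unbroken bond lifetime (exactly 1/k_off = 1 ps for the Markov model) and
`tau_R` the 1/e decay of the intermittent correlation
c(t) = p + (1−p)·e^{−(k_on+k_off)t}, whose closed-form root is 1.081 ps at
these rates — the estimates sit within sampling error of all three.

## Command line

```sh
hydrashell synth --kind brownian --n 400 --frames 2000 --prefix walk
hydrashell msd --coord walk.gro --traj walk.xtc --fit-min 10 --fit-max 100 --out msd.csv
hydrashell residence --coord sys.gro --traj sys.xtc --cutoff 0.6 --window 200
hydrashell hbond-kinetics --coord sys.gro --traj sys.xtc --max-lag 500
hydrashell run --config analysis.yaml     # full pipeline, JSON report
```

Exit codes: 0 success, 2 configuration error, 3 input error, 4 analysis
error.

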