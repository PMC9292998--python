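# rheodipole

A minimal hydrodynamic model of how a swimmer orients in a confined channel
flow. The swimmer is a potential-flow vortex dipole between two walls; the
walls are enforced by the method of images (with an exact resummation of the
image ladder), a weakly sheared background flow is superposed, and an optional
"lateral-line" feedback turns the swimmer in proportion to the circulation it
senses over a body-sized rectangle. Because the streamwise coordinate
decouples, the cross-stream position and heading obey a planar dynamical
system whose upstream equilibrium undergoes a pitchfork at
`beta* = pi^4/32 ≈ 3.044` of the combined parameter
`beta = alpha (1 + kappa) / rho^2`; above the threshold, upstream swimming is
a neutral center surrounded by periodic cross-stream sweeping orbits with
small-amplitude radian frequency `~ (pi^2/2) rho sqrt(beta/beta* - 1)`.

## Layout

- `rheodipole.flow` — dipole potential/velocity, wall images (exact closed
  form and truncated series with a `TruncationPolicy`), background profile,
  vorticity, circulation over an oriented rectangle, field-grid export.
- `rheodipole.dynamics` — dimensional equations of motion: de-singularized
  advective velocity, hydrodynamic turn rate (plus a finite-separation vortex
  pair oracle), lateral-line feedback, and trajectory integration with
  wall-proximity event termination.
- `rheodipole.planar` — the nondimensional reduced system: right-hand side,
  equilibria via bracketed root finding, trace-free linearizations,
  saddle/neutral-center classification, the bifurcation sweep, sweeping
  frequency, phase-portrait and transcendental-curve tables.
- `rheodipole.presets` — nondimensionalization helpers, the threshold-ratio
  estimate of the feedback gain, and nine packaged literature-derived
  parameter presets (point/interval/missing entries).
- `rheodipole.cli` — `rheodipole` command with subcommands
  `field`, `analyze`, `sweep`, `portrait`, `simulate`, `fig5`.

## CLI examples

```sh
# equilibria, stability and sweeping frequency at beta = 20
rheodipole analyze --rho 0.1 --alpha 0.1 --kappa 1 --out out/

# bifurcation diagram over beta in [0.1, 100] (log-spaced)
rheodipole sweep --beta-min 0.1 --beta-max 100 --n-beta 101 --out out/ --plot

# velocity field around an upstream-heading swimmer at mid-channel
rheodipole field --y0 0.5 --theta0 3.141592653589793 --out out/

# planar trajectory from (xi=0.05, theta=pi) at beta = 20
rheodipole simulate --rho 0.1 --alpha 0.1 --kappa 1 --xi0 0.05 --horizon 100 --out out/

# a packaged literature preset
rheodipole analyze --preset mexican-tetra --out out/
```

Parameters can also come from a flat YAML/JSON config (`--config file.yaml`,
flags override the file). CSV outputs carry a leading `#` JSON metadata line
with the fully resolved parameters and package version; JSON reports embed
the same block.

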