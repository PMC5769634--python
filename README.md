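# blastosim

Particle-based simulator of early nematode embryogenesis at the four-cell
stage. Blastomeres are soft spheres moving by overdamped Langevin dynamics
inside a rigid ellipsoidal eggshell, under a piecewise repulsion/attraction
pairwise force law with per-pair stable-repulsion ratios (α) and a repulsive
shell response. Programmed cell divisions (orientation, timing, volume
asymmetry) take the embryo from two to four cells; the final arrangement is
classified from the cell–cell contact graph (pyramid, diamond, T-shaped,
linear, T-reverse, H-shaped). An experiment driver runs replicated
aspect-ratio sweeps at constant eggshell volume for the repulsion-only (RO,
all α = 1) and asymmetric-attraction (AA, α = 0.90 for EMS–P2, 0.75
otherwise) models.

## Package layout

| module                    | contents                                                        |
|---------------------------|-----------------------------------------------------------------|
| `blastosim.geometry`      | eggshell ellipsoid, constant-volume reshaping by aspect ratio, minimum point-to-shell distance and inward normal |
| `blastosim.mechanics`     | pairwise force law, shell repulsion, per-pair α table, net forces |
| `blastosim.division`      | division programs (T/I/H/C orientation classes, timing and volume modes), mother→daughters transformation |
| `blastosim.simulator`     | Euler–Maruyama integration (Δt = 5 s), seeded runs, trajectories |
| `blastosim.classify`      | contact graph (strict d < Rᵢ+Rⱼ), arrangement classification, stable-repulsion ratio |
| `blastosim.experiments`   | replicated AR sweeps, frequency tables, CSV I/O                  |
| `blastosim.config`        | frozen default TOML configuration, validation                    |

## CLI

```sh
# one seeded replicate; prints the classified pattern as JSON
blastosim simulate --model aa --ar 1.6 --seed 1 --out traj.csv

# replicated aspect-ratio sweep (frequency CSV, optional stacked-bar plot)
blastosim sweep --model ro --division T --ar-min 1.0 --ar-max 4.0 \
    --ar-step 0.1 --reps 30 --seed 0 --out sweep.csv

# classify a four-cell fixture (columns: label,x,y,z,radius)
blastosim classify cells.csv

# two-cell relaxation diagnostics (equilibrium separation ratio)
blastosim calibrate --ar 1.6
```

All commands accept `--config path.toml`; the packaged default
(`src/blastosim/data/default.toml`) is the frozen configuration used by the
acceptance runs.

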