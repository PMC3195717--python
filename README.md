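# dissipy

Simulate how a localized kinetic-energy kick spreads through a
coarse-grained protein and characterize the process quantitatively.

The pipeline:

1. **structures** — read a PDB file into a one-bead-per-residue (Cα)
   chain and annotate structural regions.
2. **enm** — build a distance-cutoff harmonic (elastic) network, draw
   Maxwell–Boltzmann velocities, optionally equilibrate with a
   deterministic rescaling thermostat, then run *paired* NVE
   trajectories: one with the velocities of chosen residues scaled by a
   factor *f*, one untouched, from the identical initial state.
3. **response** — subtract the reference from the perturbed per-residue
   energy traces, assign each residue a response time Δt (earliest
   sustained threshold crossing of |ΔE|), and accumulate the dissipation
   curve NR(t) = number of residues responded by time t.
4. **fitting** — fit NR(t) with a two-state Boltzmann sigmoid
   (half response time t0, time constant dt, rate constant
   NR′ = (NR₂ − NR₁)/(4·dt)) and variant-minus-wild-type difference
   curves with a Lorentzian peak (height h = NR₀ + 2A/(πw)).
5. **modules** — bin residues into fixed-width dynamical modules by Δt
   (default 0.1 ps), cross-tabulate against regions, and difference
   variant vs wild-type tables and curves.
6. **synth** — deterministic fixtures: toy chain/helix/globule
   structures, model curves with stored ground truth, block annotations,
   and a stiffness-scaled "variant" network surrogate.

Units: Å, fs, amu, kcal/mol throughout.

## CLI

```sh
# toy structure, paired run, analysis
dissipy synth structure --n 100 --kind globule --seed 7 --out globule.pdb
dissipy simulate globule.pdb --perturb 1 --factor 4 --n-steps 8000 \
    --cutoff 7 --seed 3 --equilibration-steps 500 --out-dir run/
dissipy analyze --perturbed run/perturbed.trace.tsv \
    --reference run/reference.trace.tsv --threshold 0.007 --out-dir run/

# standalone fitting of any (t, NR) or (t, dNR) table
dissipy synth boltzmann --t0 500 --dt 100 --out curve.tsv
dissipy fit boltzmann curve.tsv --nr2 447
dissipy fit lorentz difference.tsv

# variant comparison (difference curve, peak fit, module deltas)
dissipy compare --wt-curve wt.tsv --var-curve v1.tsv --var-curve v2.tsv \
    --inhibition v1=0.08 --inhibition v2=0.23 --out-dir cmp/
```

Every stage writes a manifest (config echo, input hashes, seed) so runs
are reproducible bit-for-bit. Exit codes: 0 success, 2 input error,
3 numerical/fit error.

## Detection policy

The response criterion is explicit and configurable: a residue responds
at the earliest saved frame where |ΔE| ≥ θ holds for `sustain`
consecutive frames (defaults θ = 0.1 kcal/mol, sustain = 3); a
`relative` mode scales θ per residue from a null-control trace.
Perturbed residues respond at t = 0 by definition, so NR(0) equals the
number of perturbed residues. All outputs echo the policy used.

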