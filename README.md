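# lipidflux

Analysis toolkit for leaflet-specific phospholipid modulation of pentameric
ligand-gated ion channels: stopped-flow flux kinetics statistics, alchemical
free-energy estimation with convergence diagnostics, and an allosteric model
that converts state-dependent lipid-binding free energies into site-occupancy
curves, x50 values, and conformational-stability landscapes over ternary
lipid compositions.

## What's inside

| Subpackage | Purpose |
|---|---|
| `lipidflux.synth` | Synthetic data with known ground truth for every input class: stretched-exponential quenching traces, agonist-delay series, Crooks-consistent Gaussian work samples, Hill dose-response records, rigid-body coordinate snapshots. |
| `lipidflux.kinetics` | Stretched-exponential trace fitting, instantaneous flux rates (evaluated at 2 ms by default), activation/desensitization time courses with amplitude-weighted time constants, Hill dose-response fits. |
| `lipidflux.fep` | EXP and BAR free-energy estimators for bidirectional per-window work samples, replica aggregation, statistical-inefficiency subsampling, hysteresis and first/second-half convergence diagnostics, lambda schedules, and the distance-to-bound-configuration (DBC) coordinate with Kabsch superposition. |
| `lipidflux.thermo` | The allosteric lipid-site model: thermodynamic-cycle replacement free energies, relative binding constants, three-species occupancy, x50 on the 2:1:x POPG path, and stability log-ratio maps over the ternary simplex. A transformation free-energy table is packaged as a TSV fixture. |
| `lipidflux.io`, `lipidflux.cli`, `lipidflux.config` | TSV/CSV/JSON/fepout readers and writers with provenance headers, YAML/JSON run configuration, and the `lipidflux` command-line multiplexer. |

## CLI

All subcommands accept `--seed`, `--config` (YAML/JSON) and `--out`; outputs
carry a provenance header (package version, seed, config hash) and are
bit-reproducible for fixed seed and inputs.

```sh
lipidflux simulate-trace --tau 0.05 --beta 0.85 --noise-sd 0.01 --seed 1 --out trace.csv
lipidflux fit-flux trace.csv --out fit.json
lipidflux timecourse traces_dir/ --out timecourse.json   # files named ...delay=<s>...csv
lipidflux doseresponse dose.tsv --out hill.json

lipidflux simulate-fep --dg 1.0,-0.5,0.5 --samples 2000 --seed 1 --out work.tsv
lipidflux fep-estimate work.tsv --out dg.json            # several tables = replicas
lipidflux fep-diagnose work.tsv --out report.json
lipidflux dbc-profile ref.pdb snap1.pdb snap2.pdb --out dbc.json

lipidflux thermo-x50 --conformation WT_CA --out x50.json
lipidflux thermo-occupancy --conformation ELIC5_CA --composition 0.5,0.25,0.25
lipidflux thermo-map --resolution 51 --out stability_map.tsv
```

`thermo-*` commands default to the packaged free-energy table; pass
`--table your_table.tsv` (schema: environment, species_from, species_to,
dg_kcal_mol, err_kcal_mol) to use your own.

## Conventions

Units are fixed package-wide: seconds, kcal/mol, kelvin, angstrom, mole
fraction. RT uses R = 0.0019872041 kcal/(mol K) and defaults to T = 303.15 K.
Backward work samples are the work of the reverse (b -> a) perturbation;
backward EXP estimates are sign-corrected to the forward convention so
forward, backward, and BAR values are directly comparable.
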