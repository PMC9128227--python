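# tetherdrive

Population-genetic modeling and inference for **tethered gene-drive
systems**: a confined toxin–antidote (TARE) element carrying Cas9, coupled
to a split homing element that is only active in TARE carriers.  The
package predicts cross outcomes, computes introduction thresholds and
suppression equilibria, simulates finite cage populations with realistic
drift, and estimates drive fitness and effective population size from cage
trajectories by maximum likelihood.

See [docs/methods.md](docs/methods.md) for the scientific model and the
validation standards each component is held to.

## Worked example

Predict the inheritance bias of a TARE-heterozygous female crossed to
wild-type males, at germline cleavage 0.888 and embryo cleavage 0.632:

```python
from tetherdrive import (
    DriveParams, FitnessModel, predict_cross, tare_het_female_x_wild,
    find_introduction_threshold,
)

params = DriveParams.tare_only(c_germ_tare=0.888, c_embryo_tare=0.632)

pred = predict_cross(tare_het_female_x_wild(), params)
print(f"drive-carrier inheritance: {pred.carrier_frac_tare:.1%}")   # 71.7%
print(f"relative egg-to-pupa survival: {pred.relative_survival:.3f}")  # 0.697
```

Compute the introduction threshold (the unstable equilibrium that confines
the drive) at homozygote fitness 0.867:

```python
thr = find_introduction_threshold(params, FitnessModel(f_hom=0.867))
print(f"carrier frequency at the unstable equilibrium: {thr.threshold:.3f}")
print(f"homozygote release proportion at the boundary: {thr.release_proportion:.3f}")
```

Simulate four cages straddling that threshold and fit fitness and
effective size back from the observed phenotype counts:

```python
from tetherdrive import fit_fitness
from tetherdrive.synthetic import default_cage_spec, gen_cage_dataset

trajectories, truth = gen_cage_dataset(default_cage_spec(seed=1))
fit = fit_fitness(trajectories, params)
print(f"f_hom = {fit.f_hom:.3f}  95% CI {fit.ci_f_hom}")
print(f"Ne fraction of census = {fit.ne_fraction:.4f}")
```

Estimate cleavage rates from observed inheritance rates (the inverse of
`predict_cross`):

```python
from tetherdrive import estimate_cleavage_rates
est = estimate_cleavage_rates(inh_F=0.717, inh_HH=0.974)
print(est.c_germ, est.c_embryo)   # ~0.888, ~0.632
```

## Command line

The same operations are available under one umbrella command:

```bash
tetherdrive predict-cross --mother "h:D/W;sex:F" --father "h:W/W;sex:M" --config params.yaml
tetherdrive estimate-cleavage --inh-f 0.717 --inh-hh 0.974
tetherdrive find-threshold --config params.yaml --f-hom 0.867
tetherdrive simulate-cage --config cage.yaml --seed 17 --replicates 100 --out cage.csv
tetherdrive fit-fitness cage_000.csv cage_001.csv --config params.yaml --out fit.json
tetherdrive gen-data --kind cage --seed 1 --out data/cages.csv
```

Genotype strings read `h:<allele>/<allele>[;hom:<allele>/<allele>];sex:<F|M>`
with alleles W (wild), D (drive), R (disrupted/nonfunctional).  Config files
are YAML with `drive_params`, `fitness` and `cage` sections (see
`tetherdrive.io.read_config`).

## Layout

| module | contents |
|---|---|
| `tetherdrive.genetics` | alleles, genotypes, gametes, embryo cleavage, viability |
| `tetherdrive.dynamics` | deterministic recursion, thresholds, equilibria |
| `tetherdrive.cage` | finite-population cage simulator |
| `tetherdrive.crosses` | cross predictions, cleavage-rate inversion, vial statistics |
| `tetherdrive.likelihood` | ML fitness/effective-size estimation, profile CIs |
| `tetherdrive.synthetic`, `tetherdrive.io` | synthetic datasets, CSV/YAML/JSON I/O |

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end scientific acceptance
tests (inheritance bias, threshold band, round-trip identifiability,
enumeration-oracle equivalence, parameter recovery, phenomenology);
`scripts/acceptance.py` recomputes the headline quantities and writes them
as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
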