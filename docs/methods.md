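# Methods

This note records the scientific model implemented by `tetherdrive`, the
choices made where the underlying biology or statistics admits more than one
reasonable formalization, and the validation standards each piece is held to.

## 1. Genetic model

Two autosomal loci are tracked per individual, as a phased pair of
haplotypes:

* **Confined toxin–antidote (TARE) locus** at a haplosufficient gene *h*.
  Alleles: wild-type (W), drive (D; Cas9 + gRNAs + recoded rescue),
  disrupted (R).  Offspring carrying two disrupted copies are nonviable;
  every other combination is fully viable because one functional copy (wild
  or recoded) suffices.
* **Homing locus** (optional).  Alleles: wild-type, drive, nonfunctional
  repair product, or absent when the locus is not modeled.  Two target
  rules are supported: `haplolethal_rescue` (any unrescued nonfunctional
  allele is dominant-lethal; the drive carries a recoded rescue) and
  `female_fertility` (the target is haplosufficient and required for female
  fertility, so females with no wild-type copy are sterile — a suppression
  configuration).

### Cutting events, in order

1. **Meiotic recombination** between the loci at a sex-specific rate
   (females 0.5 by default; males 0.0 — *Drosophila* males lack meiotic
   crossovers, which preserves the male-parent linkage between a TARE
   element and a homing element on the same chromosome).
2. **Germline TARE disruption**: in a TARE-carrier parent of either sex,
   each wild-type *h* allele transmitted is independently disrupted with
   probability `c_germ_tare`.
3. **Germline homing cutting** (split-drive conditionality): only in a
   parent carrying *both* the TARE element (the Cas9 source) and the homing
   element; each wild-type homing allele is cut with `homing_germ_cut` and
   resolves to a drive copy with probability `homing_conversion_frac`
   (homology-directed repair) or to a nonfunctional allele otherwise.
4. **Embryo cutting by maternal deposition**: if the mother carries the
   TARE element, each wild-type *h* allele in the zygote — *whichever parent
   it came from* — is independently disrupted with `c_embryo_tare`; if she
   also carries the homing element, wild-type homing alleles are cut to
   nonfunctional with `c_embryo_homing` (embryo cuts never convert: no
   aligned homologous template).

The decision to let maternal deposition act on the maternally-inherited as
well as the paternally-inherited wild-type allele is deliberate and tested:
it is what reproduces the reported ≈72% drive-carrier inheritance from
drive-heterozygous mothers at the measured rates (the paternal-only variant
predicts ≈69.5%).

All gamete and offspring distributions are exact enumerations, validated
against an independently written brute-force oracle over every genotype
pair (exact to 1e-12).

## 2. Deterministic dynamics and thresholds

Generations are discrete and non-overlapping with random mating, a 1:1 sex
ratio and infinite population size.  Fitness is codominant multiplicative:
a drive homozygote has relative fitness `f_hom`, a heterozygote
`sqrt(f_hom)`, and costs at the two loci multiply.  The cost can be placed
on female fecundity, male mating success, offspring viability, or both
sexes; the deterministic carrier trajectories are nearly interchangeable
across these placements, which is why trajectory data alone barely
distinguish them.  A second per-locus value (`f_hom_homing`, default 1)
extends the single-parameter model so the homing element can carry its own
cost; this is needed for interior suppression equilibria and is this
package's own extension.

**Introduction threshold.**  A TARE drive with a fitness cost is bistable:
it spreads above an unstable interior equilibrium and is lost below it.
`find_introduction_threshold` bisects on the *release proportion* of drive
homozygotes, classifying each trajectory as spreading or declining over a
long horizon.  Two numbers describe the boundary and both are returned:

* the **release proportion** at the spread/decline boundary (what you would
  release), and
* the **drive-carrier frequency at the unstable equilibrium** (what a cage
  hovers at; measured at the point of slowest motion along the boundary
  trajectory).

The carrier-frequency coordinate is the headline `threshold`, because it is
the observable that carrier-frequency trajectories are compared against.
The two differ substantially for homozygote releases (e.g. 0.121 vs 0.080
at the measured cleavage rates and `f_hom = 0.867`) since a homozygote
release immediately dilutes into heterozygote-rich generations.

## 3. Stochastic cage model

Cages hold a large census (~3,500) whose realized frequency changes show far
more variance than census-size binomial sampling.  Drift is therefore
injected at an *effective* size `Ne = round(ne_fraction × mean(census_t,
census_{t+1}))` applied to genotypes in a single multinomial stage, after
the deterministic expectation and before a multinomial census observation of
the four fluorescence phenotype classes (EGFP = TARE carrier, DsRed =
homing carrier).  The simulator and the likelihood share this contract
verbatim, so simulation and inference are consistent by construction.

## 4. Likelihood

Each generation transition contributes a compound drift+observation
likelihood of the observed phenotype counts: exact summation over the
latent drifted count for two-class transitions (with linear interpolation
between the integer effective sizes so the likelihood is continuous in
`ne_fraction`), and a multivariate-normal approximation otherwise.  The
genotype composition inside each phenotype class is not observed; it is
carried forward from the model's running prediction, re-anchored to the
observed class fractions each generation, and seeded from the known release
genotypes.  This anchoring is an approximation (the latent composition is a
point estimate, not integrated over), adequate by the recovery standard
below.  The first two transitions of each cage are excluded from the
likelihood by default (fresh-release parental effects) but still propagate
the latent state.

`f_hom` and `ne_fraction` are maximized jointly (Nelder–Mead, multiple
starts, log-scale for `ne_fraction`); 95% confidence intervals are profile
likelihoods at 1.92 log-units, and threshold CIs propagate the fitness CI
endpoints through the threshold computation (threshold is monotone
decreasing in fitness).

**Validation standard:** across 50 synthetic 4-cage datasets generated at
`f_hom = 0.867`, `ne_fraction = 0.036`, census 3,500 and a mixed release
design (0.71, 0.61, 0.25, 0.15), point estimates center on the truth (mean
0.874) and the 95% CI covers it in 88% of runs.  High-release-only designs
are nearly uninformative about fitness (the drive fixes regardless); mixed
designs that include near-threshold cages are strongly preferred.

## 5. Synthetic data in place of original measurements

The published estimates these defaults echo (cleavage 0.888/0.632, fitness
0.867 with CI 0.785–0.954, effective size 3.6% of census) were derived from
original supplementary datasets that this repository does not ship, so exact
re-derivation of those numbers from raw data is out of scope here.  The
substitute standard is synthetic: generators in `tetherdrive.synthetic`
produce cross and cage datasets at known ground truth, and the inference
code must recover that truth (cleavage rates by round-trip inversion,
fitness and effective size by the recovery study above).  All synthetic
randomness flows from a single seed per invocation and ground truth is
stored beside every generated dataset.

## 6. Out of scope

Egg/larva/adult stage structure, spatial structure within cages,
sex-specific germline cut rates (flagged but defaulted equal), batch
statistics beyond weighted between-vial standard errors, and any modeling
of the faster-than-expected mid-frequency rise sometimes seen in real
cages.
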