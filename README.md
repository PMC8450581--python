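# ebvselect

Quantitative-genetic machinery for **estimated-breeding-value (EBV)
selection in closed breeding colonies**, written for managers and
analysts of working-dog programs (guide and service dog colonies) and for
anyone studying how such programs behave.

A modern breeding program runs a six-step loop: define goals, phenotype
every dog in a uniformly coded database, estimate heritabilities, compute
EBVs, select breeder candidates by a weighted selection index, and pair
them under constraints that protect genetic diversity. `ebvselect`
implements each step as a tested, reusable component, plus a stochastic
closed-colony simulator that generates data with exactly the statistical
structure the analyses assume — so the program-level claims (inbreeding
bounds under litter caps, heritability recovery, genetic trends,
correlated responses) can be exercised without any proprietary colony
data.

## The models

**Pedigree relationships.** Inbreeding coefficients F are computed by the
Meuwissen–Luo linear-time recursion; kinships f(x, y) by the classical
recursion (the predicted inbreeding of a litter out of a pair equals the
pair's kinship); and the inverse numerator-relationship matrix A⁻¹ is
assembled sparsely from Henderson's parent-contribution rules with full
inbreeding accounting. The per-generation inbreeding rate is reported
both as the plain difference of cohort means (percentage points per
generation) and as the classical ΔF = (F_t − F_{t−1})/(1 − F_{t−1}), with
the implied effective population size Ne = 1/(2ΔF).

**The animal model.** Phenotypes follow y = Xb + Za + e with a ~
N(0, A σ²ₐ). Variance components are estimated by EM-REML; EBVs for every
pedigree member come from Henderson's mixed-model equations

```
[ X'X   X'Z        ] [b]   [X'y]
[ Z'X   Z'Z + λA⁻¹ ] [a] = [Z'y],   λ = σ²ₑ/σ²ₐ,
```

with per-dog accuracy r = √(1 − PEV/((1+F)σ²ₐ)) and percentile ranks
within a reference cohort. Binary traits use the liability threshold
model fitted by Gibbs sampling. Traits with h² ≥ 15% are flagged as
selection candidates.

**Selection and mating.** Index weights are standardized by each trait's
genetic SD (index = Σᵢ wᵢ/σ_{a,i} · EBVᵢ); candidates are the top-index
dogs per sex after screening flags, preferring less-related dogs among
ties; mate allocation greedily minimizes predicted litter inbreeding
under litter caps (default 8 per sire, 4 per dam), the no-repeat-pair
rule and the carrier rule (no affected dog; at most one carrier per
pair), breaking ties toward equal stud usage.

## Worked example

```python
import ebvselect as ev
from ebvselect.simulate import colony_design

# a capped, index-selected colony producing ~200 pups per cycle
colony = ev.run_program(ev.SimulationConfig(seed=42, generations=6,
                                            selection="index"))
rate = ev.colony_inbreeding_rate(colony)

# heritability recovery on a neutral (random-selection) colony
cfg = ev.SimulationConfig(seed=7, generations=5, litters_per_year=58,
                          traits=(ev.TraitSpec("hip_quality", "continuous", 0.52),),
                          selection="random")
neutral = ev.run_program(cfg)
ped = neutral.pedigree
design = colony_design(neutral, "hip_quality")
ainv = ev.a_inverse(ped, ev.inbreeding(ped))
vc = ev.reml_estimate(design, ainv, max_iter=1000)
```

prints (via the snippets in the docstrings):

```
1292 dogs over 6 generations
endpoint inbreeding rate: 0.69 %/generation (Ne ~ 72)
mean true merit, generation 0 -> 6: +0.06 -> +3.73 genetic-SD units
REML on 2065 dogs: h2 = 52.9% (simulation truth 52%)
  dog_id       trait   ebv  accuracy  percentile
G05_0324 hip_quality 1.638     0.793      99.756
G05_0322 hip_quality 1.444     0.793      99.512
G05_0326 hip_quality 1.171     0.793      99.268
```

Read: the capped mating policy held inbreeding growth to 0.69 points per
generation while the index gained ~0.6 genetic SD per generation; on
neutral data the EM-REML estimate lands on the simulated heritability;
and the top-ranked young dogs carry EBVs with ~0.79 accuracy and their
percentile within their birth cohort.

The same workflow is available from the shell:

```bash
ebvselect simulate --config sim.yaml --out colony/
ebvselect inbreed --pedigree colony/pedigree.csv --out F.tsv
ebvselect reml --pedigree colony/pedigree.csv --phenotypes colony/phenotypes.csv \
               --trait hip_quality --out vc.json
ebvselect ebv  --pedigree colony/pedigree.csv --phenotypes colony/phenotypes.csv \
               --trait hip_quality --vc vc.json --out ebv.tsv
ebvselect index --ebvs ebv.tsv --spec index.yaml --out index.tsv
ebvselect candidates --index index.tsv --pedigree colony/pedigree.csv --out cand.tsv
ebvselect mate --candidates cand.tsv --pedigree colony/pedigree.csv --out plan.tsv
```

## File formats

* **Pedigree CSV/TSV** — `id,sire,dam,sex,cohort,flags`; unknown parents
  as `0` or empty; flags `;`-separated (e.g. `carrier:prcd`).
  PLINK `.fam` import is also supported.
* **Phenotypes CSV/TSV** — long format `dog_id,trait,score,<covariates…>`
  (e.g. sex, age_months, weight_kg, year, season).
* **Configs** — YAML for trait declarations, index specs and simulations
  (see `ebvselect.configs`).

## Acceptance script

`scripts/acceptance.py` recomputes the two headline quantities from
scratch by running the package end to end: the mean per-generation
inbreeding increase of the capped ~200-pup/year colony under index
selection (20 replicates, 10 generations), and the mean EM-REML
heritability recovered from data simulated at a true h² of 52% on
~2,000-dog pedigrees (20 replicates). Run it from the repository root:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

```
src/ebvselect/
  pedigree.py           inbreeding, kinship, A-inverse, inbreeding rates
  phenotypes.py         trait scales, long-format IO, design matrices
  reml.py               EM-REML variance components, heritability screen
  ebv.py                MME BLUP (single/multi-trait), threshold Gibbs, reports
  selection.py          index weighting, trends, candidates, mate allocation
  simulate.py           closed-colony generational simulator and metrics
  reference_program.py  published heritabilities/index weights (fixtures)
  configs.py, cli.py    YAML configs and the `ebvselect` command
docs/methods.md         modeling assumptions, defaults, numerics, limitations
```
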