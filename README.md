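# convmorph

Landmark-based cranial shape analysis and convergence testing for
phylogenetic comparative studies.

`convmorph` answers a question that recurs whenever an extinct species'
ecology is reconstructed from skull shape: *which living species is a
fossil or recently extinct predator actually convergent with, and what
does that imply about its prey?*  Starting from per-specimen 3D landmark
configurations, a time-scaled phylogeny, and a species ecology table
(body mass, mean prey mass, pack size, diet composition), the package
runs the full chain of analyses used in modern geometric-morphometric
convergence studies:

1. **Generalized Procrustes alignment (GPA)** — translation, scale and
   rotation removed; centroid sizes retained; facial and neurocranial
   landmark patches re-superimposed as their own shape spaces; optional
   bending-energy sliding of semilandmarks.
2. **Ordination** — PCA of Procrustes coordinates at specimen and
   species-mean level, PC selection by variance threshold, and
   phylomorphospace projection of the phylogeny.
3. **Phylogenetic comparative statistics** — multivariate phylogenetic
   signal *K*<sub>mult</sub> (≈ 1 under Brownian motion) with a
   permutation test, and distance-based PGLS of shape or log centroid
   size on allometric, ecological and clade predictors with
   residual-randomization (RRPP) inference.
4. **Prey-size discrimination** — the prey/predator mass ratio
   (per-capita for pack hunters), the 45 % small/large prey boundary,
   two-group canonical variates analysis on selected PC scores with
   leave-one-out jackknife validation and equal-prior Mahalanobis
   posteriors for unknowns, plus per-PC Wilcoxon/Spearman screens.
5. **Convergence testing, two ways** — the distance-based metrics
   C1–C4, where C1 = 1 − D<sub>tip</sub>/D<sub>max</sub> is the
   proportion of the maximal cross-lineage phenotypic distance closed by
   evolution, tested against Brownian-motion simulations parameterized
   from the data; and the phenotypic vector angle θ between the two
   species' tip-minus-MRCA vectors, time-adjusted and tested against
   random reassignments of the convergent "state" across the tips.
6. **Decision rule** — Benjamini–Hochberg FDR control (α = 0.10) within
   each dataset × test family, then the *maximal convergence* call: a
   candidate is maximally convergent with the focal species when both
   tests are significant in the total-cranium dataset and in at least
   one patch dataset.

A first-class synthetic-study generator (`convmorph.synthetic`)
produces complete fake studies — pure-birth tree, species means evolving
by multivariate Brownian motion with an optional convergent regime
pulling a focal set toward a shared phenotype, specimen-level landmarks
with allometric size effects, and a matched ecology table — so the whole
pipeline is testable and calibratable without any data download.

## Worked example

Simulate a study with a strongly convergent regime (w = 0.9 blending of
three focal species toward a shared phenotype) and run the full
pipeline, with the first focal species playing the "unknown" whose
analogues we want:

```python
import convmorph as cm

study = cm.simulate_study(cm.SyntheticScenario(seed=11, convergence_weight=0.9))
focal = study.truth["focal_set"]          # ['sp01', 'sp05', 'sp21']
cfg = cm.PipelineConfig(focal_species=focal[0], seed=1,
                        n_perm=499, n_sims=500, n_shuffles=999)
res = cm.run_pipeline(cfg, study=study)
```

The UPGMA phenogram cut selects exactly the planted companions as
candidates, and both tests certify them:

```
species    c1   p_c1  theta  p_theta
   sp05  0.890  0.002  6.909    0.002
   sp21  0.922  0.002  5.151    0.002

species  maximal_convergent
   sp05                True
   sp21                True
```

C1 ≈ 0.9 means the pair has closed ~90 % of the maximal phenotypic
distance their lineages ever spanned; θ ≈ 5–7° means their phenotypic
change vectors point in nearly the same direction despite their full
root-to-tip divergence time.  The comparative table for the total
dataset shows the expected structure — strong evolutionary allometry,
a real prey-ratio effect, and no clade or diet effect:

```
                            function   df    R2      F     p
                              K_mult              0.4595  0.002
                 Pcoords ~ ln(Csize) 1,55 0.403 37.195  0.002
                     Pcoords ~ clade 2,54 0.009  0.254  0.972
  Pcoords ~ prey/predator mass ratio 1,54 0.112  6.820  0.002
 Pcoords ~ dietary category (coarse) 2,53 0.036  1.002  0.416
```

and the jackknifed CVA places ~80 % of specimens in the correct
prey-size class, assigning the focal species (built large-prey in this
draw) with posterior ≈ 0.83:

```
     dataset  n_axes  pct_correct  focal_assignment  focal_posterior
       total       4       80.357             large            0.834
      facial       4       81.250             large            0.819
neurocranial       4       79.911             large            0.781
```

The same analysis is available from the shell:

```
convmorph simulate --scenario scenario.yaml --out study/ --seed 11
convmorph run --config config.yaml
convmorph convergence --config config.yaml --pair sp01,sp05
```

## Layout

```
src/convmorph/landmarks.py    landmark I/O, centroid size, GPA, subsets
src/convmorph/phylo.py        Newick I/O, covariance, ancestral states, BM
src/convmorph/shape_space.py  PCA, PC selection, phylomorphospace
src/convmorph/comparative.py  K_mult, PGLS with RRPP
src/convmorph/prey_size.py    ecology table, CVA, nonparametric screens
src/convmorph/convergence.py  UPGMA candidates, C1-C4, theta, BH, decision rule
src/convmorph/synthetic.py    synthetic-study generator
src/convmorph/pipeline.py     end-to-end orchestration
src/convmorph/cli.py          command-line interface
docs/methods.md               models, assumptions, numerical choices
```
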