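# aepymorph

Quantitative taxon delimitation for the extinct elephant birds
(Aepyornithidae) of Madagascar — and, more generally, for any assemblage of
fragmentary skeletal measurements that needs objective morphotype
delimitation.

Museum collections of elephant-bird leg bones (femora, tibiotarsi,
tarsometatarsi) carry a century of conflicting names. Because most bones
are broken, classical multivariate morphometrics — which needs complete
data matrices — could never use the full material. This package implements
the modern workflow for that problem:

1. **Measurement model.** Each element has a fixed scheme of linear
   measurements in mm (femur F1–F20, tibiotarsus Tt1–Tt21, tarsometatarsus
   Tmt1–Tmt44), read from wide CSV specimen tables with explicit missing
   markers.
2. **Imputation.** Missing cells are completed by iterative PCA (an EM
   algorithm): initialise at column means, reconstruct the unit-variance
   scaled matrix at rank *S*, refresh the missing cells from the fit, and
   iterate to convergence. The regularized variant shrinks singular values
   toward the mean discarded eigenvalue to curb EM overfitting. The rank
   *S* is chosen by fivefold cross-validation on held-out observed cells,
   minimising the mean squared error of prediction (MSEP). Only specimens
   missing < 25 % of their measurements enter the first analysis round.
3. **Clustering.** PCA scores of the completed matrix are fed, one
   component at a time, into finite Gaussian-mixture models over six
   covariance families (EII, VII, EEI, VVI, EEE, VVV — spherical, diagonal
   and ellipsoidal shape; equal and varying volume), fitted by EM from a
   Ward-agglomeration start. Models are compared by
   BIC = 2 log L − m log n (maximised); a clustering is *stable* when the
   best model beats the best alternative cluster count by ΔBIC > 2.
   Specimens with classification uncertainty 1 − max posterior ≥ 0.05 are
   removed. A second, inclusive round re-imputes and re-clusters the
   fragmentary remainder at the K fixed by round one.
4. **Nomenclature.** Each cluster inherits the senior available species
   name among its confidently assigned type specimens (earliest publication
   year, ties broken by month). Literature specimens known only from a
   published value are placed via discrete (non-overlapping) diagnostic
   measurement intervals.
5. **Body mass.** From femoral least-shaft circumference (F3) via the
   Campbell–Marcus avian regression, log₁₀ M(g) = 2.411 log₁₀ LCF(mm) − 0.065.

A synthetic-data module generates specimen tables with the structure this
analysis assumes — latent overall-size factor, strong positive
inter-measurement correlation, anatomically structured "breakage"
missingness — calibrated to the published per-taxon measurement ranges, so
every stage is testable without access to the original specimen table.

## Worked example

```
$ aepymorph simulate --element tarsometatarsus --seed 5 --out tmt.csv
wrote 72 specimens to tmt.csv (truth: tmt_truth.csv)

$ aepymorph impute tmt.csv --element tarsometatarsus --seed 5 --out-dir imp
ncp=4, 230 iterations (converged)

$ aepymorph cluster imp/completed.csv --out-dir clus --seed 5
K=4 family=EII pcs=1 stable=True
```

The simulated table holds 72 tarsometatarsi from four morphotypes at the
published per-taxon range midpoints, with 45 % of bones broken.
Cross-validation picks a rank-4 imputation (`ncp=4`); BIC then resolves
four clusters (`K=4`) from the first principal component alone, with a
stability margin above 2 (`stable=True`) — the planted structure, recovered.

The same library calls are available in Python:

```python
from aepymorph import mass_from_circumference

est = mass_from_circumference(308.0)   # largest femur on record
print(round(est.mass_kg, 1))           # 860.8  (kg)
```

`aepymorph pipeline` runs both analysis rounds (including the supervised
fixed-K re-fit and round-2 re-imputation) and writes per-specimen labels,
per-cluster measurement ranges and a full JSON run report.

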