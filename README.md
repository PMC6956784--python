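# ensaff

Affinity prediction for protein–ligand binding from ensemble-docking
outputs combined with ligand chemistry. The package takes per-pose docking
metric tables (19 metrics per pose, one pose per receptor template),
aggregates them into per-ligand unified instances (median + standard
deviation of each metric over the pose ensemble), joins them with 11
molecular descriptors and/or 166-bit MACCS fingerprints, and trains a
random-forest regressor on p-scale affinity labels with stratified,
ligand-grouped cross-validation. A synthetic benchmark generator emulates
the statistical structure of a docking campaign so the full pipeline runs
and is testable offline.

## Components

| module | role |
| --- | --- |
| `ensaff.chem` | 11 ligand descriptors, engineered flexibility ratio (`nRotB.nB`), MACCS keys, Tanimoto similarity, SMILES/SDF/MOL2 readers |
| `ensaff.docking` | pose-metric table schema and I/O, four-score consensus (`AtomeScore`), linear pKa calibration of raw scores |
| `ensaff.ensemble` | template selection by anchor similarity, pose clustering (single-linkage RMSD), best-pose rule, median/SD aggregation, feature assembly |
| `ensaff.dataset` | affinity transforms (Ki/IC50: `9 − log10(nM)`; RBA: `log10(RBA) − 8`), representation groupings (`dConf`/`dCharge`/`ALL`), stratified hold-out and repeated CV folds |
| `ensaff.learner` | random-forest regression, single-hyperparameter (mtry) CV search, variable importance, model archive |
| `ensaff.evaluation` | rP / rS / R² (vs the identity line) / RMSE, cross model×test-set matrices, median-score correlations |
| `ensaff.simulate` | synthetic studies with controlled signal structure; end-to-end recovery experiments |

Conventions that the data format fixes (see module docstrings): `nAtom`
includes implicit hydrogens, `nBond` counts heavy-atom bonds only,
sample (n−1) standard deviation, even-count medians as the central-pair
midpoint, per-ligand grouping of all representation rows across every
split/fold boundary. The log P feature is computed with the toolkit's
Crippen implementation.

## CLI

All stages are subcommands of `ensaff`; tables are plain CSV.

```bash
ensaff simulate --seed 17 --outdir study/                 # synthetic study
ensaff features --in ligands.sdf --tag BDB --out desc.csv --maccs maccs.csv
ensaff aggregate --poses study/poses_BDB.csv --out unified.csv --min-poses 2
ensaff select-templates --candidate lig.smi --library anchors.csv -k 20
ensaff split --in dataset.csv --fraction 0.2 --seed 17 \
             --out-train train.csv --out-test test.csv
ensaff combine --group ALL --in BDB=bdb.csv,Gast=gast.csv,... --out all.csv
ensaff train --in train.csv --cv 10x10 --seed 17 --out model.bin
ensaff predict --model model.bin --in test.csv --out pred.csv
ensaff evaluate --pred pred.csv --obs affinities.csv --out report.json
ensaff cross-evaluate --models m1=a.bin,m2=b.bin \
                      --testsets t1=x.csv,t2=y.csv --out matrix.csv
```

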