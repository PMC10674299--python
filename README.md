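# dualqsar

A QSAR pipeline for dual-target ligand design against the trace
amine-associated receptor 1 (hTAAR1) and the α₂-adrenoreceptor (α₂-ADR).
It is written for medicinal/computational chemists who want to (a) rebuild
latent-variable affinity models of the kind used for imidazole/imidazoline
TAAR1 agonist series and (b) screen candidate structures against the frozen
published equations and pharmacophore geometries from that work.

## What it does

* **Molecular descriptors** (`dualqsar.descriptors`, `dualqsar.fields`) —
  the 20 unique descriptors the two published models use: partial-charge and
  SlogP-binned van der Waals surface areas (Q_VSA_FHYD, Q_VSA_PNEG,
  Q_VSA_POL, Q_RPC−, SlogP_VSA3/4), topological indices (Balaban J,
  GCUT_SMR eigenvalue descriptors), conformation-dependent charge
  descriptors (DipoleY/Z in a canonical inertial frame, DCASA),
  MMFF94 energies (E, E_tor), a pharmacophore-feature surface sum
  (vsa_other), and VolSurf-style grid-field integy moments
  (vsurf_IW4/IW5/ID1/ID7, vsurf_EDmin1).
* **Dataset design** (`dualqsar.dataset`) — constancy filtering in
  cancellation groups, autoscaling, PCA, and the Kennard–Stone maximin
  training/test split run on the PC scores with the autoscaled response
  appended as an extra column.
* **PLS engine** (`dualqsar.pls`) — deterministic NIPALS PLS1,
  leave-group-out cross-validation (Q² = 1 − PRESS_cv/TSS), iterative
  stepwise elimination (ISE) variable selection with importances
  z_v = |b_v|·s_v / Σ|b_v|·s_v, and external validation
  r²_pred = (SD − PRESS)/SD.
* **Frozen published models** (`dualqsar.published`) — the two published
  linear pKi equations, shipped verbatim as JSON (model A, hTAAR1, 10
  descriptors, intercept 5.88651; model B, α₂-ADR, 11 descriptors,
  intercept 7.00986), with relative-importance reports and a ΔpKi
  selectivity classifier.
* **Pharmacophore models** (`dualqsar.pharmacophore`) — PM_A (hTAAR1) and
  PM_B (α₂-ADR) as typed-feature distance-constraint graphs, plus an
  exhaustive-assignment matcher.
* **Synthetic data** (`dualqsar.synthetic`) — a seeded latent-factor
  generator emulating the 45-compound × ~300-descriptor design with pKi
  responses in the observed 5.4–8.7 window, the packaged table of
  individually reported Ki pairs, and a pharmacophore point-set generator.

## Worked example

```python
import numpy as np
import dualqsar as dq

# 45 compounds, 40 descriptors, 3 latent factors, seeded
table, truth = dq.gen_pls_dataset(dq.SyntheticSpec(n=45, p=40, n_latent=3, seed=7))

filtered, _ = dq.check_constancy(table)          # drop (group-)constant columns
scaled = dq.autoscale(filtered)
scores, explained = dq.pca_scores(scaled, n_components=8)
ys = (scaled.y - scaled.y.mean()) / scaled.y.std(ddof=1)
split = dq.kennard_stone_split(np.column_stack([scores, ys]), 31,
                               scaled.compound_ids)

train = table.subset_rows(split.train_ids)
res = dq.isepls(train.X, train.y, column_names=table.column_names)
keep = [table.column_names.index(c) for c in res.final_descriptors]
model = dq.fit_pls(train.X[:, keep], train.y, res.best["n_latent"])

test = table.subset_rows(split.test_ids)
stats = dq.evaluate(model, test.X[:, keep], test.y, train.y.mean(),
                    train.X[:, keep], train.y)
print(len(split.train_ids), len(split.test_ids))   # 31 14
print(len(res.final_descriptors), round(res.best["q2"], 3))  # 11 0.879
print(round(stats.r2ncv, 3), round(stats.rmse, 3),
      round(stats.r2pred, 3))                      # 0.915 0.351 0.657
```

The split reproduces the 31/14 design; ISE keeps 11 of 40 descriptors at a
cross-validated Q² of 0.879, and the held-out set validates at
r²_pred = 0.657 — i.e. the model explains about two thirds of the test-set
deviation from the training mean.

The frozen equations and selectivity calls work on descriptor mappings:

```python
mA = dq.load_model_a()
d = {name: 0.0 for name in mA.coefficients}
dq.predict(mA, d)                       # 5.88651 (the intercept)
call = dq.selectivity(dq.ki_to_pki(68, "nM"), dq.ki_to_pki(4352, "nM"))
print(round(call.delta, 2), call.label)  # 1.81 TAAR1-selective
```

Note that the frozen coefficients are calibrated to the descriptor
conventions of the proprietary engine they were fitted with; feeding them
descriptors from this package's engine (different charge model, surface
approximation and field probes) produces systematically shifted pKi values.
See `docs/methods.md` for the conventions and this limitation.

A CLI mirrors the library: `dualqsar descriptors`, `dualqsar split`,
`dualqsar isepls`, `dualqsar predict`, `dualqsar pharm-match`,
`dualqsar simulate`.

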