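# steroscreen

In-silico environmental-fate and pregnancy-safety screening of steroid
drugs.

Steroid hormones and their synthetic analogues reach soil and surface
waters from households, farms and manufacturing, and they disturb aquatic
reproduction at sub-ng/L levels. Once absorbed by a pregnant individual,
the same molecules may cross the placenta and the blood–brain barrier and
interact with the placental detoxification enzymes glutathione
S-transferase (GST) and N-acetyltransferase 2 (NAT2). `steroscreen`
implements a desk-scale screening pipeline for exactly these questions,
for computational chemists and environmental-risk assessors: it bundles a
curated 37-steroid reference set (property tables, docking affinities and
structures), computes the molecular descriptors its QSAR equations
consume, evaluates the published fixed-coefficient models, applies the
threshold rules that turn numbers into categorical flags, and provides the
model-building machinery (collinearity screening, forward stepwise MLR,
blocked cross-validation) used to derive such equations.

## The models

Soil/water partitioning is estimated two ways and averaged
(`log K_oc^(1) = 0.52·MCI + 0.60`, `log K_oc^(2) = 0.55·log K_o/w + 0.93`;
both lack unpublished fragment corrections and are flagged *uncorrected* —
externally predicted log K_oc is the authoritative route). MCI is the
first-order Randić connectivity index Σ_bonds (δ_i·δ_j)^(−1/2); the Wiener
index W = Σ_{i<j} d(i,j) enters the brain-penetration model.

Four affine QSAR models are shipped as data:

| model | form |
|---|---|
| placental transfer | log FM = −0.038 − 0.0081·ZMIC1 − 0.011·EState_VSA8 + 0.20·GATS7Z − 0.12·Lipinski |
| brain penetration | log K_p,uu,br = 4.909 − 0.00857·W + 0.642·iLOGP + 0.893·MDCK − 0.393·PAMPA |
| NAT2 affinity | k_NAT2 = −12.09 − 0.207·(#aromatic heavy) − 0.363·(#rotatable) + 0.0242·SA |
| GST affinity | k_GST = −5.170 + 0.326·(#rotatable) − 0.0296·SA + 0.0694·MW + β_heavy·(#heavy) + 0.132·logP |

(β_heavy is unpublished; its default, −0.978, is solved by conditional
least squares on the bundled fixtures and constrained negative.)

Classification cut-offs: EPA six-class soil mobility on log K_oc;
bioaccumulation at log BCF ≥ 3.28; BBB+ at K_p,uu,br > 0.3; placental
crossing at log FM ≥ −0.52; GI absorption at HIA ≥ 30%; enzyme affinity
"high" when the docking score is strictly more negative than the natural
substrate's (glutathione −5.4, CoA −7.4 kcal/mol). A compound is a
*pregnancy-risk* candidate when it is simultaneously BBB+,
placenta-crossing, and a stronger binder than the reference ligand at both
enzymes.

## Worked example

```python
>>> import steroscreen as ss
>>> mols = ss.registry_structures()          # 37 curated steroid structures
>>> d = ss.compute_descriptors(mols["PROG"]) # progesterone
>>> d.w, round(d.mci, 2), d.n_rotatable, round(d.surface_area, 1)
(1052, 10.86, 1, 139.6)
>>> round(ss.predict_k_nat2(d), 2), round(ss.predict_k_gst(d), 2)
(-9.07, -9.02)
```

Progesterone's Wiener index (1052) and connectivity index (10.86) reflect
a compact tetracyclic skeleton; the predicted docking affinities (−9.07
and −9.02 kcal/mol) sit close to the tabulated values (−9.6, −9.6) and
well below the reference-ligand yardsticks, i.e. both placental enzymes
bind it more strongly than their natural substrates.

The end-to-end summary of the bundled reference set:

```sh
$ steroscreen report
{
  "n_compounds": 37,
  "n_hm_im": 3,
  "n_bbb_pos": 12,
  "pct_bbb_pos": 32.432432432432435,
  "n_pgp_among_bbb": 5,
  "n_bioacc": 3,
  "n_placenta_noncross": 6,
  "r2_gst_nat2": 0.11280630729842245,
  "r2_kpuubr_logbb": 0.7674318974734299,
  "n_risk": 10
}
```

Read: only 3 of 37 steroids are hardly mobile/immobile in soil (the rest
can travel far from the discharge point), 12 (32.4%) are predicted to
enter the CNS (5 of those are P-gp efflux substrates), 3 bioaccumulate,
and 10 compounds clear every pregnancy-risk gate at once. The two squared
correlations say the GST and NAT2 binding sites respond to different
ligand properties (R² = 0.11) while the two brain-penetration metrics
broadly agree (R² = 0.77). `steroscreen profile` writes the same analysis
as CSV/JSON artifacts, including the 10-row risk table; `steroscreen fit`
and `steroscreen simulate` expose the model-building and synthetic-data
machinery.

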