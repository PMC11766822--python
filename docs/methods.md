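# Methods notes

## Scope and data

The package operates at desk scale on a bundled reference set: a 37-steroid
property table (externally predicted soil/water partition, bioconcentration,
brain- and placenta-penetration, intestinal-absorption and skin-permeability
values, plus P-gp substrate flags and rule-of-five counts), a matching
docking-affinity table for the placental enzymes GST and NAT2 with their
reference-ligand yardsticks (glutathione −5.4 kcal/mol, coenzyme A
−7.4 kcal/mol), and a curated structure registry. External predictor outputs
(EpiSuite, pkCSM, SwissADME, ADMETlab) are *inputs*: the package never
re-implements those models, it consumes their values and computes everything
downstream of them. Fixtures are checksummed in the test suite, and missing
values are always explicit (`None`/empty cell), never sentinel numbers.

The registry SMILES are curated flat (2D) structures: stereochemistry is
deliberately omitted because every descriptor in scope is topological or
2D-additive, and none changes under stereo assignment. Each structure was
validated against the compound's known molecular formula before being
frozen.

## Descriptor conventions

* **Topological indices** (Wiener `W`, first-order connectivity `MCI`) use
  the hydrogen-suppressed graph; shortest paths come from a BFS-based
  all-pairs computation (tests compare against an independent hand-written
  BFS oracle and closed forms for paths and stars).
* **Counts** (aromatic heavy atoms, H-bond donors/acceptors) use RDKit's
  default aromaticity perception. **Rotatable bonds** use the strict
  definition: non-ring single bonds between two non-terminal heavy atoms,
  amide C–N excluded.
* **GATS7Z** is the Geary autocorrelation at topological lag 7 with atomic
  numbers as weights, computed on the hydrogen-suppressed graph. The
  heavy-atom convention is deliberate: with hydrogens included, the Z = 1
  vs Z = 6 contrast would dominate the statistic, and the natural
  degenerate cases (all-carbon skeleton → zero weight variance; chain
  shorter than 8 heavy atoms → no lag-7 pair) would disappear. Degenerate
  inputs yield an explicit missing value, not 0.
* **ZMIC1** is implemented as the atomic-number-weighted Shannon entropy
  (bits) over order-1 neighbourhood-symmetry classes on the
  hydrogen-*included* graph (information-content indices traditionally
  count hydrogens). Classes start from atomic number and are refined once
  by the sorted multiset of (bond order, neighbour class) pairs. The exact
  numerical convention used by the upstream descriptor service is not
  published to full precision; this package's definition is documented
  here and pinned by a hand-derived oracle (ethanol → 2.137779 bits).
* **EState_VSA8** delegates to RDKit, which implements the published
  E-state/VSA binning.
* **`Lipinski`** (the placental-transfer equation term) is the boolean
  rule-of-five pass flag (1 = zero violations), the form drug-likeness
  descriptors usually take; a violation-count reading would only rescale
  the term by its −0.12 coefficient for these compounds (all have ≤ 1
  violation).
* **`SURFACE_AREA`** is read as a *total* molecular surface area. When not
  supplied externally it is approximated by Labute's ASA. Corroboration:
  refitting the NAT2 equation's term set on the bundled affinities with
  these internal descriptors reproduces the published coefficients almost
  exactly (−12.42/−0.205/−0.383/+0.0266 vs −12.09/−0.207/−0.363/+0.0242)
  and R² = 0.68 vs the published 0.665; a polar-surface-area reading fits
  visibly worse.
* **`iLOGP`, `MDCK`, `PAMPA`** are external-only descriptors, passed
  through and never computed. `logp` and `surface_area` follow the source
  hierarchy *supplied > internal estimate* (Wildman–Crippen logP, Labute
  ASA), and the resolved source is recorded on every descriptor vector.

## QSAR equations

Models are stored as data (terms, coefficients, standard errors, fit
statistics, provenance) so a refit model is interchangeable with a printed
one; evaluation is a plain affine map and is property-tested for exact
linearity.

The GST equation is printed without the numeric value of its heavy-atom
coefficient (only the standard error ±0.262 and the negative sign are
recoverable). The default completes the *printed* equation by conditional
least squares: the five printed coefficients are held fixed and the missing
one is solved on the bundled GST affinities and registry descriptors,
giving −0.978. A free six-parameter refit would instead replace all
printed values. The solved value is computed at call time (and cached) so
it always tracks the fixtures; callers may override it, but non-negative
values are rejected because the published selection table fixes the sign.
(The printed surface-area coefficient −0.0296 carries a standard error
±0.059 larger than itself — possibly a typo for 0.0059; it is used as
printed.)

Both log K_oc estimators omit the unpublished fragment-correction terms of
their parent models and therefore return values flagged `uncorrected`; the
classification layer treats an externally supplied log K_oc as the
authoritative route (the bundled table's values include the corrections).

## Classification rules

* Soil mobility intervals are lower-inclusive (`[1,2)` mobile, `[2,3)`
  moderately mobile, ...). The source states ranges without closure; no
  tabulated compound sits on a boundary, so any convention reproduces the
  table — one had to be chosen and documented.
* The bioaccumulation default is log BCF ≥ 3.28 rather than
  log10(2000) = 3.301: the reference table's own flagging marks 3.28 and
  3.29 as bioaccumulative, consistent with upstream values being rounded
  to two decimals after thresholding. The threshold is a config parameter;
  the summary-table footnote's alternative cut-off (log BCF < 3 = low) is
  used only inside the risk-table rendering, where it reproduces the
  printed High/Low cells.
* BBB is strict (`> log10 0.3`); placental crossing is inclusive at
  −0.52 (the compound printed at exactly −0.52 is counted as crossing).
* Enzyme affinity is the strict numeric rule (score < reference). The
  source prose treats one borderline compound (spironolactone NAT2, −7.6
  vs −7.4) as "fairly similar" to the reference; the strict rule flags it.
  The discrepancy cannot affect the risk set because that compound is
  BBB−.
* The risk-table renderer also reports the coarse three-level soil-mobility
  scheme used in summary tables (log K_oc > 4 low, 2–4 medium, < 2 high
  mobility) alongside the six-class scheme.

All cut-offs live in one `Thresholds` record whose defaults are the
published values; outputs echo the thresholds in a JSON sidecar.

## Model-building machinery

Forward stepwise MLR uses F-to-enter with p_enter = 0.05 and no removal
step; the upstream statistical package's exact entry criterion is not
recoverable, so both the criterion and the threshold are configuration.
Collinearity screening removes, pair by pair (worst first), one member of
every descriptor pair with tolerance 1 − R² < 0.1; the member with the
lower marginal |correlation| to the response is dropped, lexicographically
on ties. Cross-validation permutes rows once with a caller seed, cuts k
contiguous blocks (first n mod k blocks get the extra row; n = 60, k = 5
gives the canonical 12-per-fold structure) and refits the *fixed* selected
term set per fold — selection is not re-run inside folds, matching the
validation of a finished model rather than of the selection procedure.
OLS is solved by `lstsq` with exact standard errors and F statistics;
tests cross-check every statistic against statsmodels.

## Synthetic data

The regression generator draws equicorrelated Gaussian descriptor columns
with per-column location/scale and adds seeded Gaussian noise to a linear
response. The packaged reference spec mimics the brain-penetration
model's descriptor structure: four informative columns at the scales of
(W ~ N(500, 150²), iLOGP ~ N(2.5, 1.2²), MDCK ~ N(−5, 0.8²),
PAMPA ~ N(−5.5, 1.2²)) with the published coefficients, four inert
standard-normal columns, n = 60, zero equicorrelation, and σ = 0.917 from
the analytic identity σ² = var(Xβ)(1 − R²)/R² at R² = 0.78. The
recovery study treats "selecting the informative set" as recall (all four
informative terms entered): with p_enter = 0.05, occasional entry of an
inert column is an expected property of forward selection, not a failure.
What the generator does *not* emulate: the heavy-tailed, discrete and
mutually correlated nature of real descriptor pools, model-selection bias
from screening hundreds of candidates, or measurement error in the
response — so passing recovery tests demonstrates the machinery is
correct, not that a four-descriptor model of real brain-penetration data
is well-specified.

The molecular-graph generator produces connected graphs (random
attachment tree plus optional extra ring-forming edges) purely as oracle
inputs for the topological indices; it makes no attempt at chemically
realistic valences.

## Problem sizes and determinism

Everything is seeded through `numpy.random.Generator`; a spec reproduces
byte-identical output across platforms. The bundled analyses run on the
37-compound set; the recovery study uses 200 simulations of n = 60, which
completes in seconds and gives the selection-rate estimate a standard
error of about 1.6 percentage points.

## Known limitations

* Absolute fidelity of ZMIC1/GATS7Z to the upstream descriptor service
  cannot be verified offline; the placental-transfer equation should
  therefore be used with externally computed descriptors when exact
  agreement with upstream predictions matters. (No bundled result depends
  on this: the reference table's log FM values are inputs.)
* The brain-penetration equation needs three external predictor values
  (iLOGP, MDCK, PAMPA); with structures alone the package computes W but
  leaves log K_p,uu,br missing rather than guessing.
* The docking affinities are single-pose scores from a fixed receptor
  model; the derived "high affinity" flags inherit all limitations of
  that methodology.
* The log K_oc estimators are uncorrected (see above) and should not be
  preferred over externally predicted values.
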