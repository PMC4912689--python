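# Methods

## The analysis problem

An alanine scan of a peptide-hormone GPCR's extracellular loops produces,
for every point mutant, three kinds of measurements: competition
radioligand-binding curves (ligand affinity), concentration-response curves
for several signaling pathways (cAMP accumulation, ERK1/2 phosphorylation,
intracellular Ca2+ mobilization), and a cell-surface-expression level
relative to wild-type. The package turns these into per-residue statements:
how much each mutation changes affinity (pKi), pathway-coupling efficacy
(log tau_c), and the balance of signaling between pathways
(DeltaDelta log(tau/K_A)), with multiplicity-corrected significance and a
fold-change "heat" classification suitable for painting onto a 3D model.

## Models

**Three-parameter logistic.** Agonist curves are
`Y = Bottom + (Top - Bottom) / (1 + 10^(logEC50 - log[A]))` with Hill slope
fixed at 1; competition binding uses the mirrored one-site form on
log-competitor concentration. IC50 converts to Ki by Cheng–Prusoff,
`pKi = pIC50 + log10(1 + [tracer]/Kd_tracer)`; the tracer's Kd and assay
concentration are configuration, never hard-coded.

**Operational model of agonism** (transducer slope 1):

    Y = Bottom + (Em - Bottom) / (1 + (10^logK_A + 10^log[A]) / 10^(log tau + log[A]))

`Em` is the maximal system response, `K_A` the functional agonist-receptor
dissociation constant, and `tau` the operational efficacy, which is
proportional to receptor density. Useful exact identities:
`EC50 = K_A / (tau + 1)` and `plateau = Bottom + (Em - Bottom)·tau/(tau+1)`.

**Identifiability and the K_A anchor.** Those identities also mean the
single-curve operational model is an exact reparameterization of the 3PL:
(Em, tau, K_A) trade off along a one-dimensional ridge and functional data
alone cannot pin them down, no matter how many ligands share an Em. The
default policy (`ka_policy="fix_to_binding"`) therefore anchors `logK_A`
to the binding-derived `-pKi` — standard practice when functional and
binding affinity agree — making tau and Em identifiable per curve. A free-K_A
mode exists for sensitivity analyses and is flagged as ridge-limited.
Because the anchor is itself an estimate, its SEM is propagated into
`sem_log_tau` with sensitivity `dlog(tau)/dlog(K_A) = (tau+1)/tau`; this
component is shared across experiments, so it is kept separate from
per-experiment scatter and enters difference SEMs explicitly.

**Replication structure.** Each independent experiment (day) is fitted
separately — technical duplicates averaged first, the default and
switchable — with Em and Bottom shared across the ligands of one
construct × pathway (`em_policy="shared_per_pathway"`). Parameters are
pooled as mean ± SEM over experiments, matching a design of four to six
independent experiments conducted in duplicate. Basal (zero-concentration)
wells anchor Bottom; Bottom can be fixed to 0 for baseline-subtracted assays.

**Expression correction.** `log tau_c = log tau - log10(expr/expr_WT)`:
lower expression raises the corrected efficacy, isolating intrinsic
coupling from receptor number. Expression SEMs move to the log10 scale by
the delta method (`sem/(x·ln10)`) and combine with the tau SEM in
quadrature, assuming independence. Constructs with no measurable surface
expression carry status `not_determined` end to end rather than being
dropped.

**Mutant comparison.** One family per ligand × measure: one-way ANOVA and
Dunnett's two-sided many-to-one test of every mutant against wild-type on
per-experiment values (`scipy.stats.dunnett`; an independent Monte-Carlo
max-|t| reference with exact null simulation is bundled and used to verify
calibration). All measures enter on the log10 scale, so
`fold_change = 10^|delta|` uniformly; Emax is log10-ed on entry. Significant
reduced effects bin lower-inclusive into [3,5), [5,10), [10,30), [30,inf);
significant effects under 3-fold render `no_effect` on maps (in either
direction — one reporting threshold) but stay flagged in tables. A mutant
whose curve never rises above the noise floor is floor-annotated as
`fold_gt_30` provided the wild-type tau exceeds the top bin times the
floor-implied tau bound `floor/(Em - floor)` — i.e. only when the data
could actually have revealed a 30-fold loss; otherwise, and always for
constructs with undetectable surface expression, it stays `not_determined`.

**Bias.** `log(tau/K_A) = log tau_c - log K_A` per ligand × pathway
(variance `v_tau + v_KA - 2 cov` when both come from one joint fit); Delta
normalizes to the reference ligand within a pathway, DeltaDelta to the
reference pathway within a ligand (defaults: GLP-1, cAMP). The double
normalization cancels any pathway-wide rescaling or K_A shift — system and
observation bias — which the property tests assert directly. Cross-pathway
DeltaDelta is refused when pathways are declared to come from different
cell backgrounds unless matched expression is asserted, since the
cancellation assumes one receptor population. The corrected tau_c is used
by default (raw-tau mode available). Ligand-vs-ligand bias comparison uses
a two-sided Welch t on DeltaDelta with propagated SEMs.

**Structure export.** Bundled region spans: ECL1 (incl. TM boundaries)
201–223, ECL2 285–307, ECL3 372–387; 1-based protein-sequence numbering,
with an offset knob for structures numbered differently. Heat categories
are written into the B-factor column (codes 0–5, −1 for not-determined,
sentinel −9.99 elsewhere) because every molecular viewer can color by
B-factor; a companion TSV and a category→color legend JSON (teal, yellow,
pale orange, orange, red) accompany the PDB. Class-B ("Wootten") numbers
are attached from a user-supplied lookup, never computed. Cross-ligand
summary classes: global (all assessed ligands reduced), selective (one),
shared-by-two, enhanced, mixed (opposite directions).

## The synthetic-data generator

`alascan.simulate` emulates the study design so the whole pipeline is
testable without any deposited data: three peptides (GLP-1, oxyntomodulin,
exendin-4) × three pathways × wild-type plus mutant scenarios, five
independent experiments in duplicate, 5% constant-CV multiplicative
Gaussian noise on responses (an additive mode exists), a 5%-SD
between-day random effect on Em, additive noise (5 percentage points) on
%-specific-binding so values can stray slightly outside [0, 100], and 5%
relative SEM on expression. Concentration grids default to 10 log-even
points spanning 1 pM–1 µM (binding: log −11 to −5). Receptor density
scales efficacy at generation time (`effective log tau = intrinsic log tau
+ log10(expression fraction)`), so the expression-deficit scenario is a
genuine recovery test for tau_c. Wild-type truths: pKi 8.0/7.0/8.5
(GLP-1/oxyntomodulin/exendin-4) with `log K_A = -pKi`, Em 100, Bottom 0,
and log tau values that encode a built-in 10-fold oxyntomodulin bias
toward pERK (DeltaDelta = +1.0) with exendin-4 unbiased. The scenario
library adds efficacy losses of 4/7/18/100-fold, affinity losses of
0.60/0.85/1.25/1.60 log, a 30%-expression mutant, an enhancing/mixed
mutant, and a dead-surface construct. Same seed ⇒ byte-identical CSVs.

What the generator does *not* emulate: plate-position or carry-over
artifacts, non-Gaussian outliers, heteroscedasticity beyond constant CV,
day effects on potency, or disagreement between functional K_A and binding
Ki. Passing recovery tests therefore demonstrate the estimators and error
propagation are correct under the stated model, not robustness to every
real-world pathology.

## Numerical choices

Bounded trust-region least squares with three data-driven starts (bottom =
min response, top/Em from max response, midpoint from the half-span
crossing; log tau start 0.5 ± 1), ties broken by residual sum of squares.
Bounds: log tau ∈ [−3, 4], log K_A ∈ [−12, −4]. SEMs from the Gauss–Newton
covariance. A curve is `no_response` when its response window is below the
noise floor (pipeline default 5 assay units, i.e. 5% of the wild-type
system maximum; the low-level fitters default to 4× the technical-duplicate
SD). pEC50 more than 1 log unit outside the tested range is flagged
extrapolated. Dunnett p-values are exact multivariate-t values; the
Monte-Carlo reference (10^6 draws by default) doubles as the unbalanced-edge
fallback.

## Validation studies and problem sizes

`alascan.validation` re-runs the pipeline against ground truth:
self-consistency on noiseless grids (12 parameter combinations), parameter
recovery over 100 simulated studies, the tau_c contract over 200, Dunnett
calibration on a fixed 3-mutant fixture (10^6 Monte-Carlo draws) plus 1000
all-null panels, and bias recovery over 100 studies. These sizes give
Monte-Carlo standard errors comfortably below the margins being checked
while keeping a full run to a few minutes on one CPU; the test suite and
`scripts/acceptance.py` both execute them fresh.

## Known limitations

* The Dunnett test runs on per-experiment parameter values; error
  components shared across experiments (the expression ratio, the K_A
  anchor) are included in the reported delta SEMs but not in the post-test
  itself, which can be slightly anticonservative for tau_c families.
* No variable transducer slope, two-site binding, or kinetic models.
* The free-K_A operational mode returns ridge-limited point estimates by
  construction; only the transduction coefficient is well determined there.
* Heat maps encode category, not effect-size uncertainty; consult the
  comparison table's SEMs for that.
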