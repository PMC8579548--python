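# Methods

## Problem and model

Clinical-trial safety data arrive as long listings of adverse-event (AE)
records: one row per reported event, carrying a patient id, treatment arm,
CTCAE severity grade (1 mild … 5 death) and, where coded, an organ-system
domain and a specific AE term. Comparing the *toxicity profiles* of several
arms across tens or hundreds of AE classes is a dimension-reduction problem.
`toxca` treats it with stacked correspondence analysis (CA) and summarizes
the result in asymmetric contribution biplots.

The pipeline is:

1. **Classification.** Each record maps to a class label at one of five
   refinement levels: grade (`G3`), domain (`Gastrointestinal`),
   domain x grade (`Gastrointestinal:G3`), term, term x grade. At full
   CTCAE v4 cardinality these levels allow up to 5, 26, 130, ~790 and
   ~3950 classes; the analyzed class set is whatever is *observed* in the
   data, since real trials realize far fewer classes than the catalog.
2. **Incidence.** pi_ij = proportion of patients in arm j with >= 1 event
   of class i. Repeat events of the same class in the same patient do not
   count again; event counts are deliberately not used.
3. **Doubling.** Each row pi_i is paired with its complement 1 - pi_i.
   Every (presence, absence) pair sums to 1 in each column, so every column
   of the doubled 2I x J table sums to I and all arms carry identical
   column mass 1/J. This is what makes incidence rows — which are
   proportions, not counts — a legitimate CA input, and it weights each
   arm equally regardless of enrolment.
4. **CA.** With P the doubled table scaled to unit grand total, r and c its
   margin (mass) vectors, the standardized residual matrix
   S = D_r^-1/2 (P - r c^T) D_c^-1/2 is decomposed by SVD, S = U Sigma V^T.
   Principal inertias lambda_k = sigma_k^2 decompose the total inertia
   (the chi-square statistic / grand total); their shares are the
   "percent of variability" per dimension. Row principal coordinates
   F = D_r^-1/2 U Sigma, column principal G = D_c^-1/2 V Sigma, standard
   coordinates divide out Sigma. The contribution of row i to axis k is
   r_i Phi_ik^2 = U_ik^2.
5. **Contribution biplot.** Arms are plotted in principal coordinates
   (inter-arm distances approximate chi-square distances between toxicity
   profiles; the origin is the hypothetical average profile). Classes are
   plotted in *contribution coordinates* — sqrt(mass) x standard
   coordinates, i.e. the entries of U — so a class's squared distance from
   the origin along an axis *is* its contribution to that axis. Distances
   between arm points and class points are not meaningful; directions are.

## Display selection

A class is displayed when (a) its contribution to the plotted plane,
100 * r_i (F_i,d1^2 + F_i,d2^2) / (lambda_d1 + lambda_d2), reaches
`min_contribution_pct`, and (b) its average relative frequency — the
unweighted across-arm mean incidence, matching the equal column masses of
the doubled table — reaches `min_relfreq_pct`. The AUTO contribution
threshold is 100/I, the average contribution: a class is shown when it
explains more than its equal share. Filtering affects visibility only,
never coordinates. Plane contribution is the default statistic; filtering
on the larger of the two single-axis contributions is available via
`per_dimension=True` (published figure captions do not state which was
used; for well-separated axes the two agree closely). Complement
("absence") rows are hidden by default: they carry large mass for common
AEs and would clutter the display while encoding the same contrast as
their presence rows.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `min_contribution_pct` | 0 (or `"auto"` = 100/I) | plane-contribution display cut-off, percent |
| `min_relfreq_pct` | 0 | average-incidence display cut-off, percent (0-100 scale) |
| `dims` | (1, 2) | plotted axes, 1-based, by descending inertia |
| `RANK_TOL` | 1e-12 (relative to sigma_1) | singular values below this are numerical zeros and dropped |
| `GeneratorSpec.arms` / `pi` | — | enrolment and target incidence of the synthetic world |

## Numerical choices

- Singular values below `1e-12 * sigma_1` are dropped; a table whose
  columns are all proportional yields a valid degenerate result with K = 0
  and zero inertia rather than an error.
- SVD sign ambiguity is resolved per dimension by making the row entry of
  largest |U| positive. Axis reflections relative to any externally
  published figure remain legitimate and carry no meaning.
- Ties in singular values keep LAPACK's order; the subsequent sign fix
  makes output deterministic for identical input, which is all the
  pipeline promises.
- Percentages are reported rounded to 2 decimals; full precision is kept
  internally.
- Class ordering is lexicographic, with grades compared numerically inside
  a domain/term (`Nausea:G2` before `Nausea:G10`).

## Incidence denominators

A long-format AE listing names only patients who reported at least one
event. When the enrolment (safety population) per arm is known it should
be supplied (`AEDataset.n_per_arm`; the synthetic generator records it
automatically); otherwise denominators fall back to the distinct patients
observed per arm, which overstates incidence when event-free patients
exist. Records with a grade but no domain/term are kept for grade-level
analyses and excluded, with a logged count, from domain/term levels — the
patient still counts in every denominator.

## Synthetic generator: what it does and does not emulate

`generate` draws an independent Bernoulli indicator per (patient, class)
— and per cycle if requested — at the target incidence pi*_ij and emits
one record per hit. Under this model patient-level incidence is the
sufficient statistic, so the pipeline recovers pi* up to binomial noise
and planted between-arm contrasts are recovered by CA with known power.
It does **not** simulate within-patient correlation between AE classes,
grade progression over cycles, recurrent events, onset times or dropout.
A green test on synthetic data therefore establishes the correctness of
the incidence/doubling/CA/selection chain, not robustness to the
correlation structure of real trial data — which is immaterial here
because every downstream statistic depends on the data only through the
incidence table.

Default scales used in tests (1000-5000 patients/arm, incidences 0.05-0.75,
planted contrasts >= 0.15) mirror the magnitudes of the two published
trials (n = 1308 and 3009; grade incidences from 0.2% to 74%).

## Known limitations

- The published B35 grade-level dimension-1 share (92.57%) is **not**
  reproducible from the printed cycle-1 incidence table: every doubling
  convention on the printed values gives 93.20%, and perturbing each entry
  within its printed rounding radius moves that by < 0.03 pp. The printed
  table is itself internally inconsistent (its G3 "Average" 7.63 is not
  the row mean 7.17), so the published decomposition evidently came from
  the restricted patient-level data. The corresponding acceptance test is
  allowed to fail and documents this.
- Term- and domain-level decompositions of the two trials require the
  restricted patient-level records and are out of reach; only grade-level
  tables were published.
- No inferential machinery (bootstrap confidence regions) and no joint CA
  or matched-matrices comparison; the display is exploratory.
- Incidence analysis ignores multiplicity of same-class events within a
  patient by design.
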