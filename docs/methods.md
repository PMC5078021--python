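# Methods

## Model and assumptions

`tlsea` scores the association between a phenotype's active-compound set
and a protein through two layers of empirical similarity-ensemble
statistics. The underlying assumption is the similarity principle of
ligand-based target inference: if a protein's known ligands are, as a set,
unusually similar to the compounds that drive a phenotype, the protein is a
candidate mediator of that phenotype. No compound needs to appear in both
libraries; identity (Tanimoto 1.0) is simply the strongest form of
similarity and is deliberately retained rather than deduplicated.

Layer 1 treats each phenotype compound separately. Its initial score
against a protein is the sum of its similarities to the protein's m ligands
that strictly exceed a noise floor (0.15 by default — raw background
Tanimoto values below that level are dominated by incidental substructure
sharing). Summed scores grow with m, so they are standardized by a
background scaling law fitted on random pseudo ligand sets: mean μ_m = k·m
and SD σ_m = a·m^b. The law is the standard ensemble-statistics device for
making set scores comparable across set sizes; its constants are properties
of the background library and the fingerprint, not of any protein. The
standardized score Z is converted to an empirical tail probability P_Z
against the pool of background Z values — no parametric tail model is
assumed, which costs resolution (bounded by pool size) but avoids
extreme-value fitting.

Layer 2 aggregates: a protein's original score O sums the Z values at or
above the threshold c whose background tail probability equals α_Z (0.01).
Thresholded summation makes O sensitive to a protein having *several*
individually significant compounds rather than one moderate bump spread
over many. Because every O — observed or null — is computed over the same
full phenotype column set, O needs no further standardization, and its
significance P_O is again an empirical tail probability, now against a pool
of pseudo-ligand-set original scores.

Both null pools derive from one random background similarity matrix M_r,
drawn from the same (property-filtered) compound population as the target
library. The exchangeability assumption behind the p-values is therefore:
a null protein's ligand set looks like a random subset of the background
library.

## Boundary semantics

Threshold wording is implemented literally and is configurable:

* initial-score inclusion is strict (S > 0.15);
* activity cutoffs are strict: pGI50 > 6 is active, any endpoint value
  < 1e-6 mol/L is active;
* MW and AlogP windows are closed intervals;
* ligand sets need ≥ 10 members (strictly fewer are dropped);
* the empirical tail comparisons are inclusive (≥) in both P_Z and P_O;
* network retention is strict (P_Z < 1e-4), and the degree table keeps
  proteins with degree strictly greater than the cutoff.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `sim_threshold` | 0.15 | similarity noise floor in the initial score (unitless Tanimoto) |
| `alpha_z` | 0.01 | background tail level defining the Z threshold c |
| `network_pz_cutoff` | 1e-4 | P_Z retention cutoff for network edges |
| `n_lengths` × `reps_per_length` | 200 × 500 | null pool size (10⁵) |
| `length_range` | (1, 10000) | sampling lengths m for the background |
| `o_length_range` | `None` | row counts for the O null; `None` reuses `length_range` |
| `min_ligands` | 10 | smallest admissible ligand set |
| `pgi50_min` | 6.0 | phenotype activity cutoff (pGI50 = −log10 GI50 in mol/L) |
| `target_activity_threshold` | 1e-6 mol/L | protein-ligand activity cutoff (any endpoint) |
| `fp_nbits`, `fp_diameter` | 2048, 4 | hashed fingerprint length and circular diameter |

The desk-scale sampling default (10⁵-member pools, p-value resolution
10⁻⁵) keeps a full run in seconds on one core; `RunConfig.full_scale()`
switches to 2000 × 5000 (10⁷ pools, resolution 10⁻⁷) when that resolution
is worth the cost. The reported resolution (1/N) accompanies every score.

## Numerical and design choices

* **Scores beyond the pool maximum.** An empirical tail count of zero means
  only "below 1/N". Such scores are carried numerically as 0.5/N — finite,
  sortable, strictly below any resolvable p-value — and the same
  convention feeds the network edge weights.
* **Empirical threshold c.** c is the smallest pool value whose inclusive
  tail fraction is ≤ α_Z; a guard of 1e-9 on α_Z·N absorbs binary float
  error in the count comparison. A pool smaller than 1/α_Z errors out.
* **Background fit.** k̂ is least squares through the origin on the
  per-length means; â, b̂ come from an ordinary least-squares line on
  (log m, log σ_m) over groups with σ_m > 0 (sample SD, ddof = 1). Groups
  with zero SD cannot enter the log regression; if more than half are
  degenerate, or all are, the run errors rather than fitting a vacuous law.
* **Row sampling.** Pseudo ligand sets are drawn without replacement while
  m is at most the row count of M_r and with replacement beyond it, so the
  prescribed length ranges work against small fixtures too; the selection is
  realized as membership/multiplicity matrices multiplied against the
  thresholded matrix, keeping cost linear in matrix size rather than in m.
* **Lengths.** Sampling lengths are distinct draws when the range allows
  (matching "different lengths"), falling back to uniform draws with
  replacement when more lengths are requested than the range contains.
* **Columns.** Each background sample re-draws its column uniformly at
  random; a cycling mode (exhaustive column rotation) is exposed as
  `column_mode="cycle"`.
* **One background run serves both purposes.** The Z pool used for P_Z is
  by default the same sample set used to fit (k, a, b); a
  `reuse_fit_pool=False` flag draws a fresh pool from an independent
  substream.
* **Reproducibility.** A single master seed feeds named substreams
  (background sampling, optional fresh pool, O-pool sampling) via
  `numpy.random.SeedSequence.spawn`, so stages are independently
  reproducible and the full CLI chain is byte-identical under a fixed seed.
* **Aggregation of repeated phenotype measurements** defaults to the most
  potent value per compound (a `mean` policy is available). Most-potent is
  the common screening convention and keeps the active set monotone under
  added measurements.
* **Property windows are per-library** configuration; the same window may
  be applied to both libraries or not, as the data demand.
* **AlogP** is RDKit's Crippen estimate; window membership exactly at the
  edges is implementation-specific and not claimed to match other
  descriptor engines. Likewise hashed Morgan bits differ across toolkits,
  so similarity values are formula-faithful, not bit-for-bit portable.
* **Ties in ranking** are broken by lexicographic protein id, making result
  tables deterministic.

## What the synthetic generator emulates — and what it does not

The matrix-path generator draws similarity entries i.i.d. from a mixture:
a Beta bulk with mean 0.2 (most unrelated pairs are weakly similar, around
0.2–0.3) plus a thin high-similarity tail (weight 0.01) standing for
incidental near-duplicates. Planted proteins have their row blocks redrawn
with the high-tail weight raised to the planted overlap fraction. This
gives exact control of the null and the effect size, which is what the
statistical tests need.

It does **not** emulate the correlation structure of real chemistry: real
similarity matrices have strongly dependent rows and columns (chemical
series), heavier tails, and background SD growing almost linearly in m
(b ≈ 1, as when large random sets keep hitting the same series) rather
than the √m scaling (b ≈ 0.5) that i.i.d. entries produce. Passing null
calibration and power tests on these fixtures therefore validates the
statistical machinery — standardization, empirical tails, thresholding,
ranking — under exchangeability; it does not certify calibration on a real
screening library, where the background must be refitted and the
exchangeability of ligand sets with random background sets is an
approximation. The structure-path generator, in turn, produces valid but
chemically naive fragment-grammar molecules: it exercises parsing,
fingerprints and filters, not medicinal-chemistry realism, and planted
overlap is realized as shared structures (similarity 1.0) rather than
graded analog series.

## Calibration diagnostics for a discrete statistic

O is discrete at zero (a protein with no Z above c), so the plain inclusive
p-value P_O is conservative, with an atom at 1.0 — uniformity should not
and does not hold for it. The calibration check therefore uses the
tie-randomized tail probability
p\* = (N_gt + U·(N_ge − N_gt + 1)) / (N + 1), which is exactly Uniform(0,1)
when the observed score is an independent draw from the pool's own
distribution. The uniformity test also matches the pseudo-ligand-set length
distribution to the ligand-set size distribution, since that is the
exchangeable null the p-value targets. Reported scores always use the plain
(conservative) inclusive form; randomization is a diagnostic only.

## Problem sizes

Default test and acceptance runs use matrices of a few hundred to a few
thousand background rows, 25–30 phenotype columns, ligand sets of 10–40,
and pools of 2 × 10⁴ – 10⁵, chosen as the smallest sizes at which the
Monte-Carlo error of each check is comfortably below its assertion margin.
All of them are generated at run time; nothing is bundled.

## Known limitations

* Empirical p-values are bounded below by pool resolution; at the default
  desk scale the smallest resolvable P_Z/P_O is 10⁻⁵.
* The background scaling law is a two-moment model; heavy-tailed
  backgrounds standardize to Z pools with skew, which the empirical tail
  handles but a normal interpretation of Z would not.
* Filters assume single-protein targets; complexes and mutant annotations
  are out of scope, as are structure standardization beyond RDKit
  sanitization and any live database clients.
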