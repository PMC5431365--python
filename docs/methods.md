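# Methods

## Model and procedure

The object of interest is a subject subset *M* maximizing cardinality subject
to ρ(X_M, Y_M) ≥ r\*, where ρ is the Pearson correlation of two biomarkers
restricted to *M*. Finding the true maximum-cardinality subset is
combinatorial; the package implements two greedy heuristics and makes no
optimality claim (a small-n test enumerates all subsets and records the gap
between the greedy and optimal sizes without requiring it to vanish).

**Correlation loss and gain.** For a current set *M* and subject *i*,
CLM(M, i) = ρ(M) − ρ(M ∪ {i}) and CGM(M, i) = ρ(M − {i}) − ρ(M). They satisfy
CGM(M, i) = CLM(M − {i}, i) identically. When adding/removing a subject would
leave a coordinate with zero variance (undefined ρ), the measure is set to a
±∞ sentinel so the subject can never be selected.

**Agglomerative search** grows a seed triple by the argmin of CLM over
non-members; a tentative addition whose resulting ρ falls below r\* is rejected
and the search stops, so the returned set always satisfies ρ ≥ r\*. A seed
whose own ρ is already below r\* is an error ("seed below threshold"), reported
rather than silently patched: on some variable pairs no axis supports growth,
and the agreement report marks those cells as absent instead of substituting
the divisive answer.

**Divisive search** deletes the argmax of CGM while ρ < r\* and stops at the
first set reaching r\* — the largest satisfying set on the greedy path. If the
set shrinks to 3 subjects without reaching r\*, the trace reports "exhausted"
with the final ρ. The procedure is fully deterministic.

The stopping conventions (agglomerative returns the last set meeting the
threshold, divisive the first) were a genuinely open design point; both were
chosen so that every returned set satisfies the constraint it is named for.
Ties in either argopt are broken by ascending subject id, making reruns
bit-identical.

**Complexity.** Each candidate evaluation updates the five running Pearson
sums (n, Σx, Σy, Σx², Σy², Σxy) in O(1); a step scans all candidates in O(n)
and a run costs O(n²). Coordinates are centred on the full-pair means before
accumulating, which leaves ρ unchanged and keeps the raw-sum formula well
conditioned; the test suite checks the incremental value against a two-pass
recomputation at 1e−12 absolute.

## Seeding: trimmed k-lines

Candidate linear axes are found by a trimmed k-lines clustering: initialize k
lines from random 2-point samples, assign each point to the line minimizing
its squared *vertical* residual, trim the ⌈trim·n⌉ worst-assigned points as
noise, refit each line by OLS on its untrimmed members, iterate to an
assignment fixed point (≤ 100 iterations), and keep the best of `restarts`
random restarts by total trimmed squared residual. An axis losing its members
is re-seeded from the worst-fit points. Vertical rather than orthogonal
residuals are used because the downstream seed rule is defined through a
y-on-x OLS regression. Defaults: k = 3, trim = 0.10, restarts = 50, explicit
seed. With k = 1 and trim = 0 the procedure reduces exactly to OLS. The seed
triple is the three axis members with smallest |residual| (ties by id).

This is a reimplementation of the robust linear-grouping idea rather than a
port of any reference implementation; the search only consumes "initial linear
axes", so any detector satisfying the planted-line recovery property (≥ 95%
correct assignment for well-separated noisy lines in the tests) serves.

## Preprocessing

* **Pairwise-complete extraction**: each variable pair is analysed on the
  subjects with both cells non-missing, so per-pair n values differ.
* **Normalization ratios**: `activity/CS` ratios are multiplied by 1000
  (mUnits per CS unit — the scale on which clinical reference ranges for these
  ratios are printed in hundreds); `CoQ/CS` and all other ratios are plain.
  The factor is overridable. Zero denominators yield missing cells with a
  logged warning.
* **Outlier screen**: a subject is removed when |v − median| / (1.4826·MAD)
  exceeds a threshold (default 4.0) on either coordinate; if the MAD is zero
  the IQR/1.349 scale is used, and if that is also zero the coordinate is
  skipped with a warning. Exactly one pass is applied by design — the screen is
  deliberately not iterated to a fixed point, and the removal list is returned
  and serialized. The default threshold removes on the order of 1–10 points
  from a few hundred heavy-tailed clinical values; the CLI exposes the
  threshold and a "none" mode for sensitivity analysis, since reasonable
  screens differ and downstream subpopulation sizes shift by a few subjects
  accordingly.

## Statistics

Pearson r with the exact Student-t two-sided p-value (t = r√((n−2)/(1−r²)),
n−2 df; cohort pairs have a few hundred subjects, where the normal
approximation is avoidably crude). Exact collinearity is detected by zero OLS
residuals and mapped to r = ±1, p = 0 before the generic formula runs.
Significance is flagged at p < 0.01 and raw p-values are always reported; no
multiple-testing correction is applied. Summary statistics use the sample
(n−1) SD, matching clinical laboratory convention. Correlation is undefined
(hard error) for n < 3 or a constant coordinate.

**Method agreement** between the agglomerative set A and divisive set D is
100·|A∩D|/max(|A|,|D|) — the conservative denominator; min and union
denominators are available as options. The single "n" reported per pair is the
divisive size, since the divisive method always offers exactly one solution,
including on pairs where no agglomerative seed is viable.

## Synthetic cohorts

The generator emulates the structure of a clinical biomarker scatter: a
bivariate-normal background with a chosen weak correlation (default r = 0.3,
n = 100), one or more planted linear clusters with uniform x and Gaussian
vertical noise (default: 100 subjects, slope 2 over an x-range of 100, noise
SD 8.5 — an analytic within-cluster ρ of ≈ 0.989, i.e. the "dominant tight
cluster" regime), optional gross outliers uniform over an inflated bounding
box, and uniformly random missing cells. Cluster noise is parameterized as
the SD of vertical residuals so the planted ρ is controllable in closed form
(ρ = |β₁|σ_x / √(β₁²σ_x² + σ²)).

What passing tests on these cohorts show is that the algorithms recover a
planted linear subpopulation embedded in diffuse noise and that the two
strategies agree on it; what they do not show is anything about assay-specific
error structure, detection limits, heteroscedasticity across the physiological
range, or age effects — none of which the generator models. Acceptance-style
checks average 20 replicate cohorts at these defaults (200 subjects each),
sizes at which both searches run in milliseconds.

## Numerical choices and edge cases

* ρ threshold comparisons use ≥ r\*, r\* = 0.95 default.
* All tie-breaks (argopt ties, equal residuals, equal robust-z) resolve by
  ascending subject id.
* Negative measurement values are admitted on load but flagged with a warning
  (concentrations and activities are physically non-negative); infinite values
  are rejected.
* Missing-value codes on load: empty cell, `NA`, `ND`, `n.d.` (configurable);
  a loader option converts comma decimal separators. Subject ids are strings
  throughout.
* Tables round-trip read∘write losslessly, including the missingness mask
  (values printed with 17 significant digits).

## Known limitations

* Greedy, not optimal: both searches can return smaller sets than the true
  maximum-cardinality subset at r\*; the divisive path in particular can be
  trapped by early deletions.
* The agglomerative result depends on the seeding RNG through the restart
  winner; the divisive result is seed-free.
* Univariate outlier screening only; no multivariate screen, no imputation.
* No model selection over the number of axes k, and no inference (confidence
  intervals) on subpopulation membership.
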