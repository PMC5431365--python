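# corrsubpop

Greedy subpopulation search for highly correlated biomarker pairs.

## The problem

In the biochemical work-up of suspected mitochondrial disease, respiratory-chain
(MRC) enzyme activities measured in muscle biopsies are normalized to a proxy
for mitochondrial abundance — classically citrate synthase (CS) activity,
more recently coenzyme Q10 (CoQ) content. Across a whole clinical cohort the
correlation between any two of these quantities is modest, but a *subpopulation*
of subjects may track a common linear relationship almost perfectly. Identifying
that subpopulation tells you which normalizer is biologically meaningful for
which enzyme, and which patients deviate from it.

`corrsubpop` finds, for a chosen pair of variables (X, Y), a subset *M* of
subjects whose Pearson correlation ρ(X_M, Y_M) reaches a target r\* (0.95 by
default), using two complementary greedy strategies:

* **Agglomerative.** Detect candidate linear axes with trimmed k-lines
  clustering, seed M⁽⁰⁾ with the three subjects nearest the best axis (smallest
  absolute OLS residuals |ε̂ᵢ| = |Yᵢ − Ŷᵢ|), then repeatedly add the subject i\*
  minimizing the **correlation loss**

  CLM(M, i) = ρ(X_M, Y_M) − ρ(X_{M∪{i}}, Y_{M∪{i}}),

  stopping just before the enlarged set would fall below r\*.

* **Divisive.** Start from the full cohort and repeatedly delete the subject i\*
  maximizing the **correlation gain**

  CGM(M, i) = ρ(X_{M−{i}}, Y_{M−{i}}) − ρ(X_M, Y_M),

  stopping as soon as ρ ≥ r\*; this returns the largest (first) set satisfying
  the target, with no randomness anywhere.

The two measures are the same algebra viewed from either side:
CGM(M, i) = CLM(M−{i}, i) exactly. Around the core search the package provides
cohort summary statistics, Pearson tables with per-pair pairwise-complete n and
significance at p < 0.01, CS/CoQ normalization ratios (enzyme activities per CS
unit on the customary mUnits scale), a robust single-pass outlier screen, an
agreement report between the two methods, and a synthetic-cohort generator with
planted ground truth.

## A worked example

```sh
python examples/01_search_subpopulation.py
```

```
cohort: 200 subjects, full-cohort r = 0.644
planted subpopulation: 100 subjects

divisive:      kept 158 subjects after 42 deletions, final r = 0.9507
               recovered 100/100 planted members
agglomerative: grew to 158 subjects, final r = 0.9507
               recovered 100/100 planted members
```

The generated cohort hides 100 subjects along a line (within-cluster ρ ≈ 0.99)
among 100 weakly correlated background subjects. Whole-cohort correlation is an
unremarkable 0.64; both searches return a 158-subject subset at ρ ≥ 0.95
containing every planted member — the extra 58 are background subjects lying
close enough to the planted line to survive the threshold. The other examples
print correlation/summary tables (`02_correlation_tables.py`) and the
multi-pair agreement report (`03_method_agreement.py`).

The same workflows are scriptable from a shell:

```sh
corrsubpop simulate --seed 7 --out-dir out/sim
corrsubpop search --input out/sim/cohort.csv --x X --y Y --mode divisive --out-dir out/run
corrsubpop compare --input cohort.csv --anchors CoQ,CS --targets CIII --seed 1 --out-dir out/cmp
```

Every command writes a `manifest.json` sufficient to re-run it bit-identically.

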