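# econn — effective connectivity by sparse nonlinear system identification

`econn` infers *directed* (effective) connectivity between brain
regions from their BOLD fMRI time series. It is aimed at analyses of
small region networks — e.g. retinotopic visual areas (V1, V2, V3, Vp,
V3a, V4v, V3b, V5/MT) under periodic phase-encoded stimulation — where
the question is not whether two regions co-fluctuate but which region's
past drives which region's present, and through which lag and term.

## Method

Each region in turn is the *seed*, modelled as a polynomial NARX
expansion of every region's past over lags 1…P (default 3): linear
autoregressive terms Y_r(t−l), lagged inputs u_r(t−l), and their
squares — 4·R·P predictors plus an intercept (97 parameters for R = 8,
P = 3), with no cross-region products so every term reads as a single
directed edge. The input u_r(t) is the fundamental-frequency sinusoid
of the region's own response (extracted by FFT, appropriate for
block/phase-encoded designs), a user-supplied series, or zero for
resting state.

With ~120 usable frames the full model cannot be fit by least squares,
so the structure is selected by cross-validated LASSO,

    min_{β0,β}  (1/2N) Σᵢ (yᵢ − β0 − xᵢᵀβ)²  +  λ Σⱼ |βⱼ| ,

over a descending λ path with 10-fold CV; the default λ is the
minimum-deviance choice (the one-standard-error rule is available).
The selected terms are refit by OLS and each is tested by nested
models: F = ((RRSS − URSS)/q)/(URSS/(N−k)) with q = 1 and t = ±√F
(df = N − k; 117 − 6 = 111 for a five-term model). Significant terms
(α = 0.05) form the directed edge list. A seeded simulator generates
synthetic networks from known sparse truths so the whole chain is
verifiable end to end.

## Worked example

Simulate an 8-region, 120-frame network with known sparse structure,
then analyse two seed regions using the true inputs:

```sh
econn simulate --phase-encoded --seed 1 --out demo
econn run --data demo/data.csv --input file:demo/inputs.csv \
          --drop-frames 0 --seed 1 --regions V1,V2 --out demo_out
```

which logs

```
INFO seed V1: design 117x96, |support|=23, R^2=0.980 (1.9s)
INFO seed V2: design 117x96, |support|=22, R^2=0.977 (2.7s)
INFO run complete: 2 seeds, 45 edges (18 significant)
2 seed regions analysed; 18 significant directed edges -> demo_out/edges.csv
```

The significant V1 rows of `demo_out/edges.csv`:

```
source target  lag          term_type  coefficient          F         t  df            p
    V1     V1    1    linear_response     0.254035  60.598131  7.784480  93 9.533388e-12
    V8     V1    1    linear_response     0.048122   7.539471  2.745810  93 7.246549e-03
    V2     V1    2    linear_response     0.274879  25.359905  5.035862  93 2.323192e-06
   uV1     V1    1       linear_input     0.769596 455.497681 21.342392  93 1.314547e-37
   uV4     V1    3       linear_input     0.551614 426.573494 20.653656  93 1.641492e-36
    V5     V1    1 quadratic_response     0.128238  59.033406  7.683320  93 1.546368e-11
    ...
```

Reading: V1's own lag-1 past (a self-loop, t = 7.8), V2's lag-2 past,
its own stimulus drive u₁(t−1) (t = 21.3), the cross-region input
u₄(t−3) and the squared response V5²(t−1) all drive V1 — exactly the
five terms `demo/truth.csv` lists for V1 (compare the coefficients:
truth 0.35/0.30/1.0/0.7/0.1 on the raw scale; the fitted values differ
by the Z-scoring of the analysis). The remaining significant rows
(e.g. V8 at lag 1, t = 2.7) are the over-selection of min-deviance
LASSO combined with naive post-selection refit testing — see
`docs/methods.md` for why these appear and how many to expect.

Each run also writes one JSON report per seed (λ path, CV curve,
chosen λ, support, LASSO and refit coefficients, term tests, config
echo) and a fitted-vs-observed CSV per seed.

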