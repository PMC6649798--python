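# tcspcmcr

Chemometric analysis of pH-dependent time-correlated single-photon
counting (TCSPC) fluorescence decays, built for i-motif DNA molecular
beacons: cytosine-rich sequences labelled with a fluorophore (Cy3) and a
quencher (dabcyl) whose fluorescence lifetime reports the folding state.
At neutral pH the open strand keeps fluorophore and quencher apart; at
mildly acidic pH the strand folds into the four-stranded i-motif, the
dyes approach, and a dominant ~30 ps quenched decay component appears.

The package implements the complete analysis chain used to characterise
these conformational transitions, plus a synthetic-data generator that
reproduces the acquisition statistics so the whole chain is testable
without instrument data.

## What it computes

**Global reconvolution fitting (GLA).**  Each decay is modelled as the
causal convolution of the instrument response with a sum of exponentials,

    I(t) = ∫ IRF(t′) Σᵢ Aᵢ e^−(t−t′)/τᵢ dt′,

fitted to groups of traces with *shared* lifetimes τᵢ (plus a global IRF
colour shift) and free per-trace non-negative amplitudes Aᵢ, by
trust-region nonlinear least squares with variable projection.  Quality
is judged by the reduced χ² of the Poisson-weighted residuals
R = (Decay − Fit)/√Decay and by their autocorrelation; the model order is
the minimum number of terms with χ² < 1.1 and random-looking residuals.
The amplitude-weighted mean lifetime is τ̄ = Σ τᵢAᵢ/100.

**PCA.**  Decays from all sequences/pH values are stacked into a matrix
D (rows = traces ordered by pH), autoscaled column-wise, and decomposed
as D = T Pᵀ + E to expose clustering of sequences and pH groups; local
models refit row subsets (e.g. only acidic pH).

**MCR-ALS.**  For a single sequence, D is resolved into the bilinear
model D = C Sᵀ + E where the rows of Sᵀ are pure conformer decay traces
and the columns of C their relative contributions along pH.  Alternating
non-negative least squares is initialised from evolving factor analysis
(EFA), which exploits the sequential character of the transitions along
pH.  Fit quality is the lack of fit, LOF = 100·√(ΣΣ(d−d̂)²/ΣΣd²), and the
explained variance R² = ΣΣd̂²/ΣΣd².

**Tail fitting.**  Each resolved pure trace is finally fitted, after
trimming the channels up to its maximum, with the minimum number of
exponential terms (no IRF) whose every lifetime passes a t-test and
whose R² exceeds 0.999.

## Worked example

```python
import tcspcmcr as tm

irf = tm.make_irf()                                   # Gaussian, 50 ps FWHM
scenario = tm.preset_scenario("short_sequence", seed=1)
traces = tm.simulate_ph_series(scenario, irf)         # 4 pH x 7 wavelengths

ph4 = [t for t in traces if t.ph == 4.0]
sel = tm.select_model_order(ph4, irf, max_terms=4)
print(sel.results_by_order[sel.order].summary())
```

```
Global reconvolution fit
============================================================
traces: 7   terms: 4   dof: 3354
chi2_reduced: 1.0052   converged: True   iterations: 14
IRF shift: +0.00 ps (se 0.17 ps)
mean tau_bar: 0.1259 ns
------------------------------------------------------------
 term  tau_ns  tau_se_ns  mean_%amplitude
    1   2.962    0.01234              2.1
    2  0.8188    0.01866            2.863
    3  0.1697   0.004804            8.628
    4  0.0297  0.0003987            86.41
```

Four lifetimes are needed at pH 4 and the ~30 ps component carries ~86%
of the amplitude: the folded, quenched i-motif dominates.  τ̄ ≈ 0.13 ns,
an order of magnitude below the open form.  Resolving the conformers:

```python
D = tm.build_matrix(traces)
print(tm.mcr_als(D, n_components=3).summary())
```

```
MCR-ALS: 3 components, LOF = 0.875%, R2 = 0.999923
iterations: 69   converged: True
component dominance (pH at max mean concentration): C1@pH4, C2@pH5, C3@pH7
```

Three conformers reconstruct the series to < 1% lack of fit, dominant at
pH 4 (folded i-motif A), pH 5–6 (a second folded form) and pH 7 (open
strand) — the signature of two distinct i-motif species in the short
sequences.  `tm.tail_fit(result.S[j], D.axis)` then extracts each pure
conformer's lifetimes.

A command-line interface mirrors the library:

```sh
tcspcmcr simulate --preset short_sequence --seed 1 --out data/
tcspcmcr run-all --preset short_sequence --seed 1 --out run/
```

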