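# Methods

`hydrorqa` measures the spatio-temporal coupling between water-quality
records — which factors, at which monitoring stations, move together
with a chosen target record — by combining cross-recurrence
quantification with information-theoretic dependence.  This note
documents the model, the numerical choices, and what the synthetic
validation does and does not show.

## Pipeline

For a target record and each candidate record the pipeline runs four
stages:

1. **Phase-space reconstruction.**  Each z-scored record
   `w_1 … w_i` is delay-embedded into `n` dimensions with delay `t`
   (in samples), producing `N = i − (n−1)t` state vectors
   `x_k = (w_k, w_{k+t}, …, w_{k+(n−1)t})`.  (Some presentations print
   the state count as `i + (n−1)t`; that exceeds the number of samples
   and cannot index into the record, so the standard Takens count
   `i − (n−1)t` is used throughout.)  The delay is the first local
   minimum of the average mutual information between the record and
   its lagged copy; the dimension is chosen by the false-nearest-
   neighbour criterion of Kennel, Brown & Abarbanel.  A *pair* of
   records is embedded with shared parameters: the larger of the two
   dimensions and the smaller of the two delays, so no single-series
   structure is collapsed and the finer time resolution is kept.

2. **Cross-recurrence plot.**  The binary matrix
   `CR[i,j] = Θ(ε − ‖x_i − y_j‖)` marks when the state of one record
   comes within `ε` of the state of the other.  `ε` is a fixed
   fraction of the *joint* phase-space diameter (the maximum pairwise
   distance over the union of both point clouds) so that both records
   are judged on one distance scale; boundary ties (`distance = ε`)
   count as recurrent, matching `Θ(0) = 1`.

3. **CRQA indices.**  From run-length histograms of the matrix:
   recurrence rate `RR = Σ CR / (N·M)` (the printed `1/N²` form is the
   square special case; cross-matrices may be rectangular), determinism
   `DET` (share of recurrence mass on diagonal runs of length ≥ lmin),
   laminarity `LAM` (vertical runs of length ≥ vmin) and mean diagonal
   length `MDL` (mean of diagonal runs ≥ lmin).  `lmin = vmin = 2` by
   convention.  Maximal runs are delimited by the matrix border (zero
   padding), only the direction parallel to the main diagonal is
   counted, and all empty sums follow the `0/0 → 0` convention so
   degenerate matrices never raise.  Note `MDL ≥ lmin` whenever any
   qualifying diagonal exists, so `MDL` values below 2 cannot occur
   under these definitions.

4. **Mutual information and the composite score.**  MI is computed on
   the raw aligned records after equal-width discretization
   (default 16 bins; a value on an interior bin edge belongs to the
   upper bin), in bits, via `I = H(X) + H(Y) − H(X,Y)`.  Within a
   panel of candidates, each of the five indices (RR, DET, LAM, MDL,
   MI) is min-max normalized across the panel's rows and the
   per-candidate score is the geometric mean of the five normalized
   values.  Min-max absorbs any common affine rescaling of an index —
   in particular the MI log base — so the ranking does not depend on
   such conventions.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `epsilon_fraction` | 0.006 | ε as a fraction of the joint diameter. The conventional 0.6% produces extremely sparse matrices on well-spread standardized clouds (quantized sensor records are much more repetitive than continuous simulations); treat it as a first-class analysis knob and aim for recurrence densities in the percent range. The ladder studies below use 0.05. |
| `norm` | euclidean | distance norm; maximum (Chebyshev) available. |
| `lmin`, `vmin` | 2 | minimal run lengths for DET/LAM/MDL. |
| `ami_bins` | 16 | equal-width histogram bins for the AMI curve. |
| AMI `smooth`, `order` | 3, 5 | the AMI curve of strongly periodic signals carries binning ripple; the curve is smoothed with a width-3 moving average and a minimum must be the lowest value within ±5 lags. Without this, spurious 1-lag dips dominate. |
| `max_delay` | 60 | AMI search range; fallback (with a warning) when no minimum exists. |
| `max_dim`, `fnn_rtol`, `fnn_atol`, `fnn_threshold` | 10, 15, 2, 1% | Kennel FNN criteria; `fnn_max_points` subsamples the neighbour statistics for long records. |
| `mi_bins` | 16 | discretization for MI. |
| `standardize` | on | records are z-scored before embedding so ε on the joint cloud is not dominated by unit differences (pH against mg/L-scale factors). Whether the original study standardized is unstated; this is the main expected source of numeric divergence from its tables. |
| `param_scope` | pair | `pair` resolves embedding parameters per (target, candidate); `panel` resolves one parameter set across the whole panel. Pair-wise matching lets the embedding dimension — and hence the recurrence density — vary across a panel's rows, which confounds cross-candidate comparison; panel scope puts every row in one common phase space and is used for the simulation studies. |
| `normalization_scope` | panel | min-max within each (target, station) panel, mirroring per-panel heatmap colouring; `global` pools all rows first. |
| `score_floor` | 0 | optional floor applied to normalized indices before the geometric mean. With a floor of 0 the per-index minimum candidate is forced to score 0, creating ties; the ladder studies use 0.05. |

## Synthetic data

The generator emulates the *shape* of a three-station coastal buoy
deployment (3 stations × 8 factors × 4320 samples at 30-minute
intervals) with controllable ground truth.  Each record is a sum of a
diurnal sinusoid (period 48 samples) with random phase, a slow
quasi-trend, a smooth AR(1) component, and AR(1) observation noise.
Coupling is injected through latent *drivers*: a driver is one more
signal of the same recipe, added to each attached record with a weight
`β` and a per-record lag; intrinsic components are scaled by
`sqrt(max(0, 1 − Σβ²))` to keep marginal variances comparable.  With
`β = 1`, zero lag and zero noise, two attached records are identical.
The default configuration couples each factor across stations with
strength decaying in station rank (0.55, then ×0.65 per rank) and lag
growing with rank (6 samples per rank), echoing geographic separation
without any geographic model.

What the generator does **not** emulate: tides and weather forcing,
nonstationary regime shifts, sensor drift and quantization, cross-factor
chemistry (e.g. the Do–DoP–Temp functional relationships).  Passing
the validation below therefore shows that the pipeline recovers known
lag-coupled shared drivers in smooth autocorrelated records — not that
it characterizes any real hydrodynamic system.

## Simulation studies

Both studies use a *ladder* design: one driver attached to a target
record at weight 1 and to each candidate at its own `β`, so the
pairwise coupling is controlled by `β` alone.  Signal mix: diurnal 0.4,
trend 0.1, driver 1.0, AR coefficient 0.9, observation noise 0.15, lag
4 samples.  Analysis settings: `epsilon_fraction = 0.05`,
`param_scope = panel`, `score_floor = 0.05`, `max_dim = 8`,
`max_delay = 30`, FNN on a 1000-point subsample.

* **Coupling recovery** (`experiments.coupling_recovery`): candidates
  at `β ∈ {0, 0.3, 0.6, 0.9}`, full deployment-length records (4320
  samples), 30 replicates.  Checked: mean score strictly increasing in
  β; the `β = 0.9` pair ranked first, and the `β = 0` pair outside the
  top 2, in ≥ 90% of replicates.
* **Length robustness** (`experiments.length_robustness`): candidates
  at `β ∈ {1.0, 0.8, 0.6, 0.4, 0.2}`, comparing composite rankings on
  the first 2000 samples against the full 4320, 20 replicates;
  checked: mean Spearman rank correlation ≥ 0.8.  Rungs are all
  coupled because a panel containing several effectively-uncoupled
  (near-tied) candidates has genuinely unstable low ranks — rank
  stability is a property of distinguishable couplings.

Record lengths and replicate counts are the package's own validation
sizes, chosen to make the ladder rungs statistically distinguishable
on a single workstation run.

A property of this regime worth stating plainly: on these
high-dimensional embeddings (FNN does not converge below the dimension
cap for AR-driven stochastic records — honestly reported by the
selector as a warning), a 5% threshold leaves the cross-recurrence
matrices extremely sparse.  The CRQA indices then act as a
*strong-coupling detector* — recurrences essentially only occur for
tightly coupled pairs, whose rows sweep all four indices — while MI
provides the graded signal that separates the weaker rungs.  The
composite score aggregates both, which is precisely how it recovers
the full ladder.  Denser thresholds were examined during design and
make per-panel CRQA values *less* comparable, because a
fixed-fraction-of-diameter ε inherits the candidate's own outlier
geometry (and RR-calibrated thresholding is deliberately out of
scope).

## Numerical and degenerate-input choices

* Constant records are rejected with explicit errors everywhere
  (AMI, FNN, discretization, standardization) rather than returning
  arbitrary parameters.
* A zero joint diameter (all states coincide) makes ε undefined and
  raises.
* `embed` errors name the maximal feasible dimension for the given
  delay; the FNN search range is reduced automatically (with a
  warning) when a record is too short to probe `max_dim`.
* MI is floored at 0 against rounding; entropies use `0·log 0 = 0`.
* Constant index columns min-max normalize to all ones (every
  candidate equally good on that index); ranking ties break by factor
  name for reproducibility.
* CSV ingestion interpolates gaps of at most `max_gap` (default 3)
  samples linearly and refuses longer gaps, naming the series.
* All randomness (generator, FNN subsampling) flows from explicit
  integer seeds; reruns are byte-identical.

## Known limitations

* Published per-series embedding tables for the original deployment
  cannot be regenerated without its raw data (AMI bin counts and FNN
  settings for those fits are unpublished); only the pair best-match
  arithmetic on the published values is reproducible, and it is.
* The printed 0.6% ε-fraction is kept as the module default for
  fidelity, but on standardized synthetic clouds it yields nearly
  empty matrices; analyses should set the fraction by target
  recurrence density.
* Per-pair embedding parameters make CRQA indices incomparable across
  a panel when selected dimensions differ strongly; `param_scope =
  "panel"` is provided for that reason.
* MI between strongly autocorrelated records has a large effective-
  sample bias; it enters the composite only after min-max
  normalization, which removes the common offset but not the noise.
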