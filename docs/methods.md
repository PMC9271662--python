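# Methods

`bcinet` replicates, as a tested pipeline, an EEG brain-network analysis
of rehabilitation cohorts: resting-state multichannel EEG is reduced to a
directed effective-connectivity graph per subject and session via
windowed multivariate autoregressive (MVAR) modelling and the direct
directed transfer function (dDTF); graph-theory measures summarise the
network; small-sample normality-gated tests compare treatment arms. A
synthetic cohort generator with exactly known ground-truth coupling makes
every stage verifiable without access to clinical recordings.

## Preprocessing

Each recording is truncated to its leading resting segment (default 5
min), reduced to the 22-channel 10–20 montage (F3, F4, FC3, FC4, C3, C4,
CP3, CP4, P3, P4, FT7, FT8, T3, T4, TP7, TP8, Fz, Oz, FCz, Cz, CPz, Pz;
reference electrodes such as A1/A2 are dropped), band-passed to the alpha
band (8–13 Hz), average-referenced, lesion-normalised, and cut into
rectangular windows (20 s length, 5 s step; a 300 s recording yields 57
windows).

* **FIR filter.** The source analysis names only "an FIR filter"; we use
  a Hamming-window linear-phase design with ~2 Hz transition width at
  512 Hz (845 taps), cutoffs half a transition width outside the band,
  applied forward–backward (`filtfilt`) for zero net phase. Verified: <1
  dB ripple in 8–13 Hz, >20 dB attenuation at 6 and 16 Hz per pass.
* **Lesion normalisation.** Subjects with a right-hemisphere lesion have
  the eight homologous electrode pairs swapped so that *left* always
  means *ipsilesional*. Flipping commutes with filtering and
  re-referencing (asserted in tests); the pipeline applies it after both.
* **Optional artifact hook.** Ocular-artifact removal (ICA in the
  original workflow) is exposed as a callable hook on
  `preprocess_recording`; the synthetic path generates artifact-free data
  and skips it. No ICA is implemented here.

## MVAR estimation

Per window, `X(t) = Σ_{k=1..p} A(k) X(t−k) + E(t)` is fitted by ordinary
least squares on the stacked lag regression; the innovation covariance is
the residual outer product over the `T − p` equations.

Average-referenced data is exactly rank-deficient (channels sum to zero),
and narrowband filtering makes the regressors nearly collinear; the
minimum-norm least-squares solution (pseudo-inverse of the Gram matrix)
is used, which is what EEG MVAR practice effectively does. A constant
channel is rejected outright — no autoregressive description exists.

**Order selection.** AIC, SBC (BIC), FPE and HQ are computed per
candidate order 1..p_max from the log-determinant of the innovation
covariance, averaged over windows; all candidates are scored on the same
`T − p_max` equations so the criteria are comparable, and FPE is kept on
the log scale (argmin-equivalent). The default chooser is the SBC
minimum — the most parsimonious of the four — with all curves reported.
One order per subject-session; windows are refitted at that order.
Because the covariance of average-referenced residuals has a numerically
zero eigenvalue, the log-determinant floors the eigenvalue spectrum at
1e−12 of its maximum; the floored mode is common to all orders and does
not affect the argmin.

## Spectral connectivity

From the fitted coefficients, on a linear grid 0..fs/2 at 0.5 Hz
(inclusive of the 8 and 13 Hz band edges):

    A(f) = I − Σ_k A(k) e^(−i 2π f k / fs),  H(f) = A(f)^−1,
    S(f) = H(f) V H(f)*

* **DTF** `γ²_ij(f) = |H_ij|² / Σ_n |H_in|²` — normalised inflow into
  channel *i*; rows sum to 1 at machine precision.
* **Partial coherence** `P²_ij = |N_ij|² / (N_ii N_jj)` with `N_ij` the
  minor of S(f) with row *i* and column *j* removed. Computed through the
  cofactor identity `N_ij = (−1)^{i+j} det(S) [S^{-1}]_{ji}`, which gives
  identical values at O(n³) per bin; equality with the explicit minors is
  asserted in tests. Bins whose eigenvalue spread exceeds 1e12 are
  diagonally loaded up to that floor before inversion; well-conditioned
  bins are untouched so structural zeros (a chain's end-to-end partial
  coherence is exactly zero) stay at machine level.
* **dDTF** `δ²_ij(f) = η²_ij(f) P²_ij(f)` with
  `η²_ij(f) = |H_ij(f)|² / Σ_f Σ_n |H_in(f)|²`, the frequency sum taken
  over the whole computed grid by default (`eta_band` restricts it to the
  analysis band; both modes are tested). δ² (squared) is the stored edge
  weight. Direction convention everywhere: entry (i, j) is flow from
  channel j into channel i.

The per-window δ² stacks are averaged over in-band bins, then over
windows, into one 22×22 adjacency per subject-session.

**Average reference and partial coherence.** With an exact average
reference the spectral matrix has rank n−1 and *all* its (n−1)-minors are
proportional to the null direction, which drives P² → 1 for every pair.
This is a property of the reference, not of the estimator: in the full
pipeline the dDTF therefore effectively reduces to the full-grid
normalised DTF. The indirect-suppression property of the dDTF is real and
is exercised (and asserted) on fits of unreferenced data, where the
3-node chain's cascade flow is suppressed by orders of magnitude.

## Graph analysis

The adjacency diagonal is zeroed and an absolute threshold τ applied
(grid 0.0075 : 0.0005 : 0.0095; network maps at τ = 0.0085). Survival is
strictly `w > τ`; ties at the threshold are removed (the source text
leaves equality open). Isolated nodes warn but do not abort.

On the surviving graph: node strength (inflow + outflow weights, on the
weighted matrix), and on the binary matrix network density, directed
clustering coefficient, directed local efficiency and global efficiency.

* The headline density formula `D = 2L/(N(N−1))` is the undirected
  convention applied to a directed edge count — a complete digraph scores
  2.0. It is implemented verbatim as the default for reporting fidelity;
  the conventional directed density `L/(N(N−1))` is exposed alongside.
* Directed clustering counts all triangle orientations,
  `t_i = ½[(A+A^T)³]_ii`, over the denominator
  `(k_in+k_out)(k_in+k_out−1) − 2Σ_j a_ij a_ji`; directed local
  efficiency uses inverse shortest-path lengths inside each node's
  neighbourhood subgraph with the same denominator; global efficiency is
  the mean inverse directed BFS distance over ordered pairs, with
  1/∞ = 0. Nodes with fewer than two neighbours (or a zero denominator)
  contribute 0 to network means. On symmetric graphs the directed
  formulas reduce exactly to the undirected ones. All binary metrics are
  pinned to brute-force enumeration oracles on random small digraphs
  (exact equality).

Group-average networks are the mean of subjects' *weighted* adjacencies,
thresholded afterwards. Supra-threshold edges are classed
ipsilesional-within (both endpoints left), contralesional-within (both
right), or other (midline or cross-hemisphere); the three classes
partition the edge set.

## Statistics

All comparisons are two-sided at α = 0.05, ungated by any multiplicity
correction by default (a Benjamini–Hochberg helper is provided but off,
matching the replicated analysis).

* **Gate.** Shapiro–Wilk at 0.05. For paired comparisons the gate is
  applied to the pre and the post sample (both must pass); this
  sample-wise gate — rather than a gate on the differences — is what
  reproduces published FMA comparisons on clinical score data, where the
  scores are non-normal but their differences often are not detectably
  so. Zero-variance samples are flagged non-normal.
* **Paired.** Normal → paired t. Otherwise Wilcoxon signed rank: zero
  differences dropped (Wilcoxon's original convention), average ranks for
  ties, exact two-sided p via a generating-function enumeration of all
  sign assignments up to n = 25 (normal approximation beyond). On the
  reference cohort's BCI arm (12 pairs, 4 zero differences, 8 positive)
  this yields p = 2/2⁸ = 0.0078125, printed as 0.008.
* **Independent.** Both samples normal → equal-variance t. Otherwise
  Mann–Whitney U, exact when n1+n2 ≤ 20 without ties, tie-corrected
  normal approximation otherwise. Exact branches equal exhaustive
  enumeration (asserted); type-I error of every gated branch is
  calibrated to [0.03, 0.07] at nominal 0.05 in simulation.
* **FMA summary.** Per-group mean ± SD (n−1 denominator) pre and post
  with the paired p.

## Synthetic cohort

The generator emits what the analysis assumes: stable VAR(2) processes on
the 22-channel montage driven by Gaussian white innovations (unit
covariance by default), with

* an alpha resonator on each diagonal — AR(2) poles at radius 0.98 and
  angle 2π·10/fs, the smallest damping at which every channel carries
  ≥60 % of its power in 8–13 Hz at fs = 512 Hz;
* one off-diagonal lag-1 coefficient per ground-truth edge, default
  strength 0.04 on a depth-1 graph (five edges within each hemisphere,
  five touching the midline; no target is itself a source). Depth-1 is
  deliberate: each coupling hop multiplies the resonance gain
  (≈40–200×), so cascaded chains make deep targets' direct inflows
  vanish under the dDTF row normalisation. The 0.04 strength puts a true
  edge's pipeline-estimated dDTF on the scale of the τ grid while staying
  responsive to the injected treatment gain — stronger couplings saturate
  the row-normalised dDTF and the gain response inverts. Both choices
  were calibrated once against the preprocessing chain and frozen.
* stability enforced by rescaling lag-k blocks by s^k (companion radius
  ≤ 0.98) if a spec ever exceeds it; a burn-in of max(10p, 500) samples
  is discarded; identical seeds give bit-identical recordings.

A cohort consists of paired pre/post recordings for a BCI-FES arm and an
FES arm (default 8 vs 9 subjects, 5 min at 512 Hz each, lesion side
random per subject). The injected effect mirrors the reported direction
of change: BCI-FES post models have couplings within the contralesional
hemisphere multiplied by 2.0 and FMA gains of 0–4 points (mean ≈ 2); FES
post models are mildly weakened (factor 0.9 on all couplings) with
near-zero FMA drift. Ground-truth directed graphs are returned per
session in native orientation (`flip_matrix` maps them to the
lesion-normalised frame).

What the generator does **not** emulate: volume conduction and realistic
lead fields, ocular/muscle artifacts, non-Gaussian innovations,
nonstationarity, inter-subject montage variability. A green end-to-end
test therefore establishes that the pipeline recovers *model-level*
coupling changes through its own preprocessing, not that it would recover
them from real scalp EEG.

## Numerical choices

* Frequency grid 0–fs/2 at 0.5 Hz, band edges inclusive.
* A(f) inversion rejects only truly singular bins (condition > 1e15):
  narrowband-fitted models legitimately place poles near the unit circle.
* Thresholding uses strict inequality; isolated nodes warn.
* The pipeline seeds every random draw from one `SeedSequence`; reruns
  with the same config and seed are byte-identical.
* Default `p_max` is 10 for exploratory runs; the shipped end-to-end
  checks use `p_max = 4` to stay inside their runtime budget (the
  generative order is 2 and SBC selects ≤ 4 there).

## Known limitations

* dDTF values after average referencing carry no partial-coherence
  discrimination (see above); edge detection rests on the η² term.
* The exact signed-rank enumeration treats ties by average ranks; for
  heavily tied small samples the discrete null can make the two-sided p
  conservative.
* The headline density can exceed 1 by construction; downstream
  consumers should prefer `density_directed` for interpretation.
* EDF input is not supported in this build (no EDF library available);
  recordings are exchanged as labelled delimited text.
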