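# Methods

## Model and procedure

The predictor treats a bacterial replicon as a sequence of consecutive,
non-overlapping windows of nominal length *j* (default 50 000 bp) and
summarises each window by its 4-vector of nucleotide counts (A, T, C, G;
N bases from ambiguity codes count nowhere). Windows are points in R⁴
and the analysis is pure mode-seeking on their kernel density estimate:

1. **Density.** f̂(x) = 1/(n hᵈ) Σᵢ K((x − xᵢ)/h) with
   K(x) = c_{k,d} k(‖x‖²), d = 4.
2. **Mean shift.** With the shadow g = −k′, each point iterates
   x ← x + m_h(x), where m_h is the g-weighted mean of the data minus x,
   until the displacement norm falls below ε. For the gaussian profile
   this is a monotone ascent on f̂.
3. **Clusters.** Points whose trajectories end at the same stationary
   point (mode) form one cluster; modes are identified by single-linkage
   grouping at a merge radius (h/10 by default, see below).
4. **Bandwidth tuning.** A fixed number of artificial fragments (default
   5) is drawn from donor genomes of other bacteria. A donor window
   qualifies when at least one of its four nucleotide sums falls outside
   mean ± c·sd of the host's full-window sums (c ≥ 1, default 1), and
   when it differs from every already-selected fragment by more than
   7.5% in the sum of the four nucleotides. Mean shift runs on host
   windows plus fragments, starting at the host feature-space diameter
   and shrinking h by ×0.9 per step, until every artificial fragment is
   clustered on its own. The first (largest) such h is the tuned
   bandwidth.
5. **Island calls.** The host windows are re-clustered alone at the
   tuned h. Every cluster whose total window mass does not surpass the
   cap (default 200 000 bp) is called, regardless of whether its windows
   are consecutive; for reporting, each maximal run of consecutive
   windows becomes one island interval. A cluster above the cap
   contributes nothing, even if one of its runs is small.

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| window length j | 50 000 | bp | CLI enforces j ≥ 1000; smaller windows raise statistical noise, larger ones lose resolution |
| n_fragments | 5 | — | artificial fragments for bandwidth tuning |
| std coefficient c | 1.0 | — | must be ≥ 1; larger c admits only more alien fragments |
| max island mass | 200 000 | bp | cluster-level cap; typical GI sizes are 10–200 kb |
| kernel | gaussian | — | k(x) = e^(−x/2); a flat (uniform-ball) kernel is selectable |
| ε | 10⁻³ | count units | convergence threshold on the displacement norm |
| max iterations | 500 | — | non-convergence is flagged, the endpoint still used |
| mode merge radius | h/10 | count units | identifies numerically distinct trajectory endpoints |
| h schedule | diameter, ×0.9, floor h_init/1000 | count units | geometric decay |

Feature vectors are raw counts, not frequencies, so h lives in count
units; with 50 kb windows typical tuned bandwidths are a few hundred
counts (backbone windows of one genome scatter with SD ≈ √(j·p·(1−p)) ≈
100 per component).

## Design choices at genuinely open points

- **Kernel.** The general profile formulation admits any k; the gaussian
  is the default because its ascent is smooth and provably monotone,
  which the tests exploit. The flat kernel is kept both as the classical
  alternative and because it matches scikit-learn's implementation,
  used as an independent oracle in the tests.
- **Deviation quantifier.** The fragment criterion is applied per
  nucleotide, but the four sums are constrained (they total ≈ j), so
  demanding deviation in *all four* simultaneously is near-degenerate.
  The default requires *at least one* deviating sum; the quantifier is
  config-exposed (`any`/`all`).
- **7.5% dissimilarity.** "Differ in the sum of the four nucleotides" is
  implemented as the L1 distance between count vectors divided by 2j —
  the fraction of window mass that differs. For two even-split
  compositions this equals |ΔGC|, which makes the threshold easy to
  reason about. Config-exposed.
- **Separation predicate.** Strict by default: every artificial fragment
  must be a singleton cluster (separate from the host *and* from the
  other fragments). A relaxed mode (separate-from-host only) is
  selectable, since the phrase "into different clusters" can be read
  either way.
- **Host-window stopping condition.** The described re-execution loop is
  read as a single loop over decreasing h with the fragment-separation
  stopping test; no additional condition on host windows is enforced.
- **Trailing partial window.** Retained as a clusterable point with its
  raw (smaller) counts, so islands reaching the genome end remain
  detectable, but excluded from the mean/SD statistics, whose meaning
  assumes fixed window mass. A partial window is compositionally remote
  from all full windows and typically becomes its own small cluster —
  i.e. a terminal island candidate; users of genomes whose length is not
  a window multiple should inspect a trailing call critically.
- **Final clustering.** Runs on host windows only (fragments stripped),
  since islands must be host intervals; keeping the fragments in the
  final run is config-selectable (`keep_fragments_in_final`) and then
  fragment-only clusters are discarded before island calling.
- **Non-contiguous clusters.** A low-mass cluster with scattered windows
  is reported as several intervals sharing one source cluster, the mass
  test having been applied to the whole cluster.
- **h_init.** The maximum pairwise distance among host window vectors: a
  flat kernel of that radius sees every point from every point, so the
  search provably starts from the one-cluster regime; for the gaussian
  kernel it is a generous ceiling.

## Synthetic data: what it emulates and what it does not

The generator produces i.i.d. bases at a chosen G+C fraction (A/T and
G/C split evenly), with optional implanted segments of divergent G+C at
known coordinates, and donor pools of i.i.d. genomes along a G+C
gradient. Since the method consumes only mononucleotide counts per
window, an i.i.d. model exercises every code path the method has; codon
structure, k-mer signatures, repeats, phage/transposon motifs,
GC skew and post-transfer amelioration are deliberately absent. Passing
the synthetic benchmarks therefore demonstrates the clustering and
calibration machinery, not performance on real genomes, where island
divergence is weaker and donor pools are uncontrolled.

The default donor pool holds five 500 kb genomes at G+C 0.25, 0.35,
0.45, 0.65 and 0.75: it spans the observed bacterial G+C range, and its
0.10 spacing exceeds the 7.5% dissimilarity floor (for even-split
compositions the dissimilarity equals |ΔGC|), so the default five
fragments are always drawable, one per donor.

The canonical benchmarks, used by the tests and `scripts/acceptance.py`:
a 2 Mb host at G+C 0.55 with one 150 kb implant at G+C 0.30 starting at
0.8 Mb (recovery), and the same host without implants (negative
control), ten seeds each under the default parameters. These sizes run
the full pipeline in about a second per seed.

## Numerical notes

- Gaussian weights underflow to zero for very distant points; a point
  whose weights all vanish is treated as its own mode rather than an
  error.
- Monotone-ascent checks use a relative tolerance of 10⁻⁹, since raw
  density values scale as h⁻⁴ and are tiny in count units. The
  normalization constant c_{k,d} is carried for completeness; it cancels
  in the mean-shift vector.
- Mode merging uses scipy single linkage with threshold h/10; cluster
  ids are assigned in order of first-occurring window index, which makes
  outputs independent of floating-point tie details and byte-identical
  across repeated runs with one seed.
- Bandwidth-search failure (floor reached without separation) is a
  warning plus an empty island list by default; a strict mode aborts
  instead.

## Known limitations

- A donor whose composition matches the host backbone can be selected as
  a fragment when c is small; separating it then drives h below the
  backbone's internal scatter and the search either fails or shatters
  the backbone. Diverse donors and/or larger c mitigate this; the
  default pool avoids the mid-range G+C of typical hosts.
- Islands whose composition matches the host (recent transfer between
  similar genomes) are invisible to any composition-based method,
  including this one.
- Boundary resolution is one window (50 kb by default); breakpoints are
  not refined below window resolution.
- Results depend on the donor pool; with user-supplied pools the tuned
  bandwidth, and hence the calls, can change.
- The cumulative G+C curve (`gc_profile`) is a visual aid — a running
  AT-minus-GC sum with least-squares detrending, in which islands appear
  as sloped, near-straight segments bounded by slope breaks; island
  calls never depend on it, and no bit-exact agreement with any
  particular published curve variant is claimed.
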