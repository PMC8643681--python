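# Methods

## Topology model

A covalently closed circular plasmid satisfies Lk = Tw + Wr. With the
relaxed twist as reference, Tw = N/h (N = length in bp, h = helical repeat,
default 10.5 bp/turn), the linking difference equals the writhe, and gel
topoisomer ladders resolve integer steps in Wr. The supercoiling density is
σ = Wr/Tw.

Two systematic effects separate the writhe read off a gel from the in-vivo
writhe:

- **Temperature.** The helix angle changes by c_T = 0.011°/°C/bp (magnitude;
  configurable). Bringing a plasmid from growth temperature T_g to gel
  temperature T_e shifts writhe by ΔWr_temp = (T_e − T_g)·c_T·N/360 —
  negative for cooling. For a 5455 bp plasmid grown at 85 °C and run at
  24 °C this is −10.17, rounded to −10.
- **Intercalation.** Chloroquine unwinds the helix, shifting writhe positive
  at constant Lk. The shift is measured operationally as the difference of
  major-band writhes between a with- and a without-chloroquine run of the
  same sample (ΔWr_chl), or transferred from a control sample measured
  under identical conditions when the sample's own no-chloroquine gel shows
  only a saturated front band.

The native writhe is Wr_native = Wr_apparent − ΔWr_chl − ΔWr_temp, and
σ = Wr_native/Tw, reported to 4 decimal places in summaries (full precision
internally).

**Rounding.** Corrections are rounded to the nearest whole supercoil by
default (`round_corrections=True`): supercoils are counted as integer band
steps, and mixing a fractional temperature correction with integer band
counts would misstate the measurement's granularity. A flag preserves
fractional values.

**Sign conventions.** Positive writhe = positive (overwound) supercoiling.
One formula covers heating and cooling; no per-case sign flipping.

## Virtual gels

The simulator samples topoisomer ensembles (Gaussian density over integer
writhe, SD = `spread`, multinomially sampled to `n_molecules`; all
randomness through explicit seeds) and renders them under gel conditions:

- **Chloroquine unwinding is linear** in concentration: u·c·N turns with
  u = 19/(1.5·5455) ≈ 2.32×10⁻³ turns/(µg·ml⁻¹·bp), calibrated from the one
  available paired-gel measurement (19 supercoils at 1.5 µg/ml on a 5455 bp
  plasmid). Only one calibration point exists, so anything richer than a
  linear law would be unconstrained. Extrapolated to 7.5 µg/ml the law
  predicts ~95 unwinding turns, which ignores binding saturation; the
  second dimension is therefore treated purely as an arc-separating
  (sign-resolving) device, not as a quantitative unwinding measurement.
- **Mobility is piecewise linear and saturating**: position =
  m_max·min(|Wr_eff|, S)/S. Beyond the saturation writhe S (default 20)
  bands co-migrate as a single front band; nicked species sit at the
  origin. Only qualitative migration facts are available (front band, two
  arcs), so the simplest monotone-saturating map is used; it is trivially
  invertible, which is what round-trip validation needs. The
  second-dimension saturation is widened by the dimension-2 chloroquine
  shift so the whole arc range stays in the linear regime.
- **1D profiles** are sums of Gaussian bands (SD `band_width`, area ∝
  abundance, so total area conserves total abundance) plus seeded Gaussian
  noise. **2D renders** are spot tables (x from dimension-1 effective
  writhe, y from dimension-2): species with equal first-dimension mobility
  but opposite writhe sign separate in y, producing the two arcs.

What the simulator does *not* model: electric-field/reptation physics,
agarose concentration and run-time effects, linear (broken) DNA, band
smearing, image noise of real gel photographs. Passing round trips
demonstrate that the counting and correction logic is self-consistent and
exactly invertible under the stated mobility model — not that the package
can quantify an arbitrary real gel image.

## Band counting

`detect_bands` peak-picks a lane profile (scipy `find_peaks` with
prominence and separation thresholds; band intensity = prominence, i.e.
height above local baseline; sub-grid parabolic position refinement).
`major_topoisomer` is the maximum-intensity band; exact ties break toward
the band nearer the reference, with a warning. `assign_writhe` counts from
an explicit reference band:

- **ordinal** (default): consecutive integers along the ladder — the
  band-counting method proper, valid when every intermediate topoisomer
  produced a band;
- **spacing**: bands are placed on the integer grid implied by the smallest
  inter-band spacing, equivalent to ordinal counting on contiguous ladders
  but robust to missing intermediate bands (like counting against a co-run
  marker ladder). The virtual-measurement harness uses this mode because
  strongly supercoiled populations do not produce bands all the way back to
  the relaxed origin.

Which way writhe increases with migration cannot be read from a 1D lane;
`sign_direction` is supplied by the caller after inspecting which 2D arc
the population occupies. The virtual harness automates that inspection
geometrically: a species' sign is the side of its dimension-2 ordinate
relative to that of a hypothetical dimension-1-relaxed species.

**Resolvability.** The front band is a pile-up of every species beyond the
resolution limit, never a single topoisomer, so it is excluded from
major-band candidacy. A gel is declared uncountable
(`UnresolvableFrontBandError`) when the front band outshines every
resolved band — then the population mode is at or beyond the front, and no
method could identify it. With spread ≤ 2 this triggers when the population
center is within ~2 supercoils of S; below that, virtual round trips
recover the planted writhe exactly (and hence σ to within 1/(2·Tw)).

## Transcriptome logic

Three strains: empty-vector control (Ag), catalytically dead gyrase
(Y119F; binds DNA, carries expression burden, cannot supercoil), active
gyrase (gyrAB). Supercoiling-responsive genes (SRGs) are by definition the
DEGs of gyrAB vs Y119F.

- **Generator**: negative-binomial counts (var = µ + αµ², default
  dispersion α = 0.1), 4 replicates/strain, baseline means lognormal
  (median 200, log-SD 1 — a typical bulk RNA-seq spread), planted classes:
  supercoiling-responsive genes shift only in gyrAB, burden-responsive
  genes shift equally in gyrAB and Y119F, null genes shift nowhere; planted
  |log2FC| default 2.0 with random sign. The generator emulates planted
  class structure and NB noise, not real-data features like operon
  correlation, varying gene length, or batch effects — recovery results
  quantify the set logic, not performance on any real dataset.
- **DE statistic**: median-of-ratios size factors; two-sided moderated t on
  log2(normalized count + 1). Per-gene variances are squeezed toward a
  scaled-inverse-chi-square prior fitted by moments on log variance, and
  the residual degrees of freedom increase by the prior's — at 4 replicates
  an unmoderated t is dominated by variance-estimation noise and loses
  ~15% sensitivity at planted |log2FC| = 2. Benjamini–Hochberg adjustment
  (statsmodels). All-zero genes are flagged `filtered` with NaN statistics.
  This internal statistic exists so the set algebra is testable end to end;
  DEG counts published from real data with external tools are not
  reproduction targets for it.
- **DEG filter**: padj < 0.05 and |FC| > 1.25 (i.e. |log2FC| > log2 1.25),
  both strict, two-sided; boundary genes excluded.
- **Transforms**: FPKM = counts·10⁹/(length·total_mapped) with the caller's
  mapped-fragment total; per-gene Z-scores with population SD, constant
  rows → zeros with a warning.
- **Motif scan**: IUPAC-class matching, both strands, ≤ k mismatches,
  1-based inclusive coordinates, reverse-strand hits at the forward window
  start. Verified against an independent brute-force window scan.

## Growth and retention

µ = least-squares slope of log2(density) vs time, in divisions·h⁻¹ (a
literal dY/dt linear slope is available behind `literal_dY_dt`, but its
units are density per hour). The exponential window can be found
automatically as the longest contiguous run reaching R² ≥ 0.99 (ties →
earlier run), replacing by-eye selection of the "linear portion".
Plasmid retention = selective/non-selective CFU ratio per timepoint,
clamped to [0, 1] with a warning (plating noise).

## Problem sizes and numerical choices

Round-trip validation uses 200 seeded trials (planted writhe ∈ [−25, 25],
spread ∈ [0.8, 2] — the lower bound keeps ladders multi-band so inter-band
spacing is estimable), 10⁵ molecules per sample, gel grid 0.2 position
units; SRG recovery uses 1000 genes × 3 strains × 4 replicates. Both
complete in seconds. Peak positions are refined parabolically (error
≪ the 5-unit band spacing), so grid-index rounding is exact in practice.
Degenerate inputs (flat profiles, empty ladders, constant expression rows,
all-zero genes, zero-σ controls) return empty results, warnings or typed
errors as documented per function, never silent extrapolation.
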