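# Methods

## Data

The packaged fixtures are a market survey of 23 packaged black teas from
Tehran (16 foreign brands, 7 Iranian), each analyzed by ICP-MS for
arsenic, cadmium and lead in the dry leaves (µg/kg) and in the infusion
(µg/L) brewed at 1 g leaves per 45 mL water, 90 °C, 10 min. The tables are
stored as plain CSV in `tearisk/fixtures/`, one row per sample with
per-metal leaf/infusion/transfer columns, and are loaded into validated
`ConcentrationRecord` objects (finite, non-negative, unique
(origin, sample, metal) keys). Column checksums, fixed once when the
fixtures were transcribed, make any later drift a fatal
`FixtureIntegrityError`.

One Iranian sample has arsenic reported as literal zero in both matrices.
Zeros are kept as printed by default; an explicit censoring policy
(`as_is`, `half_lod`, `lod`, using the method's LOD of 0.0003 µg/kg) is
available because substitution below the detection limit is an analyst
choice, not a property of the data.

## Transfer ratio and summary tables

The leaf-to-infusion "transfer" is 100 × infusion (µg/L) / leaves (µg/kg).
This ratio is dimensionally naive — it does not account for the
1 g : 45 mL brewing ratio — so it is not a mass-balance fraction and can
exceed 100% (it does for no fixture record, but the type flags the case).
We reproduce this definition because it is the one the survey reports;
users needing a physical extraction fraction must rescale by the brew
ratio themselves.

Group summaries are arithmetic mean ± sample SD (n−1). The combined
column over the two origins is the mean ± sample SD *of the two group
means*, computed from the group means rounded to 2 decimals. Pooling all
23 samples instead gives visibly different numbers (e.g. 1.12 vs 0.97
µg/kg for arsenic leaves), so the mean-of-means convention is implemented
as the one that regenerates the published table; it is statistically
unusual (it weights a 7-sample group equally with a 16-sample group) and
is confined to `overall_summary`.

Display rounding everywhere is *half away from zero* at the printed
number of decimals (3.105 → 3.11), implemented in `round_half_away`;
machine-readable outputs always carry full precision.

Two families of one-digit discrepancies exist between recomputation and
the published display and are treated as documented exceptions rather
than reproduced: four transfer cells whose exact ratio differs from the
printed value by < 0.006 (consistent with truncation rather than rounding
in the source), and the Iranian lead infusion SD, which computes to
0.9749 (→ 0.97) against a printed 0.98. The test suite pins the exact
values and the exception lists.

## Risk chain

EDI = DC·C_m/BW (µg/kg bw/day); HQ = (EDI/1000)/RfD; HI = ΣHQ;
ILCR = (EDI/1000)·CSF. The µg→mg conversion lives inside the HQ/ILCR
formulas and nowhere else, so callers work in the data's native units.
Reference doses: arsenic 3×10⁻⁴, cadmium 1×10⁻³, lead 4×10⁻³ mg/kg
bw/day. Slope factors: arsenic 1.5, lead 8.5×10⁻³ (mg/kg bw/day)⁻¹;
cadmium has no published oral slope factor, so its ILCR is *not
applicable* (a distinct state from zero, surfaced as None/NaN and a "–"
in displays). Exposure-duration/frequency/averaging-time factors common
in regulatory cancer-risk practice are intentionally absent from the
model; `point_risk_pipeline` exposes an `edi_scale` hook (default 1) for
users who need them.

Classification: ILCR ≤ 1e-6 "acceptable", ≤ 1e-5 "tolerable_below_who",
≤ 1e-4 "tolerable_above_who", above that "critical" (bands closed at the
upper edge); HQ/HI concern starts at exactly 1 ("lower than 1" strict).

Body weights are 50 kg (children, < 15 y) and 65 kg (adults). Daily
consumption is not pinned by the consumption surveys the assessment
relies on, so DC is a required, echoed parameter with defaults of
0.5 L/day (children) and 1.0 L/day (adults) — mid-range values for a
population where ~3–3.5 g of black tea per day is typical and children
drink weaker, smaller servings. Every report carries the DC actually
used (`dc_used` in reports and manifests).

The published risk table contains one internal inconsistency: the foreign
arsenic EDI of 0.05 µg/kg bw/day implies HQ ≈ 0.017 after unit
conversion, not the printed 0.01. The formulas are implemented exactly;
the inconsistent cells are not used as checks.

## Monte Carlo engine

Uncertain inputs are declared as `DistributionSpec`s (point, normal,
lognormal, uniform, triangular, empirical; optional [low, high]
truncation enforced by resampling, with a bounded retry count so an
empty truncation region fails loudly). The original analysis ran 10,000
iterations in a spreadsheet add-in without stating the input
distributions; those histograms are therefore acknowledged as not exactly
reproducible. The engine's defaults are the conventional choice for
contaminant data: lognormal concentrations moment-matched to each
origin's infusion mean/SD (fit on the positive values; an all-zero group
is directed to the empirical or normal family), point values for DC and
BW unless the user configures distributions. Every run echoes its full
configuration.

Sampling uses one `numpy.random.default_rng(seed)` generator with a fixed
documented order — metal concentrations alphabetically, then per group
(sorted by name) DC then BW — so identical (seed, config, data) gives
bit-identical results. One concentration draw per metal is shared across
groups (both groups drink the same tea). With all-point specs the
simulation collapses exactly to the deterministic pipeline, which the
tests assert.

Read-outs: linear-interpolation quantiles (the NumPy default convention);
equal-width cumulative/reverse-cumulative frequency tables whose
cumulative column runs 0 → 1 over the bin edges with reverse = 1 −
cumulative; exceedance fractions defined as strictly-above, with the ≤
complement reported alongside. Independence between inputs is assumed
throughout, matching the original analysis's silence on correlations.

## Sensitivity

Contribution to variance follows the convention of the spreadsheet risk
tools that popularized the chart: Spearman rank correlation r_i of each
input with the output, contribution_i = sign(r_i)·r_i²/Σr_j²·100, so
absolute contributions sum to 100%. Rank-based, hence invariant to
monotone transforms of individual inputs; constant inputs are excluded
with a warning (zero contribution); a constant output is an error. This
is a screening heuristic, not a Sobol decomposition.

## Synthetic data

The generator idealizes the contamination structure: per origin × metal,
leaves ~ lognormal(meanlog, sdlog) and infusion = leaves × Beta(α, β)
transfer fraction, so the recomputed transfer ratio equals the drawn
fraction × 100 by construction and never exceeds 100%. Default parameters
are moment-matched to the packaged survey (same 16 + 7 sample sizes),
with the Beta variance clamped just inside the m(1−m) bound so matched
shapes stay positive. What the generator does *not* emulate: the >100%
ratios a dimensionally naive printed ratio can produce, detection-limit
censoring, and any correlation between metals within a sample. Passing
tests on synthetic data therefore demonstrate the pipeline's correctness
under the assumed structure, not the idiosyncrasies of real survey data —
those are covered by the packaged fixtures.

`recover_parameters` provides moment-based estimates (mean/SD of log
leaves; mean transfer fraction) whose error provably shrinks with n; the
tests check recovery at n = 10⁴ (meanlog within 0.05, ≈ 12 standard
errors) and consistency against n = 10².

## Numerical and design choices

- Quantile convention: linear interpolation between order statistics.
- Rounding for display: half away from zero; never applied to stored data.
- Sample SD uses ddof=1 everywhere; SD of a single value is reported as
  absent, not 0.
- Problem sizes in tests: simulations use 300–10,000 iterations depending
  on what the assertion needs (exact collapse checks are size-independent;
  3-standard-error mean checks use the full 10,000).
- The report bundle is written to a temporary directory and moved into
  place only on success, so a failed stage leaves no partial outputs.

## Known limitations

- Only the oral route via tea infusion is modelled; dermal and inhalation
  exposure are out of scope, as is any ICP-MS signal processing.
- The combined-column convention and the transfer ratio are reproduced as
  published, dimensional caveats and all.
- No between-input correlations and no Sobol-style variance decomposition.
- The published histogram shapes and the "75–85% below 10⁻⁵" reading for
  foreign-tea arsenic ILCR depend on undisclosed input distributions; the
  package reports these quantities for whatever distributions the user
  configures instead of asserting them.
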