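# Methods

## Scope and data model

The package operates on nutrient-addition bioassay experiments: natural
seawater amended with single nutrients or factorial combinations drawn from
{N, P, Fe, Mn, Co, Zn, Si, B12}, incubated for a set duration, with
chlorophyll-a measured in replicate against an unamended control. An
`Experiment` carries site metadata (latitude, longitude, temperature,
duration, initial chlorophyll), ambient dissolved nutrient concentrations,
and one `Treatment` per added-nutrient set. Mesoscale in-situ enrichment
experiments (single replicate) are stored with a `design` flag and refused
by the statistical classifier.

Concentrations are canonicalized to mol/L internally. Default file units
follow reporting convention — µmol/L for N, P, Si; nmol/L for Fe, Mn, Zn,
Co; pmol/L for B12 — and are overridable per column. The conversion divides
by the unit's µmol-relative factor before scaling, so the 10³/10⁶
equivalences between unit families are exact in floating point. "N" means
dissolved inorganic nitrogen (nitrate + nitrite); organic N and P pools are
not modelled. Below-detection values are stored as the detection limit with
a flag; deficiency calculations use the limit value, which keeps ratio
denominators positive at the cost of biasing extreme ratios toward the
detection floor. Longitudes are normalized to (−180, 180]; no other
coordinate transforms are applied.

## Growth rates

Net growth is the log-ratio rate μ_net = ln(Chl_T/Chl_I)/t in d⁻¹, computed
from the arithmetic mean of replicate final chlorophyll (a per-replicate
variant exists for the classifier's statistics, where comparing log
chlorophyll is identical to comparing per-replicate rates). It is a net
rate by construction: growth minus all loss processes; no light or grazing
corrections are attempted. The temperature envelope μ_max(T) =
0.59·e^(0.0633T) d⁻¹ is an empirical upper bound calibrated over roughly
−2 to 35 °C; evaluation outside that range warns and extrapolates. The
relative rate μ_net/μ_max may exceed 1 — the envelope is empirical, not a
hard cap. Treatments whose replicate-mean final chlorophyll is zero have an
undefined log-ratio and are skipped with a log entry rather than propagated
as NaN.

## Limitation classification

The classifier performs a deterministic traversal of the addition lattice:

1. every single addition vs control; all significant increases form the
   primary level (several independent single responses are reported
   together and flagged `multiple_primary`);
2. if no single addition responds, every available pair vs control;
   a significant pair is independent co-limitation. Ties between several
   significant pairs are broken by largest mean effect, then
   alphabetically, with alternates flagged — the real compilations never
   present this case, but determinism requires a rule. If the design has no
   pairs, the experiment is *indeterminate* ("co-limitation untestable"),
   deliberately distinct from *replete*;
3. serial levels: with base set B (union of the previous levels), each
   treatment B∪{x} is tested against the literal B treatment. A missing
   base treatment stops serial testing (`no_base_treatment`) — no
   imputation from best-responding supersets, which would invent
   comparisons the experiment did not run. A double extension B∪{x,y}
   counts as serial co-limitation only when neither single extension
   responds. One further round gives the tertiary level (three levels
   maximum);
4. nothing significant anywhere, with all comparisons determinate →
   replete.

Only significant *increases* are limitation evidence. Two statistical
backends are provided because compiled source studies themselves used
either t-tests or ANOVA with post-hoc tests, and the outcome can depend on
that choice: `welch_t` (default) is a one-sided Welch test per comparison
at α = 0.05, robust to unequal variances; `anova_tukey` computes
studentized-range (Tukey HSD) adjusted p-values over all treatments of the
experiment at once, bounding the family-wise error of the whole
classification. Comparisons may run on raw chlorophyll (default, matching
how source studies compare treatment means) or on log chlorophyll
(`scale="log"`), which is equivalent to comparing per-replicate net growth
rates and is homoscedastic when replicate noise is multiplicative. No
multiple-testing correction is applied by default (matching source-study
practice); `holm=True` applies a Holm step-down adjustment over the full
comparison lattice of the experiment. Groups with fewer than three
replicates yield indeterminate comparisons, never silent significance.
Comparisons between two sets of bit-identical replicates (zero variance on
both sides) are resolved deterministically: a positive mean difference is
treated as established, a zero or negative one as absent.

For automated re-analysis of simulated surveys the recommended
configuration is `method="anova_tukey", scale="log"`: the simulator's
replicate noise is lognormal, so log-scale comparisons have equal variance
across treatments, and the family-wise Tukey procedure bounds the
probability that any false comparison corrupts an experiment's regime
label — with one-sided per-comparison tests at α = 0.05 and the two to
three true-null comparisons a factorial design contains, the expected
per-experiment error would approach 10%, which no fixed labelling could
survive.

## Stoichiometric deficiency

Quotients q_i = C_i/R_i use the relative molar requirement profile
N 16 : P 1 : Fe 7.5×10⁻³ : Mn 2.8×10⁻³ : Zn 8×10⁻⁴ : Co 1.9×10⁻⁴
(P ≡ 1). Si and B12 carry no coefficient and are excluded. Nutrients are
ranked ascending; the smallest quotient is the most-deficient nutrient. A
prediction requires at least two measured nutrients. Ties within a relative
tolerance of 10⁻⁹ are reported as joint most-deficient with alphabetical
serialization order. Zero concentrations are legal (q = 0). An optional
co-deficiency band (off by default; ±20% when enabled) widens the
most-deficient set to quotients within the band, reflecting the idea that
near-balanced depletion cannot be resolved into a single limiter.

Agreement with an observed limitation assigns exactly one of five
categories, in this precedence: *replete* (observed category replete),
*correct* (prediction in a single-tagged primary level),
*colimited_including_predicted* (prediction inside a co-tagged primary
level), *limiting_not_measured* (an observed primary nutrient absent from
the measured set), else *incorrect*. Partial matches at serial levels count
as incorrect — an explicit convention, since level-2 agreement is a weaker
claim than the primary prediction the quotient rule actually makes.

The critical ratio R_a/R_b (e.g. N:Fe = 2.13 mol:mmol, N:P = 16 mol:mol)
is the dissolved-ratio threshold separating a-deficiency from b-deficiency
in any two-nutrient comparison; the ratio-response analyses draw it as the
reference line.

## Dataset trends

Growth responses are grouped by number of nutrients added (0, 1, 2, 3+,
the top group pooling larger additions). Groups get one-way ANOVA F/p and
Tukey HSD compact letters produced by the insert-and-absorb algorithm;
letters are assigned in ascending-mean order. The regression of growth on
n_added treats the count as numeric (0–3), the ANOVA as categorical — both
are reported. Simple regressions use least squares with pairwise deletion
of non-finite values; R² = 1 − SSE/SST equals the squared Pearson
correlation and the p-value is the F-test on (1, n−2) degrees of freedom
(identical to the two-sided slope t-test). Temperature-normalized analyses
drop responses without a temperature record, so relative-rate sample sizes
are smaller than absolute ones by exactly the treatments of those
experiments. Covariate regressions use absolute latitude (responses are
symmetric about the equator). Kernel density estimates are Gaussian with
the nrd0-style default bandwidth 0.9·min(sd, IQR/1.34)·n^(−1/5), guarded
for degenerate spread (IQR 0 falls back to sd, then to |x| or 1).

## Ekman upwelling

Ekman pumping is w_E = (1/ρ₀)·ẑ·∇×(τ/f) evaluated on a regular lat/lon
grid with the full spherical curl, including the metric cos φ factor:
w_E = [∂(τ_y/f)/∂λ − ∂((τ_x/f)cos φ)/∂φ] / (ρ₀ R cos φ). For constant
zonal stress this reduces to the closed form (τ_x/ρ₀f²)(β + f tan φ/R),
which the tests evaluate analytically. Positive w_E is upwelling.
Derivatives are centered differences with one-sided edges; ρ₀ defaults to
1025 kg m⁻³; the band |lat| < 5° is masked (f → 0 singularity). All three
are configurable since no single convention is universal. Upwelled nitrate
is the elementwise product of w_E with a user-supplied
nitrate-below-mixed-layer field — no mixed-layer-depth computation is
included; downwelling cells report zero flux with the raw signed product
retained in a companion layer.

## The synthetic-data generator

The simulator exists to give every stage a testable ground truth; it
emulates the *structure* of compiled bioassay datasets, not any particular
ocean. Per treatment it integrates, in daily steps,

    μ = μ_max(T) · min_i C_i/(K_i + C_i),     Chl ← Chl·e^(μ·dt),

with new chlorophyll consuming nutrients stoichiometrically (1 µg Chl per
1 µmol N, other elements scaled by the requirement profile) and each step
capped so drawdown never exceeds availability. Half-saturation constants
are tied to the same profile, K_i = (R_i/16)·K_N with K_N = 0.5 µmol/L, a
mid-range value for mixed communities; this makes a concentration of m·K_i
support the same chlorophyll production for every nutrient, so the
quotient ordering used for ground truth equals the multiplier ordering.

Regimes place tested nutrients at depleted (0.1·K), intermediate
(serial: 1·K, or 0.61·K/2.0·K for the tertiary chain — Monod factors that
space the treatment ladder roughly evenly in log chlorophyll) or replete
(40·K) levels; replete macronutrient values land near 1–20 µmol/L and
trace metals near 1–10 nmol/L, i.e. oceanographically plausible. Additions
are saturating spikes sized to support ~10 µg/L of new chlorophyll,
matching bioassay practice. Replicates are the deterministic trajectory
times mean-one lognormal noise with CV 0.10, a typical fluorometric
triplicate scatter; replicate count defaults to 3, duration to 2 days,
initial chlorophyll to 0.2 µg/L.

Ground truth is the Liebig-minimum structure of the ambient quotients over
the tested panel: quotients ≥ 10·K cannot limit within the incubation, the
two lowest co-limit when within a factor 2 of each other, and remaining
limitable nutrients form serial levels. Surveys draw regimes with weights
(gyre 0.28, upwelling 0.22, transition 0.14, serial N→Fe 0.12, serial
Fe→N 0.09, tertiary N→Fe→Co 0.05, replete 0.10) — a mixture in which
primary N and Fe dominate and co-/serial limitation is common, as in the
compiled experimental record. Each regime occupies a characteristic
absolute-latitude band (gyres at low latitude, Fe-limited upwelling at
high), and temperature follows latitude (T = 28 − 0.38·|lat| + ε °C,
clipped to −2..30), which plants the latitude-temperature correlation and
concentrates multi-nutrient designs in warm waters — hence the
unnormalized growth-vs-n-added trend exceeds the temperature-normalized
one, and a noiseless per-treatment sidecar records the planted
relationships for recovery tests. One global random stream, seeded from
the config, drives everything; identical seeds give byte-identical output.

What the simulator does **not** emulate: grazing and viral loss dynamics,
light limitation, community composition shifts, organic nutrient pools,
contamination artifacts, and measurement error in the ambient nutrient
concentrations (station tables can add that separately). Passing recovery
tests therefore demonstrate that the pipeline's statistics faithfully
invert the generating model at realistic noise — not that real experiments
are free of the confounds above.

Problem sizes used by the test battery: 500 simulated experiments
(~2,800 treatments) for regime recovery, 100–200 stations for deficiency
labels, 150–500 experiments for trend recovery; these sizes put binomial
and regression standard errors well inside the asserted margins.

## Numerical and design choices

- Welch–Satterthwaite degrees of freedom via scipy; Tukey HSD via the
  studentized range (scipy), two-sided, with the positive-difference
  requirement enforced on top.
- Holm adjustment is computed over the full potential comparison family of
  an experiment (additions vs control, every treatment vs an immediate
  subset treatment) so the traversal consumes a single consistent set of
  adjusted p-values.
- Compact letters: Piepho-style insert-and-absorb over the significant
  pair list; deterministic letter order by ascending group mean.
- Deficiency tie tolerance 10⁻⁹ relative; classifier has no tie tolerance
  (exact float comparison of means only decides the largest-effect
  tie-break, which noise makes unique almost surely).
- Degenerate inputs: empty CSVs round-trip to empty collections with a
  warning; single-group ANOVA returns statistics without letters;
  regressions refuse zero-variance predictors and n < 3.
- The pipeline adopts recorded limitation designations when present
  (mirroring how compilations defer to source-study assessments) unless
  `--reclassify` is passed.

## Known limitations

- The classifier reproduces the *semantics* of published designations, not
  any specific study's post-hoc test; exact re-derivation of every
  recorded designation from raw replicates is not claimed.
- Agreement scoring depends on the measured-nutrient set; sparsely
  measured experiments inflate the limiter-not-measured category.
- The Ekman module assumes a steady, laterally uniform-density Ekman layer
  and ignores the mixed-layer-depth dependence of the nitrate field it is
  given.
- Serial co-limitation beyond the tertiary level is not represented.
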