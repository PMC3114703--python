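# Methods

## The experimental system being modelled

Size-fractionation microcosms separate the two main mortality agents of
heterotrophic bacteria in lake water. Filtration through 1.6 μm yields a
predator-free community of bacteria and viruses (treatment V); 5-μm
filtrate retains nanoflagellate grazers as well, incubated either in the
dark (VF) or in the light with the small autotrophs active (VFA). Bottles
run in triplicate for four days with sampling at 0, 48 and 96 h, plus
0–24 h dilution assays for viral production and ³H-leucine assays for
bacterial production on days 0, 2 and 4, and a DGGE fingerprint of the
community at the start and end.

## Estimators

**Net growth and loss rates.** Rates use two-point log ratios,
`r = (ln N(t) − ln N(0)) / t` with `t` in days, not a regression through
all time points: the design has only three sampling times and the
convention in this literature is the paired-endpoint form. The
predator-attributable loss rate is `g = r(V) − r_b(VF or VFA)`. V and
predator bottles are physically distinct, so no per-replicate pairing
exists; `g` is computed per predator replicate against the replicate-mean
V rate, and its sd combines the two treatments' sds in quadrature.

**Viral production.** The dilution assay regresses viral counts on time
(ordinary least squares over all six sampling points, no outlier
removal) and corrects the slope for host dilution as `VP = m·(b/B)`.
This is the published form of the correction; note it *shrinks* VP when
hosts are diluted (`b < B`). The inverted scale-up convention `m·(B/b)`
is available via `correction="B_over_b"` for sensitivity analysis.
Negative slopes floor VP at 0 with a warning — production is physically
non-negative. Lysed cells are `VP × 24 / burst_size` (burst size 27, the
reported average for these lakes): the ×24 converts the hourly VP to the
daily units lysis activity is reported in. Per-capita lysis mortality
divides lysed cells by the standing bacterial abundance.

**Bacterial production.** The leucine chain
`BP = Leu × 131.2 / 0.073 × 0.86 × ID` (ID = 1) collapses to
1.5456×10⁻³ μgC per pmol Leu; the unit registry carries
pmol → mol → g → μg explicitly and is validated by the 647-pmol ≡
1.000 μgC l⁻¹ h⁻¹ round number. Blank correction subtracts the mean of
the killed controls (the design has exactly two) from the mean of the
live tubes, floored at zero.

**Stimulation.** The statistic's algebraic body is implemented from its
verbal definition — the difference in relative variation between a
predator treatment and V over a window, ×100 — because that is the form
consistent with its sign conventions (0 for identical treatments, +100
when V doubles and the treatment triples). Windows are 0–48 h and
48–96 h, with 0–96 h as a convenience. An `absolute` mode (difference of
absolute changes scaled by the V baseline) is provided for sensitivity
analysis. Under noise-free exponential dynamics the statistic over a
window T equals `100·(e^{r_T·T} − e^{r_V·T})`, which grows quickly with
T and with the rates; windowed values on realistic summer rates are
therefore in the hundreds of points even though field-measured values
(on saturating, non-exponential dynamics) are tens of points. Treatment
comparisons use one-way ANOVA with Fisher's *protected* LSD (pairwise
pooled-variance t tests only when the omnibus F is significant at 0.05,
df = N − k) and two-sided paired t tests; zero-variance cases are
resolved explicitly (identical data → F = 0/t = 0, p = 1; constant
nonzero paired difference → degenerate-data error).

**Fingerprints.** Bands are matched across lanes by a greedy
nearest-position sweep in ascending position order: a band joins the
current canonical band if it lies within the tolerance (default 5 px —
no published value exists; configurable) of the running mean position
and its lane is not yet a member (two same-lane bands mapping to one
canonical band is a conflict error). Canonical position is the member
mean; the sweep is deterministic and idempotent. Relative intensities
are `P_i = n_i/N` per lane. A band belongs to a treatment if present
(`P_i` above the detection floor, default 0; 0.004 reflects the
literature's DGGE sensitivity of ~0.4% of total counts) in any of that
treatment's lanes; commonality tables tally bands in all three
treatments, in exactly one, and in exactly one pair, which partitions
the total by construction. Percentages round half away from zero.
Replicate DNA is pooled per treatment before DGGE in this design, so the
band model has no replicate axis. Lane clustering is UPGMA on
Bray–Curtis dissimilarity (scipy average linkage; exact ties merge in
lane input order), with similarity `1 − ΣΔ/Σ(p+q)` reported to match the
field's scale bars, and newick serialization via scikit-bio.

## Synthetic generator

Mean bottle dynamics are deterministic ODEs integrated with fixed-step
RK4 (step 0.1 h):

* `dB/dt = (μ_b·(1 + boosts) − δ_v − γ·[flagellates]) · B` — the
  enrichment boost (predator-mediated nutrient release, default 0.3)
  applies in VF/VFA, the autotroph boost (default 0.1) only in VFA, and
  grazing `γ` only where flagellates are present;
* `dV/dt = burst_size·δ_v·B − decay_v·V`;
* nanoflagellates follow logistic growth where present (rate 0.35 d⁻¹,
  carrying capacity 4× the inoculum — a doubling-to-tripling over four
  days, as observed in these bottles); picocyanobacteria grow
  logistically in the light, decline slowly in the dark, and persist in
  V only as a 3% filtration residual (the observed pass-through of the
  1.6-μm filter is 1–5%).

Stochasticity enters only as mean-preserving multiplicative lognormal
observation noise (default CV 5%, a typical flow-cytometry replicate
CV), so counts stay positive and the estimators' smooth-exponential
assumption holds in the mean. Demographic (birth–death) noise, spatial
structure and any explicit photochemistry are out of scope; passing
recovery tests therefore show estimator correctness under the assumed
dynamics, not robustness to model misspecification in real bottles.

Dilution assays dilute both hosts and viruses by the dilution factor
(default 1/3, i.e. 50 ml into 100 ml virus-free water) and grow viral
counts linearly at `burst_size·δ_v·b/24` per hour; the true slope is
recorded on the assay for recovery tests. Leucine assays are built
backwards from a target BP (live tubes = net rate + control background,
two killed controls). Gels place phylotypes at canonical positions
10 px apart, drop those below the detection floor, and can emit either
an aligned matrix or raw per-lane jittered band lists for exercising the
matcher.

Scenario presets LA1/LA2/LB1/LB2 seed initial abundances from the
published in situ values of the four reference experiments
(oligotrophic vs mesotrophic lake × early spring vs summer). Preset
rates are anchored on the published seasonal contrast: summer lysis
mortality ~1 d⁻¹ vs ~0.2 d⁻¹ in spring, with μ_b chosen so predator-free
net growth lands near the printed ~0.5 d⁻¹ (summer) / ~0.2 d⁻¹ (spring).
An earlier draft used a summer lysis rate of 0.3 d⁻¹, which contradicts
the published summer mortality range and makes dilution-assay slopes
noise-dominated (24-h viral accumulation ≪ viral background); the
anchored value restores the signal-to-background ratio real assays
exhibit.

## Validation experiment sizes

The Monte-Carlo stimulation recovery uses 50 independent triplicated
V/VF bundles at CV 5% with a planted +25-point stimulation per 48-h
window (treated net rate solved in closed form from the V net rate of
0.5 d⁻¹); recovery is judged against 2 Monte-Carlo standard errors of
the grand mean, and composite net rates against a 15% per-bundle band
from the 96-h two-point estimator. These sizes give comfortable margins
(observed rate errors ≈ 5%) while keeping the whole suite fast.

## Numerical choices and degenerate inputs

* RK4 at 0.1 h resolves the stiffest preset rates (~1.5 d⁻¹) to ≈1e-12
  relative error over 96 h; the virus-bookkeeping conservation test
  (viruses gained = burst size × cells lysed when decay is 0) is checked
  against an independent fine-step trapezoid integral at 0.1% tolerance.
* Seeds: every stochastic routine takes an explicit integer seed;
  bundle-level seeds derive arithmetically (not via Python's salted
  `hash`) so runs are reproducible across processes.
* Counts must be strictly positive (log rates), times strictly
  increasing with 0 present; dilution assays need ≥3 points in [0, 24] h
  and 0 < b ≤ B; all-zero gel lanes, unmapped lanes, unknown config
  keys and out-of-range parameters raise typed errors.

## Known limitations

* The exponential-mean model cannot reproduce saturating abundance
  plateaus; stimulation magnitudes on multi-day windows are accordingly
  larger than field-reported values (sign and ordering are the
  meaningful outputs there).
* Grazing is a constant per-capita loss, not a functional response in
  flagellate density, so flagellate dynamics do not feed back on
  bacteria.
* The band matcher assumes canonical spacing comfortably above the
  jitter scale; heavily co-migrating bands are reported as conflicts
  rather than deconvolved.
* Real DGGE intensity is a nonlinear function of template abundance;
  the generator's proportional intensities make Bray–Curtis recovery
  easier than on real gels.
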