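# Methods

## Model

Heights follow the Schumacher curve

    h = 1.3 + exp(β₀ + β₁ / dbh),        β₁ < 0,

an increasing, concave height–diameter relation with asymptote
1.3 + exp(β₀). Site form (SF) is this relation read at a reference
diameter d_ref (default 40 cm) — a site-quality measure that needs no
ages, which is what makes it usable in uneven-aged multispecies stands.

Two difference forms project an observed state (H₁, D₁) to a new diameter:

* **ADA** (algebraic difference approach): the level parameter cancels,
  leaving one global shape parameter β₁ > 0 (sign absorbed by the minus in
  exp(−β₁/D)); every site has its own level but a common shape —
  anamorphic curves.
* **GADA**: the site variable X₀ = (ln(H₁−1.3) − β₀/D₁)/(1 + β₁/D₁) is
  solved from the initial state and re-enters both level and slope, so
  curve shape varies with site — polymorphic curves.

Both are self-referencing (H₂ = H₁ at D₂ = D₁) and path-invariant
(D₁→D₂→D₃ equals D₁→D₃); the test suite enforces both to 1e-9 over 10⁴
random states within the tree-height scale (projected heights < 100 m —
beyond that, double-precision rounding alone exceeds such a tolerance).

## Estimation

**Difference models.** Fits minimise squared error of predicted H₂ over
remeasurement pairs of dominant trees (tree level, for SF_H-D) or of
plot-mean dominant states (for SF_MH-MD). Exponential-in-1/D models have
flat likelihood regions, so fitting is multi-start: ADA over a log-spaced
β₁ grid 1–200 cm; GADA over β₀ ∈ {−100, 100, 300, 600, 1200} crossed with
β₁/β₀ ∈ {−0.05, −0.15, −0.27, −0.40} (published GADA fits of this family
cluster near β₁/β₀ ≈ −0.25), keeping the best of all converged starts.
GADA parameters are box-bounded (|β₀| ≤ 3000, |β₁| ≤ 1000): the family
degenerates into its ADA limit along a flat ridge of very large
parameters, and the bound keeps estimates in the scientifically
interpretable region without affecting fit quality. Degrees of freedom use
the fixed-curve parameter count (ADA p = 1, GADA p = 2).

This is deliberately not a full nonlinear mixed-effects estimation with
AR1 residual correlation. The difference form already conditions on each
unit's own (H₁, D₁), absorbing most site/unit heterogeneity; an optional
two-stage refinement (`two_stage_unit_effects`) fits β₁ per unit and
shrinks it toward the pooled estimate with weight n_u/(n_u + 20) for
applications that want unit-level curves.

**Plot curves (SF_h-dbh).** Per plot and period start, the base model is
fitted to all live trees (all species pooled, ≥ 4 trees with measured
heights, heights ≤ 1.3 m excluded as sub-breast-height). Initialisation
linearises ln(h − 1.3) on 1/dbh; the fit is refined on the height scale
with an analytic Jacobian. A plot whose trees share one diameter is
reported unidentifiable and skipped with a warning, leaving other plots
untouched.

**Reference diameter.** Observed/predicted height pairs are binned into
5-cm diameter classes centred on a 10–60 cm grid; RE = RMSE/ȳ·100 per
class; the selected diameter is the smallest grid point with RE within 5%
of the minimum (the "knee then plateau" pattern seen in such profiles,
where error falls steeply up to ~40 cm and flattens beyond). Classes with
too few observations are excluded with a warning.

## Evaluation

SF for a plot-period is read at the period's first inventory (site quality
entering the growth period). Productivity is the periodic annual increment
PAI: survivor-only volume differences over the period, per hectare per
year — trees that died and ingrowth are excluded, since increment of a
changing tree set would confound growth with demography. Density is
Reineke's SDI at the period start. Responses are square-root transformed
before Pearson correlation and OLS (the increment and density scales are
right-skewed; the raw scale remains available via `transform="none"`).
Mixture strata are [0, 0.25], (0.25, 0.5], (0.5, 0.75], (0.75, 1] on the
conifer proportion — exact half-open intervals rather than the rounded
two-decimal labels such tables usually print, with 0.25 itself in the
first stratum. Empty or degenerate strata yield results marked
unavailable, not exceptions. Coefficients with p ≥ 0.05 are flagged
non-significant; Shapiro–Wilk (scipy) tests residual normality.

## Synthetic stands

The generator emulates a permanent-plot network in uneven-aged pine-oak
forest; its defaults are the study conditions the pipeline is validated
under:

| parameter | default | why |
|---|---|---|
| plots × area | 100 × 2500 m² | standard 50 × 50 m permanent plots |
| inventories | 2 (option 3), 5 yr apart | typical remeasurement design |
| stems/plot | Poisson(150) ≈ 600/ha | observed density range in such networks |
| dbh | Weibull(1.3, 13) truncated at 7.5 cm | right skew, callipering threshold, ~18 cm mean, rare 1-m giants |
| height curve | β₀ = 3.3, β₁ = −21 | ~11 m at 18 cm, ~19 m at 40 cm |
| site effect | Normal(0, 0.25) on β₀ | plot-level productivity spread |
| tree effect | Normal(0, 0.33) on β₀, persistent | a tree tall for its diameter stays tall |
| measurement noise | 0.6 m per inventory | hypsometer error |
| diameter growth | Gamma, mean 2 cm/period × exp(site) | site-coupled growth ⇒ PAI tracks site quality |
| conifer proportion | Beta(1, 1) per plot | spans pure broadleaf to pure conifer |

The split between a *persistent* tree-level height deviation and small
*independent* measurement noise matters: it reproduces the empirical
pattern that difference models on dominant trees fit tightly (RMSE
≈ 0.9 m here) while whole-plot height–diameter curves scatter widely
(RMSE ≈ 2.9 m, adjusted R² ≈ 0.6–0.7), and it keeps each tree on its own
curve so the ADA/GADA assumptions hold by construction. Mortality is off
by default (survivor-only PAI logic is tested with a dedicated flag).
Heights are floored at 1.35 m so measured live heights stay above breast
height; with the default curve this floor is touched only by extreme noise
draws. All draws flow from one `numpy` generator, so a fixed seed gives
bit-identical datasets.

What the generator does **not** emulate: spatial structure and
competition, climate covariates, species-specific growth or allometry
(volume coefficients are group-level), ingrowth, and measurement error in
dbh. Passing tests therefore demonstrate correctness of the estimators
under the model's own assumptions, not robustness to every feature of
real inventory data.

Volume coefficients ship at species-group level (conifer/broadleaf), with
magnitudes giving ~0.2–0.3 m³ for a typical 20 cm tree and plot totals of
~100–250 m³/ha; real applications supply their own species-specific
table (CSV keyed by species code with group/default fallback).

## Validation studies

* **Parameter recovery**: 400 remeasurement pairs per replicate drawn
  exactly from the difference families at the reported parameter scales
  (ADA β₁ = 23.02, noise 0.86 m; GADA β₀ = 534.60, β₁ = −144.44, noise
  0.83 m), initial diameters uniform on 12–55 cm (the quadratic-mean-
  diameter span of such networks) with 1.5–8 cm periodic increments. ADA
  β₁ is recovered within 5% in ≈98% of replicates; GADA both parameters
  within 10% in ≈100%.
* **Site-signal recovery**: on the default calibration, Spearman
  correlation between the generating site effect and SF_h-dbh exceeds 0.8,
  and SF_h-dbh correlates positively and significantly with √PAI.
* **Null calibration**: the decoupled configuration sets the site-effect
  spread and the growth–site coupling to zero, keys volume to diameter
  alone (a₂ = 0), and fixes the diameter design (identical truncated-
  Weibull quantile diameters on every plot, exactly 60 trees, 40 plots
  per replicate). All three are needed for an *exact* null: with
  height-dependent volume the same noise draws enter both the SF
  estimator and PAI, and with random diameter designs the SF fit's
  design-dependent finite-sample bias and PAI both inherit the shared
  diameter draws — either channel leaves a small real correlation that a
  replicated test of size would (correctly) detect. Under the decoupled
  configuration SF and PAI are exactly independent, and the SF–PAI
  correlation test rejects at ≈5% over 1000 replicates.

## Numerical choices and limitations

* Quota rounding: nearest integer of per_ha × area/10⁴ (exactly 25 on the
  study geometry). Dominant ranking is at the first inventory with ties
  broken by the other size variable then tree id, so selection is stable
  under input reordering; plots short of quota are kept and flagged.
* dbh-shrinkage tolerance 0.5 cm before a validation warning (caliper
  noise); shrinkage in growth pairs is clamped to zero (D₂ ≥ D₁ by model
  definition).
* Optimiser tolerances 1e-12 (xtol/ftol/gtol); exponents clipped at ±50
  inside residual functions to keep the optimiser finite far from the
  optimum.
* Trees without height measurements are excluded from curve fits and the
  volume sum but still count toward density and composition; the
  validation report lists them.
* SF classes of equal width partition the SF_h-dbh range; a degenerate
  (zero-width) range fits every class on the pooled union.
* Pooling across periods: evaluations pool plot-periods by default; with
  three inventories a plot contributes two periods. A per-period analysis
  is available by filtering the SF table on `inventory_index`.
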