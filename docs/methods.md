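# Methods

This note documents the model as implemented: its assumptions, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic fixtures do and do not establish.

## World and scales

The arena is a bounded (non-toroidal) 201 × 201 patch grid.  The bottom
70% of rows is the islet region; the top band splits by column into
circulation (left half) and PLN (right half); both fractions are
configurable (`RegionLayout`).  Only the relative placement of the three
compartments matters to the dynamics — agents relocate between
compartments by timers, not pathfinding — so band geometry is a
convenience, not a claim about anatomy.

Islets are disks of radius 38 patches around `n_islets = 25` centre
patches drawn uniformly (without replacement) inside the islet band;
disks may overlap and clip at band borders.  Beta cells occupy patches
drawn uniformly without replacement from the union of the disks until
exactly `n_beta_cells = 8080` are placed — about 1% of the ~900 000
beta cells of a NOD mouse pancreas, with other cell populations scaled
by the same factor.  With a 100 µm islet spanning a 38-patch radius, one
grid cell is 100/76 = 1.32 µm.  `init_apoptotic_beta` cells, chosen
uniformly among those placed, start apoptotic (the autoimmune trigger);
at full scale the analogous trigger threshold is ~510 cells on 8080.

## Hourly rules

One tick is one hour.  Within a tick the ten rule blocks fire in a fixed
order (antigen release; DC movement/phagocytosis; APC migration; PLN
binding/activation; differentiation/egress/transit; restimulation and
CTL killing; CTL proliferation; DC recruitment; beta quiescence;
ageing/death), and within each block the agent iteration order is
reshuffled with the run RNG — the NetLogo fairness idiom.  Known
experimental constants (APC lifespan 48–72 h in PLN, short contact
6–8 h, stable contact 2–24 h, differentiation cycles 4–8 h, egress
3–5 d, islet→PLN migration 15–18 d, PLN→islet transit 120 h, naive
lifespan 3–5 d, replication 24 h) are drawn per agent from their uniform
ranges at the relevant event.

Choices the sources leave open, as implemented:

- **Binding caps.**  The binding-site capacity lives on the naive cell
  (`max_naive_binding` DCs per naive cell) and a separate cap limits
  simultaneous contacts per APC (`apc_max_bind`); both are enforced at
  bind time, so a therapy that lowers the cap affects new contacts only.
- **Antigen handling.**  Antigens are short-lived point agents.  A cell
  entering apoptosis emits `antigens_per_apoptotic` antigens at once and
  thereafter with per-hour probability
  `antigens_per_apoptotic / antigen_lifespan_h`, which keeps roughly
  `antigens_per_apoptotic` antigens alive per apoptotic cell.
  Engulfment is a DC sharing a patch with an antigen; a DC becomes an
  APC after `dc_engulf_need` antigens.
- **Restimulation.**  An activated cell in the islets becomes a CTL on
  Moore-neighbourhood contact with free antigen *or* with an
  apoptotic/dead beta patch (antigen-bearing debris).  The debris route
  is required structurally: the islet→PLN→islet loop takes ≥ ~24 days,
  longer than free antigen from the initial trigger survives, so a
  free-antigen-only rule extinguishes autoimmunity before the first
  effector cells return.
- **Movement.**  The in-vivo CTL speed (10–15 µm/min) is hundreds of
  patches per hour on this grid, so CTL displacement is an effective
  per-tick step (`ctl_step_cells`, default 4) in a uniform random
  direction, reflecting at region borders.  Not-yet-restimulated
  effectors are confined to the islet disks (peri-insulitis); CTLs roam
  the whole islet band.  DCs take one Moore step per
  `dc_move_interval_h`; APCs in the PLN take one Moore step per hour;
  naive cells are stationary.
- **Killing.**  A CTL sets at most one healthy beta cell in its Moore
  neighbourhood apoptotic per tick (one rule firing per agent per hour).
- **Proliferation.**  The 15.4–23.8% proliferating fraction is a gate:
  each 120 h cycle a CTL divides with that probability, producing 4–7
  offspring with fresh lifespans.
- **Recruitment.**  The expected mass-action recruit count is generally
  non-integer; the default draws Poisson with that mean
  (nearest-integer rounding is available).  `k_r` is drawn once per run
  from `N(μ_r, σ_r)` truncated at 0.  Recruited DCs appear at apoptotic
  beta patches (homing to insulitis); without that, DCs placed uniformly
  on the ~28 000-patch islet band essentially never find the ~20
  antigen-bearing patches.
- **Quiescence and regeneration.**  Each beta cell's quiescence clock
  starts uniform on (0, 168) h; the threshold is the global factor
  `(1 − β_AP/β_init)^γ × 168 h` (β_AP clamped at β_init), shared by all
  cells.  A matured cell replicates over 24 h, placing one offspring on
  a random free islet-disk patch.  Replication starts are additionally
  limited by a **carrying capacity at β_init**: without it, unconditional
  ~weekly division doubles the beta mass of a healthy pancreas, which no
  observed trajectory does.  With it, regeneration exactly plays the
  recovery/honeymoon role: losses are refilled (faster as β_AP rises and
  the quiescence period shortens) until the CTL kill flux outruns the
  maturation flux and the healthy count collapses.
- **Book-keeping.**  Dead beta patches persist as inert obstacles
  (their patches are never re-used).  Agents die when `age_h` exceeds
  their drawn lifespan; the naive pool is topped back up to
  `n_naive_pool` every `naive_replenish_h` hours.

Onset is the first hour `healthy/β_init ≤ threshold`, with the
threshold drawn once per run uniformly in [0.10, 0.30]; crossings after
the 20-week observation window (and runs with none) are censored at 32
weeks, and censored runs enter every downstream analysis at the numeric
value 32.

## Unknown parameters and defaults

21 unknown scalar parameters (`t1dsim.config.UNKNOWN_PARAMS`) cover the
mechanisms not pinned by experiment: the five labelled P1–P5 in the
sensitivity analyses (CTL lifespan in islets; initial apoptotic count;
DC movement interval; naive binding capacity; DC recruiting rate μ_r)
plus pool sizes, antigen handling, apoptotic clearance, engulfment and
differentiation counts, the CTL step length, proliferation gate and
offspring, and the recruiting-rate spread σ_r.  Count-like ranges are
stated for the 320-beta-cell reference mini world and scale linearly
with `n_beta_cells`.

Defaults are **repo defaults** — no fitted reference table is available
to reproduce.  They were fixed once by a pilot
calibration at mini scale against the qualitative targets the sources
state — infiltrating CD8 counts low through ~week 8 and rising steeply
afterwards; onset most frequent between weeks 12 and 20 — by scanning
μ_r with everything else at mid-range literature-anchored values
(CTL lifespan 120 h, T₀ = 168 h, γ = 1).  The selected
μ_r = 3 × 10⁻⁵ h⁻¹cell⁻² gives 100% incidence with onset weeks ~12–20
(median ≈ 15) on the 320-cell mini world.  `apoptotic_clear_h = 600 h`
keeps β_AP (the glucose-load proxy) integrating kills over ~3.5 weeks,
which both sustains DC recruitment and drives the honeymoon-phase
recovery.  These values were not revisited after the acceptance checks
were written.

## Calibration, sensitivity, therapy

- **LHS** uses `scipy.stats.qmc.LatinHypercube`; per parameter the
  sorted samples occupy each of the `n_strata` equal-width strata
  exactly once (asserted in tests).  Candidates are scored by the
  unweighted (optionally SEM-weighted) sum of squared differences
  between their mean simulated weekly infiltrating-CD8 counts
  (weeks 4, 6, 8, 10, 12, 14 → ticks `w·168`; 20 replicates by default)
  and the data series; R² about the data mean is reported alongside and
  is computed on raw counts.
- **Local screen**: 9 level means at `P_d(1 ± {0, .05, .10, .15, .20})`,
  jitter SD `0.06·P_d` (draws reach ±30%, redrawn then clipped into the
  parameter's physical range), N = 20 replicates per level.  Quartiles
  use the order-statistic formulas `Q1 = x(⌈0.25N⌉)`,
  `Q3 = x(⌈0.75N⌉)`; the median uses the standard convention (the mean
  of the two central order statistics for even N).
  The one-way ANOVA F statistic is computed from the explicit SSR/SSE
  decomposition, with the p-value from `F(M−1, N_total−M)`; all-constant
  groups give F = 0, p = 1.
- **eFAST**: search curve `q = 1/2 + arcsin(sin(ωs))/π` on an n-point
  equi-spaced grid of (0, 2π); driving frequency `⌊(n−1)/(2m)⌋` (= 24
  at n = 200, m = 4), complementary frequencies at most
  `⌊ω_max/(2m)⌋` (= 3) assigned per Saltelli — evenly spaced when there
  are enough, cycled (with repeats) otherwise; the design is rotated so
  each factor drives once (5 × 200 = 1000 runs).  `S_i` is the spectral
  power at the driver's first m harmonics over the total power;
  `S_T = 1 −` (power below `ω_max/2`)/total — the standard low-frequency
  complement.
  Two caveats are inherent to the tiny reference design: with 5 factors
  and complementary band {1, 2, 3}, complementary frequencies repeat and
  the frequency-1 and frequency-3 triangle waves share harmonics, which
  biases indices by up to ~0.07 on an additive test model (the bias
  vanishes by n ≈ 1025, which the oracle tests use).  In reduced mode
  (onset cases only), the censored samples are dropped and the filtered
  series is re-indexed on its own equi-spaced grid; the broken sampling
  grid makes reduced-mode indices qualitative.
- **Therapy**: a dose is a persistent fractional reduction of the
  targeted parameter(s) from the administration week onward (T1 →
  `ctl_lifespan_h`, T2 → the recruiting-rate draw, T3 →
  `max_naive_binding`; at most two combined).  The 0.05 anchor dose of
  T1 maps 120 h → 114 h.  Existing CTLs keep the lifespan they were
  created with; only new draws see the therapy.  `P_T1D` is the onset
  fraction over replicate runs with paired seeds (`seed + i`), so doses
  are comparable under common random numbers.

## Synthetic fixtures and what green tests establish

`surrogate_cd8_series` is a synthetic stand-in for the undeposited
weekly CD8 counts: a logistic rise centred at week 8 with a slow
oscillation, per-week noise and SEM scaled by `1/√n_k` for the stated
replicate counts (7, 6, 5, 6, 7, 12), and the week-10 > week-6 ordering
enforced for every seed.  It reproduces the qualitative shape of the
real series, not its values; calibration results against it demonstrate
that the pipeline can recover generating parameters (self-consistency),
not that the repo defaults equal the originally fitted ones.  Likewise
the mini world preserves the full rule set and schema but not absolute
population sizes, so quantitative statements (index values, P_T1D
levels) transfer to full scale only in sign and ordering, not magnitude.
A fit of R² ≈ 0.98 against the real experimental series, or exact
onset-histogram percentages, cannot be reproduced here because the raw
data are not shipped; the corresponding checks are the property-based
ones above.

## Known limitations

No CD4⁺ T cells, regulatory T cells, cytokines, anti-CD3 therapy, or
glucose/insulin state variables (glucose enters only through β_AP); no
continuous-time events; no pathfinding (migration is timer + random
relocation); single-dose therapy regimens only; bounded 2D grid.  The
carrying-capacity regeneration rule and the debris-restimulation route
are this package's own structural choices where the sources are silent;
both are documented above precisely because alternative closures would
change quantitative onset timing.
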