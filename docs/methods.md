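# Methods

## Setting and data model

`groupnet` monitors the social structure of small, closed intervention
groups (roughly 5–20 members) measured with roster-based sociometric
surveys. At each measurement wave every attending member (the *ego*) is
shown the full roster and names the members (*alters*) with whom they have
a given relation outside of sessions — typically an *advice* and a
*discussion* name generator. Each nomination is a directed arc; the group's
network at a wave is the digraph of those arcs over the **full roster**.

Two consequences of the roster design are built into the data model:

* **Non-respondents stay in the network.** A member who skips the survey
  contributes no outgoing arcs but can still be nominated. The node set is
  always the full roster, so densities and related metrics for a
  partially-responding group are deliberately depressed relative to the
  respondent subgraph — that is the quantity the group leader needs, since
  the intervention is meant to connect *everyone*.
* **Self-nominations and off-roster alters are data errors**, rejected at
  parse time rather than silently dropped.

Wave and relation labels are free text matched case-insensitively.

## Diagnostics

For each (wave, relation) network the tool computes a fixed panel. Where
the monitoring protocol names a metric without a formula, the convention
used here is stated explicitly:

| metric | definition |
|---|---|
| density | arcs / n(n−1) |
| isolates | members with zero total degree |
| degree | per-member (in, out, total) |
| reciprocity | arc-based 2M/(2M+S) and dyad-based non-null M/(M+S) from the MAN dyad census (M mutual, S asymmetric, N null unordered pairs); the dyad-based value is the headline |
| components | weakly connected components among non-isolates, reported as the excess count beyond one |
| centralization | Freeman's index Σ(c_max − c_i)/max for total degree, in-degree, out-degree, closeness and betweenness |
| transitivity percent | fraction of ordered two-paths i→j→k (i ≠ k) closed by i→k |
| cohesion (compactness) | mean of 1/d(i,j) over ordered pairs, directed geodesics, unreachable pairs contribute 0 |

Centralization normalizations (the maximum is attained by a star): total
degree by 2(n−1)(n−2); in/out-degree by (n−1)²; betweenness (directed,
normalized by (n−1)(n−2) per node) by (n−1); closeness uses
Wasserman–Faust reachability-scaled outward closeness
c_i = (r_i/(n−1))·(r_i/Σd), 0 for members reaching no one, normalized by
(n−1)(n−2)/(2n−3). All indices are clamped to [0, 1]. Every metric is
cross-checked in the test suite against brute-force enumeration of dyads,
triples and Floyd–Warshall geodesics on ~1000 random digraphs.

Ratios with zero denominators (reciprocity of an empty network,
transitivity with no two-paths) are **undefined**, carried as `None`, and
the threshold engine marks them *cannot evaluate* — never a pass, never a
flag, never coerced to 0. Values are exact internally; presentation
rounding is 3 decimals, half-up.

## Thresholds and the action report

The shipped defaults are: isolates = 0; per-member total degree > 1;
non-null reciprocity > 0.50; excess components = 0; 0.15 < density < 0.50
(density helps diffusion up to a point, beyond which ties are redundant);
total-degree centralization < 0.25; transitivity > 0.30; compactness
cohesion > 0.25. Two interpretation choices were genuinely open and are
fixed here: the component rule is applied to the *excess* component count
(any value above 0 flags), and the cohesion rule flags *low* values
(< 0.25) since higher cohesion is the goal; both are plain YAML config and
can be overridden per study.

Each flagged metric emits its full numbered menu of teaching methods
(stored as templated YAML data, versioned with the package) with the
targeted participants' display names substituted: isolates are paired with
the highest-total-degree member (ties broken by roster order),
unreciprocated ordered dyads are listed ego→alter, subgroups get bridge
pairings across components, the central member (max total degree, with the
betweenness-central member noted when different) is named in the
decentralization methods. Reports close with the fixed instruction to
implement at least two recommendations per subsequent session, or — when
every rule passes — an explicit instruction not to alter teaching methods.
Rendering is fully deterministic: identical inputs give byte-identical
reports.

## Bootstrap comparison of density across waves

Arc indicators within a network are not independent — they share actors —
so a classical t-test on densities is invalid. The tool uses a
**node-resampling bootstrap**: draw n actors with replacement; the induced
replicate network inherits arc (i, j) for the actors sampled at ordered
positions (i, j); position pairs holding two copies of the same actor are
excluded from numerator and denominator (an actor's tie to its own copy is
undefined). For a two-wave comparison one actor sample is applied to
*both* waves, so the replicate statistic — the density difference —
preserves the dependence induced by shared membership; identical waves
give every replicate difference exactly 0.

**Calibration.** The raw SD of replicate densities overstates the sampling
uncertainty of a density even when dyads are independent, because
resampling hands each arc indicator a random multiplicity. Under an
iid-dyad reference model the overstatement factor is exactly

    R(n) = n(n−1) · E[ Σ_uv m_uv² / D² ] − 1,

with m_uv the multiplicity the bootstrap assigns to ordered pair (u, v)
and D the count of valid position pairs. R depends only on n (≈ 2.7 for
groups of about ten) and is evaluated once per group size by deterministic
Monte Carlo over the resampling distribution — no data involved. The test
statistic is t = observed difference / (replicate SD / √R), with a
two-sided p from the standard normal reference. Without the deflation the
test is severely conservative (empirical type-I error ≈ 0.005 at nominal
0.05); with it, Monte-Carlo calibration over 500 null pairs of independent
equal-probability digraphs (n = 11, B = 1000) puts the type-I error at
≈ 0.06–0.07, inside the acceptance band [0.03, 0.08], and a density jump
from 0.05 to 0.40 on 15 nodes is detected in >90% of runs. Both the
calibrated SE and the raw replicate SD are reported. Defaults: B = 5000,
seed mandatory.

`bootstrap_density_se` (single network) returns the raw replicate SD, the
quantity the resampling itself defines; the calibration belongs to the
test.

## Perceived Cohesion Scale

Six 7-point Likert items: items 1–3 are Sense of Belonging, items 4–6
Feelings of Morale. Scoring is respondent-level then wave-level means with
pairwise deletion of missing items. Reliability is Cronbach's alpha
(variance decomposition, ddof = 1) plus the first eigenvalue of the 6×6
item Pearson correlation matrix as a unidimensionality check — a
principal-component extraction, chosen because the handful of complete
responses a pilot group yields cannot support a richer factor model. Wave
comparison is a one-way ANOVA on total scores, df = (1, n1 + n2 − 2); for
two groups F equals the squared pooled t, verified in the tests.

## Synthetic data

The generators define the conditions under which the tool is demonstrated
and tested:

* **Census-exact networks.** `simulate_dyad_census` places exactly the
  requested numbers of mutual and asymmetric dyads, uniformly among
  eligible dyads (direction uniform among eligible egos), so density and
  reciprocity are deterministic functions of the requested census and the
  worked examples reproduce to the digit on every run. Respondent and
  alter restrictions let fixtures honour the non-respondent invariants.
* **Two-wave evolution.** Wave 2 keeps each existing arc with retention
  probability r and forms each absent arc with probability f, giving the
  analytic expectation E[d₂] = r·d₁ + f·(1 − d₁) used as a generator
  oracle in the tests.
* **One-factor PCS responses.** item = round(latent·loading + noise)
  truncated to [1, 7]. Rounding adds variance h²/12 (h = 1), which the
  reliability-recovery test folds into the analytic alpha; a high latent
  mean reproduces the ceiling effect typical of socially desirable
  responding.
* **Pilot-shaped demo.** An 11-member group, 8 respondents at week 4 and 7
  at week 12; advice census (3 mutual, 3 asymmetric) → (7, 6), i.e.
  density 0.082 → 0.182; discussion census (0, 3) → (1, 4), 0.027 → 0.055;
  four members who never engage (isolates at both waves); a pre-existing
  pair forming its own subgroup at week 4; near-ceiling PCS responses
  (latent means 6.1 then 6.6, SD ≈ 0.5–0.6, noise SD 0.6).

What the generators do **not** emulate: homophily or any attribute-driven
tie formation, actor-oriented network dynamics, attendance processes that
correlate non-response with isolation over time, and multiplex dependence
between the advice and discussion relations (they are generated
independently). Passing tests therefore certify the arithmetic, the
threshold logic and the statistical calibration of the tool — not that
real intervention groups evolve like the generator.

## Problem sizes and numerical choices

The test and acceptance runs use: ~1000 random digraphs (n ≤ 7) for
brute-force metric equivalence; 500 null simulations at B = 1000 for
bootstrap type-I calibration; 100 simulation runs for the power check;
n = 500 respondents for reliability recovery; B = 5000 for headline
bootstrap results. R(n) uses 40 000 Monte-Carlo draws (cached per n).
Ties in hub/central selection break by roster order; degenerate bootstrap
draws containing a single distinct actor are redrawn; all randomness flows
through seeded NumPy generators.

## Limitations

Thresholds are pragmatic starting points, not validated cut-offs; groups
built on pre-existing networks will likely need them shifted upward. The
normal reference for the bootstrap t is an approximation at very small n
or near-degenerate densities. The tool is descriptive and diagnostic: it
does not model behaviour diffusion, mediation, or selection, and weighted
or valued ties are out of scope.
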