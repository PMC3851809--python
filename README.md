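# groupnet

Sociometric diagnostics for small intervention groups.

Behavioral interventions — obesity prevention, smoking cessation, addiction
recovery — are often delivered to small groups in the hope that members
form supportive ties through which new behaviors spread. `groupnet` is a
monitoring tool for exactly that process: it takes roster-based nomination
surveys collected mid-intervention, computes whole-network and
individual-level diagnostics, compares them to pre-registered thresholds,
and renders a concrete, participant-named action report the group leader
can apply in the next sessions ("pair *Tammy* with the most connected
member", "make sure *Michelle* and *Natalie* do not form a separate
subgroup"). It also tests whether network density changed between two
measurement waves and scores the six-item Perceived Cohesion Scale.

It is written for intervention scientists and network analysts working
with small directed networks (a dozen members, two waves, partial
response) where every member of the roster counts — including the ones who
skipped the survey.

## The quantities at the core

For a digraph on the full roster of n members with A arcs and a MAN dyad
census of M mutual, S asymmetric and N null unordered pairs:

* **density** = A / n(n−1)
* **reciprocity (non-null, dyad-based)** = M / (M + S), with the arc-based
  variant 2M / (2M + S) alongside
* **centralization** = Σᵢ(c_max − cᵢ) / max (Freeman), for degree,
  in/out-degree, closeness and betweenness
* **transitivity percent** = closed fraction of ordered two-paths i→j→k
* **cohesion (compactness)** = mean over ordered pairs of 1/d(i, j),
  unreachable pairs contributing 0

Each metric has a pass/flag threshold (e.g. 0.15 < density < 0.50,
reciprocity > 0.50, isolates = 0) and each flag maps to a numbered menu of
teaching methods. Density change between waves is tested with a
**node-resampling bootstrap**: actors are resampled with replacement,
one sample applied jointly to both waves, and the observed difference is
divided by a calibrated bootstrap standard error (see `docs/methods.md`
for the resampling-multiplicity calibration). Undefined ratios (0/0) are
reported as *undefined* and never coerced to zero.

## Worked example

Generate the bundled pilot-shaped synthetic dataset (an 11-member group,
8 then 7 respondents across two waves) and run the full workflow:

```bash
groupnet simulate --out demo --seed 7
groupnet diagnose --roster demo/roster.csv --nominations demo/nominations.csv \
    --respondents-file demo/respondents.csv --wave week4 --relation advice \
    --out demo/report
```

The diagnosis prints the panel and the action report (abridged):

```
ACTION REPORT — group group, advice network, week4

  isolates               4  (should equal 0)  -> flag
  degree                 0  (should be > 1)  -> flag
  reciprocity          0.5  (should be > 0.5)  -> flag
  components             1  (should equal 0)  -> flag
  density            0.082  (should be > 0.15 and < 0.5)  -> flag
  centralization     0.144  (should be < 0.25)  -> pass
  transitivity           0  (should be > 0.3)  -> flag
  cohesion           0.103  (should be > 0.25)  -> flag

Recommendations:
  [isolates 1] Pair isolates with highly connected group members in small
  group activities in session: Brianna with Alma; Dawn with Alma; ...
  [components 2] Make sure small groups do not split along these lines
  ({Alma, Carmen, Olivia, Priya, Tammy}, {Michelle, Natalie}); ...
```

Read: at week 4 only 9 of 110 possible arcs exist (density 0.082, below
the 0.15 floor), four members are completely unconnected, and one
pre-existing pair sits apart from the main cluster — so the leader
receives the corresponding teaching methods with those members named.
Comparing waves:

```bash
groupnet compare --roster demo/roster.csv --nominations demo/nominations.csv \
    --respondents-file demo/respondents.csv --waves week4 week12 \
    --relation advice --seed 42 --out demo/cmp
# Density week4 = 0.082, week12 = 0.182; diff = +0.100,
# bootstrap SE = 0.0527 (B = 5000), t = 1.90, two-sided p = 0.058
```

Density more than doubled; the bootstrap t-statistic (which respects the
non-independence of arcs sharing actors) puts the change at the edge of
two-sided significance for a group this small. The same library calls are
available in Python (`groupnet.metrics_panel`, `groupnet.paired_density_test`,
`groupnet.pcs_summary`, ...).

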