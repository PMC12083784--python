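# Methods

`oatnet` infers clinical practice groupings ("clinics") from de-identified
prescription dispensation records, and quantifies how well the inferred
groupings agree with gold-standard clinic labels. It is aimed at health
services researchers working with administrative data in which prescriber
and client identifiers are available but facility identifiers are absent or
suppressed. This note describes the model, the parameters that matter, the
synthetic cohort generator used for validation, and the numerical choices
made where the design was genuinely open.

## Patient-sharing prescriber networks

For one calendar year of records, the prescriber network has a node for
every physician with at least one dispensation that year (isolates
included) and an undirected edge between two physicians who prescribed to
at least one common opioid agonist treatment (OAT) client. Edge weights
count distinct shared clients; node attribute `client_load` counts the
physician's distinct clients. Clinic labels on the records are never read
during network construction — they enter only through the gold standard.

Three tie-definition families thin the base network:

* **Absolute threshold k** — drop edges with fewer than k shared clients
  (k ∈ {1, 2, 5, 10, 20} in the default grid).
* **Relative threshold p%** — each physician ranks incident edges by weight
  (descending; equal weights break by lexicographic neighbour ID) and marks
  the top ⌈(p/100)·dᵢ⌉, where dᵢ is its edge count; an edge survives only
  if marked by *both* endpoints (p ∈ {20, 40, 60, 80}). Rounding up and
  both-endpoint retention are package choices where the verbal definition
  is ambiguous; both are deterministic and order-invariant. Note this
  operation is *not* idempotent: re-applying it sees smaller degrees and
  can prune further (e.g. weights a–b:1, b–c:7, a–c:3, c–d:2 at p = 50
  keep {a–c, b–c} on the first pass but only {b–c} on a second). It is
  applied exactly once per configuration.
* **Shared episode** — reweight edges by distinct clients having at least
  one treatment episode in which both physicians dispensed. Edgewise these
  weights never exceed the shared-client weights.

Thresholding removes edges only; nodes are preserved so that every
prescribing physician participates in pair-level evaluation.

## Treatment episodes

An episode is a maximal run of one client's dispensations of one drug
without an untreated gap reaching the drug-specific threshold: 5 days for
methadone, 6 days for buprenorphine/naloxone. Records carry no days-supply
field, so a "gap" is counted as fully untreated calendar days between
consecutive dispensation dates (date difference − 1), and the episode
breaks when that count is ≥ the threshold (a strictly-greater reading
would shift boundaries by one day; the ≥ convention is fixed and tested
with worked examples on both sides of each threshold). Episodes are built
per (client, drug) — a drug switch always starts a new episode — and the
episode end date is the last dispensation date (no carry-forward supply).
Episode construction is invariant to row order and to duplicated same-day
rows, and lowering a threshold never decreases the episode count.

## Community detection

**Modularity.** For a weighted partitioned graph, Q = Σ_c [e_c/m −
(d_c/2m)²], where e_c is community c's internal edge weight, d_c the total
weight incident to its nodes, and m the total edge weight. Q compares
observed within-group sharing against the expectation of a
degree-preserving random null; it is undefined (raises) on an edgeless
graph.

**Greedy agglomerative maximization.** Detection starts from singleton
communities and repeatedly merges the community pair with the largest
modularity gain Δ = w_uv/m − d_u·d_v/(2m²), stopping when no merge has
Δ > 0. Ties break by the lexicographically smallest label pair (labels are
the smallest member ID), so the procedure is fully deterministic. Two
communities with no connecting edge have Δ ≤ 0 whenever both have positive
degree, so communities never span disconnected components. A single edge
A–B is merged (Δ = 1 − 1/2 > 0, final Q = 0), and the greedy result never
ends below Q = 0 on any graph with an edge (property-tested).

**Recursion.** Depth 1 is the global greedy pass. Each further iteration
re-runs the greedy pass on every community's induced subgraph, judged on
internal edges only, and accepts the split only when the sub-partition has
strictly positive within-subgraph modularity. Because the trivial
one-community partition has Q = 0, this acceptance rule prevents infinite
fragmentation (a clique is never split at any depth), and depth t+1 always
refines depth t. Depths 1–4 are exposed; on the synthetic cohorts, as on
real prescriber data, depth 2 resolves clinic-sized subgroups that the
global pass merges.

**Comparators.** Louvain (resolution 1) and asynchronous weighted label
propagation run via networkx with explicit seeds; Walktrap runs via
python-igraph with the published default walk length of 4, cut at maximum
modularity. All operate on the same weighted graph and return disjoint,
exhaustive partitions with isolates as singletons.

## Gold standard and concordance

A **connection rule** converts clinic-labelled records into each
physician's "true" clinic set: `any` (every clinic with ≥ 1 record),
`majority` (the plurality clinic by distinct client count; ties break
lexicographically, and a plurality below 50% is logged — a strict >50%
rule could leave physicians clinic-less), or `percent:t` (every clinic
holding ≥ t% of the physician's distinct yearly clients, t ∈ {15, 30,
45}). The ≥ reading reconciles the two verbal forms of the rule ("more
than" vs "at least"); a `strict` flag switches to >.

Every unordered pair of the year's network physicians is then classified
twice — same clinic or not (gold), same community or not (detected) —
yielding a 2×2 table (a, b, c, d) with n = C(P, 2). From it:

* overall agreement (a+d)/n, positive agreement 2a/(2a+b+c), negative
  agreement 2d/(2d+b+c);
* Gwet's AC1 = (p_a − p_e)/(1 − p_e) with p_a = (a+d)/n and
  p_e = 2π(1−π), π = ((a+b)/n + (a+c)/n)/2 — chosen over Cohen's kappa
  because same-clinic pairs are rare and kappa degenerates under such
  imbalanced marginals;
* sensitivity a/(a+c), specificity d/(b+d), PPV a/(a+b), NPV d/(c+d).

Zero-denominator ratios are reported as NaN and flagged, never as 0.
Wilson score intervals cover the four validity proportions; AC1 gets a
delta-method (linearized) variance treating pairs as independent ratings,
with a pair-resampling bootstrap alternative (the two agree to well within
0.02 half-width on moderate tables). Pairs sharing a physician are not
independent; the CIs ignore this dependence by design, and should be read
as descriptive.

**Community matching.** Each detected community is matched to the clinic
maximizing member overlap (ties → clinic with more attached network
physicians, then lexicographic ID). Recall divides the overlap by the
number of *network* physicians attached to the matched clinic (a clinic's
members who did not prescribe that year are invisible by construction);
purity divides by community size; F is their harmonic mean. Medians and
quartiles across communities use numpy's linear-interpolation quantile
convention, as do the per-group structure summaries (physicians, distinct
clients, client loads, within-group tie weight).

**Best-configuration selection** prioritizes sensitivity and PPV while
expecting specificity and NPV to be high: among grid rows with specificity
and NPV ≥ 0.9, maximize min(sensitivity, PPV); if no row qualifies the
constraint is dropped; ties resolve to configuration order.

## Synthetic cohort generator

The generator plants a known clinic structure and emits dispensation
records from it, so every downstream stage can be validated exactly. What
it emulates, with defaults:

* **Clinics and physicians.** 105 clinics; physicians per clinic drawn
  from a small discrete distribution with median 2 (IQR 1–2, mean ≈ 1.9);
  30% of physicians staff a second clinic. Jointly these land the distinct
  physician count near 144. A clinic-size median of 3 — the
  administrative-clinic figure — cannot coexist with ~144 physicians at
  105 clinics unless physicians average ≈ 2.2 clinic memberships, which
  would contradict a 30% dual-clinic share; the package keeps the totals
  (which the scale test asserts within ±20%) and the community-level
  median of 2.
* **Clients.** Yearly home-panel size per physician is lognormal with
  median 93; clients persist across years with probability 0.85 and the
  panel is topped up with new clients, so the eight-year default cohort
  accumulates ≈ 33k distinct clients. Each client has a home physician
  and clinic (dual-clinic physicians send 30% of their panel to the
  secondary clinic, so the 15/30/45% connection rules discriminate); with
  probability 0.4 a within-clinic colleague co-prescribes, and with
  probability 0.05 a physician at another clinic does.
* **Dispensations.** Per active client-year, a treatment span starts
  uniformly in the year (early January for continuing clients) and emits
  dispensations with day differences drawn from a mixture of daily pickup,
  weekly carries and occasional long interruptions (1/2/3/6/7/8/14/21
  days), so both episode-breaking thresholds are exercised. 70% of scripts
  come from the home physician; the first few dispensations are assigned
  home-then-co-prescribers deterministically so that every planted
  co-prescription is realized in the records whenever the client has
  enough dispensations — planted structure therefore appears in the
  emitted records with certainty, not merely with high probability.
* **Drug.** Fixed per client: methadone with probability 0.7.

All sampling flows through one seeded generator in a fixed order, so equal
configurations reproduce byte-identical cohorts; structure and clients are
drawn before any dates, letting `generate_truth` return the exact ground
truth of `generate_cohort` without emitting records.

What the generator does **not** model: demographic covariates, dosing,
retention outcomes, geography, clinic opening/closing over time, seasonal
prescribing, or physicians leaving practice. Client sharing is pairwise
and independent across clients, so real-world correlated coverage patterns
(a locum covering a whole panel for a month) are absent. Passing tests
therefore demonstrate correctness of the pipeline and the direction of its
trade-offs under planted structure — not the numeric concordance levels to
expect on any particular real organization's records.

## Problem sizes

Validation runs at three scales, chosen to keep the full suite fast while
still exercising organization-scale inputs: enumerable graphs (≤ 7 nodes,
exhaustive partition oracles), small planted cohorts (4–20 clinics, tens
of physicians) for exact-recovery and invariance checks, and
organization-scale single-year cohorts (~105 clinics, ~150 physicians,
~17k clients, ~0.7M dispensations) for the threshold-sensitivity trend and
the acceptance script. The eight-year default cohort is exercised
structurally through truth-only generation.

## Known limitations

* The greedy merge is a local optimizer; it attains the enumerated optimum
  on all tested fixtures but carries no global guarantee on arbitrary
  graphs.
* A physician is assigned to exactly one community, so a clinic whose
  members split their caseloads across sites is structurally
  under-recovered (the fragmentation test pins the canonical case: two
  same-clinic physicians sharing no clients are returned as two
  singletons, one false-negative pair).
* CIs treat pairs as independent; with P physicians there are only P
  independent units, so intervals are anti-conservative.
* The relative threshold's rounding (⌈·⌉) and both-endpoint rule are one
  reasonable reading of an under-specified verbal definition; both are
  config-exposed in code rather than hidden.
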