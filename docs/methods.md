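# Methods

## Navigation model

An interface is modeled as a rooted tree. The root (depth 0) is the
highest-level screen; each edge descends one menu level. Nodes are
`screen`s, `menu_item`s, or leaf `data_element`s; targets (the nodes a
given clinical task needs) may be screens or data elements. Menu length at
a node defaults to its child count; `menu_length_override` exists because
real screens display parallel items that are not modeled as children (and,
conversely, ever-visible navigation rails that impose no search cost can
be overridden down to 1).

Two serialization dialects are supported. The path-per-row CSV
(`level_1..level_k` plus `kind, is_target, is_scrolling,
menu_length_override`, booleans as 0/1) merges identical label prefixes
into shared ancestors with sibling order following first appearance;
trailing blank cells denote shorter paths, internal blanks are rejected as
ambiguous. Serialization emits one row per node so interior annotations
survive the round trip; because the dialect merges by label, CSV round
trips require unique sibling labels (duplicate sibling labels are legal in
memory and in the JSON dialect, where ids are explicit). A scrolling
screen's hidden content is modeled as a node flag, not as an extra
pseudo-level.

## The measured pathway

`trace_pathway` visits targets in tree document order (an explicit order
may be supplied) starting at the root. Between consecutive targets the
route ascends to the root — the default `reasonable_maximum` policy,
giving a reproducible upper bound for interfaces with many alternate
routes — or, under `shortest`, only to the lowest common ancestor, for
tasks where the lower levels alone are involved. Ties never arise: routes
on a tree are unique once the ascent height is fixed, and target order is
deterministic.

Step semantics, chosen so the tally reproduces how navigation actions are
counted on a sunburst map (ring crossing = screen change, same-ring move =
click/scroll):

* entering a screen or menu item, in either direction, is one
  `visit_screen_transition`;
* selecting a data element on its parent screen is one `click_same_level`
  (the screen does not change);
* arriving at a target adds `reach_element`;
* every entry of a screen flagged `is_scrolling_screen` adds two `scroll`
  steps — an average over the variability of such screens — including the
  root at the start and re-entries on later legs (revisiting a scrolling
  screen costs scrolling again);
* leaving a data element emits nothing: the element sits on the parent
  screen the user is already viewing.

## Tallying and the index

`tally_actions` buckets every step by the depth of the node acted on. A
transition counts toward both `IS` and `C` at the entered node's level
(every screen change is also a click; a target screen's entry is still a
real screen change and is counted, with `E` separately recording the
access); an element selection counts toward `C` only; `ML` accumulates the
departing node's menu length once per descent through it, including
revisits on later legs. With the constant-1 multiplier this yields the
closed form `1 + (d-1) + d + d` for a single element at depth `d` on a
chain with unit menus.

`MultiplierPolicy` resolves the level weighting: `depth_weighted`
(default) weights an action at level `l` by `l`, so a click at level 0
carries no weight and deep navigation dominates; `constant` applies a flat
positive value. The published form of the index leaves the numeric
multiplier unspecified, so the policy is explicit and configurable rather
than inferred. A useful structural fact: on pathways whose targets are all
screens, the transition/click coupling makes the weighted `IS` and `C`
terms identical under any policy; for data-element targets they differ by
the weighted element clicks.

`compare_systems` reports per-term deltas and the ratio of totals (absent
when either total is zero).

## Worked-example constructions

The bundled example trees hang chains of nested target screens off a root
whose menu length is overridden to 1 (an always-visible section rail).
Under `shortest` routing and depth weighting, a chain of length `L`
contributes `L(L+1)/2` on the way down plus `L(L-1)/2` climbing back
(omitted for the final chain) to both the IS and C terms, and one menu
unit per descent to ML. Chain lengths [9, 5, 3, 2] plus seventeen single
sections (with one 4-item picker override) give E=36, IS=C=136, ML=39,
DFI=347; lengths [5, 3, 2] plus nine singles give E=19, IS=C=47, ML=19,
DFI=132 — a ratio of 0.380. These totals are computed by the measurement
chain at run time, never stored.

## Sessions, instances, ACT and PPI

Sessions hold sorted, non-overlapping segments with times in seconds from
session start. Total EHR time is the sum of segment durations — idle gaps
are not EHR time — with a span-based alternative (`time_basis="span"`). A
task instance is a maximal run of consecutive same-label segments; exactly
abutting segments merge, and any gap or interleaved other-task segment
splits (a `max_gap_s` tolerance is available for jittery logs; the strict
default matches the visible one-band-per-instance reading of a time
belt).

ACT is the mean instance duration. PPI is task total time divided by
(instance count × total EHR time). The textual form of the PPI formula
can be parenthesized two ways; the division reading is used because it is
the one under which longer sessions do not inflate the measure and lower
values mean more fragmentation — both defining properties of the measure.
It follows that PPI = ACT / total EHR time, PPI = 1 exactly when a single
task fills the session in one instance, PPI strictly decreases in instance
count at fixed totals, and PPI is invariant under uniform time rescaling.

## Visualizations

Sunburst: the root is the center disc (its segment carries ring index −1);
a node at depth `d ≥ 1` is an annular sector on ring `d − 1` inside its
parent's angular interval. Extents are exact rationals
(`fractions.Fraction` degrees), so children partition their parent exactly
under both weightings — `equal_split` (equal shares) and `leaf_weighted`
(proportional to leaf-descendant counts, the default, matching how
spreadsheet sunbursts allocate angle). Drill-down is a re-layout on a
subtree. Targets shade dark, traced pathways green.

Time belt: one row per session on a shared absolute time scale (units per
second), one rectangle per segment, gaps left unfilled to expose idle
time. Colors come from a fixed 20-entry qualitative palette assigned to
sorted labels, cycling beyond 20, so the label→color map is stable across
runs and shared across rows. Rendering is a dependency-free SVG string
builder with fixed-precision coordinates; identical inputs produce
byte-identical documents.

## Synthetic data

`generate_nav_tree` builds a complete tree (configurable depth and
per-level branching) with data elements at the leaves, targets sampled
uniformly among leaves (the bottom of menu paths, where clinical content
lives), and scroll flags drawn per screen with probability `p_scroll`.
`generate_session` emits fixed-length abutting segments whose labels
follow a Markov switching process: with probability `p_switch` per step
the task switches to a uniformly random other label. Defaults (40 steps of
5 s ≈ a 3-minute review; four task labels; `p_switch` 0.2) describe a
plausible short case review. Each call uses its own
`numpy.random.default_rng(seed)`.

What the generator does *not* emulate: dwell-time heterogeneity (real
segment durations are long-tailed, not fixed-length), structured task
ordering (real workflows are not label-symmetric Markov chains), idle
gaps, and navigation trees with irregular branching or cross-links.
Passing tests therefore demonstrate that the measures respond correctly
to controlled fragmentation — monotone decreases of mean ACT/PPI in
`p_switch`, monotone DFI growth in depth and target count — not that they
are calibrated against clinical recordings.

## Numerical and degenerate-input choices

* All DFI arithmetic is exact (integer counts, float weights; sums are
  exact for integer-valued policies).
* Empty pathways tally to zero everywhere; a zero tally scores DFI 0; a
  zero-total breakdown yields no comparison ratio.
* An empty session log parses to an empty list; zero-total sessions make
  PPI undefined (error) rather than infinite.
* Pogo-sticking windows are maximal alternating runs (length ≥ 3) over
  screen ids when every segment has one, else task labels; a run's last
  segment may open the next run with a different partner.
* Problem sizes in the test suite (trees ≤ 30 nodes for exhaustive route
  oracles, 50 seeds × 4 switch probabilities for the recovery experiment)
  were chosen to make the exhaustive checks complete in seconds while
  keeping binomial standard errors small.

## Known limitations

* The DFI multiplier semantics are declared, not empirically derived; two
  analysts using different policies must compare totals only within one
  policy.
* Pathway tracing assumes a strict tree; real EHRs have cross-links,
  search boxes and user-specific shortcuts, so the DFI is an upper-bound
  style measure of the menu-structural route, not predicted user effort.
* Time belts use absolute shared time scales across rows; no per-row
  normalization is offered.
* Session times must be pre-converted to relative seconds; parsing
  proprietary screen-recording exports is out of scope.
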