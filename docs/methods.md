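# Methods

## The argument model

An argument is a rooted tree over six node kinds. Goals state claims;
strategies decompose a claim into sub-claims; evidence terminates a branch;
context, assumption and justification nodes scope a goal or strategy.
Two edge kinds mirror the notation's connectors: `supported_by` carries the
support hierarchy, `in_context_of` attaches scoping nodes. The model is a
strict tree — every non-root node has exactly one parent — because collapse
semantics, hierarchical numbering and the layered drawing all assume a
unique path to the root. Multi-parent (module/away-goal) GSN constructs are
out of scope.

Well-formedness is defined by a fixed rule set with stable issue codes:
single goal root (`NO_ROOT`, `ROOT_NOT_GOAL`, `MULTIPLE_ROOTS`), acyclicity
(`CYCLE`), reachability (`UNREACHABLE`), edge typing (`BAD_EDGE_TYPING`),
evidence as leaves (`EVIDENCE_NOT_LEAF`), undeveloped markers only on goals
without supporting children (`UNDEVELOPED_NOT_GOAL`,
`UNDEVELOPED_WITH_CHILDREN`), and identity hygiene (`DANGLING_EDGE`,
`DUPLICATE_UID`). `validate` returns issues rather than raising so that a
decoded document can be diagnosed in full; the construction API enforces the
same rules eagerly, so any graph grown through it validates clean.

Overlapping diagnoses are resolved toward the most specific code: an edge
leaving an evidence node reports only `EVIDENCE_NOT_LEAF` (not also a typing
error); a parentless extra goal reports `MULTIPLE_ROOTS` rather than
`UNREACHABLE`; nodes inside a cycle report `CYCLE` only; with a missing
root, reachability is not assessed at all. This keeps one injected defect
mapping to one code, which the mutation tests rely on.

Design choices where the notation itself is silent:

- **Evidence under strategies.** The notation anchors evidence to claims.
  `goal → evidence` is clean; `strategy → evidence` is representable but
  reported as a `BAD_EDGE_TYPING` *warning*, because arguments in the wild
  sometimes shortcut the intermediate claim and a hard error would make such
  documents unloadable.
- **Undeveloped means unsupported.** A goal may carry context-family
  attachments and still be undeveloped; it is *supporting* children that are
  forbidden, since the open diamond asserts "nothing argues for this yet".
- **Assumptions/justifications may attach to strategies as well as goals**;
  the typing rules treat all three scoping kinds uniformly.
- **Insertion order is canonical child order** for labelling, serialization
  and layout; determinism everywhere follows from it.
- **Collapse** is a rendering flag on nodes with at least one supporting
  child; it persists in saved documents so a curated view survives a
  save/load cycle.

Labels: the root claim is `1`; the k-th `supported_by` child of a node
labelled `L` is `L.k`; context-family nodes get per-parent, per-kind
suffixes (`L-C1`, `L-A1`, `L-J1`) rather than dotted numbers, so claim and
strategy numbering matches how reviewers cite them (`1.1.3.1`) without
inventing dotted identities for scoping nodes.

Metrics: a *terminal goal* has no goal or strategy among its supporting
children; it is *substantiated* when at least one evidence child exists;
coverage is the substantiated fraction (0 when there are no terminal goals).
Support depth counts `supported_by` steps from the root (root = 1); scoping
nodes sit at their anchor's depth.

## File format

Documents are JSON with `format: "gsn-argument"`, `version: 1`. The
canonical form — nodes sorted by uid, edges by (source, target, kind),
sorted keys, two-space indent, trailing newline — makes saving a pure
function of the graph, so equality of graphs is equality of bytes. Because
sorting would destroy sibling order, every edge carries an `ordinal`: the
child's position among its parent's children at insertion time; loading
re-sorts per parent by ordinal. Hard load failures (wrong tag or version,
unknown kind, duplicated uid, edge to a missing node) raise; everything else
is returned as validation issues alongside the graph. No interoperability
with other argumentation tools' native formats is claimed.

## Layout and rendering

Layout is a bottom-up subtree-width scheme in the Reingold–Tilford family,
sufficient for strict trees: a node's slot is `max(cluster width, sum of
child slots + gaps)`, where the cluster is the node's box plus its scoping
attachments placed to its right in the same vertical band; clusters are
centred in their slots, support depth defines the band, band heights are the
per-band maxima, and a fixed vertical gap separates bands. This yields the
two geometric invariants the property tests check on random trees:
no two boxes overlap, and every parent's bottom edge sits strictly above
each supported child's top edge. Collapsed subtrees are simply omitted;
remaining siblings keep their relative order.

Box sizes come from a fixed character budget per line (26 columns, wrapped)
with minimum dimensions; fonts are not embedded, so the text metrics are
nominal rather than typographically exact. Evidence circles get a square
envelope scaled to cover the wrapped text's diagonal. SVG output is built as
an XML tree and serialized deterministically; status markers carry
`class="marker-undeveloped"` / `"marker-collapsed"` so consumers (and
tests) can address them. Evidence nodes with hyperlinks are wrapped in SVG
anchors. PNG output draws the same geometry with Pillow at
`ceil(canvas × scale)` pixels; it is pixel-deterministic on a platform but,
unlike SVG and JSON, carries no cross-platform bit-exactness promise
(default-font rasterization differs between Pillow builds). Colours are
monochrome by design; the notation's semantics live in shape, arrowhead and
marker fill, not colour.

## Track statistics

A track is a uniformly sampled sequence of 2-D positions in µm. The two
behaviour responses are velocity = total path length / total duration
(µm/min) and displacement = straight-line start-to-end distance (µm).
Velocity is computed as path/duration; under uniform sampling this equals
the mean instantaneous speed. Proximity to a forming aggregation is
assessed at the track's *first* position — group membership then stays
fixed over the observation window — with near defined strictly as
`distance < threshold` (default 50 µm), so a cell starting exactly at the
threshold is far.

The Mann–Whitney statistic is reported for the first (near) sample with
ties counted one half: U₁ = #{x > y} + ½·#{x = y}, so U₁ + U₂ = n₁n₂. For
combined samples of at most 16 the two-sided p-value enumerates all
C(n₁+n₂, n₁) group assignments of the pooled values — exact also under
ties, since the permutation distribution of U is symmetric about n₁n₂/2 —
counting assignments at least as far from the mean as observed (with a
1e-9 guard against floating-point ranking noise). Larger samples use the
normal approximation with tie-corrected variance
σ² = n₁n₂/12 · [(N+1) − Σ(t³−t)/(N(N−1))] and a 0.5 continuity correction
toward the mean; when all pooled values are identical (σ² = 0) the p-value
is 1. The cut-off at 16 keeps exact enumeration below ~13k assignments.
P-values are two-sided throughout — "no statistical difference" is a
two-sided claim — and no multiple-testing correction is applied across the
velocity and displacement responses; each evidence node records a single
test. Non-significance is worded as "no significant difference", never as
equivalence: a rank test cannot establish that two behaviours match (TOST
equivalence testing is a non-goal).

## The synthetic track generator

`synthesize_tracks` produces independent 2-D random walks: each step adds a
fixed drift plus per-axis Gaussian noise of standard deviation `step_sd`
µm. Defaults emulate the tracking protocol of the motivating *ex vivo*
cultures — one observation per minute for 60 minutes (tracking over one
hour), starts uniform over a 200 × 200 µm region, step noise 2 µm giving
baseline speeds of a few µm/min, the scale reported for haematopoietic
cells in the developing gut. The generator reproduces the *statistical
surface* of tracking data (uniform sampling, per-track responses, group
separation one can dial via drift), not its biology: no cell–cell
interaction, no confinement, no aggregation dynamics, no measurement
dropout. Tests passing on generated tracks therefore establish that the
statistical machinery is correct, not that any simulator is fit for
purpose.

Analytic anchors used in tests: with drift (d, 0) and zero noise, velocity
is exactly d/interval and displacement equals path length; with zero drift,
mean displacement grows like the square root of the step count, well below
the ballistic bound.

## The case-study fixture

The packaged document encodes the fitness-for-purpose argument for an
agent-based simulator of Peyer's Patch development: a top claim of adequate
biological representation, argued over the scientific context, abstraction
adequacy and experimental adequacy; four sub-claims covering the underlying
biological data (argued over four strategies: LTin/LTi cell properties, LTo
cell properties, the intestine environment, aggregation characteristics),
the abstractions (chemokine pathway reduced to one chemokine/receptor,
adhesion factors, the environment representation, cell signalling), 12-hour
cell behaviour (near and far claims each substantiated by Mann–Whitney
evidence carrying hyperlinks), and 72-hour aggregation formation (three
strategies: aggregation counts, replication of published physiological
conditions, spatial characteristics). Claim 1.1.1.4.2 — quantitative
similarity of simulated and in vivo aggregations — is the argument's one
undeveloped claim: no quantitative comparison data existed, and encoding
exactly one gap keeps the fixture faithful to the argument's stated
structure rather than inventing others. Statements whose exact wording is
not documented are paraphrased; the document's `meta.provenance` says so.
The builder function and the shipped JSON are byte-identical, which the
test suite enforces.

## Problem sizes and determinism

Batch property checks run at sizes that complete in seconds on one core:
1000 random trees for validation closure and serialization round-trips, 500
for layout geometry, 2000 sample pairs (n ≤ 8) for the U-statistic oracle,
300 trees per batch in the reproduction script. All randomness flows
through `numpy.random.default_rng` seeded explicitly (hypothesis suites are
derandomized), so every reported number is reproducible from the seed.

## Known limitations

- Single-parent trees only; no GSN modules, away goals, or pattern
  instantiation.
- Layout slot-centres parents over the span of their children's slots, not
  their exact visual span; very unbalanced subtrees can leave more white
  space than a full Reingold–Tilford contour merge would.
- The CLI's `--force` only bypasses the render gate; the rendering
  functions themselves still require a structurally usable graph, so
  documents with hard structural errors cannot be drawn.
- Tracks are 2-D with a static aggregation centre; per-frame dynamic
  proximity reclassification and 3-D tracking are out of scope.
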