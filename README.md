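# gsnfit

Fitness-for-purpose argumentation for biological simulations.

A computational model of a biological system is only useful if its users can
see *why* it should be trusted for the question it was built to answer.
`gsnfit` brings the assurance-case practice of safety-critical engineering to
simulation science: a fitness-for-purpose argument is a rooted tree, in a
dialect of goal structuring notation (GSN), whose nodes are **goals** (claims
to substantiate, drawn as rectangles), **strategies** (reasoning steps that
decompose a claim, parallelograms), **evidence** (statistical results or
publications, circles), and scoping **context / assumption / justification**
nodes. Support connections carry solid arrowheads, context connections open
ones. A claim that cannot yet be substantiated — a gap in the biological
knowledge — is marked *undeveloped* and drawn with an open diamond, making
missing laboratory data an explicit, reviewable part of the model's story.

The package targets simulation developers and the reviewers of their models.
It provides:

- a typed argument-graph model with a construction API that can only produce
  well-formed arguments, plus a validator with fixed rule codes for arbitrary
  decoded documents;
- hierarchical claim numbering (`1`, `1.1`, `1.1.3.1`, context suffixes
  `1-C1`), completeness metrics and evidence-coverage reporting;
- a canonical versioned JSON file format (byte-stable round trips), Graphviz
  DOT export, and deterministic layered SVG/PNG diagram rendering with the
  GSN glyph conventions;
- a statistical-evidence harness for cell-track data: per-track **velocity**
  (path length / duration, µm/min) and **displacement** (start-to-end
  distance, µm), a near/far split at 50 µm around a forming cell
  aggregation, and a two-sided Mann–Whitney *U* test
  (U₁ = #{x > y} + ½·#{x = y}; exact permutation *p* for n₁+n₂ ≤ 16,
  tie- and continuity-corrected normal approximation above) whose result is
  attached to a claim as an evidence node;
- a seeded 2-D random-walk track generator and a track CSV dialect
  (`track_id,t_min,x_um,y_um[,cell_type]`);
- a complete worked case study: the fitness-for-purpose argument for an
  agent-based simulator of Peyer's Patch (gut lymphoid organ) development,
  shipped as a packaged JSON document and a builder function.

## Worked example

```python
from gsnfit import (build_case_study, metrics, undeveloped_claims,
                    synthesize_tracks, compare_groups, attach_evidence,
                    assign_labels, validate)

g = build_case_study()          # the Peyer's Patch argument
m = metrics(g)
print(m.n_terminal_goals, m.n_substantiated_terminal_goals, round(m.coverage, 3))
# 14 10 0.714   — 10 of 14 front-line claims carry evidence

print([g.nodes[u].label for u in undeveloped_claims(g)])
# ['1.1.1.4.2']  — the one stated gap: no quantitative in vivo aggregation data

near = synthesize_tracks(10, start_region=((0, 0), (30, 30)), step_sd=0.5,
                         seed=1, id_prefix="near")
far = synthesize_tracks(10, start_region=((150, 150), (220, 220)),
                        drift=(2.0, 0.0), step_sd=0.5, seed=2, id_prefix="far")
r = compare_groups(near + far, centre=(15, 15), threshold_um=50,
                   response="velocity")
print(r.u_statistic, r.n1, r.n2, round(r.p_two_sided, 6), r.method)
# 0.0 10 10 0.000183 normal_approximation
#   U = 0: every far (drifting) cell out-ran every near cell, so the test
#   rejects "no difference in velocity between the groups".

goal = assign_labels(g) and g.node_by_label("1.1.3.1.1")
attach_evidence(g, goal.uid, r, "Near/far comparison of per-track velocity")
print(validate(g))   # []  — the argument is still well-formed
```

Longer narrative walk-throughs live in `examples/`
(`build_and_render_argument.py`, `case_study_tour.py`,
`evidence_from_tracks.py`).

## Command line

```sh
gsnfit example argument.json            # write the packaged case study
gsnfit validate argument.json           # rule report; exit 1 on errors
gsnfit stats argument.json              # metrics + undeveloped claims
gsnfit render argument.json out.svg     # also --format png|dot, --scale
gsnfit evidence argument.json tracks.csv --goal-label 1.1.3.1.1 \
    --centre-x 15 --centre-y 15 --response velocity --out updated.json
```

Exit codes: 0 success, 1 validation errors, 2 bad input/format, 3 internal
error.

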