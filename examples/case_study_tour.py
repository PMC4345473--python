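"""Walk through the packaged Peyer's Patch case-study argument.

Loads the shipped argument for a lymphoid-tissue development simulator,
prints its completeness metrics, its structural facts, and the claims the
original developers marked as gaps in the biological knowledge.
"""

from gsnfit import (
    build_case_study,
    case_study_facts,
    format_metrics,
    metrics,
    undeveloped_claims,
    validate,
)

g = build_case_study()
print("validation issues:", validate(g))  # []

m = metrics(g)
print(format_metrics(m))
print()

print("structural facts:")
for description, check in case_study_facts():
    print(f"  [{'ok' if check(g) else 'FAIL'}] {description}")
print()

print("undeveloped claims (open-diamond gaps awaiting laboratory data):")
for uid in undeveloped_claims(g):
    node = g.nodes[uid]
    print(f"  {node.label}: {node.statement}")
# 1.1.1.4.2 is the argument's one stated gap: no quantitative in vivo
# aggregation data existed to compare the simulated aggregations against.
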