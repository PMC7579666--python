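"""Which perils are the sinks and catalysts of cascading disasters?

Computes in/out-degree, harmonic closeness and betweenness on the support
graph of the empirical adjacency and prints the top-3 per measure.
"""

from cascadyn import (
    build_empirical_adjacency,
    centrality_report,
    load_taxonomy,
    parse_case_file,
)

registry = load_taxonomy()
a = build_empirical_adjacency(parse_case_file(registry=registry), registry)
report = centrality_report(a, k=3)

print(report.table.round(3).to_string())
print()
for measure, top in report.top_k.items():
    print(f"top {measure}: {top}")
print("""
High in-degree marks the main triggered events (sinks), high out-degree and
closeness the main triggers (sources), and high betweenness the catalysts
sitting on cascade pathways: network failure (NF) and business interruption
(BI) lead both in-degree and betweenness.""")
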