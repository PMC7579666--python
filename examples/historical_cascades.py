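"""The historical experiment: 29 catastrophes → empirical A → interaction M.

Encodes the packaged case transcription into the 19×19 binary adjacency
(p = 0.1 per observed pair), computes the interaction matrix truncated at
three steps, and summarizes the emergent and amplified interactions.
"""

from cascadyn import (
    amplified_pairs,
    build_empirical_adjacency,
    case_statistics,
    emergent_pairs,
    interaction_matrix_truncated,
    load_taxonomy,
    parse_case_file,
)

registry = load_taxonomy()
cases = parse_case_file(registry=registry)
stats = case_statistics(cases)
print(f"{stats['n_cases']} cases, {stats['n_distinct_pairs']} distinct directed pairs")

a = build_empirical_adjacency(cases, registry, p=0.1)
m = interaction_matrix_truncated(a, tau_max=3)

emergent = emergent_pairs(a, m)
amplified = amplified_pairs(m, p=0.1)
print(f"emergent interactions (in M, absent from A): {len(emergent)}")
print(f"amplified interactions (m_ij > 0.1):         {len(amplified)}")

di_sources = sorted(src for src, tgt in emergent | a.support() if tgt == "DI")
print(f"perils that can cascade into disease within 3 steps: {di_sources}")

amp_targets = sorted({tgt for _, tgt in amplified})
print(f"amplified target perils: {amp_targets}")
print("""
Emergent cells show the space of possibilities expanding into the
technological and socioeconomic perils for any trigger; amplification
concentrates on network failure (NF) and business interruption (BI), the
bridge events between the natural and man-made systems.""")
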