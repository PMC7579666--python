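# Packaged suite of 24 idealized 10x10 one-to-one interaction topologies,
# ordered by increasing pattern complexity.  Each entry names a generator
# family from cascadyn.topology.GENERATORS; 'gaps' removes edges after
# generation, 'extra_edges' adds them.
- name: case01_diagonal
  generator: diagonal
- name: case02_one_trigger_row
  generator: single_row
  params: {row: 0}
- name: case03_one_trigger_row_feedback
  generator: single_row
  params: {row: 0, self_loop: true}
- name: case04_one_triggered_column
  generator: single_column
  params: {column: 9}
- name: case05_one_triggered_column_feedback
  generator: single_column
  params: {column: 9, self_loop: true}
- name: case06_two_trigger_rows
  generator: rows
  params: {rows: [0, 5]}
- name: case07_two_trigger_rows_gaps
  generator: rows
  params: {rows: [0, 5], gaps: [[0, 3], [5, 7]]}
- name: case08_two_triggered_columns
  generator: columns
  params: {columns: [4, 9]}
- name: case09_two_triggered_columns_gaps
  generator: columns
  params: {columns: [4, 9], gaps: [[2, 4], [6, 9]]}
- name: case10_chain
  generator: chain
- name: case11_chain_broken
  generator: chain
  params: {gaps: [[4, 5]]}
- name: case12_cycle
  generator: chain
  params: {wrap: true}
- name: case13_chain_self_loops
  generator: chain
  params: {self_loops: true}
- name: case14_converging_paths
  generator: explicit
  params: {edges: [[0, 1], [1, 3], [0, 2], [2, 3], [3, 5], [5, 7]]}
- name: case15_converging_paths_feedback
  generator: explicit
  params: {edges: [[0, 1], [1, 3], [0, 2], [2, 3], [3, 5], [5, 7], [1, 1]]}
- name: case16_block
  generator: block
  params: {rows: [0, 5], cols: [0, 5]}
- name: case17_block_gaps
  generator: block
  params: {rows: [0, 5], cols: [0, 5], gaps: [[1, 2], [2, 3], [3, 1]]}
- name: case18_two_blocks
  generator: blocks
  params:
    blocks:
      - {rows: [0, 5], cols: [0, 5]}
      - {rows: [5, 10], cols: [5, 10]}
- name: case19_two_blocks_bridged
  generator: blocks
  params:
    blocks:
      - {rows: [0, 5], cols: [0, 5]}
      - {rows: [5, 10], cols: [5, 10]}
    extra_edges: [[4, 5]]
- name: case20_bipartite
  generator: block
  params: {rows: [0, 5], cols: [5, 10]}
- name: case21a_random
  generator: random
  seed: 20201007
  params: {density: 0.2}
- name: case21b_random
  generator: random
  seed: 19740522
  params: {density: 0.2}
- name: case22_full_no_diagonal_gaps
  generator: full
  params: {include_diagonal: false, gaps: [[0, 9], [9, 0]]}
- name: case23_full
  generator: full
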