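"""Round counts and theoretical per-step costs of the two parallel schedules.

For binary trees of growing depth, prints the logical round counts of the
branch-scheduled back-substitution (= tree depth) and of pointer jumping
(= ceil(log2(m)), m the maximal root-leaf distance in segments), together
with the closed-form per-step costs: the branch schedule pays the largest
branch at each level plus junction work, the segment schedule pays
(N / W) log2(m) for W = 32 SIMD lanes.
"""

import neurosim as ns

print(f"{'depth':>5} {'N':>5} {'m':>3} {'branch rounds':>13} "
      f"{'stone rounds':>12} {'branch cost':>11} {'stone cost':>10}")
for depth in range(1, 11):
    m = ns.make_binary_tree(depth)
    rep_b = ns.schedule_report(m, "branch")
    rep_s = ns.schedule_report(m, "stone")
    print(f"{depth:>5} {m.n_segments:>5} {m.max_root_leaf_distance:>3} "
          f"{rep_b.rounds:>13} {rep_s.rounds:>12} "
          f"{rep_b.branch_cost:>11} {rep_s.segment_cost:>10.1f}")
# Deep, bushy trees favor the branch schedule (few long levels, lots of
# simultaneous branches); long unbranched cables favor pointer jumping
# (logarithmic rounds regardless of branch structure).
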