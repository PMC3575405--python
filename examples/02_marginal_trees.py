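"""Decompose an ARG into its marginal trees.

Each run of sites between detectable breakpoints shares one ordinary
rooted tree; this prints the intervals and their Newick trees (branch
lengths in expected substitutions per site).
"""

from argsample import SimulationSpec, simulate_arg, marginal_trees, extract_marginal_tree

arg = simulate_arg(SimulationSpec(n=5, L=2_000, theta=0.05, rho=1.0), rng=11)

for interval, tree in marginal_trees(arg):
    print(f"sites [{interval.start}, {interval.end}):  TMRCA {tree.tmrca:.5f}")
    print(f"  {tree.newick(precision=5)}")

site = 0
print(f"\nthe tree at site {site} alone:")
print(extract_marginal_tree(arg, site).newick(precision=5))
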