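"""Sample ARGs from the prior by MCMC and compare with direct simulation.

With the likelihood held at 1, the chain's stationary distribution is
the coalescent-with-recombination prior, so summaries of the sampled
ARGs must match backward simulation — the package's core correctness
check.  Prints means of breakpoint count and grand-MRCA height from
both routes; they should agree within Monte-Carlo error.
"""

import numpy as np

from argsample import RunConfig, SimulationSpec, run, simulate_arg

n, L, theta, rho = 8, 500, 1.0, 1.0

config = RunConfig(
    chain_length=120_000, sample_interval=200, burn_in_fraction=0.25,
    theta=theta, rho=rho, sample_parameters=(), n_tips=n, L=L, seed=5,
    store_args=False,
)
result = run(config)
post = result.trace[result.trace.step > 30_000]

sims = [simulate_arg(SimulationSpec(n=n, L=L, theta=theta, rho=rho), s)
        for s in range(1000)]
sim_k = np.mean([len(a.recombination_nodes()) for a in sims])
sim_root = np.mean([a.root.height for a in sims])

print(f"breakpoint count:  MCMC {post.n_recombinations.mean():.2f}   "
      f"simulation {sim_k:.2f}")
print(f"root height:       MCMC {post.root_height.mean():.3f}  "
      f"simulation {sim_root:.3f}")
print("\nper-kernel acceptance rates:")
for k, v in result.acceptance_rates.items():
    print(f"  {k:22s} {v:.3f}")
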