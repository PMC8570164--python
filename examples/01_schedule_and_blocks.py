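"""Build a tempering schedule and split it over parallel workers.

The K powers are beta(0.3, 1.0) quantiles, so most of them crowd the
prior end (beta near 0) where the expected log-likelihood changes fastest.
Workers get consecutive blocks so adjacent stones sample similar
distributions, keeping per-stone burn-in short.
"""

import numpy as np

from powerpost import allocate_cpus, make_powers, partition_blocks

schedule = make_powers(K=11, alpha_sched=0.3)
print("powers in execution order (posterior -> prior):")
print(np.array2string(schedule.powers, precision=5))
print(f"fraction of powers below 0.3: {np.mean(schedule.powers < 0.3):.2f}")

plan = partition_blocks(make_powers(128), M=4)
print("\nK=128 stones over M=4 workers (stone index ranges):")
for m, block in enumerate(plan.blocks, start=1):
    print(f"  worker {m}: stones {block[0]}..{block[-1]}  ({len(block)} stones)")

workers, n_lik = allocate_cpus(16)
print(f"\n16 CPUs, default split: {workers} stone workers x {n_lik} CPUs per likelihood")
print("(the floor-sqrt rule balances stone-level and likelihood-level parallelism)")
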