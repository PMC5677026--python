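"""Where should a lossy microscope place its query boundary?

Sweeps the photon loss rate, printing the information-optimal turn-off
boundary v0, the information one query then yields, and the estimated
number of optimally-placed queries a 10^-10 localization would need.
The boundary shrinks from L/2 (lossless bisection) towards L/e; at 99%
loss a query yields ~0.005 bits, so the information budget alone predicts
thousands of queries.
"""

import math

from halflie import estimated_optimal_queries, mutual_information, optimal_boundary

print(f"{'loss a0':>8} {'v0':>8} {'bits/query':>11} {'est. queries (eps=1e-10)':>25}")
for alpha in [0.0, 0.1, 0.3, 0.5, 0.9, 0.99]:
    v0 = optimal_boundary(alpha)
    bits = mutual_information(alpha, v0) / math.log(2)
    est = estimated_optimal_queries(1e-10, alpha)
    print(f"{alpha:8.2f} {v0:8.4f} {bits:11.5f} {est:25d}")
print()
print("v0 is the fraction of the domain one query should illuminate;")
print("the estimate is ceil(33.2 bits / bits-per-query), a yardstick no")
print("verification-based search can beat.")
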