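"""The two temperature-ladder schemes and the heated acceptance rule.

Both ladders are generated by one non-negative scalar, so run-time
adaptation only ever tunes a single number regardless of chain count.
"""

import math

from mc3 import beta_quantile_betas, heated_log_accept, incremental_betas

print("incremental, dt = 0.1 :", [round(float(b), 4) for b in incremental_betas(4, 0.1)])
print("beta-quantile, b = 1  :", [round(float(b), 4) for b in beta_quantile_betas(4, 1.0)])
print("beta-quantile, b = 2.5:", [round(float(b), 4) for b in beta_quantile_betas(4, 2.5)])

# A proposal that loses 3 log-posterior units is accepted with e^-3 ~ 5%
# by the cold chain but e^-0.75 ~ 47% by a beta = 0.25 heated chain:
for beta in (1.0, 0.5, 0.25):
    la = heated_log_accept(-13.0, -10.0, 0.0, beta)
    print(f"beta {beta:4}: acceptance of a -3 log-unit move = {math.exp(la):.3f}")
# Heating flattens the posterior, letting hot chains cross probability
# valleys that trap the cold chain.
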