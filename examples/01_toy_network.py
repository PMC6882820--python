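"""From a covariance matrix to a partial correlation network.

Builds the 6-variable toy covariance, inverts it, normalizes to partial
correlations and reads off the network.  The point of the example: the
pair (X1, X5) is marginally correlated (sigma_15 = 0.63) yet carries no
edge — its association is fully explained by the other variables.
"""

import numpy as np

from pcscreen import edge_set, precision_to_partial
from pcscreen.simulation import TOY_SIGMA

gamma = precision_to_partial(np.linalg.inv(TOY_SIGMA))

print("partial correlation of (X1, X3):", round(gamma[0, 2], 2))
print("partial correlation of (X1, X5):", round(gamma[0, 4], 2))
print("marginal covariance of (X1, X5):", TOY_SIGMA[0, 4])

edges = edge_set(gamma, tol=0.05)
print("network edges (1-indexed):", [(i + 1, j + 1) for i, j in edges])
# The five edges all carry partial correlation -0.45; every other pair,
# including (1,5), is conditionally independent.
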