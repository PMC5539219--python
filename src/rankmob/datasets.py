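"""Reference transition matrices for the two-stratum Markov analysis.

``MACAQUE_MATRICES`` holds the published annual stratum-transition
matrices estimated from three decades of rank data on a wild,
provisioned Tibetan macaque group (rows H, L; columns H, L).  They let
the stratification stage — matrix powers, stationary odds, and the
0.001-level convergence horizon — be reproduced directly, without any
behavioural records.
"""

from __future__ import annotations

from .stratify import TransitionMatrix

MACAQUE_MATRICES: dict[str, TransitionMatrix] = {
    "male": TransitionMatrix.from_rows((0.9570, 0.0430), (0.1854, 0.8146)),
    "female": TransitionMatrix.from_rows((0.9184, 0.0816), (0.1985, 0.8015)),
    "combined": TransitionMatrix.from_rows((0.9375, 0.0625), (0.1922, 0.8078)),
}
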