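"""Named DFE + dominance models and model-average summaries.

The three simulation presets (Strongly / Moderately / Weakly Recessive) are
discrete-DFE models with a monotonic decay of h from the neutral to the
strongly deleterious bin, selected from the set of dominance models that fit
the human (European-ancestry) nonsynonymous SFS about equally well.  They
span the plausible range for the dominance of strongly deleterious
mutations (h = 0.05 / 0.10 / 0.15) and are the standard inputs to the
genetic-load simulations.

The model-average rows summarize Akaike-weight averages of the full
dominance scan against the same data (all models, the high-likelihood
subset, and the monotonic high-likelihood subset).
"""

from __future__ import annotations

import numpy as np

from .dfe import DiscreteDFE, DominanceMap

__all__ = [
    "SIMULATION_MODELS",
    "MODEL_AVERAGE_ROWS",
    "simulation_model",
]

# (proportions over the 5 |s| bins, h per bin), neutral bin first
SIMULATION_MODELS = {
    "strongly_recessive": (
        (0.201, 0.222, 0.018, 0.286, 0.274),
        (0.5, 0.45, 0.25, 0.15, 0.05),
    ),
    "moderately_recessive": (
        (0.244, 0.152, 0.125, 0.259, 0.22),
        (0.5, 0.5, 0.45, 0.25, 0.1),
    ),
    "weakly_recessive": (
        (0.259, 0.125, 0.176, 0.254, 0.186),
        (0.5, 0.5, 0.5, 0.35, 0.15),
    ),
}

# Akaike-weight model averages of the dominance scan fit to the human
# nonsynonymous SFS (proportions, per-bin h)
MODEL_AVERAGE_ROWS = {
    "all_models": (
        (0.229, 0.125, 0.117, 0.281, 0.248),
        (0.5, 0.231, 0.226, 0.227, 0.232),
    ),
    "high_ll": (
        (0.220, 0.139, 0.177, 0.277, 0.187),
        (0.5, 0.233, 0.387, 0.339, 0.240),
    ),
    "monotonic_decay": (
        (0.245, 0.144, 0.132, 0.266, 0.214),
        (0.5, 0.451, 0.377, 0.300, 0.189),
    ),
}


def simulation_model(name: str) -> tuple[DiscreteDFE, DominanceMap]:
    """Return (DiscreteDFE, DominanceMap) for a named preset (inference convention)."""
    p, h = SIMULATION_MODELS[name]
    props = np.asarray(p, float)
    return DiscreteDFE(props / props.sum()), DominanceMap(h)
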