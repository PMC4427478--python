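"""Small construction helpers shared by the test modules."""

import numpy as np

from dmhs.core import ParticleSystem


def make_pair(distance: float, radius: float = 0.0) -> ParticleSystem:
    """Two particles on the x axis at the given separation."""
    s = ParticleSystem.empty(2)
    s.position[:] = [[0.0, 0.0], [distance, 0.0]]
    s.radius[:] = radius
    return s
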