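"""Built-in example signatures used in documentation and sanity checks."""

from __future__ import annotations

import numpy as np

from .sigmodel import ContextSpec, ShiraishiSignature

__all__ = ["deamination_signature"]

# Independent-feature (Shiraishi) signature of age-related spontaneous
# deamination of 5-methylcytosine, over a five-base context with the
# transcription-strand feature (6 + 4*4 + 2 = 24 parameters).  C>T changes
# dominate (92.8%), the +1 base is a guanine with high probability (the CpG
# context), and there is next to no strand bias.
# Rows: change, -2, -1, +1, +2, strand.
_DEAMINATION = np.array([
    [0.004, 0.006, 0.928, 0.009, 0.038, 0.015],
    [0.237, 0.228, 0.293, 0.242, 0.0, 0.0],
    [0.362, 0.220, 0.279, 0.139, 0.0, 0.0],
    [0.131, 0.053, 0.764, 0.052, 0.0, 0.0],
    [0.232, 0.277, 0.277, 0.214, 0.0, 0.0],
    [0.493, 0.507, 0.0, 0.0, 0.0, 0.0],
])


def deamination_signature() -> ShiraishiSignature:
    """The example CpG-deamination signature (quintet context + strand)."""
    spec = ContextSpec(2, 2, True, "shiraishi")
    return ShiraishiSignature(_DEAMINATION.copy(), spec,
                              name="deamination_CpG", tolerance=1e-3)
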