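"""Residue alphabet and special symbols shared across the package.

Three non-residue symbols are kept distinct throughout: ``-`` marks an
alignment gap, ``X`` a masked residue (low-quality genotype data), and
``?`` simulated missing data introduced by in-silico fragmentation.
Completeness counts treat all three as missing; phylogenetic likelihoods
treat all three as fully ambiguous observations.
"""

from __future__ import annotations

import numpy as np

AA20: str = "ACDEFGHIKLMNPQRSTVWY"
GAP: str = "-"
MASK: str = "X"
MISSING: str = "?"
STOP: str = "*"

#: symbols that count as absent data when scoring sequence completeness
ABSENT: frozenset[str] = frozenset({GAP, MASK, MISSING})

AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AA20)}

N_STATES: int = len(AA20)


def encode(seq: str) -> np.ndarray:
    """Encode a residue string to integer states; non-residues become -1."""
    return np.array([AA_INDEX.get(c, -1) for c in seq], dtype=np.int64)


def is_residue(c: str) -> bool:
    return c in AA_INDEX
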