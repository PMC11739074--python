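"""Shared statistical helpers.

Benjamini–Hochberg adjustment is used by every stage of the pipeline
(DE callers, per-stage microarray differential expression, ORA, the
acetylation-overlap test), always as the step-up procedure:

    adj(i) = min_{j >= i} ( m * p_(j) / j ),  capped at 1,

mapped back to the input order.  The computation is delegated to
statsmodels' ``fdr_bh``.
"""

from __future__ import annotations

import hashlib

import numpy as np
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    Parameters
    ----------
    pvalues : array-like of float in [0, 1]

    Returns
    -------
    numpy.ndarray of the same length, values in [0, 1], monotone
    non-decreasing in p-rank.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1] and be non-NaN")
    return multipletests(p, method="fdr_bh")[1]


def derive_seed(seed: int, label: str) -> int:
    """Fan a global seed out to a stage-local seed by stable hashing.

    The same (seed, label) pair always yields the same sub-seed, on any
    platform; the result is below 2**31 so it is safe for every RNG API.
    """
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
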