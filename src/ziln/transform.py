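"""Compositional transforms: classical clr and the zero-preserving variant.

Sequencing depth is arbitrary, so count vectors carry only relative
information; log-ratio transforms remove that scale.  The classical clr
centers log counts by the row mean of all p log counts and is undefined at
zero — the usual pseudocount workaround destroys scale invariance.  The
zero-preserving variant centers each nonzero entry by the mean log over the
row's *nonzero* entries only and maps zeros to exactly zero, which keeps
the transform invariant to per-sample rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import CountMatrix

__all__ = ["TransformedMatrix", "clr", "zclr"]


@dataclass
class TransformedMatrix:
    """Transformed values plus the mask of original zero counts.

    The mask, not the value, is authoritative for "was zero": a count of 1
    can transform to a value that collides with 0 numerically.
    """

    values: np.ndarray
    zero_mask: np.ndarray
    sample_ids: list[str] | None = None
    taxon_ids: list[str] | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


def _as_array(counts) -> tuple[np.ndarray, list[str] | None, list[str] | None]:
    if isinstance(counts, CountMatrix):
        return np.asarray(counts.counts, dtype=float), counts.sample_ids, counts.taxon_ids
    return np.asarray(counts, dtype=float), None, None


def clr(counts, pseudocount: float = 0.0) -> TransformedMatrix:
    """Classical centered log-ratio of counts + pseudocount.

    Every entry is log(y + pc) minus the row mean of log(y + pc) over all p
    entries; rows therefore have zero mean.  The zero mask still records the
    original zeros.  With zeros present a positive pseudocount is required,
    and the result is no longer scale invariant.
    """
    y, sids, tids = _as_array(counts)
    mask = y == 0
    if mask.any() and pseudocount <= 0:
        raise ValueError("clr undefined at zero; supply a positive pseudocount")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    logs = np.log(y + pseudocount)
    values = logs - logs.mean(axis=1, keepdims=True)
    return TransformedMatrix(values=values, zero_mask=mask, sample_ids=sids, taxon_ids=tids)


def zclr(counts) -> TransformedMatrix:
    """Zero-preserving clr: center nonzero entries by their own row-mean log.

    Nonzero entries become log y_ij minus the mean of log y_ik over the
    row's nonzero k; zero entries map to exactly 0.  The map is invariant
    to multiplying a row by any positive scalar.  Accepts real-valued
    (not only integer) inputs, since the invariance is a property of the
    map itself.
    """
    y, sids, tids = _as_array(counts)
    mask = y == 0
    if mask.all(axis=1).any():
        raise ValueError("empty sample: a row has no nonzero counts")
    with np.errstate(divide="ignore"):
        logs = np.where(mask, 0.0, np.log(np.where(mask, 1.0, y)))
    nnz = (~mask).sum(axis=1, keepdims=True)
    rowmean = logs.sum(axis=1, keepdims=True) / nnz
    values = np.where(mask, 0.0, logs - rowmean)
    return TransformedMatrix(values=values, zero_mask=mask, sample_ids=sids, taxon_ids=tids)
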