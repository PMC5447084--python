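"""Data reduction: rarefaction, prevalence and SNR filters, lnMR normalization.

These are the standard reductions applied before any network inference:
OTU count tables are rarefied to a common depth; features must occur in a
minimum number of samples of the group being analysed; array probes must
clear a signal-to-noise ratio of 2; array intensities are normalized with
the lnMR transform ln(x+1)/M.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pmenet.tables import FeatureTable

logger = logging.getLogger(__name__)


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # independent stream per (seed, sample id) so results do not depend on
    # sample order or on which samples are present
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(sample_id.encode())])
    )


def rarefy(table: FeatureTable, depth: int, seed: int = 0) -> FeatureTable:
    """Subsample each sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped with a
    warning. Column sums of the result all equal ``depth`` exactly
    (multivariate hypergeometric draw per sample).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    arr = table.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("rarefy requires integer counts")
    counts = np.round(arr).astype(np.int64)
    keep_cols, out_cols = [], []
    for j, sid in enumerate(table.sample_ids):
        total = int(counts[:, j].sum())
        if total < depth:
            logger.warning("rarefy: dropping sample %s (%d < %d reads)", sid, total, depth)
            continue
        rng = _sample_rng(seed, sid)
        out_cols.append(rng.multivariate_hypergeometric(counts[:, j], depth))
        keep_cols.append(sid)
    if not keep_cols:
        logger.warning("rarefy: no sample had >= %d reads", depth)
        values = pd.DataFrame(
            np.empty((table.n_features, 0), dtype=np.int64), index=table.feature_ids
        )
        return table.copy_with(values)
    values = pd.DataFrame(
        np.column_stack(out_cols), index=table.feature_ids, columns=keep_cols
    )
    return table.copy_with(values)


def prevalence_filter(
    table: FeatureTable,
    min_occurrence: int = 4,
    sample_ids: list[str] | None = None,
) -> FeatureTable:
    """Keep features with nonzero counts in >= ``min_occurrence`` samples.

    Occurrence is evaluated within ``sample_ids`` when given (e.g. the
    samples of one depth layer), over the whole table otherwise; the
    returned table is restricted to the same sample group.
    """
    if min_occurrence < 1:
        raise ValueError("min_occurrence must be >= 1")
    sub = table.select_samples(sample_ids) if sample_ids is not None else table
    occurrence = (sub.values > 0).sum(axis=1)
    keep = occurrence >= min_occurrence
    dropped = int((~keep).sum())
    if dropped:
        logger.info("prevalence_filter: removed %d of %d features", dropped, len(keep))
    if not keep.any():
        logger.warning("prevalence_filter: no feature passed min_occurrence=%d", min_occurrence)
    return sub.copy_with(sub.values.loc[keep])


@dataclass(frozen=True)
class SnrRecord:
    """One array probe with its local background statistics."""

    probe_id: str
    signal: float
    background_mean: float
    background_sd: float

    @property
    def snr(self) -> float:
        if self.background_sd <= 0:
            raise ValueError(f"probe {self.probe_id}: background_sd must be positive")
        return (self.signal - self.background_mean) / self.background_sd


def snr_filter(records: list[SnrRecord], threshold: float = 2.0) -> set[str]:
    """Probes whose signal-to-noise ratio is at least ``threshold``.

    SNR = (signal - background mean) / background sd; probes *below* the
    threshold are removed, so a probe exactly at the threshold survives.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return {r.probe_id for r in records if r.snr >= threshold}


def lnmr_normalize(table: FeatureTable, per_sample: bool = False) -> FeatureTable:
    """lnMR normalization of array intensities: ln(x+1) / M.

    By default M is the mean over samples of the per-sample total raw
    intensity (one global scalar, which keeps samples on a common scale);
    with ``per_sample=True`` each sample is divided by its own total
    instead. Zeros map to zero and within-sample rank order is preserved
    either way.
    """
    totals = table.values.sum(axis=0)
    if (totals <= 0).all():
        raise ZeroDivisionError("lnmr_normalize: table has no signal")
    logged = np.log1p(table.values)
    if per_sample:
        if (totals <= 0).any():
            bad = list(totals.index[totals <= 0])
            raise ZeroDivisionError(f"lnmr_normalize: zero-total sample(s) {bad}")
        out = logged / totals
    else:
        out = logged / float(totals.mean())
    return table.copy_with(out)
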