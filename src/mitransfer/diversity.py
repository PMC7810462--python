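"""Alpha diversity, even-depth subsampling and Jensen-Shannon divergence.

Beta diversity between community profiles is measured as the Jensen-Shannon
divergence (natural log, so bounded by ln 2), computed on a table evenly
subsampled to a common depth; alpha diversity and everything downstream of
presence/absence use the unrarefied counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import entropy
from skbio import DistanceMatrix

from .errors import ValidationError
from .io_core import AbundanceTable


@dataclass
class CompositionTable:
    """Relative-abundance matrix; every row sums to one."""

    sample_ids: list[str]
    asv_ids: list[str]
    proportions: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if p.shape != (len(self.sample_ids), len(self.asv_ids)):
            raise ValidationError("proportion matrix shape does not match ids")
        if p.size:
            if p.min() < 0:
                raise ValidationError("proportions must be non-negative")
            if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
                bad = self.sample_ids[int(np.argmax(np.abs(p.sum(axis=1) - 1)))]
                raise ValidationError(f"sample {bad!r} does not sum to 1 (all-zero rows are invalid)")
        self.proportions = p

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.proportions, index=self.sample_ids, columns=self.asv_ids)


def to_composition(table: AbundanceTable) -> CompositionTable:
    """Normalize counts to relative abundances (rows must be non-empty)."""
    totals = table.counts.sum(axis=1)
    if np.any(totals == 0):
        bad = table.sample_ids[int(np.argmax(totals == 0))]
        raise ValidationError(f"sample {bad!r} has zero reads; cannot normalize")
    return CompositionTable(
        list(table.sample_ids), list(table.asv_ids), table.counts / totals[:, None]
    )


def observed_richness(table: AbundanceTable) -> pd.Series:
    """Number of ASVs with at least one read, per sample."""
    return pd.Series(
        (table.counts >= 1).sum(axis=1), index=table.sample_ids, name="observed_richness"
    )


def shannon_index(table: AbundanceTable) -> pd.Series:
    """Shannon diversity H = -sum p ln p, in nats, per sample."""
    totals = table.counts.sum(axis=1)
    if np.any(totals == 0):
        bad = table.sample_ids[int(np.argmax(totals == 0))]
        raise ValidationError(f"sample {bad!r} has zero reads; Shannon index undefined")
    h = entropy(table.counts, axis=1)  # normalizes rows and uses natural log
    return pd.Series(h, index=table.sample_ids, name="shannon")


def rarefy(table: AbundanceTable, depth: int = 2000, seed: int | None = None) -> AbundanceTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Each row is drawn from the multivariate hypergeometric distribution over
    that sample's reads, so no cell can exceed its original count.  Samples
    below ``depth`` raise; filter with :func:`~mitransfer.io_core.filter_min_depth`
    first.
    """
    depth = int(depth)
    totals = table.counts.sum(axis=1)
    if np.any(totals < depth):
        bad = table.sample_ids[int(np.argmax(totals < depth))]
        raise ValidationError(f"sample {bad!r} has fewer than {depth} reads; cannot rarefy")
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for i in range(table.counts.shape[0]):
        out[i] = rng.multivariate_hypergeometric(table.counts[i], depth)
    return AbundanceTable(list(table.sample_ids), list(table.asv_ids), out)


def jsd_matrix(comp: CompositionTable, sqrt: bool = False) -> DistanceMatrix:
    """Pairwise Jensen-Shannon divergence matrix.

    JSD(P, Q) = 0.5 KL(P||M) + 0.5 KL(Q||M) with M = (P+Q)/2, natural log,
    0 ln 0 = 0; bounded by ln 2.  By default the divergence itself is
    returned; ``sqrt=True`` gives its square root, which is a metric.
    """
    # scipy's jensenshannon is the square root of the divergence
    root = pdist(comp.proportions, metric="jensenshannon")
    vals = root if sqrt else root**2
    return DistanceMatrix(squareform(np.nan_to_num(vals, nan=0.0)), ids=comp.sample_ids)


def jsd(p: np.ndarray, q: np.ndarray, sqrt: bool = False) -> float:
    """Jensen-Shannon divergence between two probability vectors."""
    from scipy.spatial.distance import jensenshannon

    root = jensenshannon(np.asarray(p, float), np.asarray(q, float))
    root = 0.0 if np.isnan(root) else float(root)
    return root if sqrt else root**2
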