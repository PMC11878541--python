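"""Per-site variability and evolutionary-rate scoring.

Two complementary site scores:

* Shannon entropy of the column's symbol frequencies — model-free; by
  default gaps and masked residues count as ordinary symbols, so columns
  with much missing data score as diverse (matching how entropy is
  typically run on such supermatrices).
* An empirical-Bayes evolutionary rate: given a tree and a discrete-gamma
  prior over site rates, the posterior mean rate of each column,
  ``sum_c r_c w_c L(site|r_c) / sum_c w_c L(site|r_c)`` with likelihoods
  from Felsenstein pruning. The gamma shape is profiled over a grid by
  maximum likelihood. High score = fast-evolving site.

Scores are smoothed with a centered moving average, normalized to mean
one per protein, and split at 1 into "variable" (>= 1) and "conserved"
(< 1) sites.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

from .alphabet import ABSENT
from .models import GammaRateModel, SubstitutionModel
from .msa import ConcatenatedMSA
from .phylo import site_log_likelihoods

DEFAULT_ALPHA_GRID = np.geomspace(0.05, 10.0, 60)


@dataclass
class SiteScoreTrack:
    """One float per alignment column, with provenance."""

    values: np.ndarray
    method: str  # entropy | entropy_smoothed | rate_raw | rate_zscore | rate_mean1 ...
    window: int | None = None
    flags: np.ndarray | None = None  # per-site boolean flags (e.g. all-missing)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return self.values.size


def column_entropy(column: Sequence[str], count_gaps: bool = True) -> float:
    """Shannon entropy (bits) of one alignment column.

    With ``count_gaps`` (default), '-', 'X' and '?' are ordinary symbols
    — missing data then reads as diversity; without, they are dropped
    from the frequency counts.
    """
    symbols = list(column)
    if not symbols:
        raise ValueError("column must be non-empty")
    if not count_gaps:
        symbols = [c for c in symbols if c not in ABSENT]
        if not symbols:
            return 0.0
    counts = np.array(list(Counter(symbols).values()), dtype=float)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def entropy_track(msa: ConcatenatedMSA, count_gaps: bool = True) -> SiteScoreTrack:
    values = [column_entropy(msa.seqs[:, j], count_gaps) for j in range(msa.width)]
    return SiteScoreTrack(np.array(values), "entropy")


def moving_average(track: SiteScoreTrack | np.ndarray, window: int = 20) -> SiteScoreTrack:
    """Centered moving average with a shrinking window at the edges."""
    if window < 1:
        raise ValueError("window must be at least 1")
    values = track.values if isinstance(track, SiteScoreTrack) else np.asarray(track, float)
    n = values.size
    csum = np.concatenate([[0.0], np.cumsum(values)])
    left = np.maximum(np.arange(n) - (window - 1) // 2, 0)
    right = np.minimum(np.arange(n) + window // 2 + 1, n)
    out = (csum[right] - csum[left]) / (right - left)
    method = track.method if isinstance(track, SiteScoreTrack) else "track"
    return SiteScoreTrack(out, f"{method}_smoothed", window=window)


# ---------------------------------------------------------------------------
# empirical-Bayes site rates
# ---------------------------------------------------------------------------

def alpha_profile(
    msa: ConcatenatedMSA,
    tree: dendropy.Tree,
    k: int = 16,
    alpha_grid: np.ndarray | None = None,
    model: SubstitutionModel | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Total log-likelihood over a grid of gamma shapes."""
    if k < 2:
        raise ValueError("need at least 2 rate categories")
    grid = DEFAULT_ALPHA_GRID if alpha_grid is None else np.asarray(alpha_grid, float)
    logliks = np.empty(grid.size)
    for i, alpha in enumerate(grid):
        gm = GammaRateModel(alpha=float(alpha), k=k)
        cat = site_log_likelihoods(tree, msa, model, rates=gm.rates)
        mx = cat.max(axis=0)
        site_ll = np.log((gm.weights[:, None] * np.exp(cat - mx)).sum(axis=0)) + mx
        logliks[i] = site_ll.sum()
    return grid, logliks


def estimate_alpha(
    msa: ConcatenatedMSA,
    tree: dendropy.Tree,
    k: int = 16,
    alpha_grid: np.ndarray | None = None,
    model: SubstitutionModel | None = None,
) -> GammaRateModel:
    """Grid maximum-likelihood estimate of the gamma site-rate shape."""
    grid, logliks = alpha_profile(msa, tree, k, alpha_grid, model)
    if not np.isfinite(logliks).any():
        raise ValueError("no gamma shape on the grid yields a finite likelihood")
    if np.ptp(logliks[np.isfinite(logliks)]) < 1e-9:
        warnings.warn(
            "likelihood is flat in the gamma shape (degenerate data); "
            "returning the grid maximum",
            stacklevel=2,
        )
    best = int(np.nanargmax(logliks))
    return GammaRateModel(alpha=float(grid[best]), k=k)


@dataclass
class SiteRates:
    """Posterior-mean site rates plus their z-scores."""

    raw: SiteScoreTrack
    zscore: SiteScoreTrack
    gamma: GammaRateModel
    all_missing: np.ndarray = field(default=None)  # type: ignore[assignment]


def site_rates_eb(
    msa: ConcatenatedMSA,
    tree: dendropy.Tree,
    gamma_model: GammaRateModel,
    model: SubstitutionModel | None = None,
) -> SiteRates:
    """Empirical-Bayes posterior mean rate of every site on a fixed tree.

    Missing symbols contribute likelihood one, so an all-missing site
    falls back to the prior mean rate of exactly 1 (flagged).
    """
    cat = site_log_likelihoods(tree, msa, model, rates=gamma_model.rates)
    mx = cat.max(axis=0)
    lik = np.exp(cat - mx)  # (k, n_sites), rescaled
    w = gamma_model.weights[:, None]
    post = (w * lik) / (w * lik).sum(axis=0, keepdims=True)
    raw = (gamma_model.rates[:, None] * post).sum(axis=0)
    sd = raw.std()
    z = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
    missing = np.array(
        [all(c in ABSENT for c in msa.seqs[:, j]) for j in range(msa.width)]
    )
    return SiteRates(
        SiteScoreTrack(raw, "rate_raw", flags=missing),
        SiteScoreTrack(z, "rate_zscore", flags=missing),
        gamma_model,
        missing,
    )


# ---------------------------------------------------------------------------
# normalization, partitioning, conserved stretches
# ---------------------------------------------------------------------------

def normalize_mean_one(track: SiteScoreTrack) -> SiteScoreTrack:
    """Divide the track by its mean (which must be positive)."""
    mean = track.values.mean()
    if mean <= 0:
        raise ValueError("track mean must be positive to normalize")
    return SiteScoreTrack(track.values / mean, f"{track.method}_mean1", track.window)


def normalize_mean_one_per_protein(
    track: SiteScoreTrack, partitions: dict[str, tuple[int, int]]
) -> SiteScoreTrack:
    """Mean-one normalization applied within each protein partition."""
    out = track.values.copy()
    for name, (start, end) in partitions.items():
        mean = out[start:end].mean()
        if mean <= 0:
            raise ValueError(f"partition {name!r} has non-positive mean score")
        out[start:end] /= mean
    return SiteScoreTrack(out, f"{track.method}_mean1", track.window)


def partition_sites(track: SiteScoreTrack) -> tuple[np.ndarray, np.ndarray]:
    """Split columns into variable (score >= 1) and conserved (< 1) sets."""
    variable = np.flatnonzero(track.values >= 1.0)
    conserved = np.flatnonzero(track.values < 1.0)
    return variable, conserved


def residue_span_length(start: int, end: int) -> int:
    """Inclusive residue count of a 1-based position span (e.g. 191-239 -> 49)."""
    if end < start:
        raise ValueError("span end must not precede its start")
    return end - start + 1


def conserved_stretches(
    track: SiteScoreTrack, threshold: float = 1.0, min_length: int = 2
) -> list[tuple[int, int, int]]:
    """Maximal runs of below-threshold scores as (start, end, length), 1-based inclusive."""
    below = track.values < threshold
    out = []
    i = 0
    n = below.size
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            if j - i + 1 >= min_length:
                out.append((i + 1, j + 1, residue_span_length(i + 1, j + 1)))
            i = j + 1
        else:
            i += 1
    return out


def score_tracks_tsv(
    path,
    msa: ConcatenatedMSA,
    tracks: Sequence[SiteScoreTrack],
) -> None:
    """Write score tracks as TSV: column index, protein, one column per track."""
    import pandas as pd

    proteins = np.empty(msa.width, dtype=object)
    for name, (start, end) in msa.partitions.items():
        proteins[start:end] = name
    data = {"column": np.arange(msa.width), "protein": proteins}
    for t in tracks:
        data[t.method] = t.values
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
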