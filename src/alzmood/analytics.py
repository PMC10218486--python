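"""Cohort-level summaries: mood percentages, frequency matrices, PCA.

The per-patient mood-frequency matrix holds, for each patient, the fraction
of their classified pose pairs falling in each of the six mood categories
(rows sum to 1).  PCA on this matrix — centered, via scikit-learn — gives
the variance structure across patients; pairwise explained-variance sums
are reported for component pairs (1,2), (2,3) and (1,3), the projections a
biplot would show.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from alzmood.classifier import PairCodeTable, DEFAULT_PAIR_TABLE, classify_stream
from alzmood.ingest import PoseStream
from alzmood.labels import Mood, MOOD_PRIORITY


@dataclass
class MoodSummary:
    """Counts and percentages over the six mood categories."""

    counts: dict[Mood, int]
    percentages: dict[Mood, float]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def mood_percentages(labels: Sequence[Mood]) -> MoodSummary:
    """Tally labels into per-mood counts and percentages (summing to 100).

    Every mood appears in the output, unrepresented ones with count 0.
    """
    if len(labels) == 0:
        raise ValueError("cannot summarize an empty label list")
    counts = {m: 0 for m in MOOD_PRIORITY}
    for lab in labels:
        counts[Mood(lab)] += 1
    n = len(labels)
    percentages = {m: 100.0 * c / n for m, c in counts.items()}
    return MoodSummary(counts=counts, percentages=percentages)


def mood_frequency_matrix(
    streams: Sequence[PoseStream],
    table: PairCodeTable = DEFAULT_PAIR_TABLE,
) -> pd.DataFrame:
    """Per-patient fractions of classified pairs in each mood (rows sum to 1)."""
    if not streams:
        raise ValueError("need at least one stream")
    rows = {}
    for stream in streams:
        labels = [m for _, m in classify_stream(stream, table)]
        summary = mood_percentages(labels)
        rows[stream.patient_id] = {
            m.value: summary.counts[m] / summary.total for m in MOOD_PRIORITY
        }
    return pd.DataFrame.from_dict(rows, orient="index")[[m.value for m in MOOD_PRIORITY]]


@dataclass
class PCAResult:
    """Centered-PCA output on a mood-frequency matrix.

    ``loadings`` has one row per mood and one (orthonormal) column per
    component; ``pair_variance`` maps component pairs (1-based) to the
    percentage of total variance they jointly explain.
    """

    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame
    pair_variance: dict[tuple[int, int], float]
    total_variance: float


def pca_summary(matrix: pd.DataFrame, n_components: int = 3) -> PCAResult:
    """Centered PCA of a per-patient frequency matrix.

    Raises on degenerate input: fewer than 2 patients, zero total variance,
    or more components than min(n_patients, n_moods).
    """
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError(f"need at least 2 patients, got {n}")
    if n_components < 1 or n_components > min(n, p):
        raise ValueError(
            f"n_components={n_components} out of range for a {n}x{p} matrix"
        )
    centered = X - X.mean(axis=0)
    total_var = float(np.var(centered, axis=0, ddof=1).sum())
    if total_var <= 0.0:
        raise ValueError("matrix has zero variance; PCA is degenerate")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    ratio = pca.explained_variance_ratio_
    pair_variance: dict[tuple[int, int], float] = {}
    for i, j in ((1, 2), (2, 3), (1, 3)):
        if j <= n_components:
            pair_variance[(i, j)] = float(100.0 * (ratio[i - 1] + ratio[j - 1]))
    return PCAResult(
        loadings=pd.DataFrame(pca.components_.T, index=matrix.columns, columns=comp_names),
        explained_variance_ratio=ratio,
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        pair_variance=pair_variance,
        total_variance=total_var,
    )
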