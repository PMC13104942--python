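"""k-NN consensus label transfer with an explicit unassigned category.

For each query cell projected into the reference embedding, the k nearest
reference cells vote: a state is assigned only when it uniquely reaches the
vote threshold (default 5 of k=10); otherwise the cell is left unassigned (NA)
rather than forced into a state. The identifiability score I(q) = n_match / k
— the fraction of the k nearest atlas neighbours sharing the transferred label
— quantifies how coherently the local atlas neighbourhood supports each
assignment. Per-state summaries (neighbour-vote stability, responder
enrichment) and an identifiability-aware prioritization build on these
annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .reference import QueryEmbedding, ReferenceMapper

log = logging.getLogger(__name__)

NA_LABEL = "NA"


class UndefinedIdentifiabilityError(ValueError):
    """Raised when identifiability is requested for an unassigned cell."""


@dataclass
class CellAnnotation:
    """Transferred label (or None for NA), neighbour vote counts and confidence."""

    cell_id: str
    assigned_label: str | None
    neighbor_counts: dict[str, int]
    n_match: int
    identifiability: float | None

    @property
    def is_assigned(self) -> bool:
        return self.assigned_label is not None


@dataclass
class StateStability:
    """Per-state neighbour-vote stability: matching vs non-matching counts."""

    state: str
    match_counts: np.ndarray
    nonmatch_counts: np.ndarray
    median_diff: float


@dataclass
class StateEnrichment:
    """Responder vs non-responder cell fractions within one mapped state."""

    state: str
    r_fraction: float
    nr_fraction: float
    n_cells: int


class KNNConsensusClassifier(BaseEstimator, ClassifierMixin):
    """Majority-vote k-NN label transfer with an NA category.

    Neighbours are found by Euclidean distance in the reference embedding;
    exact distance ties break deterministically by ascending reference-cell
    index. A label is assigned only if its neighbour count is >= ``min_votes``
    and strictly maximal among qualifying labels; ties and sub-threshold
    neighbourhoods yield NA.
    """

    def __init__(self, k: int = 10, min_votes: int = 5, chunk_size: int = 1024):
        self.k = k
        self.min_votes = min_votes
        self.chunk_size = chunk_size

    def fit(self, X, y):
        X = check_array(X, dtype=float)
        y = np.asarray([str(lab) for lab in y])
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y must have equal length")
        if not (1 <= self.min_votes <= self.k):
            raise ValueError("need 1 <= min_votes <= k")
        if self.k > X.shape[0]:
            raise ValueError(f"k={self.k} exceeds {X.shape[0]} reference cells")
        self.ref_X_ = X
        self.classes_, self.label_codes_ = np.unique(y, return_inverse=True)
        self.ref_labels_ = y
        return self

    def kneighbors(self, X) -> np.ndarray:
        """Indices of the k nearest reference cells per query row (ties by index)."""
        check_is_fitted(self, "ref_X_")
        X = check_array(np.asarray(X, dtype=float), dtype=float)
        out = np.empty((X.shape[0], self.k), dtype=int)
        for start in range(0, X.shape[0], self.chunk_size):
            chunk = X[start : start + self.chunk_size]
            d2 = cdist(chunk, self.ref_X_, "sqeuclidean")
            # stable argsort: equal distances keep ascending reference index
            out[start : start + chunk.shape[0]] = np.argsort(d2, axis=1, kind="stable")[:, : self.k]
        return out

    def annotate(self, X, cell_ids: Sequence[str] | None = None) -> list[CellAnnotation]:
        if isinstance(X, QueryEmbedding):
            cell_ids = cell_ids if cell_ids is not None else X.cell_ids
            X = X.coords
        X = np.asarray(X, dtype=float)
        if cell_ids is None:
            cell_ids = [f"cell{i}" for i in range(X.shape[0])]
        nbr = self.kneighbors(X)
        n_classes = self.classes_.size
        anns = []
        for row, cid in zip(nbr, cell_ids):
            counts = np.bincount(self.label_codes_[row], minlength=n_classes)
            top = int(counts.max())
            nonzero = {
                str(self.classes_[j]): int(counts[j]) for j in np.flatnonzero(counts)
            }
            qualifies = top >= self.min_votes
            tie = int((counts == top).sum()) > 1
            if qualifies and not tie:
                lab = str(self.classes_[int(np.argmax(counts))])
                anns.append(CellAnnotation(cid, lab, nonzero, top, top / self.k))
            else:
                anns.append(CellAnnotation(cid, None, nonzero, top, None))
        return anns

    def predict(self, X) -> np.ndarray:
        """Transferred labels, with ``"NA"`` for unassigned cells."""
        return np.asarray(
            [a.assigned_label if a.is_assigned else NA_LABEL for a in self.annotate(X)]
        )


def knn_consensus(
    qe: QueryEmbedding,
    model: ReferenceMapper,
    k: int = 10,
    min_votes: int = 5,
) -> list[CellAnnotation]:
    """Assign atlas states to projected query cells by k-NN majority vote."""
    clf = KNNConsensusClassifier(k=k, min_votes=min_votes)
    clf.fit(model.ref_embedding_, model.ref_labels_)
    return clf.annotate(qe)


def identifiability(ann: CellAnnotation, k: int) -> float:
    """I(q) = n_match / k, defined only for assigned cells."""
    if not ann.is_assigned:
        raise UndefinedIdentifiabilityError(
            f"identifiability is undefined for unassigned cell {ann.cell_id!r}"
        )
    return ann.n_match / k


def stability_summary(anns: Sequence[CellAnnotation], k: int) -> list[StateStability]:
    """Per-state matching vs non-matching neighbour counts, sorted by median difference.

    NA cells are excluded; states are returned in descending order of the
    median (matching - non-matching) neighbour count.
    """
    assigned = [a for a in anns if a.is_assigned]
    if not assigned:
        raise ValueError("no assigned cells to summarize")
    out = []
    for state in sorted({a.assigned_label for a in assigned}):
        match = np.asarray([a.n_match for a in assigned if a.assigned_label == state])
        nonmatch = k - match
        out.append(StateStability(state, match, nonmatch, float(np.median(match - nonmatch))))
    out.sort(key=lambda s: (-s.median_diff, s.state))
    return out


def stability_frame(stab: Sequence[StateStability]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "state": [s.state for s in stab],
            "n_cells": [s.match_counts.size for s in stab],
            "median_diff": [s.median_diff for s in stab],
        }
    )


def median_identifiability(anns: Sequence[CellAnnotation], k: int) -> dict[str, float]:
    """Per-state median identifiability over assigned cells."""
    assigned = [a for a in anns if a.is_assigned]
    out: dict[str, float] = {}
    for state in sorted({a.assigned_label for a in assigned}):
        vals = [a.n_match / k for a in assigned if a.assigned_label == state]
        out[state] = float(np.median(vals))
    return out


def responder_enrichment(
    anns: Sequence[CellAnnotation],
    cells: pd.DataFrame,
    samples: pd.DataFrame,
) -> list[StateEnrichment]:
    """Fraction of each mapped state's cells coming from responder samples.

    The NA category participates as its own state; cells from unknown-response
    samples are excluded. States are sorted by descending responder fraction.
    """
    sample_response = dict(zip(samples["sample_id"], samples["response"]))
    cell_sample = dict(zip(cells["cell_id"], cells["sample_id"]))
    rows = []
    for a in anns:
        resp = sample_response.get(cell_sample.get(a.cell_id))
        if resp not in ("R", "NR"):
            continue
        rows.append((a.assigned_label if a.is_assigned else NA_LABEL, resp))
    if not rows:
        raise ValueError("no cells from R/NR samples")
    df = pd.DataFrame(rows, columns=["state", "response"])
    if df["response"].nunique() < 2:
        raise ValueError("need cells from at least one R and one NR sample")
    out = []
    for state, sub in df.groupby("state", sort=True):
        n = len(sub)
        r_frac = float((sub["response"] == "R").mean())
        out.append(StateEnrichment(str(state), r_frac, 1.0 - r_frac, n))
    out.sort(key=lambda e: (-e.r_fraction, e.state))
    return out


def enrichment_frame(enr: Sequence[StateEnrichment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "state": [e.state for e in enr],
            "r_fraction": [e.r_fraction for e in enr],
            "nr_fraction": [e.nr_fraction for e in enr],
            "n_cells": [e.n_cells for e in enr],
        }
    )


def prioritize_states(
    enr: Sequence[StateEnrichment],
    median_ident: Mapping[str, float],
    theta: float = 0.8,
    top_q: float = 0.25,
) -> list[str]:
    """Rank candidate response states by enrichment, gated on identifiability.

    Candidates must sit in the top ``top_q`` quantile of responder fraction AND
    have median cell identifiability >= ``theta``; the NA category is never a
    candidate. Returns state names ranked by descending responder fraction
    (possibly empty).
    """
    named = [e for e in enr if e.state != NA_LABEL]
    if not named:
        return []
    fractions = np.asarray([e.r_fraction for e in named])
    threshold = float(np.quantile(fractions, 1.0 - top_q))
    candidates = [
        e for e in named
        if e.r_fraction >= threshold and median_ident.get(e.state, -np.inf) >= theta
    ]
    candidates.sort(key=lambda e: (-e.r_fraction, e.state))
    return [e.state for e in candidates]
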