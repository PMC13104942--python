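"""Frozen reference model fitting and query projection.

A reference atlas is summarized once — highly variable genes, per-gene scaling
statistics and PCA loadings — and then frozen. Query cells are aligned to the
reference gene set (missing genes imputed as zeros), normalized, optionally
cell-cycle corrected, standardized with the *reference* statistics and
projected through the stored loadings, so every query lands in the same fixed
coordinate system the reference states are defined in.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from .io import ExpressionMatrix
from .preprocess import (
    cell_cycle_scores,
    lognormalize,
    regress_and_scale,
    regress_covariate,
)

log = logging.getLogger(__name__)


@dataclass
class QueryEmbedding:
    """Query cells projected into the reference PCA space."""

    coords: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape[0] != len(self.cell_ids):
            raise ValueError("coords rows must match cell_ids")

    @property
    def d(self) -> int:
        return self.coords.shape[1]


@dataclass
class AlignmentReport:
    """Bookkeeping from feature alignment: which genes were imputed or dropped."""

    imputed_genes: list[str]
    dropped_genes: list[str]

    @property
    def n_imputed(self) -> int:
        return len(self.imputed_genes)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped_genes)


def select_hvg(values: np.ndarray, n_hvg: int, nbins: int = 20) -> np.ndarray:
    """Top genes by standardized dispersion of log-normalized expression.

    Dispersion (variance/mean) is z-scored within equal-frequency mean-expression
    bins; returns sorted gene indices. Requesting more genes than available
    falls back to all genes with a warning.
    """
    n_genes = values.shape[1]
    if n_hvg >= n_genes:
        if n_hvg > n_genes:
            log.warning("n_hvg=%d exceeds %d genes; using all genes", n_hvg, n_genes)
        return np.arange(n_genes)
    mean = values.mean(axis=0)
    var = values.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    ranks = rankdata(mean, method="average")
    bins = pd.cut(ranks, bins=min(nbins, n_genes), labels=False, include_lowest=True)
    z = np.zeros(n_genes)
    for b in np.unique(bins):
        sel = bins == b
        mu, sd = disp[sel].mean(), disp[sel].std(ddof=0)
        if sd > 0:
            z[sel] = (disp[sel] - mu) / sd
    top = np.argsort(-z, kind="stable")[:n_hvg]
    return np.sort(top)


def _pca_loadings(scaled: np.ndarray, d: int) -> np.ndarray:
    """PCA loadings by SVD with a fixed sign convention.

    Each component is oriented so its largest-magnitude loading is positive,
    making loadings reproducible across platforms.
    """
    _, _, vt = np.linalg.svd(scaled, full_matrices=False)
    loadings = vt[:d].T.copy()
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    return loadings


class ReferenceMapper(BaseEstimator):
    """Frozen reference model: HVGs, scaling statistics and PCA embedding.

    Parameters
    ----------
    n_hvg : number of highly variable genes used for PCA (default 2000)
    n_components : embedding dimension d (default 20)
    clip : z-score clamp applied during scaling (default 10)
    scale_factor : library-size normalization target (default 1e4)

    Fitted attributes
    -----------------
    gene_set_ : all reference gene ids, in reference order (alignment target)
    hvg_ : HVG gene ids; ``hvg_idx_`` their positions in ``gene_set_``
    gene_mean_, gene_sd_ : per-HVG post-regression normalization statistics
    loadings_ : (n_hvg, d) orthonormal PCA loadings
    ref_embedding_ : (n_ref_cells, d) reference-cell coordinates
    ref_labels_ : state label per reference cell; ``state_names_`` the vocabulary
    """

    def __init__(self, n_hvg: int = 2000, n_components: int = 20,
                 clip: float = 10.0, scale_factor: float = 10_000.0):
        self.n_hvg = n_hvg
        self.n_components = n_components
        self.clip = clip
        self.scale_factor = scale_factor

    def fit(self, m: ExpressionMatrix, labels, covariate: np.ndarray | None = None):
        labels = np.asarray(labels, dtype=object)
        if labels.shape[0] != m.n_cells:
            raise ValueError("labels must match the number of reference cells")
        if any(lab is None or (isinstance(lab, float) and np.isnan(lab)) for lab in labels):
            raise ValueError("reference labels must be non-null")
        d = self.n_components
        if m.n_cells < d + 1:
            raise ValueError(f"need at least {d + 1} reference cells for d={d}")

        logn = lognormalize(m, self.scale_factor)
        if covariate is not None and logn.n_cells != m.n_cells:
            raise ValueError("zero-count reference cells are unsupported with a covariate")
        labels = labels[[m.cell_ids.index(c) for c in logn.cell_ids]] \
            if logn.n_cells != m.n_cells else labels
        hvg_idx = select_hvg(logn.values, self.n_hvg)
        if d > min(logn.n_cells, hvg_idx.size):
            raise ValueError(
                f"d={d} exceeds min(cells, hvg) = {min(logn.n_cells, hvg_idx.size)}"
            )
        sub = logn.subset_genes(hvg_idx)
        scaled, mean, sd = regress_and_scale(
            sub, covariate=covariate, clip=self.clip, return_stats=True
        )
        loadings = _pca_loadings(scaled.values, d)

        self.gene_set_ = list(logn.gene_ids)
        self.hvg_idx_ = hvg_idx
        self.hvg_ = [logn.gene_ids[i] for i in hvg_idx]
        self.gene_mean_ = mean
        self.gene_sd_ = sd
        self.loadings_ = loadings
        self.ref_embedding_ = scaled.values @ loadings
        self.ref_labels_ = np.asarray([str(lab) for lab in labels])
        self.state_names_ = sorted(set(self.ref_labels_))
        return self

    # -- query side ---------------------------------------------------------

    def align(self, q: ExpressionMatrix, return_report: bool = False):
        return align_features(q, self, return_report=return_report)

    def transform(
        self,
        q: ExpressionMatrix,
        regress_cc: bool = False,
        s_genes: list[str] | None = None,
        g2m_genes: list[str] | None = None,
        nbin: int = 24,
        nctrl: int = 100,
        seed: int = 0,
    ) -> QueryEmbedding:
        """Project query counts into the reference PCA space.

        align -> lognormalize -> (optional) regress out the query-estimated
        S-minus-G2M score difference per gene -> standardize with the frozen
        reference mean/sd (reference sd-0 genes contribute 0) -> clamp ->
        multiply by the stored loadings.
        """
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "loadings_")
        aligned = align_features(q, self)
        logn = lognormalize(aligned, self.scale_factor)
        vals = logn.values
        if regress_cc:
            if s_genes is None or g2m_genes is None:
                from .preprocess import load_cell_cycle_genes

                cc = load_cell_cycle_genes()
                s_genes = s_genes or cc["S"]
                g2m_genes = g2m_genes or cc["G2M"]
            scores = cell_cycle_scores(logn, s_genes, g2m_genes, nbin, nctrl, seed)
            vals = regress_covariate(vals, scores.cc_diff)
        hvg_vals = vals[:, self.hvg_idx_]
        sd = self.gene_sd_
        with np.errstate(invalid="ignore", divide="ignore"):
            scaled = np.where(sd > 0, (hvg_vals - self.gene_mean_) / np.where(sd > 0, sd, 1.0), 0.0)
        if self.clip is not None and np.isfinite(self.clip):
            np.clip(scaled, -self.clip, self.clip, out=scaled)
        return QueryEmbedding(scaled @ self.loadings_, logn.cell_ids)


def align_features(q: ExpressionMatrix, model, return_report: bool = False):
    """Reindex a query matrix onto the reference gene set.

    Reference genes absent from the query become all-zero columns; query-only
    genes are dropped. Errors if the query shares no genes with the reference.
    """
    gene_set = list(model.gene_set_) if hasattr(model, "gene_set_") else list(model)
    q_index = q.gene_index()
    pos = q_index.get_indexer(pd.Index(gene_set))
    present = pos >= 0
    if not present.any():
        raise ValueError("query shares no genes with the reference gene set")
    out = np.zeros((q.n_cells, len(gene_set)), dtype=float)
    out[:, present] = q.values[:, pos[present]]
    imputed = [g for g, p in zip(gene_set, present) if not p]
    dropped = sorted(set(q.gene_ids) - set(gene_set))
    if imputed or dropped:
        log.info("align_features: %d gene(s) zero-imputed, %d query-only gene(s) dropped",
                 len(imputed), len(dropped))
    aligned = ExpressionMatrix(out, gene_set, q.cell_ids, layer=q.layer)
    if return_report:
        return aligned, AlignmentReport(imputed, dropped)
    return aligned


def fit_reference(
    m: ExpressionMatrix,
    labels,
    n_hvg: int = 2000,
    d: int = 20,
    covariate: np.ndarray | None = None,
) -> ReferenceMapper:
    """Fit a frozen reference model (functional wrapper over ReferenceMapper)."""
    return ReferenceMapper(n_hvg=n_hvg, n_components=d).fit(m, labels, covariate=covariate)


def project_query(q: ExpressionMatrix, model: ReferenceMapper,
                  regress_cc: bool = False, **kwargs) -> QueryEmbedding:
    """Project query counts into a fitted reference PCA space."""
    return model.transform(q, regress_cc=regress_cc, **kwargs)


# -- persistence (directory of delimited matrices + JSON manifest) ----------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def save_reference(model: ReferenceMapper, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.Series(model.gene_set_, name="gene_id").to_csv(
        directory / "genes.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {"gene_id": model.hvg_, "gene_mean": model.gene_mean_, "gene_sd": model.gene_sd_}
    ).to_csv(directory / "hvg.tsv", sep="\t", index=False)
    pc_cols = [f"PC{j + 1}" for j in range(model.loadings_.shape[1])]
    pd.DataFrame(model.loadings_, index=model.hvg_, columns=pc_cols).to_csv(
        directory / "loadings.tsv", sep="\t", index_label="gene_id"
    )
    emb = pd.DataFrame(model.ref_embedding_, columns=pc_cols)
    emb.insert(0, "label", model.ref_labels_)
    emb.to_csv(directory / "ref_embedding.tsv", sep="\t", index_label="cell_index")
    manifest = {
        "params": model.get_params(),
        "n_ref_cells": int(model.ref_embedding_.shape[0]),
        "d": int(model.loadings_.shape[1]),
        "state_names": model.state_names_,
        "checksums": {
            f: _sha256(directory / f)
            for f in ("genes.tsv", "hvg.tsv", "loadings.tsv", "ref_embedding.tsv")
        },
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_reference(directory: str | Path) -> ReferenceMapper:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    model = ReferenceMapper(**manifest["params"])
    genes = pd.read_csv(directory / "genes.tsv", sep="\t", dtype=str)
    hvg = pd.read_csv(directory / "hvg.tsv", sep="\t")
    loadings = pd.read_csv(directory / "loadings.tsv", sep="\t", index_col=0)
    emb = pd.read_csv(directory / "ref_embedding.tsv", sep="\t", index_col=0)
    model.gene_set_ = genes["gene_id"].tolist()
    model.hvg_ = hvg["gene_id"].astype(str).tolist()
    gene_pos = {g: i for i, g in enumerate(model.gene_set_)}
    model.hvg_idx_ = np.asarray([gene_pos[g] for g in model.hvg_])
    model.gene_mean_ = hvg["gene_mean"].to_numpy()
    model.gene_sd_ = hvg["gene_sd"].to_numpy()
    model.loadings_ = loadings.to_numpy(dtype=float)
    model.ref_labels_ = emb["label"].astype(str).to_numpy()
    model.ref_embedding_ = emb.drop(columns="label").to_numpy(dtype=float)
    model.state_names_ = manifest["state_names"]
    return model
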