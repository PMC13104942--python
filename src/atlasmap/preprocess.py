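"""Normalization, gene-set module scoring, cell-cycle scoring and scaling.

Module scores follow the Tirosh-style control-gene scheme: genes are binned by
average expression, each signature gene draws expression-matched control genes
from its bin, and the score is (mean signature expression) minus (mean control
expression) per cell. Cell-cycle phase scores are module scores over S and G2M
marker lists; the S-minus-G2M difference can be regressed out of each gene
before z-scaling so proliferation does not dominate downstream structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix

log = logging.getLogger(__name__)


class EmptyMatrixError(ValueError):
    """Raised when normalization would produce an empty matrix."""


def _require_layer(m: ExpressionMatrix, layer: str) -> None:
    if m.layer != layer:
        raise ValueError(f"expected a {layer!r} matrix, got layer {m.layer!r}")


def lognormalize(m: ExpressionMatrix, scale_factor: float = 10_000.0) -> ExpressionMatrix:
    """Library-size normalize and log-transform: x -> ln(1 + scale_factor * x / total).

    Cells with zero total counts are dropped (and reported via logging).
    """
    _require_layer(m, "counts")
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = m.values.sum(axis=1)
    keep = totals > 0
    if not keep.any():
        raise EmptyMatrixError("all cells have zero total counts")
    if not keep.all():
        dropped = [m.cell_ids[i] for i in np.flatnonzero(~keep)]
        log.warning("dropping %d zero-count cell(s): %s", len(dropped), dropped[:5])
    sub = m.subset_cells(keep)
    vals = np.log1p(scale_factor * sub.values / totals[keep][:, None])
    return ExpressionMatrix(vals, sub.gene_ids, sub.cell_ids, layer="lognorm")


@dataclass
class SignatureModule:
    """A named gene set plus the control-bin parameters used to score it."""

    name: str
    genes: list[str]
    nbin: int = 24
    nctrl: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has no genes")
        if self.nbin < 2:
            raise ValueError("nbin must be >= 2")
        if self.nctrl < 1:
            raise ValueError("nctrl must be >= 1")


def _expression_bins(mean_expr: np.ndarray, nbin: int) -> np.ndarray:
    """Equal-frequency expression bins; tied averages share a bin.

    Genes are ranked by average expression (ties -> average rank) and the rank
    range is cut into ``nbin`` equal-width intervals, which coincides with
    equal-frequency binning when averages are distinct and keeps ties together
    deterministically otherwise.
    """
    ranks = rankdata(mean_expr, method="average")
    return pd.cut(ranks, bins=nbin, labels=False, include_lowest=True).astype(int)


def module_score(m: ExpressionMatrix, sig: SignatureModule) -> np.ndarray:
    """Per-cell signature score: mean(signature genes) - mean(matched control pool).

    Control genes are drawn uniformly with replacement (``sig.nctrl`` per
    signature gene) from the signature gene's expression bin, using ``sig.seed``.
    """
    _require_layer(m, "lognorm")
    if m.n_genes < sig.nbin:
        raise ValueError(f"gene pool ({m.n_genes}) too small for nbin={sig.nbin}")
    idx = m.gene_index()
    pos = idx.get_indexer(pd.Index(sig.genes))
    missing = [g for g, p in zip(sig.genes, pos) if p < 0]
    if missing:
        log.warning("signature %s: %d gene(s) absent from matrix: %s",
                    sig.name, len(missing), missing[:5])
    sig_idx = pos[pos >= 0]
    if sig_idx.size == 0:
        raise ValueError(f"signature {sig.name!r} has no genes in the matrix")

    bins = _expression_bins(m.values.mean(axis=0), sig.nbin)
    rng = np.random.default_rng(sig.seed)
    ctrl_parts = []
    for g in sig_idx:
        pool = np.flatnonzero(bins == bins[g])
        ctrl_parts.append(rng.choice(pool, size=sig.nctrl, replace=True))
    ctrl_idx = np.concatenate(ctrl_parts)
    return m.values[:, sig_idx].mean(axis=1) - m.values[:, ctrl_idx].mean(axis=1)


def cluster_mean_scores(scores: np.ndarray, labels) -> pd.DataFrame:
    """Per-cluster mean module score with its standard error (sd/sqrt(n)).

    Singleton clusters get SE 0 with a warning (SE is undefined at n=1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape[0] != labels.shape[0]:
        raise ValueError("scores and labels must have equal length")
    rows = []
    for lab in pd.unique(labels):
        vals = scores[labels == lab]
        n = vals.size
        if n == 1:
            log.warning("cluster %r has a single cell; SE reported as 0", lab)
            se = 0.0
        else:
            se = float(np.std(vals, ddof=1) / np.sqrt(n))
        rows.append({"cluster": lab, "mean": float(vals.mean()), "se": se, "n": n})
    return pd.DataFrame(rows).set_index("cluster")


@dataclass
class CellCycleScores:
    """Per-cell S and G2M module scores, phase call and their difference.

    Phase is G1 when both scores are <= 0, otherwise the phase of the larger
    score (S on an exact tie). ``cc_diff`` is exactly ``s_score - g2m_score``.
    """

    s_score: np.ndarray
    g2m_score: np.ndarray
    phase: np.ndarray = field(init=False)
    cc_diff: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        s, g = np.asarray(self.s_score, float), np.asarray(self.g2m_score, float)
        if s.shape != g.shape:
            raise ValueError("score vectors differ in length")
        self.s_score, self.g2m_score = s, g
        self.cc_diff = s - g
        phase = np.where(s >= g, "S", "G2M")
        phase[(s <= 0) & (g <= 0)] = "G1"
        self.phase = phase


def cell_cycle_scores(
    m: ExpressionMatrix,
    s_genes: list[str],
    g2m_genes: list[str],
    nbin: int = 24,
    nctrl: int = 100,
    seed: int = 0,
) -> CellCycleScores:
    """Score S and G2M marker programs per cell and call a phase."""
    s = module_score(m, SignatureModule("S", list(s_genes), nbin, nctrl, seed))
    g2m = module_score(m, SignatureModule("G2M", list(g2m_genes), nbin, nctrl, seed))
    return CellCycleScores(s, g2m)


def load_cell_cycle_genes() -> dict[str, list[str]]:
    """The canonical Tirosh et al. (2016) S and G2M marker symbol lists."""
    text = resources.files("atlasmap.data").joinpath("cell_cycle_tirosh.tsv").read_text()
    sets: dict[str, list[str]] = {}
    for line in text.strip().splitlines()[1:]:
        set_name, gene = line.split("\t")
        sets.setdefault(set_name, []).append(gene)
    return sets


def regress_covariate(values: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Remove the per-gene OLS slope on a covariate, keeping each gene's mean.

    A constant covariate leaves the matrix unchanged (logged): the regression
    degenerates to the intercept.
    """
    cov = np.asarray(covariate, dtype=float)
    if cov.shape[0] != values.shape[0]:
        raise ValueError("covariate length must equal the number of cells")
    cc = cov - cov.mean()
    denom = float(cc @ cc)
    if denom <= 0.0:
        log.warning("constant covariate: regression reduces to centering only")
        return values
    beta = (cc @ values) / denom
    return values - np.outer(cc, beta)


def regress_and_scale(
    m: ExpressionMatrix,
    covariate: np.ndarray | None = None,
    clip: float = 10.0,
    return_stats: bool = False,
):
    """Optionally regress a covariate out of each gene, then z-scale and clamp.

    Per gene: OLS residuals on (intercept, covariate) if a covariate is given;
    center to mean 0; divide by the sample sd (sd-0 genes become all-zero
    columns); clamp to [-clip, clip]. With ``return_stats`` the pre-scaling
    per-gene mean and sd are returned as well (the frozen statistics a
    reference model re-uses for queries).
    """
    _require_layer(m, "lognorm")
    if clip is not None and clip <= 0:
        raise ValueError("clip must be positive")
    vals = m.values
    if covariate is not None:
        vals = regress_covariate(vals, covariate)
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1) if vals.shape[0] > 1 else np.zeros(vals.shape[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(sd > 0, (vals - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    if clip is not None and np.isfinite(clip):
        np.clip(scaled, -clip, clip, out=scaled)
    out = ExpressionMatrix(scaled, m.gene_ids, m.cell_ids, layer="scaled")
    if return_stats:
        return out, mean, sd
    return out
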