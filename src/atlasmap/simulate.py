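"""Synthetic reference atlas and batch-shifted query cohorts with known truth.

The generator emulates the structure the mapping analyses assume: a reference
atlas of discrete transcriptional states (sparse Gaussian gene programs,
negative-binomial counts, lognormal library sizes), a cell-cycle confound on
designated S/G2M gene blocks, query cohorts whose per-sample state
compositions differ by response status (Dirichlet with extra concentration on
designated response states in responders), a per-gene multiplicative batch
shift plus extra dropout, a held-out gene fraction to exercise
zero-imputation, and a deliberately coarsened + noised "cohort" labelling that
merges functionally distinct states the way per-study clusterings do.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

log = logging.getLogger(__name__)

DEFAULT_STATE_NAMES = ("Tn", "Tcm", "Trm", "Teff", "t-Teff", "Tex", "p-Tex", "Tisg")

#: default coarsening mirrors broad per-study cluster definitions: the two
#: exhaustion-like states merge into one cohort label, and every non-exhausted
#: state — including the designated response state t-Teff — is absorbed into a
#: single mixed "Non-exhausted" cluster, hiding the atlas-level response signal
DEFAULT_COARSEN_MAP = {
    "Tn": "Non-exhausted",
    "Tcm": "Non-exhausted",
    "Trm": "Non-exhausted",
    "Teff": "Non-exhausted",
    "t-Teff": "Non-exhausted",
    "Tisg": "Non-exhausted",
    "Tex": "Exhausted",
    "p-Tex": "Exhausted",
}


@dataclass
class SyntheticConfig:
    """All generator parameters; one seed governs the full generation graph.

    ``effect_delta`` is the extra Dirichlet concentration responders receive on
    each designated response state; the default 5.2 yields a mean proportion
    shift of about 0.10 on that state under the default 8-state composition
    (base concentration 5 per state).
    """

    n_genes: int = 1500
    n_states: int = 8
    n_ref_cells: int = 4000
    latent_loading_sd: float = 0.8
    sparsity: float = 0.1
    nb_dispersion: float = 0.5
    libsize_meanlog: float = float(np.log(2000.0))
    libsize_sdlog: float = 0.35
    cc_fraction: float = 0.15
    cc_effect: float = 1.0
    n_cc_genes: int = 30
    n_samples_per_group: int = 20
    n_cells_per_sample: int = 1200
    dirichlet_base: float = 5.0
    effect_delta: float = 5.2
    batch_shift_sdlog: float = 0.2
    dropout_rate: float = 0.1
    gene_holdout_rate: float = 0.1
    state_names: tuple[str, ...] | None = None
    response_states: tuple[str, ...] = ("t-Teff",)
    coarsen_map: dict[str, str] | None = None
    label_noise_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.state_names is None:
            self.state_names = (
                DEFAULT_STATE_NAMES
                if self.n_states == len(DEFAULT_STATE_NAMES)
                else tuple(f"state{i + 1:02d}" for i in range(self.n_states))
            )
        if len(self.state_names) != self.n_states:
            raise ValueError("state_names length must equal n_states")
        if self.coarsen_map is None:
            self.coarsen_map = (
                dict(DEFAULT_COARSEN_MAP)
                if self.state_names == DEFAULT_STATE_NAMES
                else {s: s for s in self.state_names}
            )
        if set(self.coarsen_map) != set(self.state_names):
            raise ValueError("coarsen_map must cover exactly the state names")
        for name in ("sparsity", "cc_fraction", "dropout_rate",
                     "gene_holdout_rate", "label_noise_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.dirichlet_base <= 0 or self.nb_dispersion <= 0:
            raise ValueError("concentrations and dispersion must be positive")
        unknown = set(self.response_states) - set(self.state_names)
        if unknown:
            raise ValueError(f"unknown response state(s): {sorted(unknown)}")
        if self.n_genes < 2 * self.n_cc_genes:
            raise ValueError("n_genes too small for the cell-cycle gene blocks")

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i + 1:04d}" for i in range(self.n_genes)]

    @property
    def s_genes(self) -> list[str]:
        return self.gene_ids[: self.n_cc_genes]

    @property
    def g2m_genes(self) -> list[str]:
        return self.gene_ids[self.n_cc_genes : 2 * self.n_cc_genes]


@dataclass
class StatePrograms:
    """Latent gene programs shared by the reference and all cohorts."""

    gene_ids: list[str]
    state_names: tuple[str, ...]
    baseline: np.ndarray
    loadings: np.ndarray  # states x genes
    cc_s: np.ndarray
    cc_g2m: np.ndarray


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated cohort."""

    cells: pd.DataFrame  # cell_id, sample_id, true_state, cohort_label, label_noised
    samples: pd.DataFrame  # sample_id, response
    held_out_genes: list[str]
    compositions: pd.DataFrame  # sample x state Dirichlet draws


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _state_phase_profiles(programs: StatePrograms) -> np.ndarray:
    """Normalized expression profiles for (state, phase) with phase in {none, S, G2M}."""
    S, G = programs.loadings.shape
    eta = np.empty((S, 3, G))
    for s in range(S):
        base = programs.baseline + programs.loadings[s]
        eta[s, 0] = base
        eta[s, 1] = base + programs.cc_s
        eta[s, 2] = base + programs.cc_g2m
    rates = _softplus(eta)
    return rates / rates.sum(axis=2, keepdims=True)


def _draw_counts(rng: np.random.Generator, profiles: np.ndarray,
                 state: np.ndarray, phase: np.ndarray, libsize: np.ndarray,
                 dispersion: float, gene_factor: np.ndarray | None = None) -> np.ndarray:
    p = profiles[state, phase]
    if gene_factor is not None:
        p = p * gene_factor
        p = p / p.sum(axis=1, keepdims=True)
    mu = libsize[:, None] * p
    r = 1.0 / dispersion  # Var = mu + dispersion * mu^2
    return rng.negative_binomial(r, r / (r + mu)).astype(float)


def _cell_states(rng: np.random.Generator, n: int, cc_fraction: float):
    """Cell-cycle phase codes: 0 none, 1 S, 2 G2M."""
    flagged = rng.random(n) < cc_fraction
    phase = np.where(flagged, rng.integers(1, 3, size=n), 0)
    return phase


def simulate_reference(cfg: SyntheticConfig):
    """Simulate the reference atlas.

    Returns (counts ExpressionMatrix, state label per cell, StatePrograms).
    Deterministic: identical config gives bit-identical output.
    """
    ss = np.random.SeedSequence(cfg.seed)
    prog_ss, ref_ss, _ = ss.spawn(3)

    rng = np.random.default_rng(prog_ss)
    baseline = rng.normal(0.0, 1.0, cfg.n_genes)
    mask = rng.random((cfg.n_states, cfg.n_genes)) < cfg.sparsity
    loadings = np.where(
        mask, rng.normal(0.0, cfg.latent_loading_sd, (cfg.n_states, cfg.n_genes)), 0.0
    )
    n_cc = cfg.n_cc_genes
    # keep state programs off the cell-cycle blocks so the confound is orthogonal
    loadings[:, : 2 * n_cc] = 0.0
    cc_s = np.zeros(cfg.n_genes)
    cc_s[:n_cc] = cfg.cc_effect * rng.uniform(0.5, 1.5, n_cc)
    cc_g2m = np.zeros(cfg.n_genes)
    cc_g2m[n_cc : 2 * n_cc] = cfg.cc_effect * rng.uniform(0.5, 1.5, n_cc)
    programs = StatePrograms(cfg.gene_ids, cfg.state_names, baseline, loadings, cc_s, cc_g2m)

    rng = np.random.default_rng(ref_ss)
    state = rng.integers(0, cfg.n_states, cfg.n_ref_cells)
    phase = _cell_states(rng, cfg.n_ref_cells, cfg.cc_fraction)
    libsize = rng.lognormal(cfg.libsize_meanlog, cfg.libsize_sdlog, cfg.n_ref_cells)
    counts = _draw_counts(
        rng, _state_phase_profiles(programs), state, phase, libsize, cfg.nb_dispersion
    )
    labels = np.asarray(cfg.state_names, dtype=object)[state]
    cell_ids = [f"ref_c{i + 1:05d}" for i in range(cfg.n_ref_cells)]
    return (
        ExpressionMatrix(counts, cfg.gene_ids, cell_ids, layer="counts"),
        labels.astype(str),
        programs,
    )


def simulate_cohort(
    cfg: SyntheticConfig,
    programs: StatePrograms,
    group_effects: Mapping[str, float] | None = None,
):
    """Simulate a batch-shifted query cohort with response-dependent compositions.

    Responder samples draw compositions from Dirichlet(base + delta on the
    designated response states); cells share the reference gene programs but
    receive a per-gene multiplicative lognormal batch factor and extra
    dropout. A ``gene_holdout_rate`` fraction of genes is deleted from the
    query matrix, and cohort labels are coarsened (plus label noise), with all
    truth recorded.
    """
    if group_effects is None:
        group_effects = {s: cfg.effect_delta for s in cfg.response_states}
    unknown = set(group_effects) - set(cfg.state_names)
    if unknown:
        raise ValueError(f"group_effects names unknown state(s): {sorted(unknown)}")

    ss = np.random.SeedSequence(cfg.seed)
    _, _, cohort_ss = ss.spawn(3)
    rng = np.random.default_rng(cohort_ss)

    state_index = {s: i for i, s in enumerate(cfg.state_names)}
    n_r, n_cells = cfg.n_samples_per_group, cfg.n_cells_per_sample
    sample_ids = [f"R{i + 1:02d}" for i in range(n_r)] + [f"N{i + 1:02d}" for i in range(n_r)]
    responses = ["R"] * n_r + ["NR"] * n_r

    alpha_base = np.full(cfg.n_states, cfg.dirichlet_base)
    alpha_r = alpha_base.copy()
    for s, delta in group_effects.items():
        alpha_r[state_index[s]] += delta

    profiles = _state_phase_profiles(programs)
    batch = rng.lognormal(0.0, cfg.batch_shift_sdlog, cfg.n_genes)

    comps, blocks, cells_rows = [], [], []
    coarse_labels = sorted(set(cfg.coarsen_map.values()))
    for sid, resp in zip(sample_ids, responses):
        alpha = alpha_r if resp == "R" else alpha_base
        comp = rng.dirichlet(alpha)
        comps.append(comp)
        state = rng.choice(cfg.n_states, size=n_cells, p=comp)
        phase = _cell_states(rng, n_cells, cfg.cc_fraction)
        libsize = rng.lognormal(cfg.libsize_meanlog, cfg.libsize_sdlog, n_cells)
        counts = _draw_counts(rng, profiles, state, phase, libsize,
                              cfg.nb_dispersion, gene_factor=batch)
        if cfg.dropout_rate > 0:
            counts *= rng.random(counts.shape) >= cfg.dropout_rate
        blocks.append(counts)
        for i, st in enumerate(state):
            true_state = cfg.state_names[st]
            cells_rows.append((f"{sid}_c{i + 1:04d}", sid, true_state,
                               cfg.coarsen_map[true_state]))

    counts = np.vstack(blocks)
    cells = pd.DataFrame(cells_rows, columns=["cell_id", "sample_id", "true_state",
                                              "cohort_label"])

    # cohort-label noise: flip to a uniformly drawn different coarse label
    noised = rng.random(len(cells)) < cfg.label_noise_rate
    if noised.any() and len(coarse_labels) > 1:
        for i in np.flatnonzero(noised):
            current = cells.at[i, "cohort_label"]
            others = [lab for lab in coarse_labels if lab != current]
            cells.at[i, "cohort_label"] = others[rng.integers(0, len(others))]
    else:
        noised[:] = False
    cells["label_noised"] = noised

    n_hold = int(round(cfg.gene_holdout_rate * cfg.n_genes))
    held_idx = np.sort(rng.choice(cfg.n_genes, size=n_hold, replace=False))
    held_out = [cfg.gene_ids[i] for i in held_idx]
    keep_idx = np.setdiff1d(np.arange(cfg.n_genes), held_idx)

    matrix = ExpressionMatrix(
        counts[:, keep_idx],
        [cfg.gene_ids[i] for i in keep_idx],
        cells["cell_id"].tolist(),
        layer="counts",
    )
    truth = SyntheticTruth(
        cells=cells,
        samples=pd.DataFrame({"sample_id": sample_ids, "response": responses}),
        held_out_genes=held_out,
        compositions=pd.DataFrame(comps, index=sample_ids, columns=list(cfg.state_names)),
    )
    return matrix, truth


def scaled_config(cfg: SyntheticConfig | None = None, **overrides) -> SyntheticConfig:
    """Convenience: a (possibly scaled-down) copy of a config with overrides."""
    base = cfg if cfg is not None else SyntheticConfig()
    return replace(base, **overrides)
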