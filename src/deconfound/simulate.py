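"""Synthetic mixed-tissue expression data generator.

Emulates a two-group (case/control) whole-blood expression study mixed
from two cell types (a CD3+ T-cell-like population and "Other"):

* cell-type-specific signatures drawn i.i.d. Gamma(shape=12.5,
  scale=0.65), matching the mean (~8.1) and variance (~5.3) of
  normalized array intensities in a typical clinical study;
* marker genes at fixed levels — 12.0 in the expressing cell type, 6.0
  otherwise — half of them positive markers for the first cell type,
  half negative;
* differential expression spiked into the second group's signature by
  adding ``delta_diff`` to the affected genes in the first cell type
  (patterns: up in cell type 1 only, up in both, or the worst-case
  *reverse* pattern that also subtracts the same amount from cell type
  2 so mixture-level signals cancel);
* per-sample proportions of the first cell type drawn uniformly within
  ``proportion_bounds`` (second cell type is the complement);
* measurement noise on the mixture ``S @ C``: multiplicative Gaussian
  with constant coefficient of variation ``cv_biological`` (biological)
  plus additive Gaussian with variance ``var_technical`` (technical),
  clipped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .markers import MarkerSet
from .matrices import (
    ConcentrationMatrix,
    ExpressionMatrix,
    SignatureMatrix,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_signature",
    "simulate_proportions",
    "add_noise",
    "spike_differential_expression",
    "simulate_dataset",
    "DE_PATTERNS",
]

DE_PATTERNS = ("up_both", "up_first_only", "reverse", "mixed")

#: the eight non-neutral (direction in cell type 1, direction in cell type 2)
#: combinations of NEUTRAL / UP / DOWN used by the "mixed" pattern
_MIXED_DIRECTIONS = [
    (1, 1), (1, 0), (1, -1), (0, 1), (0, -1), (-1, 1), (-1, 0), (-1, -1),
]


@dataclass
class SimulationConfig:
    """All generator settings; defaults are the study conditions."""

    gamma_shape: float = 12.5
    gamma_scale: float = 0.65
    cv_biological: float = 0.17  # eta: sd of the multiplicative error term
    var_technical: float = 0.1  # chi: variance of the additive error term
    marker_level_pos: float = 12.0
    marker_level_neg: float = 6.0
    n_genes: int = 10000
    n_markers: int = 10  # half positive / half negative for cell type 1
    n_diff: int = 600
    delta_diff: float = 2.0
    n_samples_per_group: int = 20
    proportion_bounds: tuple = (0.2, 0.8)
    de_pattern: str = "up_first_only"
    random_seed: int = 0
    cell_type_labels: tuple = ("CD3", "Other")
    group_labels: tuple = ("A", "B")

    def __post_init__(self):
        if self.gamma_shape <= 0 or self.gamma_scale <= 0:
            raise ValidationError("gamma shape and scale must be positive")
        if self.cv_biological < 0 or self.var_technical < 0:
            raise ValidationError("noise parameters must be non-negative")
        if self.n_genes < 1 or self.n_markers < 2 or self.n_markers % 2:
            raise ValidationError("need n_genes >= 1 and an even n_markers >= 2")
        if self.n_diff < 0 or self.n_markers + self.n_diff > self.n_genes:
            raise ValidationError("marker and DE genes must fit disjointly into n_genes")
        if self.n_diff > 0 and self.delta_diff <= 0:
            raise ValidationError("delta_diff must be positive")
        lo, hi = self.proportion_bounds
        if not (0 <= lo <= hi <= 1):
            raise ValidationError("proportion bounds must satisfy 0 <= lower <= upper <= 1")
        if self.de_pattern not in DE_PATTERNS:
            raise ValidationError(f"de_pattern must be one of {DE_PATTERNS}")
        if self.n_samples_per_group < 2:
            raise ValidationError("need at least 2 samples per group")
        if len(self.cell_type_labels) != 2 or len(self.group_labels) != 2:
            raise ValidationError("exactly two cell types and two groups are simulated")


@dataclass
class SimulatedDataset:
    """Ground-truth factors, mixed data and metadata of one simulation."""

    config: SimulationConfig
    X: dict  # group label -> ExpressionMatrix
    S: dict  # group label -> SignatureMatrix (ground truth)
    C: dict  # group label -> ConcentrationMatrix (ground truth)
    de_gene_ids: list
    de_directions: dict  # gene id -> (direction in cell 1, direction in cell 2)
    markers: MarkerSet

    def simulate_validation(self, n_cases: int, seed: int):
        """Fresh validation cases: identical signatures, new proportions and noise.

        Cases are split as evenly as possible between the two groups.

        Returns
        -------
        (ExpressionMatrix, ConcentrationMatrix, list of true group labels)
        """
        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        g_a, g_b = cfg.group_labels
        n_a = n_cases // 2 + n_cases % 2
        labels = [g_a] * n_a + [g_b] * (n_cases - n_a)
        sample_ids = [f"val_{i + 1}" for i in range(n_cases)]
        C = simulate_proportions(cfg, n_cases, rng=rng)
        C = ConcentrationMatrix(C.values, list(C.cell_type_labels), sample_ids)
        cols = np.empty((cfg.n_genes, n_cases))
        for j, g in enumerate(labels):
            cols[:, j] = self.S[g].values @ C.values[:, j]
        X = ExpressionMatrix(cols, list(self.S[g_a].gene_ids), sample_ids)
        X = add_noise(X, cfg, rng=rng)
        return X, C, labels


def _gene_ids(config: SimulationConfig):
    half = config.n_markers // 2
    pos = [f"mpos_{i + 1:02d}" for i in range(half)]
    neg = [f"mneg_{i + 1:02d}" for i in range(config.n_markers - half)]
    width = max(5, len(str(config.n_genes)))
    rest = [f"g{i + 1:0{width}d}" for i in range(config.n_genes - config.n_markers)]
    return pos, neg, pos + neg + rest


def _make_markers(config: SimulationConfig) -> MarkerSet:
    pos, neg, _ = _gene_ids(config)
    return MarkerSet(config.cell_type_labels[0], pos, neg)


def simulate_signature(config: SimulationConfig, rng=None) -> SignatureMatrix:
    """Draw the ground-truth baseline signature matrix.

    Non-marker entries are i.i.d. Gamma(gamma_shape, gamma_scale) per
    gene per cell type; marker rows are fixed at
    ``(marker_level_pos, marker_level_neg)`` for positive markers of the
    first cell type and reversed for negative markers.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.random_seed))
    pos, neg, gene_ids = _gene_ids(config)
    S = rng.gamma(config.gamma_shape, config.gamma_scale, size=(config.n_genes, 2))
    n_pos, n_neg = len(pos), len(neg)
    S[:n_pos, 0] = config.marker_level_pos
    S[:n_pos, 1] = config.marker_level_neg
    S[n_pos : n_pos + n_neg, 0] = config.marker_level_neg
    S[n_pos : n_pos + n_neg, 1] = config.marker_level_pos
    return SignatureMatrix(S, gene_ids, list(config.cell_type_labels))


def simulate_proportions(config: SimulationConfig, n_samples: int, rng=None) -> ConcentrationMatrix:
    """Draw per-sample proportions: first cell type uniform in bounds."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.random_seed))
    lo, hi = config.proportion_bounds
    p = rng.uniform(lo, hi, size=n_samples)
    C = np.vstack([p, 1.0 - p])
    ids = [f"sample_{j + 1}" for j in range(n_samples)]
    return ConcentrationMatrix(C, list(config.cell_type_labels), ids)


def add_noise(X_clean: ExpressionMatrix, config: SimulationConfig, rng=None) -> ExpressionMatrix:
    """Constant-CV multiplicative noise plus additive technical noise.

    Every entry x becomes ``x * (1 + delta) + eps`` with
    ``delta ~ N(0, cv_biological^2)`` and ``eps ~ N(0, var_technical)``,
    clipped at zero (intensities are non-negative).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.random_seed))
    V = X_clean.values
    out = V.copy()
    if config.cv_biological > 0:
        out = out * (1.0 + rng.normal(0.0, config.cv_biological, size=V.shape))
    if config.var_technical > 0:
        out = out + rng.normal(0.0, np.sqrt(config.var_technical), size=V.shape)
    return ExpressionMatrix(np.clip(out, 0.0, None), list(X_clean.gene_ids), list(X_clean.sample_ids))


def spike_differential_expression(S_group1: SignatureMatrix, config: SimulationConfig, rng=None):
    """Build the second group's signature by spiking DE genes.

    DE genes are drawn (without replacement) from the non-marker genes.
    Patterns: ``up_first_only`` adds ``delta_diff`` in cell type 1 only;
    ``up_both`` in both cell types; ``reverse`` adds in cell type 1 and
    subtracts in cell type 2 (floored at zero) so that mixture-level
    signals cancel; ``mixed`` assigns each DE gene one of the eight
    non-neutral direction combinations at random.

    Returns
    -------
    (SignatureMatrix for group 2, list of DE gene ids,
    dict gene id -> (direction in cell type 1, direction in cell type 2))
    """
    if config.n_diff > 0 and config.delta_diff <= 0:
        raise ValidationError("delta_diff must be positive")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.random_seed))
    n_markers = config.n_markers
    n_genes = S_group1.n_genes
    if config.n_diff > n_genes - n_markers:
        raise ValidationError("not enough non-marker genes to spike")
    candidates = np.arange(n_markers, n_genes)
    idx = np.sort(rng.choice(candidates, size=config.n_diff, replace=False))

    if config.de_pattern == "up_first_only":
        directions = np.tile([1, 0], (config.n_diff, 1))
    elif config.de_pattern == "up_both":
        directions = np.tile([1, 1], (config.n_diff, 1))
    elif config.de_pattern == "reverse":
        directions = np.tile([1, -1], (config.n_diff, 1))
    else:  # mixed: each DE gene one of the eight non-neutral combinations
        choice = rng.integers(0, len(_MIXED_DIRECTIONS), size=config.n_diff)
        directions = np.array([_MIXED_DIRECTIONS[c] for c in choice])

    S2 = S_group1.values.copy()
    S2[idx, :] += config.delta_diff * directions
    S2 = np.clip(S2, 0.0, None)  # reverse spiking may undershoot zero
    de_ids = [S_group1.gene_ids[i] for i in idx]
    de_dirs = {g: tuple(d) for g, d in zip(de_ids, directions)}
    return (
        SignatureMatrix(S2, list(S_group1.gene_ids), list(S_group1.cell_type_labels)),
        de_ids,
        de_dirs,
    )


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate the full two-group dataset ``X = noise(S @ C)`` per group."""
    ss = np.random.SeedSequence(config.random_seed)
    rng_sig, rng_spike, rng_a, rng_b = (np.random.default_rng(s) for s in ss.spawn(4))

    S1 = simulate_signature(config, rng=rng_sig)
    S2, de_ids, de_dirs = spike_differential_expression(S1, config, rng=rng_spike)
    markers = _make_markers(config)

    g_a, g_b = config.group_labels
    X, S, C = {}, {}, {}
    for g, S_g, rng in ((g_a, S1, rng_a), (g_b, S2, rng_b)):
        C_g = simulate_proportions(config, config.n_samples_per_group, rng=rng)
        ids = [f"{g}_{s}" for s in C_g.sample_ids]
        C_g = ConcentrationMatrix(C_g.values, list(C_g.cell_type_labels), ids)
        clean = ExpressionMatrix(S_g.values @ C_g.values, list(S_g.gene_ids), ids)
        X[g] = add_noise(clean, config, rng=rng)
        S[g], C[g] = S_g, C_g
    return SimulatedDataset(
        config=config, X=X, S=S, C=C, de_gene_ids=de_ids, de_directions=de_dirs, markers=markers
    )


def with_overrides(config: SimulationConfig, **kwargs) -> SimulationConfig:
    """Return a copy of ``config`` with fields replaced (re-validated)."""
    return replace(config, **kwargs)
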