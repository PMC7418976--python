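"""Paired two-domain synthetic cohorts with a shared latent dose response.

Each (compound, dose) pair draws a smooth low-dimensional latent trajectory
``z(t)``; the source domain observes a gene-loading mix of ``z`` on its own
time grid, the target domain observes a mix of a fixed deterministic transform
of ``z`` on its grid. Constant (unresponsive) genes carry baseline plus
replicate noise only. The noise-free target mean is available exactly via
:func:`oracle_target`, so translation models can be validated against a known
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .datasets import DEFAULT_DOSE_LEVELS, DomainDataset, DomainDesign, build_sample_table

__all__ = [
    "SimulationConfig",
    "generate_cohort",
    "oracle_target",
    "oracle_source",
    "compound_labels",
]

# Expression values live on a log2-like scale roughly in [4, 14], resembling
# RMA-normalised microarray output; absolute scale is removed downstream by
# min/max scaling.
_BASELINE_RANGE = (6.0, 12.0)
_LOADING_SD = 0.6


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the paired-cohort generator."""

    n_compounds: int
    n_genes: int
    frac_constant_genes: float = 0.2
    replicate_noise_sd: float = 0.1
    cross_domain_nonlinearity: str = "identity"  # identity | saturating
    dose_scaling: tuple[float, float, float, float] = (0.0, 0.25, 0.5, 1.0)
    latent_dim: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be positive")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not 0.0 <= self.frac_constant_genes <= 1.0:
            raise ValueError("frac_constant_genes must be in [0, 1]")
        if self.replicate_noise_sd < 0:
            raise ValueError("replicate_noise_sd must be nonnegative")
        if self.cross_domain_nonlinearity not in ("identity", "saturating"):
            raise ValueError(
                "cross_domain_nonlinearity must be 'identity' or 'saturating'"
            )
        ds = tuple(float(x) for x in self.dose_scaling)
        if len(ds) != 4 or ds[0] != 0.0 or any(x < 0 for x in ds):
            raise ValueError(
                "dose_scaling must be 4 nonnegative multipliers with control first = 0"
            )
        object.__setattr__(self, "dose_scaling", ds)
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be positive")

    @property
    def n_constant_genes(self) -> int:
        return int(round(self.frac_constant_genes * self.n_genes))


def compound_labels(n: int) -> tuple[str, ...]:
    width = max(2, len(str(n)))
    return tuple(f"cmpd{i + 1:0{width}d}" for i in range(n))


def gene_labels(n: int) -> tuple[str, ...]:
    width = max(4, len(str(n)))
    return tuple(f"g{i + 1:0{width}d}" for i in range(n))


_SMOOTH_WINDOW = 5


def _smooth_loadings(rng: np.random.Generator, n_genes: int, latent_dim: int) -> np.ndarray:
    """Gene loadings with local correlation along the gene axis: white noise
    moving-averaged over a small window, rescaled back to _LOADING_SD."""
    white = rng.normal(0.0, 1.0, size=(n_genes + _SMOOTH_WINDOW - 1, latent_dim))
    kernel = np.ones(_SMOOTH_WINDOW) / _SMOOTH_WINDOW
    smooth = np.stack(
        [np.convolve(white[:, j], kernel, mode="valid") for j in range(latent_dim)],
        axis=1,
    )
    return smooth * (_LOADING_SD * np.sqrt(_SMOOTH_WINDOW))


class _Structure:
    """Deterministic generative parameters derived from the config seed only
    (independent of the noise stream, so the oracle can re-derive them)."""

    def __init__(self, config: SimulationConfig):
        ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(0xC0,))
        rng = np.random.default_rng(ss)
        g, l, c = config.n_genes, config.latent_dim, config.n_compounds
        n_const = config.n_constant_genes
        self.constant_mask = np.zeros(g, dtype=bool)
        if n_const:
            const_idx = rng.choice(g, size=n_const, replace=False)
            self.constant_mask[const_idx] = True
        lo, hi = _BASELINE_RANGE
        self.baseline_source = rng.uniform(lo, hi, size=g)
        self.baseline_target = rng.uniform(lo, hi, size=g)
        # Loadings vary smoothly along the gene index: neighbouring genes
        # co-express (moving-average of white noise along the gene axis),
        # giving the gene axis a local correlation structure.
        self.loadings_source = _smooth_loadings(rng, g, l)
        self.loadings_target = _smooth_loadings(rng, g, l)
        self.loadings_source[self.constant_mask] = 0.0
        self.loadings_target[self.constant_mask] = 0.0
        # per-compound latent coefficients and smooth temporal basis
        self.coefficients = rng.normal(0.0, 1.0, size=(c, l))
        self.frequency = rng.uniform(0.02, 0.12, size=l)  # cycles / hour
        self.phase = rng.uniform(0.0, 2.0 * np.pi, size=l)
        self.config = config

    def latent(self, compound_idx: int, dose_idx: int, times_h: Sequence[float]) -> np.ndarray:
        """z(t): (latent_dim, T)."""
        t = np.asarray(times_h, dtype=float)
        basis = np.sin(
            2.0 * np.pi * self.frequency[:, None] * t[None, :] + self.phase[:, None]
        )
        scale = self.config.dose_scaling[dose_idx]
        return scale * self.coefficients[compound_idx][:, None] * basis

    def source_mean(self, compound_idx: int, dose_idx: int, times_h) -> np.ndarray:
        z = self.latent(compound_idx, dose_idx, times_h)
        return self.baseline_source[:, None] + self.loadings_source @ z

    def target_mean(self, compound_idx: int, dose_idx: int, times_h) -> np.ndarray:
        z = self.latent(compound_idx, dose_idx, times_h)
        if self.config.cross_domain_nonlinearity == "saturating":
            z = np.tanh(z)
        return self.baseline_target[:, None] + self.loadings_target @ z


def _fill_domain(
    structure: _Structure,
    design: DomainDesign,
    compounds: Sequence[str],
    genes: Sequence[str],
    mean_fn,
    rng: np.random.Generator,
    noise_sd: float,
) -> DomainDataset:
    samples = build_sample_table(compounds, design)
    expr = np.empty((len(genes), len(samples)))
    col = 0
    for ci in range(len(compounds)):
        for di in range(len(design.dose_levels)):
            mean = mean_fn(ci, di, design.time_points_h)  # (G, T)
            for ti in range(design.n_time_points):
                for _rep in range(design.n_replicates):
                    noise = rng.normal(0.0, noise_sd, size=len(genes)) if noise_sd else 0.0
                    expr[:, col] = mean[:, ti] + noise
                    col += 1
    return DomainDataset(design=design, gene_ids=tuple(genes), expression=expr, samples=samples)


def generate_cohort(
    config: SimulationConfig,
    source_design: DomainDesign,
    target_design: DomainDesign,
) -> tuple[DomainDataset, DomainDataset]:
    """Generate a paired (source, target) cohort.

    The same (compound, dose) latent response underlies both domains; the
    identical seed yields bit-identical output. Source noise is drawn before
    target noise from independent seed substreams.
    """
    structure = _Structure(config)
    compounds = compound_labels(config.n_compounds)
    genes = gene_labels(config.n_genes)
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(0xA0,))
    rng_source, rng_target = (np.random.default_rng(s) for s in ss.spawn(2))
    source = _fill_domain(
        structure, source_design, compounds, genes,
        structure.source_mean, rng_source, config.replicate_noise_sd,
    )
    target = _fill_domain(
        structure, target_design, compounds, genes,
        structure.target_mean, rng_target, config.replicate_noise_sd,
    )
    return source, target


def _resolve(config: SimulationConfig, compound: str, dose: str) -> tuple[int, int]:
    compounds = compound_labels(config.n_compounds)
    if compound not in compounds:
        raise KeyError(f"unknown compound {compound!r}")
    if dose not in DEFAULT_DOSE_LEVELS:
        raise KeyError(f"unknown dose {dose!r}")
    return compounds.index(compound), DEFAULT_DOSE_LEVELS.index(dose)


def oracle_target(
    config: SimulationConfig,
    compound: str,
    dose: str,
    target_design: DomainDesign,
) -> np.ndarray:
    """Noise-free target-domain mean trajectory (genes x time) — the quantity
    a perfect translator recovers."""
    ci, di = _resolve(config, compound, dose)
    return _Structure(config).target_mean(ci, di, target_design.time_points_h)


def oracle_source(
    config: SimulationConfig,
    compound: str,
    dose: str,
    source_design: DomainDesign,
) -> np.ndarray:
    """Noise-free source-domain mean trajectory (genes x time)."""
    ci, di = _resolve(config, compound, dose)
    return _Structure(config).source_mean(ci, di, source_design.time_points_h)
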