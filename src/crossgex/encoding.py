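"""Level-plus-slope trajectory encoding into [0, 1], and its exact inverse.

For each gene with raw values x1..xT the encoded row is::

    [ (x1 - min) / (max - min),                       # scaled level
      ((x2 - x1) / (max - min) + 1) / 2,              # slopes, affinely
      ...                                             # mapped from [-1, 1]
      ((xT - x_{T-1}) / (max - min) + 1) / 2 ]        # into [0, 1]

so a constant level shift of a trajectory changes only the first entry per
gene, leaving all slope entries untouched — prediction error then rewards the
correct expression *pattern* over the absolute level. The flat layout orders
genes consecutively, each contributing its T entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import DomainDataset
from .genesets import GeneSet

__all__ = [
    "ScalingParams",
    "EncodedInstance",
    "fit_scaling",
    "encode_trajectory",
    "decode_trajectory",
    "to_flat_layout",
    "to_matrix_layout",
    "from_flat",
    "write_encoded",
    "read_encoded",
]


@dataclass(frozen=True)
class ScalingParams:
    """Domain-wide min/max over all genes and compound-dose combinations."""

    global_min: float
    global_max: float
    domain_id: str = ""

    def __post_init__(self) -> None:
        if not self.global_max > self.global_min:
            raise ValueError("global_max must exceed global_min")

    @property
    def span(self) -> float:
        return self.global_max - self.global_min


@dataclass(frozen=True)
class EncodedInstance:
    """One compound-dose-replicate trajectory in encoded space.

    ``values`` is always stored genes x T; ``layout`` records the preferred
    presentation (``flat`` or ``matrix``).
    """

    compound: str
    dose: str
    replicate: int
    values: np.ndarray  # (G, T), entries in [0, 1]
    layout: str = "flat"
    gene_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be a genes x T matrix")
        if self.layout not in ("flat", "matrix"):
            raise ValueError("layout must be 'flat' or 'matrix'")
        object.__setattr__(self, "values", v)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_time_points(self) -> int:
        return self.values.shape[1]

    @property
    def flat(self) -> np.ndarray:
        return self.values.reshape(-1)

    @property
    def matrix(self) -> np.ndarray:
        return self.values


def fit_scaling(
    dataset: DomainDataset, genes: GeneSet | Sequence[str]
) -> ScalingParams:
    """Min and max over all selected genes, compounds, doses, times and
    replicates of the domain."""
    gene_ids = genes.gene_ids if isinstance(genes, GeneSet) else tuple(genes)
    idx = dataset.gene_index(gene_ids)
    block = dataset.expression[idx, :]
    lo, hi = float(block.min()), float(block.max())
    if hi == lo:
        raise ValueError("constant dataset: max equals min, cannot scale")
    return ScalingParams(global_min=lo, global_max=hi, domain_id=dataset.design.domain_id)


def encode_trajectory(
    raw: np.ndarray,
    scaling: ScalingParams,
    *,
    compound: str = "",
    dose: str = "",
    replicate: int = 0,
    layout: str = "flat",
    gene_ids: Sequence[str] | None = None,
) -> EncodedInstance:
    """Encode a raw (genes x T) trajectory; values outside the fitted support
    are clipped with a warning."""
    x = np.asarray(raw, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] < 2:
        raise ValueError("need at least two time points to encode slopes")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in trajectory")
    if x.min() < scaling.global_min or x.max() > scaling.global_max:
        warnings.warn("trajectory outside fitted scaling support; clipping")
        x = np.clip(x, scaling.global_min, scaling.global_max)
    level = (x[:, :1] - scaling.global_min) / scaling.span
    slopes = np.diff(x, axis=1) / scaling.span  # in [-1, 1]
    enc = np.hstack([level, (slopes + 1.0) / 2.0])
    return EncodedInstance(
        compound=compound,
        dose=dose,
        replicate=int(replicate),
        values=enc,
        layout=layout,
        gene_ids=tuple(gene_ids) if gene_ids is not None else None,
    )


def decode_trajectory(enc: EncodedInstance, scaling: ScalingParams) -> np.ndarray:
    """Exact inverse of :func:`encode_trajectory`; returns genes x T raw values."""
    v = enc.values
    x1 = scaling.global_min + v[:, :1] * scaling.span
    diffs = (2.0 * v[:, 1:] - 1.0) * scaling.span
    return np.hstack([x1, x1 + np.cumsum(diffs, axis=1)])


def to_flat_layout(enc: EncodedInstance) -> np.ndarray:
    """Length G*T vector; flat entry g*T + t equals matrix row g column t."""
    return enc.values.reshape(-1)


def to_matrix_layout(enc: EncodedInstance) -> np.ndarray:
    """G x T array view of the encoded values."""
    return enc.values


def from_flat(
    flat: np.ndarray,
    n_time_points: int,
    *,
    compound: str = "",
    dose: str = "",
    replicate: int = 0,
    layout: str = "flat",
    gene_ids: Sequence[str] | None = None,
) -> EncodedInstance:
    flat = np.asarray(flat, dtype=float).reshape(-1)
    if flat.size % n_time_points:
        raise ValueError(
            f"flat length {flat.size} not divisible by T={n_time_points}"
        )
    return EncodedInstance(
        compound=compound,
        dose=dose,
        replicate=int(replicate),
        values=flat.reshape(-1, n_time_points),
        layout=layout,
        gene_ids=tuple(gene_ids) if gene_ids is not None else None,
    )


# ----------------------------------------------------------------- serialization

def write_encoded(instances: Sequence[EncodedInstance], path: str | Path) -> Path:
    """One row per instance: provenance columns then the flat encoded vector.
    Layout and T are recorded in a metadata comment line."""
    path = Path(path)
    if not instances:
        raise ValueError("nothing to write")
    t = instances[0].n_time_points
    layout = instances[0].layout
    rows = []
    for inst in instances:
        if inst.n_time_points != t:
            raise ValueError("mixed time-point counts")
        rows.append(
            [inst.compound, inst.dose, inst.replicate, *inst.flat.tolist()]
        )
    cols = ["compound", "dose", "replicate"] + [
        f"v{i}" for i in range(len(rows[0]) - 3)
    ]
    with path.open("w") as fh:
        fh.write(f"#layout={layout}\tn_time_points={t}\n")
        pd.DataFrame(rows, columns=cols).to_csv(fh, sep="\t", index=False)
    return path


def read_encoded(path: str | Path) -> list[EncodedInstance]:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        meta = dict(item.split("=") for item in header.lstrip("#").split("\t"))
        df = pd.read_csv(fh, sep="\t")
    t = int(meta["n_time_points"])
    layout = meta.get("layout", "flat")
    out = []
    for _, row in df.iterrows():
        flat = row.iloc[3:].to_numpy(dtype=float)
        out.append(
            from_flat(
                flat, t,
                compound=str(row["compound"]), dose=str(row["dose"]),
                replicate=int(row["replicate"]), layout=layout,
            )
        )
    return out
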