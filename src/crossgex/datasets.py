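"""Domain datasets: per-domain expression matrices plus sample annotations.

A :class:`DomainDataset` holds the full factorial design of one experimental
domain — every (compound, dose, time, replicate) cell must be present
("complete crossing"), mirroring how incomplete compounds are dropped from
real toxicogenomics cohorts before modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DomainDesign",
    "DomainDataset",
    "RAT_IN_VITRO",
    "HUMAN_IN_VITRO",
    "RAT_IN_VIVO",
    "DEFAULT_DOSE_LEVELS",
]

DEFAULT_DOSE_LEVELS = ("control", "low", "middle", "high")

METADATA_COLUMNS = ["sample_id", "compound", "dose", "time_h", "replicate"]


@dataclass(frozen=True)
class DomainDesign:
    """Sampling design of one experimental domain.

    Parameters
    ----------
    domain_id
        Short label, e.g. ``"rat_in_vitro"``.
    time_points_h
        Strictly increasing sampling times in hours.
    n_replicates
        Biological replicates per (compound, dose, time) cell.
    dose_levels
        Ordered dose labels; must contain ``"control"``.
    """

    domain_id: str
    time_points_h: tuple[float, ...]
    n_replicates: int
    dose_levels: tuple[str, ...] = DEFAULT_DOSE_LEVELS

    def __post_init__(self) -> None:
        tp = tuple(float(t) for t in self.time_points_h)
        object.__setattr__(self, "time_points_h", tp)
        object.__setattr__(self, "dose_levels", tuple(self.dose_levels))
        if len(tp) < 1:
            raise ValueError("at least one time point required")
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError(f"time_points_h must be strictly increasing, got {tp}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        if "control" not in self.dose_levels:
            raise ValueError("dose_levels must contain 'control'")

    @property
    def n_time_points(self) -> int:
        return len(self.time_points_h)


# Design constants of the three domains used throughout.
RAT_IN_VITRO = DomainDesign("rat_in_vitro", (2.0, 8.0, 24.0), 2)
HUMAN_IN_VITRO = DomainDesign("human_in_vitro", (2.0, 8.0, 24.0), 2)
RAT_IN_VIVO = DomainDesign("rat_in_vivo", (3.0, 6.0, 9.0, 24.0), 3)


def _sample_id(compound: str, dose: str, time_h: float, replicate: int) -> str:
    return f"{compound}:{dose}:{time_h:g}:{replicate}"


@dataclass
class DomainDataset:
    """All expression values and sample annotations for one domain.

    ``expression`` is genes x samples; ``samples`` carries one row per column
    of ``expression`` with columns ``sample_id, compound, dose, time_h,
    replicate``.
    """

    design: DomainDesign
    gene_ids: tuple[str, ...]
    expression: np.ndarray
    samples: pd.DataFrame
    _column_index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.gene_ids = tuple(self.gene_ids)
        self.expression = np.asarray(self.expression, dtype=float)
        if self.expression.ndim != 2:
            raise ValueError("expression must be 2-D (genes x samples)")
        if self.expression.shape[0] != len(self.gene_ids):
            raise ValueError("expression rows must match gene_ids")
        if self.expression.shape[1] != len(self.samples):
            raise ValueError("expression columns must match sample table")
        if not np.all(np.isfinite(self.expression)):
            raise ValueError("expression contains non-finite values")
        missing = [c for c in METADATA_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")
        self._rebuild_index()
        self._check_complete_crossing()

    def _rebuild_index(self) -> None:
        self._column_index = {
            (row.compound, row.dose, float(row.time_h), int(row.replicate)): i
            for i, row in enumerate(self.samples.itertuples(index=False))
        }

    def _check_complete_crossing(self) -> None:
        expected = (
            len(self.compounds)
            * len(self.design.dose_levels)
            * self.design.n_time_points
            * self.design.n_replicates
        )
        if len(self.samples) != expected:
            raise ValueError(
                f"incomplete crossing: {len(self.samples)} samples, "
                f"expected {expected}"
            )
        for compound in self.compounds:
            for dose in self.design.dose_levels:
                for t in self.design.time_points_h:
                    for rep in range(1, self.design.n_replicates + 1):
                        if (compound, dose, t, rep) not in self._column_index:
                            raise ValueError(
                                f"missing cell ({compound}, {dose}, {t}, {rep})"
                            )

    @property
    def compounds(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.samples["compound"]))

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self, gene_ids: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in lookup]
        if missing:
            raise KeyError(f"genes absent from dataset: {missing[:5]}")
        return np.array([lookup[g] for g in gene_ids], dtype=int)

    def trajectory(
        self,
        compound: str,
        dose: str,
        replicate: int,
        gene_ids: Sequence[str] | None = None,
    ) -> np.ndarray:
        """Expression matrix (genes x time) for one replicate trajectory."""
        cols = []
        for t in self.design.time_points_h:
            key = (compound, dose, t, int(replicate))
            if key not in self._column_index:
                raise KeyError(f"no sample for {key}")
            cols.append(self._column_index[key])
        mat = self.expression[:, cols]
        if gene_ids is not None:
            mat = mat[self.gene_index(gene_ids), :]
        return mat

    def subset_genes(self, gene_ids: Sequence[str]) -> "DomainDataset":
        idx = self.gene_index(gene_ids)
        return DomainDataset(
            design=self.design,
            gene_ids=tuple(gene_ids),
            expression=self.expression[idx, :].copy(),
            samples=self.samples.copy(),
        )

    # ------------------------------------------------------------------ I/O

    def to_tsv(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write ``<prefix>.expression.tsv`` (genes x samples) and
        ``<prefix>.samples.tsv``; returns the two paths."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        expr_path = prefix.with_suffix(".expression.tsv")
        meta_path = prefix.with_suffix(".samples.tsv")
        expr = pd.DataFrame(
            self.expression,
            index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.samples["sample_id"].tolist(),
        )
        expr.to_csv(expr_path, sep="\t")
        meta = self.samples.copy()
        meta.insert(0, "domain_id", self.design.domain_id)
        meta["time_points_h"] = ",".join(f"{t:g}" for t in self.design.time_points_h)
        meta["dose_levels"] = ",".join(self.design.dose_levels)
        meta["n_replicates"] = self.design.n_replicates
        meta.to_csv(meta_path, sep="\t", index=False)
        return expr_path, meta_path

    @classmethod
    def from_tsv(cls, prefix: str | Path) -> "DomainDataset":
        prefix = Path(prefix)
        expr = pd.read_csv(prefix.with_suffix(".expression.tsv"), sep="\t", index_col=0)
        meta = pd.read_csv(prefix.with_suffix(".samples.tsv"), sep="\t")
        design = DomainDesign(
            domain_id=str(meta["domain_id"].iloc[0]),
            time_points_h=tuple(
                float(t) for t in str(meta["time_points_h"].iloc[0]).split(",")
            ),
            n_replicates=int(meta["n_replicates"].iloc[0]),
            dose_levels=tuple(str(meta["dose_levels"].iloc[0]).split(",")),
        )
        samples = meta[METADATA_COLUMNS].copy()
        # align expression columns with the sample table order
        expr = expr[samples["sample_id"].tolist()]
        return cls(
            design=design,
            gene_ids=tuple(expr.index.astype(str)),
            expression=expr.to_numpy(dtype=float),
            samples=samples,
        )


def build_sample_table(
    compounds: Iterable[str], design: DomainDesign
) -> pd.DataFrame:
    """Sample metadata for the full factorial crossing, in canonical order
    (compound, dose, time, replicate)."""
    rows = []
    for compound in compounds:
        for dose in design.dose_levels:
            for t in design.time_points_h:
                for rep in range(1, design.n_replicates + 1):
                    rows.append(
                        {
                            "sample_id": _sample_id(compound, dose, t, rep),
                            "compound": compound,
                            "dose": dose,
                            "time_h": t,
                            "replicate": rep,
                        }
                    )
    return pd.DataFrame(rows, columns=METADATA_COLUMNS)
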