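"""Gene sets: literature lists, nested random families, ortholog restriction,
and the variance screen used to reject unresponsive selections."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datasets import DomainDataset

__all__ = [
    "GeneSet",
    "OrthologMap",
    "load_gene_set",
    "generate_nested_random_sets",
    "generate_nested_random_set_pairs",
    "restrict_to_orthologs",
    "screen_variance",
    "generate_screened_nested_sets",
    "mean_gene_variance",
]


@dataclass(frozen=True)
class GeneSet:
    """Ordered, unique gene identifiers; ``parent`` links nested families."""

    name: str
    gene_ids: tuple[str, ...]
    parent: Optional["GeneSet"] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        ids = tuple(self.gene_ids)
        if len(set(ids)) != len(ids):
            raise ValueError(f"gene set {self.name!r} has duplicate ids")
        object.__setattr__(self, "gene_ids", ids)
        if self.parent is not None and not set(self.parent.gene_ids) < set(ids):
            raise ValueError("parent gene set must be a strict subset")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in set(self.gene_ids)

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text("\n".join(self.gene_ids) + "\n")
        return path


@dataclass(frozen=True)
class OrthologMap:
    """Source-domain to target-domain gene-id pairs."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        pairs = tuple((str(s), str(t)) for s, t in self.pairs)
        sources = [s for s, _ in pairs]
        if len(set(sources)) != len(sources):
            raise ValueError("duplicate source ids in ortholog map")
        object.__setattr__(self, "pairs", pairs)

    @property
    def source_ids(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.pairs)

    def target_for(self, source_id: str) -> str:
        return dict(self.pairs)[source_id]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OrthologMap":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < 2:
            raise ValueError("ortholog map needs two columns (source_id, target_id)")
        return cls(pairs=tuple(zip(df.iloc[:, 0], df.iloc[:, 1])))

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(self.pairs).to_csv(path, sep="\t", header=False, index=False)
        return path


def load_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a plain-text gene list (one id per line), de-duplicating while
    preserving first-seen order (the order drives input-layer layout)."""
    path = Path(path)
    raw = [line.strip() for line in path.read_text().splitlines()]
    raw = [g for g in raw if g and not g.startswith("#")]
    if not raw:
        raise ValueError(f"gene-set file {path} is empty")
    seen: dict[str, None] = {}
    dupes = 0
    for g in raw:
        if g in seen:
            dupes += 1
        seen[g] = None
    if dupes:
        warnings.warn(f"{path}: {dupes} duplicate gene id(s) collapsed")
    return GeneSet(name=name or path.stem, gene_ids=tuple(seen))


def generate_nested_random_sets(
    universe: Sequence[str],
    core_size: int,
    increment: int,
    n_levels: int,
    seed: int,
    name: str = "random",
) -> list[GeneSet]:
    """Nested random gene sets: a random core, then random increments drawn
    without replacement from the remaining universe, so set k+1 ⊃ set k."""
    universe = list(universe)
    needed = core_size + (n_levels - 1) * increment
    if needed > len(universe):
        raise ValueError(
            f"universe of {len(universe)} too small for final size {needed}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(universe))
    picked = [universe[i] for i in order[:needed]]
    sets: list[GeneSet] = []
    parent = None
    for level in range(n_levels):
        size = core_size + level * increment
        gs = GeneSet(name=f"{name}_{size}", gene_ids=tuple(picked[:size]), parent=parent)
        sets.append(gs)
        parent = gs
    return sets


def generate_nested_random_set_pairs(
    source_universe: Sequence[str],
    target_universe: Sequence[str],
    core_size: int,
    increment: int,
    n_levels: int,
    seed: int,
    ortholog_map: OrthologMap | None = None,
    name: str = "random",
) -> list[tuple[GeneSet, GeneSet]]:
    """Nested random families for a (source, target) domain pair.

    Without an ortholog map, source and target genes are drawn independently;
    with one, a single draw of source ids determines the target ids through
    the map (one id pair per gene).
    """
    if ortholog_map is None:
        src = generate_nested_random_sets(
            source_universe, core_size, increment, n_levels, seed, name=f"{name}_src"
        )
        tgt = generate_nested_random_sets(
            target_universe, core_size, increment, n_levels, seed + 1, name=f"{name}_tgt"
        )
        return list(zip(src, tgt))
    restricted = restrict_to_orthologs(source_universe, ortholog_map)
    src_sets = generate_nested_random_sets(
        restricted, core_size, increment, n_levels, seed, name=f"{name}_src"
    )
    out: list[tuple[GeneSet, GeneSet]] = []
    parent = None
    for s in src_sets:
        tgt_ids = tuple(ortholog_map.target_for(g) for g in s.gene_ids)
        t = GeneSet(name=s.name.replace("_src", "_tgt"), gene_ids=tgt_ids, parent=parent)
        parent = t
        out.append((s, t))
    return out


def restrict_to_orthologs(
    universe: Sequence[str], ortholog_map: OrthologMap
) -> tuple[str, ...]:
    """Subset of ``universe`` present as source ids in the map, order kept."""
    sources = set(ortholog_map.source_ids)
    result = tuple(g for g in universe if g in sources)
    if not result:
        warnings.warn("ortholog restriction produced an empty universe")
    return result


def mean_gene_variance(gene_set: GeneSet, dataset: DomainDataset) -> float:
    """Mean over the set's genes of the per-gene expression variance across
    all samples (population variance, ddof=0)."""
    idx = dataset.gene_index(gene_set.gene_ids)
    return float(np.mean(np.var(dataset.expression[idx, :], axis=1)))


def screen_variance(
    candidate: GeneSet,
    dataset: DomainDataset,
    reference: GeneSet,
    tolerance: float = 0.03,
) -> bool:
    """Accept ``candidate`` iff its mean per-gene variance is no more than
    ``tolerance`` (default 3%) below the reference set's; boundary inclusive."""
    v_cand = mean_gene_variance(candidate, dataset)
    v_ref = mean_gene_variance(reference, dataset)
    return v_cand >= (1.0 - tolerance) * v_ref


def generate_screened_nested_sets(
    universe: Sequence[str],
    dataset: DomainDataset,
    reference: GeneSet,
    core_size: int,
    increment: int,
    n_levels: int,
    seed: int,
    tolerance: float = 0.03,
    max_retries: int = 100,
    name: str = "random",
) -> list[GeneSet]:
    """Nested random sets where every level passes the variance screen.

    Rejected draws are regenerated from the next seed substream; the nesting
    chain is preserved because each retry redraws the whole family.
    """
    for attempt in range(max_retries):
        family = generate_nested_random_sets(
            universe, core_size, increment, n_levels,
            seed=np.random.SeedSequence(entropy=seed, spawn_key=(attempt,)).generate_state(1)[0],
            name=name,
        )
        if all(screen_variance(gs, dataset, reference, tolerance) for gs in family):
            return family
    raise RuntimeError(
        f"no nested family passed the variance screen in {max_retries} attempts"
    )
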