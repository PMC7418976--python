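"""Learning-example construction by cross-domain replicate pairing, and
leave-one-compound-out splits."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .datasets import DomainDataset
from .encoding import EncodedInstance, ScalingParams, encode_trajectory
from .genesets import GeneSet

__all__ = [
    "LearningExample",
    "LocoSplit",
    "discard_in_vivo_replicate",
    "build_examples",
    "loco_splits",
    "write_examples",
    "read_examples",
]


@dataclass(frozen=True)
class LearningExample:
    """A paired (source-encoded, target-encoded) instance."""

    source: EncodedInstance
    target: EncodedInstance
    compound: str
    dose: str
    source_replicate: int
    target_replicate: int

    def __post_init__(self) -> None:
        if self.source.compound != self.target.compound:
            raise ValueError("source/target compound mismatch")
        if self.source.dose != self.target.dose:
            raise ValueError("source/target dose mismatch")


@dataclass(frozen=True)
class LocoSplit:
    held_out_compound: str
    training: tuple[LearningExample, ...]
    validation: tuple[LearningExample, ...]

    def __post_init__(self) -> None:
        if any(ex.compound == self.held_out_compound for ex in self.training):
            raise ValueError("held-out compound leaked into training block")
        if any(ex.compound != self.held_out_compound for ex in self.validation):
            raise ValueError("validation block contains foreign compounds")


def discard_in_vivo_replicate(dataset: DomainDataset, seed: int) -> DomainDataset:
    """Per compound-dose cell, drop one of three replicates uniformly at
    random (seeded); survivors are relabelled 1..2 in original order."""
    if dataset.design.n_replicates != 3:
        raise ValueError(
            f"expected a 3-replicate domain, got {dataset.design.n_replicates}"
        )
    rng = np.random.default_rng(seed)
    design = dataset.design
    keep_cols: list[int] = []
    new_reps: list[int] = []
    for compound in dataset.compounds:
        for dose in design.dose_levels:
            dropped = int(rng.integers(1, 4))  # replicate id to discard
            for t in design.time_points_h:
                new_rep = 1
                for rep in (1, 2, 3):
                    if rep == dropped:
                        continue
                    keep_cols.append(dataset._column_index[(compound, dose, t, rep)])
                    new_reps.append(new_rep)
                    new_rep += 1
    samples = dataset.samples.iloc[keep_cols].copy().reset_index(drop=True)
    samples["replicate"] = new_reps
    samples["sample_id"] = [
        f"{r.compound}:{r.dose}:{r.time_h:g}:{r.replicate}"
        for r in samples.itertuples(index=False)
    ]
    design2 = replace(design, n_replicates=2)
    return DomainDataset(
        design=design2,
        gene_ids=dataset.gene_ids,
        expression=dataset.expression[:, keep_cols].copy(),
        samples=samples,
    )


def build_examples(
    source: DomainDataset,
    target: DomainDataset,
    genes: GeneSet | tuple[GeneSet, GeneSet],
    scalings: tuple[ScalingParams, ScalingParams],
) -> list[LearningExample]:
    """Full replicate cross-product per (compound, dose): every source
    replicate pairs with every target replicate, each side encoded with its
    own domain's scaling. Controls enter as an ordinary dose level.

    ``genes`` is a single set applied to both domains, or a (source set,
    target set) pair when the domains use different identifier spaces.
    """
    if isinstance(genes, GeneSet):
        src_genes, tgt_genes = genes, genes
    else:
        src_genes, tgt_genes = genes
    src_scaling, tgt_scaling = scalings
    if set(source.compounds) != set(target.compounds):
        only = set(source.compounds) ^ set(target.compounds)
        raise ValueError(f"compounds present in only one domain: {sorted(only)[:5]}")
    if tuple(source.design.dose_levels) != tuple(target.design.dose_levels):
        raise ValueError("dose levels differ between domains")
    examples: list[LearningExample] = []
    for compound in source.compounds:
        for dose in source.design.dose_levels:
            for s_rep in range(1, source.design.n_replicates + 1):
                s_raw = source.trajectory(compound, dose, s_rep, src_genes.gene_ids)
                s_enc = encode_trajectory(
                    s_raw, src_scaling, compound=compound, dose=dose,
                    replicate=s_rep, gene_ids=src_genes.gene_ids,
                )
                for t_rep in range(1, target.design.n_replicates + 1):
                    t_raw = target.trajectory(compound, dose, t_rep, tgt_genes.gene_ids)
                    t_enc = encode_trajectory(
                        t_raw, tgt_scaling, compound=compound, dose=dose,
                        replicate=t_rep, gene_ids=tgt_genes.gene_ids,
                    )
                    examples.append(
                        LearningExample(
                            source=s_enc, target=t_enc, compound=compound,
                            dose=dose, source_replicate=s_rep, target_replicate=t_rep,
                        )
                    )
    return examples


def write_examples(examples: Sequence[LearningExample], prefix) -> tuple:
    """Serialize to three files: source matrix, target matrix, provenance TSV."""
    from pathlib import Path

    import pandas as pd

    from .encoding import write_encoded

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    src_path = write_encoded([ex.source for ex in examples], prefix.with_suffix(".source.tsv"))
    tgt_path = write_encoded([ex.target for ex in examples], prefix.with_suffix(".target.tsv"))
    prov = pd.DataFrame(
        [
            {
                "compound": ex.compound,
                "dose": ex.dose,
                "source_replicate": ex.source_replicate,
                "target_replicate": ex.target_replicate,
            }
            for ex in examples
        ]
    )
    prov_path = prefix.with_suffix(".provenance.tsv")
    prov.to_csv(prov_path, sep="\t", index=False)
    return src_path, tgt_path, prov_path


def read_examples(prefix) -> list[LearningExample]:
    from pathlib import Path

    import pandas as pd

    from .encoding import read_encoded

    prefix = Path(prefix)
    sources = read_encoded(prefix.with_suffix(".source.tsv"))
    targets = read_encoded(prefix.with_suffix(".target.tsv"))
    prov = pd.read_csv(prefix.with_suffix(".provenance.tsv"), sep="\t")
    if not (len(sources) == len(targets) == len(prov)):
        raise ValueError("example files disagree in length")
    return [
        LearningExample(
            source=s,
            target=t,
            compound=str(row.compound),
            dose=str(row.dose),
            source_replicate=int(row.source_replicate),
            target_replicate=int(row.target_replicate),
        )
        for s, t, row in zip(sources, targets, prov.itertuples(index=False))
    ]


def loco_splits(examples: Sequence[LearningExample]) -> list[LocoSplit]:
    """One split per distinct compound; the validation block holds exactly
    all of that compound's examples."""
    compounds: list[str] = []
    for ex in examples:
        if ex.compound not in compounds:
            compounds.append(ex.compound)
    if len(compounds) < 2:
        raise ValueError("leave-one-compound-out needs at least two compounds")
    splits = []
    for compound in compounds:
        training = tuple(ex for ex in examples if ex.compound != compound)
        validation = tuple(ex for ex in examples if ex.compound == compound)
        splits.append(
            LocoSplit(held_out_compound=compound, training=training, validation=validation)
        )
    return splits
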