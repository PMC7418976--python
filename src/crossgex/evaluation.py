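"""Leave-one-compound-out evaluation, model comparison and reporting.

The error metric is the mean absolute error averaged over genes and time
points of one compound-dose trajectory; per-compound validation errors are
the mean over that compound's examples, and the overall model score is the
arithmetic mean over compounds. Non-baseline models are compared to the
random-regression-forest baseline with a paired two-tailed t-test on the
per-compound errors, Benjamini–Hochberg adjusted within the comparison
family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import DomainDataset
from .encoding import EncodedInstance, ScalingParams, decode_trajectory
from .models import ModelSpec, TrainedModel, TrainingConfig, design_matrices
from .models import fit as fit_model
from .pairing import LearningExample, LocoSplit, loco_splits

__all__ = [
    "FoldResult",
    "EvaluationReport",
    "eq1_mae",
    "run_loocv",
    "average_mae",
    "benjamini_hochberg",
    "compare_to_baseline",
    "summary_table",
    "render_report",
    "plot_prediction_overlay",
]


def eq1_mae(measured: np.ndarray, predicted: np.ndarray) -> float:
    """MAE over all genes and time points of one trajectory:
    ``1/(G*T) * sum_ij |X_ij - M_ij|``."""
    x = np.asarray(measured, dtype=float)
    m = np.asarray(predicted, dtype=float)
    if x.shape != m.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {m.shape}")
    return float(np.mean(np.abs(x - m)))


@dataclass(frozen=True)
class FoldResult:
    """Validation error for one held-out compound."""

    compound: str
    mae: float
    per_gene_mae: np.ndarray
    n_examples: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_gene_mae", np.asarray(self.per_gene_mae, dtype=float))


def average_mae(folds: Sequence[FoldResult]) -> float:
    return float(np.mean([f.mae for f in folds]))


ModelFactory = Callable[[Sequence[LearningExample]], TrainedModel]


def run_loocv(
    spec_or_factory: ModelSpec | ModelFactory,
    examples: Sequence[LearningExample],
    cfg: TrainingConfig | None = None,
    progress: Callable[[str, float], None] | None = None,
) -> list[FoldResult]:
    """Fit a fresh model per leave-one-compound-out split and score its
    predictions on the held-out compound's examples.

    ``spec_or_factory`` is a :class:`ModelSpec` (fitted with ``cfg``) or a
    callable ``training_examples -> predictor``; the latter admits reference
    predictors (e.g. a noise-free oracle) in tests.
    """
    cfg = cfg or TrainingConfig()
    results: list[FoldResult] = []
    for split in loco_splits(examples):
        try:
            if callable(spec_or_factory):
                model = spec_or_factory(split.training)
                kind = getattr(getattr(model, "spec", None), "kind", "custom")
            else:
                model = fit_model(spec_or_factory, split.training, cfg)
                kind = spec_or_factory.kind
        except Exception as err:  # re-raise with fold context
            raise RuntimeError(
                f"model fit failed on fold holding out {split.held_out_compound!r}"
            ) from err
        x_val, y_val = design_matrices(split.validation, kind)
        preds = model.predict(x_val)
        maes = np.abs(preds - y_val).mean(axis=1)
        t = split.validation[0].target.n_time_points
        per_gene = np.abs(preds - y_val).reshape(len(preds), -1, t).mean(axis=(0, 2))
        fold = FoldResult(
            compound=split.held_out_compound,
            mae=float(maes.mean()),
            per_gene_mae=per_gene,
            n_examples=len(split.validation),
        )
        results.append(fold)
        if progress is not None:
            progress(split.held_out_compound, fold.mae)
    return results


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up BH adjusted p-values: ``p_(i) * m / i`` with a running minimum
    from the largest rank down, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


@dataclass
class EvaluationReport:
    """Cross-model comparison for one gene set."""

    baseline: str
    table: pd.DataFrame  # model, mean_mae, t_stat, p_raw, p_adj, significant, best
    folds: Mapping[str, Sequence[FoldResult]] = field(default_factory=dict)


def _paired_t(diff: np.ndarray) -> tuple[float, float]:
    # zero-variance differences make the t statistic degenerate: all-zero
    # diffs report p=1 (no evidence), constant nonzero diffs report p=0
    if diff.std(ddof=0) == 0.0:
        if diff[0] == 0.0:
            return 0.0, 1.0
        return float(np.sign(diff[0]) * np.inf), 0.0
    t_stat, p = stats.ttest_rel(diff, np.zeros_like(diff))
    return float(t_stat), float(p)


def compare_to_baseline(
    fold_results_by_model: Mapping[str, Sequence[FoldResult]],
    baseline: str = "rrf",
) -> EvaluationReport:
    """Paired two-tailed t-tests of each model's per-compound MAE against the
    baseline's, BH-adjusted across the comparisons; significance flags mark
    adjusted p < 0.05 with the model's mean error below the baseline's."""
    if baseline not in fold_results_by_model:
        raise ValueError(f"baseline {baseline!r} missing from results")
    base_folds = list(fold_results_by_model[baseline])
    base_compounds = [f.compound for f in base_folds]
    base_mae = np.array([f.mae for f in base_folds])
    rows = []
    raw_ps: list[float] = []
    tested: list[str] = []
    for model, folds in fold_results_by_model.items():
        folds = list(folds)
        if [f.compound for f in folds] != base_compounds:
            raise ValueError(f"fold compounds of {model!r} differ from baseline")
        mean_mae = average_mae(folds)
        if model == baseline:
            rows.append({"model": model, "mean_mae": mean_mae,
                         "t_stat": np.nan, "p_raw": np.nan})
            continue
        diff = np.array([f.mae for f in folds]) - base_mae
        t_stat, p = _paired_t(diff)
        rows.append({"model": model, "mean_mae": mean_mae, "t_stat": t_stat, "p_raw": p})
        raw_ps.append(p)
        tested.append(model)
    table = pd.DataFrame(rows).set_index("model")
    table["p_adj"] = np.nan
    if tested:
        table.loc[tested, "p_adj"] = benjamini_hochberg(raw_ps)
    table["significant"] = (
        (table["p_adj"] < 0.05) & (table["mean_mae"] < table.loc[baseline, "mean_mae"])
    ).fillna(False)
    table["best"] = table["mean_mae"] == table["mean_mae"].min()
    return EvaluationReport(
        baseline=baseline, table=table.reset_index(), folds=dict(fold_results_by_model)
    )


def summary_table(reports_by_gene_set: Mapping[str, EvaluationReport]) -> pd.DataFrame:
    """One row per model, one column per gene set; the best model per set is
    emboldened with ** and significant improvements over the baseline are
    starred, mirroring the usual results-table layout."""
    columns: dict[str, dict[str, str]] = {}
    for set_name, report in reports_by_gene_set.items():
        col = {}
        for _, row in report.table.iterrows():
            cell = f"{row['mean_mae']:.5f}"
            if bool(row["significant"]):
                cell += "*"
            if bool(row["best"]):
                cell = f"**{cell}**"
            col[row["model"]] = cell
        columns[set_name] = col
    return pd.DataFrame(columns)


# ------------------------------------------------------------------ rendering

def plot_prediction_overlay(
    source: DomainDataset,
    target: DomainDataset,
    predicted: EncodedInstance,
    target_scaling: ScalingParams,
    compound: str,
    dose: str,
    gene_ids: Sequence[str],
    path: str | Path | None = None,
    max_genes: int = 12,
):
    """Per-gene overlay: measured source trajectory (red), both measured
    target replicates (blue), model prediction decoded to expression units
    (yellow/orange). Returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    genes = list(gene_ids)[:max_genes]
    decoded = decode_trajectory(predicted, target_scaling)
    pred_genes = list(predicted.gene_ids) if predicted.gene_ids else list(gene_ids)
    ncol = min(4, len(genes))
    nrow = int(np.ceil(len(genes) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.6 * nrow), squeeze=False)
    ts, tt = source.design.time_points_h, target.design.time_points_h
    for ax, gene in zip(axes.flat, genes):
        for rep in range(1, source.design.n_replicates + 1):
            ax.plot(ts, source.trajectory(compound, dose, rep, [gene])[0],
                    color="tab:red", alpha=0.7, lw=1.0,
                    label="source" if rep == 1 else None)
        for rep in range(1, target.design.n_replicates + 1):
            ax.plot(tt, target.trajectory(compound, dose, rep, [gene])[0],
                    color="tab:blue", alpha=0.7, lw=1.0,
                    label="target" if rep == 1 else None)
        gi = pred_genes.index(gene)
        ax.plot(tt, decoded[gi], color="orange", lw=2.0, label="predicted")
        ax.set_title(gene, fontsize=8)
        ax.set_xlabel("time (h)", fontsize=7)
    for ax in axes.flat[len(genes):]:
        ax.axis("off")
    handles, labels = axes.flat[0].get_legend_handles_labels()
    fig.legend(handles, labels, loc="upper right", fontsize=7)
    fig.suptitle(f"{compound} / {dose}", fontsize=10)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def render_report(
    reports_by_gene_set: Mapping[str, EvaluationReport],
    out_dir: str | Path,
    overlays: Sequence[dict] | None = None,
) -> dict[str, Path]:
    """Write the summary table (TSV) and optional overlay figures.

    ``overlays`` entries are keyword dictionaries for
    :func:`plot_prediction_overlay`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    summary = summary_table(reports_by_gene_set)
    summary_path = out_dir / "summary.tsv"
    summary.to_csv(summary_path, sep="\t")
    written["summary"] = summary_path
    for name, report in reports_by_gene_set.items():
        p = out_dir / f"comparison_{name}.tsv"
        report.table.to_csv(p, sep="\t", index=False)
        written[f"comparison_{name}"] = p
    for i, kwargs in enumerate(overlays or []):
        p = out_dir / f"overlay_{i:02d}.png"
        plot_prediction_overlay(path=p, **kwargs)
        written[f"overlay_{i:02d}"] = p
    return written
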