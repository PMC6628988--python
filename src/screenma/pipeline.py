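"""End-to-end orchestration: counts -> controls -> normalize -> MA -> fit -> score -> call.

`analyze_counts` is the pure in-memory pipeline used by tests and scripts;
`run_pipeline` wraps it with file I/O, logging, diagnostics and a run
manifest so a run is reproducible from its output directory alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .library import (
    ReadBatch,
    ScreenCountTable,
    SgRNARecord,
    count_spacers,
    parse_library,
    read_counts,
    read_fastq,
    write_counts,
)
from .scoring import (
    DEFAULT_PSEUDOCOUNT,
    DEFAULT_TRIM_FRACTION,
    DEFAULT_WINDOW_FRACTION,
    DEFAULT_WINDOW_STEP,
    MIN_WINDOW_SIZE,
    control_median_normalize,
    fit_variance_model,
    score_pair,
    select_stable_controls,
)
from .genes import DEFAULT_ALPHA_LEVEL, DEFAULT_MIN_SGRNAS, call_candidate_genes

__all__ = ["ScreenResult", "analyze_counts", "count_from_reads", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    """Everything one analysis produces, keyed by replicate where relevant."""

    scores: dict          # replicate_id -> per-sgRNA DataFrame
    models: dict          # replicate_id -> VarianceModel
    genes: pd.DataFrame = field(repr=False)
    control_medians: pd.Series = field(repr=False)
    selection: object = None

    @property
    def candidates(self) -> list[str]:
        return sorted(self.genes.loc[self.genes["is_candidate"], "gene_id"])


def analyze_counts(
    table: ScreenCountTable,
    library: Sequence[SgRNARecord],
    trim_fraction: float = DEFAULT_TRIM_FRACTION,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    window_fraction: float = DEFAULT_WINDOW_FRACTION,
    window_step: int = DEFAULT_WINDOW_STEP,
    min_window_size: int = MIN_WINDOW_SIZE,
    alpha_level: float = DEFAULT_ALPHA_LEVEL,
    min_sgrnas: int = DEFAULT_MIN_SGRNAS,
    two_sided: bool = False,
) -> ScreenResult:
    """Run the full scoring/calling method on an in-memory count table.

    Stage order: filter unstable controls on raw counts, control-median
    normalize, then per replicate compute MA statistics against the paired
    pre-induction sample, fit the exponential variance model on the stable
    controls, score every guide, and finally apply the gene rule across
    replicates.
    """
    lib_index = pd.Index([r.sgrna_id for r in library], name="sgrna_id")
    missing = lib_index.difference(table.counts.index)
    if len(missing):
        raise ValueError(f"count table lacks library sgRNAs: {list(missing)[:5]}")
    table = ScreenCountTable(
        counts=table.counts.loc[lib_index], samples=table.samples
    )
    control_ids = [r.sgrna_id for r in library if r.is_negative_control]
    if not control_ids:
        raise ValueError("library contains no negative-control sgRNAs")

    selection = select_stable_controls(table, control_ids, trim_fraction)
    normalized, medians = control_median_normalize(table, selection)

    gene_of = {r.sgrna_id: r.gene_id for r in library}
    ctrl_flag = pd.Series(
        {r.sgrna_id: r.is_negative_control for r in library}, name="is_control"
    )

    scores: dict[str, pd.DataFrame] = {}
    models: dict[str, object] = {}
    retained = pd.Index(selection.retained_ids)
    for replicate_id, induced, control in table.pairs():
        from .scoring import compute_ma

        a_ctl, m_ctl = compute_ma(
            normalized.loc[retained, induced],
            normalized.loc[retained, control],
            pseudocount,
        )
        model = fit_variance_model(
            a_ctl, m_ctl, window_fraction, window_step, min_window_size
        )
        rep_scores = score_pair(
            normalized, induced, control, model, pseudocount, two_sided
        )
        rep_scores.insert(0, "is_control", ctrl_flag.loc[rep_scores.index].to_numpy())
        rep_scores.insert(0, "gene_id", [gene_of[i] for i in rep_scores.index])
        scores[replicate_id] = rep_scores
        models[replicate_id] = model
        logger.info(
            "replicate %s: alpha=%.4g beta=%.4g", replicate_id, model.alpha, model.beta
        )

    genes = call_candidate_genes(
        scores, library, min_sgrnas=min_sgrnas, alpha_level=alpha_level
    )
    logger.info("called %d candidate genes", int(genes["is_candidate"].sum()))
    return ScreenResult(
        scores=scores,
        models=models,
        genes=genes,
        control_medians=medians,
        selection=selection,
    )


def count_from_reads(
    batches: dict[str, ReadBatch],
    library: Sequence[SgRNARecord],
    samples: pd.DataFrame,
    spacer_length: int = 19,
) -> tuple[ScreenCountTable, dict[str, int]]:
    """Derive the count table from per-sample read batches."""
    columns, unassigned = {}, {}
    for sample_id, batch in batches.items():
        counts, un = count_spacers(batch, library, spacer_length)
        columns[sample_id] = counts
        unassigned[sample_id] = un
        logger.info(
            "sample %s: %d assigned, %d unassigned",
            sample_id, int(counts.sum()), un,
        )
    table = ScreenCountTable(counts=pd.DataFrame(columns), samples=samples)
    return table, unassigned


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _plot_ma(result: ScreenResult, out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    reps = sorted(result.scores)
    fig, axes = plt.subplots(1, len(reps), figsize=(6 * len(reps), 5), squeeze=False)
    for ax, rid in zip(axes[0], reps):
        s = result.scores[rid]
        model = result.models[rid]
        ctrl = s["is_control"].to_numpy()
        ax.scatter(s["A"][~ctrl], s["M"][~ctrl], s=3, alpha=0.3, label="targeting")
        ax.scatter(s["A"][ctrl], s["M"][ctrl], s=4, alpha=0.5, c="k", label="controls")
        grid = np.linspace(s["A"].min(), s["A"].max(), 200)
        sig = model.predict_sigma(grid)
        for k, ls in ((1, "--"), (2, ":")):
            ax.plot(grid, k * sig, "r" + ls, lw=1)
            ax.plot(grid, -k * sig, "r" + ls, lw=1)
        ax.scatter(
            model.windows["a_center"], model.windows["sigma"],
            s=8, c="orange", label="window SD",
        )
        ax.set_xlabel("A (mean log10 normalized count)")
        ax.set_ylabel("M (log10 fold change)")
        ax.set_title(f"replicate {rid}: sigma = {model.alpha:.3f}*exp(-{model.beta:.3f}*A)")
        ax.legend(markerscale=3, fontsize=8)
    fig.tight_layout()
    fig.savefig(out_dir / "ma_plot.png", dpi=120)
    plt.close(fig)


def run_pipeline(config: dict) -> Path:
    """Run the whole method from a flat config dict; returns the output directory.

    Config keys: counts/samples (TSV paths) or fastq (sample_id -> FASTQ
    path) + flank5/flank3, library, spacer_len, trim_fraction, pseudocount,
    window_frac, window_step, alpha_level, min_sgrnas, two_sided, out_dir,
    seed.
    """
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    spacer_len = int(config.get("spacer_len", 19))
    library = parse_library(config["library"], spacer_len)

    digests = {"library": _digest(Path(config["library"]))}
    if config.get("fastq"):
        samples = pd.read_csv(config["samples"], sep="\t", dtype=str)
        samples["paired_control_id"] = samples["paired_control_id"].where(
            samples["paired_control_id"].notna(), None
        )
        batches = {}
        for sample_id, fq in config["fastq"].items():
            batches[sample_id] = ReadBatch(
                reads=read_fastq(fq),
                flank5=config["flank5"],
                flank3=config["flank3"],
            )
            digests[f"fastq:{sample_id}"] = _digest(Path(fq))
        table, unassigned = count_from_reads(batches, library, samples, spacer_len)
        write_counts(table, out_dir / "counts.tsv", out_dir / "samples.tsv")
    else:
        table = read_counts(config["counts"], config["samples"])
        digests["counts"] = _digest(Path(config["counts"]))
        unassigned = None
    digests["samples"] = _digest(Path(config["samples"]))

    result = analyze_counts(
        table,
        library,
        trim_fraction=float(config.get("trim_fraction", DEFAULT_TRIM_FRACTION)),
        pseudocount=float(config.get("pseudocount", DEFAULT_PSEUDOCOUNT)),
        window_fraction=float(config.get("window_frac", DEFAULT_WINDOW_FRACTION)),
        window_step=int(config.get("window_step", DEFAULT_WINDOW_STEP)),
        alpha_level=float(config.get("alpha_level", DEFAULT_ALPHA_LEVEL)),
        min_sgrnas=int(config.get("min_sgrnas", DEFAULT_MIN_SGRNAS)),
        two_sided=bool(config.get("two_sided", False)),
    )

    for rid, s in result.scores.items():
        s.to_csv(out_dir / f"scores_{rid}.tsv", sep="\t", index_label="sgrna_id")
    model_rows = []
    for rid, model in result.models.items():
        model.windows.assign(replicate_id=rid).to_csv(
            out_dir / f"windows_{rid}.tsv", sep="\t", index=False
        )
        model_rows.append(
            {"replicate_id": rid, "alpha": model.alpha, "beta": model.beta,
             "fit_mode": model.fit_mode, "n_windows": len(model.windows)}
        )
    pd.DataFrame(model_rows).to_csv(out_dir / "model.tsv", sep="\t", index=False)
    result.genes.to_csv(out_dir / "candidates.tsv", sep="\t", index=False)
    _plot_ma(result, out_dir)

    manifest = {
        "tool": "screenma",
        "version": __version__,
        "config": {k: v for k, v in config.items() if k != "fastq"},
        "input_digests": digests,
        "control_medians": {k: float(v) for k, v in result.control_medians.items()},
        "n_controls_retained": len(result.selection.retained_ids),
        "models": model_rows,
        "unassigned_reads": unassigned,
        "n_candidates": int(result.genes["is_candidate"].sum()),
        "candidates": result.candidates,
        "seed": config.get("seed"),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("pipeline complete: %s", out_dir)
    return out_dir
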