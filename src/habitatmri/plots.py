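"""Vector-graphic report figures: ROC, calibration, decision curves and
the nomogram point scales."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_roc", "plot_calibration", "plot_dca", "plot_nomogram",
           "render_report_figures"]


def _roc_points(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    order = np.argsort(-s)
    y = y[order]
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    tpr = np.concatenate([[0], tps / max(y.sum(), 1)])
    fpr = np.concatenate([[0], fps / max((1 - y).sum(), 1)])
    return fpr, tpr


def plot_roc(score_sets: dict[str, tuple], path: Path) -> Path:
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for name, (scores, labels, auc) in score_sets.items():
        fpr, tpr = _roc_points(scores, labels)
        ax.plot(fpr, tpr, label=f"{name} (AUC {auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_calibration(curves: dict[str, "object"], path: Path) -> Path:
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for name, df in curves.items():
        if df is None:
            continue
        ax.plot(df["predicted"], df["observed"], "o-", label=name, ms=3)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("predicted probability")
    ax.set_ylabel("observed rate")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_dca(dca_frames: dict[str, "object"], path: Path) -> Path:
    fig, ax = plt.subplots(figsize=(5, 4))
    first = True
    for name, df in dca_frames.items():
        if df is None:
            continue
        ax.plot(df["threshold"], df["net_benefit"], label=name)
        if first:
            ax.plot(df["threshold"], df["treat_all"], "k:", label="treat all")
            ax.plot(df["threshold"], df["treat_none"], "k--", label="treat none")
            first = False
    ax.set_ylim(bottom=-0.1)
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_nomogram(nomo, path: Path) -> Path:
    """Point-scale view: one axis per component plus total-points->risk."""
    comps = nomo.components_
    fig, axes = plt.subplots(len(comps) + 1, 1, figsize=(6, 1.2 * (len(comps) + 1)))
    for ax, c in zip(axes[:-1], comps):
        lo, hi = nomo.ranges_[c]
        xs = np.linspace(lo, hi, 50)
        ax.plot(xs, nomo.points_for(c, xs))
        ax.set_ylabel("points", fontsize=7)
        ax.set_title(c, fontsize=8)
    total = np.linspace(0, 100 * len(comps), 100)
    axes[-1].plot(total, nomo.probability_for_total_points(total))
    axes[-1].set_xlabel("total points", fontsize=7)
    axes[-1].set_ylabel("P(pCR)", fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def render_report_figures(result, figdir: Path) -> list[Path]:
    figdir = Path(figdir)
    figdir.mkdir(parents=True, exist_ok=True)
    written = []
    scores = result.scores
    if scores is None:
        return written
    for cohort in ("train", "test"):
        score_sets = {}
        calib = {}
        dca = {}
        for (tag, label, coh), rep in result.reports.items():
            if coh != cohort:
                continue
            sub = scores[(scores["model"] == rep.name) & (scores["cohort"] == cohort)]
            score_sets[rep.name] = (sub["score"].to_numpy(),
                                    sub["outcome"].to_numpy(), rep.auc)
            calib[rep.name] = rep.calibration
            dca[rep.name] = rep.dca
        if score_sets:
            written.append(plot_roc(score_sets, figdir / f"roc_{cohort}.svg"))
            written.append(plot_calibration(calib, figdir / f"calibration_{cohort}.svg"))
            written.append(plot_dca(dca, figdir / f"dca_{cohort}.svg"))
    models = getattr(result, "models", {})
    if ("nomogram", "LR") in models:
        written.append(plot_nomogram(models[("nomogram", "LR")],
                                     figdir / "nomogram.svg"))
    return written
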