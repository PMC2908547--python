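"""Segmentation quality metrics and the method-comparison harness.

Two complementary metrics against expert ground truth:

* surface error E_S — the fraction of all image pixels misclassified; it
  weighs background and worm errors equally, and
* nematode yield E_Y — the fraction of the ground-truth worm region that is
  correctly labeled worm; background false positives do not affect it.

``compare_methods`` evaluates two segmentation outputs frame by frame
against a shared ground-truth subset and tabulates mean +/- sd per method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .errors import ContractViolation

__all__ = [
    "EvaluationReport",
    "surface_error",
    "nematode_yield",
    "evaluate_masks",
    "compare_methods",
]


@dataclass
class EvaluationReport:
    """Per-frame and aggregate segmentation quality for one method."""

    method: str
    frames: list[int]
    surface_errors: NDArray[np.float64]
    yields: NDArray[np.float64]

    @property
    def mean_surface_error(self) -> float:
        return float(np.mean(self.surface_errors))

    @property
    def sd_surface_error(self) -> float:
        return float(np.std(self.surface_errors, ddof=1)) if len(self.frames) > 1 else 0.0

    @property
    def mean_yield(self) -> float:
        return float(np.mean(self.yields))

    @property
    def sd_yield(self) -> float:
        return float(np.std(self.yields, ddof=1)) if len(self.frames) > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frames,
                "E_S": self.surface_errors,
                "E_Y": self.yields,
                "method": self.method,
            }
        )


def surface_error(S: NDArray[np.bool_], G: NDArray[np.bool_]) -> float:
    """Fraction of all pixels where the segmentation disagrees with truth."""
    S = np.asarray(S).astype(bool)
    G = np.asarray(G).astype(bool)
    if S.shape != G.shape:
        raise ContractViolation("segmentation and ground truth shapes differ")
    return float(np.mean(S != G))


def nematode_yield(S: NDArray[np.bool_], G: NDArray[np.bool_]) -> float:
    """Fraction of the ground-truth worm region labeled worm."""
    S = np.asarray(S).astype(bool)
    G = np.asarray(G).astype(bool)
    if S.shape != G.shape:
        raise ContractViolation("segmentation and ground truth shapes differ")
    worm = int(G.sum())
    if worm == 0:
        raise ContractViolation("ground truth has no worm pixels; yield undefined")
    return float(np.logical_and(S, G).sum() / worm)


def evaluate_masks(
    predictions: list[NDArray[np.bool_]],
    truths: list[NDArray[np.bool_]],
    method: str = "meme",
    frame_indices: list[int] | None = None,
) -> EvaluationReport:
    if len(predictions) != len(truths) or len(predictions) == 0:
        raise ContractViolation("need equal, non-empty prediction/truth lists")
    idx = frame_indices if frame_indices is not None else list(range(len(truths)))
    es = np.array([surface_error(s, g) for s, g in zip(predictions, truths)])
    ey = np.array([nematode_yield(s, g) for s, g in zip(predictions, truths)])
    return EvaluationReport(
        method=method, frames=list(idx), surface_errors=es, yields=ey
    )


def compare_methods(
    truths: list[NDArray[np.bool_]],
    meme_masks: list[NDArray[np.bool_]],
    baseline_masks: list[NDArray[np.bool_]],
    frame_indices: list[int] | None = None,
) -> tuple[EvaluationReport, EvaluationReport, pd.DataFrame]:
    """Paired evaluation of the model-based and baseline segmentations.

    Returns both per-method reports and a summary table with mean +/- sd of
    E_S and E_Y per method over the shared ground-truth subset.
    """
    if len(truths) == 0:
        raise ContractViolation("empty ground-truth subset")
    rep_meme = evaluate_masks(meme_masks, truths, "meme", frame_indices)
    rep_base = evaluate_masks(baseline_masks, truths, "threshold", frame_indices)
    summary = pd.DataFrame(
        [
            {
                "method": r.method,
                "mean_E_S": r.mean_surface_error,
                "sd_E_S": r.sd_surface_error,
                "mean_E_Y": r.mean_yield,
                "sd_E_Y": r.sd_yield,
                "n_frames": len(r.frames),
            }
            for r in (rep_meme, rep_base)
        ]
    )
    return rep_meme, rep_base, summary
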