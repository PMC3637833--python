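"""Retention-time reproducibility measures and cutoff sweeps.

Two families, each with four submeasures, quantify how reproducible the
retention times of aligned peaks are (smaller is better):

distance-based (seconds)
    DRT1 / DRT2 — mean absolute RT1 / RT2 difference over aligned pairs;
    DMRT — mean of DRT1 and DRT2; DRT — mean Euclidean distance in the
    (RT1, RT2) plane.

variation-based (dimensionless)
    CRT1 / CRT2 — mean coefficient of variation (sample sd / mean) of RT1 /
    RT2 over aligned pairs; CMRT — mean of CRT1 and CRT2; CRT — mean over
    pairs of the per-pair average of the two CVs.  For pairwise alignments
    CRT and CMRT coincide algebraically; both code paths are kept and
    cross-checked.

The global variants replace per-pair quantities with per-chain quantities:
mean pairwise distance among the chain's n retention times, and the CV of
the n retention times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .peaklist import PeakList
from .posthoc import (
    CUTOFF1_GRID,
    GlobalChain,
    PosthocConfig,
    build_chains,
    global_posthoc,
    pairwise_pipeline,
)
from .scoring import PairwiseAlignment, ScorerConfig

MEASURES = ("DRT1", "DRT2", "DMRT", "DRT", "CRT1", "CRT2", "CMRT", "CRT")


class MetricsError(ValueError):
    """Raised for empty inputs: the measures are undefined, not zero."""


@dataclass
class PairwiseMetrics:
    DRT1: float
    DRT2: float
    DMRT: float
    DRT: float
    CRT1: float
    CRT2: float
    CMRT: float
    CRT: float
    n_pairs: int

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass
class GlobalMetrics:
    DRT1: float
    DRT2: float
    DMRT: float
    DRT: float
    CRT1: float
    CRT2: float
    CMRT: float
    CRT: float
    n_chains: int

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _cv(values: np.ndarray) -> float:
    """Coefficient of variation with sample sd (ddof=1)."""
    return float(np.std(values, ddof=1) / np.mean(values))


def pairwise_metrics(
    positive: PairwiseAlignment, a: PeakList, b: PeakList
) -> PairwiseMetrics:
    """Distance- and variation-based measures over an alignment's pairs."""
    if not positive.pairs:
        raise MetricsError("metrics undefined for an empty alignment")
    a1 = np.array([a.peaks[p.index_a].rt1 for p in positive.pairs])
    a2 = np.array([a.peaks[p.index_a].rt2 for p in positive.pairs])
    b1 = np.array([b.peaks[p.index_b].rt1 for p in positive.pairs])
    b2 = np.array([b.peaks[p.index_b].rt2 for p in positive.pairs])

    d1 = np.abs(a1 - b1)
    d2 = np.abs(a2 - b2)
    d = np.hypot(d1, d2)
    # for two values, sample sd = |a - b| / sqrt(2)
    cv1 = (d1 / math.sqrt(2.0)) / ((a1 + b1) / 2.0)
    cv2 = (d2 / math.sqrt(2.0)) / ((a2 + b2) / 2.0)

    drt1 = float(np.mean(d1))
    drt2 = float(np.mean(d2))
    crt1 = float(np.mean(cv1))
    crt2 = float(np.mean(cv2))
    crt = float(np.mean((cv1 + cv2) / 2.0))
    cmrt = (crt1 + crt2) / 2.0
    # CRT and CMRT coincide by linearity of the mean; cross-check both paths
    assert math.isclose(crt, cmrt, rel_tol=1e-9, abs_tol=1e-12)
    return PairwiseMetrics(
        DRT1=drt1,
        DRT2=drt2,
        DMRT=(drt1 + drt2) / 2.0,
        DRT=float(np.mean(d)),
        CRT1=crt1,
        CRT2=crt2,
        CMRT=cmrt,
        CRT=crt,
        n_pairs=len(positive.pairs),
    )


def global_metrics(
    chains: Iterable[GlobalChain], lists: Sequence[PeakList]
) -> GlobalMetrics:
    """Measures over global chains (callers pass the kept chains).

    Per chain the distance terms are the mean over all C(n, 2) within-chain
    pairwise distances (marginal absolute differences for DRT1/DRT2,
    2-D Euclidean for DRT), and the CV terms are sd/mean of the chain's n
    retention times; each measure is then averaged over chains.
    """
    chains = list(chains)
    if not chains:
        raise MetricsError("metrics undefined for an empty chain set")

    per_d1, per_d2, per_d, per_cv1, per_cv2 = [], [], [], [], []
    for chain in chains:
        rt1 = np.array(
            [lists[r].peaks[idx].rt1 for r, idx in enumerate(chain.peak_indices)]
        )
        rt2 = np.array(
            [lists[r].peaks[idx].rt2 for r, idx in enumerate(chain.peak_indices)]
        )
        pairs = list(combinations(range(len(rt1)), 2))
        diffs1 = np.array([abs(rt1[i] - rt1[j]) for i, j in pairs])
        diffs2 = np.array([abs(rt2[i] - rt2[j]) for i, j in pairs])
        per_d1.append(float(np.mean(diffs1)))
        per_d2.append(float(np.mean(diffs2)))
        per_d.append(float(np.mean(np.hypot(diffs1, diffs2))))
        per_cv1.append(_cv(rt1))
        per_cv2.append(_cv(rt2))

    drt1 = float(np.mean(per_d1))
    drt2 = float(np.mean(per_d2))
    crt1 = float(np.mean(per_cv1))
    crt2 = float(np.mean(per_cv2))
    crt = float(np.mean([(c1 + c2) / 2.0 for c1, c2 in zip(per_cv1, per_cv2)]))
    cmrt = (crt1 + crt2) / 2.0
    assert math.isclose(crt, cmrt, rel_tol=1e-9, abs_tol=1e-12)
    return GlobalMetrics(
        DRT1=drt1,
        DRT2=drt2,
        DMRT=(drt1 + drt2) / 2.0,
        DRT=float(np.mean(per_d)),
        CRT1=crt1,
        CRT2=crt2,
        CMRT=cmrt,
        CRT=crt,
        n_chains=len(chains),
    )


@dataclass
class CountSummary:
    counts: tuple[int, ...]
    median: float | None


def count_aligned(alignments: Iterable) -> CountSummary:
    """Per-item aligned-peak counts and their median (midpoint for even n).

    Items may be alignments (counted by their pairs), sized collections such
    as chain lists, or plain integers.
    """
    counts: list[int] = []
    for item in alignments:
        if hasattr(item, "pairs"):
            counts.append(len(item.pairs))
        elif hasattr(item, "__len__"):
            counts.append(len(item))
        else:
            counts.append(int(item))
    if not counts:
        return CountSummary(counts=(), median=None)
    return CountSummary(counts=tuple(counts), median=float(np.median(counts)))


def _nan_measures() -> dict[str, float]:
    return {m: float("nan") for m in MEASURES}


def sweep(
    lists: Sequence[PeakList],
    scorer_cfg: ScorerConfig | None = None,
    cutoff1_grid: Sequence[float] = CUTOFF1_GRID,
    cutoff2_grid: Sequence[int] | None = None,
    *,
    correct_names: bool = False,
    plot_dir: str | None = None,
) -> pd.DataFrame:
    """Performance measures over a cutoff grid.

    Without ``cutoff2_grid`` (pairwise mode) every replicate pair is
    integrated at each cutoff 1; the row holds the measures averaged over
    pairs and the median positive-set size.  With ``cutoff2_grid`` (global
    mode) chains over the contiguous pairs are filtered at each
    (cutoff 1, cutoff 2) combination.  Combinations whose positive sets or
    chain sets are empty get NaN measures and a zero count.  With
    ``plot_dir`` set, trace plots of each measure against cutoff 1 are
    written there as PNG files.
    """
    if len(cutoff1_grid) == 0:
        raise ValueError("cutoff1 grid must be non-empty")
    if cutoff2_grid is not None and len(cutoff2_grid) == 0:
        raise ValueError("cutoff2 grid must be non-empty")
    if len(lists) < 2:
        raise ValueError("sweep requires at least 2 replicates")
    scorer_cfg = scorer_cfg if scorer_cfg is not None else ScorerConfig()

    rows: list[dict] = []
    if cutoff2_grid is None:
        index_pairs = list(combinations(range(len(lists)), 2))
        for c1 in cutoff1_grid:
            cfg = PosthocConfig(cutoff1=c1)
            per_pair = []
            counts = []
            for i, j in index_pairs:
                positive = pairwise_pipeline(lists[i], lists[j], scorer_cfg, cfg)
                counts.append(len(positive))
                try:
                    per_pair.append(pairwise_metrics(positive, lists[i], lists[j]).as_dict())
                except MetricsError:
                    pass
            row: dict = {"cutoff1": c1, "n_pairs": count_aligned(counts).median or 0.0}
            if per_pair:
                for m in MEASURES:
                    row[m] = float(np.mean([p[m] for p in per_pair]))
            else:
                row.update(_nan_measures())
            rows.append(row)
    else:
        for c1 in cutoff1_grid:
            cfg1 = PosthocConfig(cutoff1=c1)
            positives = [
                pairwise_pipeline(lists[i], lists[i + 1], scorer_cfg, cfg1)
                for i in range(len(lists) - 1)
            ]
            chains = build_chains(positives, lists)
            for c2 in cutoff2_grid:
                cfg = PosthocConfig(cutoff1=c1, cutoff2=int(c2), correct_names=correct_names)
                kept = global_posthoc(chains, cfg, n_replicates=len(lists))
                row = {"cutoff1": c1, "cutoff2": int(c2), "n_chains": len(kept)}
                try:
                    row.update(global_metrics(kept, lists).as_dict())
                except MetricsError:
                    row.update(_nan_measures())
                rows.append(row)

    df = pd.DataFrame(rows)
    if plot_dir is not None:
        _emit_plots(df, plot_dir, global_mode=cutoff2_grid is not None)
    return df


def _emit_plots(df: pd.DataFrame, plot_dir: str, *, global_mode: bool) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(plot_dir)
    out.mkdir(parents=True, exist_ok=True)
    for measure in MEASURES:
        if measure not in df.columns:
            continue
        fig, ax = plt.subplots(figsize=(5, 3.5))
        if global_mode:
            for c2, sub in df.groupby("cutoff2"):
                ax.plot(sub["cutoff1"], sub[measure], marker="o", label=f"cutoff2={c2}")
            ax.legend(fontsize=8)
        else:
            ax.plot(df["cutoff1"], df[measure], marker="o")
        ax.set_xlabel("cutoff 1")
        ax.set_ylabel(measure)
        fig.tight_layout()
        fig.savefig(out / f"{measure}.png", dpi=120)
        plt.close(fig)
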