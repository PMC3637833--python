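"""Matching scores and pairwise peak aligners.

Two aligners are provided.  The *naive* aligner matches peaks across two
replicates purely by identical compound identity (the grouping key), the way
library identifications alone would.  The *score* aligner is a best-hit,
one-to-one matcher driven by a mixture matching score in [0, 1],

    score = w * spectral_similarity + (1 - w) * rt_closeness,

combining mass-spectral similarity (cosine of the two intensity vectors, or
Pearson correlation clamped at zero) with a Gaussian closeness kernel on the
two-dimensional retention-time offsets.  The same score, exposed through
:func:`make_scorer`, is what the post-hoc integration uses to cross-check
disputed pairs; any external alignment method's output can stand in for the
score aligner as long as it is expressed as a :class:`PairwiseAlignment`
whose pairs carry scores on this [0, 1] scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .peaklist import Peak, PeakList

PROVENANCES = ("naive", "method", "both")
SPECTRAL_METHODS = ("dot", "pearson")


class ScoringError(ValueError):
    """A score could not be computed (zero-norm spectrum, missing spectrum...)."""


@dataclass
class ScorerConfig:
    """Parameters of the mixture matching score and the score aligner.

    sigma1/sigma2 are the RT tolerance scales (seconds) of the closeness
    kernel; rt_window1/rt_window2 bound the candidate search and default to
    3 sigma.  ``w`` is the weight on spectral similarity.
    """

    spectral_method: str = "dot"
    w: float = 0.5
    sigma1: float = 5.0
    sigma2: float = 0.05
    rt_window1: float | None = None
    rt_window2: float | None = None

    def __post_init__(self) -> None:
        if self.spectral_method not in SPECTRAL_METHODS:
            raise ValueError(
                f"spectral_method must be one of {SPECTRAL_METHODS}, got {self.spectral_method!r}"
            )
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"w must be in [0, 1], got {self.w}")
        if not (self.sigma1 > 0 and self.sigma2 > 0):
            raise ValueError("sigma1 and sigma2 must be > 0")
        if self.rt_window1 is not None and not self.rt_window1 > 0:
            raise ValueError("rt_window1 must be > 0")
        if self.rt_window2 is not None and not self.rt_window2 > 0:
            raise ValueError("rt_window2 must be > 0")

    @property
    def window1(self) -> float:
        return self.rt_window1 if self.rt_window1 is not None else 3.0 * self.sigma1

    @property
    def window2(self) -> float:
        return self.rt_window2 if self.rt_window2 is not None else 3.0 * self.sigma2


@dataclass
class AlignedPair:
    """One matched peak pair: positions in list A and list B, plus provenance.

    ``score`` is the matching score in [0, 1]; naive pairs start unscored
    (None) and are scored lazily by the post-hoc with the active scorer.
    """

    index_a: int
    index_b: int
    score: float | None = None
    provenance: str = "method"

    def __post_init__(self) -> None:
        if self.index_a < 0 or self.index_b < 0:
            raise ValueError("pair indices must be non-negative")
        if self.score is not None and not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must be in [0, 1], got {self.score}")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"provenance must be one of {PROVENANCES}")


@dataclass
class PairwiseAlignment:
    """A set of matched peak pairs between two replicates.

    Aligner outputs are one-to-one (no peak index on either side appears in
    more than one pair).  Post-hoc positive sets, being unions of two
    one-to-one alignments, may relax this; they are constructed with
    ``one_to_one=False``.
    """

    id_a: str
    id_b: str
    pairs: list[AlignedPair] = field(default_factory=list)
    one_to_one: bool = True

    def __post_init__(self) -> None:
        if self.one_to_one:
            left = [p.index_a for p in self.pairs]
            right = [p.index_b for p in self.pairs]
            if len(set(left)) != len(left) or len(set(right)) != len(right):
                raise ValueError(
                    f"alignment {self.id_a}~{self.id_b} violates the one-to-one invariant"
                )

    def __len__(self) -> int:
        return len(self.pairs)

    def index_pairs(self) -> set[tuple[int, int]]:
        return {(p.index_a, p.index_b) for p in self.pairs}


def spectral_similarity(
    x: dict[int, float], y: dict[int, float], method: str = "dot"
) -> float:
    """Similarity in [0, 1] of two spectra aligned onto the union of m/z bins.

    ``dot``: cosine of the two non-negative intensity vectors.  ``pearson``:
    Pearson correlation clamped below at 0 (anti-correlated spectra are
    non-matches, and the post-hoc cutoff grid presumes a similarity scale).
    """
    if method not in SPECTRAL_METHODS:
        raise ValueError(f"unknown spectral method {method!r}")
    bins = sorted(set(x) | set(y))
    if not bins:
        raise ScoringError("both spectra are empty")
    xv = np.array([x.get(b, 0.0) for b in bins], dtype=float)
    yv = np.array([y.get(b, 0.0) for b in bins], dtype=float)
    nx = float(np.linalg.norm(xv))
    ny = float(np.linalg.norm(yv))
    if nx == 0.0 or ny == 0.0:
        raise ScoringError("zero-norm spectrum: similarity undefined")
    if method == "dot":
        return float(np.clip(float(xv @ yv) / (nx * ny), 0.0, 1.0))
    if len(bins) < 2 or np.ptp(xv) == 0.0 or np.ptp(yv) == 0.0:
        raise ScoringError("constant spectrum: Pearson similarity undefined")
    r = float(np.corrcoef(xv, yv)[0, 1])
    return float(np.clip(r, 0.0, 1.0))


def rt_closeness(a: Peak, b: Peak, sigma1: float = 5.0, sigma2: float = 0.05) -> float:
    """Gaussian closeness kernel on the 2-D retention-time offset.

    exp(-[(drt1)^2 / (2 sigma1^2) + (drt2)^2 / (2 sigma2^2)]); equals 1 iff
    both RTs coincide and decreases strictly in each absolute offset.
    """
    if not (sigma1 > 0 and sigma2 > 0):
        raise ValueError("sigmas must be > 0")
    d1 = a.rt1 - b.rt1
    d2 = a.rt2 - b.rt2
    return math.exp(-(d1 * d1 / (2.0 * sigma1 * sigma1) + d2 * d2 / (2.0 * sigma2 * sigma2)))


def mixture_score(a: Peak, b: Peak, cfg: ScorerConfig) -> float:
    """Mixture matching score w*spectral + (1-w)*closeness, in [0, 1]."""
    close = rt_closeness(a, b, cfg.sigma1, cfg.sigma2)
    if cfg.w == 0.0:
        return close
    if a.spectrum is None or b.spectrum is None:
        raise ScoringError(
            "mixture score with w > 0 requires spectra on both peaks"
        )
    spec = spectral_similarity(a.spectrum, b.spectrum, cfg.spectral_method)
    return cfg.w * spec + (1.0 - cfg.w) * close


def make_scorer(cfg: ScorerConfig) -> Callable[[Peak, Peak], float]:
    """Bind a :class:`ScorerConfig` into a ``(Peak, Peak) -> score`` callable."""
    return lambda a, b: mixture_score(a, b, cfg)


def _require_merged(plist: PeakList) -> None:
    if not plist.merged:
        raise ValueError(
            f"alignment requires a merged peak list; {plist.replicate_id!r} is not merged"
        )


def naive_align(a: PeakList, b: PeakList) -> PairwiseAlignment:
    """Align peaks across two merged replicates by identical compound identity.

    One pair per grouping key present in both lists; pairs are unscored at
    this stage (the post-hoc scores them with the active method scorer when
    it needs to cross-check them).
    """
    _require_merged(a)
    _require_merged(b)
    index_a = {p.key: i for i, p in enumerate(a.peaks)}
    index_b = {p.key: i for i, p in enumerate(b.peaks)}
    shared = sorted(set(index_a) & set(index_b))
    pairs = [
        AlignedPair(index_a[key], index_b[key], score=None, provenance="naive")
        for key in shared
    ]
    return PairwiseAlignment(a.replicate_id, b.replicate_id, pairs)


def score_align(a: PeakList, b: PeakList, cfg: ScorerConfig | None = None) -> PairwiseAlignment:
    """Best-hit one-to-one alignment by descending mixture score.

    Candidate pairs are those within the RT search windows; candidates are
    accepted greedily in descending score subject to the one-to-one
    constraint.  Ties are broken by smaller 2-D RT Euclidean distance, then
    by the (order-insensitive) key pair, so the result is deterministic and
    symmetric under swapping the two lists.
    """
    cfg = cfg if cfg is not None else ScorerConfig()
    _require_merged(a)
    _require_merged(b)

    candidates: list[tuple[float, float, tuple[str, str], int, int]] = []
    for i, pa in enumerate(a.peaks):
        for j, pb in enumerate(b.peaks):
            d1 = abs(pa.rt1 - pb.rt1)
            d2 = abs(pa.rt2 - pb.rt2)
            if d1 <= cfg.window1 and d2 <= cfg.window2:
                s = mixture_score(pa, pb, cfg)
                keypair = tuple(sorted((pa.key, pb.key)))
                candidates.append((s, math.hypot(d1, d2), keypair, i, j))

    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    accepted: list[AlignedPair] = []
    for s, _dist, _kp, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        accepted.append(AlignedPair(i, j, score=s, provenance="method"))

    accepted.sort(key=lambda p: (p.index_a, p.index_b))
    return PairwiseAlignment(a.replicate_id, b.replicate_id, accepted)


def write_alignment(
    aln: PairwiseAlignment, a: PeakList, b: PeakList, path: str | Path, *, sep: str = "\t"
) -> None:
    """Write an alignment as a delimited table with keys and provenance."""
    rows = [
        {
            "index_a": p.index_a,
            "index_b": p.index_b,
            "key_a": a.peaks[p.index_a].key,
            "key_b": b.peaks[p.index_b].key,
            "score": p.score,
            "provenance": p.provenance,
        }
        for p in aln.pairs
    ]
    df = pd.DataFrame(rows, columns=["index_a", "index_b", "key_a", "key_b", "score", "provenance"])
    df.to_csv(path, sep=sep, index=False)


def read_alignment(
    path: str | Path, id_a: str, id_b: str, *, sep: str = "\t", one_to_one: bool = True
) -> PairwiseAlignment:
    """Read an alignment table written by :func:`write_alignment`."""
    df = pd.read_csv(path, sep=sep)
    pairs = [
        AlignedPair(
            int(row.index_a),
            int(row.index_b),
            score=None if pd.isna(row.score) else float(row.score),
            provenance=str(row.provenance),
        )
        for row in df.itertuples()
    ]
    return PairwiseAlignment(id_a, id_b, pairs, one_to_one=one_to_one)
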