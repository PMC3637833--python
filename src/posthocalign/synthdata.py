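"""Synthetic homogeneous GCxGC/TOF-MS replicates with exact ground truth.

The generator emulates technical replicates of one biological sample run
under identical conditions: every replicate draws on the same compound
library and differs only through instrument- and software-level noise —
per-replicate retention-time jitter, multiplicative abundance and spectral
intensity noise, peak dropout, misidentification (the software assigns
another library compound's name and CAS), and peak splitting (one compound
eluting as a main peak plus trailing sub-peaks, which is what peak merging
exists to undo).  A :class:`TruthMap` records the true library compound
behind every emitted peak, so alignment precision and recall can be scored
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .peaklist import Peak, PeakList
from .scoring import PairwiseAlignment


@dataclass
class SimConfig:
    """Generator parameters.

    Defaults are sized to a standard-compound mixture: 76 compounds across
    10 technical replicates, RT1 jitter sd 5 s and RT2 jitter sd 0.05 s,
    5% misidentification, 10% dropout, and frequent peak splitting.
    ``noiseless()`` returns a copy with every noise source off.
    """

    n_compounds: int = 76
    n_replicates: int = 10
    rt1_range: tuple[float, float] = (300.0, 3300.0)
    rt2_range: tuple[float, float] = (0.8, 5.0)
    jitter_sd1: float = 5.0
    jitter_sd2: float = 0.05
    area_logsd: float = 0.3
    spectrum_bins: int = 500
    spectrum_sparsity: float = 0.1
    spectral_noise_sd: float = 0.05
    similarity_sd: float = 15.0
    dropout_p: float = 0.1
    misid_p: float = 0.05
    split_p: float = 0.4
    split_max: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("spectrum_sparsity", "dropout_p", "misid_p", "split_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("jitter_sd1", "jitter_sd2", "area_logsd", "spectral_noise_sd", "similarity_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("rt1_range", "rt2_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ValueError(f"{name} must be positive and ordered, got ({lo}, {hi})")
        if self.n_compounds < 1 or self.n_replicates < 1:
            raise ValueError("n_compounds and n_replicates must be >= 1")
        if self.split_max < 1:
            raise ValueError("split_max must be >= 1")

    @classmethod
    def noiseless(cls, **overrides) -> "SimConfig":
        base = dict(
            jitter_sd1=0.0,
            jitter_sd2=0.0,
            area_logsd=0.0,
            spectral_noise_sd=0.0,
            similarity_sd=0.0,
            dropout_p=0.0,
            misid_p=0.0,
            split_p=0.0,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class LibraryCompound:
    compound_id: str
    name: str
    cas: str
    rt1: float
    rt2: float
    area: float
    similarity: int
    spectrum: dict[int, float]


@dataclass
class Library:
    compounds: list[LibraryCompound]

    def __len__(self) -> int:
        return len(self.compounds)

    def __iter__(self):
        return iter(self.compounds)


@dataclass
class AlignmentScore:
    precision: float
    recall: float
    f1: float
    n_true_pairs: int
    n_aligned: int
    n_correct: int


@dataclass
class TruthMap:
    """Ground truth linking emitted peaks back to library compounds.

    ``assignments[replicate_id][i]`` is the compound id of the i-th emitted
    (pre-merging) peak.  Peaks are additionally tracked by object identity,
    so merged lists — whose representatives are members of the emitted
    lists — remain resolvable within the generating session.
    """

    assignments: dict[str, tuple[str, ...]]
    compound_replicates: dict[str, frozenset[str]]
    _by_peak: dict[int, str] = field(default_factory=dict, repr=False)

    def compound_of(self, peak: Peak) -> str:
        try:
            return self._by_peak[id(peak)]
        except KeyError:
            raise KeyError(
                "peak is not tracked by this TruthMap (only peaks emitted by "
                "the generating call are)"
            ) from None

    def true_pairs(self, a: PeakList, b: PeakList) -> set[tuple[int, int]]:
        """Index pairs (i, j) whose peaks stem from the same compound."""
        by_compound_b: dict[str, list[int]] = {}
        for j, peak in enumerate(b.peaks):
            by_compound_b.setdefault(self.compound_of(peak), []).append(j)
        pairs: set[tuple[int, int]] = set()
        for i, peak in enumerate(a.peaks):
            for j in by_compound_b.get(self.compound_of(peak), []):
                pairs.add((i, j))
        return pairs

    def evaluate(self, alignment: PairwiseAlignment, a: PeakList, b: PeakList) -> AlignmentScore:
        """Precision/recall/F1 of an alignment of (possibly merged) lists.

        A pair counts as correct when both peaks stem from the same library
        compound.  Precision is per pair; recall is per compound (the
        fraction of compounds represented in both lists that received at
        least one correct pair), so duplicate correct pairs for one
        compound cannot inflate it.
        """
        compounds_a = {self.compound_of(p) for p in a.peaks}
        compounds_b = {self.compound_of(p) for p in b.peaks}
        n_true = len(compounds_a & compounds_b)
        correct_compounds: set[str] = set()
        n_correct = 0
        for p in alignment.pairs:
            ca = self.compound_of(a.peaks[p.index_a])
            if ca == self.compound_of(b.peaks[p.index_b]):
                n_correct += 1
                correct_compounds.add(ca)
        n_aligned = len(alignment.pairs)
        precision = n_correct / n_aligned if n_aligned else 0.0
        recall = len(correct_compounds) / n_true if n_true else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if (precision + recall) > 0
            else 0.0
        )
        return AlignmentScore(precision, recall, f1, n_true, n_aligned, n_correct)


def _sample_spectrum(rng: np.random.Generator, cfg: SimConfig) -> dict[int, float]:
    mask = rng.random(cfg.spectrum_bins) < cfg.spectrum_sparsity
    if not mask.any():
        mask[int(rng.integers(cfg.spectrum_bins))] = True
    intensities = rng.uniform(0.05, 1.0, size=int(mask.sum()))
    return {int(mz): float(v) for mz, v in zip(np.flatnonzero(mask), intensities)}


def generate_library(cfg: SimConfig) -> Library:
    """Draw the shared compound library, deterministically from the seed."""
    rng = np.random.default_rng([cfg.seed, 0])
    compounds: list[LibraryCompound] = []
    for i in range(cfg.n_compounds):
        compounds.append(
            LibraryCompound(
                compound_id=f"CPD{i:04d}",
                name=f"Compound {i:04d}",
                cas=f"{1000 + i}-{(7 * i) % 100:02d}-{i % 10}",
                rt1=float(rng.uniform(*cfg.rt1_range)),
                rt2=float(rng.uniform(*cfg.rt2_range)),
                area=float(rng.lognormal(mean=15.0, sigma=1.0)),
                similarity=int(rng.integers(870, 960)),
                spectrum=_sample_spectrum(rng, cfg),
            )
        )
    return Library(compounds=compounds)


def _noisy_spectrum(
    rng: np.random.Generator, base: dict[int, float], sd: float
) -> dict[int, float]:
    if sd == 0.0:
        return dict(base)
    factors = np.exp(rng.normal(0.0, sd, size=len(base)))
    return {mz: float(v * f) for (mz, v), f in zip(base.items(), factors)}


def _emit_peak(
    rng: np.random.Generator,
    comp: LibraryCompound,
    cfg: SimConfig,
    *,
    rt1: float,
    rt2: float,
    area: float,
    similarity: int,
) -> Peak:
    return Peak(
        name=comp.name,
        cas=comp.cas,
        rt1=max(rt1, 1e-9),
        rt2=max(rt2, 1e-9),
        area=max(area, 1e-12),
        similarity=int(np.clip(similarity, 0, 999)),
        spectrum=_noisy_spectrum(rng, comp.spectrum, cfg.spectral_noise_sd),
    )


def generate_replicates(
    library: Library, cfg: SimConfig
) -> tuple[list[PeakList], TruthMap]:
    """Emit ``cfg.n_replicates`` peak lists plus the exact truth map.

    Each replicate, in library order: dropout, RT jitter, abundance and
    spectral noise, optional splitting into trailing sub-peaks (smaller
    areas, RT1 offsets of a few seconds, lower similarity), then per-peak
    misidentification that swaps the identity label for another library
    compound's.  With every noise source at zero the replicates reproduce
    the library exactly.
    """
    lists: list[PeakList] = []
    assignments: dict[str, tuple[str, ...]] = {}
    compound_reps: dict[str, set[str]] = {c.compound_id: set() for c in library}
    by_peak: dict[int, str] = {}

    for r in range(cfg.n_replicates):
        rng = np.random.default_rng([cfg.seed, 1 + r])
        rid = f"R{r + 1}"
        peaks: list[Peak] = []
        truth: list[str] = []
        for ci, comp in enumerate(library):
            if rng.random() < cfg.dropout_p:
                continue
            compound_reps[comp.compound_id].add(rid)

            main_sim = comp.similarity + (
                rng.normal(0.0, cfg.similarity_sd) if cfg.similarity_sd > 0 else 0.0
            )
            emitted = [
                _emit_peak(
                    rng,
                    comp,
                    cfg,
                    rt1=comp.rt1 + (rng.normal(0.0, cfg.jitter_sd1) if cfg.jitter_sd1 > 0 else 0.0),
                    rt2=comp.rt2 + (rng.normal(0.0, cfg.jitter_sd2) if cfg.jitter_sd2 > 0 else 0.0),
                    area=comp.area * (math.exp(rng.normal(0.0, cfg.area_logsd)) if cfg.area_logsd > 0 else 1.0),
                    similarity=round(main_sim),
                )
            ]
            if rng.random() < cfg.split_p:
                n_sub = int(rng.integers(1, cfg.split_max + 1))
                main = emitted[0]
                for s in range(n_sub):
                    emitted.append(
                        _emit_peak(
                            rng,
                            comp,
                            cfg,
                            rt1=main.rt1 + (s + 1) * float(rng.uniform(3.0, 6.0)),
                            rt2=main.rt2 + (s + 1) * float(rng.uniform(0.005, 0.02)),
                            area=main.area * float(rng.uniform(0.02, 0.5)),
                            similarity=round(main_sim - float(rng.uniform(5.0, 60.0))),
                        )
                    )
            for peak in emitted:
                if cfg.misid_p > 0 and rng.random() < cfg.misid_p and len(library) > 1:
                    other = int(rng.integers(len(library) - 1))
                    if other >= ci:
                        other += 1
                    wrong = library.compounds[other]
                    peak.name = wrong.name
                    peak.cas = wrong.cas
                peaks.append(peak)
                truth.append(comp.compound_id)
                by_peak[id(peak)] = comp.compound_id

        lists.append(PeakList(replicate_id=rid, peaks=peaks, merged=False))
        assignments[rid] = tuple(truth)

    truth_map = TruthMap(
        assignments=assignments,
        compound_replicates={k: frozenset(v) for k, v in compound_reps.items()},
        _by_peak=by_peak,
    )
    return lists, truth_map


def write_truth(truth: TruthMap, path: str | Path) -> None:
    """Write the truth map as a TSV of (replicate, peak_index, compound)."""
    with Path(path).open("w") as fh:
        fh.write("replicate\tpeak_index\tcompound\n")
        for rid, compounds in truth.assignments.items():
            for i, cid in enumerate(compounds):
                fh.write(f"{rid}\t{i}\t{cid}\n")
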