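"""Post-hoc integration of a naive and a score-based peak alignment.

Pairwise stage: given the name-based (naive) alignment and an alignment
method's output over the same replicate pair, decompose their union into
common pairs (CA) and the two disjoint areas (DA1: naive-only, DA2:
method-only).  CA pairs, aligned by both routes, are kept unconditionally.
Disputed pairs are cross-checked with the method's matching score: a DA1 or
DA2 pair enters the *positive set* only if its score strictly exceeds
cutoff 1.

Global stage: over n ordered replicates, the pairwise positive sets of the
contiguous pairs (E1,E2)...(En-1,En) are chained; a compound is globally
aligned when a connection line runs through every replicate.  Cutoff 2
(> n/2) is then applied to the number of peaks in the chain sharing the
modal compound name; kept chains can optionally have minority names replaced
by the majority name, correcting likely misidentifications.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

from .peaklist import Peak, PeakList
from .scoring import (
    AlignedPair,
    PairwiseAlignment,
    ScorerConfig,
    make_scorer,
    naive_align,
    score_align,
)

#: the cutoff-1 grid used throughout sweeps
CUTOFF1_GRID = (0.5, 0.6, 0.7, 0.8, 0.85, 0.9, 0.93, 0.95, 0.97, 0.99)


@dataclass
class PosthocConfig:
    """cutoff1: matching-score threshold in [0, 1] for disputed pairs
    (strict >).  cutoff2: minimum count of same-named peaks a global chain
    must contain to be kept (must satisfy n/2 < cutoff2 <= n).  When
    ``correct_names`` is set, minority names in kept chains are replaced by
    the consensus name."""

    cutoff1: float = 0.99
    cutoff2: int | None = None
    correct_names: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.cutoff1 <= 1.0:
            raise ValueError(f"cutoff1 must be in [0, 1], got {self.cutoff1}")


@dataclass
class VennPartition:
    """CA / DA1 / DA2 decomposition of two alignments of one replicate pair."""

    ca: list[AlignedPair]
    da1: list[AlignedPair]
    da2: list[AlignedPair]

    @property
    def union_size(self) -> int:
        return len(self.ca) + len(self.da1) + len(self.da2)


@dataclass(frozen=True)
class GlobalChain:
    """One compound's peaks linked through all replicates.

    ``peak_indices[r]`` is the peak's position in replicate r's (merged)
    list; ``names`` are the corresponding identified compound names.
    ``consensus_name`` is the modal name and ``consensus_count`` its
    multiplicity; ``kept`` records the cutoff-2 verdict.
    """

    peak_indices: tuple[int, ...]
    names: tuple[str, ...]
    consensus_name: str
    consensus_count: int
    kept: bool = False

    @property
    def n_replicates(self) -> int:
        return len(self.peak_indices)


def _consensus(names: Sequence[str]) -> tuple[str, int]:
    counts = Counter(names)
    top = max(counts.values())
    # deterministic tie-break among modal names
    name = min(n for n, c in counts.items() if c == top)
    return name, top


def venn_partition(naive: PairwiseAlignment, method: PairwiseAlignment) -> VennPartition:
    """Decompose two alignments of the same replicate pair into CA/DA1/DA2.

    Pair identity is equality of (index_a, index_b).  CA pairs carry the
    method's score and provenance ``both``; DA1/DA2 keep their originals.
    """
    if (naive.id_a, naive.id_b) != (method.id_a, method.id_b):
        raise ValueError(
            f"alignments cover different replicate pairs: "
            f"{naive.id_a}~{naive.id_b} vs {method.id_a}~{method.id_b}"
        )
    method_by_key = {(p.index_a, p.index_b): p for p in method.pairs}
    naive_keys = {(p.index_a, p.index_b) for p in naive.pairs}

    ca: list[AlignedPair] = []
    da1: list[AlignedPair] = []
    for p in naive.pairs:
        m = method_by_key.get((p.index_a, p.index_b))
        if m is not None:
            ca.append(replace(m, provenance="both"))
        else:
            da1.append(replace(p))
    da2 = [replace(p) for p in method.pairs if (p.index_a, p.index_b) not in naive_keys]
    return VennPartition(ca=ca, da1=da1, da2=da2)


def _scored(
    pair: AlignedPair, a: PeakList, b: PeakList, scorer: Callable[[Peak, Peak], float]
) -> AlignedPair:
    if pair.score is not None:
        return pair
    return replace(pair, score=scorer(a.peaks[pair.index_a], b.peaks[pair.index_b]))


def pairwise_posthoc(
    naive: PairwiseAlignment,
    method: PairwiseAlignment,
    a: PeakList,
    b: PeakList,
    scorer: Callable[[Peak, Peak], float],
    cfg: PosthocConfig,
) -> PairwiseAlignment:
    """Integrate two alignments of one replicate pair into the positive set.

    positive = CA  ∪  {p in DA1 : score(p) > cutoff1}
                   ∪  {p in DA2 : score(p) > cutoff1}.

    CA pairs are kept without a score test.  Unscored disputed pairs (all of
    DA1, typically) are scored on the spot with ``scorer`` — the scoring
    system of the active alignment method.  The result retains each pair's
    provenance and score; it is returned with the one-to-one check relaxed
    because the union of two one-to-one alignments need not be one-to-one.
    """
    venn = venn_partition(naive, method)
    positive = list(venn.ca)
    for disputed in (venn.da1, venn.da2):
        for pair in disputed:
            pair = _scored(pair, a, b, scorer)
            if pair.score > cfg.cutoff1:
                positive.append(pair)
    return PairwiseAlignment(naive.id_a, naive.id_b, positive, one_to_one=False)


def build_chains(
    positives: Sequence[PairwiseAlignment], lists: Sequence[PeakList]
) -> list[GlobalChain]:
    """Chain positive pairs of contiguous replicate pairs into global chains.

    ``positives[i]`` must align ``lists[i]`` with ``lists[i+1]``.  A chain
    exists iff every consecutive link is a positive pair; chains that do not
    span all replicates are discarded.  When the positive sets are
    one-to-one the chains are vertex-disjoint; positive sets that relax
    one-to-one can branch, and every complete path is returned.
    """
    n = len(lists)
    if n < 2:
        raise ValueError("global chaining requires at least 2 replicates")
    if len(positives) != n - 1:
        raise ValueError(
            f"expected {n - 1} contiguous pairwise alignments for {n} replicates, "
            f"got {len(positives)}"
        )
    for i, aln in enumerate(positives):
        if (aln.id_a, aln.id_b) != (lists[i].replicate_id, lists[i + 1].replicate_id):
            raise ValueError(
                f"alignment {i} covers {aln.id_a}~{aln.id_b}, expected "
                f"{lists[i].replicate_id}~{lists[i + 1].replicate_id}"
            )

    adjacency: list[dict[int, list[int]]] = []
    for aln in positives:
        adj: dict[int, list[int]] = {}
        for p in aln.pairs:
            adj.setdefault(p.index_a, []).append(p.index_b)
        for targets in adj.values():
            targets.sort()
        adjacency.append(adj)

    paths: list[list[int]] = [
        [p.index_a, p.index_b] for p in sorted(positives[0].pairs, key=lambda p: (p.index_a, p.index_b))
    ]
    for adj in adjacency[1:]:
        paths = [path + [j] for path in paths for j in adj.get(path[-1], [])]

    chains: list[GlobalChain] = []
    for path in paths:
        names = tuple(lists[r].peaks[idx].name for r, idx in enumerate(path))
        name, count = _consensus(names)
        chains.append(
            GlobalChain(
                peak_indices=tuple(path),
                names=names,
                consensus_name=name,
                consensus_count=count,
            )
        )
    return chains


def global_posthoc(
    chains: Iterable[GlobalChain],
    cfg: PosthocConfig,
    *,
    n_replicates: int | None = None,
) -> list[GlobalChain]:
    """Apply cutoff 2 (and optional majority-name correction) to global chains.

    A chain is kept iff its consensus count is at least cutoff 2; cutoff 2
    must exceed n/2 (otherwise the majority verdict is undefined) and be at
    most n.  Name correction replaces minority names with the consensus name
    in kept chains only; it never changes which chains are kept.
    """
    chains = list(chains)
    if n_replicates is None:
        if not chains:
            return []
        n_replicates = chains[0].n_replicates
    if any(c.n_replicates != n_replicates for c in chains):
        raise ValueError("chains span differing numbers of replicates")
    if cfg.cutoff2 is None:
        raise ValueError("global post-hoc requires cutoff2")
    if not (n_replicates / 2 < cfg.cutoff2 <= n_replicates):
        raise ValueError(
            f"cutoff2 must satisfy n/2 < cutoff2 <= n (n={n_replicates}), got {cfg.cutoff2}"
        )

    kept: list[GlobalChain] = []
    for chain in chains:
        if chain.consensus_count < cfg.cutoff2:
            continue
        # with cutoff2 > n/2 only one name can reach it
        assert sum(1 for _, c in Counter(chain.names).items() if c >= cfg.cutoff2) <= 1
        if cfg.correct_names and chain.consensus_count < chain.n_replicates:
            corrected = tuple(chain.consensus_name for _ in chain.names)
            chain = replace(
                chain,
                names=corrected,
                consensus_count=chain.n_replicates,
                kept=True,
            )
        else:
            chain = replace(chain, kept=True)
        kept.append(chain)
    return kept


def pairwise_pipeline(
    a: PeakList,
    b: PeakList,
    scorer_cfg: ScorerConfig | None = None,
    cfg: PosthocConfig | None = None,
) -> PairwiseAlignment:
    """Naive align + score align + pairwise post-hoc, in one call."""
    scorer_cfg = scorer_cfg if scorer_cfg is not None else ScorerConfig()
    cfg = cfg if cfg is not None else PosthocConfig()
    naive = naive_align(a, b)
    method = score_align(a, b, scorer_cfg)
    return pairwise_posthoc(naive, method, a, b, make_scorer(scorer_cfg), cfg)


def global_pipeline(
    lists: Sequence[PeakList],
    scorer_cfg: ScorerConfig | None = None,
    cfg: PosthocConfig | None = None,
) -> list[GlobalChain]:
    """Pairwise post-hoc on every contiguous pair, chain, and apply cutoff 2."""
    scorer_cfg = scorer_cfg if scorer_cfg is not None else ScorerConfig()
    cfg = cfg if cfg is not None else PosthocConfig()
    positives = [
        pairwise_pipeline(lists[i], lists[i + 1], scorer_cfg, cfg)
        for i in range(len(lists) - 1)
    ]
    chains = build_chains(positives, lists)
    return global_posthoc(chains, cfg, n_replicates=len(lists))
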