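"""Small built-in example inputs used in the documentation and tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .peaklist import Peak, PeakList
from .scoring import AlignedPair, PairwiseAlignment

#: five detected peaks of pyridine (CAS 110-86-1) from a standard-compound
#: mixture run — the classic multi-peak group that peak merging collapses.
_PYRIDINE_ROWS = (
    ("Pyridine", "110-86-1", 369.719, 1.162, 28831918, 943),
    ("Pyridine", "110-86-1", 379.711, 1.175, 2788666, 948),
    ("Pyridine", "110-86-1", 384.707, 1.188, 925142, 931),
    ("Pyridine", "110-86-1", 389.704, 1.208, 548115, 914),
    ("Pyridine", "110-86-1", 394.7, 1.214, 569849, 882),
)


def pyridine_standards() -> PeakList:
    """The five pyridine peaks as an (unmerged) PeakList."""
    peaks = [
        Peak(name=n, cas=c, rt1=r1, rt2=r2, area=a, similarity=s)
        for n, c, r1, r2, a, s in _PYRIDINE_ROWS
    ]
    return PeakList(replicate_id="std_mixture", peaks=peaks)


@dataclass
class PairwiseDemo:
    """A worked pairwise-integration instance with known section sizes.

    Two replicates share 49 compounds aligned by both name and score (CA);
    7 compounds are name-aligned only (DA1), of which the last three carry
    matching RTs and spectra (high matching score) while the first four
    were genuinely misidentified (distant RTs, disjoint spectra); and 8
    pairs come from the external method only (DA2), with scores such that
    exactly two clear the recommended cutoff.
    """

    a: PeakList
    b: PeakList
    method: PairwiseAlignment
    cutoff1: float
    expected_ca: int = 49
    expected_da1: int = 7
    expected_da2: int = 8
    expected_positive: int = 54


def pairwise_demo(seed: int = 0) -> PairwiseDemo:
    """Build the worked pairwise instance (49 CA + 7 DA1 + 8 DA2 pairs).

    The two peak lists are constructed so that the name-based aligner finds
    56 pairs; the external method's alignment (57 pairs) is supplied as a
    ready-made :class:`PairwiseAlignment`, standing in for any score-based
    alignment method's output.  ``seed`` only perturbs peak areas; the
    combinatorial structure is fixed.
    """
    rng = np.random.default_rng(seed)
    peaks_a: list[Peak] = []
    peaks_b: list[Peak] = []

    def add(side: list[Peak], name: str, cas: str, rt1: float, rt2: float, mz: int) -> None:
        side.append(
            Peak(
                name=name,
                cas=cas,
                rt1=rt1,
                rt2=rt2,
                area=float(rng.uniform(1e5, 1e7)),
                similarity=900,
                spectrum={mz: 1.0},
            )
        )

    # 49 compounds aligned by both routes: same identity, same RT, same spectrum
    for i in range(49):
        name, cas = f"Shared {i:02d}", f"5{i:03d}-00-{i % 10}"
        rt1, rt2 = 400.0 + 30.0 * i, 1.0 + 0.05 * i
        add(peaks_a, name, cas, rt1, rt2, mz=i)
        add(peaks_b, name, cas, rt1, rt2, mz=i)

    # 7 name-aligned-only compounds; the last three score highly
    for j in range(7):
        name, cas = f"NameOnly {j}", f"7{j:03d}-00-{j}"
        if j >= 4:
            rt1, rt2 = 2200.0 + 50.0 * j, 3.0 + 0.05 * j
            add(peaks_a, name, cas, rt1, rt2, mz=100 + j)
            add(peaks_b, name, cas, rt1, rt2, mz=100 + j)
        else:
            rt1, rt2 = 2200.0 + 50.0 * j, 3.0 + 0.05 * j
            add(peaks_a, name, cas, rt1, rt2, mz=200 + j)
            add(peaks_b, name, cas, rt1 + 600.0, min(rt2 + 1.5, 5.9), mz=300 + j)

    # 8 method-aligned-only pairs: different identities, so names cannot match
    for k in range(8):
        rt1, rt2 = 2900.0 + 40.0 * k, 2.0 + 0.05 * k
        add(peaks_a, f"MethodA {k}", f"8{k:03d}-00-{k}", rt1, rt2, mz=400 + k)
        add(peaks_b, f"MethodB {k}", f"9{k:03d}-00-{k}", rt1, rt2, mz=400 + k)

    a = PeakList(replicate_id="E1", peaks=peaks_a, merged=True)
    b = PeakList(replicate_id="E2", peaks=peaks_b, merged=True)

    method_pairs = [AlignedPair(i, i, score=1.0, provenance="method") for i in range(49)]
    for k in range(8):
        idx = 56 + k
        score = 0.95 if k < 2 else 0.2
        method_pairs.append(AlignedPair(idx, idx, score=score, provenance="method"))
    method = PairwiseAlignment("E1", "E2", method_pairs)

    return PairwiseDemo(a=a, b=b, method=method, cutoff1=0.9)
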