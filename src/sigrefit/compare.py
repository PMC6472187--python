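"""Distances between signatures and mappings between signature sets."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .decompose import flatten

__all__ = [
    "signature_distance",
    "SignatureMapping",
    "map_signature_sets",
    "pairwise_distance_summary",
]

METRICS = ("frobenius", "l1", "cosine")


def _compatible(s1, s2) -> None:
    if type(s1) is not type(s2):
        raise ValueError("signatures have different representations")
    if getattr(s1, "spec", None) != getattr(s2, "spec", None):
        raise ValueError(f"context specs differ: {s1.spec} vs {s2.spec}")


def signature_distance(s1, s2, metric: str = "frobenius") -> float:
    """Distance between two signatures of identical representation.

    ``frobenius`` — sqrt of the summed squared elementwise differences of
    the (padded) matrices; identical to the Euclidean distance of the
    flattened parameter vectors because the zero pads cancel.  ``l1`` —
    rectilinear distance; ``cosine`` — 1 minus the cosine similarity of the
    flattened vectors.
    """
    _compatible(s1, s2)
    v1, v2 = flatten(s1), flatten(s2)
    if metric == "frobenius":
        return float(np.linalg.norm(v1 - v2))
    if metric == "l1":
        return float(np.abs(v1 - v2).sum())
    if metric == "cosine":
        denom = np.linalg.norm(v1) * np.linalg.norm(v2)
        if denom == 0:
            raise ValueError("cosine distance undefined for zero signatures")
        # clamp float rounding so d(s, s) is exactly 0
        return float(max(0.0, 1.0 - (v1 @ v2) / denom))
    raise ValueError(f"unknown metric {metric!r} (choose from {METRICS})")


@dataclass
class SignatureMapping:
    """A mapping from one signature set to another.

    ``pairs`` holds (source name, target name, distance) triples; with
    ``method="one_to_one"`` the assignment is injective and minimizes the
    total distance (optimal linear assignment).
    """

    pairs: list[tuple[str, str, float]]
    method: str
    metric: str

    def as_dict(self) -> dict[str, str]:
        return {a: b for a, b, _ in self.pairs}

    @property
    def total_distance(self) -> float:
        return sum(d for _, _, d in self.pairs)


def map_signature_sets(A, B, method: str = "nearest",
                       metric: str = "frobenius") -> SignatureMapping:
    """Map each signature in A onto a signature in B.

    ``nearest`` maps every A-signature to its minimum-distance B-signature
    (many-to-one allowed); ``one_to_one`` computes the injective assignment
    of minimum total distance via the Hungarian algorithm; ``greedy``
    assigns sequentially by ascending pair distance, for strict reproduction
    of greedy matchers.
    """
    A, B = list(A), list(B)
    if not A or not B:
        raise ValueError("both signature sets must be non-empty")
    D = np.array([[signature_distance(a, b, metric) for b in B] for a in A])
    pairs: list[tuple[str, str, float]] = []
    if method == "nearest":
        for i, a in enumerate(A):
            j = int(np.argmin(D[i]))
            pairs.append((a.name, B[j].name, float(D[i, j])))
    elif method == "one_to_one":
        if len(A) > len(B):
            raise ValueError(
                f"one_to_one mapping impossible: |A|={len(A)} > |B|={len(B)}")
        rows, cols = scipy.optimize.linear_sum_assignment(D)
        for i, j in zip(rows, cols):
            pairs.append((A[i].name, B[j].name, float(D[i, j])))
    elif method == "greedy":
        if len(A) > len(B):
            raise ValueError(
                f"greedy injective mapping impossible: |A|={len(A)} > |B|={len(B)}")
        order = np.dstack(np.unravel_index(np.argsort(D, axis=None), D.shape))[0]
        used_a: set[int] = set()
        used_b: set[int] = set()
        for i, j in order:
            if i in used_a or j in used_b:
                continue
            used_a.add(int(i))
            used_b.add(int(j))
            pairs.append((A[i].name, B[j].name, float(D[i, j])))
        pairs.sort(key=lambda p: [a.name for a in A].index(p[0]))
    else:
        raise ValueError(f"unknown method {method!r}")
    return SignatureMapping(pairs, method, metric)


def pairwise_distance_summary(signatures, metric: str = "frobenius"
                              ) -> tuple[float, float, np.ndarray]:
    """Mean, standard deviation (unbiased, n-1) and full matrix of all
    unordered pairwise distances within a signature set."""
    sigs = list(signatures)
    if len(sigs) < 2:
        raise ValueError("need at least two signatures")
    n = len(sigs)
    D = np.zeros((n, n))
    dists = []
    for i in range(n):
        for j in range(i + 1, n):
            d = signature_distance(sigs[i], sigs[j], metric)
            D[i, j] = D[j, i] = d
            dists.append(d)
    dists = np.array(dists)
    sd = float(dists.std(ddof=1)) if len(dists) > 1 else 0.0
    return float(dists.mean()), sd, D
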