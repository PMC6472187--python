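"""Signature refitting: constrained quadratic programming on the simplex.

Given a tumor catalog g and a P x K matrix S of signatures in the same
representation, the exposures w solve

    minimize (g - S w)^T (g - S w)
    subject to  sum_s w_s = 1,  w_s >= 0,

equivalently  minimize -g^T S w + 1/2 w^T (S^T S) w  on the simplex.  The
Gram matrix S^T S may be only positive *semi*-definite; it is replaced by
its nearest positive definite matrix (a negligible perturbation in
practice) before solving, while residuals and explained variance are always
evaluated against the original, uncorrected S.

The strictly convex QP is solved by reducing it to a non-negative
least-squares problem on the Cholesky factor of the corrected Gram matrix,
with the simplex equality enforced through a strongly weighted penalty row;
the resulting active-set solve recovers exact decompositions to machine
precision.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize

from .sigmodel import (
    AlexandrovSignature,
    ContextSpec,
    GenomeProfile,
    ShiraishiSignature,
    flat_genome,
)

__all__ = [
    "ExposureVector",
    "DecompositionResult",
    "flatten",
    "signature_matrix",
    "nearest_positive_definite",
    "SimplexSolver",
    "solve_exposures",
    "explained_variance",
    "decompose_tumor",
    "explained_variance_curve",
]

logger = logging.getLogger("sigrefit")

#: eigenvalue floor for the PD correction, relative to the spectral norm
PD_EPS = 1e-8
#: weight of the simplex-equality penalty row in the NNLS reduction
EQUALITY_WEIGHT = 1e4
#: fitted weights below this are clamped to zero and the rest renormalized
WEIGHT_CLAMP = 1e-8
#: exhaustive subset enumeration refuses more than this many combinations
SUBSET_CAP = 200_000


def flatten(obj) -> np.ndarray:
    """Flatten a signature or profile into its length-P parameter vector.

    Shiraishi matrices are flattened row-major over the valid (unpadded)
    entries — change row (6), flanking rows (4 each), strand row (2);
    Alexandrov vectors are returned as-is (P = 96).
    """
    if isinstance(obj, AlexandrovSignature):
        return np.asarray(obj.probs, dtype=float)
    if isinstance(obj, ShiraishiSignature):
        values, spec = obj.matrix, obj.spec
    elif isinstance(obj, GenomeProfile):
        if obj.spec.model == "alexandrov":
            return np.asarray(obj.values, dtype=float)
        values, spec = obj.values, obj.spec
    elif isinstance(obj, np.ndarray):
        return np.asarray(obj, dtype=float).ravel()
    else:
        raise TypeError(f"cannot flatten {type(obj)!r}")
    return np.concatenate(
        [values[r, :w] for r, w in enumerate(spec.row_widths())])


def _common_spec(signatures) -> ContextSpec:
    specs = {s.spec for s in signatures}
    if len(specs) != 1:
        raise ValueError(f"signatures mix context specs: {sorted(map(str, specs))}")
    return next(iter(specs))


def signature_matrix(signatures) -> np.ndarray:
    """Stack signatures column-wise into the P x K matrix S."""
    if len(signatures) == 0:
        raise ValueError("empty signature set")
    _common_spec(signatures)
    return np.column_stack([flatten(s) for s in signatures])


# ---------------------------------------------------------------------------
# positive definiteness
# ---------------------------------------------------------------------------

def nearest_positive_definite(M: np.ndarray, eps: float = PD_EPS) -> np.ndarray:
    """Nearest symmetric positive definite matrix in the Frobenius sense.

    If M is already positive definite (smallest eigenvalue above
    ``eps * spectral_norm``), M is returned unchanged.  Otherwise the
    eigenvalues are clipped at that floor and the matrix reassembled — the
    minimal-Frobenius projection onto the PD cone up to the clipping floor —
    iterating with a growing jitter until a Cholesky factorization succeeds.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {M.shape}")
    if not np.allclose(M, M.T, rtol=0, atol=1e-12 * max(1.0, np.abs(M).max())):
        raise ValueError("matrix is not symmetric")
    eigvals = scipy.linalg.eigvalsh(M)
    norm = eigvals[-1] if eigvals[-1] > 0 else 1.0
    if eigvals[0] > eps * norm:
        return M
    B = (M + M.T) / 2.0
    vals, vecs = scipy.linalg.eigh(B)
    floor = eps * max(vals[-1], np.finfo(float).tiny)
    vals = np.maximum(vals, floor)
    A = (vecs * vals) @ vecs.T
    A = (A + A.T) / 2.0
    jitter = floor
    for _ in range(100):
        try:
            scipy.linalg.cholesky(A, lower=True)
            return A
        except scipy.linalg.LinAlgError:
            A = A + jitter * np.eye(A.shape[0])
            jitter *= 10.0
    raise np.linalg.LinAlgError("PD correction failed to converge")


# ---------------------------------------------------------------------------
# the QP solve
# ---------------------------------------------------------------------------

@dataclass
class ExposureVector:
    """Per-signature weights of one tumor on the probability simplex."""

    weights: np.ndarray
    signature_ids: tuple[str, ...]
    tumor: str = "tumor"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.signature_ids):
            raise ValueError("one weight per signature required")
        if np.any(self.weights < -1e-12):
            raise ValueError("negative exposure")
        if abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError(f"exposures sum to {self.weights.sum():.12g}, not 1")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.signature_ids, self.weights))


@dataclass
class DecompositionResult:
    """Outcome of refitting one tumor against a signature set."""

    exposures: ExposureVector
    rss: float
    explained_variance: float
    subset: tuple[str, ...]
    spec: ContextSpec
    n_mutations: int | None = None
    threshold_reached: bool | None = field(default=None)
    # None: no threshold was requested


class SimplexSolver:
    """Precomputed simplex-constrained least-squares solver for one S.

    Building the PD-corrected Gram matrix and its Cholesky factor once lets
    many genomes be refit against the same signature set cheaply.
    """

    def __init__(self, S: np.ndarray, equality_weight: float = EQUALITY_WEIGHT):
        S = np.asarray(S, dtype=float)
        if S.ndim != 2:
            raise ValueError("S must be a P x K matrix")
        self.S = S
        self.K = S.shape[1]
        gram = S.T @ S
        self.gram_corrected = nearest_positive_definite(gram)
        try:
            self._L = scipy.linalg.cholesky(self.gram_corrected, lower=True)
        except scipy.linalg.LinAlgError as exc:   # pragma: no cover
            raise RuntimeError(
                "QP setup failed: corrected Gram matrix not positive definite "
                f"(cond={np.linalg.cond(gram):.3g})") from exc
        lam = equality_weight
        self._A = np.vstack([self._L.T, lam * np.ones((1, self.K))])
        self._lam = lam

    def solve(self, g: np.ndarray) -> tuple[np.ndarray, float]:
        """Return (w, rss) minimizing ||g - S w||^2 on the simplex.

        rss is evaluated against the original, uncorrected S.
        """
        g = np.asarray(g, dtype=float)
        if g.shape != (self.S.shape[0],):
            raise ValueError(
                f"profile length {g.shape} does not match P={self.S.shape[0]}")
        d = self.S.T @ g
        z = scipy.linalg.solve_triangular(self._L, d, lower=True)
        b = np.concatenate([z, [self._lam]])
        try:
            w, _ = scipy.optimize.nnls(self._A, b)
        except Exception as exc:
            raise RuntimeError(
                "QP solve failed "
                f"(K={self.K}, cond(S^T S)={np.linalg.cond(self.S.T @ self.S):.3g})"
            ) from exc
        w[w < WEIGHT_CLAMP] = 0.0
        total = w.sum()
        if total <= 0:   # pragma: no cover - cannot happen with the penalty row
            raise RuntimeError("QP solve returned the zero vector")
        w = w / total
        resid = g - self.S @ w
        return w, float(resid @ resid)


def solve_exposures(g, signatures_or_S, signature_ids=None, tumor="tumor"
                    ) -> tuple[ExposureVector, float]:
    """One-shot simplex-constrained refit of a single profile.

    ``g`` may be a GenomeProfile or a flat vector; ``signatures_or_S`` a list
    of signatures or a prebuilt P x K matrix.  Returns (exposures, rss).
    """
    if isinstance(g, GenomeProfile):
        tumor = g.sample
        g = flatten(g)
    if isinstance(signatures_or_S, np.ndarray):
        S = signatures_or_S
        ids = tuple(signature_ids) if signature_ids is not None else tuple(
            f"s{i + 1}" for i in range(S.shape[1]))
    else:
        S = signature_matrix(signatures_or_S)
        ids = tuple(s.name for s in signatures_or_S)
    w, rss = SimplexSolver(S).solve(np.asarray(g, dtype=float))
    return ExposureVector(w, ids, tumor=tumor), rss


# ---------------------------------------------------------------------------
# explained variance
# ---------------------------------------------------------------------------

def _reference_vector(g: np.ndarray, spec: ContextSpec) -> np.ndarray:
    if spec.model == "alexandrov":
        return np.full_like(g, g.mean())
    return flatten(flat_genome(spec))


def explained_variance(g, S=None, w=None, spec: ContextSpec | None = None,
                       g_hat=None) -> float:
    """Coefficient of determination R^2 = 1 - RSS / baseline deviation.

    The baseline is the deviation of g from the flat genome: for the
    Alexandrov model the flat genome (1/96 everywhere) coincides with the
    mean of g, giving the textbook R^2; for the Shiraishi model the flat
    genome has 1/6, 1/4 and 1/2 per feature state and replaces the mean.

    Accepts either ``g_hat`` directly or ``S`` and ``w`` to form g_hat = S w.
    """
    if isinstance(g, GenomeProfile):
        spec = g.spec
        g = flatten(g)
    if spec is None:
        raise ValueError("spec required when g is a plain vector")
    g = np.asarray(g, dtype=float)
    if g_hat is None:
        if S is None or w is None:
            raise ValueError("provide g_hat, or S and w")
        g_hat = np.asarray(S, dtype=float) @ np.asarray(w, dtype=float)
    ref = _reference_vector(g, spec)
    denom = float(np.sum((g - ref) ** 2))
    if denom <= 0:
        raise ValueError(
            "explained variance undefined: profile equals the flat genome")
    rss = float(np.sum((g - np.asarray(g_hat, dtype=float)) ** 2))
    return 1.0 - rss / denom


# ---------------------------------------------------------------------------
# subset selection
# ---------------------------------------------------------------------------

def _fit_subset(g, S, ids, subset, spec, tumor, n_mutations):
    sub = list(subset)
    w, rss = SimplexSolver(S[:, sub]).solve(g)
    full_w = np.zeros(S.shape[1])
    full_w[sub] = w
    ev = explained_variance(g, spec=spec, g_hat=S[:, sub] @ w)
    exposures = ExposureVector(full_w, ids, tumor=tumor)
    return DecompositionResult(exposures, rss, ev,
                               tuple(ids[i] for i in sub), spec,
                               n_mutations=n_mutations)


def decompose_tumor(profile: GenomeProfile, signatures,
                    min_explained_variance: float | None = None,
                    min_num_signatures: int = 2,
                    max_num_signatures: int | None = None,
                    subset_cap: int = SUBSET_CAP,
                    greedy: bool = False) -> DecompositionResult:
    """Refit one tumor, optionally searching for a minimal signature subset.

    Without ``min_explained_variance`` the full set is used (or, if
    ``max_num_signatures`` is below K, the exhaustively best subset of
    exactly that size).  With a threshold, subset sizes k from
    ``min_num_signatures`` upward are enumerated exhaustively; the search
    stops at the first k where some subset reaches the threshold and returns
    the subset with the highest explained variance at that k.  If no subset
    reaches the threshold, the overall best result is returned with
    ``threshold_reached=False``.  Ties are broken by lexicographic subset
    order.  Enumeration beyond ``subset_cap`` combinations per size either
    raises or, with ``greedy``, falls back to forward selection.
    """
    sigs = list(signatures)
    if not sigs:
        raise ValueError("empty signature set")
    if profile.spec != _common_spec(sigs):
        raise ValueError("profile and signatures have different context specs")
    K = len(sigs)
    ids = tuple(s.name for s in sigs)
    max_k = K if max_num_signatures is None else max_num_signatures
    if not (1 <= max_k <= K):
        raise ValueError(f"max_num_signatures must be in [1, {K}]")
    if min_num_signatures > max_k:
        raise ValueError("min_num_signatures exceeds max_num_signatures")
    g = flatten(profile)
    S = signature_matrix(sigs)
    nm = profile.n_mutations

    def best_of_size(k: int) -> DecompositionResult:
        n_comb = math.comb(K, k)
        if n_comb > subset_cap:
            if not greedy:
                raise ValueError(
                    f"C({K},{k})={n_comb} subsets exceeds cap {subset_cap}; "
                    "pass greedy=True for forward selection")
            return _greedy_of_size(k)
        best = None
        for subset in itertools.combinations(range(K), k):
            res = _fit_subset(g, S, ids, subset, profile.spec,
                              profile.sample, nm)
            if best is None or res.explained_variance > best.explained_variance:
                best = res
        return best

    def _greedy_of_size(k: int) -> DecompositionResult:
        chosen: list[int] = []
        best = None
        for _ in range(k):
            step_best, step_idx = None, None
            for j in range(K):
                if j in chosen:
                    continue
                res = _fit_subset(g, S, ids, chosen + [j], profile.spec,
                                  profile.sample, nm)
                if step_best is None or res.explained_variance > step_best.explained_variance:
                    step_best, step_idx = res, j
            chosen.append(step_idx)
            best = step_best
        return best

    if min_explained_variance is None:
        if max_k == K:
            res = _fit_subset(g, S, ids, range(K), profile.spec,
                              profile.sample, nm)
        else:
            res = best_of_size(max_k)
        return res

    overall_best = None
    for k in range(min_num_signatures, max_k + 1):
        res = best_of_size(k)
        if overall_best is None or res.explained_variance > overall_best.explained_variance:
            overall_best = res
        if res.explained_variance >= min_explained_variance:
            res.threshold_reached = True
            logger.info("%s: %d signatures reach R^2=%.4f (threshold %.4f)",
                        profile.sample, k, res.explained_variance,
                        min_explained_variance)
            return res
    overall_best.threshold_reached = False
    logger.info("%s: threshold %.4f not reached; best R^2=%.4f",
                profile.sample, min_explained_variance,
                overall_best.explained_variance)
    return overall_best


def explained_variance_curve(profile: GenomeProfile, signatures,
                             subset_cap: int = SUBSET_CAP,
                             greedy: bool = False):
    """Best explained variance as a function of subset size k = 1..K.

    Returns a list of (k, best_explained_variance, best_subset_ids); the
    curve is non-decreasing in k because any smaller subset embeds into a
    larger one with zero weights.
    """
    sigs = list(signatures)
    rows = []
    for k in range(1, len(sigs) + 1):
        res = decompose_tumor(profile, sigs, min_num_signatures=k,
                              max_num_signatures=k, subset_cap=subset_cap,
                              greedy=greedy)
        rows.append((k, res.explained_variance, res.subset))
    return rows
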