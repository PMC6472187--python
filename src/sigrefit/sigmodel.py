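"""Core data model for mutational signatures and tumor mutational catalogs.

Two signature parameterizations are supported:

* the *Alexandrov* model — a joint probability distribution over the 96
  pyrimidine-centered trinucleotide mutation categories (6 substitution
  classes x 4 five-prime bases x 4 three-prime bases);
* the *Shiraishi* model — a factorized model that treats the substitution
  class, each flanking position and (optionally) the transcription strand
  as independent features, each with its own probability distribution.

A Shiraishi signature is stored as a rectangular matrix with 6 columns:
row 1 is the base-change distribution (C>A, C>G, C>T, T>A, T>C, T>G),
the following rows are flanking-position base distributions (A, C, G, T,
padded with two zeros) ordered 5' to 3', and an optional final strand row
(plus, minus, padded with four zeros).  Tumor mutational catalogs
(GenomeProfile) use the identical representation, which is what makes
refitting a simple least-squares problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "BASES",
    "SUBSTITUTION_CLASSES",
    "ALEXANDROV_CATEGORIES",
    "ContextSpec",
    "AlexandrovSignature",
    "ShiraishiSignature",
    "GenomeProfile",
    "InvalidSignatureError",
    "validate_signature",
    "convert_alexandrov_to_shiraishi",
    "downgrade_shiraishi",
    "flat_genome",
]

BASES = "ACGT"
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: canonical COSMIC category order: substitution class slowest, then 5' base,
#: then 3' base, each in A,C,G,T order (e.g. "A[C>A]A", "A[C>A]C", ...).
ALEXANDROV_CATEGORIES = tuple(
    f"{five}[{cls}]{three}"
    for cls in SUBSTITUTION_CLASSES
    for five in BASES
    for three in BASES
)

_CATEGORY_INDEX = {lab: i for i, lab in enumerate(ALEXANDROV_CATEGORIES)}

#: default tolerance for probability normalization checks
NORM_TOL = 1e-10


class InvalidSignatureError(ValueError):
    """A signature or genome profile violates a model invariant."""


@dataclass(frozen=True)
class ContextSpec:
    """Shape of the sequence-context model a signature is defined over.

    Parameters
    ----------
    flank_left, flank_right
        Number of flanking bases 5' and 3' of the mutated base.
    use_strand
        Whether the model carries a transcription-strand feature
        (Shiraishi only).
    model
        ``"alexandrov"`` (joint trinucleotide model) or ``"shiraishi"``
        (independent-feature model).
    """

    flank_left: int = 1
    flank_right: int = 1
    use_strand: bool = False
    model: Literal["alexandrov", "shiraishi"] = "shiraishi"

    def __post_init__(self) -> None:
        if self.flank_left < 0 or self.flank_right < 0:
            raise ValueError("flank counts must be non-negative")
        if self.model == "alexandrov":
            if self.use_strand:
                raise ValueError("the Alexandrov model has no strand feature")
            if (self.flank_left, self.flank_right) != (1, 1):
                raise ValueError(
                    "the canonical Alexandrov model uses one flanking base "
                    "on each side (96 categories)"
                )
        elif self.model != "shiraishi":
            raise ValueError(f"unknown model {self.model!r}")

    @property
    def n_flanks(self) -> int:
        return self.flank_left + self.flank_right

    @property
    def n_rows(self) -> int:
        """Feature rows of the Shiraishi matrix (1 for the base change,
        one per flanking position, plus one strand row if used)."""
        if self.model == "alexandrov":
            raise ValueError("row layout applies to the Shiraishi model only")
        return 1 + self.n_flanks + int(self.use_strand)

    @property
    def n_params(self) -> int:
        """Number of free parameters of the model.

        6 * 4^(flanks) for the joint Alexandrov model, versus
        6 + 4 * flanks (+ 2 for strand) for the factorized Shiraishi model.
        """
        if self.model == "alexandrov":
            return 6 * 4**self.n_flanks
        return 6 + 4 * self.n_flanks + 2 * int(self.use_strand)

    def row_widths(self) -> list[int]:
        """Number of valid (unpadded) entries of each Shiraishi feature row."""
        if self.model == "alexandrov":
            raise ValueError("row layout applies to the Shiraishi model only")
        widths = [6] + [4] * self.n_flanks
        if self.use_strand:
            widths.append(2)
        return widths

    def row_labels(self) -> list[str]:
        """Human-readable feature-row names (change, -n..-1, +1..+n, strand)."""
        labels = ["change"]
        labels += [str(-i) for i in range(self.flank_left, 0, -1)]
        labels += [f"+{i}" for i in range(1, self.flank_right + 1)]
        if self.use_strand:
            labels.append("strand")
        return labels


ALEXANDROV_SPEC = ContextSpec(1, 1, False, "alexandrov")


def _check_rows(matrix: np.ndarray, spec: ContextSpec, what: str,
                tolerance: float) -> None:
    expected = (spec.n_rows, 6)
    if matrix.shape != expected:
        raise InvalidSignatureError(
            f"{what}: expected matrix of shape {expected} for {spec}, "
            f"got {matrix.shape}"
        )
    if np.any(matrix < 0):
        r, c = np.argwhere(matrix < 0)[0]
        raise InvalidSignatureError(
            f"{what}: negative entry at row {r}, column {c}"
        )
    for r, width in enumerate(spec.row_widths()):
        pad = matrix[r, width:]
        if np.any(pad != 0.0):
            raise InvalidSignatureError(
                f"{what}: padding entries of row {r} must be exactly 0"
            )
        s = matrix[r, :width].sum()
        if abs(s - 1.0) > tolerance:
            raise InvalidSignatureError(
                f"{what}: row {r} not normalized (sum {s:.12g})"
            )


def _check_vector(probs: np.ndarray, what: str, tolerance: float) -> None:
    if probs.shape != (96,):
        raise InvalidSignatureError(
            f"{what}: expected 96 category probabilities, got shape {probs.shape}"
        )
    if np.any(probs < 0):
        (i,) = np.argwhere(probs < 0)[0]
        raise InvalidSignatureError(
            f"{what}: negative probability at index {i} "
            f"({ALEXANDROV_CATEGORIES[i]})"
        )
    s = probs.sum()
    if abs(s - 1.0) > tolerance:
        raise InvalidSignatureError(f"{what}: not normalized (sum {s:.12g})")


@dataclass
class AlexandrovSignature:
    """A 96-entry trinucleotide mutation-probability vector in canonical
    COSMIC category order."""

    probs: np.ndarray
    name: str = "signature"
    tolerance: float = NORM_TOL

    spec: ContextSpec = field(default=ALEXANDROV_SPEC, init=False)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        _check_vector(self.probs, self.name, self.tolerance)

    @property
    def labels(self) -> tuple[str, ...]:
        return ALEXANDROV_CATEGORIES


@dataclass
class ShiraishiSignature:
    """An independent-feature signature: one probability row per feature."""

    matrix: np.ndarray
    spec: ContextSpec
    name: str = "signature"
    tolerance: float = NORM_TOL

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.spec.model != "shiraishi":
            raise InvalidSignatureError(
                f"{self.name}: ShiraishiSignature requires a shiraishi spec"
            )
        _check_rows(self.matrix, self.spec, self.name, self.tolerance)


@dataclass
class GenomeProfile:
    """A tumor mutational catalog in the same representation as a signature.

    ``values`` is a 96-vector for the Alexandrov model or a padded feature
    matrix for the Shiraishi model.  ``n_mutations`` is the number of somatic
    SNVs the profile was built from (``None`` for idealized profiles such as
    the flat genome or expectation profiles).
    """

    values: np.ndarray
    spec: ContextSpec
    n_mutations: int | None = None
    sample: str = "tumor"
    tolerance: float = NORM_TOL

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.n_mutations is not None and self.n_mutations < 1:
            raise InvalidSignatureError(
                f"{self.sample}: n_mutations must be >= 1"
            )
        if self.spec.model == "alexandrov":
            _check_vector(self.values, self.sample, self.tolerance)
        else:
            _check_rows(self.values, self.spec, self.sample, self.tolerance)


Signature = AlexandrovSignature | ShiraishiSignature


def validate_signature(sig, tolerance: float = NORM_TOL):
    """Re-check all invariants of a signature or genome profile.

    Returns the object unchanged if every invariant holds; raises
    :class:`InvalidSignatureError` naming the offending row/index otherwise.
    """
    if isinstance(sig, AlexandrovSignature):
        _check_vector(np.asarray(sig.probs, float), sig.name, tolerance)
    elif isinstance(sig, ShiraishiSignature):
        _check_rows(np.asarray(sig.matrix, float), sig.spec, sig.name, tolerance)
    elif isinstance(sig, GenomeProfile):
        if sig.spec.model == "alexandrov":
            _check_vector(np.asarray(sig.values, float), sig.sample, tolerance)
        else:
            _check_rows(np.asarray(sig.values, float), sig.spec, sig.sample,
                        tolerance)
    else:
        raise TypeError(f"not a signature or profile: {type(sig)!r}")
    return sig


def category_index(five: str, cls: str, three: str) -> int:
    """Index of a trinucleotide mutation category in canonical order."""
    return _CATEGORY_INDEX[f"{five}[{cls}]{three}"]


def convert_alexandrov_to_shiraishi(
    a: AlexandrovSignature, renormalize: bool = False
) -> ShiraishiSignature:
    """Marginalize a 96-category signature into a triplet Shiraishi signature.

    The base-change row is the sum of probabilities over the 16 contexts of
    each substitution class; the flanking rows are the 5' and 3' base
    marginals (plain summation over categories, weighting each context by its
    total probability).  With ``renormalize`` the input vector is divided by
    its sum first, which absorbs rounding in published tables.
    """
    probs = np.asarray(a.probs, dtype=float)
    if renormalize:
        probs = probs / probs.sum()
    cube = probs.reshape(6, 4, 4)  # class x 5' x 3'
    matrix = np.zeros((3, 6))
    matrix[0, :] = cube.sum(axis=(1, 2))
    matrix[1, :4] = cube.sum(axis=(0, 2))
    matrix[2, :4] = cube.sum(axis=(0, 1))
    # plain summation keeps each row summing to the vector total; guard
    # against rounded inputs drifting past the strict tolerance
    tol = max(a.tolerance, NORM_TOL)
    spec = ContextSpec(1, 1, False, "shiraishi")
    return ShiraishiSignature(matrix, spec, name=a.name, tolerance=tol)


def downgrade_shiraishi(
    s: ShiraishiSignature,
    target_flank_left: int,
    target_flank_right: int,
    keep_strand: bool = False,
) -> ShiraishiSignature:
    """Reduce a Shiraishi signature to a smaller context.

    Drops the outermost flanking rows and/or the strand row.  Because the
    features are independent, the remaining rows are valid marginals as they
    stand and no renormalization is needed.
    """
    spec = s.spec
    if target_flank_left > spec.flank_left or target_flank_right > spec.flank_right:
        raise ValueError(
            f"cannot downgrade to ({target_flank_left},{target_flank_right}) "
            f"flanks from ({spec.flank_left},{spec.flank_right})"
        )
    if keep_strand and not spec.use_strand:
        raise ValueError("signature has no strand row to keep")
    rows = [0]
    # left flanks are rows 1..flank_left ordered -flank_left..-1: keep innermost
    rows += list(range(1 + spec.flank_left - target_flank_left,
                       1 + spec.flank_left))
    rows += list(range(1 + spec.flank_left,
                       1 + spec.flank_left + target_flank_right))
    if keep_strand:
        rows.append(spec.n_rows - 1)
    new_spec = ContextSpec(target_flank_left, target_flank_right,
                           keep_strand, "shiraishi")
    return ShiraishiSignature(s.matrix[rows, :].copy(), new_spec,
                              name=s.name, tolerance=s.tolerance)


def flat_genome(spec: ContextSpec) -> GenomeProfile:
    """The uniform ("flat") tumor genome for a model.

    Alexandrov: all 96 categories at 1/96.  Shiraishi: 1/6 per base change,
    1/4 per flanking base, 1/2 per strand.  Used as the baseline in the
    explained-variance denominator.
    """
    if spec.model == "alexandrov":
        return GenomeProfile(np.full(96, 1.0 / 96), spec, sample="flat")
    matrix = np.zeros((spec.n_rows, 6))
    for r, width in enumerate(spec.row_widths()):
        matrix[r, :width] = 1.0 / width
    return GenomeProfile(matrix, spec, sample="flat")
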