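"""Turn somatic SNVs plus reference context into model-specific profiles.

Every SNV is first *pyrimidine-normalized*: if the reference base is a
purine (A/G), the change and its flanking context are reverse-complemented
so that the mutated base is always C or T, collapsing reverse-complement
pairs into the canonical 6 substitution classes.  The strand feature then
records whether the pyrimidine-carrying reference strand matches the strand
of the overlapping transcript.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .io_formats import MutationRecord, StrandedRegions, normalize_chrom
from .sigmodel import (
    BASES,
    ContextSpec,
    GenomeProfile,
    SUBSTITUTION_CLASSES,
    category_index,
)

__all__ = [
    "CanonicalMutation",
    "normalize_to_pyrimidine",
    "assign_strand",
    "build_profile",
    "ReferenceMismatchError",
]

logger = logging.getLogger("sigrefit")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class ReferenceMismatchError(ValueError):
    """The VCF/MPF ref allele disagrees with the reference FASTA base."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CanonicalMutation:
    """A pyrimidine-normalized SNV with its flanking context.

    ``pyrimidine_strand`` is the reference strand that carried the
    pyrimidine before normalization: '+' if the original ref base was C/T,
    '-' otherwise.  ``strand_feature`` is set later by :func:`assign_strand`.
    """

    change: str                 # one of the 6 classes, e.g. "C>T"
    left: str                   # 5' flanking bases after normalization
    right: str                  # 3' flanking bases after normalization
    pyrimidine_strand: str      # '+' or '-'
    strand_feature: str = "undefined"   # plus | minus | undefined


def normalize_to_pyrimidine(ref: str, alt: str, left: str, right: str
                            ) -> CanonicalMutation | None:
    """Represent an SNV on the strand where the mutated base is a pyrimidine.

    ``left``/``right`` are the flanking bases read 5'→3' on the reference
    strand.  Returns None when the context contains a base outside A/C/G/T
    (such mutations are excluded from profiles and counted by the caller).
    """
    ref, alt = ref.upper(), alt.upper()
    left, right = left.upper(), right.upper()
    for b in ref + alt + left + right:
        if b not in BASES:
            return None
    if ref == alt:
        raise ValueError(f"ref == alt ({ref})")
    if ref in "CT":
        return CanonicalMutation(f"{ref}>{alt}", left, right, "+")
    ref_c = ref.translate(_COMPLEMENT)
    alt_c = alt.translate(_COMPLEMENT)
    # reverse-complementing the whole local sequence swaps and flips flanks
    return CanonicalMutation(f"{ref_c}>{alt_c}", revcomp(right), revcomp(left), "-")


def assign_strand(canon: CanonicalMutation, chrom: str, pos: int,
                  regions: StrandedRegions) -> str:
    """Transcription-strand feature of a normalized mutation.

    'plus' when the pyrimidine-carrying strand equals the transcript strand,
    'minus' when opposite, 'undefined' when the position is uncovered or
    covered by transcripts on both strands.
    """
    tau = regions.strand_at(chrom, pos)
    if tau is None:
        return "undefined"
    return "plus" if canon.pyrimidine_strand == tau else "minus"


def _fetch_context(reference, chrom: str, pos: int, flank_left: int,
                   flank_right: int) -> str | None:
    """1-based inclusive slice [pos-flank_left, pos+flank_right] of the
    reference, or None if out of bounds.  Accepts a pyfaidx.Fasta or any
    mapping of chromosome name to sequence string."""
    chrom = normalize_chrom(chrom)
    if isinstance(reference, Mapping):
        names = {normalize_chrom(k): k for k in reference.keys()}
    else:   # pyfaidx.Fasta
        names = {normalize_chrom(k): k for k in reference.keys()}
    key = names.get(chrom)
    if key is None:
        return None
    seq = reference[key]
    start = pos - 1 - flank_left
    end = pos + flank_right
    if start < 0 or end > len(seq):
        return None
    return str(seq[start:end]).upper()


def build_profile(records: Iterable[MutationRecord], reference,
                  spec: ContextSpec, regions: StrandedRegions | None = None,
                  sample: str | None = None,
                  on_mismatch: str = "error") -> GenomeProfile:
    """Build the mutational catalog of one tumor.

    Parameters
    ----------
    records
        Somatic SNVs of one sample.
    reference
        ``pyfaidx.Fasta`` or a mapping chrom → sequence; flanking context is
        always taken from here, never from the variant file.
    spec
        Target model.  With ``use_strand`` set, ``regions`` is required and
        mutations whose transcription strand is undefined are excluded.
    on_mismatch
        ``"error"`` (default) or ``"skip"`` when the record's ref allele
        disagrees with the reference base.

    Returns a :class:`GenomeProfile`; raises ValueError when no usable
    mutation remains after exclusions.
    """
    if spec.use_strand and regions is None:
        raise ValueError("use_strand requires stranded regions")
    fl, fr = spec.flank_left, spec.flank_right
    if spec.model == "alexandrov":
        counts = np.zeros(96)
    else:
        counts = np.zeros((spec.n_rows, 6))
    n_used = 0
    n_context = n_mismatch = n_strand = 0
    sample_name = sample
    for rec in records:
        if sample_name is None:
            sample_name = rec.sample
        ctx = _fetch_context(reference, rec.chrom, rec.pos, fl, fr)
        if ctx is None:
            n_context += 1
            continue
        ref_base = ctx[fl]
        if ref_base != rec.ref:
            if on_mismatch == "skip":
                n_mismatch += 1
                continue
            raise ReferenceMismatchError(
                f"{rec.chrom}:{rec.pos}: VCF ref {rec.ref!r} != reference "
                f"base {ref_base!r}")
        canon = normalize_to_pyrimidine(rec.ref, rec.alt, ctx[:fl], ctx[fl + 1:])
        if canon is None:
            n_context += 1
            continue
        if spec.use_strand:
            feat = assign_strand(canon, rec.chrom, rec.pos, regions)
            if feat == "undefined":
                n_strand += 1
                continue
        else:
            feat = "undefined"
        if spec.model == "alexandrov":
            counts[category_index(canon.left, canon.change, canon.right)] += 1
        else:
            counts[0, SUBSTITUTION_CLASSES.index(canon.change)] += 1
            flanks = canon.left + canon.right
            for i, base in enumerate(flanks):
                counts[1 + i, BASES.index(base)] += 1
            if spec.use_strand:
                counts[spec.n_rows - 1, 0 if feat == "plus" else 1] += 1
        n_used += 1
    if n_context or n_mismatch or n_strand:
        logger.info(
            "build_profile(%s): excluded %d (context), %d (ref mismatch), "
            "%d (undefined strand)", sample_name, n_context, n_mismatch, n_strand)
    if n_used == 0:
        raise ValueError(f"{sample_name}: no usable SNV after exclusions")
    return GenomeProfile(counts / n_used, spec, n_mutations=n_used,
                         sample=sample_name or "tumor")
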