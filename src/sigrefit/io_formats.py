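"""Readers and writers for the on-disk formats the tool touches.

Variant input comes as VCF 4.x (via pysam) or MPF — "Mutation Position
Format", tab-separated ``sample  chrom  pos  ref  alt`` lines with 1-based
positions.  Signature sets come as COSMIC-style tab-separated probability
tables (Alexandrov) or one whitespace-separated flat file per signature
(Shiraishi, one line per feature row, 6 zero-padded columns).  Stranded
transcript annotations come as BED6.

Chromosome names are normalized by stripping a leading ``chr`` prefix so
that mixed conventions across FASTA/VCF/BED inputs still match.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .sigmodel import (
    ALEXANDROV_CATEGORIES,
    BASES,
    AlexandrovSignature,
    ContextSpec,
    ShiraishiSignature,
)

__all__ = [
    "MutationRecord",
    "StrandedRegions",
    "FormatError",
    "read_vcf",
    "read_mpf",
    "write_mpf",
    "write_vcf",
    "read_cosmic_signatures",
    "read_shiraishi_signatures",
    "read_stranded_regions",
    "write_signature",
    "write_exposures",
]

logger = logging.getLogger("sigrefit")

#: published probability tables are rounded; file readers accept this much
#: deviation from exact normalization (in-memory constructions stay at 1e-10)
FILE_NORM_TOL = 1e-4


class FormatError(ValueError):
    """A file does not conform to its expected format."""


def normalize_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass(frozen=True)
class MutationRecord:
    """One somatic single-nucleotide variant of one sample (1-based pos)."""

    sample: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise FormatError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")


def _is_snv(ref: str, alt: str) -> bool:
    return len(ref) == 1 and len(alt) == 1 and ref in BASES and alt in BASES and ref != alt


# ---------------------------------------------------------------------------
# variant input
# ---------------------------------------------------------------------------

def read_vcf(path, sample_selector: Sequence[str] | None = None
             ) -> dict[str, list[MutationRecord]]:
    """Read somatic SNVs from a VCF 4.x file (plain or bgzipped).

    If the VCF has genotype columns, each variant is assigned to every
    sample whose genotype carries the alternate allele; without genotype
    columns the whole file is treated as a single tumor named after the
    file.  Multi-allelic sites are split into one record per alternate
    allele; non-SNV alleles are skipped and counted.
    """
    path = os.fspath(path)
    by_sample: dict[str, list[MutationRecord]] = {}
    n_skipped = 0
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        if sample_selector is not None:
            missing = set(sample_selector) - set(samples)
            if missing:
                raise FormatError(f"samples not in VCF: {sorted(missing)}")
            samples = [s for s in samples if s in set(sample_selector)]
        default_sample = Path(path).name.split(".")[0]
        for rec in vcf:
            chrom = normalize_chrom(rec.chrom)
            for ai, alt in enumerate(rec.alts or (), start=1):
                if not _is_snv(rec.ref, alt):
                    n_skipped += 1
                    continue
                if not samples:
                    by_sample.setdefault(default_sample, []).append(
                        MutationRecord(default_sample, chrom, rec.pos, rec.ref, alt))
                    continue
                for s in samples:
                    gt = rec.samples[s].get("GT")
                    if gt is not None and ai in gt:
                        by_sample.setdefault(s, []).append(
                            MutationRecord(s, chrom, rec.pos, rec.ref, alt))
    if n_skipped:
        logger.info("read_vcf(%s): skipped %d non-SNV allele(s)", path, n_skipped)
    if not by_sample:
        raise FormatError(f"{path}: no SNVs retained")
    return by_sample


def read_mpf(path, header: str = "auto") -> dict[str, list[MutationRecord]]:
    """Read Mutation Position Format: tab-separated sample/chrom/pos/ref/alt.

    ``header`` is ``"auto"`` (skip a first line whose third column is not an
    integer), ``"present"`` or ``"absent"``.  Non-SNV lines are skipped and
    counted; a line with the wrong number of columns is an error reported
    with its line number.
    """
    by_sample: dict[str, list[MutationRecord]] = {}
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise FormatError(
                    f"{path}:{lineno}: expected 5 tab-separated columns, "
                    f"got {len(fields)}")
            if lineno == 1:
                if header == "present":
                    continue
                if header == "auto" and not fields[2].isdigit():
                    continue
            sample, chrom, pos, ref, alt = fields
            if not pos.isdigit():
                raise FormatError(f"{path}:{lineno}: position {pos!r} not an integer")
            ref, alt = ref.upper(), alt.upper()
            if not _is_snv(ref, alt):
                n_skipped += 1
                continue
            by_sample.setdefault(sample, []).append(
                MutationRecord(sample, normalize_chrom(chrom), int(pos), ref, alt))
    if n_skipped:
        logger.info("read_mpf(%s): skipped %d non-SNV line(s)", path, n_skipped)
    if not by_sample:
        raise FormatError(f"{path}: no SNVs retained")
    return by_sample


def write_mpf(records: Iterable[MutationRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.sample}\t{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\n")


def write_vcf(records: Sequence[MutationRecord], path,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write records as a minimal multi-sample VCF 4.2 with GT columns."""
    samples = sorted({r.sample for r in records})
    sample_idx = {s: i for i, s in enumerate(samples)}
    sites: dict[tuple[str, int, str, str], set[str]] = {}
    for r in records:
        sites.setdefault((r.chrom, r.pos, r.ref, r.alt), set()).add(r.sample)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for (chrom, pos, ref, alt), carriers in sorted(sites.items()):
            gts = ["0/1" if s in carriers else "0/0" for s in samples]
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")
    del sample_idx


# ---------------------------------------------------------------------------
# signature input/output
# ---------------------------------------------------------------------------

def read_cosmic_signatures(path, tolerance: float = FILE_NORM_TOL,
                           renormalize: bool = False) -> list[AlexandrovSignature]:
    """Read a COSMIC-style tab-separated signature probability table.

    Expects columns ``Substitution Type``, ``Trinucleotide``, ``Somatic
    Mutation Type`` followed by one column per signature, with 96 data rows
    in any order; rows are reordered into canonical category order.
    """
    df = pd.read_csv(path, sep="\t")
    df = df.dropna(axis=1, how="all")  # trailing tab columns in some dumps
    required = ["Substitution Type", "Trinucleotide", "Somatic Mutation Type"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    labels = df["Somatic Mutation Type"].astype(str)
    seen = set(labels)
    missing = set(ALEXANDROV_CATEGORIES) - seen
    if missing:
        raise FormatError(f"{path}: missing category {sorted(missing)[0]!r}"
                          + (f" and {len(missing) - 1} more" if len(missing) > 1 else ""))
    if len(labels) != len(seen):
        dup = labels[labels.duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate category {dup!r}")
    df = df.set_index(labels).loc[list(ALEXANDROV_CATEGORIES)]
    sigs = []
    for col in df.columns:
        if col in required:
            continue
        probs = df[col].to_numpy(dtype=float)
        if np.any(probs < 0):
            raise FormatError(f"{path}: negative probability in column {col!r}")
        if abs(probs.sum() - 1.0) > tolerance:
            raise FormatError(
                f"{path}: column {col!r} not normalized (sum {probs.sum():.6g})")
        if renormalize:
            probs = probs / probs.sum()
        sigs.append(AlexandrovSignature(probs, name=str(col),
                                        tolerance=max(tolerance, 1e-10)))
    if not sigs:
        raise FormatError(f"{path}: no signature columns found")
    return sigs


def _infer_spec(matrix: np.ndarray, path) -> ContextSpec:
    """Infer a ContextSpec from a flat-file matrix: a last row with exactly
    two nonzero leading entries (summing to ~1) is a strand row; flanking
    rows are split evenly 5'/3'."""
    n_rows = matrix.shape[0]
    if n_rows < 3:
        raise FormatError(f"{path}: too few feature rows ({n_rows})")
    last = matrix[-1]
    has_strand = (np.all(last[2:] == 0.0)
                  and abs(last[:2].sum() - 1.0) <= FILE_NORM_TOL)
    n_flanks = n_rows - 1 - int(has_strand)
    if n_flanks % 2 != 0:
        raise FormatError(
            f"{path}: cannot infer context ({n_flanks} flanking rows is odd)")
    half = n_flanks // 2
    return ContextSpec(half, half, has_strand, "shiraishi")


def read_shiraishi_signatures(source, spec: ContextSpec | None = None,
                              tolerance: float = FILE_NORM_TOL,
                              renormalize: bool = False
                              ) -> list[ShiraishiSignature]:
    """Read Shiraishi signatures from flat files (one per signature) or a
    directory of such files; one line per feature row, whitespace-separated,
    6 zero-padded columns.  All signatures read together must share one
    ContextSpec (required for joint decomposition)."""
    if isinstance(source, (str, Path)) and Path(source).is_dir():
        paths = sorted(p for p in Path(source).iterdir() if p.is_file())
    elif isinstance(source, (str, Path)):
        paths = [Path(source)]
    else:
        paths = [Path(p) for p in source]
    sigs: list[ShiraishiSignature] = []
    for path in paths:
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                vals = line.split()
                if len(vals) != 6:
                    raise FormatError(
                        f"{path}:{lineno}: expected 6 columns, got {len(vals)}")
                rows.append([float(v) for v in vals])
        matrix = np.array(rows, dtype=float)
        if np.any(matrix < 0):
            r = int(np.argwhere(matrix < 0)[0][0])
            raise FormatError(f"{path}: negative probability in row {r + 1}")
        this_spec = spec or _infer_spec(matrix, path)
        if renormalize:
            for r, width in enumerate(this_spec.row_widths()):
                matrix[r, :width] /= matrix[r, :width].sum()
        sigs.append(ShiraishiSignature(matrix, this_spec, name=path.stem,
                                       tolerance=max(tolerance, 1e-10)))
    specs = {s.spec for s in sigs}
    if len(specs) > 1:
        raise FormatError(
            f"inconsistent signature specs across set: {sorted(map(str, specs))}")
    return sigs


def write_signature(sig, path) -> None:
    """Write a signature in the flat-file dialect the readers accept
    (round-trip safe at 10 significant digits)."""
    if isinstance(sig, AlexandrovSignature):
        with open(path, "w") as fh:
            fh.write("Substitution Type\tTrinucleotide\tSomatic Mutation Type\t"
                     f"{sig.name}\n")
            for lab, p in zip(ALEXANDROV_CATEGORIES, sig.probs):
                cls = lab[2:5]
                tri = lab[0] + lab[2] + lab[6]
                fh.write(f"{cls}\t{tri}\t{lab}\t{p:.10g}\n")
    else:
        with open(path, "w") as fh:
            for row in sig.matrix:
                fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# stranded regions (BED6)
# ---------------------------------------------------------------------------

class StrandedRegions:
    """Transcribed regions with strand, queried per position.

    Positions covered by regions of both strands are ambiguous and yield
    ``None`` from :meth:`strand_at`, as do uncovered positions (callers
    distinguish the two via :meth:`covered`).
    """

    def __init__(self) -> None:
        self._trees: dict[tuple[str, str], IntervalTree] = {}

    def add(self, chrom: str, start: int, end: int, strand: str) -> None:
        """Add a region with 1-based inclusive coordinates."""
        if start > end:
            raise FormatError(f"region start {start} > end {end}")
        if strand not in "+-":
            raise FormatError(f"invalid strand {strand!r}")
        key = (normalize_chrom(chrom), strand)
        self._trees.setdefault(key, IntervalTree()).addi(start, end + 1)

    def covered(self, chrom: str, pos: int) -> bool:
        chrom = normalize_chrom(chrom)
        return any(self._trees.get((chrom, s), IntervalTree()).overlaps(pos)
                   for s in "+-")

    def strand_at(self, chrom: str, pos: int) -> str | None:
        """'+' or '-' if the position is covered by exactly one strand,
        else None (uncovered or ambiguous)."""
        chrom = normalize_chrom(chrom)
        plus = bool(self._trees.get((chrom, "+"), IntervalTree()).overlaps(pos))
        minus = bool(self._trees.get((chrom, "-"), IntervalTree()).overlaps(pos))
        if plus == minus:
            return None
        return "+" if plus else "-"

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())


def read_stranded_regions(path) -> StrandedRegions:
    """Read a BED6 file of stranded transcripts (0-based half-open on disk,
    converted to 1-based inclusive internally)."""
    regions = StrandedRegions()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(
                    f"{path}:{lineno}: BED6 requires 6 columns, got {len(fields)}")
            chrom, start, end, _name, _score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if strand not in "+-":
                raise FormatError(f"{path}:{lineno}: invalid strand {strand!r}")
            regions.add(chrom, start_i + 1, end_i, strand)
    return regions


# ---------------------------------------------------------------------------
# result output
# ---------------------------------------------------------------------------

def write_exposures(results, path, signature_names: Sequence[str] | None = None
                    ) -> None:
    """Write decomposition results as a tab-separated exposure table.

    Rows are tumors; columns are one exposure per signature (signatures
    outside the selected subset written as 0), followed by ``n_mutations``,
    ``rss``, ``explained_variance`` and the ``subset`` actually used.
    """
    results = list(results)
    if signature_names is None:
        names: list[str] = []
        for res in results:
            for sid in res.exposures.signature_ids:
                if sid not in names:
                    names.append(sid)
        signature_names = names
    rows = []
    for res in results:
        w = dict(zip(res.exposures.signature_ids, res.exposures.weights))
        row = {"sample": res.exposures.tumor}
        for name in signature_names:
            row[name] = w.get(name, 0.0)
        row["n_mutations"] = res.n_mutations if res.n_mutations is not None else ""
        row["rss"] = res.rss
        row["explained_variance"] = res.explained_variance
        row["subset"] = ",".join(res.subset)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
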