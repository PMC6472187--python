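"""Simulated tumor genomes with known exposures, and synthetic fixtures.

A simulated genome draws each of its n mutations from a signature chosen
according to the exposure vector, then draws the mutation's features from
that signature (for the independent-feature Shiraishi model each feature
row is sampled independently; for the Alexandrov model one of the 96 joint
categories is drawn).  Aggregating the draws yields a GenomeProfile in the
same representation as the signatures, which can then be refit to measure
how well the known exposures are recovered.

The module doubles as the fixture generator for the test suite: it can
produce random signature sets with a guaranteed minimum pairwise
separation, a random reference sequence, and variant records consistent
with that reference, so that every file-format code path can be exercised
without external downloads.

Reproducibility: one global seed; each genome uses an independent substream
``default_rng([seed, genome_index])`` so genome i can be regenerated in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .decompose import SimplexSolver, signature_matrix
from .io_formats import MutationRecord
from .sigmodel import (
    BASES,
    AlexandrovSignature,
    ContextSpec,
    GenomeProfile,
    ShiraishiSignature,
)

__all__ = [
    "SimulationSpec",
    "make_exposures",
    "simulate_genome",
    "random_signature_set",
    "evaluate_recovery",
    "random_reference",
    "random_mutation_records",
]


@dataclass
class SimulationSpec:
    """One simulation condition: a signature set, a true exposure vector,
    and how many genomes of how many mutations to draw."""

    signatures: Sequence
    exposures: np.ndarray
    n_mutations: int
    n_genomes: int = 1
    seed: int = 0
    driving: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.exposures = np.asarray(self.exposures, dtype=float)
        if len(self.exposures) != len(self.signatures):
            raise ValueError("one exposure per signature required")
        if np.any(self.exposures < 0) or abs(self.exposures.sum() - 1.0) > 1e-9:
            raise ValueError("exposures must be a probability vector")
        if self.n_mutations < 1:
            raise ValueError("n_mutations must be >= 1")


def make_exposures(K: int, driving: Sequence[tuple[int, float]]) -> np.ndarray:
    """Exposure vector with given driving signatures; the remaining mass is
    spread uniformly over the non-driving signatures.

    E.g. one driver at 0.8 among K=15 leaves 0.2/14 for each of the rest.
    """
    idx = [i for i, _ in driving]
    if len(set(idx)) != len(idx):
        raise ValueError("driving indices must be distinct")
    total = sum(wt for _, wt in driving)
    if total > 1.0 + 1e-12:
        raise ValueError(f"driving weights sum to {total} > 1")
    w = np.zeros(K)
    for i, wt in driving:
        if wt < 0:
            raise ValueError("driving weights must be non-negative")
        w[i] = wt
    rest = K - len(idx)
    if rest > 0:
        w[w == 0] = (1.0 - total) / rest
    elif abs(total - 1.0) > 1e-12:
        raise ValueError("all signatures driving but weights do not sum to 1")
    return w


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_genome(signatures, exposures, n_mutations: int, rng=0,
                    sample: str = "simulated", return_counts: bool = False):
    """Draw one simulated tumor genome.

    Each mutation is assigned to a signature with probability equal to its
    exposure, then its features are drawn from that signature.  Because the
    Shiraishi model samples each feature row independently, the per-genome
    draw reduces to nested multinomials (signature assignment counts, then
    per-row feature counts), which is exactly equivalent to per-mutation
    sampling.  With ``return_counts`` the per-signature assignment counts
    are returned alongside the profile.
    """
    rng = _as_rng(rng)
    sigs = list(signatures)
    w = np.asarray(exposures, dtype=float)
    if len(w) != len(sigs):
        raise ValueError("one exposure per signature required")
    spec = sigs[0].spec
    if any(s.spec != spec for s in sigs):
        raise ValueError("signatures mix context specs")
    assignment = rng.multinomial(n_mutations, w)
    if spec.model == "alexandrov":
        counts = np.zeros(96)
        for s, m in zip(sigs, assignment):
            if m:
                counts += rng.multinomial(m, s.probs)
        profile = GenomeProfile(counts / n_mutations, spec,
                                n_mutations=n_mutations, sample=sample)
    else:
        counts = np.zeros((spec.n_rows, 6))
        widths = spec.row_widths()
        for s, m in zip(sigs, assignment):
            if not m:
                continue
            for r, width in enumerate(widths):
                counts[r, :width] += rng.multinomial(m, s.matrix[r, :width])
        profile = GenomeProfile(counts / n_mutations, spec,
                                n_mutations=n_mutations, sample=sample)
    if return_counts:
        return profile, assignment
    return profile


def random_signature_set(K: int, spec: ContextSpec, seed=0,
                         min_separation: float | None = None,
                         concentration: float = 0.5,
                         max_redraws: int = 100):
    """Random signature set, each feature row drawn from a sparse symmetric
    Dirichlet.  With ``min_separation`` the whole set is redrawn until every
    pairwise Frobenius distance exceeds it (bounded number of attempts)."""
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = _as_rng(seed)

    def draw_one(name: str):
        if spec.model == "alexandrov":
            probs = rng.dirichlet(np.full(96, concentration))
            return AlexandrovSignature(probs, name=name)
        matrix = np.zeros((spec.n_rows, 6))
        for r, width in enumerate(spec.row_widths()):
            matrix[r, :width] = rng.dirichlet(np.full(width, concentration))
        return ShiraishiSignature(matrix, spec, name=name)

    from .compare import signature_distance

    for _ in range(max_redraws):
        sigs = [draw_one(f"s{i + 1}") for i in range(K)]
        if min_separation is None:
            return sigs
        ok = all(
            signature_distance(sigs[i], sigs[j]) > min_separation
            for i in range(K) for j in range(i + 1, K))
        if ok:
            return sigs
    raise RuntimeError(
        f"could not draw {K} signatures with pairwise separation "
        f"> {min_separation} in {max_redraws} attempts")


def evaluate_recovery(specs: Sequence[SimulationSpec]) -> pd.DataFrame:
    """Run the simulate-then-refit evaluation for a list of conditions.

    For every simulated genome the fitted exposures are compared with the
    true ones; the long-format result has one row per genome and signature
    with columns ``condition``, ``genome``, ``signature``, ``true``,
    ``fitted``, ``deviation`` (absolute difference) and ``role``
    (driving / other).  Use :func:`recovery_summary` for quantiles.
    """
    frames = []
    for ci, spec in enumerate(specs):
        sigs = list(spec.signatures)
        S = signature_matrix(sigs)
        solver = SimplexSolver(S)
        names = [s.name for s in sigs]
        driving = set(spec.driving)
        rows = []
        for gi in range(spec.n_genomes):
            rng = np.random.default_rng([spec.seed, ci, gi])
            profile = simulate_genome(sigs, spec.exposures, spec.n_mutations,
                                      rng, sample=f"g{gi}")
            from .decompose import flatten
            w, _rss = solver.solve(flatten(profile))
            for si, name in enumerate(names):
                rows.append((ci, gi, name, spec.exposures[si], w[si],
                             abs(w[si] - spec.exposures[si]),
                             "driving" if si in driving else "other"))
        frames.append(pd.DataFrame(
            rows, columns=["condition", "genome", "signature", "true",
                           "fitted", "deviation", "role"]))
    return pd.concat(frames, ignore_index=True)


def recovery_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Median / 90th / 99th percentile of deviations, split by role."""
    return (table.groupby("role")["deviation"]
            .quantile([0.5, 0.9, 0.99]).unstack()
            .rename(columns={0.5: "median", 0.9: "p90", 0.99: "p99"})
            .reset_index())


# ---------------------------------------------------------------------------
# synthetic fixtures: reference + variants
# ---------------------------------------------------------------------------

def random_reference(chrom_lengths: dict[str, int], seed=0) -> dict[str, str]:
    """Random A/C/G/T reference sequences, as a chrom -> string mapping."""
    rng = _as_rng(seed)
    return {c: "".join(rng.choice(list(BASES), size=n))
            for c, n in chrom_lengths.items()}


def random_mutation_records(reference: dict[str, str], n: int, seed=0,
                            samples: Sequence[str] = ("T1",),
                            margin: int = 2) -> list[MutationRecord]:
    """Random SNVs consistent with a reference (for fixture files).

    Positions are drawn away from the sequence ends by ``margin`` bases so
    flanking context is always available; the ref allele is read from the
    reference and the alt drawn uniformly from the other three bases.
    """
    rng = _as_rng(seed)
    chroms = list(reference)
    records = []
    used = set()
    while len(records) < n:
        chrom = chroms[rng.integers(len(chroms))]
        seq = reference[chrom]
        if len(seq) <= 2 * margin:
            raise ValueError(f"chromosome {chrom} shorter than 2*margin")
        pos = int(rng.integers(margin + 1, len(seq) - margin + 1))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        ref = seq[pos - 1]
        alt = rng.choice([b for b in BASES if b != ref])
        sample = samples[rng.integers(len(samples))]
        records.append(MutationRecord(sample, chrom, pos, ref, str(alt)))
    return records
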