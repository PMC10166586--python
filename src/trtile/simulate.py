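"""Synthetic TR allele generation and brute-force oracles.

The simulator emulates resolved TR alleles at desk scale: each allele is a
concatenation of motif copies, each copy independently mutated with i.i.d.
per-base substitutions (to a uniformly chosen different base) and
single-base indels.  A truth table records the generating motif of every
copy, so tests can score copy-number recovery.  The brute-force
decomposition oracle enumerates every partition of a short sequence and is
deliberately independent of the production dynamic program.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decompose import ScoringParams, _clean_seq

__all__ = [
    "SimParams",
    "SimulatedAllele",
    "simulate_alleles",
    "write_fasta",
    "write_truth_tsv",
    "brute_force_decompose",
]

_BASES = "ACGT"
_MAX_ORACLE_LEN = 15


@dataclass
class SimParams:
    """Generator settings for a synthetic allele collection.

    copy_number_range is inclusive on both ends; substitution_rate and
    indel_rate are per-base, per-copy probabilities.  Defaults emulate a
    polymorphic VNTR panel at desk scale: ~100 alleles over a 6-bp motif,
    5-20 copies, 1% substitutions and 0.2% single-base indels.
    """

    motifs: tuple[str, ...] = ("ACGTTG",)
    copy_number_range: tuple[int, int] = (5, 20)
    substitution_rate: float = 0.01
    indel_rate: float = 0.002
    n_alleles: int = 100
    groups: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.motifs:
            raise ValueError("at least one motif is required")
        self.motifs = tuple(_clean_seq(m, "motif") for m in self.motifs)
        lo, hi = self.copy_number_range
        if lo < 1 or hi < lo:
            raise ValueError("copy-number range must be positive and ordered")
        for r in (self.substitution_rate, self.indel_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_alleles < 1:
            raise ValueError("n_alleles must be >= 1")


@dataclass
class SimulatedAllele:
    allele_id: str
    sequence: str
    true_motifs: list[str] = field(default_factory=list)  # one per copy
    group: str | None = None

    @property
    def copy_number(self) -> int:
        return len(self.true_motifs)


def _mutate_copy(motif: str, sub_rate: float, indel_rate: float, rng) -> str:
    out = []
    for base in motif:
        if sub_rate > 0 and rng.random() < sub_rate:
            base = rng.choice([b for b in _BASES if b != base])
        if indel_rate > 0 and rng.random() < indel_rate:
            if rng.random() < 0.5:
                base = ""  # single-base deletion
            else:
                base = base + rng.choice(list(_BASES))  # insertion after
        out.append(base)
    return "".join(out)


def simulate_alleles(params: SimParams) -> list[SimulatedAllele]:
    """Generate a seeded collection of mutated tandem-repeat alleles.

    Each allele draws a copy number uniformly from the configured range and
    a generating motif per copy (uniform over the motif set), then mutates
    every copy independently.  Deterministic for a fixed seed.  Copies that
    mutate to the empty string (deletion of a 1-bp motif) are dropped from
    both sequence and truth.
    """
    rng = np.random.default_rng(params.seed)
    lo, hi = params.copy_number_range
    out: list[SimulatedAllele] = []
    for i in range(params.n_alleles):
        ncopy = int(rng.integers(lo, hi + 1))
        copies, truth = [], []
        for _ in range(ncopy):
            motif = params.motifs[int(rng.integers(len(params.motifs)))]
            mutated = _mutate_copy(
                motif, params.substitution_rate, params.indel_rate, rng
            )
            if mutated:
                copies.append(mutated)
                truth.append(motif)
        if not copies:  # pathological rates; keep the allele non-empty
            copies, truth = [params.motifs[0]], [params.motifs[0]]
        group = (
            params.groups[i % len(params.groups)] if params.groups else None
        )
        out.append(
            SimulatedAllele(f"sample{i:03d}", "".join(copies), truth, group)
        )
    return out


def write_fasta(alleles: list[SimulatedAllele], path) -> None:
    with open(path, "w") as fh:
        for a in alleles:
            fh.write(f">{a.allele_id}\n{a.sequence}\n")


def write_truth_tsv(alleles: list[SimulatedAllele], path) -> None:
    """Truth table: allele_id, copy_index (0-based), true_motif."""
    with open(path, "w") as fh:
        fh.write("allele_id\tcopy_index\ttrue_motif\n")
        for a in alleles:
            for k, m in enumerate(a.true_motifs):
                fh.write(f"{a.allele_id}\t{k}\t{m}\n")


def write_annotations_tsv(alleles: list[SimulatedAllele], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for a in alleles:
            if a.group is not None:
                fh.write(f"{a.allele_id}\t{a.group}\n")


def _nw_score(x: str, m: str, params: ScoringParams) -> int:
    """Plain quadratic global-alignment DP, kept independent of the
    production scorer on purpose (test oracle)."""
    n, k = len(x), len(m)
    prev = [j * params.indel for j in range(k + 1)]
    for i in range(1, n + 1):
        cur = [i * params.indel] + [0] * k
        for j in range(1, k + 1):
            hit = x[i - 1] == m[j - 1] and x[i - 1] != "N"
            cur[j] = max(
                prev[j - 1] + (params.match if hit else params.mismatch),
                prev[j] + params.indel,
                cur[j - 1] + params.indel,
            )
        prev = cur
    return prev[k]


def brute_force_decompose(
    x: str, motifs, params: ScoringParams | None = None
) -> int:
    """Optimal decomposition score by exhaustive partition enumeration.

    Every one of the 2^(|x|-1) ordered partitions of ``x`` is scored as the
    sum over parts of the best plain global-alignment score against any
    motif.  Exponential — inputs longer than 15 bp are rejected.
    """
    params = params or ScoringParams()
    x = _clean_seq(x, "sequence")
    motifs = [_clean_seq(m, "motif") for m in motifs]
    if not motifs:
        raise ValueError("at least one motif is required")
    n = len(x)
    if n > _MAX_ORACLE_LEN:
        raise ValueError(
            f"oracle input is limited to {_MAX_ORACLE_LEN} bp (got {n})"
        )
    part_score: dict[tuple[int, int], int] = {}
    for i in range(n):
        for j in range(i + 1, n + 1):
            part_score[(i, j)] = max(
                _nw_score(x[i:j], m, params) for m in motifs
            )
    best = None
    for mask in range(1 << (n - 1)):
        cuts = [0] + [k + 1 for k in range(n - 1) if mask >> k & 1] + [n]
        total = sum(
            part_score[(cuts[t], cuts[t + 1])] for t in range(len(cuts) - 1)
        )
        if best is None or total > best:
            best = total
    return best
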