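"""Synthetic annotations and multi-phylum distance tables for pipeline testing.

Two generators:

* :func:`simulate_genome_annotation` lays genes along replicons with a
  Markov strand process and draws each consecutive-boundary distance from a
  configurable mixture whose default emulates the empirical distance
  distribution of prokaryotic genomes: point masses at −8/−4/−1, a short
  nonnegative band, a narrow +9..+12 component, a broad +50..+150
  component, and long-overlap tails in both reading-frame phases (the
  phase-1 tail heavier).  Optionally a replicon sequence is emitted whose
  serial-pair boundaries carry start/stop codon motifs consistent with the
  drawn overlap, and shared-stem gene-name pairs are planted with
  bin-dependent probability so a known complex enrichment exists.

* :func:`simulate_multi_phylum_dataset` generates distance observations as
  COG-pair effect + phylum effect + rounded Gaussian noise, returning the
  ground truth for recovery tests.

Both are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .complex_enrichment import distance_bin
from .factor_model import DistanceObservation
from .pair_analysis import CodonSets, GeneRecord, _constrained_layout, overlap_feasibility

__all__ = [
    "GenomeSimSpec",
    "MultiPhylumSimSpec",
    "simulate_genome_annotation",
    "simulate_multi_phylum_dataset",
    "DEFAULT_DISTANCE_MIXTURE",
]

# (component, weight); components: ("point", v), ("uniform", lo, hi),
# ("choice", (v1, v2, ...)).  Weights sum to 1.
DEFAULT_DISTANCE_MIXTURE: tuple[tuple[tuple, float], ...] = (
    (("point", -4), 0.14),
    (("point", -1), 0.05),
    (("point", -8), 0.03),
    (("uniform", 0, 6), 0.10),
    (("uniform", 9, 12), 0.07),
    (("uniform", 50, 150), 0.35),
    (("choice", tuple(range(-11, -60, -3))), 0.03),  # phase-1 long-overlap tail
    (("choice", tuple(range(-10, -60, -3))), 0.01),  # phase-2 long-overlap tail
    (("uniform", 13, 49), 0.12),
    (("uniform", 151, 300), 0.10),
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _component_support(component: tuple) -> set[int]:
    kind = component[0]
    if kind == "point":
        return {int(component[1])}
    if kind == "uniform":
        return set(range(int(component[1]), int(component[2]) + 1))
    if kind == "choice":
        return {int(v) for v in component[1]}
    raise ValueError(f"unknown mixture component kind {kind!r}")


@dataclass(frozen=True)
class GenomeSimSpec:
    """Parameters of the synthetic-annotation generator."""

    n_genes: int = 2000
    n_replicons: int = 1
    strand_switch_prob: float = 0.2
    distance_mixture: tuple[tuple[tuple, float], ...] = DEFAULT_DISTANCE_MIXTURE
    complex_pair_prob_short: float = 0.355
    complex_pair_prob_long: float = 0.225
    emit_sequences: bool = False
    codon_sets: CodonSets = field(default_factory=CodonSets)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_replicons < 1:
            raise ValueError("need at least 2 genes and 1 replicon")
        if not 0.0 <= self.strand_switch_prob <= 1.0:
            raise ValueError("strand_switch_prob must be a probability")
        for p in (self.complex_pair_prob_short, self.complex_pair_prob_long):
            if not 0.0 <= p <= 1.0:
                raise ValueError("complex-pair probabilities must be in [0, 1]")
        weights = [w for _, w in self.distance_mixture]
        if any(w <= 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must be positive and sum to 1")
        support: set[int] = set()
        for component, _ in self.distance_mixture:
            support |= _component_support(component)
        if self.emit_sequences:
            infeasible = {
                k
                for k in support
                if -5 <= k <= -1 and not overlap_feasibility(k, self.codon_sets)
            }
            if infeasible:
                raise ValueError(
                    f"mixture support contains overlap distances {sorted(infeasible)} "
                    "for which no start/stop codon boundary motif exists with the "
                    "configured codon sets; sequences cannot be emitted"
                )


@dataclass(frozen=True)
class MultiPhylumSimSpec:
    """Parameters of the multi-phylum distance-observation generator.

    Defaults mirror the study conditions of the cross-taxon analysis: 214
    widespread COG pairs across 49 phyla, COG-pair effects with ~38 nt
    dispersion dwarfing phylum effects (~3 nt), ~25 observations per
    occupied cell, and complex-flag fractions of 35.5% (short bin) vs 22.5%
    (long bin).
    """

    n_cog_pairs: int = 214
    n_phyla: int = 49
    C_distribution: tuple[float, float] = (15.0, 38.2)  # (mean nt, sd nt)
    P_distribution: tuple[float, float] = (0.0, 2.9)  # reference phylum pinned to 0
    obs_per_cell: int | tuple[int, int] = 25
    noise_sd: float = 10.0
    complex_fraction_short: float = 0.355
    complex_fraction_long: float = 0.225
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cog_pairs < 1 or self.n_phyla < 1:
            raise ValueError("need at least one COG pair and one phylum")
        if self.C_distribution[1] < 0 or self.P_distribution[1] < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        for p in (self.complex_fraction_short, self.complex_fraction_long):
            if not 0.0 <= p <= 1.0:
                raise ValueError("complex fractions must be in [0, 1]")


def _sample_mixture(
    rng: np.random.Generator, mixture: Sequence[tuple[tuple, float]], n: int
) -> np.ndarray:
    weights = np.array([w for _, w in mixture])
    which = rng.choice(len(mixture), size=n, p=weights / weights.sum())
    out = np.empty(n, dtype=np.int64)
    for idx, (component, _) in enumerate(mixture):
        sel = which == idx
        count = int(sel.sum())
        if count == 0:
            continue
        kind = component[0]
        if kind == "point":
            out[sel] = int(component[1])
        elif kind == "uniform":
            out[sel] = rng.integers(int(component[1]), int(component[2]) + 1, size=count)
        elif kind == "choice":
            out[sel] = rng.choice(np.array(component[1], dtype=np.int64), size=count)
    return out


def _sample_nonnegative(
    rng: np.random.Generator, mixture: Sequence[tuple[tuple, float]]
) -> int:
    # boundaries between opposite-strand genes never overlap in the simulation
    # (overlapping start/stop codons of antiparallel genes are not modeled)
    for _ in range(1000):
        d = int(_sample_mixture(rng, mixture, 1)[0])
        if d >= 0:
            return d
    return 50


def _stamp(seq: list[str], pos_1based: int, base: str) -> None:
    seq[pos_1based - 1] = base


def simulate_genome_annotation(
    spec: GenomeSimSpec,
) -> tuple[list[GeneRecord], dict[str, str] | None]:
    """Generate gene records (and optionally replicon sequences).

    Gene lengths are uniform multiples of 3 in 300..3000 nt; consecutive
    boundaries between same-strand genes take i.i.d. mixture draws as their
    intergenic distance, while opposite-strand boundaries redraw until
    nonnegative.  Shared-stem complex name pairs (e.g. cx0012A/cx0012B, A
    upstream) are planted at alternating serial boundaries with probability
    ``complex_pair_prob_short`` or ``complex_pair_prob_long`` according to
    the drawn distance's bin, so pair-level flags are independent.
    """
    rng = np.random.default_rng(spec.seed)
    per_replicon = [spec.n_genes // spec.n_replicons] * spec.n_replicons
    per_replicon[0] += spec.n_genes - sum(per_replicon)

    records: list[GeneRecord] = []
    sequences: dict[str, str] | None = {} if spec.emit_sequences else None
    complex_counter = 0
    gene_counter = 0

    for rep_idx, n_genes in enumerate(per_replicon):
        replicon_id = f"replicon{rep_idx:02d}"
        strands: list[str] = ["+" if rng.random() < 0.5 else "-"]
        for _ in range(n_genes - 1):
            prev = strands[-1]
            if rng.random() < spec.strand_switch_prob:
                strands.append("-" if prev == "+" else "+")
            else:
                strands.append(prev)

        lengths = 3 * rng.integers(100, 1001, size=n_genes)
        starts = np.empty(n_genes, dtype=np.int64)
        stops = np.empty(n_genes, dtype=np.int64)
        distances = np.empty(n_genes - 1, dtype=np.int64) if n_genes > 1 else np.empty(0, dtype=np.int64)
        starts[0] = 1000
        stops[0] = starts[0] + lengths[0] - 1
        for i in range(1, n_genes):
            serial = strands[i] == strands[i - 1]
            if serial:
                d = int(_sample_mixture(rng, spec.distance_mixture, 1)[0])
            else:
                d = _sample_nonnegative(rng, spec.distance_mixture)
            distances[i - 1] = d
            starts[i] = stops[i - 1] + 1 + d
            stops[i] = starts[i] + lengths[i] - 1

        # plant shared-stem complex names at alternating serial boundaries
        names: list[str | None] = [None] * n_genes
        upper = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
        for i in range(0, n_genes - 1, 2):
            if strands[i] != strands[i + 1]:
                continue
            bin_label = distance_bin(int(distances[i]))
            p = (
                spec.complex_pair_prob_short
                if bin_label == "short"
                else spec.complex_pair_prob_long
            )
            if rng.random() < p:
                stem = f"cx{complex_counter:05d}"
                complex_counter += 1
                up, down = (i, i + 1) if strands[i] == "+" else (i + 1, i)
                names[up] = stem + "A"
                names[down] = stem + "B"
        for i in range(n_genes):
            if names[i] is None and rng.random() < 0.5:
                names[i] = f"g{gene_counter + i:06d}" + upper[rng.integers(26)]

        for i in range(n_genes):
            records.append(
                GeneRecord(
                    replicon_id=replicon_id,
                    start=int(starts[i]),
                    stop=int(stops[i]),
                    strand=strands[i],  # type: ignore[arg-type]
                    locus_tag=f"SIM_{gene_counter + i:06d}",
                    gene_name=names[i],
                )
            )

        if sequences is not None:
            sequences[replicon_id] = _build_sequence(
                rng, spec, strands, starts, stops, distances
            )
        gene_counter += n_genes

    return records, sequences


def _build_sequence(
    rng: np.random.Generator,
    spec: GenomeSimSpec,
    strands: Sequence[str],
    starts: np.ndarray,
    stops: np.ndarray,
    distances: np.ndarray,
) -> str:
    codons = spec.codon_sets
    start_pool = sorted(codons.start_codons)
    stop_pool = sorted(codons.stop_codons)
    length = int(stops[-1]) + 1000
    seq = list(rng.choice(list("ACGT"), size=length))

    def place(pos: int, text: str) -> None:
        for offset, base in enumerate(text):
            _stamp(seq, pos + offset, base)

    for i, strand in enumerate(strands):
        start_codon = start_pool[rng.integers(len(start_pool))]
        stop_codon = stop_pool[rng.integers(len(stop_pool))]
        if strand == "+":
            place(int(starts[i]), start_codon)
            place(int(stops[i]) - 2, stop_codon)
        else:
            place(int(starts[i]), stop_codon[::-1].translate(_COMPLEMENT))
            place(int(stops[i]) - 2, start_codon[::-1].translate(_COMPLEMENT))

    # overwrite constrained serial boundaries with a jointly feasible motif
    for i in range(len(strands) - 1):
        if strands[i] != strands[i + 1]:
            continue
        k = int(distances[i])
        if not -5 <= k <= -1:
            continue
        motifs = sorted(overlap_feasibility(k, codons))  # non-empty by spec validation
        motif = motifs[rng.integers(len(motifs))]
        _, stop_off, _ = _constrained_layout(k)
        if strands[i] == "+":
            # upstream stop codon's last base sits at stops[i]
            anchor = int(stops[i]) - (stop_off + 2)
            for m, base in enumerate(motif):
                _stamp(seq, anchor + m, base)
        else:
            # upstream (right) gene's stop-codon last base sits at starts[i+1]
            anchor = int(starts[i + 1]) + stop_off + 2
            for m, base in enumerate(motif):
                _stamp(seq, anchor - m, base.translate(_COMPLEMENT))
    return "".join(seq)


def simulate_multi_phylum_dataset(
    spec: MultiPhylumSimSpec,
) -> tuple[list[DistanceObservation], dict]:
    """Distance observations drawn as round(C_i + P_j + N(0, noise_sd)).

    Returns the observations plus a truth dictionary with the drawn effects
    (reference phylum effect exactly 0), the per-COG-pair complex flags
    (Bernoulli with bin-dependent probability, the bin taken from the
    planted C_i), and the reference phylum name.
    """
    rng = np.random.default_rng(spec.seed)
    cogs = [f"cp{i:04d}" for i in range(spec.n_cog_pairs)]
    phyla = [f"phy{j:02d}" for j in range(spec.n_phyla)]
    reference = phyla[0]

    C = rng.normal(spec.C_distribution[0], spec.C_distribution[1], size=spec.n_cog_pairs)
    P = rng.normal(spec.P_distribution[0], spec.P_distribution[1], size=spec.n_phyla)
    P[0] = 0.0

    flags: dict[str, bool] = {}
    for i, cog in enumerate(cogs):
        bin_label = distance_bin(float(C[i]))
        p = (
            spec.complex_fraction_short
            if bin_label == "short"
            else spec.complex_fraction_long
        )
        flags[cog] = bool(rng.random() < p)

    observations: list[DistanceObservation] = []
    for i, cog in enumerate(cogs):
        for j, phylum in enumerate(phyla):
            if isinstance(spec.obs_per_cell, tuple):
                n_obs = int(rng.integers(spec.obs_per_cell[0], spec.obs_per_cell[1] + 1))
            else:
                n_obs = spec.obs_per_cell
            noise = rng.normal(0.0, spec.noise_sd, size=n_obs) if spec.noise_sd > 0 else np.zeros(n_obs)
            values = np.rint(C[i] + P[j] + noise)
            observations.extend(
                DistanceObservation(cog_pair_id=cog, phylum=phylum, distance=float(v))
                for v in values
            )

    truth = {
        "C": dict(zip(cogs, (float(v) for v in C))),
        "P": dict(zip(phyla, (float(v) for v in P))),
        "complex_flags": flags,
        "reference_phylum": reference,
    }
    return observations, truth
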