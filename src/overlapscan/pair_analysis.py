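"""Adjacent gene-pair extraction, classification and overlap arithmetic.

The analysis works in an internal coordinate format in which every coding
region is described by (start, stop, strand) with ``start < stop`` always.
On the forward strand, ``start`` is the first base of the start codon and
``stop`` the last base of the stop codon; on the reverse strand, ``start``
is the last base of the stop codon and ``stop`` the first base of the start
codon.  This makes the intergenic distance of a same-strand (serial) pair a
single strand-independent expression::

    distance = second.start - first.stop - 1

Negative distances denote gene overlaps.  The two most common overlap
configurations in prokaryotic genomes anchor the sign convention: the
``ATGA`` boundary motif (start codon ATG overlapping stop codon TGA by four
bases of gene span) gives distance −4, and ``TAATG`` gives −1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Iterable, Literal, Sequence

__all__ = [
    "GeneRecord",
    "GenePair",
    "CodonSets",
    "UNCONSTRAINED",
    "filter_protein_coding",
    "remove_transposase_insertions",
    "extract_adjacent_pairs",
    "classify_orientation",
    "drop_truncated_pairs",
    "intergenic_distance",
    "overlap_phase",
    "overlap_feasibility",
    "serial_pairs",
    "reverse_complement_records",
]

Strand = Literal["+", "-"]
Orientation = Literal["serial", "convergent", "divergent"]

#: Sentinel returned by :func:`overlap_feasibility` for distances at which the
#: start and stop codons occupy disjoint bases, so any codon combination works.
UNCONSTRAINED = "unconstrained"

#: Distances flagged as anomalous in pair tables: overlaps longer than 60 nt
#: are overwhelmingly annotation artifacts in prokaryotes.
ANOMALOUS_OVERLAP = -60


@dataclass(frozen=True, slots=True)
class GeneRecord:
    """One gene in the internal coordinate format (``start < stop``)."""

    replicon_id: str
    start: int
    stop: int
    strand: Strand
    locus_tag: str
    gene_name: str | None = None
    cog_id: str | None = None
    is_protein_coding: bool = True
    truncated_start: bool = False
    truncated_stop: bool = False
    transposase_internal: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.stop:
            raise ValueError(
                f"gene {self.locus_tag!r}: start ({self.start}) must be < stop ({self.stop})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.locus_tag!r}: strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True, slots=True)
class GenePair:
    """Two coordinate-adjacent genes on one replicon.

    ``first`` has the smaller start coordinate.  ``distance``/``phase`` and
    the transcription-order locus tags are set for serial pairs only.
    """

    replicon_id: str
    first: GeneRecord
    second: GeneRecord
    orientation: Orientation | None = None
    distance: int | None = None
    phase: int | None = None
    upstream_locus: str | None = None
    downstream_locus: str | None = None

    def __post_init__(self) -> None:
        if self.first.replicon_id != self.second.replicon_id:
            raise ValueError("pair members must share a replicon")
        if self.first.start > self.second.start:
            raise ValueError("pair members must be ordered by start coordinate")

    @property
    def upstream(self) -> GeneRecord:
        """Transcriptionally upstream gene of a serial pair."""
        if self.orientation != "serial":
            raise ValueError("transcription order is defined for serial pairs only")
        return self.first if self.first.strand == "+" else self.second

    @property
    def downstream(self) -> GeneRecord:
        if self.orientation != "serial":
            raise ValueError("transcription order is defined for serial pairs only")
        return self.second if self.first.strand == "+" else self.first

    @property
    def anomalous_overlap(self) -> bool:
        """True for overlaps deeper than 60 nt (flagged, never dropped)."""
        return self.distance is not None and self.distance < ANOMALOUS_OVERLAP


@dataclass(frozen=True)
class CodonSets:
    """Start and stop codon repertoires used for overlap feasibility."""

    start_codons: frozenset[str] = frozenset({"ATG", "GTG", "TTG"})
    stop_codons: frozenset[str] = frozenset({"TAA", "TAG", "TGA"})
    extended_start_codons: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for codon in (
            set(self.start_codons) | set(self.stop_codons) | set(self.extended_start_codons)
        ):
            if len(codon) != 3 or set(codon) - set("ACGT"):
                raise ValueError(f"not a DNA codon: {codon!r}")
        object.__setattr__(self, "start_codons", frozenset(self.start_codons))
        object.__setattr__(self, "stop_codons", frozenset(self.stop_codons))
        object.__setattr__(self, "extended_start_codons", frozenset(self.extended_start_codons))

    @property
    def all_start_codons(self) -> frozenset[str]:
        return self.start_codons | self.extended_start_codons


def filter_protein_coding(records: Iterable[GeneRecord]) -> list[GeneRecord]:
    """Drop stable-RNA and other non-coding features, preserving order."""
    return [r for r in records if r.is_protein_coding]


def remove_transposase_insertions(records: Iterable[GeneRecord]) -> list[GeneRecord]:
    """Remove transposase genes inserted inside another gene.

    A transposon landing in a gene splits it into two fragments with the
    transposase in between; the transposase must not contribute gene pairs.
    Surviving records are returned unaltered, in order.
    """
    return [r for r in records if not r.transposase_internal]


def _sort_key(r: GeneRecord) -> tuple[str, int, int, str]:
    return (r.replicon_id, r.start, r.stop, r.locus_tag)


def extract_adjacent_pairs(records: Iterable[GeneRecord]) -> list[GenePair]:
    """Sort genes per replicon by start coordinate and pair neighbours.

    Per replicon with ``n`` genes, exactly ``n − 1`` pairs are formed; pairs
    never span replicons.  Replicons are treated as linear: no pair is formed
    across a circular origin.  Ties in start coordinate are broken by
    (stop, locus_tag).
    """
    recs = sorted(records, key=_sort_key)
    seen: set[tuple[str, int, int, str, str]] = set()
    for r in recs:
        key = (r.replicon_id, r.start, r.stop, r.strand, r.locus_tag)
        if key in seen:
            raise ValueError(f"duplicate gene record: {key}")
        seen.add(key)
    pairs: list[GenePair] = []
    for a, b in zip(recs, recs[1:]):
        if a.replicon_id != b.replicon_id:
            continue
        pairs.append(GenePair(replicon_id=a.replicon_id, first=a, second=b))
    return pairs


def classify_orientation(pair: GenePair) -> GenePair:
    """Assign serial / convergent (→ ←) / divergent (← →) orientation.

    For serial pairs the transcription-order locus tags are also set:
    on the forward strand the first (leftmost) gene is upstream, on the
    reverse strand the second one is.
    """
    s1, s2 = pair.first.strand, pair.second.strand
    if s1 == s2:
        up, down = (pair.first, pair.second) if s1 == "+" else (pair.second, pair.first)
        return replace(
            pair,
            orientation="serial",
            upstream_locus=up.locus_tag,
            downstream_locus=down.locus_tag,
        )
    orientation: Orientation = "convergent" if s1 == "+" else "divergent"
    return replace(pair, orientation=orientation)


def drop_truncated_pairs(pairs: Iterable[GenePair]) -> list[GenePair]:
    """Remove serial pairs whose distance-defining termini are truncated.

    The intergenic distance runs from the upstream gene's stop codon to the
    downstream gene's start codon, so a pair is dropped iff the upstream gene
    lacks its stop codon or the downstream gene lacks its start codon.
    """
    kept = []
    for p in pairs:
        if p.orientation == "serial" and (p.upstream.truncated_stop or p.downstream.truncated_start):
            continue
        kept.append(p)
    return kept


def intergenic_distance(pair: GenePair) -> int:
    """Distance in nt between the upstream stop codon and downstream start codon.

    Negative values denote overlaps (−4 for the ATGA boundary, −1 for TAATG);
    0 means the genes abut with no gap.  Valid for serial pairs only.
    """
    if pair.orientation != "serial":
        raise ValueError("intergenic distance is defined for serial pairs only")
    return pair.second.start - pair.first.stop - 1


def overlap_phase(k: int) -> int:
    """Reading-frame phase of a distance, in {0, 1, 2}.

    Defined piecewise: ``p = k − 3·⌊k/3⌋`` for k ≥ 0 and ``p = k + 3·⌈−k/3⌉``
    for k < 0; both branches equal the nonnegative residue of k modulo 3.
    Phase-1 overlaps are −8, −11, −14, …; phase-2 overlaps are −7, −10, −13, …
    """
    if k >= 0:
        return k - 3 * (k // 3)
    return k + 3 * math.ceil(-k / 3)


def serial_pairs(
    records: Iterable[GeneRecord],
    *,
    drop_truncated: bool = True,
) -> list[GenePair]:
    """Full cleanup-and-classify pipeline; returns serial pairs with distances.

    Steps: keep protein-coding genes, remove gene-internal transposases,
    extract adjacent pairs, classify orientation, (optionally) drop pairs
    with truncated distance-defining termini, and attach distance and phase.
    """
    recs = remove_transposase_insertions(filter_protein_coding(records))
    pairs = [classify_orientation(p) for p in extract_adjacent_pairs(recs)]
    pairs = [p for p in pairs if p.orientation == "serial"]
    if drop_truncated:
        pairs = drop_truncated_pairs(pairs)
    out = []
    for p in pairs:
        k = intergenic_distance(p)
        out.append(replace(p, distance=k, phase=overlap_phase(k)))
    return out


def _constrained_layout(k: int) -> tuple[int, int, int]:
    """Motif geometry for −5 ≤ k ≤ −1.

    Returns (motif_length, stop_offset, start_offset): 0-based offsets of the
    stop and start codons within the joint boundary motif.  Derived from the
    distance definition: with the stop codon's last base at position ``s`` the
    start codon's first base sits at ``s + k + 1``.
    """
    a = k + 3  # start-codon offset relative to the stop codon's first base
    shift = -min(0, a)
    stop_off = shift
    start_off = shift + a
    length = max(stop_off + 3, start_off + 3) - min(stop_off, start_off)
    return length, stop_off, start_off


def overlap_feasibility(
    k: int, codons: CodonSets | None = None
) -> frozenset[str] | str:
    """Enumerate boundary motifs compatible with a k-nt serial overlap.

    For −5 ≤ k ≤ −1 the downstream start codon and the upstream stop codon
    share bases, so only some codon combinations are realizable; the function
    returns the set of joint boundary motifs (empty set = the overlap is
    impossible with the given codon repertoires).  With canonical codons the
    impossible distances are −2 (an NTG start would need an NNT stop), −5
    (all starts end in G, all stops begin with T) and the degenerate −3
    (start codon and stop codon would have to be the same triplet).  For
    k ≥ 0 or k ≤ −6 the codons occupy disjoint bases and the sentinel
    :data:`UNCONSTRAINED` is returned.
    """
    if codons is None:
        codons = CodonSets()
    if k >= 0 or k <= -6:
        return UNCONSTRAINED
    length, stop_off, start_off = _constrained_layout(k)
    motifs: set[str] = set()
    for stop, start in product(codons.stop_codons, codons.all_start_codons):
        motif: list[str | None] = [None] * length
        ok = True
        for codon, off in ((stop, stop_off), (start, start_off)):
            for i, base in enumerate(codon):
                pos = off + i
                if motif[pos] is None:
                    motif[pos] = base
                elif motif[pos] != base:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            motifs.add("".join(b for b in motif if b is not None))
    return frozenset(motifs)


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement_records(
    records: Sequence[GeneRecord], replicon_length: int
) -> list[GeneRecord]:
    """Mirror a replicon: flip coordinates and strands of every gene.

    Utility for strand-symmetry checks: serial-pair distances are invariant
    under this transformation.
    """
    out = []
    for r in records:
        out.append(
            replace(
                r,
                start=replicon_length - r.stop + 1,
                stop=replicon_length - r.start + 1,
                strand="-" if r.strand == "+" else "+",
            )
        )
    return out
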