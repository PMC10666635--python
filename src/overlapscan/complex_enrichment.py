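"""Enrichment of heteromeric-complex subunits among tightly coupled gene pairs.

Gene pairs (or COG-pair median summaries) are binned by intergenic
distance — short (−8..+10 nt, predictive of termination–reinitiation
coupling) vs long (> +20 nt, predictive of independent translation), with
the gene-specific +11..+20 band and distances below −8 excluded — and
cross-tabulated against complex membership.  Complex membership comes
either from explicit curation flags or from the shared-gene-name-stem
heuristic (xyzA upstream / xyzB downstream implies interacting subunits).

Significance is assessed two ways: a Pearson χ² test on the 2×2 table, and
a double-resampling bootstrap over COG pairs then gene pairs, summarized by
a z-score of the log enrichment ratios.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "BootstrapResult",
    "EnrichmentReport",
    "CogPairCell",
    "shared_stem_complex_flag",
    "distance_bin",
    "bin_by_distance",
    "contingency_table",
    "enrichment_ratio",
    "chi_square_test",
    "bootstrap_enrichment",
    "enrichment_report",
]

SHORT_LO = -8
SHORT_HI = 10
LONG_GT = 20
INCLUSION_PROB = 1.0 - math.exp(-1.0)  # ≈ 0.63


@dataclass(frozen=True, slots=True)
class ContingencyTable2x2:
    """Complex status vs distance bin.

    a: complex & short, b: non-complex & short, c: complex & long,
    d: non-complex & long.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def short_total(self) -> int:
        return self.a + self.b

    @property
    def long_total(self) -> int:
        return self.c + self.d

    @property
    def short_fraction(self) -> float:
        return self.a / self.short_total

    @property
    def long_fraction(self) -> float:
        return self.c / self.long_total


@dataclass(frozen=True)
class BootstrapResult:
    replicate_ratios: tuple[float, ...]
    n_reps: int
    n_degenerate: int
    z: float
    p_normal: float
    seed: int
    inclusion_prob: float


@dataclass(frozen=True)
class EnrichmentReport:
    table: ContingencyTable2x2
    short_fraction: float
    long_fraction: float
    enrichment: float
    chi2: float
    p_chi2: float
    bootstrap: BootstrapResult | None = None

    def to_json(self, **kwargs) -> str:
        payload = asdict(self)
        return json.dumps(payload, **kwargs)


@dataclass(frozen=True, slots=True)
class CogPairCell:
    """Bootstrap input: one COG pair's flag, distance bin and gene-pair count."""

    cog_pair_id: str
    complex_flag: bool
    distance_bin: str  # "short" | "long" | "excluded"
    gene_pair_count: int

    def __post_init__(self) -> None:
        if self.distance_bin not in ("short", "long", "excluded"):
            raise ValueError(f"unknown distance bin {self.distance_bin!r}")
        if self.gene_pair_count < 0:
            raise ValueError("gene_pair_count must be nonnegative")


def shared_stem_complex_flag(name_up: str | None, name_down: str | None) -> bool:
    """Shared-gene-name-stem heuristic for heteromeric-complex subunits.

    True iff both names end in a single uppercase letter, the final letters
    differ, and the stems (name minus the final letter) are equal and
    non-empty — e.g. hyfH/hyfI.  The heuristic is knowingly imperfect (menD
    and menH share a stem but encode consecutive enzymes, not complex
    subunits); explicit curation flags override it where available.
    """
    if not name_up or not name_down:
        return False
    up_last, down_last = name_up[-1], name_down[-1]
    if not (up_last.isalpha() and up_last.isupper()):
        return False
    if not (down_last.isalpha() and down_last.isupper()):
        return False
    if up_last == down_last:
        return False
    stem_up, stem_down = name_up[:-1], name_down[:-1]
    return bool(stem_up) and stem_up == stem_down


def distance_bin(
    distance: float,
    short_lo: int = SHORT_LO,
    short_hi: int = SHORT_HI,
    long_gt: int = LONG_GT,
) -> str:
    """Classify a distance (or COG-pair median) as short / long / excluded."""
    if short_lo > short_hi or short_hi > long_gt:
        raise ValueError("bins overlap: need short_lo <= short_hi <= long_gt")
    if short_lo <= distance <= short_hi:
        return "short"
    if distance > long_gt:
        return "long"
    return "excluded"


def bin_by_distance(
    distances: Iterable[float],
    short_lo: int = SHORT_LO,
    short_hi: int = SHORT_HI,
    long_gt: int = LONG_GT,
) -> dict[str, list[int]]:
    """Partition indices by distance bin; short + long + excluded is exhaustive."""
    bins: dict[str, list[int]] = {"short": [], "long": [], "excluded": []}
    for i, d in enumerate(distances):
        bins[distance_bin(d, short_lo, short_hi, long_gt)].append(i)
    return bins


def contingency_table(
    binned: Mapping[str, Sequence[int]], complex_flags: Sequence[bool]
) -> ContingencyTable2x2:
    """Cross-tabulate bins against complex flags; excluded items never count."""
    a = sum(1 for i in binned["short"] if complex_flags[i])
    b = len(binned["short"]) - a
    c = sum(1 for i in binned["long"] if complex_flags[i])
    d = len(binned["long"]) - c
    return ContingencyTable2x2(a, b, c, d)


def enrichment_ratio(table: ContingencyTable2x2) -> float:
    """Complex fraction in the short bin over that in the long bin."""
    if table.short_total == 0 or table.long_total == 0:
        raise ValueError("both distance bins must be populated")
    if table.c == 0:
        warnings.warn("no complex pairs in the long bin: enrichment ratio is infinite")
        return math.inf
    return table.short_fraction / table.long_fraction


def chi_square_test(table: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson χ² (df=1, no continuity correction) on the 2×2 table."""
    observed = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    if (observed.sum(axis=0) == 0).any() or (observed.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a zero marginal leaves nothing to test")
    chi2, p, _, _ = stats.chi2_contingency(observed, correction=False)
    return float(chi2), float(p)


def bootstrap_enrichment(
    cog_pair_table: Sequence[CogPairCell],
    n_reps: int = 1000,
    inclusion_prob: float = INCLUSION_PROB,
    seed: int = 0,
    total_draws: int | None = None,
) -> BootstrapResult:
    """Double-resampling bootstrap of the enrichment ratio.

    Each replicate (i) retains every COG pair independently with probability
    ``inclusion_prob`` (default 1 − e⁻¹ ≈ 0.63), then (ii) draws
    ``total_draws`` gene pairs with replacement from the retained COG pairs,
    weighted by their gene-pair counts, and recomputes the enrichment ratio
    on the resampled 2×2 table.  Excluded-bin COG pairs participate in both
    resampling stages but never enter the table.

    The z-score is mean(log ratio) / sd(log ratio) over replicates, with a
    one-sided upper-tail standard-normal p-value (natural logs; the base
    cancels in mean/sd).  Replicates with an empty long bin or no complex
    pairs in the long bin are dropped and counted; a warning is issued if
    more than 10% of replicates are degenerate.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if not 0.0 < inclusion_prob <= 1.0:
        raise ValueError("inclusion_prob must be in (0, 1]")
    cells = list(cog_pair_table)
    counts = np.array([c.gene_pair_count for c in cells], dtype=float)
    if counts.sum() <= 0:
        raise ValueError("total gene-pair count must be positive")
    if total_draws is None:
        total_draws = int(counts.sum())

    # category of each COG pair among the five resampling cells
    category_names = [
        ("short", True), ("short", False), ("long", True), ("long", False),
    ]
    cat = np.full(len(cells), 4, dtype=np.intp)  # 4 = excluded
    for idx, cell in enumerate(cells):
        if cell.distance_bin != "excluded":
            cat[idx] = category_names.index((cell.distance_bin, cell.complex_flag))

    rng = np.random.default_rng(seed)
    ratios: list[float] = []
    n_degenerate = 0
    for _ in range(n_reps):
        mask = rng.random(len(cells)) < inclusion_prob
        weights = np.where(mask, counts, 0.0)
        total_weight = weights.sum()
        if total_weight == 0:
            n_degenerate += 1
            continue
        cell_weights = np.bincount(cat, weights=weights, minlength=5)
        drawn = rng.multinomial(total_draws, cell_weights / total_weight)
        a, b, c, d = (int(x) for x in drawn[:4])
        if c + d == 0 or a + b == 0 or c == 0 or a == 0:
            n_degenerate += 1
            continue
        ratios.append((a / (a + b)) / (c / (c + d)))

    if n_degenerate > 0.1 * n_reps:
        warnings.warn(
            f"{n_degenerate} of {n_reps} bootstrap replicates were degenerate "
            "(empty or complex-free long bin)"
        )
    if len(ratios) < 2:
        raise ValueError("fewer than two non-degenerate bootstrap replicates")
    log_ratios = np.log(ratios)
    sd = float(np.std(log_ratios, ddof=1))
    z = float(np.mean(log_ratios) / sd) if sd > 0 else math.inf
    p_normal = float(stats.norm.sf(z)) if math.isfinite(z) else 0.0
    return BootstrapResult(
        replicate_ratios=tuple(ratios),
        n_reps=n_reps,
        n_degenerate=n_degenerate,
        z=z,
        p_normal=p_normal,
        seed=seed,
        inclusion_prob=inclusion_prob,
    )


def enrichment_report(
    table: ContingencyTable2x2,
    bootstrap: BootstrapResult | None = None,
) -> EnrichmentReport:
    """Assemble fractions, enrichment ratio and χ² test into one report."""
    chi2, p = chi_square_test(table)
    return EnrichmentReport(
        table=table,
        short_fraction=table.short_fraction,
        long_fraction=table.long_fraction,
        enrichment=enrichment_ratio(table),
        chi2=chi2,
        p_chi2=p,
        bootstrap=bootstrap,
    )
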