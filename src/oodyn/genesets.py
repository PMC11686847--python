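"""Overlap of differential-expression lists with reference gene sets.

Reports the overlap fraction the way such results are usually printed
(integer percent of the list, rounded half away from zero) alongside the
exact arithmetic, plus an upper-tail hypergeometric enrichment p value.
The universe defaults to the set of genes actually tested, supplied by the
caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from scipy import stats

from .io_formats import GeneSet, ValidationError


@dataclass
class OverlapStat:
    set_name: str
    list_name: str
    overlap: int
    list_size: int
    set_size: int
    universe: int | None = None
    p_hyper: float | None = None

    def __post_init__(self) -> None:
        if self.overlap > min(self.list_size, self.set_size):
            raise ValidationError("overlap cannot exceed list or set size")

    @property
    def percent(self) -> float:
        return 100.0 * self.overlap / self.list_size

    @property
    def display_percent(self) -> int:
        """Integer percent, rounded half away from zero (reporting style)."""
        return int(math.floor(self.percent + 0.5))


def overlap_percentage(
    deg_list: Iterable[str], gene_set: GeneSet, list_name: str = "deg_list"
) -> OverlapStat:
    """Fraction of a DEG list captured by a gene set (no p value)."""
    genes = set(deg_list)
    if not genes:
        raise ValidationError("empty gene list")
    return OverlapStat(
        set_name=gene_set.name,
        list_name=list_name,
        overlap=len(genes & set(gene_set.members)),
        list_size=len(genes),
        set_size=len(gene_set.members),
    )


def hypergeometric_test(
    overlap: int, list_size: int, set_size: int, universe: int
) -> float:
    """Upper-tail P[X >= overlap] for X ~ Hypergeometric(universe, set_size, list_size)."""
    if max(list_size, set_size) > universe or not 0 <= overlap <= min(list_size, set_size):
        raise ValidationError(
            f"inconsistent counts: overlap={overlap}, list={list_size}, "
            f"set={set_size}, universe={universe}"
        )
    if overlap == 0:
        return 1.0
    return float(stats.hypergeom.sf(overlap - 1, universe, set_size, list_size))


def annotate_enrichment(stat: OverlapStat, universe: int) -> OverlapStat:
    """Attach the universe and hypergeometric p to an overlap record."""
    stat.universe = universe
    stat.p_hyper = hypergeometric_test(stat.overlap, stat.list_size, stat.set_size, universe)
    return stat
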