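"""Sorting statistic for ordered categorical (sortable) variables.

Ordinal data — severity grades, Likert responses, staging systems — admit
no meaningful subtraction, so the numeric sorting statistic is adapted by
replacing the difference of medians with a rank distance: the number of
category steps separating the two group medians, normalised by the number
of steps separating the first-n and last-m medians of the jointly sorted
values.  The result stays in [0, 1], is 0 exactly when the group medians
fall on the same category, and depends only on the category order, never
on any numeric coding.

A category-valued median is required for "number of categories between
the medians" to be an integer, so for even counts where the two middle
ranks differ the lower of the two middle categories is returned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = ["OrdinalSample", "ordinal_median", "ordinal_sorting_statistic"]


@dataclass(frozen=True)
class OrdinalSample:
    """Two groups of category labels over a shared ordered level list.

    ``levels`` is ordered lowest-first (rank 0 = lowest category).  Every
    value in either group must be a member of ``levels``.
    """

    levels: tuple[str, ...]
    values_x: tuple[str, ...]
    values_y: tuple[str, ...]
    label_x: str = "x"
    label_y: str = "y"

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        object.__setattr__(self, "values_x", tuple(self.values_x))
        object.__setattr__(self, "values_y", tuple(self.values_y))
        if len(set(self.levels)) != len(self.levels):
            raise ValueError("levels must be distinct")
        if len(self.levels) < 2:
            raise ValueError("need at least 2 ordered levels")
        rank = {lev: i for i, lev in enumerate(self.levels)}
        for name, vals in ((self.label_x, self.values_x), (self.label_y, self.values_y)):
            if not vals:
                raise ValueError(f"no data: group '{name}' is empty")
            for v in vals:
                if v not in rank:
                    raise KeyError(f"value {v!r} in group '{name}' is not a declared level")


def _ranks(values: Sequence[str], rank: dict[str, int], name: str = "values") -> list[int]:
    if not values:
        raise ValueError(f"no data: {name} is empty")
    try:
        return sorted(rank[v] for v in values)
    except KeyError as exc:
        raise KeyError(f"value {exc.args[0]!r} is not a declared level") from None


def _median_rank(sorted_ranks: Sequence[int]) -> int:
    # lower-middle convention for even counts: a category must be returned
    c = len(sorted_ranks)
    return sorted_ranks[(c - 1) // 2]


def ordinal_median(values: Sequence[str], levels: Sequence[str]) -> str:
    """Median category of ``values`` under the ordering given by ``levels``.

    Odd counts return the middle category; even counts where the two
    middle ranks differ return the lower of the two middle categories.
    """
    levels = tuple(levels)
    rank = {lev: i for i, lev in enumerate(levels)}
    return levels[_median_rank(_ranks(values, rank))]


def ordinal_sorting_statistic(sample: OrdinalSample) -> float:
    """Rank-distance sorting statistic for an ordinal two-group sample.

    Same construction as the numeric statistic: orient so the group with
    the higher median category plays the role of x, sort the pooled
    values descending by rank, and divide the median category gap by the
    gap between the first-n and last-m medians.  Returns 0 when the group
    medians coincide.
    """
    rank = {lev: i for i, lev in enumerate(sample.levels)}
    rx = _ranks(sample.values_x, rank)
    ry = _ranks(sample.values_y, rank)
    med_x, med_y = _median_rank(rx), _median_rank(ry)
    if med_x == med_y:
        return 0.0
    if med_x < med_y:
        rx, ry = ry, rx
        med_x, med_y = med_y, med_x
    n = len(rx)
    z = sorted(rx + ry, reverse=True)
    z_hi = _median_rank(sorted(z[:n]))
    z_lo = _median_rank(sorted(z[n:]))
    return (med_x - med_y) / (z_hi - z_lo)
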