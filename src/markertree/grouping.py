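"""Partitions of base cluster labels — the unit the score and marker finder
operate on."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ValidationError


def _ordered(groups: Iterable[frozenset]) -> tuple[frozenset, ...]:
    return tuple(sorted((frozenset(g) for g in groups), key=lambda g: min(g)))


@dataclass(frozen=True)
class ClusterGrouping:
    """A disjoint partition of base cluster labels into ordered groups.

    Groups are ordered deterministically by their smallest member label.
    """

    groups: tuple[frozenset, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", _ordered(self.groups))
        seen: set = set()
        for g in self.groups:
            if not g:
                raise ValidationError("empty group in grouping")
            if seen & g:
                raise ValidationError("groups are not disjoint")
            seen |= g

    @classmethod
    def singletons(cls, labels: Sequence) -> "ClusterGrouping":
        return cls(tuple(frozenset([lab]) for lab in labels))

    @property
    def scope(self) -> frozenset:
        return frozenset().union(*self.groups)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_label(self, i: int) -> str:
        return "+".join(sorted(self.groups[i]))

    @property
    def group_labels(self) -> list[str]:
        return [self.group_label(i) for i in range(self.n_groups)]

    def merge(self, i: int, j: int) -> "ClusterGrouping":
        """Return a new grouping with groups i and j merged."""
        if i == j or not (0 <= i < self.n_groups and 0 <= j < self.n_groups):
            raise ValidationError(f"invalid merge pair ({i}, {j})")
        if self.n_groups <= 2:
            raise ValidationError("merging would leave a single group")
        merged = self.groups[i] | self.groups[j]
        rest = [g for k, g in enumerate(self.groups) if k not in (i, j)]
        return ClusterGrouping(tuple(rest) + (merged,))

    def key(self) -> frozenset:
        """Hashable canonical form (set of groups), for memoization."""
        return frozenset(self.groups)

    def __repr__(self) -> str:
        return "ClusterGrouping[" + " | ".join(self.group_labels) + "]"
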