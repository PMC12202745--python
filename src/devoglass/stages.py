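"""Developmental stage ordering and adjacency.

The study design samples whole animals at ten ordered timepoints spanning
complete metamorphosis: embryo (E), larva (L, all instars pooled as
replicates of one larval stage), the five classical prepupal/pupal stages
P1-P5 (P4 is the "buoyant" stage, head-sac eversion), an intermediate
(Pmid) and a late (Plate) pupa, and the adult imago (A).

Adjacency is along this chain and is non-circular: A is not adjacent to E.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DEFAULT_STAGES: tuple[str, ...] = (
    "E", "L", "P1", "P2", "P3", "P4", "P5", "Pmid", "Plate", "A",
)

#: The seven stages spanning pre-pupal and pupal development, used for
#: trajectory clustering.
PUPAL_STAGES: tuple[str, ...] = ("P1", "P2", "P3", "P4", "P5", "Pmid", "Plate")


@dataclass(frozen=True)
class StageOrder:
    """An ordered, non-circular chain of developmental stage labels."""

    labels: tuple[str, ...] = DEFAULT_STAGES
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        if len(labels) != len(set(labels)):
            raise ValueError("stage labels must be unique")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "_index", {s: i for i, s in enumerate(labels)})

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unknown stage label: {label!r}") from None

    def adjacent(self, a: str, b: str) -> bool:
        """True if the two stages are immediate neighbours in the chain."""
        return abs(self.index(a) - self.index(b)) == 1

    def neighbors(self, label: str) -> tuple[str, ...]:
        i = self.index(label)
        out = []
        if i > 0:
            out.append(self.labels[i - 1])
        if i < len(self.labels) - 1:
            out.append(self.labels[i + 1])
        return tuple(out)

    def interior(self) -> tuple[str, ...]:
        """All stages except the first and last."""
        return self.labels[1:-1]
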