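"""Edge-level prior constraints for network inference.

A :class:`PriorEdgeSet` holds unordered gene pairs labelled either
*must-present* (observed co-localized in the nuclear space, so the penalty on
the pair is relaxed and the edge is kept) or *forbidden* (observed not
co-localized, so the edge is excluded from the support).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

Pair = tuple[str, str]


def canonical_pair(a: str, b: str) -> Pair:
    """Return the pair in canonical (sorted) order; reject self-pairs."""
    a, b = str(a), str(b)
    if a == b:
        raise ValueError(f"self-pair ({a!r}, {a!r}) is not a valid gene pair")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class PriorEdgeSet:
    """Disjoint sets of must-present and forbidden gene pairs.

    Pairs are stored canonically (lexicographically sorted symbols); the two
    sets are validated to be disjoint and free of self-pairs.
    """

    must: frozenset = field(default_factory=frozenset)
    forbidden: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        must = frozenset(canonical_pair(*p) for p in self.must)
        forbidden = frozenset(canonical_pair(*p) for p in self.forbidden)
        clash = must & forbidden
        if clash:
            raise ValueError(
                f"pairs present in both must and forbidden sets: {sorted(clash)}"
            )
        object.__setattr__(self, "must", must)
        object.__setattr__(self, "forbidden", forbidden)

    @classmethod
    def empty(cls) -> "PriorEdgeSet":
        return cls()

    @property
    def genes(self) -> frozenset:
        return frozenset(g for p in (self.must | self.forbidden) for g in p)

    def __len__(self) -> int:
        return len(self.must) + len(self.forbidden)

    def merge(self, other: "PriorEdgeSet") -> "PriorEdgeSet":
        """Union of two prior sets; a pair flipping between the must and
        forbidden status across the operands is a contradiction and raises."""
        clash = (self.must & other.forbidden) | (self.forbidden & other.must)
        if clash:
            raise ValueError(
                f"contradictory prior evidence for pairs: {sorted(clash)}"
            )
        return PriorEdgeSet(
            must=self.must | other.must, forbidden=self.forbidden | other.forbidden
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, b, "present") for a, b in sorted(self.must)]
        rows += [(a, b, "absent") for a, b in sorted(self.forbidden)]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "status"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PriorEdgeSet":
        must, forbidden = set(), set()
        for _, row in frame.iterrows():
            status = str(row["status"]).strip().lower()
            pair = canonical_pair(row["gene_a"], row["gene_b"])
            if status in ("present", "must"):
                must.add(pair)
            elif status in ("absent", "forbidden"):
                forbidden.add(pair)
            else:
                raise ValueError(
                    f"unknown prior status {row['status']!r} for pair {pair}"
                )
        return cls(must=frozenset(must), forbidden=frozenset(forbidden))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PriorEdgeSet":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def merge_priors(priors: Iterable[PriorEdgeSet]) -> PriorEdgeSet:
    """Merge an iterable of prior sets, raising on any contradiction."""
    out = PriorEdgeSet.empty()
    for p in priors:
        out = out.merge(p)
    return out
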