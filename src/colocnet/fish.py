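"""3D DNA FISH distance and association analysis.

Each analysed nucleus carries four fluorescent signals for a tested gene
pair (two alleles per gene).  Signal coordinates come in voxels (anisotropic
confocal stacks, 0.077 × 0.077 × 0.284 µm per voxel by default) or directly
in µm.  A nucleus's inter-gene distance is the minimum centre-to-centre 3D
Euclidean distance over the 2 × 2 cross-gene allele pairs; distances are
classified as co-localized (d ≤ 0.5 µm), close (0.5 < d ≤ 1 µm) or distant
(d > 1 µm), and a gene pair is called associated when more than 10% of
nuclei (strictly) fall within 1 µm.  Associated pairs become must-present
priors for the next inference iteration, non-associated tested pairs become
forbidden priors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .priors import PriorEdgeSet, canonical_pair

DISTANCE_CLASSES = ("colocalized", "close", "distant")


@dataclass(frozen=True)
class FishConfig:
    """Geometry and decision parameters of the FISH analysis.

    voxel_size
        µm per voxel along x, y, z; the default reflects a confocal stack
        with 0.077 µm lateral and 0.284 µm axial resolution.
    colocalized_max / associated_max
        Class boundaries in µm (0.5 and 1.0).  The axial resolution limits
        separability below ≈0.85 µm, motivating 1 µm as the association
        cut-off.
    association_threshold
        Percentage of associated nuclei a pair must strictly exceed to be
        called associated; 10% reflects the sporadic ≈8% association level
        of negative-control pairs.
    required_signals
        Signals a nucleus must show for the tested pair (4 = 2 alleles × 2
        genes); nuclei with any other count are rejected.
    colocalized_inclusive
        Whether d equal to ``colocalized_max`` counts as co-localized.
    """

    voxel_size: tuple[float, float, float] = (0.077, 0.077, 0.284)
    colocalized_max: float = 0.5
    associated_max: float = 1.0
    association_threshold: float = 10.0
    required_signals: int = 4
    colocalized_inclusive: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.colocalized_max < self.associated_max:
            raise ValueError(
                "class boundaries must satisfy 0 < colocalized_max < associated_max"
            )
        if not 0 <= self.association_threshold <= 100:
            raise ValueError("association_threshold must lie in [0, 100]")


@dataclass(frozen=True)
class Signal:
    """One fluorescent spot: gene (or locus) label and 3D coordinates."""

    gene: str
    x: float
    y: float
    z: float
    unit: str = "um"  # "um" or "voxel"


@dataclass(frozen=True)
class NucleusRecord:
    """All signals detected in one nucleus."""

    nucleus_id: object
    signals: tuple[Signal, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "signals", tuple(self.signals))


@dataclass(frozen=True)
class AssociationResult:
    """Distance-class composition of a tested pair and the association call.

    ``pct_*`` are the reported percentages (rounded half away from zero to
    integers, as in published association tables); the exact values are kept
    in ``exact_pct_*``.  The decision rule compares the reported associated
    percentage strictly against the threshold.
    """

    pair: tuple[str, str]
    n_nuclei: int
    pct_distant: int
    pct_close: int
    pct_colocalized: int
    pct_associated: int
    is_associated: bool
    exact_pct_distant: float = field(default=math.nan, compare=False)
    exact_pct_close: float = field(default=math.nan, compare=False)
    exact_pct_colocalized: float = field(default=math.nan, compare=False)
    exact_pct_associated: float = field(default=math.nan, compare=False)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def to_micrometers(signal: Signal, cfg: FishConfig | None = None) -> Signal:
    """Convert voxel coordinates to µm (µm-flagged input is returned as is)."""
    if signal.unit == "um":
        return signal
    if signal.unit != "voxel":
        raise ValueError(f"unknown coordinate unit {signal.unit!r}")
    cfg = cfg or FishConfig()
    sx, sy, sz = cfg.voxel_size
    return replace(
        signal, x=signal.x * sx, y=signal.y * sy, z=signal.z * sz, unit="um"
    )


def _distance_um(a: Signal, b: Signal, cfg: FishConfig) -> float:
    a = to_micrometers(a, cfg)
    b = to_micrometers(b, cfg)
    return math.dist((a.x, a.y, a.z), (b.x, b.y, b.z))


def pair_signals(
    nucleus: NucleusRecord, pair: tuple[str, str], cfg: FishConfig | None = None
) -> tuple[list[Signal], list[Signal]]:
    """The two alleles of each gene of the pair, validating the 4-signal rule."""
    cfg = cfg or FishConfig()
    a, b = pair
    if a == b:
        raise ValueError(f"tested pair must involve two distinct loci, got {pair}")
    sig_a = [s for s in nucleus.signals if s.gene == a]
    sig_b = [s for s in nucleus.signals if s.gene == b]
    per_gene = cfg.required_signals // 2
    if len(sig_a) != per_gene or len(sig_b) != per_gene:
        raise ValueError(
            f"nucleus {nucleus.nucleus_id!r} does not show "
            f"{cfg.required_signals} signals for pair {a}-{b} "
            f"(found {len(sig_a)} for {a}, {len(sig_b)} for {b})"
        )
    return sig_a, sig_b


def min_intergene_distance(
    nucleus: NucleusRecord, pair: tuple[str, str], cfg: FishConfig | None = None
) -> float:
    """Minimum 3D distance (µm) over the cross-gene allele pairs of a nucleus."""
    cfg = cfg or FishConfig()
    sig_a, sig_b = pair_signals(nucleus, pair, cfg)
    return min(_distance_um(sa, sb, cfg) for sa in sig_a for sb in sig_b)


def classify_distance(d: float, cfg: FishConfig | None = None) -> str:
    """Distance class of d (µm): 'colocalized', 'close' or 'distant'."""
    cfg = cfg or FishConfig()
    if d < 0:
        raise ValueError(f"a distance cannot be negative, got {d}")
    coloc = d <= cfg.colocalized_max if cfg.colocalized_inclusive else d < cfg.colocalized_max
    if coloc:
        return "colocalized"
    if d <= cfg.associated_max:
        return "close"
    return "distant"


def association_rate(
    nuclei: Sequence[NucleusRecord],
    pair: tuple[str, str],
    cfg: FishConfig | None = None,
) -> AssociationResult:
    """Distance-class percentages and association call for a tested pair.

    Each nucleus is classified by its minimum inter-gene allele distance (a
    nucleus counts as associated when at least one cross-gene allele pair is
    within the association cut-off).  Reported percentages are rounded half
    away from zero; the association decision applies the strict >threshold
    rule to the reported associated percentage.
    """
    cfg = cfg or FishConfig()
    if not nuclei:
        raise ValueError("association_rate needs at least one valid nucleus")
    counts = {c: 0 for c in DISTANCE_CLASSES}
    for nucleus in nuclei:
        d = min_intergene_distance(nucleus, pair, cfg)
        counts[classify_distance(d, cfg)] += 1
    n = len(nuclei)
    exact = {c: 100.0 * counts[c] / n for c in DISTANCE_CLASSES}
    exact_assoc = exact["close"] + exact["colocalized"]
    pct_assoc = _round_half_away(exact_assoc)
    return AssociationResult(
        pair=canonical_pair(*pair),
        n_nuclei=n,
        pct_distant=_round_half_away(exact["distant"]),
        pct_close=_round_half_away(exact["close"]),
        pct_colocalized=_round_half_away(exact["colocalized"]),
        pct_associated=pct_assoc,
        is_associated=pct_assoc > cfg.association_threshold,
        exact_pct_distant=exact["distant"],
        exact_pct_close=exact["close"],
        exact_pct_colocalized=exact["colocalized"],
        exact_pct_associated=exact_assoc,
    )


def priors_from_associations(
    results: Iterable[AssociationResult],
    locus_map: Mapping[str, Sequence[str]] | None = None,
) -> PriorEdgeSet:
    """Turn tested-pair association calls into must/forbidden edge priors.

    ``locus_map`` expands composite FISH loci (a single BAC probe covering
    two clustered genes, e.g. "DLK1/MEG3" → [DLK1, MEG3]) into their
    constituent gene symbols; unmapped labels stand for themselves.
    Associated pairs contribute the cross-product of constituent genes to
    the must set, non-associated tested pairs to the forbidden set.  A gene
    pair receiving both labels is contradictory evidence and raises.
    """
    locus_map = locus_map or {}
    must: set = set()
    forbidden: set = set()
    for res in results:
        la, lb = res.pair
        genes_a = list(locus_map.get(la, [la]))
        genes_b = list(locus_map.get(lb, [lb]))
        expanded = {
            canonical_pair(ga, gb)
            for ga in genes_a
            for gb in genes_b
            if ga != gb
        }
        if res.is_associated:
            must |= expanded
        else:
            forbidden |= expanded
    clash = must & forbidden
    if clash:
        raise ValueError(
            f"contradictory association evidence for gene pair(s): {sorted(clash)}"
        )
    return PriorEdgeSet(must=frozenset(must), forbidden=frozenset(forbidden))
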