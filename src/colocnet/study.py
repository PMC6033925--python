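"""Reference inputs from the porcine foetal muscle study this tool supports.

The iterative design was developed around a study of muscle maturation in
late-gestation pig foetuses: 61 skeletal-muscle transcriptomes, three
imprinted anchor genes (IGF2, DLK1, MEG3), and 3D DNA FISH validation of
candidate gene pairs.  This module records the published per-pair FISH
distance-class compositions and the resulting four-iteration prior schedule,
so examples and validation runs can reconstruct the study's inputs without
any download.

The DLK1/MEG3 locus is a single FISH probe covering both clustered genes;
it expands to both symbols when association calls are turned into edge
priors.
"""

from __future__ import annotations

from .fish import AssociationResult
from .priors import PriorEdgeSet, canonical_pair

#: composite FISH locus → constituent gene symbols
LOCUS_MAP: dict[str, tuple[str, ...]] = {"DLK1/MEG3": ("DLK1", "MEG3")}

#: published distance-class compositions of the tested pairs:
#: (locus_a, locus_b) → (n_nuclei, pct_distant, pct_close, pct_colocalized)
#: The final two rows are the negative-control pairs that motivated the 10%
#: association threshold.
FISH_COMPOSITIONS: dict[tuple[str, str], tuple[int, int, int, int]] = {
    ("MEST", "IGF2"): (100, 66, 32, 2),
    ("MEST", "DLK1/MEG3"): (90, 66, 28, 6),
    ("DCN", "DLK1/MEG3"): (73, 85, 15, 0),
    ("RPL32", "IGF2"): (80, 80, 16, 4),
    ("DCN", "IGF2"): (98, 90, 7, 3),
    ("IGF2", "MYH3"): (58, 48, 43, 9),
    ("DLK1/MEG3", "MYH3"): (69, 55, 38, 7),
    ("MEST", "MYH3"): (103, 74, 23, 3),
    ("ZAR1", "IGF2"): (61, 92, 8, 0),
    ("ZAR1", "PRLR"): (63, 92, 8, 0),
}

#: published associated percentage per tested pair (close + co-localized)
FISH_ASSOCIATED_PCT: dict[tuple[str, str], int] = {
    ("MEST", "IGF2"): 34,
    ("MEST", "DLK1/MEG3"): 34,
    ("DCN", "DLK1/MEG3"): 15,
    ("RPL32", "IGF2"): 20,
    ("DCN", "IGF2"): 10,
    ("IGF2", "MYH3"): 52,
    ("DLK1/MEG3", "MYH3"): 45,
    ("MEST", "MYH3"): 26,
    ("ZAR1", "IGF2"): 8,
    ("ZAR1", "PRLR"): 8,
}


def class_counts(pair: tuple[str, str]) -> tuple[int, int, int, int]:
    """Integer (distant, close, colocalized) nucleus counts for a tested pair.

    Counts are reconstructed from the published class percentages by
    per-class rounding of pct·n/100; the nucleus total is their sum (it can
    differ from the published n by one when the printed percentages admit no
    exact integer composition).  Returns (n, distant, close, colocalized).
    """
    n, pct_d, pct_c, pct_co = FISH_COMPOSITIONS[pair]
    counts = tuple(int(round(p * n / 100.0)) for p in (pct_d, pct_c, pct_co))
    return (sum(counts), *counts)


def prior_schedule() -> list[PriorEdgeSet]:
    """Incremental prior sets of the study's four inference iterations.

    Iteration 0 is the baseline (no priors); iteration 1 introduces the
    previously known triple co-localization of the anchor genes; iterations
    2 and 3 introduce the FISH-validated pairs (with the DCN-IGF2 pair
    forbidden).  Cumulative must-pair counts are 0, 3, 9, 13 and forbidden
    counts 0, 0, 1, 1.
    """
    baseline = PriorEdgeSet.empty()
    iter1 = PriorEdgeSet(
        must=frozenset(
            {
                canonical_pair("IGF2", "DLK1"),
                canonical_pair("IGF2", "MEG3"),
                canonical_pair("DLK1", "MEG3"),
            }
        )
    )
    iter2 = PriorEdgeSet(
        must=frozenset(
            {
                canonical_pair("IGF2", "MEST"),
                canonical_pair("DLK1", "MEST"),
                canonical_pair("MEG3", "MEST"),
                canonical_pair("DLK1", "DCN"),
                canonical_pair("MEG3", "DCN"),
                canonical_pair("RPL32", "IGF2"),
            }
        ),
        forbidden=frozenset({canonical_pair("IGF2", "DCN")}),
    )
    iter3 = PriorEdgeSet(
        must=frozenset(
            {
                canonical_pair("IGF2", "MYH3"),
                canonical_pair("DLK1", "MYH3"),
                canonical_pair("MEG3", "MYH3"),
                canonical_pair("MEST", "MYH3"),
            }
        )
    )
    return [baseline, iter1, iter2, iter3]


STUDY_LOCI: tuple[str, ...] = (
    "IGF2",
    "DLK1",
    "MEG3",
    "MEST",
    "DCN",
    "RPL32",
    "MYH3",
    "ZAR1",
)


def simulate_study_like_expression(p: int = 120, n: int = 61, seed: int = 0):
    """Synthetic gene-level matrix whose first genes carry the study loci.

    Convenience for examples and end-to-end runs: draws a modular synthetic
    expression matrix (see :mod:`colocnet.simdata`) and renames its first
    genes to the study's anchor and FISH-tested loci so the published prior
    schedule applies.  Returns (matrix, ground-truth graph).
    """
    from .simdata import SimNetworkSpec, simulate_expression

    m, truth = simulate_expression(SimNetworkSpec(p=p, n=n, seed=seed))
    renames = dict(zip(list(m.index)[: len(STUDY_LOCI)], STUDY_LOCI))
    import networkx as nx

    return m.rename(index=renames), nx.relabel_nodes(truth, renames)


def association_results() -> list[AssociationResult]:
    """Published association table as :class:`AssociationResult` records.

    Percentages are the published integers; exact percentages are left
    unset.  The association call applies the strict >10% rule to the
    published associated percentage.
    """
    out = []
    for pair, (n, pct_d, pct_c, pct_co) in FISH_COMPOSITIONS.items():
        assoc = FISH_ASSOCIATED_PCT[pair]
        out.append(
            AssociationResult(
                pair=canonical_pair(*pair),
                n_nuclei=n,
                pct_distant=pct_d,
                pct_close=pct_c,
                pct_colocalized=pct_co,
                pct_associated=assoc,
                is_associated=assoc > 10,
            )
        )
    return out
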