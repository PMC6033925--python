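"""Probe-level preprocessing: imputation, probe collapse, candidate selection.

The inference input is a gene × sample matrix of log2 intensities.  Raw
microarray tables are probe-level with occasional missing values, so the
standard path is: k-NN imputation (k = 3), collapse of multi-probe genes to
the probe best correlated with its siblings, then restriction to genes
strongly correlated (|r| ≥ 0.84 by default) with at least one target gene
(IGF2, DLK1, MEG3 — the imprinted loci anchoring the study).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

DEFAULT_TARGETS: tuple[str, ...] = ("IGF2", "DLK1", "MEG3")


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs for the preprocessing stage.

    k_neighbors
        Neighbour count for k-NN imputation (3 by default).
    correlation_threshold
        Minimum correlation with a target gene for a candidate to be kept,
        in [0, 1] (0.84 by default).
    target_genes
        Anchor genes that candidates must correlate with; always retained.
    correlation_mode
        "r" applies the threshold to |Pearson r|; "r2" applies it to r².
    """

    k_neighbors: int = 3
    correlation_threshold: float = 0.84
    target_genes: Sequence[str] = DEFAULT_TARGETS
    correlation_mode: str = "r"

    def __post_init__(self) -> None:
        if self.k_neighbors <= 0:
            raise ValueError(f"k_neighbors must be positive, got {self.k_neighbors}")
        if not 0.0 <= self.correlation_threshold <= 1.0:
            raise ValueError(
                f"correlation_threshold must lie in [0, 1], got "
                f"{self.correlation_threshold}"
            )
        if self.correlation_mode not in ("r", "r2"):
            raise ValueError("correlation_mode must be 'r' or 'r2'")


def impute_missing(m: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Fill missing cells with the column-mean of the k nearest feature rows.

    Nearest neighbours are determined by Euclidean distance over columns
    observed in both rows, rescaled by the fraction of co-observed columns
    (nan-Euclidean); observed entries are left untouched.
    """
    if k <= 0:
        raise ValueError(f"k must be a positive integer, got {k}")
    values = m.to_numpy(dtype=float)
    all_missing = np.isnan(values).all(axis=1)
    if all_missing.any():
        rows = m.index[all_missing].tolist()
        raise ValueError(f"rows with all values missing cannot be imputed: {rows}")
    if not np.isnan(values).any():
        return m.copy()
    if k >= m.shape[0]:
        raise ValueError(
            f"k={k} must be smaller than the number of feature rows ({m.shape[0]})"
        )
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(values)
    # keep observed cells bit-identical (the imputer only writes NaN cells,
    # but make the contract explicit)
    mask = ~np.isnan(values)
    filled[mask] = values[mask]
    return pd.DataFrame(filled, index=m.index, columns=m.columns)


def collapse_probes(m: pd.DataFrame, ann: Mapping[str, str]) -> pd.DataFrame:
    """Collapse a probe-level matrix to one representative probe per gene.

    For genes measured by several probes, the probe with the highest mean
    Pearson correlation with the gene's other probes is retained; ties break
    on the lexicographically smallest probe id.  Probes absent from the
    annotation are dropped (unannotated); annotated probes missing from the
    matrix are skipped with a warning.  Output rows are keyed by gene symbol
    and sorted.
    """
    if not ann:
        raise ValueError("annotation mapping is empty")
    missing = sorted(set(ann) - set(m.index))
    if missing:
        warnings.warn(
            f"{len(missing)} annotated probe(s) absent from the matrix, "
            f"skipped: {missing[:10]}{'...' if len(missing) > 10 else ''}",
            stacklevel=2,
        )
    by_gene: dict[str, list[str]] = {}
    for probe in m.index:
        gene = ann.get(probe)
        if gene is not None:
            by_gene.setdefault(gene, []).append(probe)

    chosen: dict[str, str] = {}
    for gene, probes in by_gene.items():
        if len(probes) == 1:
            chosen[gene] = probes[0]
            continue
        probes = sorted(probes)
        sub = m.loc[probes].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(sub)
        corr = np.nan_to_num(corr, nan=0.0)  # constant probes contribute 0
        np.fill_diagonal(corr, np.nan)
        mean_corr = np.nanmean(corr, axis=1)
        best = int(np.argmax(mean_corr))  # argmax takes the first (smallest id) on ties
        chosen[gene] = probes[best]

    genes = sorted(chosen)
    out = m.loc[[chosen[g] for g in genes]].copy()
    out.index = pd.Index(genes, name=m.index.name)
    return out


def select_candidate_genes(
    m: pd.DataFrame, cfg: PreprocessConfig | None = None
) -> pd.DataFrame:
    """Keep genes strongly correlated with at least one target gene.

    A gene is retained when its |Pearson r| (or r², per ``correlation_mode``)
    with any target gene meets the threshold.  Target genes are always
    retained.  Rows of the result are sorted by gene symbol.
    """
    cfg = cfg or PreprocessConfig()
    targets = list(cfg.target_genes)
    absent = [t for t in targets if t not in m.index]
    if absent:
        raise ValueError(f"target gene(s) missing from the matrix: {absent}")

    x = m.to_numpy(dtype=float)
    t = m.loc[targets].to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    tc = t - t.mean(axis=1, keepdims=True)
    xs = np.sqrt((xc**2).sum(axis=1))
    ts = np.sqrt((tc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ tc.T) / np.outer(xs, ts)
    r = np.nan_to_num(r, nan=0.0)

    score = r**2 if cfg.correlation_mode == "r2" else np.abs(r)
    keep = (score >= cfg.correlation_threshold).any(axis=1)
    keep |= m.index.isin(targets)
    return m.loc[keep].sort_index()
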