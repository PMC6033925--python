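"""Synthetic data with the statistical structure the method assumes.

Expression matrices are drawn from a multivariate normal with a known
sparse, modular precision matrix (co-expression modules = blocks of
partially correlated genes), mirroring the study conditions of a few hundred
candidate genes measured on ~61 samples.  FISH nuclei are simulated with a
planted per-pair association rate: with that probability the closest
cross-gene allele pair sits within the 1 µm association cut-off, otherwise
beyond it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .fish import FishConfig, NucleusRecord, Signal


@dataclass(frozen=True)
class SimNetworkSpec:
    """Ground-truth network and sampling parameters for expression data.

    Defaults emulate the study conditions: ~120 genes in a handful of
    co-expression modules observed on 61 samples, with a realized network
    density of a few percent and partial correlations of moderate size.
    """

    p: int = 120
    n: int = 61
    n_modules: int = 6
    within_module_edge_prob: float = 0.25
    partial_correlation_magnitude: float = 0.3
    seed: int = 0
    min_eigenvalue: float = 0.05

    def __post_init__(self) -> None:
        if self.p < 2 or self.n < 2:
            raise ValueError("need at least 2 genes and 2 samples")
        if not 1 <= self.n_modules <= self.p:
            raise ValueError("n_modules must lie in [1, p]")
        if not 0 <= self.within_module_edge_prob <= 1:
            raise ValueError("within_module_edge_prob must lie in [0, 1]")
        if not 0 <= self.partial_correlation_magnitude < 1:
            raise ValueError("partial_correlation_magnitude must lie in [0, 1)")


@dataclass(frozen=True)
class SimFishSpec:
    """Planted association rate and geometry for simulated FISH nuclei.

    Associated nuclei draw their minimum cross-gene distance uniformly from
    (0, 1) µm; background nuclei from (1.2, 5) µm, leaving a margin around
    the 1 µm cut-off so classification noise does not blur the planted rate.
    """

    n_nuclei: int = 100
    association_rate: float = 0.3
    associated_range: tuple[float, float] = (0.0, 1.0)
    background_range: tuple[float, float] = (1.2, 5.0)
    nucleus_radius: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei <= 0:
            raise ValueError("n_nuclei must be positive")
        if not 0 <= self.association_rate <= 1:
            raise ValueError("association_rate must lie in [0, 1]")
        if self.background_range[1] > 2 * self.nucleus_radius:
            raise ValueError(
                "background distances cannot exceed the nucleus diameter"
            )


def _module_sizes(p: int, k: int) -> list[int]:
    base, extra = divmod(p, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def simulate_expression(
    spec: SimNetworkSpec | None = None,
) -> tuple[pd.DataFrame, nx.Graph]:
    """Expression data from a known sparse modular precision matrix.

    Builds a block-structured precision with ±magnitude partial correlations
    on within-module edges (random signs), shrinks the off-diagonal part
    just enough to keep the matrix positive definite (smallest eigenvalue ≥
    ``min_eigenvalue``), samples n multivariate-normal observations, and
    returns the gene × sample matrix together with the ground-truth graph.
    The realized partial-correlation magnitude is stored on each true edge
    (attribute ``weight``) and the attained shrink factor in
    ``graph.graph["attenuation"]``.
    """
    spec = spec or SimNetworkSpec()
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:04d}" for i in range(1, spec.p + 1)]
    sizes = _module_sizes(spec.p, spec.n_modules)

    truth = nx.Graph()
    truth.add_nodes_from(genes)
    start = 0
    a = np.zeros((spec.p, spec.p))
    m = spec.partial_correlation_magnitude
    for size in sizes:
        block = range(start, start + size)
        for i in block:
            for j in block:
                if j <= i:
                    continue
                if rng.random() < spec.within_module_edge_prob and m > 0:
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    a[i, j] = a[j, i] = sign * m
                    truth.add_edge(genes[i], genes[j])
        start += size

    omega0 = np.eye(spec.p) + a
    if m > 0 and truth.number_of_edges() > 0:
        lam_min = float(np.linalg.eigvalsh(omega0)[0])
        if lam_min < spec.min_eigenvalue:
            # shrink the off-diagonal block so λ_min hits the floor exactly
            alpha = (1.0 - spec.min_eigenvalue) / (1.0 - lam_min)
            omega = np.eye(spec.p) + alpha * a
        else:
            alpha = 1.0
            omega = omega0
    else:
        alpha = 1.0
        omega = omega0
    lam_min = float(np.linalg.eigvalsh(omega)[0])
    if lam_min <= 0:
        raise ValueError(
            f"generated precision matrix is not positive definite "
            f"(λ_min = {lam_min:.3g}); lower the magnitude or edge probability"
        )

    planted = alpha * m
    truth.graph["attenuation"] = alpha
    truth.graph["planted_partial_correlation"] = planted
    for u, v in truth.edges:
        truth.edges[u, v]["weight"] = planted

    sigma = np.linalg.inv(omega)
    x = rng.multivariate_normal(
        np.zeros(spec.p), sigma, size=spec.n, method="cholesky"
    ).T
    samples = [f"S{i:03d}" for i in range(1, spec.n + 1)]
    return pd.DataFrame(x, index=genes, columns=samples), truth


def true_density(truth: nx.Graph) -> float:
    """Ground-truth density of a simulated network, as a percentage."""
    p = truth.number_of_nodes()
    return 100.0 * truth.number_of_edges() / (p * (p - 1) / 2.0)


def _uniform_in_sphere(rng: np.random.Generator, radius: float) -> np.ndarray:
    while True:
        pt = rng.uniform(-radius, radius, size=3)
        if np.dot(pt, pt) <= radius * radius:
            return pt


def _nucleus_with_min_distance(
    pair: tuple[str, str],
    d: float,
    rng: np.random.Generator,
    radius: float,
    nucleus_id: object,
    floor: float = 0.0,
) -> NucleusRecord:
    """Place 4 signals so the minimum cross-gene distance lies in [floor, d].

    One cross-gene allele pair is anchored at distance exactly ``d``; the
    remaining alleles are placed uniformly subject to all other cross
    distances staying above ``floor`` (the lower edge of d's distance
    class), so the nucleus's minimum cross-gene distance never leaves the
    intended class.
    """
    a, b = pair
    # anchor allele pair at distance d, both inside the nucleus sphere
    while True:
        pa = _uniform_in_sphere(rng, radius)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pb = pa + d * direction
        if np.dot(pb, pb) <= radius * radius:
            break
    # remaining alleles anywhere that does not undercut the class floor
    while True:
        pa2 = _uniform_in_sphere(rng, radius)
        pb2 = _uniform_in_sphere(rng, radius)
        others = (
            np.linalg.norm(pa - pb2),
            np.linalg.norm(pa2 - pb),
            np.linalg.norm(pa2 - pb2),
        )
        if min(others) >= floor:
            break
    signals = (
        Signal(gene=a, x=pa[0], y=pa[1], z=pa[2]),
        Signal(gene=a, x=pa2[0], y=pa2[1], z=pa2[2]),
        Signal(gene=b, x=pb[0], y=pb[1], z=pb[2]),
        Signal(gene=b, x=pb2[0], y=pb2[1], z=pb2[2]),
    )
    return NucleusRecord(nucleus_id=nucleus_id, signals=signals)


def simulate_fish(
    spec: SimFishSpec | None = None, pair: tuple[str, str] = ("GENE_A", "GENE_B")
) -> list[NucleusRecord]:
    """Simulated nuclei for one tested pair with a planted association rate.

    Each nucleus independently is associated with probability
    ``association_rate``; its minimum cross-gene allele distance is drawn
    from the associated distance range, otherwise from the background range.
    Remaining alleles are placed uniformly in the nucleus sphere subject to
    not undercutting the planted minimum.  Coordinates are in µm.
    """
    spec = spec or SimFishSpec()
    rng = np.random.default_rng(spec.seed)
    nuclei = []
    for i in range(spec.n_nuclei):
        if rng.random() < spec.association_rate:
            lo, hi = spec.associated_range
        else:
            lo, hi = spec.background_range
        d = rng.uniform(lo, hi)
        nuclei.append(
            _nucleus_with_min_distance(pair, d, rng, spec.nucleus_radius, i, floor=lo)
        )
    return nuclei


def simulate_fish_composition(
    pair: tuple[str, str],
    n_distant: int,
    n_close: int,
    n_colocalized: int,
    seed: int = 0,
    cfg: FishConfig | None = None,
    nucleus_radius: float = 3.0,
) -> list[NucleusRecord]:
    """Nuclei realizing an exact distant/close/co-localized class composition.

    Distances are drawn from sub-ranges safely inside each class (margins
    around the 0.5 and 1 µm boundaries), so the classified composition of the
    returned nuclei equals the requested counts exactly.  Nucleus order is
    shuffled deterministically.
    """
    cfg = cfg or FishConfig()
    rng = np.random.default_rng(seed)
    margin = 0.05
    ranges = {
        "colocalized": (margin, cfg.colocalized_max - margin),
        "close": (cfg.colocalized_max + margin, cfg.associated_max - margin),
        "distant": (cfg.associated_max + 2 * margin, min(3.0, 2 * nucleus_radius)),
    }
    plan = (
        ["distant"] * n_distant
        + ["close"] * n_close
        + ["colocalized"] * n_colocalized
    )
    rng.shuffle(plan)
    nuclei = []
    for i, cls in enumerate(plan):
        lo, hi = ranges[cls]
        d = rng.uniform(lo, hi)
        nuclei.append(
            _nucleus_with_min_distance(pair, d, rng, nucleus_radius, i, floor=lo)
        )
    return nuclei
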