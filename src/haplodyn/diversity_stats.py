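"""Per-population and total sequence diversity statistics.

Implements the classical chloroplast summary statistics: number of
segregating sites S, number of haplotypes h, Nei's unbiased haplotype (gene)
diversity Hd, per-site nucleotide diversity pi, Watterson's theta, and
Tajima's D, plus the configuration-inversion search that recovers a
population's haplotype-count/site structure from its printed summary row.

Coded indel characters are excluded from the nucleotide statistics
(S, pi, theta, D) but participate in haplotype identity, so h with indels
can exceed h without.  D is reported as 0 when S = 0, matching the printed
convention for monomorphic populations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment_io import AMBIGUOUS, GAP, Alignment, collapse_haplotypes

__all__ = [
    "TajimaConstants",
    "haplotype_diversity",
    "pairwise_difference_total",
    "nucleotide_diversity",
    "watterson_theta",
    "tajima_constants",
    "tajimas_d",
    "diversity_summary",
    "derive_configuration",
]


def haplotype_diversity(counts) -> float:
    """Nei's unbiased gene diversity ``Hd = n/(n-1) * (1 - sum p_i^2)``."""
    counts = np.asarray(list(counts), dtype=float)
    if (counts < 1).any():
        raise ValueError("all haplotype counts must be >= 1")
    n = counts.sum()
    if n < 2:
        raise ValueError("need at least 2 sequences")
    p = counts / n
    return float(n / (n - 1.0) * (1.0 - (p ** 2).sum()))


def _nucleotide_matrix(aln: Alignment) -> np.ndarray:
    """Nucleotide columns usable for distance computations.

    Drops trailing coded indel characters and any column containing a gap
    or an ambiguous base.
    """
    mat = aln.matrix()[:, : aln.length - aln.n_indel_chars]
    bad = (mat == GAP.encode()) | (mat == AMBIGUOUS.encode())
    return mat[:, ~bad.any(axis=0)]


def pairwise_difference_total(aln: Alignment) -> tuple[int, int]:
    """(sum over pairs of per-pair differing sites, number of pairs)."""
    mat = _nucleotide_matrix(aln)
    n = mat.shape[0]
    if n < 2:
        raise ValueError("need at least 2 sequences")
    # count, per usable column, derived-allele products: sum_{i<j} [x_i != x_j]
    total = 0
    for col in range(mat.shape[1]):
        _, cnt = np.unique(mat[:, col], return_counts=True)
        if len(cnt) > 1:
            total += (n * n - (cnt ** 2).sum()) // 2
    return int(total), n * (n - 1) // 2


def nucleotide_diversity(aln: Alignment, length: int | None = None) -> float:
    """Per-site pi: mean pairwise differences / alignment length.

    ``length`` defaults to the nucleotide length of the alignment (coded
    indel characters excluded); pass the pre-filtering length explicitly to
    match statistics quoted for a fixed matrix size.
    """
    L = length if length is not None else aln.length - aln.n_indel_chars
    if L == 0:
        raise ValueError("alignment length is zero")
    total, pairs = pairwise_difference_total(aln)
    return total / pairs / L


def watterson_theta(S: int, n: int, L: int) -> float:
    """Watterson's estimator per site, ``S / (a1 * L)``."""
    if n < 2:
        raise ValueError("need at least 2 sequences")
    a1 = np.sum(1.0 / np.arange(1, n))
    return float(S / (a1 * L))


@dataclass(frozen=True)
class TajimaConstants:
    """The n-dependent constants of Tajima's D variance (Tajima 1989)."""

    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    if n < 2:
        raise ValueError("need n >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n ** 2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return TajimaConstants(a1, a2, b1, b2, c1, c2, e1, e2)


def tajimas_d(S: int, mean_pairwise_diff: float, n: int) -> float:
    """Tajima's D from S and the mean pairwise difference (absolute, not
    per site).  Returns 0 by convention when S = 0."""
    if S == 0:
        return 0.0
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4 when S > 0")
    c = tajima_constants(n)
    variance = c.e1 * S + c.e2 * S * (S - 1.0)
    return float((mean_pairwise_diff - S / c.a1) / np.sqrt(variance))


def diversity_summary(
    aln: Alignment,
    populations: pd.DataFrame | dict[str, str],
    length: int | None = None,
    include_total: bool = True,
) -> pd.DataFrame:
    """Per-population summary table (n, S, h, h_star, Hd, pi, theta_w, D).

    ``h`` counts haplotypes with coded indel characters, ``h_star`` without.
    The optional ``total`` row pools all sequences.  ``length`` overrides
    the per-site denominator (e.g. the full pre-filtering matrix length).
    """
    if isinstance(populations, pd.DataFrame):
        pop_of = dict(zip(populations["sequence_id"], populations["population"]))
    else:
        pop_of = dict(populations)
    pop_order = list(dict.fromkeys(pop_of[sid] for sid in aln.ids))
    groups: dict[str, list[str]] = {p: [] for p in pop_order}
    for sid in aln.ids:
        groups[pop_of[sid]].append(sid)

    rows = []
    units: list[tuple[str, list[str]]] = [(p, groups[p]) for p in pop_order]
    if include_total:
        units.append(("total", list(aln.ids)))
    for name, ids in units:
        sub = aln.subset(ids)
        table = collapse_haplotypes(sub, {sid: name for sid in ids}, use_indels=True)
        table_star = collapse_haplotypes(
            sub, {sid: name for sid in ids}, use_indels=False
        )
        n = sub.n
        L = length if length is not None else sub.length - sub.n_indel_chars
        S = table.S
        if n >= 2:
            hd = haplotype_diversity(table.total_counts())
            total, pairs = pairwise_difference_total(sub)
            k_hat = total / pairs
            pi = k_hat / L
            theta = watterson_theta(S, n, L)
            d = tajimas_d(S, k_hat, n) if (S == 0 or n >= 4) else np.nan
        else:
            hd = pi = theta = d = np.nan
        rows.append(
            {
                "population": name,
                "n": n,
                "S": S,
                "h": table.h,
                "h_star": table_star.h,
                "Hd": hd,
                "pi": pi,
                "theta_w": theta,
                "D": d,
            }
        )
    return pd.DataFrame(rows).set_index("population")


def write_summary_tsv(summary: pd.DataFrame, path: str | Path) -> None:
    summary.to_csv(path, sep="\t", float_format="%.5f")


# ---------------------------------------------------------------------------
# Configuration inversion: recover haplotype structure from a summary row
# ---------------------------------------------------------------------------


def _partitions(n: int, parts: int, maximum: int | None = None):
    """Integer partitions of n into exactly `parts` positive parts,
    non-increasing order."""
    if maximum is None:
        maximum = n
    if parts == 1:
        if n <= maximum:
            yield (n,)
        return
    for first in range(min(n - parts + 1, maximum), 0, -1):
        for rest in _partitions(n - first, parts - 1, first):
            yield (first,) + rest


def _labeled_trees(h: int):
    """All labeled trees on h nodes as edge lists (via Prufer sequences)."""
    if h == 1:
        yield ()
        return
    if h == 2:
        yield ((0, 1),)
        return
    import heapq

    for prufer in itertools.product(range(h), repeat=h - 2):
        degree = [1] * h
        for v in prufer:
            degree[v] += 1
        edges = []
        leaves = [i for i in range(h) if degree[i] == 1]
        heapq.heapify(leaves)
        for v in prufer:
            leaf = heapq.heappop(leaves)
            edges.append((leaf, v))
            degree[v] -= 1
            if degree[v] == 1:
                heapq.heappush(leaves, v)
        # after consuming the Prufer sequence exactly two leaves remain
        edges.append((heapq.heappop(leaves), heapq.heappop(leaves)))
        yield tuple(edges)


@dataclass(frozen=True)
class HaplotypeConfiguration:
    """A haplotype-count partition plus tree topology and per-edge sites."""

    counts: tuple[int, ...]
    edges: tuple[tuple[int, int], ...]  # tree on haplotype indices
    sites_per_edge: tuple[int, ...]
    site_split_counts: tuple[int, ...]  # derived-allele count per site

    @property
    def n(self) -> int:
        return sum(self.counts)

    @property
    def S(self) -> int:
        return sum(self.sites_per_edge)

    def pairwise_total(self) -> int:
        """Sum over sequence pairs of their site differences."""
        n = self.n
        return sum(c * (n - c) for c in self.site_split_counts)


def _edge_splits(counts, edges):
    """Derived-side haplotype-count sum for each tree edge (smaller side)."""
    h = len(counts)
    adj = {i: [] for i in range(h)}
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    splits = []
    for u, v in edges:
        # size of the component containing v when edge (u, v) is removed
        seen = {u, v}
        stack = [v]
        total = counts[v]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    total += counts[y]
                    stack.append(y)
        splits.append(min(total, sum(counts) - total))
    return splits


def derive_configuration(
    n: int,
    h: int,
    S: int,
    Hd: float,
    pi: float,
    L: int,
    hd_decimals: int = 5,
    pi_decimals: int = 5,
) -> list[HaplotypeConfiguration]:
    """Enumerate haplotype configurations consistent with a printed summary.

    Brute-force search over integer partitions of ``n`` into ``h`` positive
    haplotype counts, labeled tree topologies among the ``h`` haplotypes,
    and assignments of the ``S`` segregating sites to tree edges (each edge
    carrying at least one site), keeping configurations whose Hd and pi
    round to the printed values.  Raises if nothing matches (transcription
    error in the input).  Matches are deduplicated by (counts, sorted site
    split counts).
    """
    if h > 6:
        raise ValueError("inversion search supported for h <= 6")
    tol_hd = 0.5 * 10 ** (-hd_decimals) + 1e-12
    tol_pi = 0.5 * 10 ** (-pi_decimals) + 1e-12
    matches: list[HaplotypeConfiguration] = []
    seen: set[tuple] = set()
    for counts in _partitions(n, h):
        try:
            hd_calc = haplotype_diversity(counts)
        except ValueError:
            continue
        if abs(hd_calc - Hd) > tol_hd:
            continue
        if h == 1:
            if S == 0 and abs(pi) <= tol_pi:
                cfg = HaplotypeConfiguration(counts, (), (), ())
                matches.append(cfg)
            continue
        n_edges = h - 1
        if S < n_edges:
            continue
        for edges in _labeled_trees(h):
            splits = _edge_splits(counts, edges)
            # compositions of S into n_edges positive parts
            for cut in itertools.combinations(range(1, S), n_edges - 1):
                bounds = (0,) + cut + (S,)
                sites = tuple(bounds[i + 1] - bounds[i] for i in range(n_edges))
                site_counts = tuple(
                    sorted(
                        itertools.chain.from_iterable(
                            [splits[e]] * sites[e] for e in range(n_edges)
                        )
                    )
                )
                total = sum(c * (n - c) for c in site_counts)
                pi_calc = total / (n * (n - 1) / 2) / L
                if abs(pi_calc - pi) > tol_pi:
                    continue
                key = (counts, site_counts)
                if key in seen:
                    continue
                seen.add(key)
                matches.append(
                    HaplotypeConfiguration(counts, edges, sites, site_counts)
                )
    if not matches:
        raise ValueError(
            f"no haplotype configuration matches n={n}, h={h}, S={S}, "
            f"Hd={Hd}, pi={pi} (possible transcription error)"
        )
    return matches
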