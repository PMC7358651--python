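"""Synthetic study generator with closed-form ground truth.

Everything downstream of field/lab work is testable against data built here:
concatenated chloroplast alignments whose haplotype structure (counts and
star/chain mutation topology) is known exactly, population coordinate
tables, per-epoch climatic-suitability surfaces with planted temporal trends
at each locality, and stacks of bioclim-style environmental layers with a
planted within-group variance structure and a planted diversity~variance
regression slope.

The flagship fixture reconstructs the eight-population study design: 128
sequences of 2,188 bp in populations of sizes 20/4/8/20/23/20/20/13, with
the three polymorphic populations carrying haplotype counts (16,2,1,1) on a
star, (16,4) across a two-site edge, and (12,1) across one site, and with
the three northern populations sharing the widespread central haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .alignment_io import Alignment
from .diversity_stats import haplotype_diversity, tajimas_d
from .rasters import Raster

__all__ = [
    "PopulationConfig",
    "SyntheticTruth",
    "make_alignment",
    "make_study_fixture",
    "make_study_alignment",
    "make_study_dataset",
    "make_suitability_rasters",
    "make_env_layers",
    "expected_summary",
    "EPOCHS",
]

#: epoch labels, oldest first: Last Interglacial, Last Glacial Maximum,
#: mid-Holocene, present
EPOCHS = ("LIG", "LGM", "MH", "PRE")

BASES = np.array([b"A", b"C", b"G", b"T"])


@dataclass(frozen=True)
class PopulationConfig:
    """One population's haplotype structure and location.

    ``topology`` is a tuple of ``(u, v, n_sites)`` edges over haplotype
    indices ``0..h-1`` (``counts[i]`` sequences carry haplotype ``i``); each
    edge carries ``n_sites`` distinct mutated alignment columns.  The total
    number of distinct mutated sites is the population's S.
    """

    name: str
    haplotype_counts: tuple[int, ...]
    topology: tuple[tuple[int, int, int], ...] = ()
    coords: tuple[float, float] = (0.0, 0.0)  # (lat, lon) decimal degrees

    @property
    def n(self) -> int:
        return sum(self.haplotype_counts)

    @property
    def h(self) -> int:
        return len(self.haplotype_counts)

    @property
    def S(self) -> int:
        return sum(e[2] for e in self.topology)

    def validate(self) -> None:
        if any(c < 1 for c in self.haplotype_counts):
            raise ValueError("haplotype counts must be positive")
        if self.h > 1:
            if len(self.topology) != self.h - 1:
                raise ValueError("topology must be a tree on the haplotypes")
            if not _is_connected(self.h, [(u, v) for u, v, _ in self.topology]):
                raise ValueError("topology is disconnected")
        if any(s < 1 for _, _, s in self.topology):
            raise ValueError("each edge must carry at least one site")


@dataclass
class SyntheticTruth:
    """Closed-form expected values for generated data."""

    per_population: pd.DataFrame  # n, S, h, Hd, pi (per site), D
    partition: dict[str, int] | None = None  # planted group per population
    regression_slope: float | None = None
    epoch_trends: dict[str, tuple[float, ...]] | None = None


def _is_connected(n_nodes: int, edges: list[tuple[int, int]]) -> bool:
    adj: dict[int, list[int]] = {i: [] for i in range(n_nodes)}
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    seen = {0}
    stack = [0]
    while stack:
        x = stack.pop()
        for y in adj[x]:
            if y not in seen:
                seen.add(y)
                stack.append(y)
    return len(seen) == n_nodes


def _path_lengths(h: int, edges: tuple[tuple[int, int, int], ...]) -> np.ndarray:
    """Pairwise mutational distances between haplotypes on the tree."""
    dist = np.full((h, h), np.inf)
    np.fill_diagonal(dist, 0.0)
    for u, v, s in edges:
        dist[u, v] = dist[v, u] = s
    for k in range(h):  # Floyd-Warshall; h is tiny
        dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
    return dist


def expected_summary(config: PopulationConfig, length: int) -> dict[str, float]:
    """Expected (n, S, h, Hd, pi, D) computed from counts and topology alone."""
    config.validate()
    counts = np.array(config.haplotype_counts)
    n = config.n
    dist = _path_lengths(config.h, config.topology)
    total = 0.0
    for i in range(config.h):
        for j in range(i + 1, config.h):
            total += dist[i, j] * counts[i] * counts[j]
    pairs = n * (n - 1) / 2
    k_hat = total / pairs
    return {
        "n": n,
        "S": config.S,
        "h": config.h,
        "Hd": haplotype_diversity(counts) if n >= 2 else float("nan"),
        "pi": k_hat / length,
        "D": tajimas_d(config.S, k_hat, n) if (config.S == 0 or n >= 4) else float("nan"),
    }


def _haplotype_sequences(
    h: int,
    edges: tuple[tuple[int, int, int], ...],
    length: int,
    rng: np.random.Generator,
) -> list[str]:
    """Backbone plus single-base substitutions at distinct columns per edge."""
    S = sum(s for _, _, s in edges)
    if length < S:
        raise ValueError(f"alignment length {length} < number of mutated sites {S}")
    backbone = rng.choice(BASES, size=length)
    cols = rng.choice(length, size=S, replace=False)
    col_iter = iter(cols)
    seqs: list[np.ndarray | None] = [None] * h
    seqs[0] = backbone.copy()
    adj: dict[int, list[tuple[int, int]]] = {i: [] for i in range(h)}
    for u, v, s in edges:
        adj[u].append((v, s))
        adj[v].append((u, s))
    edge_cols: dict[frozenset, list[int]] = {}
    for u, v, s in edges:
        edge_cols[frozenset((u, v))] = [next(col_iter) for _ in range(s)]
    stack = [0]
    while stack:
        u = stack.pop()
        for v, _s in adj[u]:
            if seqs[v] is None:
                seq = seqs[u].copy()
                for col in edge_cols[frozenset((u, v))]:
                    current = seq[col]
                    alternatives = BASES[BASES != current]
                    seq[col] = rng.choice(alternatives)
                seqs[v] = seq
                stack.append(v)
    return [b"".join(s).decode() for s in seqs]


def make_alignment(
    config: PopulationConfig, length: int, seed: int
) -> tuple[Alignment, pd.DataFrame]:
    """Generate one population's alignment plus its population table."""
    config.validate()
    rng = np.random.default_rng(seed)
    hap_seqs = _haplotype_sequences(config.h, config.topology, length, rng)
    ids, seqs, rows = [], [], []
    counter = 0
    for hap_index, count in enumerate(config.haplotype_counts):
        for _ in range(count):
            counter += 1
            sid = f"{config.name}_{counter:03d}"
            ids.append(sid)
            seqs.append(hap_seqs[hap_index])
            rows.append(
                {
                    "sequence_id": sid,
                    "population": config.name,
                    "lat": config.coords[0],
                    "lon": config.coords[1],
                }
            )
    return Alignment(ids=ids, seqs=seqs), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# The eight-population study fixture
# ---------------------------------------------------------------------------

#: decimal-degree coordinates of the eight sampled populations (lat, lon);
#: longitudes are west, hence negative
STUDY_COORDS: dict[str, tuple[float, float]] = {
    "P1": (18.4000, -97.4333),
    "P2": (17.7000, -97.6167),
    "P3": (17.6833, -97.5833),
    "P4": (17.8667, -97.1667),
    "P5": (17.8333, -97.2167),
    "P6": (16.9500, -96.1833),
    "P7": (18.1500, -97.1333),
    "P8": (18.1833, -97.1333),
}

STUDY_MATRIX_LENGTH = 2188

#: global haplotype graph for the study fixture: edges (u, v, n_sites) over
#: named haplotypes.  H2 is the widespread central haplotype shared by the
#: northern populations P1, P7 and P8; every other haplotype is private.
STUDY_TOPOLOGY: tuple[tuple[str, str, int], ...] = (
    ("H2", "H3", 1),   # P1 derived haplotype, 2 copies
    ("H2", "H4", 1),   # P1 singleton
    ("H2", "H5", 1),   # P1 singleton
    ("H2", "H6", 1),   # P8 singleton
    ("H2", "H7", 1),   # P4 major haplotype
    ("H7", "H8", 2),   # P4 minor haplotype, two sites on the edge
    ("H2", "H9", 3),   # P2 fixed
    ("H2", "H10", 3),  # P3 fixed
    ("H2", "H11", 4),  # P5 fixed
    ("H2", "H12", 8),  # P6 fixed; seven unsampled intermediates
)

#: per-population haplotype composition of the study fixture
STUDY_COMPOSITION: dict[str, tuple[tuple[str, int], ...]] = {
    "P1": (("H2", 16), ("H3", 2), ("H4", 1), ("H5", 1)),
    "P2": (("H9", 4),),
    "P3": (("H10", 8),),
    "P4": (("H7", 16), ("H8", 4)),
    "P5": (("H11", 23),),
    "P6": (("H12", 20),),
    "P7": (("H2", 20),),
    "P8": (("H2", 12), ("H6", 1)),
}


def make_study_fixture() -> list[PopulationConfig]:
    """Per-population configurations matching the printed summary rows.

    Populations 1, 4 and 8 carry the unique haplotype structures recovered
    by configuration inversion from their printed (n, h, S, Hd, pi); the
    other five are monomorphic at their printed sample sizes.
    """
    star3 = ((0, 1, 1), (0, 2, 1), (0, 3, 1))
    return [
        PopulationConfig("P1", (16, 2, 1, 1), star3, STUDY_COORDS["P1"]),
        PopulationConfig("P2", (4,), (), STUDY_COORDS["P2"]),
        PopulationConfig("P3", (8,), (), STUDY_COORDS["P3"]),
        PopulationConfig("P4", (16, 4), ((0, 1, 2),), STUDY_COORDS["P4"]),
        PopulationConfig("P5", (23,), (), STUDY_COORDS["P5"]),
        PopulationConfig("P6", (20,), (), STUDY_COORDS["P6"]),
        PopulationConfig("P7", (20,), (), STUDY_COORDS["P7"]),
        PopulationConfig("P8", (12, 1), ((0, 1, 1),), STUDY_COORDS["P8"]),
    ]


def make_study_alignment(
    topology: tuple[tuple[str, str, int], ...],
    composition: dict[str, tuple[tuple[str, int], ...]],
    coords: dict[str, tuple[float, float]],
    length: int,
    seed: int,
) -> tuple[Alignment, pd.DataFrame]:
    """Multi-population alignment over a shared global haplotype graph."""
    names = sorted({x for u, v, _ in topology for x in (u, v)})
    index = {name: i for i, name in enumerate(names)}
    edges = tuple((index[u], index[v], s) for u, v, s in topology)
    if not _is_connected(len(names), [(u, v) for u, v, _ in edges]):
        raise ValueError("global haplotype topology is disconnected")
    rng = np.random.default_rng(seed)
    hap_seqs = _haplotype_sequences(len(names), edges, length, rng)
    ids, seqs, rows = [], [], []
    for pop, comp in composition.items():
        counter = 0
        for hap_name, count in comp:
            for _ in range(count):
                counter += 1
                sid = f"{pop}_{counter:03d}"
                ids.append(sid)
                seqs.append(hap_seqs[index[hap_name]])
                lat, lon = coords[pop]
                rows.append(
                    {"sequence_id": sid, "population": pop, "lat": lat, "lon": lon}
                )
    return Alignment(ids=ids, seqs=seqs), pd.DataFrame(rows)


def make_study_dataset(seed: int = 0) -> tuple[Alignment, pd.DataFrame, SyntheticTruth]:
    """The complete 128-sequence, 2,188-bp study fixture.

    The truth table carries each population's closed-form expected summary;
    the planted SAMOVA-style partition groups the northern populations
    P1/P7/P8 (which share the central haplotype) and leaves every other
    population in its own group.
    """
    aln, pops = make_study_alignment(
        STUDY_TOPOLOGY, STUDY_COMPOSITION, STUDY_COORDS, STUDY_MATRIX_LENGTH, seed
    )
    rows = {}
    for cfg in make_study_fixture():
        rows[cfg.name] = expected_summary(cfg, STUDY_MATRIX_LENGTH)
    truth = SyntheticTruth(
        per_population=pd.DataFrame(rows).T,
        partition={"P1": 0, "P7": 0, "P8": 0, "P2": 1, "P3": 2, "P4": 3, "P5": 4, "P6": 5},
    )
    return aln, pops, truth


# ---------------------------------------------------------------------------
# Suitability surfaces with planted temporal trends
# ---------------------------------------------------------------------------


def _grid_for(
    localities: dict[str, tuple[float, float]], cellsize: float, margin: float
) -> tuple[np.ndarray, np.ndarray, float, float]:
    lats = np.array([c[0] for c in localities.values()])
    lons = np.array([c[1] for c in localities.values()])
    yll = np.floor((lats.min() - margin) / cellsize) * cellsize
    xll = np.floor((lons.min() - margin) / cellsize) * cellsize
    nrows = int(np.ceil((lats.max() + margin - yll) / cellsize))
    ncols = int(np.ceil((lons.max() + margin - xll) / cellsize))
    lat_centers = yll + nrows * cellsize - (np.arange(nrows) + 0.5) * cellsize
    lon_centers = xll + (np.arange(ncols) + 0.5) * cellsize
    return lat_centers, lon_centers, xll, yll


def _rbf_field(
    localities: dict[str, tuple[float, float]],
    values: dict[str, float],
    lat_centers: np.ndarray,
    lon_centers: np.ndarray,
    sigma: float,
) -> np.ndarray:
    """Partition-of-unity Gaussian interpolation of per-locality values.

    Far from every locality the field relaxes to the mean planted value.
    """
    lat_grid = lat_centers[:, None]
    lon_grid = lon_centers[None, :]
    weight_sum = np.full((len(lat_centers), len(lon_centers)), 1e-9)
    value_sum = weight_sum * np.mean(list(values.values()))
    for name, (lat, lon) in localities.items():
        d2 = (lat_grid - lat) ** 2 + (lon_grid - lon) ** 2
        w = np.exp(-d2 / (2.0 * sigma ** 2))
        weight_sum = weight_sum + w
        value_sum = value_sum + w * values[name]
    return value_sum / weight_sum


def _smooth_noise(
    shape: tuple[int, int], amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Smoothed white noise rescaled so its maximum magnitude is `amplitude`."""
    if amplitude == 0:
        return np.zeros(shape)
    noise = gaussian_filter(rng.standard_normal(shape), sigma=2.0)
    peak = np.abs(noise).max()
    return noise / peak * amplitude if peak > 0 else noise


def make_suitability_rasters(
    localities: dict[str, tuple[float, float]],
    trends: dict[str, tuple[float, ...]],
    seed: int,
    epochs: tuple[str, ...] = EPOCHS,
    cellsize: float = 0.02,
    margin: float = 0.2,
    noise_amplitude: float = 0.02,
    rbf_sigma: float = 0.05,
) -> dict[str, Raster]:
    """One suitability raster per epoch with planted per-locality values.

    ``trends[name]`` gives the target suitability at that locality for each
    epoch in order.  Cell values are the Gaussian interpolation of the
    targets plus smoothed noise of bounded amplitude, clipped to [0, 1];
    grid geometry is identical across epochs.
    """
    for name, t in trends.items():
        if len(t) != len(epochs):
            raise ValueError(f"{name}: expected {len(epochs)} trend values")
        if any(not 0 <= v <= 1 for v in t):
            raise ValueError(f"{name}: trend values must lie in [0, 1]")
    missing = set(localities) - set(trends)
    if missing:
        raise ValueError(f"no trend for localities: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    lat_centers, lon_centers, xll, yll = _grid_for(localities, cellsize, margin)
    rasters = {}
    for e, epoch in enumerate(epochs):
        values = {name: trends[name][e] for name in localities}
        surface = _rbf_field(localities, values, lat_centers, lon_centers, rbf_sigma)
        surface = surface + _smooth_noise(surface.shape, noise_amplitude, rng)
        rasters[epoch] = Raster(
            data=np.clip(surface, 0.0, 1.0), xll=xll, yll=yll, cellsize=cellsize
        )
    return rasters


# ---------------------------------------------------------------------------
# Environmental layers with planted group variances and regression slope
# ---------------------------------------------------------------------------


def make_env_layers(
    groups: dict[str, dict[str, tuple[float, float]]],
    planted_variances: dict[str, float],
    planted_slope: float,
    seed: int,
    n_layers: int = 20,
    n_reps: int = 100,
    cellsize: float = 0.02,
    margin: float = 0.2,
    rbf_sigma: float = 0.02,
    diversity_noise_sd: float = 0.02,
    diversity_intercept: float = 0.2,
) -> tuple[dict[str, Raster], dict]:
    """Environmental layer stack with a planted variance/diversity structure.

    Each locality receives a scalar position ``z`` on a dominant
    environmental gradient; within group ``g`` the locality ``z`` values
    have sample variance exactly ``planted_variances[g]`` around a
    well-separated group center.  Every layer is an affine transform of the
    smooth ``z`` field (the first layer is ``z`` itself), so the leading
    principal component of the standardized layer matrix is the gradient.
    Group diversity values are drawn as
    ``intercept + planted_slope * E[var_g(PC1 score)] + noise`` where the
    expectation is computed from the ideal replicate matrix (each locality
    repeated ``n_reps`` times), so an ordinary regression of diversity on
    measured PC1 score variance has slope ``planted_slope`` in expectation.

    Returns the layers plus a truth dict with per-locality ``z`` values,
    per-group gradient variances, expected PC1-score variances, and the
    drawn diversity values.

    The planted structure is recovered exactly only when localities are
    mutually separated by clearly more than the interpolation kernel width
    (``rbf_sigma``); for closely spaced localities the smooth field blends
    neighboring gradient values.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    rng = np.random.default_rng(seed)
    z_values: dict[str, float] = {}
    all_localities: dict[str, tuple[float, float]] = {}
    for g_index, (g, locs) in enumerate(sorted(groups.items())):
        variance = planted_variances[g]
        names = list(locs)
        if len(names) == 1 and variance > 0:
            raise ValueError(f"group {g!r} has one locality but nonzero variance")
        center = 10.0 * g_index
        if variance == 0 or len(names) == 1:
            offsets = np.zeros(len(names))
        else:
            offsets = rng.standard_normal(len(names))
            offsets = offsets - offsets.mean()
            sd = offsets.std(ddof=1)
            if sd == 0:
                offsets = np.linspace(-1, 1, len(names))
                offsets = offsets - offsets.mean()
                sd = offsets.std(ddof=1)
            offsets = offsets / sd * np.sqrt(variance)
        for name, off in zip(names, offsets):
            if name in all_localities:
                raise ValueError(f"duplicate locality name {name!r}")
            z_values[name] = center + off
            all_localities[name] = locs[name]

    lat_centers, lon_centers, xll, yll = _grid_for(all_localities, cellsize, margin)
    z_field = _rbf_field(all_localities, z_values, lat_centers, lon_centers, rbf_sigma)
    coeffs = [(1.0, 0.0)]  # first layer is the gradient itself
    for j in range(1, n_layers):
        a = rng.uniform(0.5, 1.5) * (1 if j % 2 == 0 else -1)
        b = rng.uniform(-5, 5)
        coeffs.append((a, b))
    layers = {
        f"env{j + 1:02d}": Raster(
            data=a * z_field + b, xll=xll, yll=yll, cellsize=cellsize
        )
        for j, (a, b) in enumerate(coeffs)
    }

    # expected PC1-score variance per group, from the ideal replicate matrix
    group_of = {
        name: g for g, locs in groups.items() for name in locs
    }
    z_rows = np.repeat([z_values[name] for name in all_localities], n_reps)
    row_groups = np.repeat([group_of[name] for name in all_localities], n_reps)
    z_std = (z_rows - z_rows.mean()) / z_rows.std()
    pc1_ideal = np.sqrt(n_layers) * z_std
    expected_pc1_var = {
        g: float(np.var(pc1_ideal[row_groups == g], ddof=1))
        for g in groups
    }
    diversity = {
        g: diversity_intercept
        + planted_slope * expected_pc1_var[g]
        + rng.normal(0.0, diversity_noise_sd)
        for g in sorted(groups)
    }
    truth = {
        "z_values": z_values,
        "group_of": group_of,
        "planted_variances": dict(planted_variances),
        "gradient_variance": {
            g: float(np.var([z_values[n] for n in groups[g]], ddof=1))
            if len(groups[g]) > 1
            else 0.0
            for g in groups
        },
        "expected_pc1_variance": expected_pc1_var,
        "diversity": diversity,
        "planted_slope": planted_slope,
    }
    return layers, truth
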