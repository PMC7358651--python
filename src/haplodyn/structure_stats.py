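"""Population differentiation and spatial genetic structure.

Haplotypic AMOVA (one and two hierarchical levels) partitions squared
pairwise haplotype distances into variance components with permutational
significance; GST/NST compare differentiation without and with haplotype
distances (ordered-allele estimators with small-sample corrections); SAMOVA
searches, by simulated annealing over geographically contiguous partitions,
for the grouping of populations that maximizes the among-group variance
fraction F_CT; the Mantel test correlates genetic and geographic distance
matrices.

Negative variance components are reported as computed and flagged, never
clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

from .alignment_io import HaplotypeTable

__all__ = [
    "DistanceMatrix",
    "AmovaResult",
    "PermutResult",
    "SamovaResult",
    "MantelResult",
    "pairwise_distances",
    "individual_distance_matrix",
    "amova",
    "pairwise_fst",
    "gst_nst_permut",
    "samova",
    "mantel",
    "great_circle_matrix",
    "delaunay_adjacency",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("diagonal must be zero")
        if (m < 0).any():
            raise ValueError("distances must be non-negative")

    def loc(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.matrix[i, j])

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.matrix[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def pairwise_distances(haplotypes: dict[str, str]) -> DistanceMatrix:
    """Character differences between coded haplotype sequences.

    Coded indel characters are ordinary characters here, i.e. an indel is a
    fifth state contributing one step.
    """
    labels = list(haplotypes)
    seqs = [haplotypes[l] for l in labels]
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError("haplotype sequences differ in length")
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), -1)
    diff = (arr[:, None, :] != arr[None, :, :]).sum(axis=2).astype(float)
    return DistanceMatrix(labels, diff)


def individual_distance_matrix(
    table: HaplotypeTable, hap_dist: DistanceMatrix | None = None
) -> DistanceMatrix:
    """Expand haplotype distances to per-individual distances."""
    if hap_dist is None:
        hap_dist = pairwise_distances(table.haplotypes)
    hap_index = {l: i for i, l in enumerate(hap_dist.labels)}
    ids = list(table.assignments.index)
    idx = np.array([hap_index[table.assignments[sid]] for sid in ids])
    return DistanceMatrix(ids, hap_dist.matrix[np.ix_(idx, idx)])


@dataclass
class AmovaResult:
    table: pd.DataFrame  # source, df, SSD, MS, variance, percent
    phi: dict[str, float]
    p_values: dict[str, float]
    n_permutations: int
    warnings: list[str] = field(default_factory=list)

    @property
    def variance_components(self) -> pd.Series:
        return self.table.set_index("source")["variance"].drop("total", errors="ignore")

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _block_sums(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """B[k, l] = sum of d2 over i in k, j in l (both orders; diag included)."""
    ind = np.zeros((n_groups, d2.shape[0]))
    ind[codes, np.arange(d2.shape[0])] = 1.0
    return ind @ d2 @ ind.T


def _one_level_components(d2, codes, P, N):
    B = _block_sums(d2, codes, P)
    sizes = np.bincount(codes, minlength=P).astype(float)
    ssd_total = B.sum() / 2.0 / N
    ssd_wp = float(np.sum(np.diag(B) / 2.0 / sizes))
    ssd_ap = ssd_total - ssd_wp
    df_a, df_w = P - 1, N - P
    ms_a, ms_w = ssd_ap / df_a, ssd_wp / df_w
    n_prime = (N - np.sum(sizes ** 2) / N) / (P - 1)
    sigma_w = ms_w
    sigma_a = (ms_a - ms_w) / n_prime
    return ssd_total, ssd_ap, ssd_wp, df_a, df_w, ms_a, ms_w, sigma_a, sigma_w


def _two_level_components(d2, pop_codes, group_of_pop, P, G, N):
    """Variance components for the group / population / individual design.

    ``group_of_pop`` maps population code -> group code.
    """
    B = _block_sums(d2, pop_codes, P)
    n_k = np.bincount(pop_codes, minlength=P).astype(float)
    gcodes = np.asarray(group_of_pop)
    ssd_total = B.sum() / 2.0 / N
    ssd_wp = float(np.sum(np.diag(B) / 2.0 / n_k))
    ssd_group_tot = 0.0
    sum_nk2_over_Ng = 0.0
    N_g = np.zeros(G)
    for g in range(G):
        members = np.flatnonzero(gcodes == g)
        Ng = n_k[members].sum()
        N_g[g] = Ng
        ssd_group_tot += B[np.ix_(members, members)].sum() / 2.0 / Ng
        sum_nk2_over_Ng += np.sum(n_k[members] ** 2) / Ng
    ssd_ap_wg = ssd_group_tot - ssd_wp
    ssd_ag = ssd_total - ssd_group_tot
    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    ms_ag, ms_ap, ms_wp = ssd_ag / df_ag, ssd_ap_wg / df_ap, ssd_wp / df_wp
    n_c = (N - sum_nk2_over_Ng) / (P - G)
    n_c1 = (sum_nk2_over_Ng - np.sum(n_k ** 2) / N) / (G - 1)
    n_c2 = (N - np.sum(N_g ** 2) / N) / (G - 1)
    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n_c
    sigma_a = (ms_ag - sigma_c - n_c1 * sigma_b) / n_c2
    return {
        "ssd": (ssd_ag, ssd_ap_wg, ssd_wp, ssd_total),
        "df": (df_ag, df_ap, df_wp),
        "ms": (ms_ag, ms_ap, ms_wp),
        "sigma": (sigma_a, sigma_b, sigma_c),
    }


def _prepare(dist: DistanceMatrix, populations) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(populations, pd.DataFrame):
        pop_of = dict(zip(populations["sequence_id"], populations["population"]))
    else:
        pop_of = dict(populations)
    pops = list(dict.fromkeys(pop_of[l] for l in dist.labels))
    codes = np.array([pops.index(pop_of[l]) for l in dist.labels])
    sizes = np.bincount(codes, minlength=len(pops))
    if (sizes == 0).any():
        raise ValueError("population with zero individuals")
    return dist.matrix ** 2, codes, pops


def amova(
    dist: DistanceMatrix,
    populations,
    groups: dict[str, str] | None = None,
    n_perm: int = 0,
    seed: int | None = None,
) -> AmovaResult:
    """Haplotypic analysis of molecular variance.

    ``dist`` holds per-individual distances (number of character
    differences); squared distances enter the sums of squares.  With
    ``groups`` (population -> group) a two-level design partitions variance
    among groups / among populations within groups / within populations.
    Permutation p-values: individuals among populations for Phi_ST; for the
    two-level design additionally populations among groups for F_CT and
    individuals among populations within groups for F_SC.
    """
    d2, codes, pops = _prepare(dist, populations)
    P, N = len(pops), len(codes)
    if P < 2:
        raise ValueError("need at least 2 populations")
    rng = np.random.default_rng(seed)
    warnings: list[str] = []

    if groups is None:
        (ssd_total, ssd_ap, ssd_wp, df_a, df_w, ms_a, ms_w,
         sigma_a, sigma_w) = _one_level_components(d2, codes, P, N)
        total_var = sigma_a + sigma_w
        if sigma_a < 0:
            warnings.append("negative among-population variance component")
        phi_st = sigma_a / total_var if total_var != 0 else 0.0
        table = pd.DataFrame(
            {
                "source": ["among_populations", "within_populations", "total"],
                "df": [df_a, df_w, df_a + df_w],
                "SSD": [ssd_ap, ssd_wp, ssd_total],
                "MS": [ms_a, ms_w, np.nan],
                "variance": [sigma_a, sigma_w, total_var],
                "percent": [
                    100.0 * sigma_a / total_var if total_var else np.nan,
                    100.0 * sigma_w / total_var if total_var else np.nan,
                    100.0,
                ],
            }
        )
        p_values = {}
        if n_perm > 0:
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(codes)
                *_rest, s_a, s_w = _one_level_components(d2, perm, P, N)
                tot = s_a + s_w
                phi_p = s_a / tot if tot != 0 else 0.0
                if phi_p >= phi_st - 1e-12:
                    count += 1
            p_values["phi_st"] = (count + 1) / (n_perm + 1)
        return AmovaResult(table, {"phi_st": phi_st}, p_values, n_perm, warnings)

    # two-level design
    group_names = list(dict.fromkeys(groups[p] for p in pops))
    G = len(group_names)
    if G < 2:
        raise ValueError("need at least 2 groups")
    gof = np.array([group_names.index(groups[p]) for p in pops])
    comp = _two_level_components(d2, codes, gof, P, G, N)
    sigma_a, sigma_b, sigma_c = comp["sigma"]
    total_var = sigma_a + sigma_b + sigma_c
    for name, s in zip(("among-group", "among-population", "within-population"),
                       comp["sigma"]):
        if s < 0:
            warnings.append(f"negative {name} variance component")
    f_ct = sigma_a / total_var if total_var != 0 else 0.0
    f_sc = sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) != 0 else 0.0
    f_st = (sigma_a + sigma_b) / total_var if total_var != 0 else 0.0
    ssd_ag, ssd_ap, ssd_wp, ssd_total = comp["ssd"]
    df_ag, df_ap, df_wp = comp["df"]
    ms_ag, ms_ap, ms_wp = comp["ms"]
    table = pd.DataFrame(
        {
            "source": [
                "among_groups",
                "among_populations_within_groups",
                "within_populations",
                "total",
            ],
            "df": [df_ag, df_ap, df_wp, N - 1],
            "SSD": [ssd_ag, ssd_ap, ssd_wp, ssd_total],
            "MS": [ms_ag, ms_ap, ms_wp, np.nan],
            "variance": [sigma_a, sigma_b, sigma_c, total_var],
            "percent": [
                100.0 * sigma_a / total_var if total_var else np.nan,
                100.0 * sigma_b / total_var if total_var else np.nan,
                100.0 * sigma_c / total_var if total_var else np.nan,
                100.0,
            ],
        }
    )
    phi = {"f_ct": f_ct, "f_sc": f_sc, "f_st": f_st}
    p_values = {}
    if n_perm > 0:
        count_ct = count_sc = count_st = 0
        for _ in range(n_perm):
            # F_CT: permute whole populations among groups
            perm_gof = rng.permutation(gof)
            c = _two_level_components(d2, codes, perm_gof, P, G, N)
            sa, sb, sc = c["sigma"]
            tot = sa + sb + sc
            if (sa / tot if tot != 0 else 0.0) >= f_ct - 1e-12:
                count_ct += 1
            # F_SC: permute individuals among populations within groups
            perm_codes = codes.copy()
            for g in range(G):
                pops_in_g = np.flatnonzero(gof == g)
                mask = np.isin(codes, pops_in_g)
                perm_codes[mask] = rng.permutation(codes[mask])
            c = _two_level_components(d2, perm_codes, gof, P, G, N)
            sa, sb, sc = c["sigma"]
            if (sb / (sb + sc) if (sb + sc) != 0 else 0.0) >= f_sc - 1e-12:
                count_sc += 1
            # F_ST: permute individuals among all populations
            c = _two_level_components(d2, rng.permutation(codes), gof, P, G, N)
            sa, sb, sc = c["sigma"]
            tot = sa + sb + sc
            if ((sa + sb) / tot if tot != 0 else 0.0) >= f_st - 1e-12:
                count_st += 1
        p_values = {
            "f_ct": (count_ct + 1) / (n_perm + 1),
            "f_sc": (count_sc + 1) / (n_perm + 1),
            "f_st": (count_st + 1) / (n_perm + 1),
        }
    return AmovaResult(table, phi, p_values, n_perm, warnings)


def pairwise_fst(dist: DistanceMatrix, populations) -> pd.DataFrame:
    """Population x population matrix of two-population AMOVA Phi_ST."""
    if isinstance(populations, pd.DataFrame):
        pop_of = dict(zip(populations["sequence_id"], populations["population"]))
    else:
        pop_of = dict(populations)
    pops = list(dict.fromkeys(pop_of[l] for l in dist.labels))
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for a_i in range(len(pops)):
        for b_i in range(a_i + 1, len(pops)):
            a, b = pops[a_i], pops[b_i]
            ids = [l for l in dist.labels if pop_of[l] in (a, b)]
            sub = dist.reorder(ids)
            res = amova(sub, {l: pop_of[l] for l in ids})
            out.loc[a, b] = out.loc[b, a] = res.phi["phi_st"]
    return out


# ---------------------------------------------------------------------------
# GST / NST with permutation (ordered vs unordered alleles)
# ---------------------------------------------------------------------------


@dataclass
class PermutResult:
    g_st: float
    n_st: float
    h_s: float
    h_t: float
    v_s: float
    v_t: float
    p_value: float
    n_permutations: int


def _nst_statistic(freqs: np.ndarray, sizes: np.ndarray, pi_mat: np.ndarray):
    """1 - v_S / v_T with unbiased within/total diversities.

    ``freqs`` is populations x haplotypes; with ``pi_mat`` equal to
    ``1 - identity`` this is exactly the unordered G_ST.
    """
    P = freqs.shape[0]
    v_k = np.array(
        [
            sizes[k] / (sizes[k] - 1.0) * freqs[k] @ pi_mat @ freqs[k]
            for k in range(P)
        ]
    )
    v_s = v_k.mean()
    n_harm = P / np.sum(1.0 / sizes)
    p_bar = freqs.mean(axis=0)
    v_t = p_bar @ pi_mat @ p_bar + v_s / (n_harm * P)
    if v_t == 0:
        raise ValueError("monomorphic total sample: total diversity is zero")
    return 1.0 - v_s / v_t, v_s, v_t


def gst_nst_permut(
    table: HaplotypeTable,
    hap_dist: DistanceMatrix | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> PermutResult:
    """Compare unordered (G_ST) and ordered (N_ST) differentiation.

    N_ST weights haplotype pairs by their normalized mutational distance;
    N_ST exceeding G_ST indicates phylogeographic structure.  The p-value
    is the fraction of permutations of haplotype identities on the distance
    matrix with N_ST - G_ST at least the observed difference.
    """
    if table.h < 2:
        raise ValueError("need at least 2 haplotypes")
    if len(table.populations) < 2:
        raise ValueError("need at least 2 populations")
    if hap_dist is None:
        hap_dist = pairwise_distances(table.haplotypes)
    hap_labels = list(table.counts.columns)
    hap_dist = hap_dist.reorder(hap_labels)
    counts = table.counts.to_numpy().astype(float)
    sizes = counts.sum(axis=1)
    if (sizes < 2).any():
        raise ValueError("every population needs at least 2 sequences")
    freqs = counts / sizes[:, None]

    dmax = hap_dist.matrix.max()
    pi_ordered = hap_dist.matrix / dmax if dmax > 0 else hap_dist.matrix
    pi_unordered = 1.0 - np.eye(len(hap_labels))

    g_st, h_s, h_t = _nst_statistic(freqs, sizes, pi_unordered)
    n_st, v_s, v_t = _nst_statistic(freqs, sizes, pi_ordered)
    observed = n_st - g_st

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(hap_labels))
        n_st_p, _, _ = _nst_statistic(freqs, sizes, pi_ordered[np.ix_(perm, perm)])
        if n_st_p - g_st >= observed - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PermutResult(g_st, n_st, h_s, h_t, v_s, v_t, p, n_perm)


# ---------------------------------------------------------------------------
# SAMOVA: simulated annealing over contiguous partitions maximizing F_CT
# ---------------------------------------------------------------------------


@dataclass
class SamovaResult:
    K: int
    partition: dict[str, int]
    f_ct: float
    f_sc: float
    f_st: float
    n_starts: int
    trace: list[float]  # best F_CT per restart


def delaunay_adjacency(coords: dict[str, tuple[float, float]]) -> dict[str, set[str]]:
    """Neighbor sets from the Delaunay triangulation of (lon, lat) points."""
    names = list(coords)
    pts = np.array([(coords[n][1], coords[n][0]) for n in names])
    if len(np.unique(pts, axis=0)) < len(names):
        raise ValueError("co-located populations")
    tri = Delaunay(pts, qhull_options="QJ")
    adj: dict[str, set[str]] = {n: set() for n in names}
    for simplex in tri.simplices:
        for i in range(3):
            for j in range(i + 1, 3):
                a, b = names[simplex[i]], names[simplex[j]]
                adj[a].add(b)
                adj[b].add(a)
    return adj


def _connected(members: set[int], adj_idx: list[set[int]]) -> bool:
    if not members:
        return False
    start = next(iter(members))
    seen = {start}
    stack = [start]
    while stack:
        x = stack.pop()
        for y in adj_idx[x]:
            if y in members and y not in seen:
                seen.add(y)
                stack.append(y)
    return len(seen) == len(members)


class _FctEvaluator:
    """Fast F_CT for partitions, from population-level block sums."""

    def __init__(self, d2: np.ndarray, codes: np.ndarray, P: int):
        N = len(codes)
        self.B = _block_sums(d2, codes, P)
        self.n_k = np.bincount(codes, minlength=P).astype(float)
        self.N = float(N)
        self.P = P
        self.ssd_total = self.B.sum() / 2.0 / N
        self.ssd_wp = float(np.sum(np.diag(self.B) / 2.0 / self.n_k))
        self.nk2 = self.n_k ** 2
        self.sum_nk2 = float(np.sum(self.nk2))
        self._arange = np.arange(P)

    def f_stats(self, assign: np.ndarray, K: int) -> tuple[float, float, float]:
        N, P = self.N, self.P
        onehot = np.zeros((K, P))
        onehot[assign, self._arange] = 1.0
        group_pair = ((onehot @ self.B) * onehot).sum(axis=1)
        N_g = onehot @ self.n_k
        ssd_group_tot = float(np.sum(group_pair / 2.0 / N_g))
        sum_nk2_over_Ng = float(np.sum((onehot @ self.nk2) / N_g))
        sum_Ng2 = float(np.sum(N_g ** 2))
        ssd_ap = ssd_group_tot - self.ssd_wp
        ssd_ag = self.ssd_total - ssd_group_tot
        ms_ag = ssd_ag / (K - 1)
        ms_ap = ssd_ap / (P - K)
        ms_wp = self.ssd_wp / (N - P)
        n_c = (N - sum_nk2_over_Ng) / (P - K)
        n_c1 = (sum_nk2_over_Ng - self.sum_nk2 / N) / (K - 1)
        n_c2 = (N - sum_Ng2 / N) / (K - 1)
        sigma_c = ms_wp
        sigma_b = (ms_ap - sigma_c) / n_c
        sigma_a = (ms_ag - sigma_c - n_c1 * sigma_b) / n_c2
        total = sigma_a + sigma_b + sigma_c
        f_ct = sigma_a / total if total != 0 else 0.0
        f_sc = sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) != 0 else 0.0
        f_st = (sigma_a + sigma_b) / total if total != 0 else 0.0
        return f_ct, f_sc, f_st


def _random_contiguous_partition(
    P: int, K: int, adj_idx: list[set[int]], rng: np.random.Generator
) -> np.ndarray:
    seeds = rng.choice(P, size=K, replace=False)
    assign = np.full(P, -1)
    frontier = {int(s): g for g, s in enumerate(seeds)}
    for s, g in frontier.items():
        assign[s] = g
    unassigned = set(range(P)) - set(int(s) for s in seeds)
    while unassigned:
        candidates = [
            (p, assign[q])
            for p in unassigned
            for q in adj_idx[p]
            if assign[q] >= 0
        ]
        if not candidates:  # disconnected adjacency graph; assign arbitrarily
            p = unassigned.pop()
            assign[p] = rng.integers(K)
            continue
        p, g = candidates[rng.integers(len(candidates))]
        assign[p] = g
        unassigned.discard(p)
    return assign


def samova(
    dist: DistanceMatrix,
    populations,
    coords: dict[str, tuple[float, float]],
    K: int,
    n_starts: int = 100,
    seed: int | None = None,
    cooling: float = 0.95,
    n_temps: int = 40,
    proposals_per_temp: int | None = None,
) -> SamovaResult:
    """Spatial analysis of molecular variance.

    Searches partitions of the populations into ``K`` groups, each
    contiguous on the Delaunay neighbor graph of the population
    coordinates, maximizing F_CT from the two-level AMOVA.  Simulated
    annealing (geometric cooling, boundary-move proposals) with
    ``n_starts`` independent restarts; deterministic under ``seed``.
    """
    d2, codes, pops = _prepare(dist, populations)
    P = len(pops)
    if not 2 <= K <= P - 1:
        raise ValueError(f"K must be in [2, {P - 1}], got {K}")
    adj = delaunay_adjacency({p: coords[p] for p in pops})
    adj_idx: list[set[int]] = [
        {pops.index(q) for q in adj[pops[i]]} for i in range(P)
    ]
    evaluator = _FctEvaluator(d2, codes, P)
    if proposals_per_temp is None:
        proposals_per_temp = 50 * P
    rng = np.random.default_rng(seed)

    best_f = -np.inf
    best_assign: np.ndarray | None = None
    best_rest = (0.0, 0.0)
    trace: list[float] = []

    for _start in range(n_starts):
        assign = _random_contiguous_partition(P, K, adj_idx, rng)
        f_cur, *_ = evaluator.f_stats(assign, K)
        # calibrate initial temperature on sampled worsening moves
        deltas = []
        for _ in range(30):
            move = _propose(assign, K, adj_idx, rng)
            if move is None:
                continue
            p, g_new = move
            trial = assign.copy()
            trial[p] = g_new
            f_trial, *_ = evaluator.f_stats(trial, K)
            if f_trial < f_cur:
                deltas.append(f_cur - f_trial)
        t = (np.mean(deltas) / np.log(2.0)) if deltas else 1e-3
        start_best_f = f_cur
        start_best = assign.copy()
        for _temp in range(n_temps):
            accepted = 0
            for _ in range(proposals_per_temp):
                move = _propose(assign, K, adj_idx, rng)
                if move is None:
                    continue
                p, g_new = move
                trial = assign.copy()
                trial[p] = g_new
                f_trial, f_sc_t, f_st_t = evaluator.f_stats(trial, K)
                delta = f_trial - f_cur
                if delta >= 0 or rng.random() < np.exp(delta / t):
                    assign = trial
                    f_cur = f_trial
                    accepted += 1
                    if f_cur > start_best_f:
                        start_best_f = f_cur
                        start_best = assign.copy()
            t *= cooling
            if accepted == 0:
                break
        trace.append(start_best_f)
        if start_best_f > best_f:
            best_f = start_best_f
            best_assign = start_best

    f_ct, f_sc, f_st = evaluator.f_stats(best_assign, K)
    # canonical group ids: by first population occurrence
    remap: dict[int, int] = {}
    partition = {}
    for i, p in enumerate(pops):
        g = int(best_assign[i])
        if g not in remap:
            remap[g] = len(remap)
        partition[p] = remap[g]
    return SamovaResult(K, partition, f_ct, f_sc, f_st, n_starts, trace)


def _propose(assign: np.ndarray, K: int, adj_idx: list[set[int]], rng):
    """A boundary move keeping all groups non-empty and contiguous."""
    P = len(assign)
    order = rng.permutation(P)
    for p in order:
        g_old = assign[p]
        group = set(np.flatnonzero(assign == g_old))
        if len(group) == 1:
            continue  # would empty the group
        if not _connected(group - {p}, adj_idx):
            continue
        neighbor_groups = {int(assign[q]) for q in adj_idx[p]} - {int(g_old)}
        if not neighbor_groups:
            continue
        g_new = list(neighbor_groups)[rng.integers(len(neighbor_groups))]
        return int(p), g_new
    return None


# ---------------------------------------------------------------------------
# Mantel test and geographic distances
# ---------------------------------------------------------------------------


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    flagged: bool = False
    note: str = ""


def mantel(
    genetic: DistanceMatrix,
    geographic: DistanceMatrix,
    n_perm: int = 10000,
    seed: int | None = None,
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the off-diagonal entries; the one-sided
    p-value permutes rows/columns of the geographic matrix.  A constant
    matrix leaves r undefined: the result is flagged with r = nan.
    """
    if genetic.labels != geographic.labels:
        geographic = geographic.reorder(genetic.labels)
    n = len(genetic.labels)
    iu = np.triu_indices(n, k=1)
    x = genetic.matrix[iu]
    y = geographic.matrix[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        return MantelResult(float("nan"), 1.0, 0, flagged=True,
                            note="constant distance matrix; r undefined")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        y_perm = geographic.matrix[np.ix_(perm, perm)][iu]
        if float(np.corrcoef(x, y_perm)[0, 1]) >= r_obs - 1e-12:
            count += 1
    return MantelResult(r_obs, (count + 1) / (n_perm + 1), n_perm)


EARTH_RADIUS_KM = 6371.0


def great_circle_matrix(coords: dict[str, tuple[float, float]]) -> DistanceMatrix:
    """Haversine great-circle distances (km) between localities."""
    names = list(coords)
    lat = np.radians([coords[n][0] for n in names])
    lon = np.radians([coords[n][1] for n in names])
    if (np.abs(np.degrees(lat)) > 90).any() or (np.abs(np.degrees(lon)) > 180).any():
        raise ValueError("coordinates out of range")
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = (
        np.sin(dlat / 2.0) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
    )
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(names, d)
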