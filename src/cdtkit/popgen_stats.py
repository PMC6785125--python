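"""Classical single-locus population-genetic statistics.

Operates on aligned mitochondrial haplotype data: haplotype collapsing,
diversity indices (H, h, pi), the expansion-sensitive neutrality statistics
(Tajima's D, Fu's Fs, Ramos-Onsins & Rozas' R2) with coalescent nulls,
AMOVA-based pairwise Phi_st with permutation tests, Tamura (1992) + Gamma
distances, and the haplotype minimum spanning network.

Missing data (``N`` or ``-``) are handled by *complete deletion* by default:
any column containing a missing character in any sequence is dropped before
a statistic is computed.  ``missing="pairwise"`` switches the pairwise
distances to per-pair deletion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
import numpy as np
from scipy.special import logsumexp

__all__ = [
    "Alignment",
    "HaplotypeTable",
    "NeutralityResult",
    "DistanceMatrix",
    "UndefinedStatisticError",
    "collapse_haplotypes",
    "haplotype_diversity",
    "nucleotide_diversity",
    "tajimas_d",
    "fus_fs",
    "r2_statistic",
    "neutrality_null",
    "pairwise_phi_st",
    "t92_gamma_distance",
    "minimum_spanning_tree",
]

ALPHABET = "ACGTN-"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_MISSING = frozenset({_CODE["N"], _CODE["-"]})


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is mathematically undefined for the input
    (e.g. Tajima's D with no segregating sites)."""


@dataclass
class Alignment:
    """Equal-length nucleotide sequences with labels and population tags."""

    sequences: list[str]
    labels: list[str]
    populations: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("alignment must contain at least one sequence")
        self.sequences = [s.upper() for s in self.sequences]
        length = len(self.sequences[0])
        if length < 1:
            raise ValueError("zero-length sequences")
        for lab, s in zip(self.labels, self.sequences):
            if len(s) != length:
                raise ValueError(f"ragged alignment: sequence {lab!r} has length {len(s)} != {length}")
            bad = set(s) - set(ALPHABET)
            if bad:
                pos = next(i for i, c in enumerate(s) if c in bad)
                raise ValueError(
                    f"illegal character {s[pos]!r} in sequence {lab!r} at column {pos + 1}"
                )
        if len(self.labels) != len(self.sequences):
            raise ValueError("labels/sequences length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate sequence labels")
        if self.populations is not None and len(self.populations) != len(self.sequences):
            raise ValueError("populations/sequences length mismatch")
        self._matrix: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def matrix(self) -> np.ndarray:
        """(n, length) uint8 codes over the ACGTN- alphabet."""
        if self._matrix is None:
            raw = np.frombuffer(
                "".join(self.sequences).encode(), dtype=np.uint8
            ).reshape(self.n, self.length)
            lut = np.zeros(256, dtype=np.uint8)
            for c, i in _CODE.items():
                lut[ord(c)] = i
            self._matrix = lut[raw]
        return self._matrix

    def subset(self, indices: list[int] | None = None, population: str | None = None) -> "Alignment":
        if population is not None:
            if self.populations is None:
                raise ValueError("alignment carries no population labels")
            indices = [i for i, p in enumerate(self.populations) if p == population]
        if not indices:
            raise ValueError("empty subset")
        return Alignment(
            [self.sequences[i] for i in indices],
            [self.labels[i] for i in indices],
            [self.populations[i] for i in indices] if self.populations else None,
        )

    def population_names(self) -> list[str]:
        if self.populations is None:
            return []
        seen: list[str] = []
        for p in self.populations:
            if p not in seen:
                seen.append(p)
        return seen


@dataclass
class HaplotypeTable:
    haplotype_sequences: list[str]
    counts: np.ndarray
    per_population_counts: np.ndarray  # (n_haplotypes, n_populations)
    population_names: list[str]
    segregating_sites: list[int]  # 0-based original columns
    members: list[list[int]]  # input-sequence indices per haplotype

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_sequences)


@dataclass
class NeutralityResult:
    statistic_name: str
    value: float
    p_value: float
    n_reps: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0,1]")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray
    distance_kind: str

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if np.nanmax(np.abs(m - m.T), initial=0.0) > 1e-12:
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        self.matrix = m


# ---------------------------------------------------------------------------
# column bookkeeping
# ---------------------------------------------------------------------------

def complete_columns(matrix: np.ndarray) -> np.ndarray:
    """Columns free of N/gap in every sequence (complete-deletion policy)."""
    missing = (matrix == _CODE["N"]) | (matrix == _CODE["-"])
    return ~missing.any(axis=0)


def _clean_matrix(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    keep = complete_columns(aln.matrix)
    return aln.matrix[:, keep], np.flatnonzero(keep)


def _base_counts(mat: np.ndarray) -> np.ndarray:
    """(4, n_cols) counts of A,C,G,T per column (missing-free input)."""
    return np.stack([(mat == b).sum(axis=0) for b in range(4)])


def _segregating_mask(mat: np.ndarray) -> np.ndarray:
    counts = _base_counts(mat)
    return (counts > 0).sum(axis=0) > 1


def _mean_pairwise_diffs(mat: np.ndarray) -> float:
    """Mean pairwise difference *count* (pi_total, not per site)."""
    n = mat.shape[0]
    counts = _base_counts(mat)
    per_col = (n * n - (counts**2).sum(axis=0)) / 2.0
    return float(per_col.sum()) / (n * (n - 1) / 2.0)


def _singletons_per_sequence(mat: np.ndarray) -> np.ndarray:
    """U_i: number of singleton mutations carried by each sequence.

    A singleton is a column where some base is observed exactly once; the
    carrier of that base is charged with the mutation.
    """
    n = mat.shape[0]
    u = np.zeros(n)
    counts = _base_counts(mat)
    for col in np.flatnonzero((counts == 1).any(axis=0)):
        for b in np.flatnonzero(counts[:, col] == 1):
            u[int(np.flatnonzero(mat[:, col] == b)[0])] += 1
    return u


def _n_distinct_rows(mat: np.ndarray) -> int:
    return len({row.tobytes() for row in mat})


# ---------------------------------------------------------------------------
# haplotypes and diversity
# ---------------------------------------------------------------------------

def collapse_haplotypes(aln: Alignment) -> HaplotypeTable:
    """Group identical sequences (after complete deletion of missing-data
    columns) into haplotypes, keeping per-population counts."""
    mat, kept_cols = _clean_matrix(aln)
    order: dict[bytes, int] = {}
    members: list[list[int]] = []
    for i in range(aln.n):
        key = mat[i].tobytes()
        if key not in order:
            order[key] = len(members)
            members.append([])
        members[order[key]].append(i)
    pops = aln.population_names() or ["all"]
    pop_of = aln.populations or ["all"] * aln.n
    per_pop = np.zeros((len(members), len(pops)), dtype=int)
    for h, mem in enumerate(members):
        for i in mem:
            per_pop[h, pops.index(pop_of[i])] += 1
    hap_mat = mat[[mem[0] for mem in members]]
    seg = kept_cols[_segregating_mask(hap_mat)]
    hap_seqs = [aln.sequences[mem[0]] for mem in members]
    return HaplotypeTable(
        haplotype_sequences=hap_seqs,
        counts=np.array([len(m) for m in members]),
        per_population_counts=per_pop,
        population_names=pops,
        segregating_sites=[int(c) for c in seg],
        members=members,
    )


def haplotype_diversity(table: HaplotypeTable) -> tuple[float, float]:
    """Nei's haplotype (gene) diversity h and its standard error.

    h = n/(n-1) (1 - sum p_i^2); variance from Nei (1987, eq. 8.12).
    """
    n = int(table.counts.sum())
    if n < 2:
        raise ValueError("haplotype diversity needs n >= 2")
    p = table.counts / n
    s2, s3 = float((p**2).sum()), float((p**3).sum())
    h = n / (n - 1) * (1.0 - s2)
    var = (2.0 / (n * (n - 1))) * (2.0 * (n - 2) * (s3 - s2**2) + s2 - s2**2)
    return h, math.sqrt(max(var, 0.0))


def nucleotide_diversity(aln: Alignment) -> tuple[float, float]:
    """Per-site nucleotide diversity pi and its standard error (Nei 1987).

    pi is the mean proportion of differing sites over all sequence pairs,
    computed on missing-free columns.
    """
    if aln.n < 2:
        raise ValueError("nucleotide diversity needs n >= 2")
    mat, _ = _clean_matrix(aln)
    length = mat.shape[1]
    if length == 0:
        raise UndefinedStatisticError("no comparable sites after missing-data filtering")
    n = aln.n
    pi = _mean_pairwise_diffs(mat) / length
    var = (n + 1) / (3.0 * (n - 1) * length) * pi + (
        2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    ) * pi**2
    return pi, math.sqrt(max(var, 0.0))


# ---------------------------------------------------------------------------
# neutrality statistics
# ---------------------------------------------------------------------------

def _tajima_constants(n: int) -> tuple[float, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def _tajima_d_from_summary(n: int, s: int, pi_total: float) -> float:
    if s < 1:
        raise UndefinedStatisticError("Tajima's D undefined with no segregating sites")
    a1 = sum(1.0 / i for i in range(1, n))
    e1, e2 = _tajima_constants(n)
    return (pi_total - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def tajimas_d(aln: Alignment) -> float:
    """Tajima (1989) D from mean pairwise differences vs Watterson's theta."""
    if aln.n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    mat, _ = _clean_matrix(aln)
    s = int(_segregating_mask(mat).sum())
    return _tajima_d_from_summary(aln.n, s, _mean_pairwise_diffs(mat))


@lru_cache(maxsize=None)
def _log_stirling_row(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 1..n (unsigned Stirling numbers, first kind)."""
    row = [0, 1]  # s(1, 0..1)
    for m in range(1, n):
        nxt = [0] * (m + 2)
        for k in range(1, m + 2):
            nxt[k] = row[k - 1] + m * (row[k] if k <= m else 0)
        row = nxt
    return np.array([math.log(v) for v in row[1:]])


def _fs_from_summary(n: int, k_obs: int, theta: float) -> float:
    """Fu's Fs = ln(S'/(1-S')), S' = P(K >= k_obs | theta) under the Ewens
    sampling formula; the rising-factorial normalization cancels in the
    odds ratio, leaving two Stirling-number tail sums."""
    if theta <= 0:
        raise UndefinedStatisticError("Fu's Fs undefined when mean pairwise difference is 0")
    if k_obs <= 1:
        return math.inf
    logterms = _log_stirling_row(n) + np.arange(1, n + 1) * math.log(theta)
    upper = logsumexp(logterms[k_obs - 1 :])
    lower = logsumexp(logterms[: k_obs - 1])
    return float(upper - lower)


def fus_fs(aln: Alignment) -> float:
    """Fu (1997) Fs using theta-hat = mean pairwise differences and the
    observed number of distinct haplotypes."""
    if aln.n < 2:
        raise ValueError("Fu's Fs requires n >= 2")
    mat, _ = _clean_matrix(aln)
    return _fs_from_summary(aln.n, _n_distinct_rows(mat), _mean_pairwise_diffs(mat))


def _r2_from_summary(n: int, s: int, pi_total: float, u: np.ndarray) -> float:
    if s < 1:
        raise UndefinedStatisticError("R2 undefined with no segregating sites")
    return math.sqrt(float(((u - pi_total / 2.0) ** 2).mean())) / s


def r2_statistic(aln: Alignment) -> float:
    """Ramos-Onsins & Rozas (2002) R2: contrast of singletons with pi."""
    if aln.n < 2:
        raise ValueError("R2 requires n >= 2")
    mat, _ = _clean_matrix(aln)
    s = int(_segregating_mask(mat).sum())
    return _r2_from_summary(aln.n, s, _mean_pairwise_diffs(mat), _singletons_per_sequence(mat))


_NULL_STATS = ("tajima_d", "fu_fs", "r2")


def _observed_statistic(aln: Alignment, statistic: str) -> float:
    if statistic == "tajima_d":
        return tajimas_d(aln)
    if statistic == "fu_fs":
        return fus_fs(aln)
    if statistic == "r2":
        return r2_statistic(aln)
    raise ValueError(f"unknown statistic {statistic!r}; expected one of {_NULL_STATS}")


def neutrality_null(
    aln: Alignment, statistic: str, n_reps: int = 1000, seed: int = 0
) -> NeutralityResult:
    """One-tailed test of *statistic* against a constant-size coalescent null.

    Replicate datasets are simulated conditioned on (n, S): a standard
    constant-size genealogy is drawn and S infinite-sites mutations are
    placed uniformly on its branches.  Small values of every supported
    statistic indicate expansion, so the p-value is the fraction of
    replicates with statistic <= observed (pseudocount-corrected).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    from .synthetic_data import TwoEpochModel, simulate_coalescent  # lazy: avoids cycle

    observed = _observed_statistic(aln, statistic)
    mat, _ = _clean_matrix(aln)
    s_obs = int(_segregating_mask(mat).sum())
    if s_obs < 1:
        raise UndefinedStatisticError("cannot build a null with S = 0")
    n = aln.n
    const = TwoEpochModel("exponential", 1.0, 1.0, 1.0)
    rng = np.random.default_rng(seed)
    n_le = 0
    for _ in range(n_reps):
        gen = simulate_coalescent(n, const, seed=int(rng.integers(2**31)))
        bl = gen.branch_lengths()
        nodes = np.flatnonzero(bl > 0)
        probs = bl[nodes] / bl[nodes].sum()
        hits = rng.choice(nodes, size=s_obs, p=probs)
        tipsets = gen.clade_tipsets()
        carriers = np.zeros((n, s_obs), dtype=np.uint8)
        for j, node in enumerate(hits):
            tips = tipsets[node] if node >= n else frozenset([int(node)])
            carriers[list(tips), j] = 1
        c = carriers.sum(axis=0)
        pi_total = float((c * (n - c)).sum()) / (n * (n - 1) / 2.0)
        if statistic == "tajima_d":
            val = _tajima_d_from_summary(n, s_obs, pi_total)
        elif statistic == "fu_fs":
            val = (
                _fs_from_summary(n, _n_distinct_rows(carriers), pi_total)
                if pi_total > 0
                else math.inf
            )
        else:
            minor = np.minimum(c, n - c)
            u = np.zeros(n)
            for j in np.flatnonzero(minor == 1):
                col = carriers[:, j]
                carrier = np.flatnonzero(col == (1 if c[j] == 1 else 0))[0]
                u[int(carrier)] += 1
            val = _r2_from_summary(n, s_obs, pi_total, u)
        if val <= observed:
            n_le += 1
    p = (n_le + 1) / (n_reps + 1)
    return NeutralityResult(statistic, observed, min(p, 1.0), n_reps)


# ---------------------------------------------------------------------------
# Phi_st (two-population AMOVA)
# ---------------------------------------------------------------------------

def _pairwise_diff_counts(mat: np.ndarray) -> np.ndarray:
    n = mat.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        d[i, i + 1 :] = (mat[i + 1 :] != mat[i]).sum(axis=1)
    return d + d.T


def _amova_phi(d: np.ndarray, groups: np.ndarray) -> float:
    """Phi_st from a squared-distance matrix and a binary group vector."""
    n = d.shape[0]
    ssd_total = d[np.triu_indices(n, 1)].sum() / n
    ssd_within = 0.0
    sizes = []
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        sizes.append(idx.size)
        sub = d[np.ix_(idx, idx)]
        ssd_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    n_pops = len(sizes)
    ssd_among = ssd_total - ssd_within
    sigma_w = ssd_within / (n - n_pops)
    n_c = (n - sum(s**2 for s in sizes) / n) / (n_pops - 1)
    sigma_a = (ssd_among / (n_pops - 1) - sigma_w) / n_c
    denom = sigma_a + sigma_w
    if denom == 0:
        return 0.0
    return sigma_a / denom


def pairwise_phi_st(
    aln: Alignment,
    pop_a: str,
    pop_b: str,
    n_perms: int = 1000,
    seed: int = 0,
    distance: str = "pairwise_diff_count",
    gamma_shape: float | None = None,
) -> tuple[float, float]:
    """AMOVA Phi_st between two populations with a permutation p-value.

    ``distance`` selects the squared molecular distance between individuals:
    pairwise difference counts (default) or ``"t92_gamma"`` (requires
    ``gamma_shape``).  The p-value is the fraction of random reassignments of
    individuals to populations (sizes held fixed) with Phi_st >= observed.
    """
    if aln.populations is None:
        raise ValueError("alignment carries no population labels")
    idx = [i for i, p in enumerate(aln.populations) if p in (pop_a, pop_b)]
    groups = np.array([0 if aln.populations[i] == pop_a else 1 for i in idx])
    if (groups == 0).sum() < 2 or (groups == 1).sum() < 2:
        raise ValueError("each population needs at least 2 sequences")
    sub = aln.subset(indices=idx)
    if distance == "pairwise_diff_count":
        mat, _ = _clean_matrix(sub)
        d = _pairwise_diff_counts(mat)
    elif distance == "t92_gamma":
        if gamma_shape is None:
            raise ValueError("t92_gamma distance requires gamma_shape")
        d = t92_gamma_distance(sub, gamma_shape).matrix
        if np.isnan(d).any():
            raise ValueError("undefined T92 distances present")
    else:
        raise ValueError(f"unknown distance {distance!r}")
    observed = _amova_phi(d, groups)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perms):
        if _amova_phi(d, rng.permutation(groups)) >= observed:
            n_ge += 1
    return observed, (n_ge + 1) / (n_perms + 1)


# ---------------------------------------------------------------------------
# T92 + Gamma distances and the minimum spanning network
# ---------------------------------------------------------------------------

def _t92_pair(p: float, q: float, gc: float, alpha: float | None) -> float:
    h = 2.0 * gc * (1.0 - gc)
    x1 = 1.0 - p / h - q if h > 0 else 1.0 - q
    x2 = 1.0 - 2.0 * q
    if x1 <= 0 or x2 <= 0:
        return math.nan
    if alpha is None or math.isinf(alpha):
        return -h * math.log(x1) - 0.5 * (1.0 - h) * math.log(x2)
    return alpha * (
        h * (x1 ** (-1.0 / alpha) - 1.0) + 0.5 * (1.0 - h) * (x2 ** (-1.0 / alpha) - 1.0)
    )


def t92_gamma_distance(
    aln: Alignment, alpha: float | None, missing: str = "complete"
) -> DistanceMatrix:
    """Tamura (1992) 3-parameter distance with Gamma rate correction.

    Per pair: P and Q are the observed transition/transversion proportions,
    the GC content is averaged over both sequences at the compared sites,
    and ``alpha`` is the Gamma shape (``None`` or ``inf`` = no correction).
    Saturated pairs (non-positive log/power arguments) yield NaN.
    """
    if alpha is not None and not math.isinf(alpha) and alpha <= 0:
        raise ValueError("gamma shape must be positive")
    mat = aln.matrix
    if missing == "complete":
        keep = complete_columns(mat)
        mat = mat[:, keep]
    elif missing != "pairwise":
        raise ValueError("missing must be 'complete' or 'pairwise'")
    n = aln.n
    d = np.zeros((n, n))
    is_missing = (mat == _CODE["N"]) | (mat == _CODE["-"])
    purine = (mat == _CODE["A"]) | (mat == _CODE["G"])
    gc_base = (mat == _CODE["G"]) | (mat == _CODE["C"])
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(is_missing[i] | is_missing[j])
            L = int(ok.sum())
            if L == 0:
                d[i, j] = d[j, i] = math.nan
                continue
            diff = (mat[i] != mat[j]) & ok
            ts = diff & (purine[i] == purine[j])
            p = float(ts.sum()) / L
            q = float((diff & ~ts).sum()) / L
            gc = float(gc_base[i, ok].sum() + gc_base[j, ok].sum()) / (2 * L)
            val = _t92_pair(p, q, gc, alpha)
            d[i, j] = d[j, i] = val
    return DistanceMatrix(list(aln.labels), d, "t92_gamma")


def minimum_spanning_tree(
    dist: DistanceMatrix, freqs: np.ndarray | None = None
) -> list[tuple[str, str, float]]:
    """Minimum spanning tree over the complete haplotype graph.

    Ties are broken deterministically by (distance, lexicographic label
    pair).  Returns the edge list; node sizes are the supplied haplotype
    frequencies (attached to the result as is conventional for network
    figures, but returned separately by the caller).
    """
    if np.isnan(dist.matrix).any():
        raise ValueError("undefined distances present; supply a fallback distance")
    labels = dist.labels
    edges = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = sorted((labels[i], labels[j]))
            edges.append((float(dist.matrix[i, j]), a, b))
    edges.sort()
    g = nx.Graph()
    g.add_nodes_from(labels)
    if freqs is not None:
        for lab, f in zip(labels, np.asarray(freqs)):
            g.nodes[lab]["size"] = int(f)
    for w, a, b in edges:
        g.add_edge(a, b, weight=w)
    mst = nx.minimum_spanning_tree(g, algorithm="kruskal")
    out = sorted((min(a, b), max(a, b)) for a, b in mst.edges)
    return [(a, b, float(dist.matrix[labels.index(a), labels.index(b)])) for a, b in out]
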