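"""Per-layer diversity statistics and the ABC summary-statistic vector.

For each time layer of a temporal alignment: sample size n, haplotype count
h, segregating sites S, haplotype diversity Hd (with Nei's standard error),
mean pairwise differences k, nucleotide diversity pi = k / L_eff (with a
no-recombination coalescent standard error), Tajima's D and Fu's Fs.

Missing data: the default ``complete_deletion`` policy removes every column
containing an N or a gap from the whole alignment before any statistic is
computed, so all layers see the same effective sites (DnaSP-style default).
A ``pairwise`` policy keeps all columns and counts differences per pair over
their jointly determined sites.

Fu's Fs is evaluated exactly through the Ewens sampling formula with
arbitrary-precision unsigned Stirling numbers of the first kind, so the
deep tail (e.g. 36 haplotypes among 39 samples) does not underflow.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TemporalAlignment",
    "LayerSummaryStats",
    "effective_columns",
    "segregating_sites",
    "mean_pairwise_differences",
    "nucleotide_diversity",
    "haplotype_stats",
    "tajimas_d",
    "unsigned_stirling_first",
    "fus_fs",
    "layer_stats",
    "abc_feature_vector",
    "features_from_variants",
    "fold_change_report",
    "FEATURES_PER_LAYER",
]

FEATURES_PER_LAYER = ("h", "S", "k", "D")

_MISSING = frozenset(b"N-")


@dataclass
class TemporalAlignment:
    """Aligned sequences with a time-layer label and age per sequence.

    ``matrix`` is an (n, L) byte array over {A,C,G,T,N,-}; ``ages`` maps
    layer label to age in generations before present.
    """

    matrix: np.ndarray
    ids: list[str]
    layers: list[str]
    ages: dict[str, float]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="S1")
        if self.matrix.ndim != 2:
            raise ValueError("alignment matrix must be 2-D (sequences x sites)")
        n = self.matrix.shape[0]
        if not (len(self.ids) == len(self.layers) == n):
            raise ValueError("ids/layers must match the number of sequences")
        missing = set(self.layers) - set(self.ages)
        if missing:
            raise ValueError(f"no age given for layer(s): {sorted(missing)}")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def layers_by_age(self) -> list[str]:
        """Layer labels in increasing age order (youngest first)."""
        present = dict.fromkeys(self.layers)
        return sorted(present, key=lambda l: self.ages[l])

    def layer_rows(self, layer: str) -> np.ndarray:
        return np.array([i for i, l in enumerate(self.layers) if l == layer], dtype=np.intp)

    def subset(self, rows: np.ndarray) -> "TemporalAlignment":
        return TemporalAlignment(
            matrix=self.matrix[rows],
            ids=[self.ids[i] for i in rows],
            layers=[self.layers[i] for i in rows],
            ages=self.ages,
        )

    @classmethod
    def from_simulation(cls, sim) -> "TemporalAlignment":
        return cls(matrix=sim.matrix, ids=list(sim.ids), layers=list(sim.layers), ages=dict(sim.ages))


@dataclass
class LayerSummaryStats:
    n: int
    h: int
    S: int
    Hd: float
    Hd_se: float
    pi: float
    pi_se: float
    k: float
    D: float | None
    Fs: float | None
    L_eff: int

    def as_row(self) -> dict:
        return {
            "n": self.n,
            "h": self.h,
            "S": self.S,
            "Hd": self.Hd,
            "Hd_SE": self.Hd_se,
            "pi": self.pi,
            "pi_SE": self.pi_se,
            "k": self.k,
            "D": self.D,
            "Fs": self.Fs,
            "L_eff": self.L_eff,
        }


def effective_columns(alignment: TemporalAlignment, policy: str = "complete_deletion") -> np.ndarray:
    """Column indices retained under the missing-data policy."""
    if policy == "pairwise":
        return np.arange(alignment.length, dtype=np.intp)
    if policy != "complete_deletion":
        raise ValueError(f"unknown missing-data policy {policy!r}")
    mat = alignment.matrix
    bad = (mat == b"N") | (mat == b"-")
    keep = np.flatnonzero(~bad.any(axis=0))
    if keep.size == 0:
        raise ValueError("no alignment columns survive complete deletion")
    return keep.astype(np.intp)


def _clean_matrix(alignment: TemporalAlignment, policy: str) -> np.ndarray:
    return alignment.matrix[:, effective_columns(alignment, policy)]


def segregating_sites(alignment: TemporalAlignment, policy: str = "complete_deletion") -> int:
    """Number of effective columns with >= 2 distinct (determined) bases."""
    if alignment.n < 2:
        raise ValueError("segregating sites need >= 2 sequences")
    mat = alignment.matrix[:, effective_columns(alignment, policy)]
    S = 0
    for col in mat.T:
        bases = {b for b in col.tobytes() if b not in _MISSING}
        if len(bases) >= 2:
            S += 1
    return S


def _pair_difference_total(mat: np.ndarray) -> float:
    """Sum over unordered pairs of their difference counts (no missing data).

    Uses the per-column allele-count identity: the number of differing pairs
    at one column is (n^2 - sum_b c_b^2)/2.
    """
    n = mat.shape[0]
    total = 0.0
    view = mat.view(np.uint8)
    for col in view.T:
        counts = np.bincount(col)
        total += (n * n - float((counts.astype(np.float64) ** 2).sum())) / 2.0
    return total


def mean_pairwise_differences(
    alignment: TemporalAlignment, policy: str = "complete_deletion"
) -> float:
    """Average number of differing sites over all n(n-1)/2 sequence pairs."""
    n = alignment.n
    if n < 2:
        raise ValueError("pairwise differences need >= 2 sequences")
    n_pairs = n * (n - 1) / 2
    if policy == "complete_deletion":
        mat = _clean_matrix(alignment, policy)
        return _pair_difference_total(mat) / n_pairs
    # pairwise policy: per column, count differing pairs among determined bases
    total = 0.0
    for col in alignment.matrix.T:
        col_b = col.tobytes()
        counts: dict[int, int] = {}
        m = 0
        for b in col_b:
            if b not in _MISSING:
                counts[b] = counts.get(b, 0) + 1
                m += 1
        total += (m * m - sum(c * c for c in counts.values())) / 2.0
    return total / n_pairs


def nucleotide_diversity(
    alignment: TemporalAlignment, policy: str = "complete_deletion"
) -> tuple[float, float]:
    """(pi, k): per-site nucleotide diversity and mean pairwise differences,
    with pi = k / L_eff."""
    k = mean_pairwise_differences(alignment, policy)
    L_eff = effective_columns(alignment, policy).size
    return k / L_eff, k


def _haplotype_counts(mat: np.ndarray) -> np.ndarray:
    _, counts = np.unique(mat, axis=0, return_counts=True)
    return counts


def haplotype_stats(
    alignment: TemporalAlignment, policy: str = "complete_deletion"
) -> tuple[int, float, float]:
    """(h, Hd, SE(Hd)) over effective columns.

    Hd = n (1 - sum p_i^2) / (n - 1); the sampling variance is Nei's (1987)
    standard formula
        V = 2/(n(n-1)) * [ 2(n-2) (sum p^3 - (sum p^2)^2) + sum p^2 - (sum p^2)^2 ].
    """
    n = alignment.n
    if n < 2:
        raise ValueError("haplotype diversity needs >= 2 sequences")
    counts = _haplotype_counts(_clean_matrix(alignment, policy))
    h = int(counts.size)
    p = counts / n
    sp2 = float((p**2).sum())
    sp3 = float((p**3).sum())
    hd = n * (1.0 - sp2) / (n - 1)
    var = 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (sp3 - sp2**2) + sp2 - sp2**2)
    return h, hd, math.sqrt(max(var, 0.0))


def _tajima_constants(n: int) -> tuple[float, ...]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, b1, b2, e1, e2


def tajimas_d(n: int, S: int, k: float) -> float | None:
    """Tajima's D from sample size, segregating sites and mean pairwise
    differences; ``None`` when undefined (S = 0)."""
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    if S < 0:
        raise ValueError("S must be >= 0")
    if S == 0:
        return None
    a1, _, _, e1, e2 = _tajima_constants(n)
    return (k - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


@lru_cache(maxsize=None)
def unsigned_stirling_first(n: int) -> tuple[int, ...]:
    """Row of unsigned Stirling numbers of the first kind |s(n, j)|, j=0..n,
    as exact integers via |s(n,j)| = |s(n-1,j-1)| + (n-1)|s(n-1,j)|."""
    if n < 1:
        raise ValueError("n must be >= 1")
    row = [1]
    for m in range(1, n + 1):
        prev = row
        row = [0] * (m + 1)
        for j in range(1, m + 1):
            row[j] = prev[j - 1] + (m - 1) * (prev[j] if j < m else 0)
    return tuple(row)


def _ewens_tail(n: int, h: int, theta: Fraction) -> Fraction:
    """P(number of haplotypes >= h) under the Ewens sampling formula."""
    s = unsigned_stirling_first(n)
    rising = Fraction(1)
    for i in range(n):
        rising *= theta + i
    num = sum(s[j] * theta**j for j in range(h, n + 1))
    return num / rising


def fus_fs(n: int, h: int, k: float) -> float | None:
    """Fu's Fs: log-odds of observing at least h haplotypes under neutrality.

    With theta set to the layer's mean pairwise differences k,
    S' = P(K >= h | theta) via the Ewens sampling formula and
    Fs = ln(S' / (1 - S')).  Returns ``+inf`` for h = 1 (S' = 1) and
    ``None`` for k <= 0 (theta undefined).
    """
    if n < 2:
        raise ValueError("Fu's Fs needs n >= 2")
    if not 1 <= h <= n:
        raise ValueError("haplotype count must satisfy 1 <= h <= n")
    if k <= 0:
        return None
    if h == 1:
        return math.inf
    sp = _ewens_tail(n, h, Fraction(k))
    if sp >= 1:  # pragma: no cover - only reachable via h=1
        return math.inf
    # exact rational -> log via integer arithmetic-safe float conversion
    ratio = sp / (1 - sp)
    return _log_fraction(ratio)


def _log_fraction(x: Fraction) -> float:
    num, den = x.numerator, x.denominator
    return _log_int(num) - _log_int(den)


def _log_int(v: int) -> float:
    if v <= 0:
        raise ValueError("log of non-positive integer")
    bits = v.bit_length()
    if bits <= 900:
        return math.log(v)
    shift = bits - 900
    return math.log(v >> shift) + shift * math.log(2.0)


def _fus_fs_float(n: int, h: int, k: float) -> float:
    """Floating log-space evaluation of Fs (cross-check for the exact path)."""
    from scipy.special import logsumexp

    s = unsigned_stirling_first(n)
    log_s = np.array([_log_int(v) if v > 0 else -np.inf for v in s])
    logs_theta = math.log(k)
    log_terms = log_s + np.arange(n + 1) * logs_theta
    log_rising = float(np.sum(np.log(k + np.arange(n))))
    log_tail = float(logsumexp(log_terms[h:])) - log_rising
    # log(S'/(1-S')) computed stably
    if log_tail >= 0:
        return math.inf
    return log_tail - math.log1p(-math.exp(log_tail))


def layer_stats(
    alignment: TemporalAlignment, policy: str = "complete_deletion", strict: bool = True
) -> dict[str, LayerSummaryStats]:
    """All per-layer summary statistics, keyed by layer label.

    The missing-data policy is applied once to the whole alignment so all
    layers share the same effective columns.  In strict mode a layer with
    fewer than 2 sequences raises; otherwise it is skipped.
    """
    keep = effective_columns(alignment, policy)
    out: dict[str, LayerSummaryStats] = {}
    for layer in alignment.layers_by_age():
        rows = alignment.layer_rows(layer)
        if rows.size < 2:
            if strict:
                raise ValueError(f"layer {layer!r} has fewer than 2 sequences")
            continue
        sub = alignment.matrix[np.ix_(rows, keep)]
        sub_aln = TemporalAlignment(
            matrix=sub,
            ids=[alignment.ids[i] for i in rows],
            layers=[layer] * rows.size,
            ages=alignment.ages,
        )
        n = rows.size
        L_eff = keep.size
        S = segregating_sites(sub_aln, policy="pairwise")  # columns already clean
        k = mean_pairwise_differences(sub_aln, policy="complete_deletion")
        pi = k / L_eff
        h, hd, hd_se = haplotype_stats(sub_aln, policy="pairwise")
        _, b1, b2, _, _ = _tajima_constants(n)
        pi_var = b1 * pi / L_eff + b2 * pi**2
        D = tajimas_d(n, S, k) if n >= 4 else None
        Fs = fus_fs(n, h, k)
        out[layer] = LayerSummaryStats(
            n=n, h=h, S=S, Hd=hd, Hd_se=hd_se, pi=pi, pi_se=math.sqrt(max(pi_var, 0.0)),
            k=k, D=D, Fs=Fs, L_eff=L_eff,
        )
    return out


def _features_one_layer(n: int, h: int, S: int, k: float) -> list[float]:
    if S == 0 or n < 4:
        D = 0.0
        if S > 0:
            logger.warning("Tajima's D undefined for layer (n=%d); encoded as 0", n)
    else:
        d = tajimas_d(n, S, k)
        if d is None:
            logger.warning("Tajima's D undefined (S=0); encoded as 0")
            D = 0.0
        else:
            D = d
    return [float(h), float(S), float(k), D]


def abc_feature_vector(
    alignment: TemporalAlignment, policy: str = "complete_deletion"
) -> np.ndarray:
    """Ordered ABC summary vector: (h, S, k, D) per layer, layers in
    increasing age order.  An undefined D (monomorphic layer) is encoded as
    0 with a logged warning so the vector is always complete."""
    stats = layer_stats(alignment, policy=policy, strict=True)
    feats: list[float] = []
    for layer in alignment.layers_by_age():
        st = stats[layer]
        feats.extend(_features_one_layer(st.n, st.h, st.S, st.k))
    return np.asarray(feats)


def features_from_variants(derived: np.ndarray, tip_layers, ages: dict[str, float]) -> np.ndarray:
    """ABC feature vector straight from an infinite-sites incidence matrix.

    ``derived`` is the (n, n_mutations) boolean matrix from
    :func:`mitodem.coalsim.simulate_variants`; no missing data.  Equivalent
    to building full sequences and calling :func:`abc_feature_vector`, but
    much faster for reference-table construction.
    """
    tip_layers = list(tip_layers)
    order = sorted(dict.fromkeys(tip_layers), key=lambda l: ages[l])
    feats: list[float] = []
    for layer in order:
        rows = np.array([i for i, l in enumerate(tip_layers) if l == layer], dtype=np.intp)
        nl = rows.size
        if nl < 2:
            raise ValueError(f"layer {layer!r} has fewer than 2 sequences")
        sub = derived[rows]
        c = sub.sum(axis=0)
        poly = (c > 0) & (c < nl)
        S = int(poly.sum())
        n_pairs = nl * (nl - 1) / 2
        cp = c[poly].astype(np.float64)
        k = float((cp * (nl - cp)).sum() / n_pairs)
        if S:
            segs = np.packbits(sub[:, poly], axis=1)
            h = len({row.tobytes() for row in segs})
        else:
            h = 1
        feats.extend(_features_one_layer(nl, h, S, k))
    return np.asarray(feats)


def fold_change_report(
    hist_stats: LayerSummaryStats, mod_stats: LayerSummaryStats
) -> tuple[float, float]:
    """(Hd ratio, pi ratio) of the older layer over the younger layer — the
    'x-fold diversity loss' report."""
    ratios = []
    for a, b, name in (
        (hist_stats.Hd, mod_stats.Hd, "Hd"),
        (hist_stats.pi, mod_stats.pi, "pi"),
    ):
        if b == 0:
            warnings.warn(f"modern {name} is zero; fold change reported as inf")
            ratios.append(math.inf)
        else:
            ratios.append(a / b)
    return tuple(ratios)  # type: ignore[return-value]
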