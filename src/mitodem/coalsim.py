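"""Serial-sample (heterochronous) coalescent simulation with mutations.

Simulates binary genealogies of haploid lineages sampled at different ages
under a piecewise-constant size history, then drops mutations on branches:
Poisson(mu * L * branch length) per branch, under either an infinite-sites
model (default; every mutation hits a fresh site) or a finite-sites
Jukes-Cantor model.

Lineages become "active" backwards in time at their sampling age; while k
lineages are active within an epoch of haploid size N the waiting time to
the next coalescence is Exponential with rate k(k-1)/(2N), truncated at
epoch boundaries and at lineage-activation times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .demography import DemographicScenario

__all__ = [
    "SampleConfig",
    "Genealogy",
    "SimAlignment",
    "SiteExhaustionError",
    "default_sample_config",
    "simulate_genealogy",
    "drop_mutations",
    "simulate_variants",
    "to_newick",
]

DEFAULT_LOCUS_LENGTH = 16_588

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class SiteExhaustionError(RuntimeError):
    """More infinite-sites mutations than available sites."""


@dataclass(frozen=True)
class SampleLayer:
    label: str
    count: int
    age: float  # generations before present

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("layer sample count must be >= 1")
        if self.age < 0:
            raise ValueError("layer age must be >= 0")


@dataclass
class SampleConfig:
    """Temporal sampling design: per-layer counts and ages, plus locus length."""

    layers: list[SampleLayer]
    locus_length: int = DEFAULT_LOCUS_LENGTH

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("need at least one sampling layer")
        if self.locus_length < 1:
            raise ValueError("locus length must be >= 1")
        self.layers = [l if isinstance(l, SampleLayer) else SampleLayer(*l) for l in self.layers]

    @property
    def n_total(self) -> int:
        return sum(l.count for l in self.layers)

    def tip_layers(self) -> list[str]:
        out: list[str] = []
        for layer in self.layers:
            out.extend([layer.label] * layer.count)
        return out

    def tip_ages(self) -> np.ndarray:
        return np.concatenate([np.full(l.count, l.age) for l in self.layers])

    def ages_by_layer(self) -> dict[str, float]:
        return {l.label: l.age for l in self.layers}


def default_sample_config(
    n_modern: int = 79,
    n_historical: int = 39,
    age_historical: float = 5.0,
    locus_length: int = DEFAULT_LOCUS_LENGTH,
) -> SampleConfig:
    """The study-shaped design: 79 modern samples at age 0 and 39 historical
    museum samples at ~5 generations before present, one 16,588 bp locus."""
    return SampleConfig(
        layers=[
            SampleLayer("modern", n_modern, 0.0),
            SampleLayer("historical", n_historical, age_historical),
        ],
        locus_length=locus_length,
    )


@dataclass
class Genealogy:
    """Rooted binary tree over serially sampled tips.

    Nodes 0..n-1 are tips (at their sampling ages), nodes n..2n-2 internal.
    ``parent[root] == -1``.  All times are generations before present.
    """

    n_tips: int
    parent: np.ndarray  # (2n-1,) int
    time: np.ndarray  # (2n-1,) float
    tip_labels: list[str]
    tip_layers: list[str]

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1 if self.n_tips > 1 else 1

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    def children(self) -> list[list[int]]:
        kids: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes):
            p = self.parent[v]
            if p >= 0:
                kids[p].append(v)
        return kids

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (0 for the root)."""
        lens = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        lens[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return lens

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def tmrca(self) -> float:
        return float(self.time[self.root])

    def descendant_tips(self) -> list[np.ndarray]:
        """Tip index sets below each node (postorder accumulation)."""
        kids = self.children()
        sets: list[list[int] | None] = [None] * self.n_nodes
        order = np.argsort(self.time, kind="stable")  # tips first (smallest times)
        for v in order:
            if not kids[v]:
                sets[v] = [v]
            else:
                acc: list[int] = []
                for c in kids[v]:
                    acc.extend(sets[c])  # type: ignore[arg-type]
                sets[v] = acc
        return [np.asarray(s, dtype=np.intp) for s in sets]  # type: ignore[arg-type]


@dataclass
class SimAlignment:
    """Simulated sequences: (n, L) byte matrix over {A,C,G,T} (N only ever
    added later by the missing-data injector)."""

    matrix: np.ndarray  # (n, L) dtype S1
    ids: list[str]
    layers: list[str]
    ages: dict[str, float]

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def sequences(self) -> list[str]:
        return [bytes(row).decode() for row in self.matrix]


def simulate_genealogy(
    scenario: DemographicScenario,
    sample_config: SampleConfig,
    rng: np.random.Generator,
) -> Genealogy:
    """Simulate one coalescent genealogy under ``scenario``."""
    ages = sample_config.tip_ages()
    layers = sample_config.tip_layers()
    n = len(ages)
    labels = [f"{layer}_{i}" for i, layer in enumerate(layers)]
    if n == 1:
        return Genealogy(
            n_tips=1,
            parent=np.array([-1]),
            time=np.array([float(ages[0])]),
            tip_labels=labels,
            tip_layers=layers,
        )

    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    time[:n] = ages

    order = np.argsort(ages, kind="stable")
    pending = list(order)  # tip indices by increasing age
    epoch_starts = [t for t, _ in scenario.epochs]

    active: list[int] = []
    t = float(ages[pending[0]])
    while pending and pending[0] is not None and float(ages[pending[0]]) <= t:
        active.append(int(pending.pop(0)))

    next_internal = n
    while next_internal < n_nodes:
        k = len(active)
        next_activation = float(ages[pending[0]]) if pending else np.inf
        if k < 2:
            # cannot coalesce; jump to the next sample activation
            t = next_activation
            while pending and float(ages[pending[0]]) <= t:
                active.append(int(pending.pop(0)))
            continue
        N = scenario.size_at(t)
        nxt_epoch = np.inf
        for es in epoch_starts:
            if es > t:
                nxt_epoch = es
                break
        bound = min(next_activation, nxt_epoch)
        wait = rng.exponential(2.0 * N / (k * (k - 1)))
        if t + wait < bound:
            t = t + wait
            i, j = rng.choice(k, size=2, replace=False)
            a, b = active[i], active[j]
            node = next_internal
            next_internal += 1
            parent[a] = node
            parent[b] = node
            time[node] = t
            # remove higher index first
            for idx in sorted((i, j), reverse=True):
                active.pop(idx)
            active.append(node)
        else:
            t = bound
            while pending and float(ages[pending[0]]) <= t:
                active.append(int(pending.pop(0)))

    return Genealogy(n_tips=n, parent=parent, time=time, tip_labels=labels, tip_layers=layers)


def _branch_mutation_counts(
    g: Genealogy, mu: float, locus_length: int, rng: np.random.Generator
) -> np.ndarray:
    if mu <= 0:
        raise ValueError("mutation rate must be > 0")
    lens = g.branch_lengths()
    return rng.poisson(mu * locus_length * lens)


def simulate_variants(
    scenario: DemographicScenario,
    sample_config: SampleConfig,
    mu: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[str]]:
    """Fast path: infinite-sites derived-allele incidence matrix.

    Returns ``(derived, tip_layers)`` where ``derived`` is a boolean
    (n_tips, n_mutations) matrix — entry True where the tip carries the
    derived allele of that mutation.  Column count equals the number of
    mutations placed on the genealogy (each at a distinct site).  Raises
    :class:`SiteExhaustionError` if more mutations arise than sites exist.
    """
    g = simulate_genealogy(scenario, sample_config, rng)
    counts = _branch_mutation_counts(g, mu, sample_config.locus_length, rng)
    total = int(counts.sum())
    if total > sample_config.locus_length:
        raise SiteExhaustionError(
            f"{total} mutations exceed {sample_config.locus_length} sites; "
            "use the jukes_cantor finite-sites model"
        )
    derived = np.zeros((g.n_tips, total), dtype=bool)
    if total:
        desc = g.descendant_tips()
        col = 0
        for v in np.flatnonzero(counts):
            m = int(counts[v])
            derived[desc[v], col : col + m] = True
            col += m
    return derived, g.tip_layers


def drop_mutations(
    genealogy: Genealogy,
    mu: float,
    locus_length: int,
    rng: np.random.Generator,
    model: str = "infinite_sites",
    ages: dict[str, float] | None = None,
) -> SimAlignment:
    """Drop mutations on ``genealogy`` and return full sequences.

    ``infinite_sites`` (default): each mutation occupies a fresh site; the
    ancestral sequence is all-A (only the variation pattern is meaningful)
    and each mutation's derived base is drawn uniformly from {C,G,T}.
    ``jukes_cantor``: uniform random ancestral sequence; each mutation picks
    a site uniformly with replacement and substitutes one of the three
    alternative bases; mutations are applied root-to-tip so repeat hits
    overwrite.
    """
    g = genealogy
    L = locus_length
    counts = _branch_mutation_counts(g, mu, L, rng)
    n = g.n_tips
    if ages is None:
        ages = {}
        for i, layer in enumerate(g.tip_layers):
            ages.setdefault(layer, float(g.time[i]))

    if model == "infinite_sites":
        total = int(counts.sum())
        if total > L:
            raise SiteExhaustionError(
                f"{total} mutations exceed {L} sites; use the jukes_cantor model"
            )
        matrix = np.full((n, L), b"A", dtype="S1")
        if total:
            sites = rng.choice(L, size=total, replace=False)
            alt = _BASES[1:][rng.integers(0, 3, size=total)]
            desc = g.descendant_tips()
            col = 0
            for v in np.flatnonzero(counts):
                m = int(counts[v])
                for s_idx in range(col, col + m):
                    matrix[desc[v], sites[s_idx]] = alt[s_idx]
                col += m
    elif model == "jukes_cantor":
        seqs = np.empty((g.n_nodes, L), dtype=np.uint8)
        kids = g.children()
        root = g.root
        seqs[root] = rng.integers(0, 4, size=L)
        # preorder: parents before children, root has the largest time
        order = np.argsort(-g.time, kind="stable")
        for v in order:
            if v == root:
                continue
            seq = seqs[g.parent[v]].copy()
            m = int(counts[v])
            if m:
                sites = rng.integers(0, L, size=m)
                shift = rng.integers(1, 4, size=m)
                for s, d in zip(sites, shift):
                    seq[s] = (seq[s] + d) % 4
            seqs[v] = seq
        matrix = _BASES[seqs[:n]]
    else:
        raise ValueError(f"unknown mutation model {model!r}")

    return SimAlignment(
        matrix=matrix, ids=list(g.tip_labels), layers=list(g.tip_layers), ages=ages
    )


def to_newick(genealogy: Genealogy, precision: int = 17) -> str:
    """Newick string with branch lengths in generations.

    A single tip renders as ``"t0;"``.  Parses back (e.g. with dendropy) to
    the same topology and node times.
    """
    g = genealogy
    if g.n_tips == 1:
        return f"{g.tip_labels[0]};"
    kids = g.children()
    lens = g.branch_lengths()

    def fmt(x: float) -> str:
        return f"{x:.{precision}g}"

    # iterative postorder to avoid recursion limits on caterpillar trees
    out: dict[int, str] = {}
    stack: list[tuple[int, bool]] = [(g.root, False)]
    while stack:
        v, done = stack.pop()
        if not kids[v]:
            out[v] = g.tip_labels[v]
        elif not done:
            stack.append((v, True))
            for c in kids[v]:
                stack.append((c, False))
        else:
            out[v] = "(" + ",".join(f"{out[c]}:{fmt(lens[c])}" for c in kids[v]) + ")"
    return out[g.root] + ";"
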