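"""Scale-free network generation with tunable clustering.

Networks grow by preferential attachment with triad formation: each new node
attaches its first edge preferentially (probability proportional to degree) and
each of its remaining ``m - 1`` edges is, with probability ``p_triad``, a triad
step — an edge to a not-yet-connected neighbour of the most recent
preferential-attachment target — otherwise another preferential-attachment
step.  Triad formation closes triangles, so the mean local clustering
coefficient rises monotonically with ``p_triad`` while the degree distribution
stays skewed.  Every new node contributes exactly ``m`` distinct edges, so a
network with ``n`` nodes always has exactly ``(n - m) * m`` edges and is
connected by construction.

Networks are classified by density and mean clustering into Low/Medium/High
classes (Low = [0, 0.1], Medium = (0.1, 0.2], High = (0.2, 1]), giving six
realisable category acronyms (LD-LC ... HD-HC); the three remaining
combinations (MD-LC, HD-LC, HD-MC) cannot be realised as connected networks in
this family and are rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from . import community as _community
from ._fast import distance_stats, mean_clustering
from .errors import CalibrationError, CategoryError, ParameterError

__all__ = [
    "GenerationParams",
    "NetworkCategory",
    "StructuralSummary",
    "SIZE_NODES",
    "VALID_ACRONYMS",
    "EXCLUDED_ACRONYMS",
    "DEFAULT_TARGETS",
    "grow_network",
    "choose_m_for_density",
    "calibrate_triad_probability",
    "generate_category_batch",
    "largest_connected_component",
    "structural_summary",
    "categorize",
]

#: Number of nodes per size class.
SIZE_NODES = {"small": 200, "medium": 1000, "large": 2000}

#: Half-open class boundaries shared by density and clustering.
_CLASS_EDGES = ((0.1, "L"), (0.2, "M"), (1.0, "H"))
_CLASS_NAMES = {"L": "Low", "M": "Medium", "H": "High"}

#: The six acronyms realisable as connected scale-free networks.
VALID_ACRONYMS = ("LD-LC", "LD-MC", "LD-HC", "MD-MC", "MD-HC", "HD-HC")

#: Density/clustering combinations that cannot be realised (too dense to stay
#: weakly clustered): a connected graph in the Medium/High density range drags
#: the clustering coefficient above the lower classes.
EXCLUDED_ACRONYMS = ("MD-LC", "HD-LC", "HD-MC")

#: Default (density, clustering) calibration targets per (acronym, size class).
#: These are the achieved batch means of the reference generated networks for
#: each category and size, used as de facto targets; callers may override both.
DEFAULT_TARGETS: dict[tuple[str, str], tuple[float, float]] = {
    ("LD-LC", "small"): (0.03, 0.10),
    ("LD-MC", "small"): (0.08, 0.16),
    ("LD-HC", "small"): (0.02, 0.40),
    ("MD-MC", "small"): (0.11, 0.20),
    ("MD-HC", "small"): (0.18, 0.31),
    ("HD-HC", "small"): (0.46, 0.55),
    ("LD-LC", "medium"): (0.04, 0.10),
    ("LD-MC", "medium"): (0.04, 0.15),
    ("LD-HC", "medium"): (0.08, 0.43),
    ("MD-MC", "medium"): (0.11, 0.19),
    ("MD-HC", "medium"): (0.15, 0.36),
    ("HD-HC", "medium"): (0.36, 0.43),
    ("LD-LC", "large"): (0.03, 0.08),
    ("LD-MC", "large"): (0.05, 0.14),
    ("LD-HC", "large"): (0.08, 0.29),
    ("MD-MC", "large"): (0.11, 0.19),
    ("MD-HC", "large"): (0.18, 0.34),
    ("HD-HC", "large"): (0.25, 0.35),
}


@dataclass(frozen=True)
class GenerationParams:
    """Parameters of the growth model.

    n: final node count; m: edges contributed by every new node (1 <= m < n);
    p_triad: probability that a non-first edge is a triad-formation step;
    rng_seed: seed of the generation RNG.
    """

    n: int
    m: int
    p_triad: float
    rng_seed: int = 0

    def __post_init__(self):
        if self.n < 2 or self.m < 1 or self.m >= self.n:
            raise ParameterError(f"need 1 <= m < n, got n={self.n}, m={self.m}")
        if not 0.0 <= self.p_triad <= 1.0:
            raise ParameterError(f"p_triad must be in [0, 1], got {self.p_triad}")


@dataclass(frozen=True)
class NetworkCategory:
    """Density/clustering classification of a network."""

    density_class: str
    clustering_class: str
    size_class: str | None = None
    acronym: str = field(init=False, default="")
    out_of_model: bool = field(init=False, default=False)

    def __post_init__(self):
        d = self.density_class[0].upper()
        c = self.clustering_class[0].upper()
        acronym = f"{d}D-{c}C"
        object.__setattr__(self, "acronym", acronym)
        object.__setattr__(self, "out_of_model", acronym in EXCLUDED_ACRONYMS)


@dataclass(frozen=True)
class StructuralSummary:
    """Whole-graph structural statistics (path statistics on the LCC)."""

    n_nodes: int
    n_edges: int
    density: float
    mean_clustering: float
    mean_degree: float
    n_communities: int
    modularity: float
    diameter: int
    mean_shortest_path: float
    assortativity: float
    connected: bool

    def as_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "density": self.density,
            "mean_clustering": self.mean_clustering,
            "mean_degree": self.mean_degree,
            "n_communities": self.n_communities,
            "modularity": self.modularity,
            "diameter": self.diameter,
            "mean_shortest_path": self.mean_shortest_path,
            "assortativity": self.assortativity,
            "connected": self.connected,
        }


def grow_network(params: GenerationParams) -> nx.Graph:
    """Grow a scale-free network with tunable clustering.

    Starts from ``m`` isolated founders; the first growing node attaches to all
    of them, and every later node adds exactly ``m`` distinct edges following
    the preferential-attachment / triad-formation rule described in the module
    docstring.  When a triad step finds no eligible neighbour it falls back to
    preferential attachment, so the edge count ``(n - m) * m`` is exact.
    """
    n, m, p_triad = params.n, params.m, params.p_triad
    rng = np.random.default_rng(params.rng_seed)

    adj: list[set[int]] = [set() for _ in range(n)]
    # Degree-proportional sampling via the repeated-endpoints list.
    repeated: list[int] = []

    def add_edge(u: int, v: int) -> None:
        adj[u].add(v)
        adj[v].add(u)
        repeated.append(u)
        repeated.append(v)

    def pa_target(new: int) -> int:
        # Rejection sampling against duplicates; the bounded fallback keeps the
        # worst (very dense) case from degenerating.
        for _ in range(200):
            t = repeated[rng.integers(len(repeated))]
            if t != new and t not in adj[new]:
                return int(t)
        eligible = [v for v in range(new) if v not in adj[new]]
        return int(eligible[rng.integers(len(eligible))])

    for founder in range(m):
        add_edge(m, founder)
    for new in range(m + 1, n):
        anchor = pa_target(new)
        add_edge(new, anchor)
        for _ in range(m - 1):
            if rng.random() < p_triad:
                candidates = [w for w in adj[anchor] if w != new and w not in adj[new]]
                if candidates:
                    add_edge(new, int(candidates[rng.integers(len(candidates))]))
                    continue
            anchor = pa_target(new)
            add_edge(new, anchor)

    g = nx.Graph(name=f"growth(n={n},m={m},p={p_triad:g})")
    g.add_nodes_from(range(n))
    g.add_edges_from((u, v) for u in range(n) for v in adj[u] if u < v)
    return g


def choose_m_for_density(n: int, target_density: float) -> int:
    """Integer m whose exact edge count (n-m)*m best matches a density target.

    Minimises ``|(n - m) * m - target_density * n * (n - 1) / 2|`` over
    ``1 <= m < n``; ties resolve to the smaller m.  Targets above the family's
    maximum density simply return the edge-maximising m ≈ n/2.
    """
    if not 0.0 < target_density < 1.0:
        raise ParameterError(f"target_density must be in (0, 1), got {target_density}")
    if n < 2:
        raise ParameterError("need n >= 2")
    target_edges = target_density * n * (n - 1) / 2.0
    return min(range(1, n), key=lambda m: (abs((n - m) * m - target_edges), m))


def calibrate_triad_probability(
    n: int,
    m: int,
    target_clustering: float,
    tolerance: float = 0.02,
    reps: int = 3,
    rng_seed: int = 0,
) -> float:
    """Find p_triad whose mean clustering over ``reps`` realisations hits a target.

    Checks the achievable bracket [C(p=0), C(p=1)] first and raises
    :class:`CalibrationError` when the target lies outside it (the model's
    clustering ceiling falls with m, so not every target is reachable at every
    density).  Inside the bracket, a stochastic bisection (fresh realisations
    per iterate, seeds derived from ``rng_seed``) stops once the mean clustering
    is within ``tolerance / 2`` of the target, leaving headroom so that fresh
    realisations at the returned value stay within ``tolerance``.
    """
    if not 0.0 < tolerance < 1.0:
        raise ParameterError("tolerance must be in (0, 1)")

    def mean_cc(p: float, block: int) -> float:
        vals = [
            mean_clustering(grow_network(GenerationParams(n, m, p, rng_seed=rng_seed + block + r)))
            for r in range(reps)
        ]
        return float(np.mean(vals))

    c_lo = mean_cc(0.0, 1_000)
    c_hi = mean_cc(1.0, 2_000)
    lo_bound, hi_bound = min(c_lo, c_hi), max(c_lo, c_hi)
    if not lo_bound - tolerance <= target_clustering <= hi_bound + tolerance:
        raise CalibrationError(target_clustering, (c_lo, c_hi))
    if abs(c_lo - target_clustering) <= tolerance / 2:
        return 0.0
    if abs(c_hi - target_clustering) <= tolerance / 2:
        return 1.0

    lo, hi = 0.0, 1.0
    increasing = c_hi >= c_lo
    for it in range(25):
        mid = (lo + hi) / 2.0
        c_mid = mean_cc(mid, 10_000 + it * reps)
        if abs(c_mid - target_clustering) <= tolerance / 2:
            return mid
        if (c_mid < target_clustering) == increasing:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def largest_connected_component(g: nx.Graph) -> nx.Graph:
    """Node-induced subgraph on the largest component (ties: smallest node id)."""
    if g.number_of_nodes() == 0:
        raise ParameterError("empty graph has no components")
    best = max(nx.connected_components(g), key=lambda c: (len(c), -min(c)))
    sub = g.subgraph(best).copy()
    sub.graph.update(g.graph)
    return sub


def categorize(
    density: float, clustering: float, size_class: str | None = None
) -> NetworkCategory:
    """Classify density/clustering into the Low/Medium/High category grid."""
    for name, x in (("density", density), ("clustering", clustering)):
        if not 0.0 <= x <= 1.0:
            raise CategoryError(f"{name} must be in [0, 1], got {x}")

    def cls(x: float) -> str:
        for edge, code in _CLASS_EDGES:
            if x <= edge:
                return _CLASS_NAMES[code]
        return "High"

    return NetworkCategory(cls(density), cls(clustering), size_class)


def class_range(class_name: str) -> tuple[float, float]:
    """(low, high] interval of a Low/Medium/High class (Low includes 0)."""
    return {"Low": (0.0, 0.1), "Medium": (0.1, 0.2), "High": (0.2, 1.0)}[class_name]


def _acronym_ranges(acronym: str) -> tuple[tuple[float, float], tuple[float, float]]:
    codes = {"L": "Low", "M": "Medium", "H": "High"}
    d, c = acronym.split("-")
    return class_range(codes[d[0]]), class_range(codes[c[0]])


def _in_range(x: float, rng_: tuple[float, float]) -> bool:
    lo, hi = rng_
    return (x >= 0.0 if lo == 0.0 else x > lo) and x <= hi


def generate_category_batch(
    acronym: str,
    size_class: str,
    count: int,
    rng_seed: int,
    density_target: float | None = None,
    clustering_target: float | None = None,
    tolerance: float = 0.02,
    reps: int = 3,
    max_tries: int = 50,
) -> list[nx.Graph]:
    """Generate ``count`` networks of one category and size class.

    m comes from the density target and p_triad from clustering calibration
    (defaults per :data:`DEFAULT_TARGETS`).  Per-network seeds are
    ``rng_seed + index``; a realisation whose clustering falls outside the
    category's range is re-drawn with a displaced seed (bounded), so every
    returned network verifiably belongs to the requested category.
    """
    acronym = acronym.upper()
    if acronym in EXCLUDED_ACRONYMS:
        raise CategoryError(f"category {acronym} cannot be realised as a connected network")
    if acronym not in VALID_ACRONYMS:
        raise CategoryError(f"unknown category acronym {acronym!r}")
    size_class = size_class.lower()
    if size_class not in SIZE_NODES:
        raise CategoryError(f"unknown size class {size_class!r}")
    if count < 1:
        raise ParameterError("count must be >= 1")

    default_d, default_c = DEFAULT_TARGETS[(acronym, size_class)]
    density_target = default_d if density_target is None else density_target
    clustering_target = default_c if clustering_target is None else clustering_target

    n = SIZE_NODES[size_class]
    m = choose_m_for_density(n, density_target)
    p_triad = calibrate_triad_probability(
        n, m, clustering_target, tolerance=tolerance, reps=reps, rng_seed=rng_seed + 900_000
    )

    d_range, c_range = _acronym_ranges(acronym)
    batch = []
    for i in range(count):
        for attempt in range(max_tries):
            seed = rng_seed + i + attempt * 7_000_003
            g = grow_network(GenerationParams(n, m, p_triad, rng_seed=seed))
            density = 2.0 * g.number_of_edges() / (n * (n - 1))
            if _in_range(density, d_range) and _in_range(mean_clustering(g), c_range):
                g.graph["category"] = acronym
                g.graph["size_class"] = size_class
                g.graph["rng_seed"] = seed
                batch.append(g)
                break
        else:
            raise CalibrationError(clustering_target, c_range)
    return batch


def structural_summary(g: nx.Graph, rng_seed: int = 0) -> StructuralSummary:
    """Structural statistics; path statistics fall back to the LCC if needed."""
    n = g.number_of_nodes()
    ne = g.number_of_edges()
    if n == 0:
        raise ParameterError("empty graph")
    density = 0.0 if n < 2 else 2.0 * ne / (n * (n - 1))
    mean_degree = 2.0 * ne / n
    connected = nx.is_connected(g)
    lcc = g if connected else largest_connected_component(g)
    diameter, mean_path = distance_stats(lcc)
    partition = _community.detect_communities(g, rng_seed=rng_seed)
    try:
        with np.errstate(invalid="ignore"):
            assortativity = float(nx.degree_assortativity_coefficient(g))
        if math.isnan(assortativity):  # regular graphs: zero degree variance
            assortativity = 0.0
    except (ZeroDivisionError, ValueError):
        assortativity = 0.0
    return StructuralSummary(
        n_nodes=n,
        n_edges=ne,
        density=density,
        mean_clustering=mean_clustering(g),
        mean_degree=mean_degree,
        n_communities=partition.n_communities,
        modularity=partition.modularity,
        diameter=diameter,
        mean_shortest_path=mean_path,
        assortativity=assortativity,
        connected=connected,
    )
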