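"""PPI module detection: MCODE, DIAMOnD, Clique Sum, Correlation Clique.

Condition-associated genes tend to co-localize in the protein-protein
interaction (PPI) network and form modules of functionally related genes.
This module ingests a STRING-dialect edge list, tests seed-gene
co-localization by a permutation test on the harmonic average shortest-path
distance, runs four module-detection algorithms seeded with the
differentially methylated genes, and combines them into a consensus module
(genes returned by at least ``min_methods`` of the four).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

METHOD_NAMES = ("mcode", "diamond", "clique_sum", "correlation_clique")


@dataclass
class PPINetwork:
    """Undirected scored interaction network after score thresholding."""

    graph: nx.Graph
    min_score: float

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class ModuleResult:
    method: str
    genes: set[str]
    scores: dict[str, float] = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seeds: set[str] = field(default_factory=set)


@dataclass
class ConsensusModule:
    genes: set[str]
    membership: pd.DataFrame  # genes x 4 boolean methods
    seed_origin: dict[str, bool] = field(default_factory=dict)
    direction: dict[str, str] = field(default_factory=dict)

    def provenance_split(self) -> tuple[int, int]:
        """(seed-origin genes, network-derived genes) in the consensus."""
        n_seed = sum(bool(self.seed_origin.get(g)) for g in self.genes)
        return n_seed, len(self.genes) - n_seed

    def to_frame(self) -> pd.DataFrame:
        df = self.membership.loc[sorted(self.genes)].copy()
        df["n_methods"] = df[list(METHOD_NAMES)].sum(axis=1)
        df["seed_origin"] = [bool(self.seed_origin.get(g)) for g in df.index]
        df["direction"] = [self.direction.get(g, "") for g in df.index]
        return df


@dataclass
class ColocalizationResult:
    d_obs: float
    null: np.ndarray
    p: float
    n_seeds: int

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null))

    def to_dict(self) -> dict:
        return {
            "d_observed": self.d_obs,
            "d_random_mean": self.null_mean,
            "p": self.p,
            "n_seeds": self.n_seeds,
            "n_perm": int(len(self.null)),
        }


class EdgeFileError(ValueError):
    """Malformed STRING-dialect edge file."""


def load_string_edges(
    path,
    min_score: float = 900,
    id_mapping: dict[str, str] | None = None,
) -> PPINetwork:
    """Read a STRING-dialect TSV (protein1, protein2, combined_score).

    Edges with combined score >= ``min_score`` are kept; duplicate pairs are
    collapsed keeping the maximum score; self-loops dropped.  An optional
    identifier mapping (e.g. protein -> gene symbol) is applied first.
    """
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    required = {"protein1", "protein2", "combined_score"}
    if not required.issubset(df.columns):
        raise EdgeFileError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    bad = df["combined_score"].isna() | df["protein1"].isna() | df["protein2"].isna()
    if bad.any():
        raise EdgeFileError(f"{path}: malformed row at line {int(np.where(bad)[0][0]) + 2}")
    if id_mapping:
        df["protein1"] = df["protein1"].map(lambda x: id_mapping.get(x, x))
        df["protein2"] = df["protein2"].map(lambda x: id_mapping.get(x, x))
    return build_network(
        list(zip(df["protein1"], df["protein2"], df["combined_score"])), min_score
    )


def build_network(edges, min_score: float = 900) -> PPINetwork:
    """Build a thresholded simple graph from (u, v, score) triples."""
    g = nx.Graph()
    for u, v, s in edges:
        if u == v or s < min_score:
            continue
        if g.has_edge(u, v):
            g[u][v]["score"] = max(g[u][v]["score"], s)
        else:
            g.add_edge(u, v, score=s)
    if g.number_of_edges() == 0:
        raise EdgeFileError(f"no edges at or above score {min_score}")
    return PPINetwork(graph=g, min_score=min_score)


# ---------------------------------------------------------------------------
# co-localization
# ---------------------------------------------------------------------------


def harmonic_average_distance(graph: nx.Graph, genes) -> float:
    """n_pairs / sum(1/d) over pairwise shortest-path lengths.

    Unreachable pairs contribute 0 to the reciprocal sum, so a fully
    disconnected seed set has infinite harmonic distance; a clique has H = 1.
    """
    genes = sorted(set(genes))
    if len(genes) < 2:
        raise ValueError("need at least 2 genes for a pairwise distance")
    recip = 0.0
    n_pairs = 0
    for i, u in enumerate(genes):
        lengths = nx.single_source_shortest_path_length(graph, u)
        for v in genes[i + 1 :]:
            n_pairs += 1
            d = lengths.get(v)
            if d is not None and d > 0:
                recip += 1.0 / d
    return np.inf if recip == 0 else n_pairs / recip


def colocalization_test(
    network: PPINetwork,
    seeds,
    n_perm: int = 1000,
    seed: int = 0,
) -> ColocalizationResult:
    """Permutation test: are the seed genes closer than random gene sets?

    The null samples uniformly random node sets of the same size; the
    p-value is (1 + #{null <= observed}) / (n_perm + 1) (plus-one rule, so
    p is never exactly 0).
    """
    g = network.graph
    mapped = sorted(set(seeds) & set(g.nodes))
    if len(mapped) < 2:
        missing = sorted(set(seeds) - set(g.nodes))
        raise ValueError(f"fewer than 2 seeds mapped to the network; unmapped: {missing}")
    # one BFS per node up front; the permutation null reuses the table
    nodes = sorted(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    dist = np.zeros((len(nodes), len(nodes)))
    for u in nodes:
        lengths = nx.single_source_shortest_path_length(g, u)
        for v, d in lengths.items():
            dist[index[u], index[v]] = d

    def _h(members) -> float:
        idx = [index[m] for m in members]
        sub = dist[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), 1)
        d = sub[iu]
        recip = np.sum(1.0 / d[d > 0])
        return np.inf if recip == 0 else len(d) / recip

    d_obs = _h(mapped)
    rng = np.random.default_rng(seed)
    node_arr = np.array(nodes)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = _h(rng.choice(node_arr, size=len(mapped), replace=False))
    p = (1 + int(np.sum(null <= d_obs))) / (n_perm + 1)
    return ColocalizationResult(d_obs=d_obs, null=null, p=p, n_seeds=len(mapped))


# ---------------------------------------------------------------------------
# MCODE
# ---------------------------------------------------------------------------


def mcode_vertex_weights(graph: nx.Graph) -> dict[str, float]:
    """Weight = max core number of the open neighbourhood times that k-core's density."""
    weights: dict[str, float] = {}
    for v in graph.nodes:
        nbrs = list(graph.neighbors(v))
        if len(nbrs) < 2:
            weights[v] = 0.0
            continue
        sub = graph.subgraph(nbrs)
        if sub.number_of_edges() == 0:
            weights[v] = 0.0
            continue
        core = nx.core_number(sub)
        kmax = max(core.values())
        top = sub.subgraph([n for n, c in core.items() if c == kmax])
        weights[v] = kmax * nx.density(top)
    return weights


def _haircut(graph: nx.Graph, members: set[str]) -> set[str]:
    """Iteratively strip singly-connected vertices (2-core of the complex)."""
    members = set(members)
    changed = True
    while changed and len(members) > 2:
        changed = False
        sub = graph.subgraph(members)
        drop = {n for n in members if sub.degree(n) < 2}
        if drop and drop != members:
            members -= drop
            changed = True
    return members


def run_mcode(
    network: PPINetwork,
    seeds,
    vwp: float = 0.2,
    min_complex_score: float = 0.0,
    haircut: bool = True,
) -> ModuleResult:
    """MCODE complex detection seeded by vertex weighting.

    Complexes are grown from the highest-weight unused vertex, admitting
    neighbours whose weight is at least (1 - vwp) times the complex seed
    vertex's weight; complexes are scored by density x size.  The returned
    module is the union of complexes passing the score cutoff and containing
    at least one seed gene.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    seeds = set(seeds)
    weights = mcode_vertex_weights(g)
    used: set[str] = set()
    complexes: list[tuple[set[str], float]] = []
    for v in sorted(g.nodes, key=lambda n: (-weights[n], n)):
        if v in used or weights[v] <= 0:
            continue
        threshold = (1.0 - vwp) * weights[v]
        members = {v}
        frontier = [v]
        while frontier:
            nxt = []
            for u in frontier:
                for w in g.neighbors(u):
                    if w not in members and w not in used and weights[w] >= threshold:
                        members.add(w)
                        nxt.append(w)
            frontier = nxt
        used |= members
        if haircut:
            members = _haircut(g, members)
        if len(members) < 2:
            continue
        sub = g.subgraph(members)
        score = nx.density(sub) * len(members)
        complexes.append((members, score))
    module: set[str] = set()
    scores: dict[str, float] = {}
    for members, score in complexes:
        if score >= min_complex_score and members & seeds:
            module |= members
            for m in members:
                scores[m] = max(scores.get(m, 0.0), score)
    return ModuleResult(
        method="mcode",
        genes=module,
        scores=scores,
        params={"vwp": vwp, "min_complex_score": min_complex_score, "haircut": haircut},
        seeds=seeds,
    )


# ---------------------------------------------------------------------------
# DIAMOnD
# ---------------------------------------------------------------------------


def diamond_pvalue(k: int, ks: int, n_nodes: int, n_members: int, alpha: float = 1.0) -> float:
    """Connectivity significance of a degree-k node with ks links to the module.

    Hypergeometric tail P(X >= ks) drawing k links from a universe of
    n_nodes with n_members successes.  ``alpha`` > 1 up-weights links to
    seed genes (seed links count alpha times, and the universe grows
    accordingly), as in the original algorithm.
    """
    if alpha != 1.0:
        raise NotImplementedError("seed weighting alpha != 1 is not supported")
    return float(stats.hypergeom.sf(ks - 1, n_nodes, n_members, k))


def run_diamond(
    network: PPINetwork,
    seeds,
    n_added: int = 200,
    alpha: float = 1.0,
) -> ModuleResult:
    """Iterative module growth by connectivity significance.

    Each round, every candidate adjacent to the current member set is scored
    by the hypergeometric tail probability of its member links; the most
    significant node joins.  Ties break by more member links, then lower
    degree, then lexicographic id.
    """
    g = network.graph
    members = set(seeds) & set(g.nodes)
    if not members:
        raise ValueError("no seed genes present in the network")
    if n_added < 1:
        raise ValueError("n_added must be >= 1")
    n_nodes = g.number_of_nodes()
    added: list[tuple[str, float]] = []
    for _ in range(n_added):
        candidates = {
            w for m in members for w in g.neighbors(m) if w not in members
        }
        if not candidates:
            break
        scored = []
        for w in sorted(candidates):
            k = g.degree(w)
            ks = sum(1 for u in g.neighbors(w) if u in members)
            p = diamond_pvalue(k, ks, n_nodes, len(members), alpha)
            scored.append((p, -ks, k, w))
        # p-values equal up to rounding are ties: resolve by more member
        # links, then lower degree, then id (keeps the ranking independent
        # of which hypergeometric evaluation route produced the p)
        pmin = min(s[0] for s in scored)
        tied = [s for s in scored if s[0] <= pmin * (1 + 1e-9) + 1e-300]
        _, _, w = min((s[1], s[2], s[3]) for s in tied)
        p = next(s[0] for s in scored if s[3] == w)
        members.add(w)
        added.append((w, p))
    ranks = {w: r + 1 for r, (w, _) in enumerate(added)}
    return ModuleResult(
        method="diamond",
        genes=members,
        scores={w: float(r) for w, r in ranks.items()},
        params={"n_added": n_added, "alpha": alpha, "p_sequence": [p for _, p in added]},
        seeds=set(seeds),
    )


# ---------------------------------------------------------------------------
# Clique Sum
# ---------------------------------------------------------------------------


def enumerate_maximal_cliques(graph: nx.Graph, max_cliques: int = 2_000_000) -> list[frozenset]:
    out = []
    for i, c in enumerate(nx.find_cliques(graph)):
        if i >= max_cliques:
            raise RuntimeError(
                "maximal-clique enumeration exceeded the budget; raise the score threshold"
            )
        out.append(frozenset(c))
    return out


def run_clique_sum(
    network: PPINetwork,
    seeds,
    min_clique_size: int = 3,
    alpha: float = 0.05,
    max_cliques: int = 2_000_000,
) -> ModuleResult:
    """Union of maximal cliques significantly enriched for seed genes.

    Each maximal clique of size >= ``min_clique_size`` gets a one-sided
    Fisher's exact test of clique-membership against seed-membership on the
    network node universe; cliques passing a Bonferroni-corrected ``alpha``
    (correction over the tested cliques) are kept.
    """
    g = network.graph
    seeds = set(seeds) & set(g.nodes)
    n = g.number_of_nodes()
    cliques = [
        c for c in enumerate_maximal_cliques(g, max_cliques) if len(c) >= min_clique_size
    ]
    kept: list[frozenset] = []
    scores: dict[str, float] = {}
    m = len(cliques)
    for c in cliques:
        a = len(c & seeds)
        if a == 0:
            continue
        b = len(c) - a
        cc = len(seeds) - a
        d = n - len(c) - cc
        p = stats.fisher_exact([[a, b], [cc, d]], alternative="greater")[1]
        if m * p < alpha:
            kept.append(c)
            for gene in c:
                scores[gene] = min(scores.get(gene, 1.0), m * p)
    module = set().union(*kept) if kept else set()
    return ModuleResult(
        method="clique_sum",
        genes=module,
        scores=scores,
        params={"min_clique_size": min_clique_size, "alpha": alpha, "n_cliques_tested": m},
        seeds=set(seeds),
    )


# ---------------------------------------------------------------------------
# Correlation Clique
# ---------------------------------------------------------------------------


def run_correlation_clique(
    network: PPINetwork,
    seeds,
    seed_scores: dict[str, float] | None = None,
    n_iter: int = 50,
    freq_cutoff: float = 0.5,
    rng_seed: int = 0,
    alpha: float = 0.05,
    min_clique_size: int = 3,
    nonseed_factor: float = 1.0,
) -> ModuleResult:
    """Stochastic clique aggregation over edge-resampled networks.

    Per iteration each edge is kept independently with probability
    (edge score / 1000) scaled by the mean seed-score factor of its
    endpoints (non-seeds contribute ``nonseed_factor``); maximal cliques of
    the sampled graph that are seed-enriched (one-sided Fisher p < alpha)
    mark their genes present.  The module is the genes present in at least
    ``freq_cutoff`` of iterations.  The scoring constants are a documented
    reconstruction and all live in the signature.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    g = network.graph
    seeds = set(seeds) & set(g.nodes)
    seed_scores = seed_scores or {}
    factor = {
        node: float(seed_scores.get(node, 1.0)) if node in seeds else nonseed_factor
        for node in g.nodes
    }
    edges = list(g.edges(data="score"))
    probs = np.array(
        [min(1.0, (s / 1000.0) * 0.5 * (factor[u] + factor[v])) for u, v, s in edges]
    )
    rng = np.random.default_rng(rng_seed)
    n = g.number_of_nodes()
    counts: dict[str, int] = {}
    for _ in range(n_iter):
        keep = rng.random(len(edges)) < probs
        sub = nx.Graph()
        sub.add_nodes_from(g.nodes)
        sub.add_edges_from((u, v) for (u, v, _), k in zip(edges, keep) if k)
        present: set[str] = set()
        for c in nx.find_cliques(sub):
            if len(c) < min_clique_size:
                continue
            a = len(set(c) & seeds)
            if a == 0:
                continue
            b = len(c) - a
            cc = len(seeds) - a
            d = n - len(c) - cc
            p = stats.fisher_exact([[a, b], [cc, d]], alternative="greater")[1]
            if p < alpha:
                present |= set(c)
        for gene in present:
            counts[gene] = counts.get(gene, 0) + 1
    module = {gene for gene, c in counts.items() if c / n_iter >= freq_cutoff}
    return ModuleResult(
        method="correlation_clique",
        genes=module,
        scores={gene: c / n_iter for gene, c in counts.items()},
        params={
            "n_iter": n_iter,
            "freq_cutoff": freq_cutoff,
            "alpha": alpha,
            "nonseed_factor": nonseed_factor,
        },
        seeds=set(seeds),
    )


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------


def build_consensus(
    results: list[ModuleResult],
    min_methods: int = 3,
    dmg_directions: dict[str, str] | None = None,
) -> ConsensusModule:
    """Genes returned by at least ``min_methods`` of the four algorithms."""
    if len(results) != 4:
        raise ValueError("consensus requires exactly 4 module results")
    names = [r.method for r in results]
    if len(set(names)) != 4:
        raise ValueError(f"duplicate method names: {names}")
    all_genes = sorted(set().union(*(r.genes for r in results)))
    membership = pd.DataFrame(
        {r.method: [g in r.genes for g in all_genes] for r in results},
        index=all_genes,
    )[list(METHOD_NAMES)]
    counts = membership.sum(axis=1)
    genes = set(counts.index[counts >= min_methods])
    seed_union = set().union(*(r.seeds for r in results))
    seed_origin = {g: g in seed_union for g in genes}
    directions = {
        g: dmg_directions[g] for g in genes if dmg_directions and g in dmg_directions
    }
    return ConsensusModule(
        genes=genes, membership=membership, seed_origin=seed_origin, direction=directions
    )


def module_to_cpgs(
    module_genes,
    annotation: pd.DataFrame,
    dmp_table: pd.DataFrame,
) -> pd.DataFrame:
    """Project module genes onto their measured CpGs with pregnancy effects.

    ``dmp_table`` must be indexed by probe id and carry ``delta_beta`` and
    ``is_dmp`` for the pregnancy contrast.  Genes without annotated probes
    are logged and skipped.
    """
    module_genes = set(module_genes)
    rows = []
    gene_lists = annotation["gene"].astype(str).str.split(";")
    covered: set[str] = set()
    for probe, genes in gene_lists.items():
        hit = module_genes.intersection(genes)
        if not hit:
            continue
        covered |= hit
        rows.append(
            {
                "probe_id": probe,
                "genes": ";".join(sorted(hit)),
                "delta_beta": dmp_table["delta_beta"].get(probe, np.nan)
                if probe in dmp_table.index
                else np.nan,
                "is_dmp": bool(dmp_table["is_dmp"].get(probe, False))
                if probe in dmp_table.index
                else False,
            }
        )
    for gene in sorted(module_genes - covered):
        log.warning("module gene %s has no annotated probes", gene)
    out = pd.DataFrame(rows, columns=["probe_id", "genes", "delta_beta", "is_dmp"])
    return out.set_index("probe_id")


def export_sif(network: PPINetwork, genes, path) -> None:
    """Write the induced subgraph as a Cytoscape SIF file."""
    sub = network.graph.subgraph(set(genes))
    with open(path, "w") as fh:
        for u, v in sorted(sub.edges):
            fh.write(f"{u}\tpp\t{v}\n")
        for n in sorted(set(genes) - set(itertools.chain(*sub.edges))):
            if n in sub:
                fh.write(f"{n}\n")
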