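"""Synthetic case-control microbiome data generator.

The generator reproduces the statistical structure of a targeted-
sequencing case-control study: per-sample sequencing depths from a
negative binomial (mean 1000, size 25), over-dispersed OTU counts from a
Dirichlet-multinomial with baseline proportions pi and dispersion theta,
signal OTUs chosen either as a phylogenetically tight cluster (PAM on the
cophenetic distance matrix), as phylogenetically scattered top-abundance
OTUs, or a mixture of both, and a logistic outcome model driven by the
standardized summed abundance (Model A) or presence count (Model B) of the
signal OTUs.

The shipped default parameters are synthetic: a random Kingman-coalescent
tree and log-normal baseline proportions with a realistic rank-abundance
skew.  Parameter sets estimated from real data (tree + proportions +
dispersion) can be supplied through file paths instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data_io import PhyloTree, read_newick, to_relative_abundance

__all__ = [
    "SimConfig",
    "SimDataset",
    "default_parameters",
    "dm_counts",
    "pam_clusters",
    "select_signals",
    "linear_predictor",
    "simulate_outcome",
    "simulate_study",
    "oracle_auc_replicates",
]


# ---------------------------------------------------------------------------
# default synthetic parameters
# ---------------------------------------------------------------------------

def _coalescent_newick(q: int, rng: np.random.Generator) -> str:
    """Random Kingman-coalescent tree over q labelled leaves."""
    width = len(str(q))
    labels = [f"OTU{i + 1:0{width}d}" for i in range(q)]
    nodes = list(labels)
    heights = [0.0] * q
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        right = nodes.pop(j)
        hr = heights.pop(j)
        left = nodes.pop(i)
        hl = heights.pop(i)
        merged = f"({left}:{t - hl:.10g},{right}:{t - hr:.10g})"
        nodes.append(merged)
        heights.append(t)
    return nodes[0] + ";"


def default_parameters(
    q: int, seed: int
) -> tuple[PhyloTree, pd.Series, float]:
    """Synthetic stand-in parameter set: (tree, baseline proportions, theta).

    The tree is a random coalescent over q leaves; proportions are drawn
    log-normal (sigma_log = 2, giving a heavy-tailed rank-abundance curve
    typical of 16S surveys) and normalized; theta = 0.02.
    """
    if q < 20:
        raise ValueError("need at least 20 OTUs")
    rng = np.random.default_rng(seed)
    tree = PhyloTree.from_newick(_coalescent_newick(q, rng))
    raw = rng.lognormal(mean=0.0, sigma=2.0, size=q)
    pi = pd.Series(raw / raw.sum(), index=tree.leaf_names)
    return tree, pi, 0.02


def load_parameters(
    tree_path: str, pi_path: str, theta: float
) -> tuple[PhyloTree, pd.Series, float]:
    """Load an externally estimated parameter set (tree, proportions, theta).

    *pi_path* is a two-column TSV (OTU id, proportion); proportions are
    re-normalized to sum to 1 and must cover the tree leaves.
    """
    tree = read_newick(tree_path)
    tab = pd.read_csv(pi_path, sep="\t", index_col=0)
    pi = tab.iloc[:, 0].astype(float)
    pi.index = pi.index.astype(str)
    missing = set(tree.leaf_names) - set(pi.index)
    if missing:
        raise ValueError(f"proportions missing for tree leaves: {sorted(missing)[:5]}")
    pi = pi.reindex(tree.leaf_names)
    pi = pi / pi.sum()
    return tree, pi, float(theta)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def dm_counts(
    n: int,
    pi: pd.Series,
    theta: float,
    seed,
    total_mean: float = 1000.0,
    total_size: float = 25.0,
) -> pd.DataFrame:
    """Dirichlet-multinomial OTU counts with negative-binomial totals.

    Totals N_i ~ NegBin(mean=total_mean, size=total_size), i.e. variance
    mean + mean^2/size.  Per sample, proportions p ~ Dirichlet(alpha) with
    alpha = pi (1 - theta) / theta (the standard over-dispersion
    parameterization), then counts ~ Multinomial(N_i, p).
    """
    if not 0 < theta < 1:
        raise ValueError("theta must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_nb = total_size / (total_size + total_mean)
    totals = rng.negative_binomial(total_size, p_nb, size=n)
    alpha = pi.to_numpy(dtype=float) * (1.0 - theta) / theta
    counts = np.empty((n, len(pi)), dtype=np.int64)
    for i in range(n):
        p = rng.dirichlet(alpha)
        counts[i] = rng.multinomial(totals[i], p)
    width = len(str(n))
    ids = [f"S{i + 1:0{width}d}" for i in range(n)]
    return pd.DataFrame(counts, index=ids, columns=list(pi.index))


# ---------------------------------------------------------------------------
# signal-OTU selection
# ---------------------------------------------------------------------------

def pam_clusters(D: pd.DataFrame, k: int, seed: int = 0) -> pd.Series:
    """Partitioning around medoids (BUILD + SWAP) on a distance matrix.

    Classic k-medoids: BUILD greedily seeds medoids minimizing total
    within-cluster distance; SWAP exchanges a medoid for a non-medoid
    whenever that lowers the total cost, until no improving swap exists.
    Ties break on the lowest index, so the result is deterministic.
    """
    if k < 2:
        raise ValueError("need k >= 2 clusters")
    if k > D.shape[0]:
        raise ValueError("k exceeds the number of items")
    dist = D.to_numpy(dtype=float)
    n = dist.shape[0]
    # BUILD
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    nearest = dist[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[:, None] - dist, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        m = int(np.argmax(gains))
        medoids.append(m)
        nearest = np.minimum(nearest, dist[:, m])
    # SWAP
    medoids = sorted(medoids)
    for _ in range(200):
        med = np.array(medoids)
        cost = dist[:, med].min(axis=1).sum()
        best_delta, best_swap = -1e-12, None
        non = np.array([i for i in range(n) if i not in set(medoids)], dtype=int)
        if non.size == 0:
            break
        for pos in range(len(med)):
            rest = np.delete(med, pos)
            rest_min = dist[:, rest].min(axis=1)
            cand_cost = np.minimum(rest_min[:, None], dist[:, non]).sum(axis=0)
            j = int(np.argmin(cand_cost))
            delta = cand_cost[j] - cost
            if delta < best_delta:
                best_delta, best_swap = delta, (pos, int(non[j]))
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
        medoids = sorted(medoids)
    med = np.array(medoids)
    assign = med[dist[:, med].argmin(axis=1)]
    # relabel clusters 0..k-1 in medoid order
    relabel = {m: c for c, m in enumerate(med)}
    return pd.Series([relabel[a] for a in assign], index=D.index, name="cluster")


def _cluster_abundance_ranks(clusters: pd.Series, rel: pd.DataFrame) -> pd.Series:
    """Clusters ordered by total mean relative abundance; rank 1 = most abundant."""
    otu_mean = rel.mean(axis=0)
    totals = otu_mean.groupby(clusters).sum()
    order = totals.sort_values(ascending=False).index
    return pd.Series(np.arange(1, len(order) + 1), index=order)


def select_signals(
    clusters: pd.Series,
    rel: pd.DataFrame,
    scenario: str = "I",
    cluster_rank: int | list[int] = 2,
    n_unrelated: int = 9,
    exclude: set | None = None,
) -> list[str] | tuple[list[str], list[str]]:
    """Choose signal OTUs.

    Scenario I (phylogenetically related): all OTUs of the cluster(s) at
    the requested total-abundance rank(s).
    Scenario II (unrelated): scanning OTUs by descending mean abundance,
    take the first OTU seen from each of *n_unrelated* distinct clusters.
    Scenario III: returns (G1, G2) — a scenario-I set and a disjoint
    scenario-II set drawn from the remaining clusters.
    """
    ranks = _cluster_abundance_ranks(clusters, rel)
    k = len(ranks)
    if scenario == "I":
        req = [cluster_rank] if np.isscalar(cluster_rank) else list(cluster_rank)
        if any(r > k or r < 1 for r in req):
            raise ValueError(f"cluster rank out of range 1..{k}: {req}")
        chosen = set(ranks.index[ranks.isin(req)])
        return [o for o in rel.columns if clusters[o] in chosen]
    if scenario == "II":
        excl_clusters = (
            {clusters[o] for o in exclude} if exclude else set()
        )
        otu_order = rel.mean(axis=0).sort_values(ascending=False).index
        seen, out = set(excl_clusters), []
        for otu in otu_order:
            c = clusters[otu]
            if c not in seen:
                seen.add(c)
                out.append(otu)
            if len(out) == n_unrelated:
                return out
        raise ValueError(
            f"only {len(out)} distinct clusters available for scenario II"
        )
    if scenario == "III":
        g1 = select_signals(clusters, rel, "I", cluster_rank=cluster_rank)
        g2 = select_signals(
            clusters, rel, "II", n_unrelated=n_unrelated, exclude=set(g1)
        )
        assert not set(g1) & set(g2)
        return g1, g2
    raise ValueError(f"unknown scenario {scenario!r}")


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------

def _scale(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd <= 1e-12 * max(1.0, float(np.abs(x).max())):
        raise ValueError(
            "signal predictor is constant across the pool; scale() undefined"
        )
    return (x - x.mean()) / sd


def linear_predictor(rel: pd.DataFrame, terms) -> np.ndarray:
    """eta_i = sum_k beta_k * scale(term_k), each term a (signal set,
    form, beta) triple with form 'A' (summed abundance) or 'B' (presence
    count, I(p > 0))."""
    eta = np.zeros(rel.shape[0])
    for signals, form, beta in terms:
        sub = rel[list(signals)].to_numpy(dtype=float)
        if form == "A":
            raw = sub.sum(axis=1)
        elif form == "B":
            raw = (sub > 0).sum(axis=1).astype(float)
        else:
            raise ValueError(f"unknown outcome model {form!r}")
        eta += beta * _scale(raw)
    return eta


def simulate_outcome(
    rel: pd.DataFrame,
    signals,
    model: str,
    beta,
    n_cases: int,
    n_controls: int,
    seed,
) -> tuple[pd.Index, np.ndarray, np.ndarray]:
    """Draw binary outcomes over the pool and subsample an exactly
    balanced case-control set.

    y_i ~ Bernoulli(expit(eta_i)) with eta the standardized signal
    predictor; the first *n_cases* cases and *n_controls* controls in pool
    order are kept (sampling without replacement from an oversampled
    pool).  Returns (selected sample ids, their labels, eta over the pool).
    """
    from scipy.special import expit

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(model, str) and len(model) == 1:
        terms = [(signals, model, beta)]
    else:
        terms = model  # pre-built term list; signals/beta ignored
    eta = linear_predictor(rel, terms)
    y = rng.binomial(1, expit(eta))
    case_idx = np.flatnonzero(y == 1)
    ctrl_idx = np.flatnonzero(y == 0)
    if len(case_idx) < n_cases or len(ctrl_idx) < n_controls:
        raise ValueError(
            f"pool exhausted: {len(case_idx)} cases / {len(ctrl_idx)} controls "
            f"available, {n_cases}/{n_controls} requested; enlarge the pool"
        )
    sel = np.concatenate([case_idx[:n_cases], ctrl_idx[:n_controls]])
    sel.sort()
    return rel.index[sel], y[sel], eta


def oracle_auc_replicates(
    beta: float = 2.0,
    n_per_class: int = 250,
    replicates: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Testing-set AUCs of the oracle classifier across balanced replicates.

    The oracle scores each sample by its true linear predictor eta = beta*z,
    with z the standardized signal predictor (standard normal by
    construction of scale()).  Outcomes are y ~ Bernoulli(expit(eta));
    each replicate subsamples an exactly balanced testing set of
    *n_per_class* cases and controls and records the rank-based AUC of
    the oracle score.  This is the ceiling any classifier can reach under
    the generative model.
    """
    from scipy.special import expit

    from .evaluate import auc

    rng = np.random.default_rng(seed)
    pool = 12 * n_per_class
    out = np.empty(replicates)
    for r in range(replicates):
        z = rng.standard_normal(pool)
        y = (rng.random(pool) < expit(beta * z)).astype(int)
        cases = np.flatnonzero(y == 1)[:n_per_class]
        ctrls = np.flatnonzero(y == 0)[:n_per_class]
        if len(cases) < n_per_class or len(ctrls) < n_per_class:
            raise RuntimeError("oracle pool exhausted; enlarge the pool")
        sel = np.r_[cases, ctrls]
        out[r] = auc(z[sel], y[sel])
    return out


# ---------------------------------------------------------------------------
# end-to-end study generator
# ---------------------------------------------------------------------------

_SCENARIO_III_COMBOS = {
    1: ("B", "B"),
    2: ("B", "A"),
    3: ("A", "B"),
    4: ("A", "B"),  # both terms on the unrelated set, abundance + presence
}


@dataclass
class SimConfig:
    """Study-design parameters for one simulated dataset pair."""

    n: int = 500              # samples per set (train and test each)
    q: int = 856              # number of OTUs
    scenario: str = "I"       # I related, II unrelated, III mixture
    model: str = "A"          # A abundance, B presence (scenarios I/II)
    combo: int = 1            # scenario-III term combination id
    beta: float = 2.0
    beta2: float | None = None  # scenario III second effect (defaults to beta)
    cluster_rank: int | None = None   # scenario I/III; default 2 (A) or 8 (B)
    n_unrelated: int = 9
    k_clusters: int = 20
    theta: float = 0.02
    total_mean: float = 1000.0
    total_size: float = 25.0
    pool_factor: int = 4
    seed: int = 0
    tree_file: str | None = None   # externally estimated parameter set
    pi_file: str | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self))


@dataclass
class SimDataset:
    counts: pd.DataFrame
    rel: pd.DataFrame
    labels: pd.Series
    tree: PhyloTree = field(repr=False)
    signal_otus: list = field(default_factory=list)
    eta: pd.Series | None = field(default=None, repr=False)

    @property
    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame({"label": self.labels})


def _signal_terms(cfg: SimConfig, clusters: pd.Series, rel: pd.DataFrame):
    rank = cfg.cluster_rank
    if rank is None:
        rank = 2 if cfg.model == "A" else 8
    if cfg.scenario == "I":
        g = select_signals(clusters, rel, "I", cluster_rank=rank)
        return [(g, cfg.model, cfg.beta)], g
    if cfg.scenario == "II":
        g = select_signals(clusters, rel, "II", n_unrelated=cfg.n_unrelated)
        return [(g, cfg.model, cfg.beta)], g
    if cfg.scenario == "III":
        g1, g2 = select_signals(
            clusters, rel, "III", cluster_rank=rank, n_unrelated=cfg.n_unrelated
        )
        f1, f2 = _SCENARIO_III_COMBOS[cfg.combo]
        b2 = cfg.beta if cfg.beta2 is None else cfg.beta2
        if cfg.combo == 4:
            terms = [(g2, f1, cfg.beta), (g2, f2, b2)]
        else:
            terms = [(g1, f1, cfg.beta), (g2, f2, b2)]
        return terms, sorted(set(g1) | set(g2))
    raise ValueError(f"unknown scenario {cfg.scenario!r}")


def simulate_study(cfg: SimConfig) -> tuple[SimDataset, SimDataset]:
    """Generate one (training set, testing set) pair under a SimConfig.

    Both sets are drawn without replacement from a common oversampled
    pool, each with exactly n/2 cases and n/2 controls.  Identical configs
    (including seed) give identical datasets.
    """
    if cfg.n % 2:
        raise ValueError("n must be even (equal cases and controls)")
    ss = np.random.SeedSequence(cfg.seed)
    s_param, s_counts, s_outcome = ss.spawn(3)
    if cfg.tree_file:
        tree, pi, theta = load_parameters(cfg.tree_file, cfg.pi_file, cfg.theta)
    else:
        tree, pi, theta = default_parameters(
            cfg.q, np.random.default_rng(s_param)
        )
        theta = cfg.theta
    pool_n = cfg.pool_factor * 2 * cfg.n
    counts = dm_counts(
        pool_n, pi, theta, np.random.default_rng(s_counts),
        cfg.total_mean, cfg.total_size,
    )
    rel = to_relative_abundance(counts)
    clusters = pam_clusters(tree.cophenetic(), cfg.k_clusters)
    clusters = clusters.reindex(rel.columns)
    terms, signal_otus = _signal_terms(cfg, clusters, rel)

    half = cfg.n // 2
    ids, labels, eta = simulate_outcome(
        rel, None, terms, None, 2 * half, 2 * half,
        np.random.default_rng(s_outcome),
    )
    eta_s = pd.Series(eta, index=rel.index)
    lab = pd.Series(labels, index=ids)
    case_ids = lab.index[lab == 1]
    ctrl_ids = lab.index[lab == 0]
    train_ids = case_ids[:half].append(ctrl_ids[:half])
    test_ids = case_ids[half:].append(ctrl_ids[half:])

    def make(sel) -> SimDataset:
        sel = [s for s in rel.index if s in set(sel)]  # pool order
        return SimDataset(
            counts=counts.loc[sel],
            rel=rel.loc[sel],
            labels=lab.loc[sel].astype(int),
            tree=tree,
            signal_otus=list(signal_otus),
            eta=eta_s.loc[sel],
        )

    return make(train_ids), make(test_ids)
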