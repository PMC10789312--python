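"""The multi-kernel boosted-metric classifier.

Kernel weights minimize an entropy-regularized alignment objective

    min_w  -sum_{i,j} sum_l w_l K_l(i,j) CC(i,j) + rho sum_l w_l log w_l
    s.t.   sum_l w_l = 1,  w_l >= 0,

where CC is the pairwise class-agreement matrix (+1 same class, -1
different, 0 diagonal).  The stationarity conditions give the closed form
w = softmax(S / rho) with per-kernel alignment scores
S_l = sum_{i,j} K_l(i,j) CC(i,j); rho = 0 puts all mass on the best-
aligned kernel.  rho is tuned on an 11-point grid {0, rho_max/10, ...,
rho_max} by stratified 5-fold cross-validated AUC, where rho_max is the
smallest rho whose solution is (numerically) maximum-entropy.

Prediction: each sample gets a similarity t-score — the Welch two-sample
t-statistic comparing its combined-kernel similarities to training cases
versus training controls (training samples leave themselves out) — and a
univariate logistic model on the t-score yields case probabilities.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from . import boosted_distances as bd
from . import kernels as kmod
from .data_io import (
    BranchProfiles,
    PhyloTree,
    align_tree_and_table,
    branch_profiles,
    to_relative_abundance,
)
from .evaluate import auc, stratified_folds

__all__ = [
    "CCMatrix",
    "KernelWeights",
    "FitConfig",
    "MKBMCModel",
    "cc_matrix",
    "kernel_score",
    "solve_weights",
    "rho_max",
    "tune_rho",
    "similarity_tscore",
    "fit",
    "predict_proba",
]

MICROBIOME_KERNELS = (
    "weighted_unifrac",
    "unweighted_unifrac",
    "bray_curtis",
    "hamming",
)

BETA1_CLAMP = 30.0


def cc_matrix(labels) -> np.ndarray:
    """Class-agreement matrix: +1 same class, -1 different, 0 on the diagonal."""
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    same = (y[:, None] == y[None, :])
    cc = np.where(same, 1, -1)
    np.fill_diagonal(cc, 0)
    return cc


def kernel_score(K, CC) -> float:
    """Alignment score S_l = sum_{i,j} K(i,j) CC(i,j) (full double sum)."""
    Kv = K.values if isinstance(K, kmod.KernelMatrix) else np.asarray(K)
    CC = np.asarray(CC)
    if Kv.shape != CC.shape:
        raise ValueError(f"shape mismatch: K {Kv.shape} vs CC {CC.shape}")
    return float((Kv * CC).sum())


@dataclass
class KernelWeights:
    """Simplex weights over the kernels, with the rho that produced them."""

    values: np.ndarray
    rho: float
    names: list[str] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.values, dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("kernel weights must be a probability vector")
        self.values = w


def solve_weights(S, rho: float, names: list[str] | None = None) -> KernelWeights:
    """Closed-form minimizer of the entropy-regularized alignment objective.

    rho > 0: w = softmax(S / rho) (computed with max-subtraction).
    rho = 0: all mass on the argmax score; exact ties split equally.
    """
    S = np.asarray(S, dtype=float)
    if rho < 0:
        raise ValueError("rho must be nonnegative")
    if rho == 0:
        tol = 1e-12 * max(1.0, np.abs(S).max())
        best = S >= S.max() - tol
        w = best / best.sum()
    else:
        z = (S - S.max()) / rho
        e = np.exp(z)
        w = e / e.sum()
    return KernelWeights(w, float(rho), names)


def _entropy(w: np.ndarray) -> float:
    w = w[w > 0]
    return float(-(w * np.log(w)).sum())


def rho_max(S, n_kernels: int | None = None) -> float:
    """Smallest rho (doubling search) whose weights are near maximum entropy.

    The softmax solution reaches the uniform (max-entropy) point only in
    the rho -> infinity limit, so "maximum entropy" is read as entropy >=
    (1 - 1e-3) * log(L).  Equal scores are already uniform: return 1.
    """
    S = np.asarray(S, dtype=float)
    L = n_kernels if n_kernels is not None else len(S)
    if L < 2:
        raise ValueError("need at least two kernels")
    if np.ptp(S) == 0:
        return 1.0
    target = (1.0 - 1e-3) * np.log(L)
    rho = 1.0
    while rho <= 2.0**60:
        if _entropy(solve_weights(S, rho).values) >= target:
            return rho
        rho *= 2.0
    raise ValueError("rho_max search exceeded 2^60: pathological scores")


def similarity_tscore(k_row, labels, self_index: int | None = None) -> float:
    """Welch t-statistic of a sample's similarities to cases vs controls.

    *k_row* holds the sample's combined-kernel similarities to the N
    training samples; *self_index* removes the sample itself when it is
    one of them.  Positive t means "more similar to cases".
    """
    k = np.asarray(k_row, dtype=float)
    y = np.asarray(labels).astype(int)
    mask = np.ones(len(k), dtype=bool)
    if self_index is not None:
        mask[self_index] = False
    a = k[mask & (y == 1)]
    b = k[mask & (y == 0)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 training cases and >= 2 controls")
    denom = a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)
    if denom == 0:
        warnings.warn("zero variance in both similarity groups; t set to 0")
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(denom))


def _training_tscores(Kc: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Leave-self-out similarity t-scores for every training sample."""
    n = Kc.shape[0]
    return np.array([similarity_tscore(Kc[i], y, self_index=i) for i in range(n)])


def _test_tscores(Kc_cross: np.ndarray, y_train: np.ndarray) -> np.ndarray:
    return np.array(
        [similarity_tscore(row, y_train, self_index=None) for row in Kc_cross]
    )


# ---------------------------------------------------------------------------
# logistic classifier on the t-score
# ---------------------------------------------------------------------------

def _fit_logistic(t: np.ndarray, y: np.ndarray, max_iter: int = 100,
                  tol: float = 1e-8) -> tuple[float, float]:
    """Univariate logistic regression by Newton (IRLS).

    Complete separation drives |beta1| to infinity; it is clamped at 30
    (a slope already saturating the link on any realistic t-scale) and
    beta0 is then re-optimized with the slope held fixed.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)

    def clamped(sign: float) -> tuple[float, float]:
        warnings.warn(
            "complete separation in the t-score logistic; "
            f"clamping |beta1| at {BETA1_CLAMP}"
        )
        b1 = sign * BETA1_CLAMP
        b0 = 0.0
        for _ in range(max_iter):
            mu = expit(b0 + b1 * t)
            h = float((mu * (1 - mu)).sum())
            if h == 0:
                break
            step = float((y - mu).sum()) / h
            b0 += step
            if abs(step) < tol:
                break
        return b0, float(b1)

    # complete separation: disjoint t ranges make the MLE slope infinite
    if t[y == 0].max() < t[y == 1].min():
        return clamped(1.0)
    if t[y == 1].max() < t[y == 0].min():
        return clamped(-1.0)

    X = np.column_stack([np.ones_like(t), t])
    beta = np.zeros(2)

    def nll(b):
        eta = X @ b
        return float(np.logaddexp(0.0, eta).sum() - y @ eta)

    prev = nll(beta)
    converged = False
    for _ in range(max_iter):
        mu = expit(X @ beta)
        Wd = mu * (1 - mu)
        grad = X.T @ (y - mu)
        H = (X * Wd[:, None]).T @ X
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(2), grad)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"logistic fit failed: singular Hessian ({exc})")
        lam = 1.0  # step-halving keeps Newton monotone on the likelihood
        for _ in range(30):
            if nll(beta + lam * step) <= prev + 1e-12:
                break
            lam /= 2.0
        beta = beta + lam * step
        cur = nll(beta)
        if np.abs(beta[1]) > BETA1_CLAMP:
            break
        if np.max(np.abs(lam * step)) < tol or prev - cur < tol:
            converged = True
            break
        prev = cur
    if not converged and np.abs(beta[1]) > BETA1_CLAMP:
        return clamped(float(np.sign(beta[1])))
    if not converged:
        raise RuntimeError(
            "logistic fit did not converge in "
            f"{max_iter} iterations (beta={beta.tolist()})"
        )
    return float(beta[0]), float(beta[1])


# ---------------------------------------------------------------------------
# configuration and fitted-model state
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    covariates: tuple[str, ...] = ()
    folds: int = 5
    seed: int = 0
    rho: float | str = "tune"  # "tune" or a fixed nonnegative value
    boost: bool = True
    boost_level: str = "branch"  # branch-level tests for tree metrics; or "otu"
    n_rho: int = 11


@dataclass
class MKBMCModel:
    kernel_names: list[str]
    weights: np.ndarray
    rho: float
    rho_grid_max: float
    sigmas: dict[str, float]
    boosts: dict[str, bd.BoostWeights]
    covariate_scalers: dict[str, kmod.CovariateScaler]
    train_rel: pd.DataFrame = field(repr=False)
    train_labels: np.ndarray = field(repr=False)
    tree: PhyloTree = field(repr=False)
    beta0: float = 0.0
    beta1: float = 0.0
    config: FitConfig = field(default_factory=FitConfig)
    train_covariates: pd.DataFrame | None = field(default=None, repr=False)
    train_kernels: dict[str, kmod.KernelMatrix] | None = field(
        default=None, repr=False
    )
    train_tscores: np.ndarray | None = field(default=None, repr=False)
    _train_bp: BranchProfiles | None = field(default=None, repr=False)

    @property
    def train_bp(self) -> BranchProfiles:
        if self._train_bp is None:
            self._train_bp = branch_profiles(self.tree, self.train_rel)
        return self._train_bp

    def write_kernels_tsv(self, prefix: str) -> None:
        """Export the training kernel matrices as TSV files (debug aid)."""
        if not self.train_kernels:
            raise ValueError("training kernels were not retained on this model")
        for name, K in self.train_kernels.items():
            K.write_tsv(f"{prefix}.{name.replace(':', '_')}.tsv")

    def _train_covariate_z(self, cov: str) -> np.ndarray:
        if self.train_covariates is None or cov not in self.train_covariates:
            raise ValueError(f"model lacks training covariate {cov!r}")
        return self.covariate_scalers[cov].transform(
            self.train_covariates[cov].to_numpy(dtype=float)
        )

    # -- serialization ----------------------------------------------------
    def to_json(self, path: str) -> None:
        fingerprints = {}
        if self.train_kernels:
            for name, K in self.train_kernels.items():
                h = hashlib.sha256(np.round(K.values, 10).tobytes())
                fingerprints[name] = h.hexdigest()[:16]
        payload = {
            "format": "mkbmc-model-1",
            "kernel_names": self.kernel_names,
            "weights": self.weights.tolist(),
            "rho": self.rho,
            "rho_grid_max": self.rho_grid_max,
            "sigmas": self.sigmas,
            "beta0": self.beta0,
            "beta1": self.beta1,
            "boosts": {
                m: {
                    "ids": list(map(str, b.weights.index)),
                    "values": b.weights.tolist(),
                    "normalization": b.normalization,
                }
                for m, b in self.boosts.items()
            },
            "covariates": {
                name: {"mean": s.mean, "sd": s.sd, "sigma": s.sigma}
                for name, s in self.covariate_scalers.items()
            },
            "config": {
                "covariates": list(self.config.covariates),
                "folds": self.config.folds,
                "seed": self.config.seed,
                "rho": self.config.rho,
                "boost": self.config.boost,
                "boost_level": self.config.boost_level,
                "n_rho": self.config.n_rho,
            },
            "train": {
                "sample_ids": list(map(str, self.train_rel.index)),
                "otu_ids": list(map(str, self.train_rel.columns)),
                "rel_abundance": self.train_rel.values.tolist(),
                "labels": self.train_labels.tolist(),
                "covariates": (
                    {
                        c: self.train_covariates[c].tolist()
                        for c in self.train_covariates.columns
                    }
                    if self.train_covariates is not None
                    else {}
                ),
            },
            "tree_newick": self.tree.to_newick(),
            "kernel_fingerprints": fingerprints,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "MKBMCModel":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("format") != "mkbmc-model-1":
            raise ValueError(f"{path!r} is not an mkbmc model file")
        boosts = {
            m: bd.BoostWeights(
                pd.Series(b["values"], index=b["ids"]), b["normalization"]
            )
            for m, b in d["boosts"].items()
        }
        scalers = {
            name: kmod.CovariateScaler(name, s["mean"], s["sd"], s["sigma"])
            for name, s in d["covariates"].items()
        }
        cfg = FitConfig(
            covariates=tuple(d["config"]["covariates"]),
            folds=d["config"]["folds"],
            seed=d["config"]["seed"],
            rho=d["config"]["rho"],
            boost=d["config"]["boost"],
            boost_level=d["config"]["boost_level"],
            n_rho=d["config"]["n_rho"],
        )
        rel = pd.DataFrame(
            d["train"]["rel_abundance"],
            index=d["train"]["sample_ids"],
            columns=d["train"]["otu_ids"],
        )
        covs = d["train"].get("covariates") or {}
        train_cov = (
            pd.DataFrame(covs, index=d["train"]["sample_ids"]) if covs else None
        )
        return cls(
            kernel_names=d["kernel_names"],
            weights=np.asarray(d["weights"]),
            rho=d["rho"],
            rho_grid_max=d["rho_grid_max"],
            sigmas=d["sigmas"],
            boosts=boosts,
            covariate_scalers=scalers,
            train_rel=rel,
            train_labels=np.asarray(d["train"]["labels"], dtype=int),
            tree=PhyloTree.from_newick(d["tree_newick"]),
            beta0=d["beta0"],
            beta1=d["beta1"],
            config=cfg,
            train_covariates=train_cov,
        )


# ---------------------------------------------------------------------------
# kernel construction helpers
# ---------------------------------------------------------------------------

def _branch_min_p(tree: PhyloTree, otu_p: pd.Series) -> pd.Series:
    """Map OTU p-values to branches: each branch takes the minimum p among
    its descendant leaves (leaf branches inherit their own OTU's p)."""
    m = len(tree.names)
    vals = np.ones(m)
    for i, (name, leaf) in enumerate(zip(tree.names, tree.is_leaf)):
        if leaf:
            vals[i] = float(otu_p[name])
    for i in range(m):
        p = tree.parent[i]
        if p >= 0:
            vals[p] = min(vals[p], vals[i])
    keep = np.arange(m) != tree.root_index
    return pd.Series(vals[keep], index=tree.branch_names)


def compute_boosts(
    rel: pd.DataFrame,
    bp: BranchProfiles,
    y: np.ndarray,
    tree: PhyloTree | None = None,
    boost_level: str = "branch",
) -> dict[str, bd.BoostWeights]:
    """Boosting weights for each of the four metrics from training data only.

    Tree metrics are boosted per branch — the branch profile is tested
    directly (abundance t-test for weighted UniFrac, presence test for
    unweighted) — which is the reading consistent with a_r sharing the
    branch index of b_r.  With ``boost_level="otu"`` the tests run on OTUs
    and each branch inherits the strongest (minimum) descendant p-value.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if boost_level == "branch":
            p_w = bd.abundance_pvalues(bp.values, y)
            p_un = bd.presence_pvalues(bp.values, y)
        elif boost_level == "otu":
            if tree is None:
                raise ValueError("otu-level tree boosting needs the tree")
            p_w = _branch_min_p(tree, bd.abundance_pvalues(rel, y))
            p_un = _branch_min_p(tree, bd.presence_pvalues(rel, y))
        else:
            raise ValueError(f"unknown boost_level {boost_level!r}")
        p_bc = bd.abundance_pvalues(rel, y)
        p_h = bd.presence_pvalues(rel, y)
        return {
            "weighted_unifrac": bd.pvalues_to_weights(p_w),
            "unweighted_unifrac": bd.pvalues_to_weights(p_un),
            "bray_curtis": bd.pvalues_to_weights(p_bc),
            "hamming": bd.pvalues_to_weights(p_h),
        }


def _microbiome_distances(
    rel, bp, boosts, rel_other=None, bp_other=None
) -> dict[str, bd.DistanceMatrix]:
    g = lambda m: boosts.get(m) if boosts else None
    return {
        "weighted_unifrac": bd.weighted_unifrac(bp, g("weighted_unifrac"), other=bp_other),
        "unweighted_unifrac": bd.unweighted_unifrac(bp, g("unweighted_unifrac"), other=bp_other),
        "bray_curtis": bd.bray_curtis(rel, g("bray_curtis"), other=rel_other),
        "hamming": bd.hamming(rel, g("hamming"), other=rel_other),
    }


def _combined(kernel_list: list[np.ndarray], w: np.ndarray) -> np.ndarray:
    out = np.zeros_like(kernel_list[0])
    for wi, K in zip(w, kernel_list):
        out += wi * K
    return out


# ---------------------------------------------------------------------------
# rho tuning
# ---------------------------------------------------------------------------

def _fold_eval(prep: dict, rho: float) -> float:
    """Validation AUC of the full classifier at a given rho on one fold."""
    w = solve_weights(prep["S"], rho).values
    Kc = _combined(prep["K_tt"], w)
    t_tr = _training_tscores(Kc, prep["y_t"])
    beta0, beta1 = _fit_logistic(t_tr, prep["y_t"])
    Kc_v = _combined(prep["K_vt"], w)
    t_v = _test_tscores(Kc_v, prep["y_t"])
    return auc(expit(beta0 + beta1 * t_v), prep["y_v"])


def tune_rho(
    kernels: list[kmod.KernelMatrix],
    labels,
    folds: int = 5,
    seed: int = 0,
    refit=None,
    n_rho: int = 11,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Select rho on the grid {0, rho_max/10, ..., rho_max} by CV AUC.

    For each fold the kernels are restricted to the training split (or
    rebuilt from scratch by *refit(train_idx, val_idx)*, which lets the
    boosting stage be recomputed inside the fold), the full classifier is
    fitted, and the held-out fold scored.  Ties go to the largest rho.

    Returns (best_rho, grid, mean_auc_per_grid_point).
    """
    y = np.asarray(labels).astype(int)
    S_full = np.array([kernel_score(K, cc_matrix(y)) for K in kernels])
    rmax = rho_max(S_full, len(kernels))
    grid = np.linspace(0.0, rmax, n_rho)

    fold_ids = stratified_folds(y, folds, seed)
    preps = []
    for f in range(folds):
        val = fold_ids == f
        tr = ~val
        tr_idx = np.flatnonzero(tr)
        val_idx = np.flatnonzero(val)
        if refit is not None:
            K_tt, K_vt = refit(tr_idx, val_idx)
        else:
            K_tt = [K.values[np.ix_(tr_idx, tr_idx)] for K in kernels]
            K_vt = [K.values[np.ix_(val_idx, tr_idx)] for K in kernels]
        y_t = y[tr_idx]
        S = np.array([kernel_score(K, cc_matrix(y_t)) for K in K_tt])
        preps.append(
            {"K_tt": K_tt, "K_vt": K_vt, "y_t": y_t, "y_v": y[val_idx], "S": S}
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mean_auc = np.array(
            [np.mean([_fold_eval(p, r) for p in preps]) for r in grid]
        )
    best = np.flatnonzero(mean_auc >= mean_auc.max() - 1e-12)[-1]
    return float(grid[best]), grid, mean_auc


# ---------------------------------------------------------------------------
# fit / predict
# ---------------------------------------------------------------------------

def fit(
    tab: pd.DataFrame,
    tree: PhyloTree,
    meta: pd.DataFrame,
    config: FitConfig | None = None,
) -> MKBMCModel:
    """Fit the full pipeline on training data.

    counts -> relative abundance -> branch profiles -> boosting weights ->
    four boosted distances -> Gaussian kernels (+ one per covariate) ->
    tune rho by CV -> closed-form kernel weights -> leave-self-out
    similarity t-scores -> univariate logistic classifier.
    """
    config = config or FitConfig()
    try:
        meta = meta.loc[tab.index]
    except KeyError:
        meta = meta.loc[[str(s) for s in tab.index]]
    y = meta["label"].to_numpy(dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("training labels must contain both classes")

    rel = to_relative_abundance(tab)
    tree, rel = align_tree_and_table(tree, rel)
    bp = branch_profiles(tree, rel)

    def build(rel_s, bp_s, y_s):
        boosts = (
            compute_boosts(rel_s, bp_s, y_s, tree, config.boost_level)
            if config.boost
            else None
        )
        dists = _microbiome_distances(rel_s, bp_s, boosts)
        kerns = {m: kmod.gaussian_kernel(D) for m, D in dists.items()}
        return boosts, kerns

    boosts, kerns = build(rel, bp, y)
    kernel_names = list(MICROBIOME_KERNELS)
    kernel_objs = [kerns[m] for m in MICROBIOME_KERNELS]
    scalers: dict[str, kmod.CovariateScaler] = {}
    for cov in config.covariates:
        K, sc = kmod.covariate_kernel(meta[cov].to_numpy(dtype=float), cov)
        kernel_names.append(K.metric)
        kernel_objs.append(K)
        scalers[cov] = sc

    if config.rho == "tune":

        def refit(tr_idx, val_idx):
            rel_t, rel_v = rel.iloc[tr_idx], rel.iloc[val_idx]
            bp_t = BranchProfiles(bp.values.iloc[tr_idx], bp.branch_lengths)
            bp_v = BranchProfiles(bp.values.iloc[val_idx], bp.branch_lengths)
            b_f, k_f = build(rel_t, bp_t, y[tr_idx])
            d_x = _microbiome_distances(
                rel_v, bp_v, b_f, rel_other=rel_t, bp_other=bp_t
            )
            K_tt = [k_f[m].values for m in MICROBIOME_KERNELS]
            K_vt = [
                kmod.cross_kernel(d_x[m], k_f[m].sigma).values
                for m in MICROBIOME_KERNELS
            ]
            for cov in config.covariates:
                x = meta[cov].to_numpy(dtype=float)
                Kc, sc = kmod.covariate_kernel(x[tr_idx], cov)
                K_tt.append(Kc.values)
                K_vt.append(
                    kmod.covariate_cross_kernel(x[val_idx], x[tr_idx], sc).values
                )
            return K_tt, K_vt

        rho, _, _ = tune_rho(
            kernel_objs, y, folds=config.folds, seed=config.seed,
            refit=refit, n_rho=config.n_rho,
        )
        S_full = np.array(
            [kernel_score(K, cc_matrix(y)) for K in kernel_objs]
        )
        rho_grid_max = rho_max(S_full, len(kernel_objs))
    else:
        rho = float(config.rho)
        S_full = np.array(
            [kernel_score(K, cc_matrix(y)) for K in kernel_objs]
        )
        rho_grid_max = rho_max(S_full, len(kernel_objs))

    w = solve_weights(S_full, rho, kernel_names).values
    Kc = _combined([K.values for K in kernel_objs], w)
    t_train = _training_tscores(Kc, y)
    beta0, beta1 = _fit_logistic(t_train, y)

    return MKBMCModel(
        kernel_names=kernel_names,
        weights=w,
        rho=rho,
        rho_grid_max=rho_grid_max,
        sigmas={n: K.sigma for n, K in zip(kernel_names, kernel_objs)},
        boosts=boosts or {},
        covariate_scalers=scalers,
        train_rel=rel,
        train_labels=y,
        tree=tree,
        beta0=beta0,
        beta1=beta1,
        config=config,
        train_covariates=(
            meta[list(config.covariates)].copy() if config.covariates else None
        ),
        train_kernels=dict(zip(kernel_names, kernel_objs)),
        train_tscores=t_train,
        _train_bp=bp,
    )


def predict_proba(
    model: MKBMCModel,
    tab_test: pd.DataFrame,
    meta_test: pd.DataFrame | None = None,
) -> pd.Series:
    """Case probability for each test sample.

    Test samples are projected onto the training feature space (training
    OTU set; unseen OTUs dropped, missing ones zero), cross kernels are
    computed with frozen training boost weights and bandwidths, and each
    sample's similarity t-score feeds the fitted logistic classifier.
    Predictions depend only on the model and the sample itself.
    """
    train_cols = model.train_rel.columns
    overlap = set(map(str, tab_test.columns)) & set(train_cols)
    if not overlap:
        raise ValueError("test OTU ids share nothing with the training set")
    rel_t = to_relative_abundance(tab_test)
    rel_t.columns = rel_t.columns.astype(str)
    rel_t = rel_t.reindex(columns=train_cols, fill_value=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rel_t = to_relative_abundance(rel_t)  # renormalize after projection
    bp_t = branch_profiles(model.tree, rel_t)

    boosts = model.boosts if model.boosts else None
    d_x = _microbiome_distances(
        rel_t, bp_t, boosts, rel_other=model.train_rel, bp_other=model.train_bp
    )
    K_list = [
        kmod.cross_kernel(d_x[m], model.sigmas[m]).values
        for m in MICROBIOME_KERNELS
    ]
    for cov in model.config.covariates:
        if meta_test is None or cov not in meta_test.columns:
            raise ValueError(f"test metadata with covariate {cov!r} required")
        x_test = meta_test.loc[tab_test.index, cov].to_numpy(dtype=float)
        sc = model.covariate_scalers[cov]
        zt = sc.transform(x_test)
        ztr = model._train_covariate_z(cov)
        D = np.abs(zt[:, None] - ztr[None, :])
        K_list.append(np.exp(-(D**2) / (2.0 * sc.sigma**2)))
    Kc = _combined(K_list, model.weights)
    t = _test_tscores(Kc, model.train_labels)
    probs = expit(model.beta0 + model.beta1 * t)
    return pd.Series(probs, index=tab_test.index, name="prob_case")
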