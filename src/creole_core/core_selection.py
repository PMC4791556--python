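"""Mixed-variable core reference set engine.

Pipeline: (1) PCA reduction of the marker matrix; (2) two-block multiple factor
analysis (genotype PCs + phenotype) with a weight search so the two blocks hit a
target contribution ratio (default genotype:phenotype = 75:25) over the selected
axes; (3) two-stage Ward-MLM clustering of the axis scores (Ward agglomeration to
initialize a Gaussian-mixture EM with shared covariance); (4) quota allocation per
mixture group proportional to within-group Gower diversity (D-method); (5)
stratified random sampling of many candidate subsets, keeping the candidate with the
maximum mean Gower distance; plus a Monte-Carlo sampling curve used to pick the core
size.

Every stochastic step draws from a single seeded generator, so the whole pipeline is
reproducible from its inputs and one integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .diversity import DistanceMatrix, largest_remainder
from .io_core import MISSING, GenotypeMatrix, GroupAssignment, PhenotypeTable

__all__ = [
    "HMFAResult",
    "MixtureFit",
    "AllocationPlan",
    "CoreSet",
    "CoreSizeCurve",
    "pca_reduce",
    "hmfa_two_block",
    "ward_mlm_cluster",
    "gower_distance",
    "axis_gower",
    "d_method_allocation",
    "stratified_core_search",
    "simulate_core_size",
    "select_core",
]


# ---------------------------------------------------------------------------
# PCA reduction of the marker block
# ---------------------------------------------------------------------------

def impute_mean(g: GenotypeMatrix) -> np.ndarray:
    """Dosage matrix with missing calls replaced by the per-marker mean."""
    X = g.calls.astype(float)
    X[g.missing_mask] = np.nan
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    inds = np.where(np.isnan(X))
    X[inds] = col_mean[inds[1]]
    return X


def pca_reduce(
    g: GenotypeMatrix, n_components: int | float, random_state: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Centered PCA of the mean-imputed dosage matrix.

    ``n_components`` is either an integer count or a variance target in (0, 1)
    (smallest number of components whose cumulative explained variance reaches the
    target). Returns (scores, explained variance ratio); components are ordered by
    variance and reproducible up to sign.
    """
    X = impute_mean(g)
    max_rank = min(X.shape)
    if isinstance(n_components, float):
        if not 0 < n_components < 1:
            raise ValueError("variance target must be in (0, 1)")
        pca = PCA(n_components=None, svd_solver="full").fit(X)
        cum = np.cumsum(pca.explained_variance_ratio_)
        k = int(np.searchsorted(cum, n_components) + 1)
        return pca.transform(X)[:, :k], pca.explained_variance_ratio_[:k]
    k = int(n_components)
    if k > max_rank:
        raise ValueError(f"n_components {k} exceeds rank bound {max_rank}")
    solver = "randomized" if k < max_rank // 5 else "full"
    pca = PCA(n_components=k, svd_solver=solver, random_state=random_state).fit(X)
    return pca.transform(X), pca.explained_variance_ratio_


# ---------------------------------------------------------------------------
# two-block MFA with contribution targeting
# ---------------------------------------------------------------------------

@dataclass
class HMFAResult:
    """Scores and block contributions of the weighted two-block factor analysis."""

    scores: np.ndarray  # accessions x n_axes
    eigenvalues: np.ndarray  # per-axis variance
    variance_ratio: np.ndarray  # per-axis share of total variance
    axis_block_contrib: np.ndarray  # n_axes x 2, rows sum to 100 (geno%, pheno%)
    cumulative_contrib: tuple[float, float]  # (geno%, pheno%) over the axes
    phenotype_weight: float
    n_axes: int


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    return np.where(np.isnan(Z), 0.0, Z)


def phenotype_block(pheno: PhenotypeTable) -> np.ndarray:
    """Numeric phenotype block: ordinal level codes and continuous traits z-scored."""
    return _standardize(pheno.data.to_numpy(dtype=float))


def _first_eigenvalue(Z: np.ndarray) -> float:
    n = Z.shape[0]
    s = np.linalg.svd(Z - Z.mean(axis=0), compute_uv=False)
    return float(s[0] ** 2 / (n - 1)) if len(s) else 0.0


def _mfa_decompose(A: np.ndarray, B: np.ndarray, w: float, n_axes: int):
    """Eigendecomposition of [A, wB] via the column Gram matrix.

    Returns eigenvalues, block contribution fractions per axis, and scores.
    """
    X = np.hstack([A, w * B])
    Xc = X - X.mean(axis=0)
    n = Xc.shape[0]
    C = (Xc.T @ Xc) / (n - 1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1][:n_axes]
    lam = np.maximum(evals[order], 0.0)
    V = evecs[:, order]
    geno_frac = (V[: A.shape[1]] ** 2).sum(axis=0)  # per-axis, in [0, 1]
    scores = Xc @ V
    return lam, geno_frac, scores


def _cumulative_geno_pct(lam: np.ndarray, geno_frac: np.ndarray) -> float:
    tot = lam.sum()
    return 100.0 * float((lam * geno_frac).sum() / tot) if tot > 0 else float("nan")


def hmfa_two_block(
    geno_scores: np.ndarray,
    pheno: PhenotypeTable | np.ndarray,
    n_axes: int = 6,
    target_ratio: tuple[float, float] = (75.0, 25.0),
    tol: float = 1.0,
    max_iter: int = 200,
) -> HMFAResult:
    """Two-block MFA with the phenotype block rescaled to hit a contribution ratio.

    Both blocks are column-standardized and divided by the square root of their
    first principal eigenvalue (the MFA normalization, so neither block dominates
    axis 1 a priori). A scalar weight ``w`` on the phenotype block is then found by
    bisection so that the cumulative genotype:phenotype contributions over the
    first ``n_axes`` axes match ``target_ratio`` within ``tol`` percent. The
    contribution of a block to an axis is the summed squared loadings of its
    columns on that axis.
    """
    A = _standardize(np.asarray(geno_scores, dtype=float))
    B = phenotype_block(pheno) if isinstance(pheno, PhenotypeTable) else _standardize(
        np.asarray(pheno, dtype=float)
    )
    if A.shape[0] != B.shape[0]:
        raise ValueError("blocks must cover the same accessions")
    lam_a, lam_b = _first_eigenvalue(A), _first_eigenvalue(B)
    if lam_a <= 0:
        raise ValueError("genotype block has no variance")
    A = A / np.sqrt(lam_a)
    target = float(target_ratio[0]) / (target_ratio[0] + target_ratio[1]) * 100.0
    if lam_b <= 0:
        raise ValueError(
            "phenotype block has no variance: contributions are 100:0, "
            f"cannot reach {target_ratio[0]:g}:{target_ratio[1]:g}"
        )
    B = B / np.sqrt(lam_b)

    def geno_pct(log_w: float) -> float:
        lam, frac, _ = _mfa_decompose(A, B, 10.0**log_w, n_axes)
        return _cumulative_geno_pct(lam, frac)

    lo, hi = -6.0, 6.0
    g_lo, g_hi = geno_pct(lo), geno_pct(hi)  # decreasing in w
    if not (g_hi - tol <= target <= g_lo + tol):
        raise ValueError(
            f"target genotype contribution {target:.1f}% unattainable; achievable "
            f"range over w in [1e-6, 1e6] is [{g_hi:.1f}%, {g_lo:.1f}%]"
        )
    log_w = 0.0
    for _ in range(max_iter):
        log_w = 0.5 * (lo + hi)
        val = geno_pct(log_w)
        if abs(val - target) <= 0.1 * tol:
            break
        if val > target:
            lo = log_w
        else:
            hi = log_w
    w = 10.0**log_w
    lam, geno_frac, scores = _mfa_decompose(A, B, w, n_axes)
    achieved = _cumulative_geno_pct(lam, geno_frac)
    if abs(achieved - target) > tol:
        raise ValueError(
            f"weight search stalled at {achieved:.2f}% genotype contribution "
            f"(target {target:.2f}% +- {tol:g}%)"
        )
    total_var = lam.sum()
    return HMFAResult(
        scores=scores[:, :n_axes],
        eigenvalues=lam,
        variance_ratio=lam / total_var if total_var > 0 else lam,
        axis_block_contrib=np.column_stack([100 * geno_frac, 100 * (1 - geno_frac)]),
        cumulative_contrib=(achieved, 100.0 - achieved),
        phenotype_weight=w,
        n_axes=n_axes,
    )


# ---------------------------------------------------------------------------
# Ward-MLM: Ward-initialized Gaussian mixture with model selection
# ---------------------------------------------------------------------------

@dataclass
class MixtureFit:
    """Selected Gaussian-mixture model plus per-candidate selection scores."""

    n_groups: int
    means: np.ndarray
    covariance: np.ndarray
    weights: np.ndarray
    responsibilities: np.ndarray
    assignment: GroupAssignment
    log_likelihood: float
    loglik_trace: list[float]
    selection_scores: dict[int, float]
    criterion: str


def _init_from_labels(X: np.ndarray, labels: np.ndarray, covariance: str, reg: float):
    G = labels.max()
    d = X.shape[1]
    means = np.vstack([X[labels == g + 1].mean(axis=0) for g in range(G)])
    weights = np.array([(labels == g + 1).mean() for g in range(G)])
    pooled = np.cov(X.T, ddof=0) + reg * np.eye(d)
    if covariance == "tied":
        prec = np.linalg.inv(pooled)
    elif covariance == "diag":
        prec = np.vstack([
            1.0 / (X[labels == g + 1].var(axis=0) + reg) for g in range(G)
        ])
    else:
        raise ValueError(f"unsupported covariance {covariance!r}")
    return means, weights, prec


def _fit_em(
    X: np.ndarray, labels: np.ndarray, covariance: str, seed: int,
    reg: float, tol: float, max_iter: int,
) -> tuple[GaussianMixture, list[float]]:
    """EM from a Ward initialization, tracking the log-likelihood per iteration."""
    means, weights, prec = _init_from_labels(X, labels, covariance, reg)
    gm = GaussianMixture(
        n_components=len(weights),
        covariance_type=covariance,
        means_init=means,
        weights_init=weights,
        precisions_init=prec,
        reg_covar=reg,
        max_iter=1,
        warm_start=True,
        random_state=seed,
        n_init=1,
    )
    trace: list[float] = []
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*did not converge.*")
        warnings.filterwarnings("ignore", category=UserWarning)
        for _ in range(max_iter):
            gm.fit(X)
            ll = float(gm.score(X) * X.shape[0])
            if trace and ll - trace[-1] < tol:
                trace.append(ll)
                break
            trace.append(ll)
    return gm, trace


def ward_mlm_cluster(
    scores: np.ndarray | HMFAResult,
    g_range: Sequence[int] | range = range(1, 11),
    seed: int = 0,
    covariance: str = "tied",
    criterion: str = "bic",
    reg: float = 1e-6,
    tol: float = 1e-4,
    max_iter: int = 200,
    accession_ids: Sequence[str] | None = None,
) -> MixtureFit:
    """Two-stage Ward-MLM clustering over candidate group counts.

    Stage 1 cuts a Ward dendrogram of the axis scores at each candidate G; stage 2
    refines each partition by Gaussian-mixture EM (shared full covariance by
    default). Model selection is by BIC (default) or by a log-likelihood plateau
    rule (``criterion='loglik'``: smallest G whose relative gain over G-1 falls
    below 1%). Deterministic given the seed.
    """
    X = scores.scores if isinstance(scores, HMFAResult) else np.asarray(scores, float)
    n = X.shape[0]
    if accession_ids is None:
        accession_ids = [str(i) for i in range(n)]
    Z = linkage(X, method="ward")
    fits: dict[int, tuple[GaussianMixture, list[float]]] = {}
    scores_by_g: dict[int, float] = {}
    logliks: dict[int, float] = {}
    for G in g_range:
        if G < 1 or G > n:
            raise ValueError(f"candidate group count {G} out of range")
        labels = fcluster(Z, t=G, criterion="maxclust") if G > 1 else np.ones(n, int)
        gm, trace = _fit_em(X, labels, covariance, seed, reg, tol, max_iter)
        fits[G] = (gm, trace)
        logliks[G] = trace[-1]
        scores_by_g[G] = float(gm.bic(X)) if criterion == "bic" else -trace[-1]
    if criterion == "bic":
        best = min(scores_by_g, key=lambda g: (scores_by_g[g], g))
    elif criterion == "loglik":
        gs = sorted(logliks)
        best = gs[-1]
        for prev, cur in zip(gs, gs[1:]):
            gain = (logliks[cur] - logliks[prev]) / max(abs(logliks[prev]), 1e-12)
            if gain < 0.01:
                best = prev
                break
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    gm, trace = fits[best]
    resp = gm.predict_proba(X)
    hard = resp.argmax(axis=1)
    cov = gm.covariances_
    return MixtureFit(
        n_groups=best,
        means=gm.means_,
        covariance=cov,
        weights=gm.weights_,
        responsibilities=resp,
        assignment=GroupAssignment.from_arrays(
            list(accession_ids), [f"MG{h + 1:02d}" for h in hard], provenance="mixture"
        ),
        log_likelihood=trace[-1],
        loglik_trace=trace,
        selection_scores=scores_by_g,
        criterion=criterion,
    )


# ---------------------------------------------------------------------------
# Gower distance
# ---------------------------------------------------------------------------

def _gower_accumulate(sim: np.ndarray, wsum: np.ndarray, values: np.ndarray,
                      kind: str, weight: float) -> None:
    present = ~np.isnan(values)
    both = present[:, None] & present[None, :]
    if kind == "categorical":
        s = (values[:, None] == values[None, :]).astype(float)
    else:
        rng = np.nanmax(values) - np.nanmin(values)
        if rng == 0:
            s = np.ones((len(values), len(values)))
        else:
            s = 1.0 - np.abs(values[:, None] - values[None, :]) / rng
    sim += weight * np.where(both, s, 0.0)
    wsum += weight * both


def gower_distance(
    geno: GenotypeMatrix | None = None,
    pheno: PhenotypeTable | None = None,
    weights: dict[str, float] | None = None,
    ids: Sequence[str] | None = None,
) -> DistanceMatrix:
    """Gower's mixed-variable distance over marker and/or trait columns.

    Marker calls are categorical (similarity 1 on an exact genotype match, else 0);
    continuous and ordinal traits use the range-normalized similarity
    ``1 - |x_i - x_j| / range``. The distance is one minus the weighted mean
    similarity over the variables observed in both records, hence always in [0, 1].
    """
    if geno is None and pheno is None:
        raise ValueError("need at least one block")
    if geno is not None and pheno is not None and geno.accession_ids != pheno.accession_ids:
        raise ValueError("genotype and phenotype accession order differ")
    if ids is None:
        ids = geno.accession_ids if geno is not None else list(pheno.accession_ids)
    n = len(ids)
    sim = np.zeros((n, n))
    wsum = np.zeros((n, n))
    if geno is not None:
        calls = geno.calls.astype(float)
        calls[geno.missing_mask] = np.nan
        for j, mk in enumerate(geno.markers):
            w = 1.0 if weights is None else weights.get(mk.marker_id, 1.0)
            _gower_accumulate(sim, wsum, calls[:, j], "categorical", w)
    if pheno is not None:
        for trait in pheno.traits:
            w = 1.0 if weights is None else weights.get(trait, 1.0)
            _gower_accumulate(sim, wsum, pheno.data[trait].to_numpy(float), "continuous", w)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - sim / wsum
    d[wsum == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(ids), np.clip(d, 0.0, 1.0), pair_counts=wsum)


def axis_gower(
    scores: np.ndarray | HMFAResult,
    axis_weights: np.ndarray | None = None,
    ids: Sequence[str] | None = None,
) -> DistanceMatrix:
    """Gower distance over factor-analysis axes (continuous variables).

    Each axis contributes the range-normalized absolute difference, weighted by
    ``axis_weights`` (default: the axis variance shares when an
    :class:`HMFAResult` is given, else uniform). This is the selection-stage
    distance used on large panels, where a raw marker-level Gower matrix per
    candidate would be intractable.
    """
    if isinstance(scores, HMFAResult):
        if axis_weights is None:
            axis_weights = scores.variance_ratio
        scores = scores.scores
    X = np.asarray(scores, dtype=float)
    n, k = X.shape
    w = np.ones(k) if axis_weights is None else np.asarray(axis_weights, float)
    rng = X.max(axis=0) - X.min(axis=0)
    rng[rng == 0] = 1.0
    d = np.zeros((n, n))
    for j in range(k):
        d += w[j] * np.abs(X[:, j, None] - X[None, :, j]) / rng[j]
    d /= w.sum()
    np.fill_diagonal(d, 0.0)
    if ids is None:
        ids = [str(i) for i in range(n)]
    return DistanceMatrix(list(ids), d)


# ---------------------------------------------------------------------------
# D-method allocation
# ---------------------------------------------------------------------------

@dataclass
class AllocationPlan:
    """Per-group core quotas, proportional to within-group Gower diversity."""

    quotas: dict[str, int]
    diversity: dict[str, float]
    members: dict[str, list[str]]
    core_size: int

    def __post_init__(self) -> None:
        if sum(self.quotas.values()) != self.core_size:
            raise ValueError("quotas do not sum to the core size")
        for k, q in self.quotas.items():
            if q < 0 or q > len(self.members[k]):
                raise ValueError(f"group {k}: quota {q} out of range")


def d_method_allocation(
    groups: GroupAssignment, d: DistanceMatrix, core_size: int
) -> AllocationPlan:
    """Allocate core quotas proportional to group diversity (mean within-group
    Gower distance), by largest-remainder rounding, clamped at group sizes with
    iterative redistribution; non-empty groups get at least one slot when the core
    is large enough.
    """
    parts = {k: v for k, v in groups.groups().items()}
    names = sorted(parts)
    lookup = {a: i for i, a in enumerate(d.ids)}
    n_total = sum(len(v) for v in parts.values())
    if not 0 < core_size <= n_total:
        raise ValueError("core_size out of range")
    div: dict[str, float] = {}
    for k in names:
        idx = np.array([lookup[a] for a in parts[k]])
        if len(idx) < 2:
            div[k] = 0.0
        else:
            sub = d.values[np.ix_(idx, idx)]
            iu = np.triu_indices(len(idx), k=1)
            div[k] = float(np.nanmean(sub[iu]))

    sizes = {k: len(parts[k]) for k in names}
    quotas = {k: 0 for k in names}
    active = list(names)
    remaining = core_size
    total_div = sum(div[k] for k in active)
    # all-equal (or all-zero) diversity degenerates to equal apportionment
    while remaining > 0 and active:
        if total_div > 0:
            shares = np.array([remaining * div[k] / total_div for k in active])
        else:
            shares = np.full(len(active), remaining / len(active))
        alloc = largest_remainder(shares, remaining)
        overflow = False
        for k, q in zip(list(active), alloc):
            room = sizes[k] - quotas[k]
            take = min(int(q), room)
            quotas[k] += take
            remaining -= take
            if quotas[k] >= sizes[k]:
                active.remove(k)
                total_div -= div[k]
                overflow = True
        if not overflow and remaining > 0:  # pragma: no cover - safety valve
            break
    # minimum-quota rule: each non-empty group keeps at least one slot if feasible
    if core_size >= len(names):
        for k in names:
            while quotas[k] == 0:
                donor = max(
                    (kk for kk in names if quotas[kk] > 1), key=lambda kk: quotas[kk],
                    default=None,
                )
                if donor is None:
                    break
                quotas[donor] -= 1
                quotas[k] += 1
    return AllocationPlan(quotas=quotas, diversity=div, members=parts, core_size=core_size)


# ---------------------------------------------------------------------------
# stratified max-Gower search
# ---------------------------------------------------------------------------

@dataclass
class CoreSet:
    """A selected core subset with its provenance."""

    accession_ids: list[str]
    mean_gower: float
    candidate_index: int
    plan: AllocationPlan
    seed: int
    n_candidates: int = 1


def _mean_pairwise(d: np.ndarray, idx: np.ndarray) -> float:
    sub = d[np.ix_(idx, idx)]
    k = len(idx)
    if k < 2:
        return 0.0
    iu = np.triu_indices(k, 1)
    return float(np.nanmean(sub[iu]))


def stratified_core_search(
    plan: AllocationPlan,
    d: DistanceMatrix,
    n_candidates: int = 1000,
    seed: int = 0,
) -> CoreSet:
    """Sample stratified candidate subsets; keep the one with maximum mean distance.

    Each candidate draws ``quota_k`` accessions uniformly without replacement
    within group k. The score is the mean pairwise distance within the candidate;
    ties go to the lowest candidate index. Reproducible from the seed.
    """
    if n_candidates < 1:
        raise ValueError("need at least one candidate")
    rng = np.random.default_rng(seed)
    lookup = {a: i for i, a in enumerate(d.ids)}
    group_idx = {
        k: np.array([lookup[a] for a in members], dtype=np.intp)
        for k, members in plan.members.items()
    }
    best_score, best_idx, best_i = -np.inf, None, -1
    for i in range(n_candidates):
        pieces = [
            rng.choice(group_idx[k], size=q, replace=False)
            for k, q in sorted(plan.quotas.items())
            if q > 0
        ]
        idx = np.concatenate(pieces)
        score = _mean_pairwise(d.values, idx)
        if score > best_score:
            best_score, best_idx, best_i = score, idx, i
    ids = [d.ids[j] for j in np.sort(best_idx)]
    return CoreSet(
        accession_ids=ids,
        mean_gower=best_score,
        candidate_index=best_i,
        plan=plan,
        seed=seed,
        n_candidates=n_candidates,
    )


# ---------------------------------------------------------------------------
# Monte-Carlo core-size curve
# ---------------------------------------------------------------------------

@dataclass
class CoreSizeCurve:
    """Genetic-variance curve across subsampling levels."""

    levels: np.ndarray  # sampling fractions
    s2: np.ndarray  # aggregated genetic variance per level
    n_reps: int
    statistic: str

    @property
    def argmax_level(self) -> float:
        return float(self.levels[int(np.argmax(self.s2))])

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"level": self.levels, "s2": self.s2})


def simulate_core_size(
    g: GenotypeMatrix,
    levels: Sequence[float] | None = None,
    n_reps: int = 1000,
    statistic: str = "var_p",
    seed: int = 0,
) -> CoreSizeCurve:
    """Monte-Carlo subsampling curve of genetic variance vs core size.

    At each level (default 5%..100% in 5% steps) draw ``n_reps`` subsamples
    without replacement, estimate per-marker allele frequencies per replicate, and
    aggregate across markers:

    - ``var_p``: mean over markers of the across-replicate variance of p. This is
      the sampling variance of the frequency estimate and decreases monotonically
      toward 0 at the 100% level.
    - ``fst``: mean over markers of var(p) / (p_bar * q_bar) — the f_ST-style
      standardized frequency-difference statistic across the replicate populations.

    Markers with undefined values (no calls in a replicate, or monomorphic mean
    frequency under ``fst``) are excluded from the marker average.
    """
    if levels is None:
        levels = np.arange(5, 101, 5) / 100.0
    levels = np.asarray(levels, dtype=float)
    if statistic not in ("var_p", "fst"):
        raise ValueError(f"unknown statistic {statistic!r}")
    rng = np.random.default_rng(seed)
    n = g.n_accessions
    present = (g.calls != MISSING)
    dos = np.where(present, g.calls, 0).astype(np.float64)
    presentf = present.astype(np.float64)
    s2 = np.empty(len(levels))
    for li, frac in enumerate(levels):
        size = max(1, int(round(frac * n)))
        sel = np.zeros((n_reps, n))
        for r in range(n_reps):
            sel[r, rng.choice(n, size=size, replace=False)] = 1.0
        alt = sel @ dos  # reps x markers: summed dosages
        cnt = sel @ presentf  # reps x markers: non-missing calls
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(cnt > 0, alt / (2.0 * cnt), np.nan)
        var_p = np.nanvar(p, axis=0, ddof=0)
        if statistic == "var_p":
            vals = var_p
        else:
            p_bar = np.nanmean(p, axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                vals = var_p / (p_bar * (1.0 - p_bar))
        s2[li] = float(np.nanmean(vals))
    return CoreSizeCurve(levels=levels, s2=s2, n_reps=n_reps, statistic=statistic)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class CoreSelectionResult:
    core: CoreSet
    hmfa: HMFAResult
    mixture: MixtureFit
    plan: AllocationPlan
    distance: DistanceMatrix


def select_core(
    g: GenotypeMatrix,
    pheno: PhenotypeTable,
    core_fraction: float = 0.15,
    n_geno_components: int = 50,
    n_axes: int = 6,
    target_ratio: tuple[float, float] = (75.0, 25.0),
    g_range: Sequence[int] | range = range(2, 13),
    n_candidates: int = 1000,
    seed: int = 0,
    criterion: str = "bic",
) -> CoreSelectionResult:
    """Full mixed-variable core selection on one genotype + phenotype panel.

    Chains PCA reduction, contribution-targeted two-block MFA, Ward-MLM mixture
    grouping, D-method allocation on the axis-level Gower distance, and the
    stratified max-Gower candidate search. All stochastic stages derive their
    seeds from ``seed``.
    """
    if g.accession_ids != pheno.accession_ids:
        raise ValueError("genotype and phenotype accession order differ")
    core_size = max(1, int(round(core_fraction * g.n_accessions)))
    scores, _ = pca_reduce(g, n_components=min(n_geno_components, min(g.calls.shape) - 1),
                           random_state=seed)
    hmfa = hmfa_two_block(scores, pheno, n_axes=n_axes, target_ratio=target_ratio)
    mixture = ward_mlm_cluster(
        hmfa, g_range=g_range, seed=seed, criterion=criterion,
        accession_ids=g.accession_ids,
    )
    dist = axis_gower(hmfa, ids=g.accession_ids)
    plan = d_method_allocation(mixture.assignment, dist, core_size)
    core = stratified_core_search(plan, dist, n_candidates=n_candidates, seed=seed + 1)
    return CoreSelectionResult(core=core, hmfa=hmfa, mixture=mixture, plan=plan, distance=dist)
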