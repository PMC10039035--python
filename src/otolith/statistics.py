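"""Shape statistics: PCA, OLS batteries, integration and modularity tests.

Integration between landmark blocks is measured by two-block partial least
squares (2B-PLS): the SVD of the cross-block covariance matrix of the
superimposed coordinates, with r-PLS the Pearson correlation of the first
pair of block scores and a permutation null built by shuffling specimen rows
of one block.  Modularity is measured by the covariance ratio
CR = ||S_AB||_F / sqrt(||S_AA°||_F ||S_BB°||_F) (° = off-diagonal elements
only), with a null built by randomly reassigning landmarks to modules of the
original sizes; CR < 1 indicates modular structure, so the test is
lower-tailed.  Permutation p-values use the add-one estimator
(1 + #extreme)/(1 + n_perm) and are reproducible given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .landmarks import AlignedShapeSet, LandmarkSetDefinition, centroid_size

__all__ = [
    "PcaResult",
    "OlsFit",
    "IntegrationResult",
    "ModularityResult",
    "shape_pca",
    "ols_regress",
    "regression_battery",
    "two_block_pls",
    "modularity_cr",
    "wilcoxon_rank_sum",
]


@dataclass
class PcaResult:
    """PCA of flattened Procrustes coordinates (centered SVD)."""

    scores: np.ndarray  # (n, c)
    loadings: np.ndarray  # (c, 3k) orthonormal rows
    eigenvalues: np.ndarray  # descending, non-negative

    @property
    def explained_ratio(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        return self.eigenvalues / tot if tot > 0 else self.eigenvalues

    def pc(self, i: int = 0) -> np.ndarray:
        return self.scores[:, i]


def shape_pca(block: AlignedShapeSet | np.ndarray) -> PcaResult:
    """Principal components of shape for one (jointly aligned) block.

    The sign of each loading is fixed so its largest-magnitude element is
    positive, making downstream PC1 regressions sign-stable across runs.
    """
    X = block.flat() if isinstance(block, AlignedShapeSet) else np.asarray(block, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("shape PCA needs at least 3 specimens")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s ** 2 / (n - 1)
    # deterministic sign: largest-|.| element of each loading positive
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    scores = Xc @ Vt.T
    return PcaResult(scores=scores, loadings=Vt, eigenvalues=eig)


@dataclass
class OlsFit:
    """Simple bivariate OLS fit with the F-test of zero slope."""

    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    p_value: float
    n: int


def ols_regress(x: np.ndarray, y: np.ndarray) -> OlsFit:
    """Least-squares line of y on x; two-sided p from F(1, n-2)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    n = x.size
    if n < 3:
        raise ValueError("regression needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("explanatory variable is constant")
    res = sps.linregress(x, y)
    r2 = float(res.rvalue ** 2)
    # F for the 1-df slope test equals t^2; identical p-value
    with np.errstate(divide="ignore"):
        f = float(res.slope ** 2 / res.stderr ** 2) if res.stderr > 0 else np.inf
    return OlsFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        f_statistic=f,
        p_value=float(res.pvalue),
        n=n,
    )


# ---------------------------------------------------------------------------
# regression batteries (PC1 models and log centroid-size models)
# ---------------------------------------------------------------------------

@dataclass
class BatteryRow:
    set_id: str
    response: str
    predictor: str
    statistic: str  # "pc1" or "log_centroid_size"
    fit: OlsFit | None
    error: str | None = None


def _subset_coords(aligned: AlignedShapeSet, labels: list[str]) -> AlignedShapeSet:
    idx = []
    missing = []
    for lab in labels:
        try:
            idx.append(aligned.labels.index(lab))
        except ValueError:
            missing.append(lab)
    if missing:
        raise KeyError(f"labels missing: {missing}")
    return aligned.take(np.asarray(idx, dtype=int))


def _statistic_vector(aligned: AlignedShapeSet, labels: list[str], statistic: str) -> np.ndarray:
    view = _subset_coords(aligned, labels)
    if statistic == "pc1":
        return shape_pca(view).pc(0)
    if statistic == "log_centroid_size":
        # sizes in the original mm frame: rescale aligned coords by the
        # stored pre-scaling centroid sizes of the full configuration
        full_cs = view.centroid_sizes
        vals = np.array(
            [centroid_size(view.coords[i] * full_cs[i]) for i in range(view.n)]
        )
        return np.log(vals)
    raise ValueError(f"unknown statistic {statistic!r}")


def regression_battery(
    aligned: AlignedShapeSet,
    rows: list[tuple[str, list[str], list[str], str]],
) -> pd.DataFrame:
    """Run a battery of OLS models over landmark subsets.

    Each row is (set_id, response_labels, predictor_labels, statistic) with
    statistic one of ``pc1`` or ``log_centroid_size`` (natural log applied to
    centroid sizes only).  Failures are recorded per row; the battery
    continues.
    """
    records = []
    for set_id, resp_labels, pred_labels, statistic in rows:
        rec = {
            "set_id": set_id,
            "response": "+".join(resp_labels[:4]) + ("..." if len(resp_labels) > 4 else ""),
            "predictor": "+".join(pred_labels[:4]) + ("..." if len(pred_labels) > 4 else ""),
            "statistic": statistic,
        }
        try:
            if not resp_labels or not pred_labels:
                raise ValueError("empty landmark subset")
            y = _statistic_vector(aligned, resp_labels, statistic)
            x = _statistic_vector(aligned, pred_labels, statistic)
            fit = ols_regress(x, y)
            rec.update(
                slope=fit.slope, intercept=fit.intercept, r_squared=fit.r_squared,
                f_statistic=fit.f_statistic, p_value=fit.p_value, n=fit.n, error="",
            )
        except Exception as exc:  # noqa: BLE001 - battery must continue
            rec.update(
                slope=np.nan, intercept=np.nan, r_squared=np.nan,
                f_statistic=np.nan, p_value=np.nan, n=aligned.n, error=str(exc),
            )
        records.append(rec)
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# integration (2B-PLS) and modularity (CR)
# ---------------------------------------------------------------------------

@dataclass
class IntegrationResult:
    r_pls: float
    effect_size_z: float
    p_value: float
    n_permutations: int
    left_vector: np.ndarray
    right_vector: np.ndarray
    permutation_mean: float
    permutation_sd: float
    seed: int


@dataclass
class ModularityResult:
    cr: float
    p_value: float
    effect_size_z: float
    n_permutations: int
    module_assignment: np.ndarray
    permutation_mean: float
    permutation_sd: float
    seed: int


def _first_pls_pair(A: np.ndarray, B: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """r-PLS and first singular vectors of the cross-block covariance."""
    C = A.T @ B / (A.shape[0] - 1)
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    u, v = U[:, 0], Vt[0]
    # deterministic sign
    iu = int(np.argmax(np.abs(u)))
    if u[iu] < 0:
        u, v = -u, -v
    sa, sb = A @ u, B @ v
    return _pearson(sa, sb), u, v


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt(np.dot(xc, xc) * np.dot(yc, yc))
    return float(np.dot(xc, yc) / denom) if denom > 0 else 0.0


def two_block_pls(
    block_a: np.ndarray | AlignedShapeSet,
    block_b: np.ndarray | AlignedShapeSet,
    n_perm: int = 10_000,
    seed: int = 0,
) -> IntegrationResult:
    """Two-block PLS test of integration between two landmark blocks.

    The observed statistic is the correlation of the first-pair block scores
    (r-PLS).  The null permutes specimen rows of block B; the upper-tail
    add-one p-value and the effect size z = (obs - mean)/sd of the permuted
    distribution are reported.
    """
    A = block_a.flat() if isinstance(block_a, AlignedShapeSet) else np.asarray(block_a, dtype=float)
    B = block_b.flat() if isinstance(block_b, AlignedShapeSet) else np.asarray(block_b, dtype=float)
    if A.shape[0] != B.shape[0]:
        raise ValueError("blocks must be row-matched by specimen")
    n = A.shape[0]
    if n < 4:
        raise ValueError("2B-PLS needs n >= 4 specimens")
    if n_perm < 99:
        warnings.warn("n_perm < 99 gives a very coarse permutation p-value", stacklevel=2)
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    if not (A.std(axis=0).max() > 0 and B.std(axis=0).max() > 0):
        raise ValueError("zero-variance block")
    r_obs, u, v = _first_pls_pair(A, B)
    rng = np.random.default_rng(seed)
    # permutation loop in the n-dimensional row spaces: with thin SVDs
    # A = Ua Sa Va', B = Ub Sb Vb', the cross-covariance of A and the
    # row-permuted B has the same singular structure as the small matrix
    # Sa (Ua' P Ub) Sb, so each permutation needs only an
    # min(n,p) x min(n,q) SVD
    Ua, sa, _ = np.linalg.svd(A, full_matrices=False)
    Ub, sb, _ = np.linalg.svd(B, full_matrices=False)
    ka, kb = int(np.sum(sa > 1e-12 * sa[0])), int(np.sum(sb > 1e-12 * sb[0]))
    Ua, sa, Ub, sb = Ua[:, :ka], sa[:ka], Ub[:, :kb], sb[:kb]
    perm_stats = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        M = sa[:, None] * (Ua.T @ Ub[perm]) * sb[None, :]
        mu, _, mvt = np.linalg.svd(M)
        perm_stats[i] = _pearson(Ua @ (sa * mu[:, 0]), Ub[perm] @ (sb * mvt[0]))
    p = (1 + np.sum(perm_stats >= r_obs)) / (n_perm + 1)
    sd = perm_stats.std()
    z = float((r_obs - perm_stats.mean()) / sd) if sd > 0 else 0.0
    return IntegrationResult(
        r_pls=r_obs,
        effect_size_z=z,
        p_value=float(p),
        n_permutations=n_perm,
        left_vector=u,
        right_vector=v,
        permutation_mean=float(perm_stats.mean()),
        permutation_sd=float(sd),
        seed=seed,
    )


def _cr_statistic(S: np.ndarray, module_a: np.ndarray) -> float:
    """Covariance ratio for a joint covariance matrix and a landmark split.

    ``S`` is the (3k, 3k) covariance of the flattened joint block;
    ``module_a`` is a boolean landmark mask of length k.  The denominators
    exclude each landmark's own 3x3 covariance block (the "diagonal"), which
    makes CR invariant to rotations of the joint configuration — a scalar
    diagonal exclusion would not be, since rotations mix a landmark's x/y/z
    components.  The covariance itself is permutation-invariant, so the same
    S serves every partition.
    """
    cols_a = np.repeat(module_a, 3)
    S_ab = S[np.ix_(cols_a, ~cols_a)]
    S_aa = S[np.ix_(cols_a, cols_a)].copy()
    S_bb = S[np.ix_(~cols_a, ~cols_a)].copy()
    for M in (S_aa, S_bb):
        kk = M.shape[0] // 3
        for j in range(kk):
            M[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] = 0.0
    denom = np.sqrt(np.linalg.norm(S_aa) * np.linalg.norm(S_bb))
    if denom == 0:
        return np.inf
    return float(np.linalg.norm(S_ab) / denom)


def modularity_cr(
    block_a: np.ndarray | AlignedShapeSet,
    block_b: np.ndarray | AlignedShapeSet,
    n_perm: int = 10_000,
    seed: int = 0,
) -> ModularityResult:
    """Covariance-ratio test of modularity between two landmark modules.

    Blocks are (n, k, 3) landmark arrays (or aligned views).  Landmarks — not
    individual coordinates — are the permutable units: the null reassigns
    landmarks at random to modules of the original sizes.  Small CR indicates
    modularity, so p is the lower-tail fraction of permuted CR <= observed
    (add-one estimator).
    """
    Ka = block_a.coords if isinstance(block_a, AlignedShapeSet) else np.asarray(block_a, dtype=float)
    Kb = block_b.coords if isinstance(block_b, AlignedShapeSet) else np.asarray(block_b, dtype=float)
    if Ka.ndim != 3 or Kb.ndim != 3:
        raise ValueError("modularity blocks must be (n, k, 3) landmark arrays")
    if Ka.shape[0] != Kb.shape[0]:
        raise ValueError("blocks must be row-matched by specimen")
    ka, kb = Ka.shape[1], Kb.shape[1]
    if min(ka, kb) < 2:
        raise ValueError("each module needs at least 2 landmarks")
    n = Ka.shape[0]
    joint = np.concatenate([Ka, Kb], axis=1)  # (n, ka+kb, 3)
    X = joint.reshape(n, -1)
    S = np.cov(X, rowvar=False)
    module_a = np.zeros(ka + kb, dtype=bool)
    module_a[:ka] = True
    cr_obs = _cr_statistic(S, module_a)
    rng = np.random.default_rng(seed)
    perm_stats = np.empty(n_perm)
    for i in range(n_perm):
        perm_mask = np.zeros(ka + kb, dtype=bool)
        perm_mask[rng.choice(ka + kb, size=ka, replace=False)] = True
        perm_stats[i] = _cr_statistic(S, perm_mask)
    p = (1 + np.sum(perm_stats <= cr_obs)) / (n_perm + 1)
    sd = perm_stats.std()
    z = float((cr_obs - perm_stats.mean()) / sd) if sd > 0 else 0.0
    return ModularityResult(
        cr=cr_obs,
        p_value=float(p),
        effect_size_z=z,
        n_permutations=n_perm,
        module_assignment=module_a,
        permutation_mean=float(perm_stats.mean()),
        permutation_sd=float(sd),
        seed=seed,
    )


def integration_for_set(
    aligned: AlignedShapeSet,
    setdef: LandmarkSetDefinition,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[IntegrationResult, ModularityResult]:
    """2B-PLS and CR for one landmark-set definition's two modules."""
    from .landmarks import subset_blocks

    views = subset_blocks(aligned, setdef)
    names = list(views)
    if len(names) != 2:
        raise ValueError(f"landmark set {setdef.set_id} does not define exactly 2 modules")
    a, b = views[names[0]], views[names[1]]
    integ = two_block_pls(a, b, n_perm=n_perm, seed=seed)
    mod = modularity_cr(a, b, n_perm=n_perm, seed=seed)
    return integ, mod


# ---------------------------------------------------------------------------
# rank-sum comparison
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    continuity: bool = True,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses exact enumeration when both samples have n <= 8 and there are no
    ties, otherwise the normal approximation with midranks and (optionally)
    continuity correction.  Returns (rank-sum statistic U of sample_a, p).
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical across both samples; p = 1", stacklevel=2)
        return float(a.size * b.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if a.size <= 8 and b.size <= 8 and not has_ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic",
            use_continuity=continuity,
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))
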