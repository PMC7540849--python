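"""Correlation-matrix PCA with Kaiser retention and varimax rotation.

For each species x cultivation subset the trait matrix holds nine
standardized variables per half-pot: the four interval relative growth
rates, absolute growth, shoot N and P concentrations, and soil extractable
N and P.  Components are retained when their eigenvalue exceeds 1 (Kaiser
criterion, strict), the retained loadings are varimax-rotated (Kaiser
normalized, iterative pairwise planar rotations), and rotated loadings with
magnitude below 0.30 are masked as not significant in the report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PcaResult",
    "DEFAULT_VARIABLES",
    "build_trait_matrix",
    "pca",
    "varimax",
    "loading_report",
    "pca_report",
]

DEFAULT_VARIABLES = (
    "RGR_35_40",
    "RGR_40_50",
    "RGR_50_60",
    "RGR_60_70",
    "AG",
    "shoot_n",
    "shoot_p",
    "soil_n",
    "soil_p",
)

LOADING_THRESHOLD = 0.30


@dataclass
class PcaResult:
    variables: list[str]
    eigenvalues: np.ndarray
    loadings: np.ndarray  # unrotated, variables x components (all components)
    n_retained: int
    rotated: np.ndarray | None  # variables x retained components
    rotation: np.ndarray | None  # retained x retained orthogonal matrix
    communalities: np.ndarray  # over retained components
    variance_explained: np.ndarray  # eigenvalue / n_variables, all components
    n_obs: int


def build_trait_matrix(
    joined: pd.DataFrame, variables: tuple[str, ...] = DEFAULT_VARIABLES
) -> pd.DataFrame:
    """Listwise-delete missing cells and check column variability."""
    m = joined[list(variables)].dropna(axis=0, how="any")
    if len(m) < 2:
        raise ValueError("fewer than 2 complete rows after listwise deletion")
    sds = m.std(ddof=1)
    constant = sds[sds == 0].index.tolist()
    if constant:
        raise ValueError(f"constant column(s) {constant} cannot be standardized")
    return m


def pca(matrix: pd.DataFrame | np.ndarray) -> PcaResult:
    """Eigendecomposition of the correlation matrix.

    Loadings are eigenvectors scaled by sqrt(eigenvalue), so the squared
    loadings of a variable sum to 1 over all components and the retained-
    component row sums are the communalities.  Components with eigenvalue
    strictly greater than 1 are retained.
    """
    if isinstance(matrix, pd.DataFrame):
        variables = list(matrix.columns)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        variables = [f"v{i+1}" for i in range(X.shape[1])]
    n, k = X.shape
    if n < 2:
        raise ValueError("need at least 2 rows")
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        raise ValueError("constant column in trait matrix")
    Xs = (X - X.mean(axis=0)) / sds
    corr = (Xs.T @ Xs) / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # sign convention: largest-magnitude element of each eigenvector positive
    for j in range(k):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    loadings = eigvec * np.sqrt(eigval)
    # strict Kaiser rule, with a tolerance so an exactly-unit eigenvalue
    # perturbed by floating-point noise is not retained
    n_ret = int(np.sum(eigval > 1.0 + 1e-9))
    result = PcaResult(
        variables=variables,
        eigenvalues=eigval,
        loadings=loadings,
        n_retained=n_ret,
        rotated=None,
        rotation=None,
        communalities=np.sum(loadings[:, :max(n_ret, 1)] ** 2, axis=1),
        variance_explained=eigval / k,
        n_obs=n,
    )
    if n_ret == 0:
        warnings.warn(
            "no component has eigenvalue > 1; reporting the unrotated solution",
            stacklevel=2,
        )
        return result
    if n_ret == 1:
        result.rotated = loadings[:, :1].copy()
        result.rotation = np.eye(1)
    else:
        rot, R = varimax(loadings[:, :n_ret])
        result.rotated = rot
        result.rotation = R
    result.communalities = np.sum(result.rotated**2, axis=1)
    return result


def _varimax_criterion(L: np.ndarray) -> float:
    """Sum over factors of the variance of squared loadings."""
    sq = L**2
    return float(np.sum(sq**2) / L.shape[0] - np.sum((sq.mean(axis=0)) ** 2))


def varimax(
    loadings: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 1000,
    kaiser_normalize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal varimax rotation by iterative pairwise planar rotations.

    Maximizes the varimax criterion (variance of squared loadings summed
    over factors), with rows optionally Kaiser-normalized to unit
    communality during rotation.  For each factor pair the optimal angle has
    the closed form  phi = atan2(2 sum(u v), sum(u^2 - v^2)) / 4  with
    u = a^2 - b^2, v = 2ab for the pair's loading columns (a, b).  Returns
    (rotated loadings, rotation matrix) with the sign of each column
    normalized so its largest-magnitude loading is positive.
    """
    L = np.asarray(loadings, dtype=float)
    if not np.all(np.isfinite(L)):
        raise ValueError("non-finite loadings")
    p, m = L.shape
    if m < 2:
        return L.copy(), np.eye(m)
    comm = np.sqrt(np.sum(L**2, axis=1))
    if kaiser_normalize:
        safe = np.where(comm > 0, comm, 1.0)
        W = L / safe[:, None]
    else:
        W = L.copy()
    R = np.eye(m)
    last = _varimax_criterion(W)
    for _ in range(max_iter):
        for i in range(m - 1):
            for j in range(i + 1, m):
                a, b = W[:, i], W[:, j]
                u = a**2 - b**2
                v = 2.0 * a * b
                num = 2.0 * (np.sum(u * v) - np.sum(u) * np.sum(v) / p)
                den = np.sum(u**2 - v**2) - (np.sum(u) ** 2 - np.sum(v) ** 2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-14:
                    continue
                c, s = np.cos(phi), np.sin(phi)
                G = np.array([[c, -s], [s, c]])
                W[:, [i, j]] = W[:, [i, j]] @ G
                R[:, [i, j]] = R[:, [i, j]] @ G
        crit = _varimax_criterion(W)
        if crit - last < tol:
            break
        last = crit
    rotated = L @ R
    # sign convention per factor
    for j in range(m):
        i = np.argmax(np.abs(rotated[:, j]))
        if rotated[i, j] < 0:
            rotated[:, j] = -rotated[:, j]
            R[:, j] = -R[:, j]
    return rotated, R


def loading_report(result: PcaResult, threshold: float = LOADING_THRESHOLD) -> pd.DataFrame:
    """Rotated loadings with sub-threshold entries masked (NaN).

    Adds the percent of each variable's variance carried by each retained
    component (squared loading x 100) and flags variables with no
    significant loading on any retained component.
    """
    L = result.rotated if result.rotated is not None else result.loadings[:, : max(result.n_retained, 1)]
    m = L.shape[1]
    out = pd.DataFrame({"variable": result.variables})
    sig_any = np.zeros(len(result.variables), dtype=bool)
    for j in range(m):
        col = L[:, j]
        mask = np.abs(col) >= threshold
        sig_any |= mask
        out[f"PC{j+1}"] = np.where(mask, col, np.nan)
        out[f"PC{j+1}_pct_var"] = col**2 * 100.0
    out["no_significant_component"] = ~sig_any
    return out


def pca_report(
    joined: pd.DataFrame,
    variables: tuple[str, ...] = DEFAULT_VARIABLES,
    threshold: float = LOADING_THRESHOLD,
) -> tuple[PcaResult, pd.DataFrame]:
    """Trait-matrix construction, PCA, rotation and masking in one call."""
    m = build_trait_matrix(joined, variables)
    res = pca(m)
    return res, loading_report(res, threshold)
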