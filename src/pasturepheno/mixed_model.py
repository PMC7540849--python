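"""REML linear mixed models with grouped residual variances.

Half-pot responses y are modelled as

    y = X beta + Z u + e

with fixed effects partitioned as overall mean, replicate, greenhouse-side
and pot-half effects (spatial trend), a species main effect, and a separate
cultivation x nitrogen x phosphorus factorial block per species (main
effects, two-factor and three-factor interactions; the block's columns are
structurally zero for the other species' observations).  Random effects are
main units within replicates and pots within main units.  Residuals are
independent normal with variance allowed to differ between the four
species x nitrogen groups; nested reductions of that grouping (by species
only, by nitrogen only, homogeneous) are compared by residual likelihood
ratio tests with the fixed structure held constant.

Variance parameters are estimated by maximizing the REML log-likelihood over
log-variances with a quasi-Newton iteration (numerically differentiated
L-BFGS-B with multi-start fallback); fixed effects follow by generalized
least squares at the optimum.  Wald F-tests for the per-species factorial
terms use the containment heuristic for denominator degrees of freedom and
the hierarchical gating rule: the three-factor interaction first, two-factor
interactions only if it is not significant, and a main effect only if its
factor occurs in no significant interaction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize, stats

__all__ = [
    "ModelSpec",
    "DesignMatrices",
    "MixedModelFit",
    "VARIANCE_MODELS",
    "FACTORIAL_TERMS",
    "build_design_matrices",
    "fit_reml",
    "fit_trait",
    "simplify_variance",
    "select_variance_model",
    "gate_pvalues",
    "wald_hierarchy",
    "emmeans",
    "compact_letter_display",
]

#: residual-variance grouping options, from richest to most parsimonious
VARIANCE_MODELS = ("full", "species", "nitrogen", "homogeneous")

#: per-species factorial terms in testing order (three-way first)
FACTORIAL_TERMS = ("C*N*P", "C*N", "C*P", "N*P", "C", "N", "P")

_TERM_FACTORS = {
    "C*N*P": ("C", "N", "P"),
    "C*N": ("C", "N"),
    "C*P": ("C", "P"),
    "N*P": ("N", "P"),
    "C": ("C",),
    "N": ("N",),
    "P": ("P",),
}


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: the response column and the residual-variance grouping."""

    response: str = "AG"
    variance_model: str = "full"  # one of VARIANCE_MODELS, or "auto"
    alpha: float = 0.05


@dataclass
class DesignMatrices:
    """Encoded model matrices plus the bookkeeping needed downstream."""

    y: np.ndarray
    X: np.ndarray
    columns: list[str]  # label per X column
    terms: dict[str, list[int]]  # term label -> X column indices
    Z: np.ndarray  # n x q, main-unit columns then pot columns
    z_component: np.ndarray  # 0 = main unit, 1 = pot, per Z column
    group_labels: dict[str, np.ndarray]  # variance model -> group label per obs
    factors: pd.DataFrame  # per-observation factor frame
    pot_codes: np.ndarray
    mainunit_codes: np.ndarray


def _half_coding(values: pd.Series, positive: str) -> np.ndarray:
    return np.where(values == positive, 0.5, -0.5)


def _encode_fixed(
    factors: pd.DataFrame, rep_levels: list
) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    """Sum-to-zero / half coding of the fixed-effect partition.

    Factor frame columns: replicate, greenhouse_side, side, species,
    cultivation (mono/mixture), nitrogen, phosphorus.
    """
    n = len(factors)
    cols: list[np.ndarray] = [np.ones(n)]
    labels: list[str] = ["mu"]
    terms: dict[str, list[int]] = {"mu": [0]}

    # replicate sum-to-zero dummies (absent for a single replicate)
    rep = factors["replicate"].to_numpy()
    idxs = []
    for r in rep_levels[:-1]:
        col = np.where(rep == r, 1.0, np.where(rep == rep_levels[-1], -1.0, 0.0))
        idxs.append(len(cols))
        labels.append(f"R[{r}]")
        cols.append(col)
    terms["R"] = idxs

    for name, colname, positive in (
        ("Si", "greenhouse_side", "E"),
        ("H", "side", "E"),
        ("Sp", "species", "grass"),
    ):
        terms[name] = [len(cols)]
        labels.append(name)
        cols.append(_half_coding(factors[colname], positive))

    codes = {
        "C": _half_coding(factors["cultivation"], "mixture"),
        "N": _half_coding(factors["nitrogen"], "H"),
        "P": _half_coding(factors["phosphorus"], "H"),
    }
    for species in ("grass", "legume"):
        ind = (factors["species"] == species).to_numpy(dtype=float)
        for term in ("C", "N", "P", "C*N", "C*P", "N*P", "C*N*P"):
            col = ind.copy()
            for f in _TERM_FACTORS[term]:
                col = col * codes[f]
            key = f"{species}:{term}"
            terms[key] = [len(cols)]
            labels.append(key)
            cols.append(col)
    return np.column_stack(cols), labels, terms


def build_design_matrices(
    design: pd.DataFrame, data: pd.DataFrame, response: str
) -> DesignMatrices:
    """Join trait data to the design and encode y, X, Z and residual groups.

    ``design`` is the half-pot design table; ``data`` must carry half_pot_id
    and the response column.  Observations missing from ``data`` (excluded
    harvest units) simply drop out.  Structurally zero factorial columns
    (single-species subsets) are removed.
    """
    merged = design.merge(data[["half_pot_id", response]], on="half_pot_id", how="inner")
    orphans = set(data["half_pot_id"]) - set(design["half_pot_id"])
    if orphans:
        raise ValueError(f"observations reference unknown half-pots: {sorted(orphans)[:5]}")
    merged = merged.dropna(subset=[response]).reset_index(drop=True)

    factors = merged[
        ["replicate", "greenhouse_side", "side", "species", "nitrogen", "phosphorus"]
    ].copy()
    factors["cultivation"] = np.where(
        merged["cultivation"] == "mixture", "mixture", "mono"
    )
    rep_levels = sorted(factors["replicate"].unique())

    X, labels, terms = _encode_fixed(factors, rep_levels)
    # full-rank reduction: drop structurally zero columns (the other
    # species' block in a subset) and aliased columns (pivoted QR), keeping
    # earlier terms of the partition in preference to later ones
    keep = [j for j in range(X.shape[1]) if np.any(X[:, j] != 0)]
    r_total = np.linalg.matrix_rank(X[:, keep], tol=1e-8)
    if r_total < len(keep):
        # greedy forward sweep: keep a column iff it adds rank, so earlier
        # terms of the partition take precedence over aliased later ones
        Q = np.zeros((X.shape[0], 0))
        kept = []
        for j in keep:
            c = X[:, j] - Q @ (Q.T @ X[:, j])
            nrm = np.linalg.norm(c)
            if nrm > 1e-8 * max(1.0, np.linalg.norm(X[:, j])):
                Q = np.hstack([Q, (c / nrm)[:, None]])
                kept.append(j)
        keep = kept
    if len(keep) < X.shape[1]:
        remap = {old: new for new, old in enumerate(keep)}
        X = X[:, keep]
        labels = [labels[j] for j in keep]
        terms = {
            t: [remap[j] for j in js if j in remap]
            for t, js in terms.items()
            if any(j in remap for j in js)
        }

    # Z columns for every design main unit and pot, observed or not (an
    # unobserved level's contribution to the REML criterion cancels exactly)
    mu_all = np.unique(design["replicate"].astype(str) + ":" + design["main_unit"].astype(str))
    pot_all = np.unique(design["pot_id"])
    mu_codes = mu_all
    mu_idx = pd.Categorical(
        merged["replicate"].astype(str) + ":" + merged["main_unit"].astype(str),
        categories=mu_all,
    ).codes.astype(int)
    pot_codes = pot_all
    pot_idx = pd.Categorical(merged["pot_id"], categories=pot_all).codes.astype(int)
    Z_mu = np.zeros((len(merged), len(mu_codes)))
    Z_mu[np.arange(len(merged)), mu_idx] = 1.0
    Z_pot = np.zeros((len(merged), len(pot_codes)))
    Z_pot[np.arange(len(merged)), pot_idx] = 1.0
    Z = np.hstack([Z_mu, Z_pot])
    z_component = np.concatenate(
        [np.zeros(len(mu_codes), dtype=int), np.ones(len(pot_codes), dtype=int)]
    )

    sp = factors["species"].to_numpy()
    ni = factors["nitrogen"].to_numpy()
    group_labels = {
        "full": np.char.add(np.char.add(sp.astype(str), ":"), ni.astype(str)),
        "species": sp.astype(str),
        "nitrogen": ni.astype(str),
        "homogeneous": np.full(len(merged), "all"),
    }
    return DesignMatrices(
        y=merged[response].to_numpy(dtype=float),
        X=X,
        columns=labels,
        terms=terms,
        Z=Z,
        z_component=z_component,
        group_labels=group_labels,
        factors=factors,
        pot_codes=pot_idx,
        mainunit_codes=mu_idx,
    )


@dataclass
class MixedModelFit:
    """A converged REML fit and everything downstream stages consume."""

    beta: np.ndarray
    cov_beta: np.ndarray
    columns: list[str]
    terms: dict[str, list[int]]
    var_components: dict[str, float]  # "mainunit", "pot" (absent if no Z)
    resid_vars: dict[str, float]  # residual group label -> sigma^2
    variance_model: str
    loglik: float  # REML log-likelihood at the optimum
    n_variance_params: int
    converged: bool
    gradient_norm: float
    n_obs: int
    matrices: DesignMatrices | None = field(default=None, repr=False)

    @property
    def rank_x(self) -> int:
        return len(self.beta)


class _RemlWorkspace:
    """Per-dataset cross-products so each likelihood evaluation is O(q^3)."""

    def __init__(self, y, X, Z, groups):
        self.n, self.p = X.shape
        self.q = Z.shape[1] if Z is not None and Z.size else 0
        self.y, self.X = y, X
        self.Z = Z if self.q else None
        self.labels = list(dict.fromkeys(groups))  # stable order of appearance
        self.masks = [groups == g for g in self.labels]
        self.parts = []
        for m in self.masks:
            Xg, yg = X[m], y[m]
            Zg = Z[m] if self.q else None
            self.parts.append(
                {
                    "n": int(m.sum()),
                    "XtX": Xg.T @ Xg,
                    "Xty": Xg.T @ yg,
                    "yty": float(yg @ yg),
                    "ZtZ": Zg.T @ Zg if self.q else None,
                    "ZtX": Zg.T @ Xg if self.q else None,
                    "Zty": Zg.T @ yg if self.q else None,
                }
            )

    def neg_reml(self, log_s2_comp, log_s2_groups, z_component, grad: bool = False):
        """-2 x REML log-likelihood (up to the additive constant).

        With ``grad=True`` also returns the analytic gradient with respect to
        the log-variances, from d(-2l)/d phi = tr(P dV) - y'P dV P y with the
        trace terms evaluated through the Woodbury pieces.
        """
        log_s2_comp = np.asarray(log_s2_comp, dtype=float)
        log_s2_groups = np.asarray(log_s2_groups, dtype=float)
        w = np.exp(-log_s2_groups)  # 1/sigma^2_g
        XtVX = sum(wg * p["XtX"] for wg, p in zip(w, self.parts))
        XtVy = sum(wg * p["Xty"] for wg, p in zip(w, self.parts))
        yty = sum(wg * p["yty"] for wg, p in zip(w, self.parts))
        logdet_V = float(sum(p["n"] * ls for ls, p in zip(log_s2_groups, self.parts)))
        chol = None
        if self.q:
            ZtVZ = sum(wg * p["ZtZ"] for wg, p in zip(w, self.parts))
            ZtVX = sum(wg * p["ZtX"] for wg, p in zip(w, self.parts))
            ZtVy = sum(wg * p["Zty"] for wg, p in zip(w, self.parts))
            g_inv = np.exp(-log_s2_comp)[z_component]
            M = ZtVZ + np.diag(g_inv)
            try:
                chol = sla.cho_factor(M, lower=True, check_finite=False)
            except np.linalg.LinAlgError:
                return (1e12, None, None, None) if grad else (1e12, None, None)
            logdet_V += 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
            logdet_V += float(np.sum(log_s2_comp[z_component]))
            MiZtVX = sla.cho_solve(chol, ZtVX, check_finite=False)
            MiZtVy = sla.cho_solve(chol, ZtVy, check_finite=False)
            XtVX = XtVX - ZtVX.T @ MiZtVX
            XtVy = XtVy - ZtVX.T @ MiZtVy
            yty = yty - float(ZtVy @ MiZtVy)
        sign, logdet_XtVX = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return (1e12, None, None, None) if grad else (1e12, None, None)
        beta = np.linalg.solve(XtVX, XtVy)
        yPy = yty - float(XtVy @ beta)
        neg2 = logdet_V + logdet_XtVX + yPy
        if not grad:
            return neg2, beta, XtVX

        n_comp = log_s2_comp.size
        XtVX_inv = np.linalg.inv(XtVX)
        w_obs = np.empty(self.n)
        for wg, m in zip(w, self.masks):
            w_obs[m] = wg
        e = self.y - self.X @ beta
        if self.q:
            Zt_v_pre = sla.cho_solve(
                chol, sum(wg * p["Zty"] for wg, p in zip(w, self.parts)) - (
                    sum(wg * p["ZtX"] for wg, p in zip(w, self.parts)) @ beta
                ),
                check_finite=False,
            )
            v = w_obs * e - w_obs * (self.Z @ Zt_v_pre)
            Q = w_obs[:, None] * self.X - (w_obs[:, None] * self.Z) @ MiZtVX
            Minv = sla.cho_solve(chol, np.eye(self.q), check_finite=False)
            Ztv = self.Z.T @ v
        else:
            v = w_obs * e
            Q = w_obs[:, None] * self.X

        grad_out = np.empty(n_comp + len(self.parts))
        for c in range(n_comp):
            idx = z_component == c
            s2c = float(np.exp(log_s2_comp[c]))
            qc = int(idx.sum())
            tr_W = qc / s2c - float(np.sum(np.diag(Minv)[idx])) / s2c**2
            Sc = self.Z[:, idx].T @ Q  # q_c x p
            tr_X = float(np.sum(XtVX_inv * (Sc.T @ Sc)))
            quad = float(np.sum(Ztv[idx] ** 2))
            grad_out[c] = s2c * (tr_W - tr_X - quad)
        for gi, (m, p_) in enumerate(zip(self.masks, self.parts)):
            s2g = float(np.exp(log_s2_groups[gi]))
            wg = w[gi]
            if self.q:
                tr_W = p_["n"] * wg - wg**2 * float(np.sum(Minv * p_["ZtZ"]))
            else:
                tr_W = p_["n"] * wg
            Qg = Q[m]
            tr_X = float(np.sum(XtVX_inv * (Qg.T @ Qg)))
            quad = float(np.sum(v[m] ** 2))
            grad_out[n_comp + gi] = s2g * (tr_W - tr_X - quad)
        return neg2, beta, XtVX, grad_out


class _BlockRemlWorkspace:
    """Likelihood evaluation exploiting a block-diagonal covariance.

    With nested random effects and independent residuals, V is block
    diagonal over the connected components of observations linked by shared
    random-effect levels (here: main units).  Blocks are padded to a common
    size and evaluated with batched dense algebra; a padded row has unit
    residual variance, zero response and zero design rows, contributing
    nothing to any term.
    """

    def __init__(self, y, X, Z, groups, z_component, blocks):
        self.n, self.p = X.shape
        self.labels = list(dict.fromkeys(groups))
        self.n_comp = int(z_component.max()) + 1 if Z is not None and Z.size else 0
        B = len(blocks)
        m = max(len(b) for b in blocks)
        kmax = 0
        cols_per_block = []
        for b in blocks:
            cols = np.flatnonzero(np.any(Z[b] != 0, axis=0))
            cols_per_block.append(cols)
            kmax = max(kmax, len(cols))
        self.B, self.m, self.kmax = B, m, kmax
        self.Xp = np.zeros((B, m, self.p))
        self.yp = np.zeros((B, m))
        self.Zp = np.zeros((B, m, kmax))
        self.colcomp = np.zeros((B, kmax, self.n_comp))
        self.rowgroup = np.zeros((B, m, len(self.labels)))
        self.pad = np.zeros((B, m))  # 1 on padded rows
        lab_idx = {g: i for i, g in enumerate(self.labels)}
        for bi, (b, cols) in enumerate(zip(blocks, cols_per_block)):
            nb = len(b)
            self.Xp[bi, :nb] = X[b]
            self.yp[bi, :nb] = y[b]
            self.Zp[bi, :nb, : len(cols)] = Z[np.ix_(b, cols)]
            for kj, c in enumerate(cols):
                self.colcomp[bi, kj, z_component[c]] = 1.0
            for rj, r in enumerate(b):
                self.rowgroup[bi, rj, lab_idx[groups[r]]] = 1.0
            self.pad[bi, nb:] = 1.0

    def neg_reml(self, log_s2_comp, log_s2_groups, z_component=None, grad: bool = False):
        log_s2_comp = np.asarray(log_s2_comp, dtype=float)
        log_s2_groups = np.asarray(log_s2_groups, dtype=float)
        s2g = np.exp(log_s2_groups)
        s2c = np.exp(log_s2_comp)
        r = self.rowgroup @ s2g + self.pad  # (B, m)
        gvals = self.colcomp @ s2c if self.n_comp else np.zeros((self.B, self.kmax))
        V = (self.Zp * gvals[:, None, :]) @ self.Zp.transpose(0, 2, 1)
        V[:, np.arange(self.m), np.arange(self.m)] += r
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return (1e12, None, None, None) if grad else (1e12, None, None)
        logdet_V = 2.0 * float(np.sum(np.log(np.diagonal(L, axis1=1, axis2=2))))
        Vi = np.linalg.inv(V)
        VX = Vi @ self.Xp  # (B, m, p)
        Vy = (Vi @ self.yp[:, :, None])[:, :, 0]
        XtVX = np.tensordot(self.Xp, VX, axes=([0, 1], [0, 1]))
        XtVy = np.tensordot(self.Xp, Vy, axes=([0, 1], [0, 1]))
        ytVy = float(np.sum(self.yp * Vy))
        sign, logdet_XtVX = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return (1e12, None, None, None) if grad else (1e12, None, None)
        beta = np.linalg.solve(XtVX, XtVy)
        neg2 = logdet_V + logdet_XtVX + (ytVy - float(XtVy @ beta))
        if not grad:
            return neg2, beta, XtVX

        XtVX_inv = np.linalg.inv(XtVX)
        e = self.yp - self.Xp @ beta
        e *= 1.0 - self.pad
        v = (Vi @ e[:, :, None])[:, :, 0]
        diagVi = np.diagonal(Vi, axis1=1, axis2=2)
        grad_out = np.empty(self.n_comp + len(self.labels))
        if self.n_comp:
            T = Vi @ self.Zp  # (B, m, k)
            ZT = np.sum(self.Zp * T, axis=1)  # (B, k): diag of Z'V^-1Z per col
            XVZ = VX.transpose(0, 2, 1) @ self.Zp  # (B, p, k)
            u = np.sum(self.Zp * v[:, :, None], axis=1)  # (B, k)
            for c in range(self.n_comp):
                cc = self.colcomp[:, :, c]
                tr1 = float(np.sum(ZT * cc))
                W = XVZ * cc[:, None, :]
                Ac = np.tensordot(W, XVZ, axes=([0, 2], [0, 2]))
                tr2 = float(np.sum(XtVX_inv * Ac))
                quad = float(np.sum(u**2 * cc))
                grad_out[c] = s2c[c] * (tr1 - tr2 - quad)
        for gi in range(len(self.labels)):
            mk = self.rowgroup[:, :, gi]
            tr1 = float(np.sum(diagVi * mk))
            VXm = VX * mk[:, :, None]
            Ag = np.tensordot(VXm, VX, axes=([0, 1], [0, 1]))
            tr2 = float(np.sum(XtVX_inv * Ag))
            quad = float(np.sum(v**2 * mk))
            grad_out[self.n_comp + gi] = s2g[gi] * (tr1 - tr2 - quad)
        return neg2, beta, XtVX, grad_out


def _row_blocks(Z: np.ndarray) -> list[np.ndarray]:
    """Connected components of observations linked by shared Z columns."""
    n = Z.shape[0]
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for c in range(Z.shape[1]):
        rows = np.flatnonzero(Z[:, c])
        if rows.size > 1:
            r0 = find(rows[0])
            for r in rows[1:]:
                parent[find(r)] = r0
    roots = np.array([find(i) for i in range(n)])
    return [np.flatnonzero(roots == r) for r in np.unique(roots)]


def fit_reml(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray | None,
    groups: np.ndarray,
    z_component: np.ndarray | None = None,
    start: np.ndarray | None = None,
    max_iter: int = 500,
    grad_tol: float = 1e-6,
    variance_model: str = "custom",
) -> MixedModelFit:
    """Maximize the REML log-likelihood over log-variances.

    Parameters are [log sigma^2 per random component, log sigma^2 per residual
    group].  The optimum is polished until the numerical gradient norm falls
    below ``grad_tol`` (on the -2 log-likelihood scale, relative to the
    response variance); a small multi-start grid guards against bad starts.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n <= np.linalg.matrix_rank(X):
        raise ValueError("need more observations than fixed-effect rank")
    groups = np.asarray(groups)
    has_z = Z is not None and Z.size > 0
    if has_z:
        Z = np.asarray(Z, dtype=float)
        if z_component is None:
            z_component = np.zeros(Z.shape[1], dtype=int)
        n_comp = int(z_component.max()) + 1
    else:
        Z, z_component, n_comp = None, None, 0

    ws = None
    if has_z:
        blocks = _row_blocks(Z)
        if len(blocks) >= 4 and max(len(b) for b in blocks) <= 200:
            ws = _BlockRemlWorkspace(y, X, Z, groups, z_component, blocks)
    if ws is None:
        ws = _RemlWorkspace(y, X, Z, groups)
    n_groups = len(ws.labels)

    # base scale from the OLS residual variance
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    s2_ols = max(float(np.sum((y - X @ beta_ols) ** 2)) / max(n - p, 1), 1e-12)

    def objective(theta):
        neg2, _, _, g = ws.neg_reml(theta[:n_comp], theta[n_comp:], z_component, grad=True)
        if g is None:
            return 0.5 * neg2, np.zeros_like(theta)
        return 0.5 * neg2, 0.5 * g

    starts = []
    if start is not None:
        starts.append(np.asarray(start, dtype=float))
    base = np.log(s2_ols)
    starts.append(np.concatenate([np.full(n_comp, base - 2.0), np.full(n_groups, base)]))
    starts.append(np.concatenate([np.full(n_comp, base), np.full(n_groups, base)]))
    starts.append(np.concatenate([np.full(n_comp, base - 5.0), np.full(n_groups, base + 1.0)]))

    lb, ub = base - 25.0, base + 25.0

    def polished_gnorm(theta):
        # gradient norm at a candidate, ignoring components pinned at a bound
        _, _, _, g = ws.neg_reml(theta[:n_comp], theta[n_comp:], z_component, grad=True)
        if g is None:
            return np.inf
        interior = (theta > lb + 1e-9) & (theta < ub - 1e-9)
        return float(np.linalg.norm(0.5 * g[interior])) if np.any(interior) else 0.0

    best, best_gnorm = None, np.inf
    for s0 in starts:
        res = optimize.minimize(
            objective,
            np.clip(s0, lb, ub),
            method="L-BFGS-B",
            jac=True,
            bounds=[(lb, ub)] * (n_comp + n_groups),
            options={"maxiter": max_iter, "ftol": 1e-13, "gtol": grad_tol},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
            best_gnorm = polished_gnorm(res.x)
        # accept once at a numerical optimum: either the projected gradient
        # met grad_tol or the line search exhausted double precision with a
        # near-zero gradient
        if best.fun < 1e11 and best_gnorm < max(grad_tol, 1e-3):
            break
    theta = best.x
    gnorm = best_gnorm
    converged = bool(best.success or gnorm < 1e-3)

    neg2, beta, XtVX = ws.neg_reml(theta[:n_comp], theta[n_comp:], z_component)
    cov_beta = np.linalg.inv(XtVX)
    const = -0.5 * (n - p) * np.log(2.0 * np.pi)
    loglik = -0.5 * neg2 + const

    comp_names = ["mainunit", "pot"][:n_comp] if n_comp <= 2 else [
        f"comp{i}" for i in range(n_comp)
    ]
    var_components = {
        name: float(np.exp(theta[i])) for i, name in enumerate(comp_names)
    }
    resid_vars = {
        str(g): float(np.exp(theta[n_comp + i])) for i, g in enumerate(ws.labels)
    }
    return MixedModelFit(
        beta=beta,
        cov_beta=cov_beta,
        columns=[],
        terms={},
        var_components=var_components,
        resid_vars=resid_vars,
        variance_model=variance_model,
        loglik=float(loglik),
        n_variance_params=n_comp + n_groups,
        converged=converged,
        gradient_norm=gnorm,
        n_obs=n,
    )


def fit_trait(
    design: pd.DataFrame,
    data: pd.DataFrame,
    spec: ModelSpec,
    variance_model: str | None = None,
    include_random: bool = True,
) -> MixedModelFit:
    """Build matrices for a trait and fit one variance model by REML.

    ``include_random=False`` drops the main-unit and pot random effects
    (fixed-effects-only generalized least squares), mainly for oracle
    comparisons against classical ANOVA.
    """
    vm = variance_model or spec.variance_model
    dm = build_design_matrices(design, data, spec.response)
    fit = fit_reml(
        dm.y,
        dm.X,
        dm.Z if include_random else None,
        dm.group_labels[vm],
        z_component=dm.z_component if include_random else None,
        variance_model=vm,
    )
    fit.columns = dm.columns
    fit.terms = dm.terms
    fit.matrices = dm
    return fit


def simplify_variance(
    fits: dict[str, MixedModelFit], alpha: float = 0.05
) -> tuple[str, pd.DataFrame]:
    """Backward selection of the residual-variance grouping by REML LRTs.

    All fits must share the fixed structure (REML comparability).  The
    nitrogen variance difference is tested for removal first, then the
    species difference, then both; the most parsimonious grouping not
    rejected at ``alpha`` is retained.
    """
    needed = set(VARIANCE_MODELS)
    if not needed.issubset(fits):
        raise ValueError(f"need fits for {sorted(needed)}")
    n_params = {k: fits[k].n_variance_params for k in fits}

    def lrt(reduced: str, full: str) -> tuple[float, int, float]:
        stat = 2.0 * (fits[full].loglik - fits[reduced].loglik)
        stat = max(stat, 0.0)
        df = n_params[full] - n_params[reduced]
        if df <= 0:
            raise ValueError(f"model {reduced!r} is not nested in {full!r}")
        return stat, df, float(stats.chi2.sf(stat, df))

    records = []
    current = "full"
    stat, df, p = lrt("species", "full")  # drop the nitrogen difference
    records.append(("species vs full", stat, df, p, p >= alpha))
    if p >= alpha:
        current = "species"
        stat, df, p = lrt("homogeneous", "species")  # then drop species
        records.append(("homogeneous vs species", stat, df, p, p >= alpha))
        if p >= alpha:
            current = "homogeneous"
    else:
        stat, df, p = lrt("nitrogen", "full")  # drop the species difference
        records.append(("nitrogen vs full", stat, df, p, p >= alpha))
        if p >= alpha:
            current = "nitrogen"
            stat, df, p = lrt("homogeneous", "nitrogen")
            records.append(("homogeneous vs nitrogen", stat, df, p, p >= alpha))
            if p >= alpha:
                current = "homogeneous"
    table = pd.DataFrame(
        records, columns=["comparison", "lrt_stat", "df", "p_value", "accepted"]
    )
    return current, table


def select_variance_model(
    design: pd.DataFrame, data: pd.DataFrame, spec: ModelSpec
) -> tuple[MixedModelFit, pd.DataFrame]:
    """Fit all four residual groupings and return the selected fit."""
    fits = {vm: fit_trait(design, data, spec, variance_model=vm) for vm in VARIANCE_MODELS}
    chosen, table = simplify_variance(fits, alpha=spec.alpha)
    return fits[chosen], table


def gate_pvalues(pvalues: dict[str, float], alpha: float = 0.05) -> dict[str, bool]:
    """Hierarchical reporting mask for one species' factorial test table.

    Returns term -> reported flag.  The three-factor interaction is always
    reported; if it is significant everything below is suppressed ("nr").
    Otherwise all two-factor interactions are reported, and a main effect is
    reported only if its factor occurs in no significant two-factor
    interaction.
    """
    reported = {t: False for t in FACTORIAL_TERMS}
    reported["C*N*P"] = True
    if pvalues["C*N*P"] < alpha:
        return reported
    for t in ("C*N", "C*P", "N*P"):
        reported[t] = True
    sig2 = {t for t in ("C*N", "C*P", "N*P") if pvalues[t] < alpha}
    for main in ("C", "N", "P"):
        in_sig = any(main in _TERM_FACTORS[t] for t in sig2)
        reported[main] = not in_sig
    return reported


def _containment_ddf(dm: DesignMatrices, X_rank: int, has_random: bool = True) -> float:
    """Residual-stratum denominator df by the containment heuristic.

    With pot random effects present, rank([X Z]) = (number of pots) + rank
    of X after sweeping out pot means, because the pot indicators span the
    main-unit indicators.  Without random effects the residual df are
    n - rank(X).
    """
    n = len(dm.y)
    if not has_random:
        return float(n - X_rank)
    n_pots = int(np.unique(dm.pot_codes).size)  # pots with observations
    Xc = dm.X.copy()
    df_pm = pd.DataFrame(Xc)
    means = df_pm.groupby(dm.pot_codes).transform("mean").to_numpy()
    r = np.linalg.matrix_rank(Xc - means, tol=1e-8)
    return float(n - n_pots - r)


def wald_hierarchy(fit: MixedModelFit, species: str, alpha: float = 0.05) -> pd.DataFrame:
    """Hierarchical Wald F-tests for one species' factorial terms.

    Columns: species, term, F, num_df, den_df, p_value, reported.  F for a
    term is the quadratic form in its coefficients against their covariance;
    denominator df come from the containment heuristic (all per-species
    factorial columns vary within pots, hence the residual stratum).
    """
    if fit.matrices is None or not fit.terms:
        raise ValueError("fit lacks design-matrix bookkeeping; use fit_trait()")
    dm = fit.matrices
    ddf = _containment_ddf(dm, len(fit.beta), has_random=bool(fit.var_components))
    rows = []
    pvals: dict[str, float] = {}
    for term in FACTORIAL_TERMS:
        key = f"{species}:{term}"
        if key not in fit.terms:
            raise ValueError(f"term {key!r} missing from the fitted model")
        idx = fit.terms[key]
        b = fit.beta[idx]
        C = fit.cov_beta[np.ix_(idx, idx)]
        q = len(idx)
        F = float(b @ np.linalg.solve(C, b)) / q
        p = float(stats.f.sf(F, q, ddf))
        pvals[term] = p
        rows.append({"species": species, "term": term, "F": F, "num_df": q, "den_df": ddf, "p_value": p})
    mask = gate_pvalues(pvals, alpha=alpha)
    table = pd.DataFrame(rows)
    table["reported"] = table["term"].map(mask)
    return table


def _reference_grid(fit: MixedModelFit) -> pd.DataFrame:
    f = fit.matrices.factors
    levels = {
        "replicate": sorted(f["replicate"].unique()),
        "greenhouse_side": sorted(f["greenhouse_side"].unique()),
        "side": sorted(f["side"].unique()),
        "species": sorted(f["species"].unique()),
        "cultivation": sorted(f["cultivation"].unique()),
        "nitrogen": sorted(f["nitrogen"].unique()),
        "phosphorus": sorted(f["phosphorus"].unique()),
    }
    names = list(levels)
    rows = list(itertools.product(*(levels[k] for k in names)))
    return pd.DataFrame(rows, columns=names)


def emmeans(fit: MixedModelFit, factors: list[str], alpha: float = 0.05) -> pd.DataFrame:
    """Estimated marginal means over the requested factor combination.

    Fitted values are averaged with equal weights over the levels of every
    non-requested factor on a full reference grid.  Columns: the requested
    factors, emm, se, half_lsd (t(0.975, ddf) x mean SED / 2, one value per
    table) and letters (compact letter display from unadjusted pairwise
    t-comparisons at ``alpha``).
    """
    if fit.matrices is None:
        raise ValueError("fit lacks design-matrix bookkeeping; use fit_trait()")
    dm = fit.matrices
    bad = [f for f in factors if f not in _reference_grid(fit).columns]
    if bad:
        raise ValueError(f"unknown factors {bad}")
    grid = _reference_grid(fit)
    rep_levels = sorted(dm.factors["replicate"].unique())
    Xg, labels, _ = _encode_fixed(grid, rep_levels)
    # align columns with the fitted (possibly reduced) X
    col_pos = {lab: i for i, lab in enumerate(labels)}
    Xg = Xg[:, [col_pos[lab] for lab in fit.columns]]

    grid = grid.copy()
    keys = list(factors)
    rows = []
    L_rows = []
    for vals, sub in grid.groupby(keys, sort=True):
        if not isinstance(vals, tuple):
            vals = (vals,)
        xbar = Xg[sub.index].mean(axis=0)
        L_rows.append(xbar)
        rows.append(dict(zip(keys, vals)))
    L = np.vstack(L_rows)
    emm = L @ fit.beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", L, fit.cov_beta, L))
    ddf = _containment_ddf(dm, len(fit.beta), has_random=bool(fit.var_components))
    tcrit = stats.t.ppf(0.975, ddf)

    k = len(emm)
    seds, sig_pairs = [], []
    for i in range(k):
        for j in range(i + 1, k):
            d = L[i] - L[j]
            sed = float(np.sqrt(d @ fit.cov_beta @ d))
            seds.append(sed)
            tstat = abs(emm[i] - emm[j]) / sed if sed > 0 else np.inf
            if 2.0 * stats.t.sf(tstat, ddf) < alpha:
                sig_pairs.append((i, j))
    half_lsd = tcrit * (np.mean(seds) if seds else 0.0) / 2.0
    letters = compact_letter_display(emm, sig_pairs)

    out = pd.DataFrame(rows)
    out["emm"] = emm
    out["se"] = se
    out["half_lsd"] = half_lsd
    out["letters"] = letters
    return out


def emm_contrast(
    fit: MixedModelFit,
    factors: list[str],
    level_a: dict[str, str],
    level_b: dict[str, str],
) -> dict:
    """Unadjusted t-comparison between two marginal-mean cells.

    Returns the estimated difference (a - b), its SE, t, denominator df and
    two-sided p-value, averaging over non-requested factors as in
    :func:`emmeans`.
    """
    if fit.matrices is None:
        raise ValueError("fit lacks design-matrix bookkeeping; use fit_trait()")
    dm = fit.matrices
    grid = _reference_grid(fit)
    rep_levels = sorted(dm.factors["replicate"].unique())
    Xg, labels, _ = _encode_fixed(grid, rep_levels)
    col_pos = {lab: i for i, lab in enumerate(labels)}
    Xg = Xg[:, [col_pos[lab] for lab in fit.columns]]

    def xbar(level: dict) -> np.ndarray:
        m = np.ones(len(grid), dtype=bool)
        for k, v in level.items():
            if k not in grid.columns:
                raise ValueError(f"unknown factor {k!r}")
            m &= (grid[k] == v).to_numpy()
        if not m.any():
            raise ValueError(f"no reference-grid cell matches {level}")
        return Xg[m].mean(axis=0)

    d = xbar(level_a) - xbar(level_b)
    est = float(d @ fit.beta)
    se = float(np.sqrt(d @ fit.cov_beta @ d))
    ddf = _containment_ddf(dm, len(fit.beta), has_random=bool(fit.var_components))
    t = est / se if se > 0 else np.inf
    return {
        "estimate": est,
        "se": se,
        "t": t,
        "ddf": ddf,
        "p_value": float(2.0 * stats.t.sf(abs(t), ddf)),
    }


def compact_letter_display(means: np.ndarray, sig_pairs: list[tuple[int, int]]) -> list[str]:
    """Insert-and-absorb letter assignment: two means share a letter iff
    their difference is not significant."""
    k = len(means)
    groups: list[set[int]] = [set(range(k))]
    for i, j in sig_pairs:
        new_groups = []
        for g in groups:
            if i in g and j in g:
                new_groups.append(g - {i})
                new_groups.append(g - {j})
            else:
                new_groups.append(g)
        # absorb subsets
        groups = []
        for g in sorted(new_groups, key=len, reverse=True):
            if g and not any(g <= h for h in groups):
                groups.append(g)
    # order letters by the largest mean they contain, for stable display
    groups.sort(key=lambda g: -max(means[m] for m in g))
    letters = ["" for _ in range(k)]
    for li, g in enumerate(groups):
        ch = chr(ord("a") + li)
        for m in g:
            letters[m] += ch
    return ["".join(sorted(s)) for s in letters]
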