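"""REML variance components, BLUP breeding values, missing heritability and
cross-validation accuracy for animal models with relationship-matrix
covariance structures.

The model is ``y = X b + sum_r Z_r u_r + e`` with ``u_r ~ N(0, C_r s2_r)``
and ``e ~ N(0, I s2_e)``, where each ``C_r`` is a relationship matrix (NRM,
GRM or a CRM).  Variance components maximise the restricted likelihood;
breeding values solve the mixed-model equations at those components.

Implementation notes
--------------------
The restricted log-likelihood is evaluated directly,

    -2 l_R = (n - p) log(2 pi) + log|V| + log|X' V^-1 X| + y' P y,

via a Cholesky factor of ``V = sum_r Z_r C_r Z_r' s2_r + I s2_e``, and
maximised over log-variances with a quasi-Newton optimiser (robust at the
scale this package targets; no AI-REML machinery).  For a single random term
``V`` is diagonalised once by an eigendecomposition of ``Z C Z'``, making
each likelihood evaluation O(n p^2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .io import PhenotypeTable, RelationshipMatrix, ValidationError

logger = logging.getLogger(__name__)

LOG2PI = float(np.log(2.0 * np.pi))


class ConvergenceWarning(UserWarning):
    pass


class IdentifiabilityWarning(UserWarning):
    pass


@dataclass
class RandomTerm:
    """One random effect: an incidence matrix and its covariance structure."""

    name: str
    Z: np.ndarray  # (n_obs, q)
    C: np.ndarray  # (q, q)

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        self.C = self.C.values if isinstance(self.C, RelationshipMatrix) else np.asarray(self.C, dtype=float)
        if self.C.shape[0] != self.C.shape[1]:
            raise ValidationError(f"covariance for term {self.name!r} is not square")
        if self.Z.shape[1] != self.C.shape[0]:
            raise ValidationError(
                f"term {self.name!r}: Z has {self.Z.shape[1]} columns but C is "
                f"{self.C.shape[0]}x{self.C.shape[0]}"
            )


@dataclass
class ModelSpec:
    """Response, fixed-effect design and random terms of one animal model."""

    y: np.ndarray
    X: np.ndarray
    random: list[RandomTerm]
    animal_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = self.y.size
        if self.X.shape[0] != n:
            raise ValidationError("X row count does not match y")
        if not self.random:
            raise ValidationError("at least one random term is required")
        for t in self.random:
            if t.Z.shape[0] != n:
                raise ValidationError(f"term {t.name!r}: Z row count does not match y")

    def subset(self, rows: np.ndarray) -> "ModelSpec":
        """Model restricted to a subset of observations (C matrices untouched)."""
        return ModelSpec(
            self.y[rows],
            self.X[rows],
            [RandomTerm(t.name, t.Z[rows], t.C) for t in self.random],
            animal_ids=self.animal_ids,
        )


def model_from_tables(
    phenotypes: PhenotypeTable,
    matrices: dict[str, RelationshipMatrix],
    fixed: list[str] | None = None,
) -> ModelSpec:
    """Build a ModelSpec from a phenotype table and relationship matrices.

    Fixed covariates named in ``fixed`` enter as one-hot factors when
    non-numeric and as centred covariates when numeric; an intercept is always
    included.  Observations with a missing trait value are dropped; the
    incidence matrices still index every animal of each relationship matrix,
    so un-phenotyped relatives receive breeding values.
    """
    import pandas as pd

    df = phenotypes.data
    obs = df[df[phenotypes.trait].notna()].reset_index(drop=True)
    y = obs[phenotypes.trait].to_numpy(dtype=float)
    cols = [np.ones(len(obs))]
    for name in fixed or []:
        col = obs[name]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float) - float(col.mean()))
        else:
            dummies = pd.get_dummies(col, drop_first=True)
            cols.extend(dummies[c].to_numpy(dtype=float) for c in dummies.columns)
    X = np.column_stack(cols)
    terms = []
    ids = obs[phenotypes.id_col].astype(str).tolist()
    for name, mat in matrices.items():
        index = {a: k for k, a in enumerate(mat.animal_ids)}
        missing = [a for a in ids if a not in index]
        if missing:
            raise ValidationError(f"animals {missing[:5]} absent from {name} matrix")
        Z = np.zeros((len(obs), len(mat.animal_ids)))
        for r, a in enumerate(ids):
            Z[r, index[a]] = 1.0
        terms.append(RandomTerm(name, Z, mat))
    first = next(iter(matrices.values()))
    return ModelSpec(y, X, terms, animal_ids=list(first.animal_ids))


@dataclass
class VarianceComponents:
    """REML estimates: one genetic variance per random term plus residual."""

    sigma2: dict[str, float]
    sigma2_e: float
    loglik: float
    converged: bool
    n_iter: int

    @property
    def phenotypic_variance(self) -> float:
        return float(sum(self.sigma2.values()) + self.sigma2_e)

    def heritability(self, term: str) -> float:
        return self.sigma2[term] / self.phenotypic_variance


@dataclass
class EbvResult:
    """BLUP solutions: fixed-effect estimates and per-term breeding values."""

    beta: np.ndarray
    ebv: dict[str, np.ndarray]

    def total(self) -> np.ndarray:
        return np.sum(list(self.ebv.values()), axis=0)


@dataclass
class RemlOptions:
    max_iter: int = 200
    ll_tol: float = 1e-8
    par_tol: float = 1e-6
    bend: bool = True
    bend_floor: float = 1e-6
    start: dict[str, float] | None = None


def bend_psd(C: np.ndarray, floor: float = 1e-6) -> tuple[np.ndarray, bool]:
    """Floor negative eigenvalues so the matrix is usable as a covariance."""
    w, U = np.linalg.eigh(0.5 * (C + C.T))
    if w.min() >= 0:
        return C, False
    w = np.maximum(w, floor)
    return (U * w) @ U.T, True


def _full_rank(X: np.ndarray) -> np.ndarray:
    """Drop linearly dependent fixed-effect columns (pivoted QR)."""
    q, r, piv = _qr_pivot(X)
    tol = abs(r[0, 0]) * max(X.shape) * np.finfo(float).eps if r.size else 0.0
    rank = int(np.sum(np.abs(np.diag(r)) > tol))
    if rank < X.shape[1]:
        warnings.warn(
            f"dropping {X.shape[1] - rank} confounded fixed-effect column(s)",
            IdentifiabilityWarning,
            stacklevel=3,
        )
    keep = np.sort(piv[:rank])
    return X[:, keep]


def _qr_pivot(X):
    from scipy.linalg import qr

    q, r, piv = qr(X, mode="economic", pivoting=True)
    return q, np.atleast_2d(r), piv


def _reml_ll_dense(y, X, K_list, var, var_e):
    """Restricted log-likelihood from an explicit V (any number of terms)."""
    n, p = X.shape
    V = var_e * np.eye(n)
    for K, v in zip(K_list, var):
        V += v * K
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(L))))
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    sign, logdet_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    resid_quad = float(y @ Vi_y - (X.T @ Vi_y) @ beta)
    return -0.5 * ((n - p) * LOG2PI + logdet_v + logdet_x + resid_quad)


class _SingleTermFast:
    """Rotated-data likelihood for one random term: V diagonal after eigh(K)."""

    def __init__(self, y, X, K):
        w, U = np.linalg.eigh(K)
        self.w = np.maximum(w, 0.0)
        self.y = U.T @ y
        self.X = U.T @ X
        self.n, self.p = X.shape

    def ll(self, var_u, var_e):
        d = var_u * self.w + var_e
        if (d <= 0).any():
            return -np.inf
        logdet_v = float(np.sum(np.log(d)))
        Xd = self.X / d[:, None]
        XtViX = self.X.T @ Xd
        sign, logdet_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return -np.inf
        Xty = Xd.T @ self.y
        beta = np.linalg.solve(XtViX, Xty)
        resid_quad = float(self.y @ (self.y / d) - Xty @ beta)
        return -0.5 * ((self.n - self.p) * LOG2PI + logdet_v + logdet_x + resid_quad)


def reml_fit(spec: ModelSpec, options: RemlOptions | None = None) -> VarianceComponents:
    """Maximise the restricted likelihood over non-negative variances.

    Deterministic given data, options and starting values.  Non-PSD
    relationship matrices are bent (eigenvalue floor) with a logged warning
    when ``options.bend`` is set, otherwise rejected.  Aliased terms (equal
    ``Z C Z'``) trigger an identifiability warning — only their sum is
    estimable.
    """
    opt = options or RemlOptions()
    X = _full_rank(spec.X)
    y = spec.y
    n, p = X.shape
    if n <= p:
        raise ValidationError("more fixed effects than observations")

    K_list = []
    for t in spec.random:
        C = 0.5 * (t.C + t.C.T)
        C_b, bent = bend_psd(C, opt.bend_floor) if opt.bend else (C, False)
        if not opt.bend:
            w = np.linalg.eigvalsh(C)
            if w.min() < -1e-8:
                raise ValidationError(f"relationship matrix for {t.name!r} is not PSD")
        if bent:
            warnings.warn(
                f"relationship matrix for term {t.name!r} bent to PSD "
                f"(eigenvalue floor {opt.bend_floor:g})",
                UserWarning,
                stacklevel=2,
            )
            logger.warning("bent non-PSD covariance for term %r", t.name)
        K_list.append(t.Z @ C_b @ t.Z.T)
    for i in range(len(K_list)):
        for j in range(i + 1, len(K_list)):
            if np.allclose(K_list[i], K_list[j], atol=1e-10):
                warnings.warn(
                    f"random terms {spec.random[i].name!r} and {spec.random[j].name!r} "
                    "are aliased; only their sum is estimable",
                    IdentifiabilityWarning,
                    stacklevel=2,
                )

    vy = float(np.var(y, ddof=1))
    if vy <= 0:
        raise ValidationError("response has zero variance")
    k = len(K_list)
    start = np.full(k + 1, vy / (k + 1))
    if opt.start:
        for i, t in enumerate(spec.random):
            if t.name in opt.start:
                start[i] = opt.start[t.name]
        if "residual" in opt.start:
            start[-1] = opt.start["residual"]
    lo, hi = np.log(vy) - 18.0, np.log(vy) + 6.0
    theta0 = np.clip(np.log(start), lo + 1e-9, hi - 1e-9)

    fast = _SingleTermFast(y, X, K_list[0]) if k == 1 else None

    def ll(theta):
        var = np.exp(theta)
        if fast is not None:
            return fast.ll(var[0], var[1])
        return _reml_ll_dense(y, X, K_list, var[:-1], var[-1])

    nll = lambda th: -ll(th)
    res = optimize.minimize(
        nll,
        theta0,
        method="L-BFGS-B",
        bounds=[(lo, hi)] * (k + 1),
        options={"maxiter": opt.max_iter, "ftol": opt.ll_tol, "gtol": opt.par_tol},
    )
    ll0 = ll(theta0)
    ll_hat = ll(res.x)
    # Never report a point below the start (likelihood monotonicity contract).
    if ll_hat < ll0:
        theta_hat, ll_hat, converged = theta0, ll0, False
    else:
        theta_hat, converged = res.x, bool(res.success)
    if not converged:
        warnings.warn(
            f"REML did not converge: {res.message}", ConvergenceWarning, stacklevel=2
        )
    var = np.exp(theta_hat)
    sigma2 = {t.name: float(var[i]) for i, t in enumerate(spec.random)}
    return VarianceComponents(
        sigma2=sigma2,
        sigma2_e=float(var[-1]),
        loglik=float(ll_hat),
        converged=converged,
        n_iter=int(res.nit),
    )


def blup_ebv(spec: ModelSpec, vc: VarianceComponents, bend: bool = True) -> EbvResult:
    """Solve the mixed-model equations at the given variance components.

    Returns GLS fixed-effect estimates and, per random term,
    ``u_r = s2_r C_r Z_r' V^-1 (y - X beta)`` — the BLUP / conditional-mean
    solution, defined for every animal in ``C_r`` including un-phenotyped
    relatives.
    """
    if not vc.converged:
        logger.warning("BLUP requested from a non-converged REML fit")
    X = _full_rank(spec.X)
    n = spec.y.size
    V = vc.sigma2_e * np.eye(n)
    C_bent = []
    for t in spec.random:
        C = 0.5 * (t.C + t.C.T)
        if bend:
            C, _ = bend_psd(C)
        C_bent.append(C)
        V += vc.sigma2[t.name] * (t.Z @ C @ t.Z.T)
    Vi_y = np.linalg.solve(V, spec.y)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    cond = np.linalg.cond(XtViX)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValidationError("singular coefficient matrix: confounded fixed effects")
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    resid_proj = Vi_y - Vi_X @ beta  # V^-1 (y - X beta)
    ebv = {
        t.name: vc.sigma2[t.name] * (C @ (t.Z.T @ resid_proj))
        for t, C in zip(spec.random, C_bent)
    }
    return EbvResult(beta=beta, ebv=ebv)


def missing_heritability(sigma2_a: float, sigma2_u: float) -> float:
    """Fraction of pedigree-defined additive variance the markers miss.

    ``C_miss = 1 - s2_u / (s2_a + s2_u)`` where ``s2_a`` is the pedigree
    (NRM) additive variance and ``s2_u`` the marker-matrix variance from the
    same two-component fit.
    """
    if sigma2_a < 0 or sigma2_u < 0:
        raise ValueError("variance components must be non-negative")
    total = sigma2_a + sigma2_u
    if total == 0:
        raise ValueError("C_miss undefined when both components are zero")
    return 1.0 - sigma2_u / total


def cv_accuracy(
    spec: ModelSpec,
    n_splits: int = 20,
    holdout: float = 0.2,
    seed: int | None = None,
    options: RemlOptions | None = None,
) -> tuple[float, float, list[float]]:
    """Cross-validation accuracy of EBV prediction.

    Per split a random ``holdout`` fraction of phenotypes is set to missing,
    the model is refit on the remainder, and accuracy is the correlation
    between the held-out animals' EBVs (summed over random terms) and their
    phenotypes adjusted by the training-fit fixed effects (``y - X beta``).
    Returns the mean, SD and per-split accuracies; reproducible under a fixed
    seed.  Degenerate splits (zero variance on either side of the
    correlation) are skipped with a log entry.
    """
    rng = np.random.default_rng(seed)
    n = spec.y.size
    n_hold = max(1, int(round(holdout * n)))
    if n - n_hold <= spec.X.shape[1]:
        raise ValidationError("not enough phenotyped animals for the split")
    accs: list[float] = []
    for split in range(n_splits):
        hold = np.zeros(n, dtype=bool)
        hold[rng.choice(n, size=n_hold, replace=False)] = True
        train = spec.subset(~hold)
        vc = reml_fit(train, options)
        fit = blup_ebv(train, vc)
        # Map held-out observations to their animal levels via Z.
        pred = np.zeros(n_hold)
        for t, t_full in zip(train.random, spec.random):
            pred += t_full.Z[hold] @ fit.ebv[t.name]
        X_full = _full_rank(spec.X)
        adj = spec.y[hold] - X_full[hold] @ fit.beta
        if np.std(pred) == 0 or np.std(adj) == 0:
            logger.info("split %d skipped: zero variance in holdout", split)
            continue
        accs.append(float(np.corrcoef(pred, adj)[0, 1]))
    if not accs:
        raise ValidationError("every cross-validation split was degenerate")
    return float(np.mean(accs)), float(np.std(accs, ddof=1)), accs
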