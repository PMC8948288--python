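"""Multinomial mixed-effects comparison of seed-composition logos.

Sequence logos display the positional nucleotide frequencies of a seed
group but offer no inferential comparison. Here each 6mer seed contributes
six repeated categorical measurements (the nucleotide at positions 1-6),
modelled with a multinomial (baseline-category) logit:

    log P(N_ij = k) / P(N_ij = G)  =  x_ij' beta_k + (Z u_i)_k

for non-reference nucleotides k in {A, C, U}, with fixed effects for
group, position and their interaction, and a per-seed random intercept
u_i ~ N(0, Sigma) capturing within-seed correlation across positions.
Sigma may be unstructured (3x3), diagonal, or a scalar shared intercept
(1-D, loaded equally onto the three logits). The marginal likelihood

    prod_i  integral  prod_j P(n_ij | beta, u)  phi(u; 0, Sigma) du

is maximized with a Laplace approximation of each cluster integral
(adaptive Gauss-Hermite quadrature is available for the 1-D scalar
structure); with the structure "none" the model collapses to a pooled
multinomial logistic regression fitted by Newton-Raphson.

Group contrasts are reported as odds ratios of A/C/U vs G, marginalized
over positions with equal weights, with Wald intervals from the observed
information of the fixed effects (random-effect covariance held at its
estimate). Omnibus group and group-by-position tests use likelihood
ratios between nested fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .alphabet import RNA_ALPHABET, validate_word

LOGO_COLUMNS = ["seed_id", "group", "position", "nucleotide"]
N_POSITIONS = 6


class ConvergenceError(RuntimeError):
    pass


class SeparationWarning(UserWarning):
    """A nucleotide is absent from a group x position cell."""


# ---------------------------------------------------------------------------
# data wrangling
# ---------------------------------------------------------------------------

def validate_logo_table(data: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format logo table: 6 rows per seed, valid letters."""
    missing = [c for c in LOGO_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"logo table missing columns: {missing}")
    data = data.copy()
    data["nucleotide"] = data["nucleotide"].str.upper().str.replace("T", "U")
    bad = set(data["nucleotide"]) - set(RNA_ALPHABET)
    if bad:
        raise ValueError(f"invalid nucleotides in logo table: {sorted(bad)}")
    counts = data.groupby("seed_id").size()
    if (counts != N_POSITIONS).any():
        off = counts[counts != N_POSITIONS].index[:3].tolist()
        raise ValueError(f"seeds without exactly 6 position rows: {off}")
    per_seed_groups = data.groupby("seed_id")["group"].nunique()
    if (per_seed_groups != 1).any():
        raise ValueError("a seed_id maps to more than one group")
    return data


def long_table_from_seeds(groups: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Build a LogoLongTable from per-group seed lists.

    Seed ids are made unique per group so the same 6mer occurring in two
    groups forms two independent clusters.
    """
    rows = []
    for group, seeds in groups.items():
        for i, seed in enumerate(seeds):
            w = validate_word(seed, N_POSITIONS, name=seed)
            sid = f"{group}:{i:05d}:{w}"
            for pos, base in enumerate(w, start=1):
                rows.append((sid, group, pos, base))
    if not rows:
        raise ValueError("no seeds provided")
    return pd.DataFrame(rows, columns=LOGO_COLUMNS)


# ---------------------------------------------------------------------------
# model specification / results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GLMMSpec:
    """Model specification for the logo comparison.

    covariance: "unstructured" | "diagonal" | "scalar" | "none".
    method: "laplace" (any structure) or "agq" (scalar only), with
    ``agq_points`` quadrature nodes. ``include_*`` toggles define the
    fixed-effect terms (used for nested reduced models).
    """

    reference_nucleotide: str = "G"
    covariance: str = "unstructured"
    include_group: bool = True
    include_position: bool = True
    include_interaction: bool = True
    method: str = "laplace"
    agq_points: int = 15
    gtol: float = 1e-6
    maxiter: int = 500

    def __post_init__(self) -> None:
        if self.reference_nucleotide not in RNA_ALPHABET:
            raise ValueError(f"reference must be one of {RNA_ALPHABET}")
        if self.covariance not in ("unstructured", "diagonal", "scalar", "none"):
            raise ValueError(f"unknown covariance structure {self.covariance!r}")
        if self.method not in ("laplace", "agq"):
            raise ValueError(f"unknown integration method {self.method!r}")
        if self.method == "agq" and self.covariance not in ("scalar", "none"):
            raise ValueError("adaptive quadrature is only available for the "
                             "1-D scalar structure")
        if self.include_interaction and not (self.include_group and self.include_position):
            raise ValueError("interaction requires both main effects")


@dataclass
class GLMMFit:
    """Fitted logo model.

    ``beta`` is a (non-reference categories) x (terms) coefficient frame on
    the log-odds scale; ``beta_cov`` its estimated covariance (rows/cols
    ordered category-major, matching ``beta.values.ravel()``); ``re_cov``
    the random-effect covariance on the 3 non-reference logits.
    """

    beta: pd.DataFrame
    beta_cov: np.ndarray
    re_cov: np.ndarray
    loglik: float
    converged: bool
    n_obs: int
    n_clusters: int
    spec: GLMMSpec
    groups: list[str]
    categories: list[str]  # non-reference, in order
    terms: list[str]
    _design_info: dict = field(default_factory=dict, repr=False)

    @property
    def n_fixed_params(self) -> int:
        return self.beta.size

    def coefficients_table(self) -> pd.DataFrame:
        """Per-(category, term) estimates with SE, OR and Wald CI/p."""
        se = np.sqrt(np.diag(self.beta_cov))
        est = self.beta.values.ravel()
        rows = []
        i = 0
        for cat in self.categories:
            for term in self.terms:
                z = est[i] / se[i] if se[i] > 0 else np.nan
                rows.append(
                    {
                        "category": cat,
                        "term": term,
                        "estimate": est[i],
                        "se": se[i],
                        "OR": np.exp(est[i]),
                        "ci_low": np.exp(est[i] - 1.959963984540054 * se[i]),
                        "ci_high": np.exp(est[i] + 1.959963984540054 * se[i]),
                        "p": 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                    }
                )
                i += 1
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# internal fitter
# ---------------------------------------------------------------------------

def _design_row(
    group: str,
    pos: int,
    groups: list[str],
    spec: GLMMSpec,
) -> np.ndarray:
    cols = [1.0]
    if spec.include_group:
        cols += [1.0 if group == g else 0.0 for g in groups[1:]]
    if spec.include_position:
        cols += [1.0 if pos == j else 0.0 for j in range(2, N_POSITIONS + 1)]
    if spec.include_interaction:
        for g in groups[1:]:
            for j in range(2, N_POSITIONS + 1):
                cols.append(1.0 if (group == g and pos == j) else 0.0)
    return np.array(cols)


def _term_names(groups: list[str], spec: GLMMSpec) -> list[str]:
    terms = ["intercept"]
    if spec.include_group:
        terms += [f"group[{g}]" for g in groups[1:]]
    if spec.include_position:
        terms += [f"pos[{j}]" for j in range(2, N_POSITIONS + 1)]
    if spec.include_interaction:
        terms += [
            f"group[{g}]:pos[{j}]"
            for g in groups[1:]
            for j in range(2, N_POSITIONS + 1)
        ]
    return terms


class _LogoGLMM:
    """Vectorised Laplace/AGQ fitter; one instance per (data, spec)."""

    def __init__(self, data: pd.DataFrame, spec: GLMMSpec) -> None:
        data = validate_logo_table(data)
        self.spec = spec
        ref = spec.reference_nucleotide
        self.categories = [b for b in RNA_ALPHABET if b != ref]  # non-ref
        self.groups = sorted(data["group"].unique())
        if spec.include_group and len(self.groups) < 2:
            raise ValueError("group effects require at least 2 groups")
        # observed group x position cells for every position in every group
        obs = data.groupby(["group", "position"]).size().unstack("position")
        if obs.isna().any().any() or obs.shape[1] != N_POSITIONS:
            raise ValueError("every position must be observed in every group")
        cell = (
            data.groupby(["group", "position", "nucleotide"]).size().unstack(
                "nucleotide", fill_value=0
            )
        )
        for base in RNA_ALPHABET:
            if base not in cell.columns or (cell[base] == 0).any():
                warnings.warn(
                    f"nucleotide {base} absent from at least one group x position "
                    "cell; estimates rely on partial pooling and may be unstable",
                    SeparationWarning,
                    stacklevel=3,
                )
                break

        self.terms = _term_names(self.groups, spec)
        self.p = len(self.terms)
        self.C = len(self.categories)
        cat_idx = {b: i for i, b in enumerate(self.categories)}

        pivot = data.pivot(index="seed_id", columns="position", values="nucleotide")
        pivot = pivot[range(1, N_POSITIONS + 1)] if set(pivot.columns) == set(
            range(1, N_POSITIONS + 1)
        ) else pivot.sort_index(axis=1)
        grp = data.groupby("seed_id")["group"].first().loc[pivot.index]
        self.n = len(pivot)
        self.n_obs = self.n * N_POSITIONS
        # one-hot outcomes, (n, 6, C); reference rows are all-zero
        self.Y = np.zeros((self.n, N_POSITIONS, self.C))
        vals = pivot.to_numpy()
        for c, base in enumerate(self.categories):
            self.Y[:, :, c] = vals == base
        # design (n, 6, p) — depends only on (group, position)
        row_cache = {
            (g, j): _design_row(g, j, self.groups, spec)
            for g in self.groups
            for j in range(1, N_POSITIONS + 1)
        }
        self.X = np.stack(
            [
                np.stack([row_cache[(g, j)] for j in range(1, N_POSITIONS + 1)])
                for g in grp
            ]
        )
        # random-effect loading: b_eff = Z @ u
        if spec.covariance == "scalar":
            self.Z = np.ones((self.C, 1))
        else:
            self.Z = np.eye(self.C)
        self.d = 0 if spec.covariance == "none" else self.Z.shape[1]
        self.n_cov_params = {
            "unstructured": 6,
            "diagonal": 3,
            "scalar": 1,
            "none": 0,
        }[spec.covariance]
        self._warm_u = np.zeros((self.n, self.d)) if self.d else None
        ghx, ghw = np.polynomial.hermite.hermgauss(spec.agq_points)
        self._gh = (ghx, ghw)

    # -- covariance parameterisation --------------------------------------
    def _chol(self, theta: np.ndarray) -> np.ndarray:
        """Lower Cholesky factor of Sigma_u from unconstrained params."""
        d = self.d
        L = np.zeros((d, d))
        if self.spec.covariance == "unstructured":
            L[np.diag_indices(3)] = np.exp(theta[:3])
            L[1, 0], L[2, 0], L[2, 1] = theta[3], theta[4], theta[5]
        else:
            L[np.diag_indices(d)] = np.exp(theta[:d])
        return L

    def sigma_from_theta(self, theta: np.ndarray) -> np.ndarray:
        L = self._chol(theta)
        return L @ L.T

    # -- conditional pieces -------------------------------------------------
    def _eta_prob(self, F: np.ndarray, beff: np.ndarray):
        """Category probabilities for fixed part F (n,6,C) and effects beff (n,C)."""
        eta = F + beff[:, None, :]
        m = np.maximum(eta.max(axis=2), 0.0)
        denom = np.exp(-m) + np.exp(eta - m[:, :, None]).sum(axis=2)
        logdenom = m + np.log(denom)
        prob = np.exp(eta - logdenom[:, :, None])
        return eta, prob, logdenom

    def _cond_loglik(self, F, beff):
        eta, _, logdenom = self._eta_prob(F, beff)
        return (self.Y * eta).sum(axis=(1, 2)) - logdenom.sum(axis=1)

    # -- inner mode finding -------------------------------------------------
    def _modes(self, F: np.ndarray, Sigma_inv: np.ndarray):
        """Per-cluster posterior modes of u, vectorised Newton.

        Returns (u_hat, H) where H is the negative Hessian at the mode.
        """
        u = self._warm_u.copy()
        Z = self.Z
        for _ in range(100):
            beff = u @ Z.T
            _, prob, _ = self._eta_prob(F, beff)
            resid = (self.Y - prob).sum(axis=1)  # (n, C)
            grad = resid @ Z - u @ Sigma_inv  # (n, d)
            # W = sum_j diag(p) - p p^T per cluster, (n, C, C)
            W = np.einsum("njc,cd->ncd", prob, np.eye(self.C)) - np.einsum(
                "njc,njd->ncd", prob, prob
            )
            H = np.einsum("ck,ncd,dl->nkl", Z, W, Z) + Sigma_inv  # (n, d, d)
            step = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
            u = u + step
            if np.abs(grad).max() < 1e-10:
                break
        beff = u @ Z.T
        _, prob, _ = self._eta_prob(F, beff)
        W = np.einsum("njc,cd->ncd", prob, np.eye(self.C)) - np.einsum(
            "njc,njd->ncd", prob, prob
        )
        H = np.einsum("ck,ncd,dl->nkl", Z, W, Z) + Sigma_inv
        self._warm_u = u.copy()
        return u, H

    # -- marginal log-likelihood --------------------------------------------
    def loglik(self, params: np.ndarray) -> float:
        beta = params[: self.C * self.p].reshape(self.C, self.p)
        F = np.einsum("njp,cp->njc", self.X, beta)
        if self.d == 0:
            return float(self._cond_loglik(F, np.zeros((self.n, self.C))).sum())
        theta = params[self.C * self.p :]
        L = self._chol(theta)
        # guard against exploding/vanishing variances during line searches
        Sigma = L @ L.T + 1e-10 * np.eye(self.d)
        Sigma_inv = np.linalg.inv(Sigma)
        sign, logdet_sigma = np.linalg.slogdet(Sigma)
        u, H = self._modes(F, Sigma_inv)
        cond = self._cond_loglik(F, u @ self.Z.T)
        quad = np.einsum("nd,de,ne->n", u, Sigma_inv, u)
        sign_h, logdet_h = np.linalg.slogdet(H)
        if self.spec.method == "agq" and self.d == 1:
            ghx, ghw = self._gh
            tau = 1.0 / np.sqrt(H[:, 0, 0])  # (n,)
            nodes = u[:, 0][:, None] + np.sqrt(2.0) * tau[:, None] * ghx[None, :]
            vals = np.empty((self.n, ghx.size))
            for k in range(ghx.size):
                uk = nodes[:, k][:, None]
                ck = self._cond_loglik(F, uk @ self.Z.T)
                vals[:, k] = ck - 0.5 * uk[:, 0] ** 2 * Sigma_inv[0, 0]
            # log integral of exp(f) du via adaptive GH
            m = vals.max(axis=1)
            integ = np.log(
                (ghw[None, :] * np.exp(vals - m[:, None] + ghx[None, :] ** 2)).sum(
                    axis=1
                )
            ) + m + 0.5 * np.log(2.0) + np.log(tau)
            ll = integ - 0.5 * logdet_sigma - 0.5 * np.log(2 * np.pi)
            return float(ll.sum())
        # Laplace: the (d/2) log 2pi of the integral cancels the Gaussian norm
        ll = cond - 0.5 * quad - 0.5 * logdet_sigma - 0.5 * logdet_h
        return float(ll.sum())

    def neg_loglik(self, params: np.ndarray) -> float:
        try:
            return -self.loglik(params)
        except np.linalg.LinAlgError:
            return 1e12

    # -- pooled (no random effect) Newton fit -------------------------------
    def fit_pooled(self, gtol: float = 1e-10, maxiter: int = 100) -> np.ndarray:
        """MLE of the pooled multinomial logit (Sigma = 0), Newton-Raphson."""
        R = self.X.reshape(-1, self.p)  # (M, p)
        Yf = self.Y.reshape(-1, self.C)  # (M, C)
        beta = np.zeros((self.C, self.p))
        for _ in range(maxiter):
            eta = R @ beta.T  # (M, C)
            m = np.maximum(eta.max(axis=1), 0.0)
            logdenom = m + np.log(
                np.exp(-m) + np.exp(eta - m[:, None]).sum(axis=1)
            )
            prob = np.exp(eta - logdenom[:, None])
            grad = (Yf - prob).T @ R  # (C, p)
            if np.abs(grad).max() < gtol:
                break
            W = np.einsum("mc,cd->mcd", prob, np.eye(self.C)) - np.einsum(
                "mc,md->mcd", prob, prob
            )
            Hess = np.einsum("mi,mcd,mj->cidj", R, W, R).reshape(
                self.C * self.p, self.C * self.p
            )
            Hess += 1e-10 * np.eye(self.C * self.p)
            step = np.linalg.solve(Hess, grad.ravel()).reshape(self.C, self.p)
            # damped Newton: halve until the likelihood does not decrease
            ll0 = float((Yf * eta).sum() - logdenom.sum())
            scale = 1.0
            for _ in range(30):
                cand = beta + scale * step
                eta_c = R @ cand.T
                m_c = np.maximum(eta_c.max(axis=1), 0.0)
                ld_c = m_c + np.log(
                    np.exp(-m_c) + np.exp(eta_c - m_c[:, None]).sum(axis=1)
                )
                if float((Yf * eta_c).sum() - ld_c.sum()) >= ll0 - 1e-12:
                    break
                scale *= 0.5
            beta = beta + scale * step
        return beta

    def pooled_beta_cov(self, beta: np.ndarray) -> np.ndarray:
        R = self.X.reshape(-1, self.p)
        eta = R @ beta.T
        m = np.maximum(eta.max(axis=1), 0.0)
        logdenom = m + np.log(np.exp(-m) + np.exp(eta - m[:, None]).sum(axis=1))
        prob = np.exp(eta - logdenom[:, None])
        W = np.einsum("mc,cd->mcd", prob, np.eye(self.C)) - np.einsum(
            "mc,md->mcd", prob, prob
        )
        Hess = np.einsum("mi,mcd,mj->cidj", R, W, R).reshape(
            self.C * self.p, self.C * self.p
        )
        return np.linalg.inv(Hess + 1e-12 * np.eye(self.C * self.p))


def fit_multinomial_glmm(data: pd.DataFrame, spec: GLMMSpec | None = None) -> GLMMFit:
    """Fit the positional-nucleotide model to a long-format logo table."""
    spec = spec or GLMMSpec()
    model = _LogoGLMM(data, spec)
    beta0 = model.fit_pooled()

    if spec.covariance == "none":
        cov = model.pooled_beta_cov(beta0)
        ll = model.loglik(beta0.ravel())
        fit = GLMMFit(
            beta=pd.DataFrame(beta0, index=model.categories, columns=model.terms),
            beta_cov=cov,
            re_cov=np.zeros((model.C, model.C)),
            loglik=ll,
            converged=True,
            n_obs=model.n_obs,
            n_clusters=model.n,
            spec=spec,
            groups=model.groups,
            categories=model.categories,
            terms=model.terms,
        )
        return fit

    theta0 = np.full(model.n_cov_params, np.log(0.3))
    if spec.covariance == "unstructured":
        theta0 = np.concatenate([np.full(3, np.log(0.3)), np.zeros(3)])
    x0 = np.concatenate([beta0.ravel(), theta0])
    res = optimize.minimize(
        model.neg_loglik,
        x0,
        method="L-BFGS-B",
        options={
            "maxiter": spec.maxiter,
            "gtol": spec.gtol,
            "ftol": 1e-11,
            "maxcor": 25,
        },
    )
    n_beta = model.C * model.p
    beta_hat = res.x[:n_beta].reshape(model.C, model.p)
    theta_hat = res.x[n_beta:]
    sigma_u = model.sigma_from_theta(theta_hat)
    re_cov = model.Z @ sigma_u @ model.Z.T  # on the 3 logits

    # observed information of the fixed effects at Sigma-hat
    from statsmodels.tools.numdiff import approx_hess1

    def f_beta(b: np.ndarray) -> float:
        return model.neg_loglik(np.concatenate([b, theta_hat]))

    hess = approx_hess1(res.x[:n_beta].copy(), f_beta)
    hess = 0.5 * (hess + hess.T)
    try:
        beta_cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        beta_cov = np.linalg.pinv(hess)

    converged = bool(res.success and np.isfinite(res.fun))
    if not converged:
        warnings.warn(
            f"logo model did not converge: {res.message}", RuntimeWarning, stacklevel=2
        )
    return GLMMFit(
        beta=pd.DataFrame(beta_hat, index=model.categories, columns=model.terms),
        beta_cov=beta_cov,
        re_cov=re_cov,
        loglik=float(-res.fun),
        converged=converged,
        n_obs=model.n_obs,
        n_clusters=model.n,
        spec=spec,
        groups=model.groups,
        categories=model.categories,
        terms=model.terms,
        _design_info={"theta": theta_hat},
    )


def loglik_at(
    data: pd.DataFrame,
    spec: GLMMSpec,
    beta: np.ndarray,
    theta: np.ndarray | None = None,
) -> float:
    """Marginal log-likelihood at given parameters (for sanity checks)."""
    model = _LogoGLMM(data, spec)
    params = np.asarray(beta, dtype=float).ravel()
    if model.n_cov_params:
        if theta is None:
            theta = np.full(model.n_cov_params, np.log(1e-3))
        params = np.concatenate([params, np.asarray(theta, dtype=float)])
    return model.loglik(params)


def group_odds_ratios(
    fit: GLMMFit, group_a: str, group_b: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Odds ratios of A/C/U vs the reference for group_a relative to group_b.

    The group contrast is marginalized over the six positions with equal
    weights (relevant when the interaction is in the model). Wald CI and
    p-value from the fixed-effect covariance.
    """
    if not fit.converged:
        raise ConvergenceError("cannot report odds ratios from a non-converged fit")
    for g in (group_a, group_b):
        if g not in fit.groups:
            raise ValueError(f"group {g!r} not in fitted design {fit.groups}")
    rows_a = np.stack(
        [_design_row(group_a, j, fit.groups, fit.spec) for j in range(1, 7)]
    ).mean(axis=0)
    rows_b = np.stack(
        [_design_row(group_b, j, fit.groups, fit.spec) for j in range(1, 7)]
    ).mean(axis=0)
    contrast = rows_a - rows_b  # length p, same for every category
    p_terms = len(fit.terms)
    z_crit = stats.norm.ppf(1 - alpha / 2)
    out = []
    for ci, cat in enumerate(fit.categories):
        full = np.zeros(fit.n_fixed_params)
        full[ci * p_terms : (ci + 1) * p_terms] = contrast
        est = float(full @ fit.beta.values.ravel())
        se = float(np.sqrt(full @ fit.beta_cov @ full))
        z = est / se if se > 0 else np.nan
        out.append(
            {
                "nucleotide": cat,
                "log_or": est,
                "se": se,
                "OR": np.exp(est),
                "ci_low": np.exp(est - z_crit * se),
                "ci_high": np.exp(est + z_crit * se),
                "p": 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
            }
        )
    return pd.DataFrame(out).set_index("nucleotide")


def test_effect(full: GLMMFit, reduced: GLMMFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fits: (LR, df, p)."""
    if full.n_obs != reduced.n_obs or full.n_clusters != reduced.n_clusters:
        raise ValueError("fits are not on the same data")
    if not set(reduced.terms) <= set(full.terms):
        raise ValueError("reduced model terms are not a subset of the full model")
    df = full.n_fixed_params - reduced.n_fixed_params
    if df < 0:
        raise ValueError("reduced model has more parameters than the full model")
    lr = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    p = float(stats.chi2.sf(lr, df)) if df > 0 else 1.0
    return float(lr), int(df), p
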