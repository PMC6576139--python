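"""REML variance components, BLUPs and broad-sense heritability for
multi-environment row-column (alpha-lattice) trials.

Model: for genotype a, location b, replication i, column j, row k,

    Y = mu + G_a + L_b + GL_ab + b_i + c_j(i) + r_k(i) + e

with location fixed and genotype, genotype-by-location, replication,
column-in-replication and row-in-replication random, all mutually
independent with their own variance.  Genotype is treated as random so that
BLUPs are defined.  The variance components are estimated by
average-information REML run entirely in mixed-model-equation space (no
n x n matrices), to a relative log-likelihood tolerance of 1e-6.

Broad-sense heritability is on an entry-mean basis across l locations and
r replications:

    h2 = sigma2_G / (sigma2_G + sigma2_GL / l + sigma2_e / (l * r))
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, sparse

__all__ = ["VarComp", "fit_trial_model", "heritability", "RemlError"]


class RemlError(RuntimeError):
    def __init__(self, msg, diagnostics=None):
        super().__init__(msg)
        self.diagnostics = diagnostics or {}


@dataclass
class VarComp:
    """Fitted variance components and fixed effects of the trial model."""

    sigma2: dict[str, float]          # per random term, plus "resid"
    mu: float
    location_effects: pd.Series
    loglik: float
    n_iter: int
    converged: bool
    n_obs: int
    design: dict = field(default_factory=dict)

    def __getattr__(self, name):
        if name.startswith("sigma2_"):
            key = name[len("sigma2_"):]
            alias = {"g": "genotype", "gl": "gl", "e": "resid", "eps": "resid"}
            key = alias.get(key, key)
            if key in self.sigma2:
                return self.sigma2[key]
        raise AttributeError(name)


def _levels(series: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    codes, uniques = pd.factorize(series, sort=True)
    return codes, uniques


def _design(records: pd.DataFrame, random_terms):
    y = records["value"].to_numpy(float)
    n = len(records)
    loc_codes, loc_levels = _levels(records["location"])
    X = np.ones((n, 1))
    if len(loc_levels) > 1:
        dummies = np.eye(len(loc_levels))[loc_codes][:, 1:]  # first level is baseline
        X = np.hstack([X, dummies])

    def key(cols):
        return records[cols].astype(str).agg(":".join, axis=1)

    term_keys = {
        "genotype": records["genotype"].astype(str),
        "gl": key(["genotype", "location"]),
        "rep": key(["location", "replication"]),
        "col": key(["location", "replication", "column"]),
        "row": key(["location", "replication", "row"]),
    }
    Zs, blocks, levels = [], {}, {}
    start = 0
    for t in random_terms:
        codes, lv = _levels(term_keys[t])
        q = len(lv)
        Z = sparse.csr_matrix((np.ones(n), (np.arange(n), codes)), shape=(n, q))
        Zs.append(Z)
        blocks[t] = slice(start, start + q)
        levels[t] = lv
        start += q
    Z = sparse.hstack(Zs, format="csr")
    return y, X, Z, blocks, levels, loc_levels


class _RemlWork:
    """Precomputed cross-products; everything per-iteration lives in the
    q-dimensional mixed-model-equation space."""

    def __init__(self, y, X, Z, blocks):
        self.y, self.X, self.Z, self.blocks = y, X, Z, blocks
        self.n, self.p = X.shape
        self.q = Z.shape[1]
        self.ZtZ = np.asarray((Z.T @ Z).todense())
        self.ZtX = np.asarray(Z.T @ X)
        self.Zty = np.asarray(Z.T @ y).ravel()
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.terms = list(blocks)

    def _assemble(self, theta):
        s2e = theta[-1]
        gam = np.empty(self.q)
        for t, s2 in zip(self.terms, theta[:-1]):
            gam[self.blocks[t]] = s2e / s2
        Mt = self.ZtZ + np.diag(gam)
        cho = linalg.cho_factor(Mt, lower=True)
        logdet_Mt = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        sM = lambda B: linalg.cho_solve(cho, B)
        XtVinvX = (self.XtX - self.ZtX.T @ sM(self.ZtX)) / s2e
        XtVinvy = (self.Xty - self.ZtX.T @ sM(self.Zty)) / s2e
        try:
            beta = linalg.solve(XtVinvX, XtVinvy, assume_a="pos")
            Gx = linalg.inv(XtVinvX)
        except linalg.LinAlgError as e:
            raise RemlError(f"singular fixed-effect design: {e}")
        r = self.y - self.X @ beta
        Ztr = self.Zty - self.ZtX @ beta
        Py = (r - self.Z @ sM(Ztr)) / s2e
        return dict(s2e=s2e, sM=sM, logdet_Mt=logdet_Mt, XtVinvX=XtVinvX,
                    beta=beta, Gx=Gx, Py=Py, gam=gam)

    def loglik(self, theta, w=None):
        w = w or self._assemble(theta)
        s2e = w["s2e"]
        logdet_V = (self.n * np.log(s2e) + w["logdet_Mt"]
                    - sum((self.blocks[t].stop - self.blocks[t].start)
                          * np.log(s2e / s2)
                          for t, s2 in zip(self.terms, theta[:-1])))
        sign, logdet_XtVinvX = np.linalg.slogdet(w["XtVinvX"])
        yPy = float(self.y @ w["Py"])
        return -0.5 * (logdet_V + logdet_XtVinvX + yPy
                       + (self.n - self.p) * np.log(2 * np.pi)), w

    def grad_ai(self, theta, w):
        """REML gradient and average-information matrix at theta."""
        sM, s2e, Gx = w["sM"], w["s2e"], w["Gx"]
        Py = w["Py"]
        ZtPy = np.asarray(self.Z.T @ Py).ravel()
        k = len(self.terms) + 1
        grad = np.empty(k)
        ws = []
        for ui, t in enumerate(self.terms):
            bl = self.blocks[t]
            S = self.ZtZ[:, bl]
            trVinvA = (np.trace(self.ZtZ[bl, bl]) - float(np.sum(S * sM(S)))) / s2e
            E = (self.ZtX[bl].T - self.ZtX.T @ sM(S)) / s2e  # p x q_u
            trcorr = float(np.sum(E * (Gx @ E)))
            quad = float(ZtPy[bl] @ ZtPy[bl])
            grad[ui] = -0.5 * ((trVinvA - trcorr) - quad)
            ws.append(np.asarray(self.Z[:, bl] @ ZtPy[bl]).ravel())
        # residual component
        T = sM(self.ZtZ)
        trVinv = (self.n - float(np.trace(T))) / s2e
        VinvX = (self.X - self.Z @ sM(self.ZtX)) / s2e
        trcorr_e = float(np.sum((VinvX @ Gx) * VinvX))
        grad[-1] = -0.5 * ((trVinv - trcorr_e) - float(Py @ Py))
        ws.append(Py)

        def Pw(v):
            Ztv = np.asarray(self.Z.T @ v).ravel()
            Vinv_v = (v - self.Z @ sM(Ztv)) / s2e
            XtVinv_v = (self.X.T @ v - self.ZtX.T @ sM(Ztv)) / s2e
            return Vinv_v - VinvX @ (Gx @ XtVinv_v)

        Pws = [Pw(v) for v in ws]
        ai = 0.5 * np.array([[float(ws[i] @ Pws[j]) for j in range(k)]
                             for i in range(k)])
        return grad, ai


def fit_trial_model(records: pd.DataFrame, random_terms=None,
                    max_iter: int = 100, tol: float = 1e-6,
                    ) -> tuple[VarComp, pd.Series]:
    """Fit the trial mixed model by AI-REML and extract genotype BLUPs.

    ``records`` needs columns genotype, location, replication, row, column,
    value (a single trait).  ``random_terms`` defaults to every term the
    design supports: genotype, gl (only with >1 location), rep, col, row.
    """
    req = {"genotype", "location", "replication", "row", "column", "value"}
    if not req.issubset(records.columns):
        raise ValueError(f"records need columns {sorted(req)}")
    if records["genotype"].nunique() < 2:
        raise ValueError("need at least two genotypes")
    if random_terms is None:
        random_terms = ["genotype"]
        if records["location"].nunique() > 1:
            random_terms.append("gl")
        for t, col in (("rep", "replication"), ("col", "column"), ("row", "row")):
            if records.groupby("location")[col].nunique().max() > 1 or t == "rep":
                random_terms.append(t)
    y, X, Z, blocks, levels, loc_levels = _design(records, random_terms)
    work = _RemlWork(y, X, Z, blocks)

    vy = float(np.var(y))
    k = len(random_terms)
    floor = max(vy, 1e-12) * 1e-10
    theta = np.full(k + 1, vy / (2 * k) if k else vy)
    theta[-1] = vy / 2

    # Newton/AI steps taken on log-variances: multiplicative updates stay
    # positive and tame the flat directions of near-degenerate fits
    ll, w = work.loglik(theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad, ai = work.grad_ai(theta, w)
        g_log = grad * theta
        h_log = ai * np.outer(theta, theta)
        ridge = 1e-8 * max(1.0, float(np.trace(h_log))) * np.eye(len(g_log))
        try:
            step = linalg.solve(h_log + ridge, g_log, assume_a="pos")
        except linalg.LinAlgError:
            step = np.sign(g_log)
        step = np.clip(step, -3.0, 3.0)
        improved = False
        for _ in range(40):
            cand = np.maximum(theta * np.exp(step), floor)
            try:
                ll_new, w_new = work.loglik(cand)
            except (linalg.LinAlgError, RemlError):
                step *= 0.5
                continue
            if np.isfinite(ll_new) and ll_new >= ll - 1e-10:
                improved = True
                break
            step *= 0.5
        if not improved:
            converged = True  # no uphill direction left at line-search resolution
            break
        delta = ll_new - ll
        theta, ll, w = cand, ll_new, w_new
        if abs(delta) < tol * (1.0 + abs(ll)):
            converged = True
            break
    if not converged:
        raise RemlError("REML did not converge",
                        diagnostics={"loglik": ll, "theta": theta.tolist(),
                                     "iterations": it})

    sigma2 = {t: float(max(theta[i], 0.0)) for i, t in enumerate(random_terms)}
    sigma2["resid"] = float(theta[-1])
    beta = w["beta"]
    loc_eff = pd.Series(0.0, index=list(loc_levels), name="location_effect")
    if len(loc_levels) > 1:
        loc_eff.iloc[1:] = beta[1:1 + len(loc_levels) - 1]
    vc = VarComp(sigma2, float(beta[0]), loc_eff, float(ll), it, converged,
                 n_obs=len(y),
                 design={"n_locations": int(records["location"].nunique()),
                         "n_reps": int(records.groupby("location")["replication"]
                                       .nunique().max()),
                         "random_terms": list(random_terms)})

    # BLUP of genotype effects: u_G = sigma2_G * Z_G' P y
    bl = blocks["genotype"]
    ZtPy = np.asarray(Z.T @ w["Py"]).ravel()
    blups = pd.Series(sigma2["genotype"] * ZtPy[bl], index=list(levels["genotype"]),
                      name="blup")
    return vc, blups


def heritability(vc: VarComp, n_locations: int | None = None,
                 n_reps: int | None = None) -> float:
    """Entry-mean broad-sense heritability across locations and reps."""
    l = n_locations if n_locations is not None else vc.design.get("n_locations", 1)
    r = n_reps if n_reps is not None else vc.design.get("n_reps", 1)
    s2g = vc.sigma2.get("genotype", 0.0)
    s2gl = vc.sigma2.get("gl", 0.0)
    s2e = vc.sigma2.get("resid", 0.0)
    denom = s2g + s2gl / l + s2e / (l * r)
    if denom <= 0:
        raise ZeroDivisionError("zero phenotypic variance")
    return s2g / denom
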