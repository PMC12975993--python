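"""Trial genetics: variance components, heritability, BLUPs, Wald tests.

Per-environment analysis treats the trial as a randomised complete block
design (RCBD) with genotype and block random:

    y_ij = mu + block_j + genotype_i + e_ij

Balanced data are fitted by ANOVA method-of-moments (which coincides with
REML); unbalanced data by Fisher-scoring REML on the same model.
Broad-sense heritability is reported on a line-mean basis,

    H^2 = sigma2_g / (sigma2_g + sigma2_e / r),

with r the (harmonic-mean) number of replicates.  Genotype BLUPs shrink
raw genotype-mean deviations toward the grand mean by the same factor.

Multi-environment analysis fits fixed effects in the order
Year, Environment, Year:Environment, Genotype, Genotype:Environment with
replicate-within-environment random, and reports an incremental
(sequential) Wald statistic per term.  ``p_value`` uses the Wald-F
reference F(df_term, df_residual) — the conventional mixed-model Wald
test — while the raw chi-square p is exposed as ``p_chi2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConvergenceError, InsufficientDesign

__all__ = [
    "TrialObservation",
    "VarianceComponents",
    "HeritabilityResult",
    "WaldResult",
    "trial_frame",
    "fit_rcbd",
    "heritability",
    "blup",
    "met_wald",
    "significance_code",
]


@dataclass(frozen=True)
class TrialObservation:
    environment: tuple[int, int]
    genotype: str
    replicate: str
    trait_name: str
    value: float


def trial_frame(obs: Sequence[TrialObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "year": [o.environment[0] for o in obs],
            "tos": [o.environment[1] for o in obs],
            "genotype": [o.genotype for o in obs],
            "replicate": [o.replicate for o in obs],
            "trait_name": [o.trait_name for o in obs],
            "value": [o.value for o in obs],
        }
    )


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    sigma2_block: float
    n_reps_effective: float
    method: str                      # "anova_mom" or "reml"
    truncated: bool = False          # a negative MoM component was set to 0
    loglik: float | None = None
    n_iter: int = 0


@dataclass(frozen=True)
class HeritabilityResult:
    H2: float
    basis: str = "line-mean"
    undefined: bool = False


@dataclass(frozen=True)
class WaldResult:
    term: str
    wald_chi2: float
    df: int
    wald_f: float
    p_value: float
    p_chi2: float
    significance: str


# ---------------------------------------------------------------------------
# per-environment RCBD fit

def _is_balanced(df: pd.DataFrame) -> bool:
    counts = df.groupby(["genotype", "replicate"], observed=True).size()
    g = df["genotype"].nunique()
    r = df["replicate"].nunique()
    return len(counts) == g * r and (counts == 1).all()


def _anova_mom(df: pd.DataFrame) -> VarianceComponents:
    y = df["value"].to_numpy(dtype=float)
    g = df["genotype"].nunique()
    r = df["replicate"].nunique()
    grand = y.mean()
    gm = df.groupby("genotype", observed=True)["value"].mean()
    bm = df.groupby("replicate", observed=True)["value"].mean()
    ssg = r * float(((gm - grand) ** 2).sum())
    ssb = g * float(((bm - grand) ** 2).sum())
    sst = float(((y - grand) ** 2).sum())
    sse = max(sst - ssg - ssb, 0.0)
    msg = ssg / (g - 1)
    mse = sse / ((g - 1) * (r - 1))
    s2g_raw = (msg - mse) / r
    truncated = s2g_raw < 0
    msb = ssb / (r - 1)
    s2b = max((msb - mse) / g, 0.0)
    return VarianceComponents(
        sigma2_g=max(s2g_raw, 0.0),
        sigma2_e=mse,
        sigma2_block=s2b,
        n_reps_effective=float(r),
        method="anova_mom",
        truncated=truncated,
    )


def _indicator(labels: pd.Series) -> np.ndarray:
    codes, _ = pd.factorize(labels)
    Z = np.zeros((len(codes), codes.max() + 1))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


def _reml_neg2loglik(y, X, Gs, sigmas):
    n, p = X.shape
    V = sigmas[-1] * np.eye(n)
    for G, s in zip(Gs, sigmas[:-1]):
        V += s * G
    L = np.linalg.cholesky(V)
    logdet_v = 2.0 * np.sum(np.log(np.diag(L)))
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    sign, logdet_x = np.linalg.slogdet(XtViX)
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    Py = Vi_y - Vi_X @ beta
    return logdet_v + logdet_x + float(y @ Py), Py, Vi_X, XtViX, V


def _fisher_reml(y, X, Gs, start, tol=1e-8, max_iter=200):
    """Fisher-scoring REML for variance components (last entry = residual).

    Stops when successive REML log-likelihoods differ by < tol.  Components
    driven to the boundary are clamped at a small floor and truncated to 0
    on exit.
    """
    n = len(y)
    scale = float(np.var(y)) or 1.0
    floor = 1e-10 * scale
    sigmas = np.maximum(np.asarray(start, dtype=float), floor)
    all_G = list(Gs) + [np.eye(n)]
    crit, Py, *_ = _reml_neg2loglik(y, X, Gs, sigmas)
    trace = [(-0.5 * crit, sigmas.copy())]
    for it in range(1, max_iter + 1):
        # score_i = -1/2 (tr(P G_i) - y'P G_i P y);  info_ij = 1/2 tr(P G_i P G_j)
        _, Py, Vi_X, XtViX, V = _reml_neg2loglik(y, X, Gs, sigmas)
        Vi = np.linalg.inv(V)
        P = Vi - Vi_X @ np.linalg.solve(XtViX, Vi_X.T)
        PG = [P @ G for G in all_G]
        k = len(all_G)
        score = np.array(
            [-0.5 * (np.trace(PG[i]) - float(Py @ all_G[i] @ Py)) for i in range(k)]
        )
        info = np.empty((k, k))
        for i in range(k):
            for j in range(i, k):
                info[i, j] = info[j, i] = 0.5 * np.trace(PG[i] @ PG[j])
        try:
            step = np.linalg.solve(info + 1e-12 * np.eye(k), score)
        except np.linalg.LinAlgError:
            raise ConvergenceError("singular information matrix", trace)
        # step-halving to keep components positive and the likelihood improving
        lam = 1.0
        for _ in range(40):
            cand = np.maximum(sigmas + lam * step, floor)
            cand_crit, *_ = _reml_neg2loglik(y, X, Gs, cand)
            if cand_crit <= crit + 1e-12:
                break
            lam *= 0.5
        else:
            cand, cand_crit = sigmas, crit
        delta = abs(cand_crit - crit)
        sigmas, crit = cand, cand_crit
        trace.append((-0.5 * crit, sigmas.copy()))
        if delta < tol:
            out = sigmas.copy()
            out[out <= 2 * floor] = 0.0
            return out, -0.5 * crit, it
    raise ConvergenceError(f"REML did not converge in {max_iter} iterations", trace)


def fit_rcbd(
    df: pd.DataFrame,
    genotype_random: bool = True,
    method: str = "auto",
) -> tuple[VarianceComponents, dict]:
    """Fit one environment's RCBD and return variance components + effects.

    ``df`` needs columns genotype, replicate, value.  ``method`` is
    ``auto`` (ANOVA for balanced data, REML otherwise), ``anova`` or
    ``reml``.  Effects are the grand mean and raw genotype means.
    """
    if not genotype_random:
        raise NotImplementedError("genotype must be random for variance components")
    if df["genotype"].nunique() < 2:
        raise InsufficientDesign("need >= 2 genotypes")
    if df["replicate"].nunique() < 2:
        raise InsufficientDesign("need >= 2 replicates")
    if not np.all(np.isfinite(df["value"].to_numpy(dtype=float))):
        raise ValueError("non-finite trait values")
    balanced = _is_balanced(df)
    if method == "auto":
        method = "anova" if balanced else "reml"
    if method == "anova":
        if not balanced:
            raise InsufficientDesign("ANOVA method-of-moments requires balanced data")
        vc = _anova_mom(df)
    elif method == "reml":
        y = df["value"].to_numpy(dtype=float)
        X = np.ones((len(y), 1))
        Zg = _indicator(df["genotype"])
        Zb = _indicator(df["replicate"])
        Gs = [Zg @ Zg.T, Zb @ Zb.T]
        if balanced:
            mom = _anova_mom(df)
            start = [max(mom.sigma2_g, 1e-6), max(mom.sigma2_block, 1e-6),
                     max(mom.sigma2_e, 1e-6)]
        else:
            v = float(np.var(y, ddof=1)) or 1.0
            start = [v / 3, v / 3, v / 3]
        sig, ll, it = _fisher_reml(y, X, Gs, start)
        reps = df.groupby("genotype", observed=True).size().to_numpy(dtype=float)
        r_eff = len(reps) / float(np.sum(1.0 / reps))
        vc = VarianceComponents(
            sigma2_g=float(sig[0]),
            sigma2_e=float(sig[2]),
            sigma2_block=float(sig[1]),
            n_reps_effective=r_eff,
            method="reml",
            loglik=ll,
            n_iter=it,
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    effects = {
        "grand_mean": float(df["value"].mean()),
        "genotype_means": df.groupby("genotype", observed=True)["value"].mean(),
    }
    return vc, effects


def heritability(
    vc: VarianceComponents,
    r: float | None = None,
    basis: str = "line-mean",
) -> HeritabilityResult:
    """Broad-sense heritability H^2 = sigma2_g / (sigma2_g + sigma2_e / r).

    ``basis='cullis'`` reports the generalised (prediction-accuracy based)
    heritability 1 - PEV/sigma2_g, which coincides with the line-mean form
    for balanced designs.  Both components zero is undefined and reported
    as 0 with a flag.
    """
    r = vc.n_reps_effective if r is None else float(r)
    if r < 1:
        raise ValueError("need r >= 1 replicates")
    s2g, s2e = vc.sigma2_g, vc.sigma2_e
    if s2g == 0 and s2e == 0:
        return HeritabilityResult(0.0, basis=basis, undefined=True)
    if s2g == 0:
        return HeritabilityResult(0.0, basis=basis)
    if basis == "line-mean":
        return HeritabilityResult(s2g / (s2g + s2e / r), basis=basis)
    if basis == "cullis":
        pev = (s2g * s2e / r) / (s2g + s2e / r)
        return HeritabilityResult(1.0 - pev / s2g, basis=basis)
    raise ValueError(f"unknown heritability basis {basis!r}")


def blup(
    vc: VarianceComponents,
    genotype_means: pd.Series,
    grand_mean: float,
    r: float | None = None,
) -> pd.Series:
    """Genotype BLUPs: shrink mean deviations toward the grand mean.

    For a balanced single-environment fit the shrinkage factor equals H^2,
    so BLUP_g = H^2 * (ybar_g - grand mean).
    """
    r = vc.n_reps_effective if r is None else float(r)
    denom = vc.sigma2_g + vc.sigma2_e / r
    shrink = 0.0 if denom == 0 else vc.sigma2_g / denom
    return (genotype_means - grand_mean) * shrink


# ---------------------------------------------------------------------------
# multi-environment Wald tests

def significance_code(p: float) -> str:
    """Map a p-value to the conventional star code (NS above 0.05)."""
    if not (0 < p <= 1):
        raise ValueError(f"p-value {p} outside (0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def _term_columns(df: pd.DataFrame, factors: list[str]) -> np.ndarray:
    key = df[factors[0]].astype(str)
    for f in factors[1:]:
        key = key + ":" + df[f].astype(str)
    return _indicator(key)


def _rank_reduce(blocks: list[tuple[str, np.ndarray]], n: int, tol: float = 1e-8):
    """Keep, term by term, only columns that increase the design rank."""
    Q = np.zeros((n, 0))
    cols: list[np.ndarray] = []
    spans: list[tuple[str, int, int]] = []   # (term, start, stop) into cols
    for name, Z in blocks:
        start = len(cols)
        for j in range(Z.shape[1]):
            c = Z[:, j]
            resid = c - Q @ (Q.T @ c)
            nrm = np.linalg.norm(resid)
            if nrm > tol * max(np.linalg.norm(c), 1.0):
                Q = np.column_stack([Q, resid / nrm])
                cols.append(c)
        spans.append((name, start, len(cols)))
    X = np.column_stack(cols) if cols else np.zeros((n, 0))
    return X, spans


def _whiten(M: np.ndarray, gamma: float, block_codes: np.ndarray, block_sizes: np.ndarray):
    """Transform so that cov of residuals becomes sigma2_e * I.

    For V = sigma2_e (I + gamma Z Z') with Z a block indicator,
    A^{-1/2} x = x - c_b * blockmean(x) with c_b = 1 - 1/sqrt(1 + gamma m_b).
    """
    if gamma == 0:
        return M
    one_d = M.ndim == 1
    M2 = M[:, None] if one_d else M
    sums = np.zeros((len(block_sizes), M2.shape[1]))
    np.add.at(sums, block_codes, M2)
    means = sums / block_sizes[:, None]
    c = 1.0 - 1.0 / np.sqrt(1.0 + gamma * block_sizes)
    out = M2 - c[block_codes, None] * means[block_codes]
    return out[:, 0] if one_d else out


def met_wald(
    df: pd.DataFrame,
    trait: str = "value",
    random: str | None = "replicate_within_environment",
) -> list[WaldResult]:
    """Sequential Wald tests for the multi-environment fixed-effect model.

    Terms enter in the order Year, Environment (time of sowing),
    Year:Environment, Genotype, Genotype:Environment, where the
    genotype-by-environment cells use the (year, tos) combination.
    Replicate-within-environment is a random intercept whose variance
    ratio is estimated by profiled REML.  Columns that do not increase
    the design rank after earlier terms are dropped (df reduced).
    """
    df = df.reset_index(drop=True)
    envs = df["year"].astype(str) + "_" + df["tos"].astype(str)
    if envs.nunique() < 2:
        raise InsufficientDesign("need >= 2 environments")
    work = df.assign(env=envs)
    y = work[trait].to_numpy(dtype=float)
    n = len(y)

    blocks = [("intercept", np.ones((n, 1)))]
    blocks.append(("year", _term_columns(work, ["year"])))
    blocks.append(("environment", _term_columns(work, ["tos"])))
    blocks.append(("year:environment", _term_columns(work, ["year", "tos"])))
    blocks.append(("genotype", _term_columns(work, ["genotype"])))
    blocks.append(("genotype:environment", _term_columns(work, ["genotype", "env"])))
    X, spans = _rank_reduce(blocks, n)
    p = X.shape[1]
    if n - p < 1:
        raise InsufficientDesign("no residual degrees of freedom")

    if random == "replicate_within_environment":
        grp = work["env"].astype(str) + "/" + work["replicate"].astype(str)
        codes, uniq = pd.factorize(grp)
        sizes = np.bincount(codes).astype(float)

        def crit(gamma: float) -> float:
            Xw = _whiten(X, gamma, codes, sizes)
            yw = _whiten(y, gamma, codes, sizes)
            G = Xw.T @ Xw
            beta = np.linalg.solve(G, Xw.T @ yw)
            rss = float(yw @ yw - beta @ (Xw.T @ yw))
            _, logdet_g = np.linalg.slogdet(G)
            log_a = float(np.sum(np.log1p(gamma * sizes)))
            return (n - p) * np.log(max(rss, 1e-300)) + log_a + logdet_g

        res = optimize.minimize_scalar(crit, bounds=(0.0, 1e3), method="bounded",
                                       options={"xatol": 1e-8})
        gamma = float(res.x) if res.fun <= crit(0.0) else 0.0
    elif random is None:
        codes = np.zeros(n, dtype=int)
        sizes = np.array([float(n)])
        gamma = 0.0
    else:
        raise ValueError(f"unknown random specification {random!r}")

    Xw = _whiten(X, gamma, codes, sizes)
    yw = _whiten(y, gamma, codes, sizes)
    Q, R = np.linalg.qr(Xw)
    qty = Q.T @ yw
    rss = float(yw @ yw - qty @ qty)
    sigma2_e = rss / (n - p)

    results = []
    dendf = n - p
    for name, start, stop in spans:
        if name == "intercept":
            continue
        dfj = stop - start
        if dfj == 0:
            results.append(WaldResult(name, 0.0, 0, float("nan"), 1.0, 1.0, "NS"))
            continue
        w = float(np.sum(qty[start:stop] ** 2)) / sigma2_e
        wald_f = w / dfj
        p_f = float(stats.f.sf(wald_f, dfj, dendf))
        p_c = float(stats.chi2.sf(w, dfj))
        results.append(
            WaldResult(name, w, dfj, wald_f, max(p_f, np.nextafter(0, 1)),
                       max(p_c, np.nextafter(0, 1)), significance_code(max(p_f, 1e-300)))
        )
    return results
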