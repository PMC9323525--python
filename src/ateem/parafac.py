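"""Trilinear PARAFAC decomposition of EEM arrays with model diagnostics.

The model is X_ijk = sum_f a_if * b_jf * c_kf + e_ijk: per-sample scores
(mode A) and emission / excitation loading spectra (modes B and C) of F
fluorescent components. Fitting is alternating least squares (ALS) on the
observed (non-excised) cells only -- scatter-masked cells are ignored in
every least-squares update, never imputed -- with optional non-negativity
on all three modes, which matches the physical meaning of concentrations
and spectra. B and C columns are scaled to unit Euclidean norm so the
scores carry the intensity scale.

Diagnostics follow multiway practice: explained variance, the core
consistency diagnostic (CORCONDIA; distance of the least-squares Tucker3
core from the superidentity), and split-half validation with component
matching by Tucker congruence.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment, nnls

from .core import EEMDataset
from .errors import ClassError, DimensionError

__all__ = [
    "ParafacModel",
    "fit_parafac",
    "explained_variance",
    "core_consistency",
    "split_half",
    "select_n_components",
    "match_components",
    "compare_class_scores",
    "tucker_congruence",
    "congruence_matrix",
]


# ---------------------------------------------------------------------------
# Congruence helpers
# ---------------------------------------------------------------------------


def tucker_congruence(u: np.ndarray, v: np.ndarray) -> float:
    """Tucker congruence coefficient (cosine similarity) of two vectors."""
    u = np.asarray(u, float).ravel()
    v = np.asarray(v, float).ravel()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


def congruence_matrix(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Pairwise congruences between the columns of U and V."""
    U = np.asarray(U, float)
    V = np.asarray(V, float)
    un = np.linalg.norm(U, axis=0)
    vn = np.linalg.norm(V, axis=0)
    un[un == 0] = 1.0
    vn[vn == 0] = 1.0
    return (U / un).T @ (V / vn)


# ---------------------------------------------------------------------------
# Exact small-dimension NNLS from normal equations
# ---------------------------------------------------------------------------


def _nnls_gram(G: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Row-wise non-negative least squares from normal equations.

    Solves min_x 0.5 x'Gx - h'x subject to x >= 0 for every row h of H.
    ``G`` is (F, F) (shared) or (R, F, F) (per row). For the small F used
    here the unique KKT point is found by enumerating active sets, solving
    each candidate support in a batch across rows.
    """
    H = np.atleast_2d(H)
    R, F = H.shape
    shared = G.ndim == 2
    scale = np.trace(G) if shared else np.trace(G, axis1=1, axis2=2).max()
    eps = 1e-10 * max(scale, 1.0)
    G = G + (1e-12 * scale) * np.eye(F)  # guards nearly collinear components
    if F > 10:  # enumeration blows up; fall back to scipy per row
        return _nnls_gram_fallback(G, H)
    # the unconstrained solution is optimal wherever it is feasible; only
    # the violating rows need the support enumeration
    try:
        if shared:
            X = np.linalg.solve(G, H.T).T
        else:
            X = np.linalg.solve(G, H[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError:
        return _nnls_gram_fallback(G, H)
    pend = ~(X >= -eps).all(axis=1)
    X = np.clip(X, 0.0, None)
    if not pend.any():
        return X
    rows = np.nonzero(pend)[0]
    Hp = H[rows]
    Gp = G if shared else G[rows]
    Xp = np.zeros((len(rows), F))
    best_obj = np.zeros(len(rows))  # objective of x = 0
    # the constrained optimum has an active zero, so supports of size < F
    # suffice; evaluate each support's stationary point where feasible and
    # keep the lowest objective (exact for positive-definite Grams)
    for size in range(1, F):
        for S in itertools.combinations(range(F), size):
            S = list(S)
            Gss = Gp[np.ix_(S, S)] if shared else Gp[:, S][:, :, S]
            try:
                if shared:
                    xs = np.linalg.solve(Gss, Hp[:, S].T).T
                else:
                    xs = np.linalg.solve(Gss, Hp[:, S, None])[:, :, 0]
            except np.linalg.LinAlgError:
                continue
            feas = (xs >= -eps).all(axis=1)
            if not feas.any():
                continue
            xs = np.clip(xs, 0.0, None)
            if shared:
                obj = 0.5 * ((xs @ Gss) * xs).sum(axis=1) - (
                    xs * Hp[:, S]
                ).sum(axis=1)
            else:
                obj = 0.5 * (
                    np.matmul(Gss, xs[:, :, None])[:, :, 0] * xs
                ).sum(axis=1) - (xs * Hp[:, S]).sum(axis=1)
            better = feas & (obj < best_obj)
            if better.any():
                Xp[better] = 0.0
                Xp[np.ix_(np.nonzero(better)[0], S)] = xs[better]
                best_obj[better] = obj[better]
    X[rows] = Xp
    return X


def _nnls_gram_fallback(G: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Lawson-Hanson NNLS per row via a Cholesky square root of the Gram."""
    H = np.atleast_2d(H)
    R, F = H.shape
    out = np.zeros((R, F))
    shared = G.ndim == 2
    for r in range(R):
        Gr = G if shared else G[r]
        Gr = Gr + 1e-12 * np.trace(Gr) * np.eye(F)
        L = np.linalg.cholesky(Gr)
        y = np.linalg.solve(L, H[r])
        out[r], _ = nnls(L.T, y)
    return out


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------


@dataclass
class ParafacModel:
    """A fitted trilinear model: scores A and unit-norm loadings B, C."""

    n_components: int
    scores: np.ndarray  # (n_samples, F), intensity-scaled
    em_loadings: np.ndarray  # (|em|, F), unit-norm columns
    ex_loadings: np.ndarray  # (|ex|, F), unit-norm columns
    fit_percent: float = np.nan
    corcondia: float | None = None
    n_iter: int = 0
    converged: bool = False
    sse_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    def reconstruct(self) -> np.ndarray:
        return np.einsum(
            "if,jf,kf->ijk", self.scores, self.em_loadings, self.ex_loadings
        )


def _as_array(X) -> np.ndarray:
    if isinstance(X, EEMDataset):
        return X.masked_array()
    return np.asarray(X, dtype=float)


# ---------------------------------------------------------------------------
# ALS fitting
# ---------------------------------------------------------------------------


def _als_once(
    X0: np.ndarray,
    W: np.ndarray,
    uniform_mask: bool,
    F: int,
    nonneg: bool,
    tol: float,
    max_iter: int,
    rng: np.random.Generator,
):
    """One ALS run from a random start; returns (A, B, C, sse_history, converged)."""
    n, J, K = X0.shape
    W2 = W[0] if uniform_mask else None
    sst = float((X0**2).sum())
    A = rng.uniform(0.1, 1.0, (n, F))
    B = rng.uniform(0.1, 1.0, (J, F))
    C = rng.uniform(0.1, 1.0, (K, F))

    def qobj(G, H, X):
        """Row-wise 0.5 x'Gx - h'x for shared or per-row Grams."""
        GX = X @ G.T if G.ndim == 2 else np.matmul(G, X[:, :, None])[:, :, 0]
        return 0.5 * (GX * X).sum(axis=1) - (X * H).sum(axis=1)

    def solve(G, H, prev_X):
        if nonneg:
            new = _nnls_gram(G, H)
        elif G.ndim == 2:
            new = np.linalg.solve(G + 1e-12 * np.trace(G) * np.eye(F), H.T).T
        else:
            ridge = 1e-12 * np.trace(G, axis1=1, axis2=2).max()
            new = np.linalg.solve(G + ridge * np.eye(F), H[:, :, None])[:, :, 0]
        # ill-conditioned Grams (near-duplicate components) can yield a
        # numerically bad row; never accept an update that worsens it
        worse = qobj(G, H, new) > qobj(G, H, prev_X)
        if worse.any():
            new[worse] = prev_X[worse]
        return new

    # einsum contraction paths are shape-stable across iterations
    paths: dict[str, list] = {}

    def ein(key, subscripts, *ops):
        if key not in paths:
            paths[key] = np.einsum_path(subscripts, *ops, optimize="greedy")[0]
        return np.einsum(subscripts, *ops, optimize=paths[key])

    history = []
    prev = np.inf
    converged = False
    for it in range(max_iter):
        if uniform_mask:
            # mode A: shared Gram since every sample sees the same cells
            G = ein("ga", "jk,jf,jg,kf,kg->fg", W2, B, B, C, C)
            H = ein("ha", "ijk,jf,kf->if", X0, B, C)
            A = solve(G, H, A)
            AtA = A.T @ A
            CWC = ein("gb", "jk,kf,kg->jfg", W2, C, C)
            H = ein("hb", "ijk,if,kf->jf", X0, A, C)
            B = solve(AtA[None] * CWC, H, B)
            BWB = ein("gc", "jk,jf,jg->kfg", W2, B, B)
            AtA = A.T @ A
            H = ein("hc", "ijk,if,jf->kf", X0, A, B)
            C = solve(AtA[None] * BWB, H, C)
        else:
            G = ein("ga", "ijk,jf,jg,kf,kg->ifg", W, B, B, C, C)
            H = ein("ha", "ijk,jf,kf->if", X0, B, C)
            A = solve(G, H, A)
            G = ein("gb", "ijk,if,ig,kf,kg->jfg", W, A, A, C, C)
            H = ein("hb", "ijk,if,kf->jf", X0, A, C)
            B = solve(G, H, B)
            G = ein("gc", "ijk,if,ig,jf,jg->kfg", W, A, A, B, B)
            H = ein("hc", "ijk,if,jf->kf", X0, A, B)
            C = solve(G, H, C)

        # rescale: push magnitudes into A, revive dead components
        revived = False
        for M in (B, C):
            norms = np.linalg.norm(M, axis=0)
            dead = norms < 1e-12
            if dead.any():
                M[:, dead] = rng.uniform(0.1, 1.0, (M.shape[0], int(dead.sum())))
                norms = np.linalg.norm(M, axis=0)
                revived = True
            A *= norms
            M /= norms

        R = ein("rec", "if,jf,kf->ijk", A, B, C)
        sse = float((((X0 - R) ** 2) * W).sum())
        history.append(sse)
        if revived:
            prev = np.inf  # reinjection may raise the objective once
            continue
        if np.isfinite(prev):
            if sse > prev * (1 + 1e-7) + 1e-10 * sst:
                raise ArithmeticError(
                    f"ALS objective increased at iteration {it}: {prev} -> {sse}"
                )
            if prev - sse <= tol * max(prev, 1e-300) or sse <= 1e-14 * max(sst, 1.0):
                converged = True
                prev = sse
                break
        prev = sse
    return A, B, C, np.asarray(history), converged


def fit_parafac(
    X,
    n_components: int,
    nonneg: bool = True,
    tol: float = 1e-8,
    max_iter: int = 2000,
    n_starts: int = 10,
    seed: int | None = None,
    compute_corcondia: bool = True,
) -> ParafacModel:
    """Fit an F-component (non-negative) PARAFAC model by multi-start ALS.

    ``X`` is an :class:`~ateem.core.EEMDataset` or an array
    (samples x emission x excitation) with NaN marking excised cells.
    Missing cells are excluded from every least-squares update. The best
    of ``n_starts`` random initialisations (by residual sum of squares)
    is kept; components are sorted by explained sum of squares, B and C
    columns are unit-normalised with the magnitude pushed into the
    scores, and (without the non-negativity constraint) each loading's
    largest-magnitude element is made positive.
    """
    Xa = _as_array(X)
    F = int(n_components)
    if F < 1:
        raise DimensionError("n_components must be >= 1")
    if Xa.ndim != 3:
        raise DimensionError("X must be a three-way array")
    if min(Xa.shape) < F:
        raise DimensionError(
            f"n_components={F} exceeds a mode dimension of {Xa.shape}"
        )
    W = np.isfinite(Xa)
    if not W.any():
        raise DimensionError("X has no observed cells")
    X0 = np.where(W, Xa, 0.0)
    Wf = W.astype(float)
    uniform = bool(np.all(W == W[0]))

    ss = np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(max(1, int(n_starts))):
        rng = np.random.default_rng(child)
        A, B, C, hist, conv = _als_once(
            X0, Wf, uniform, F, nonneg, tol, max_iter, rng
        )
        if best is None or hist[-1] < best[3][-1]:
            best = (A, B, C, hist, conv)
    A, B, C, hist, conv = best
    if not conv:
        warnings.warn(
            f"PARAFAC did not converge within {max_iter} iterations "
            f"(relative tol {tol:g})",
            stacklevel=2,
        )

    # sort components by explained sum of squares (B, C are unit norm)
    order = np.argsort(-np.linalg.norm(A, axis=0))
    A, B, C = A[:, order], B[:, order], C[:, order]
    if not nonneg:  # resolve sign indeterminacy
        for M in (B, C):
            for f in range(F):
                j = np.argmax(np.abs(M[:, f]))
                if M[j, f] < 0:
                    M[:, f] *= -1.0
                    A[:, f] *= -1.0

    sst = float((X0**2)[W].sum())
    fit_pct = 100.0 * (1.0 - hist[-1] / sst) if sst > 0 else np.nan
    model = ParafacModel(
        n_components=F,
        scores=A,
        em_loadings=B,
        ex_loadings=C,
        fit_percent=fit_pct,
        n_iter=len(hist),
        converged=conv,
        sse_history=hist,
    )
    if compute_corcondia:
        try:
            model.corcondia = core_consistency(model, Xa)
        except ArithmeticError as e:
            # overfactored models can produce near-duplicate components;
            # report the diagnostic as undefined rather than aborting
            warnings.warn(f"CORCONDIA undefined: {e}", stacklevel=2)
            model.corcondia = float("nan")
    return model


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def explained_variance(model: ParafacModel, X) -> float:
    """Percent of the observed sum of squares explained by the model."""
    Xa = _as_array(X)
    W = np.isfinite(Xa)
    if not W.any():
        raise DimensionError("X has no observed cells")
    R = model.reconstruct()
    sst = float((Xa[W] ** 2).sum())
    ssr = float(((Xa - R)[W] ** 2).sum())
    if sst == 0:
        raise DimensionError("X has zero total sum of squares")
    return 100.0 * (1.0 - ssr / sst)


def core_consistency(model: ParafacModel, X) -> float:
    """Core consistency diagnostic (CORCONDIA) in percent.

    With A, B, C fixed, the least-squares Tucker3 core G (F x F x F) is
    computed over the observed cells and compared with the superidentity
    T (ones on the superdiagonal): 100 * (1 - ||G - T||^2 / ||T||^2).
    Near 100 supports the trilinear structure and the component count.
    """
    Xa = _as_array(X)
    A, B, C = model.scores, model.em_loadings, model.ex_loadings
    F = model.n_components
    W = np.isfinite(Xa)
    obs = np.nonzero(W.ravel())[0]
    # explicit design restricted to observed cells: columns indexed (d,e,f)
    D = np.einsum("id,je,kf->ijkdef", A, B, C).reshape(-1, F**3)[obs]
    y = Xa.ravel()[obs]
    G = D.T @ D
    cond = np.linalg.cond(G)
    if cond > 1e12:
        raise ArithmeticError(
            f"loading matrices are numerically singular (cond={cond:.3g})"
        )
    g = np.linalg.solve(G, D.T @ y)
    t = np.zeros(F**3)
    t[[f * F**2 + f * F + f for f in range(F)]] = 1.0
    return float(100.0 * (1.0 - ((g - t) ** 2).sum() / (t**2).sum()))


def match_components(model_a: ParafacModel, model_b: ParafacModel):
    """Match components of two models by spectral congruence.

    Maximises total mean |congruence| over emission and excitation
    loadings (Hungarian assignment). Returns ``(perm, cong_em, cong_ex)``
    where component f of ``model_a`` is paired with ``perm[f]`` of
    ``model_b``.
    """
    if model_a.n_components != model_b.n_components:
        raise DimensionError("models have different numbers of components")
    cb = np.abs(congruence_matrix(model_a.em_loadings, model_b.em_loadings))
    cc = np.abs(congruence_matrix(model_a.ex_loadings, model_b.ex_loadings))
    score = (cb + cc) / 2.0
    ri, ci = linear_sum_assignment(-score)
    perm = np.empty(model_a.n_components, dtype=int)
    perm[ri] = ci
    cong_em = cb[ri, ci][np.argsort(ri)]
    cong_ex = cc[ri, ci][np.argsort(ri)]
    return perm, cong_em, cong_ex


def split_half(
    X,
    n_components: int,
    scheme: str = "stratified",
    seed: int | None = None,
    labels=None,
    return_details: bool = False,
    **fit_kwargs,
):
    """Split-half validation: similarity (percent) of two half-data models.

    Samples are partitioned into two halves (random, or stratified by
    class when labels are supplied), each half is fitted independently,
    components are matched by Tucker congruence, and the similarity is
    100 x the mean absolute congruence over emission and excitation
    loadings of the matched components.
    """
    Xa = _as_array(X)
    if labels is None and isinstance(X, EEMDataset):
        labels = X.labels
    n = Xa.shape[0]
    if n < 2 * n_components:
        raise DimensionError(
            f"need at least {2 * n_components} samples for split-half"
        )
    rng = np.random.default_rng(seed)
    if scheme == "stratified" and labels is not None:
        half1, half2 = [], []
        for cls in pd.unique(np.asarray(labels)):
            idx = np.nonzero(np.asarray(labels) == cls)[0]
            idx = rng.permutation(idx)
            half1.extend(idx[0::2])
            half2.extend(idx[1::2])
        half1, half2 = np.sort(half1), np.sort(half2)
    else:
        idx = rng.permutation(n)
        half1, half2 = np.sort(idx[: n // 2]), np.sort(idx[n // 2:])
    if min(len(half1), len(half2)) < n_components:
        raise DimensionError("a half has fewer samples than components")
    fit_kwargs.setdefault("seed", int(rng.integers(2**31 - 1)))
    fit_kwargs.setdefault("compute_corcondia", False)
    m1 = fit_parafac(Xa[half1], n_components, **fit_kwargs)
    fit_kwargs["seed"] = fit_kwargs["seed"] + 1
    m2 = fit_parafac(Xa[half2], n_components, **fit_kwargs)
    perm, cong_em, cong_ex = match_components(m1, m2)
    similarity = float(100.0 * np.mean(np.concatenate([cong_em, cong_ex])))
    if return_details:
        return similarity, {
            "half1": half1,
            "half2": half2,
            "model1": m1,
            "model2": m2,
            "perm": perm,
            "cong_em": cong_em,
            "cong_ex": cong_ex,
        }
    return similarity


def select_n_components(
    X,
    candidates,
    corcondia_floor: float = 80.0,
    labels=None,
    seed: int | None = None,
    **fit_kwargs,
):
    """Scan candidate component counts; pick by core consistency.

    The chosen F is the largest candidate whose CORCONDIA stays at or
    above ``corcondia_floor``; if none passes, the smallest candidate is
    returned with a warning. A diagnostics table (fit %, CORCONDIA,
    split-half similarity per candidate) is always returned alongside.
    """
    candidates = sorted(int(f) for f in candidates)
    if not candidates:
        raise DimensionError("candidate list is empty")
    Xa = _as_array(X)
    if labels is None and isinstance(X, EEMDataset):
        labels = X.labels
    ss = np.random.SeedSequence(seed)
    rows = []
    for F, child in zip(candidates, ss.spawn(len(candidates))):
        rng = np.random.default_rng(child)
        mseed = int(rng.integers(2**31 - 1))
        model = fit_parafac(Xa, F, seed=mseed, **fit_kwargs)
        sim = split_half(
            Xa,
            F,
            labels=labels,
            seed=int(rng.integers(2**31 - 1)),
            **fit_kwargs,
        )
        rows.append(
            {
                "n_components": F,
                "fit_percent": model.fit_percent,
                "corcondia": model.corcondia,
                "split_half_similarity": sim,
            }
        )
    table = pd.DataFrame(rows).set_index("n_components")
    passing = table.index[table["corcondia"] >= corcondia_floor]
    if len(passing) == 0:
        warnings.warn(
            f"no candidate reaches CORCONDIA >= {corcondia_floor}; "
            f"returning the smallest candidate {candidates[0]}",
            stacklevel=2,
        )
        return candidates[0], table
    return int(passing.max()), table


def compare_class_scores(scores: np.ndarray, labels) -> pd.DataFrame:
    """Two-sample Student's t-test of component scores between two classes.

    Returns one row per component with class means +- sd, the pooled-
    variance t statistic, its p-value, and a significance flag at the
    0.05 level.
    """
    scores = np.atleast_2d(np.asarray(scores, float))
    labels = np.asarray(labels)
    classes = [c for c in ("direct", "processed") if c in labels]
    if len(classes) != 2:
        classes = list(pd.unique(labels))
    if len(classes) != 2:
        raise ClassError(f"need exactly two classes, got {list(classes)}")
    g1 = scores[labels == classes[0]]
    g2 = scores[labels == classes[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ClassError("each class needs at least 2 samples")
    rows = []
    for f in range(scores.shape[1]):
        t, p = stats.ttest_ind(g1[:, f], g2[:, f], equal_var=True)
        rows.append(
            {
                "component": f + 1,
                f"mean_{classes[0]}": g1[:, f].mean(),
                f"sd_{classes[0]}": g1[:, f].std(ddof=1),
                f"mean_{classes[1]}": g2[:, f].mean(),
                f"sd_{classes[1]}": g2[:, f].std(ddof=1),
                "t": float(t),
                "p_value": float(p),
                "significant": bool(p < 0.05),
            }
        )
    return pd.DataFrame(rows).set_index("component")
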