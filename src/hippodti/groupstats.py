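"""Group and age statistics for parcel tables and vertex maps.

Three layers mirror the study design this package supports:

* **Hemisphere x group screening** — for each metric, a nested-model F-test
  compares ``DV ~ age + hemi + group + age:group + age:hemi`` against the
  same model plus ``hemi:group``.  Metrics without a significant interaction
  (after BH-FDR across metrics) have their hemispheres averaged.
* **Parcel-level group differences** — Welch's ANOVA per parcel (robust to
  unequal variances and group sizes), BH-FDR over the parcel family
  (5 subfields or 3 anterior-posterior bins) per metric, then Games-Howell
  pairwise post-hoc tests at alpha = 0.01 wherever the corrected ANOVA is
  significant.
* **Vertex-wise linear models** — per-vertex OLS
  ``DV_vertex ~ age + thickness_vertex + sex + age:sex`` fitted per group for
  age-contrast t-maps, or pooled with group dummies (AD as the reference
  level, so encoded in the intercept) for MCI/CN group-contrast t-maps.

Categorical terms are dummy-coded against fixed reference levels: group AD,
sex F, hemisphere L.  All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError

GROUPS = ("AD", "MCI", "CN")
REFERENCE_LEVELS = {"group": "AD", "sex": "F", "hemi": "L"}


# ---------------------------------------------------------------------------
# linear-model core
# ---------------------------------------------------------------------------

@dataclass
class LinearFit:
    terms: tuple[str, ...]
    column_names: tuple[str, ...]
    coef: np.ndarray
    rss: float
    df_resid: int
    n: int


@dataclass
class FTestResult:
    F: float
    df_num: float
    df_den: float
    p: float
    degenerate: bool = False


def _encode_column(data: pd.DataFrame, var: str) -> tuple[np.ndarray, list[str]]:
    """One variable -> columns. Categoricals are dummy-coded vs the reference."""
    col = data[var]
    if var in REFERENCE_LEVELS or col.dtype == object or isinstance(
        col.dtype, pd.CategoricalDtype
    ):
        ref = REFERENCE_LEVELS.get(var)
        levels = sorted((l for l in pd.unique(col) if l != ref), key=str)
        if not levels:  # only the reference level present: nothing to encode
            return np.empty((len(col), 0)), []
        cols = np.column_stack([(col == l).to_numpy(float) for l in levels])
        return cols, [f"{var}[{l}]" for l in levels]
    return col.to_numpy(float)[:, None], [var]


def build_design(data: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[str]]:
    """Design matrix with intercept from a list of terms.

    Terms are variable names or two-way interactions written ``a:b``
    (elementwise products of the encoded columns).
    """
    cols = [np.ones((len(data), 1))]
    names = ["Intercept"]
    for term in terms:
        parts = term.split(":")
        enc = [_encode_column(data, p) for p in parts]
        block, bnames = enc[0]
        for nxt, nxt_names in enc[1:]:
            block = np.einsum("ni,nj->nij", block, nxt).reshape(len(data), -1)
            bnames = [f"{a}:{b}" for a in bnames for b in nxt_names]
        cols.append(block)
        names.extend(bnames)
    return np.concatenate(cols, axis=1), names


def fit_lm(data: pd.DataFrame, y: str | np.ndarray, terms: list[str]) -> LinearFit:
    """OLS fit via a QR-based least-squares solve.

    Raises :class:`ConfigurationError` on a rank-deficient design, naming the
    collinear columns.
    """
    X, names = build_design(data, terms)
    yv = data[y].to_numpy(float) if isinstance(y, str) else np.asarray(y, float)
    if len(yv) <= X.shape[1]:
        raise ConfigurationError("more parameters than observations")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns not adding rank
        bad = []
        r = 0
        for j in range(X.shape[1]):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                bad.append(names[j])
            r = rj
        raise ConfigurationError(f"rank-deficient design; collinear terms: {bad}")
    coef, _, _, _ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ coef
    return LinearFit(
        terms=tuple(terms),
        column_names=tuple(names),
        coef=coef,
        rss=float(resid @ resid),
        df_resid=len(yv) - X.shape[1],
        n=len(yv),
    )


def nested_f_test(
    data: pd.DataFrame, y: str | np.ndarray, reduced: list[str], full: list[str]
) -> FTestResult:
    """F-test between nested OLS models on the same rows."""
    if not set(reduced).issubset(full):
        raise ConfigurationError("models are not nested: reduced terms must be in full")
    fit_r = fit_lm(data, y, reduced)
    fit_f = fit_lm(data, y, full)
    df_num = fit_r.df_resid - fit_f.df_resid
    if df_num <= 0:
        raise ConfigurationError("full model adds no parameters")
    # an essentially perfect full-model fit: F blows up, report the floor
    if fit_f.rss <= 1e-12 * max(fit_r.rss, np.finfo(float).eps) or fit_f.df_resid <= 0:
        return FTestResult(
            F=np.inf, df_num=df_num, df_den=max(fit_f.df_resid, 0),
            p=np.finfo(float).tiny, degenerate=True,
        )
    F = ((fit_r.rss - fit_f.rss) / df_num) / (fit_f.rss / fit_f.df_resid)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, df_num, fit_f.df_resid))
    return FTestResult(F=float(F), df_num=df_num, df_den=fit_f.df_resid, p=p)


# ---------------------------------------------------------------------------
# Welch ANOVA / Games-Howell / FDR
# ---------------------------------------------------------------------------

def welch_anova(groups: list[np.ndarray]) -> FTestResult:
    """Welch's heteroscedastic one-way ANOVA.

    Weights are n_i / s_i^2; the denominator degrees of freedom follow
    Welch-Satterthwaite.  Requires k >= 2 groups with n >= 2 and positive
    within-group variance.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise DataError("Welch ANOVA needs at least two groups")
    n = np.array([len(g) for g in groups], dtype=float)
    if np.any(n < 2):
        raise DataError("each group needs n >= 2")
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    if np.any(v <= 0):
        raise DataError("zero within-group variance")
    w = n / v
    W = w.sum()
    mw = np.sum(w * m) / W
    A = np.sum(w * (m - mw) ** 2) / (k - 1)
    tmp = np.sum((1.0 - w / W) ** 2 / (n - 1))
    B = 1.0 + (2.0 * (k - 2) / (k**2 - 1.0)) * tmp
    F = A / B
    df1 = k - 1
    df2 = (k**2 - 1.0) / (3.0 * tmp)
    p = float(stats.f.sf(F, df1, df2))
    return FTestResult(F=float(F), df_num=df1, df_den=float(df2), p=p)


def games_howell(
    groups: list[np.ndarray], labels: list[str] | None = None, alpha: float = 0.01
) -> pd.DataFrame:
    """Games-Howell pairwise comparisons after a heteroscedastic ANOVA.

    For each pair, t = |mean_i - mean_j| / sqrt(s_i^2/n_i + s_j^2/n_j) with
    Welch-Satterthwaite df; the p-value comes from the studentized-range
    distribution with k groups at q = t * sqrt(2).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if labels is None:
        labels = [f"g{i}" for i in range(k)]
    n = np.array([len(g) for g in groups], dtype=float)
    if k < 2 or np.any(n < 2):
        raise DataError("Games-Howell needs >= 2 groups with n >= 2")
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    if np.any(v <= 0):
        raise DataError("zero within-group variance")
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se2 = v[i] / n[i] + v[j] / n[j]
            t = np.abs(m[i] - m[j]) / np.sqrt(se2)
            df = se2**2 / (
                (v[i] / n[i]) ** 2 / (n[i] - 1) + (v[j] / n[j]) ** 2 / (n[j] - 1)
            )
            p = float(stats.studentized_range.sf(t * np.sqrt(2.0), k, df))
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mean_diff": float(m[i] - m[j]),
                    "t": float(t),
                    "df": float(df),
                    "p": min(p, 1.0),
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)


def fdr_bh(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p-values)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    p_adj = np.empty(m)
    p_adj[order] = adj
    return p_adj <= alpha, p_adj


# ---------------------------------------------------------------------------
# assembled analyses
# ---------------------------------------------------------------------------

def subfield_group_analysis(
    cohort: pd.DataFrame,
    metric: str,
    parcels: list[str] | None = None,
    group_col: str = "group",
    alpha_anova: float = 0.05,
    alpha_posthoc: float = 0.01,
) -> pd.DataFrame:
    """Per-parcel Welch ANOVA -> BH-FDR over the parcel family -> Games-Howell.

    ``cohort`` is long-format with columns (participant, group, parcel,
    metric, value), one row per participant-parcel for the chosen metric.
    Post-hoc tests run only where the FDR-corrected ANOVA is significant.
    Returns a long report with one 'anova' row per parcel and 'posthoc' rows
    per significant parcel.
    """
    sub = cohort[cohort["metric"] == metric]
    if parcels is None:
        parcels = list(pd.unique(sub["parcel"]))
    anovas = []
    grouped = {}
    for parcel in parcels:
        block = sub[sub["parcel"] == parcel]
        groups, labels = [], []
        for g in GROUPS:
            vals = block.loc[block[group_col] == g, "value"].to_numpy(float)
            vals = vals[np.isfinite(vals)]
            if len(vals):
                groups.append(vals)
                labels.append(g)
        grouped[parcel] = (groups, labels)
        res = welch_anova(groups)
        anovas.append(
            {
                "parcel": parcel,
                "kind": "anova",
                "F": res.F,
                "df_num": res.df_num,
                "df_den": res.df_den,
                "p_raw": res.p,
                "n": int(sum(len(g) for g in groups)),
            }
        )
    report = pd.DataFrame(anovas)
    reject, p_adj = fdr_bh(report["p_raw"].to_numpy(), alpha=alpha_anova)
    report["p_fdr"] = p_adj
    report["significant"] = reject
    posthoc_rows = []
    for parcel, sig in zip(report["parcel"], reject):
        if not sig:
            continue
        groups, labels = grouped[parcel]
        gh = games_howell(groups, labels, alpha=alpha_posthoc)
        gh.insert(0, "parcel", parcel)
        gh.insert(1, "kind", "posthoc")
        posthoc_rows.append(gh)
    if posthoc_rows:
        report = pd.concat([report] + posthoc_rows, ignore_index=True)
    return report


def hemisphere_group_screen(
    cohort: pd.DataFrame,
    metrics: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Nested-model hemi:group interaction F-test per metric, FDR across metrics.

    ``cohort`` is long-format with columns (participant, group, age, hemi,
    metric, value); values are participant-level summaries (e.g. whole-surface
    or parcel means).  Returns per-metric F, p, FDR-corrected p and the
    resulting 'average hemispheres' decision (True where not significant).
    """
    reduced = ["age", "hemi", "group", "age:group", "age:hemi"]
    full = reduced + ["hemi:group"]
    rows = []
    for metric in metrics:
        block = cohort[cohort["metric"] == metric].dropna(subset=["value"])
        res = nested_f_test(block, "value", reduced, full)
        rows.append(
            {"metric": metric, "F": res.F, "df_num": res.df_num,
             "df_den": res.df_den, "p_raw": res.p}
        )
    report = pd.DataFrame(rows)
    if (report["p_raw"] < alpha).any():
        reject, p_adj = fdr_bh(report["p_raw"].to_numpy(), alpha=alpha)
    else:
        reject = np.zeros(len(report), dtype=bool)
        p_adj = report["p_raw"].to_numpy()
    report["p_fdr"] = p_adj
    report["interaction_significant"] = reject
    report["average_hemispheres"] = ~reject
    return report


# ---------------------------------------------------------------------------
# vertex-wise models
# ---------------------------------------------------------------------------

@dataclass
class ContrastMap:
    t: np.ndarray                 # (V,) t-statistic, NaN at invalid vertices
    beta: np.ndarray              # (V,) contrast coefficient
    valid: np.ndarray             # (V,) bool
    contrast: str
    model: str
    n: int
    group: str | None = None


def _batched_ols_t(X: np.ndarray, Y: np.ndarray, col: int):
    """Per-vertex OLS t for one coefficient.

    X is (V, n, k) — per-vertex designs (thickness varies by vertex) — and
    Y is (V, n).  Returns (t, beta, valid); vertices with an ill-conditioned
    normal matrix are invalid.
    """
    V, n, k = X.shape
    XtX = np.einsum("vnk,vnl->vkl", X, X)
    XtY = np.einsum("vnk,vn->vk", X, Y)
    # conditioning check via eigenvalues of the normalized normal matrix
    scale = np.sqrt(np.einsum("vkk->vk", XtX))
    scale = np.where(scale > 0, scale, 1.0)
    N = XtX / (scale[:, :, None] * scale[:, None, :])
    eigvals = np.linalg.eigvalsh(N)
    valid = (eigvals[:, 0] > 1e-10) & np.isfinite(Y).all(axis=1)
    beta = np.zeros((V, k))
    tstat = np.full(V, np.nan)
    bsel = np.zeros(V)
    if valid.any():
        XtXv = XtX[valid]
        beta_v = np.linalg.solve(XtXv, XtY[valid][..., None])[..., 0]
        resid = Y[valid] - np.einsum("vnk,vk->vn", X[valid], beta_v)
        dof = n - k
        sigma2 = np.einsum("vn,vn->v", resid, resid) / dof
        inv = np.linalg.inv(XtXv)
        se = np.sqrt(sigma2 * inv[:, col, col])
        with np.errstate(divide="ignore", invalid="ignore"):
            t_v = beta_v[:, col] / se
        beta[valid] = beta_v
        tstat[valid] = t_v
        bsel[valid] = beta_v[:, col]
    return tstat, bsel, valid


def vertexwise_contrast(
    maps: np.ndarray,
    covariates: pd.DataFrame,
    thickness: np.ndarray,
    contrast: str,
    valid: np.ndarray | None = None,
) -> ContrastMap:
    """Per-vertex linear model and t-map for one contrast.

    Parameters
    ----------
    maps:
        (P, V) dependent values, participants x vertices.
    covariates:
        Frame with ``age``, ``sex`` and (for group contrasts) ``group``.
    thickness:
        (P, V) vertex-wise thickness covariate.
    contrast:
        ``"age"`` (model ``DV ~ age + thickness + sex + age:sex``) or
        ``"group:MCI"`` / ``"group:CN"`` (same model plus group dummies with
        AD in the intercept).
    valid:
        Optional (P, V) mask; a vertex invalid for any participant is dropped
        listwise (left NaN in the output map).
    """
    maps = np.asarray(maps, dtype=float)
    thickness = np.asarray(thickness, dtype=float)
    P, V = maps.shape
    if thickness.shape != (P, V):
        raise DataError("thickness must match maps (participants x vertices)")
    if valid is None:
        valid = np.isfinite(maps) & np.isfinite(thickness)
    vertex_ok = valid.all(axis=0)

    age = covariates["age"].to_numpy(float)
    sex = (covariates["sex"].to_numpy() != REFERENCE_LEVELS["sex"]).astype(float)
    base_cols = [np.ones(P), age, None, sex, age * sex]  # None -> thickness slot
    names = ["Intercept", "age", "thickness", "sex[M]", "age:sex[M]"]
    if contrast.startswith("group:"):
        for g in ("CN", "MCI"):
            base_cols.append((covariates["group"].to_numpy() == g).astype(float))
            names.append(f"group[{g}]")
        col = names.index(f"group[{contrast.split(':', 1)[1]}]")
        model = "DV ~ age + thickness + sex + age:sex + group"
    elif contrast == "age":
        col = names.index("age")
        model = "DV ~ age + thickness + sex + age:sex"
    else:
        raise ConfigurationError(f"unknown contrast {contrast!r}")

    idx = np.flatnonzero(vertex_ok)
    X = np.empty((len(idx), P, len(base_cols)))
    for c, colv in enumerate(base_cols):
        X[:, :, c] = thickness[:, idx].T if colv is None else colv[None, :]
    t, beta, ok = _batched_ols_t(X, maps[:, idx].T, col)
    tmap = np.full(V, np.nan)
    bmap = np.full(V, np.nan)
    vmap = np.zeros(V, dtype=bool)
    tmap[idx] = t
    bmap[idx] = beta
    vmap[idx] = ok
    tmap[~vmap] = np.nan
    return ContrastMap(t=tmap, beta=bmap, valid=vmap, contrast=contrast, model=model, n=P)


def age_contrast_maps(
    maps: np.ndarray,
    covariates: pd.DataFrame,
    thickness: np.ndarray,
    valid: np.ndarray | None = None,
) -> dict[str, ContrastMap]:
    """Age-contrast t-map fitted separately within each group."""
    out = {}
    for g in GROUPS:
        sel = (covariates["group"] == g).to_numpy()
        if sel.sum() < 6:
            continue
        cm = vertexwise_contrast(
            maps[sel],
            covariates.loc[sel].reset_index(drop=True),
            thickness[sel],
            "age",
            None if valid is None else valid[sel],
        )
        cm.group = g
        out[g] = cm
    return out
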