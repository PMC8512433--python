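"""Differential statistics on the feature table.

Workflow: internal-standard normalisation, log transform and unit-variance
autoscaling; one-way fixed-effects ANOVA per feature per factor with
Benjamini–Hochberg FDR control; PCA of the significant features; PLS-DA
(NIPALS PLS2) with leave-one-out cross-validation, VIP scores and label
permutation validation; and a per-PC variance partition across rootstock,
irrigation and their interaction.

The univariate screen is deliberately one-way per factor — mirroring how
features are filtered at the untargeted stage — while the two-way ANOVA with
interaction lives in :mod:`vinomix.quantify`, where quantified compounds are
modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthio import SampleMeta

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "PCAModel",
    "PLSDAModel",
    "preprocess",
    "anova_per_feature",
    "bh_fdr",
    "pca_fit",
    "plsda_fit",
    "permutation_test",
    "variance_partition",
    "overlap_counts",
    "top_k_table",
]


@dataclass
class FeatureMatrix:
    """Samples × features matrix with metadata and a processing-state tag.

    ``values`` is a DataFrame indexed by sample id with feature-id columns.
    ``state`` walks raw → is_normalized → log → autoscaled; operations guard
    against being applied twice.
    """

    values: pd.DataFrame
    meta: dict[str, SampleMeta]
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("feature matrix contains missing entries; run fill_missing first")
        missing = [s for s in self.values.index if s not in self.meta]
        if missing:
            raise ValueError(f"samples without metadata: {missing[:5]}")

    def factor_levels(self, factor: str) -> pd.Series:
        return pd.Series(
            {s: getattr(self.meta[s], factor) for s in self.values.index}, name=factor
        ).loc[self.values.index]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def restrict(self, feature_ids: Sequence[str]) -> "FeatureMatrix":
        keep = [f for f in self.values.columns if f in set(feature_ids)]
        return replace(self, values=self.values[keep])


def preprocess(matrix: FeatureMatrix, is_feature_id: str) -> FeatureMatrix:
    """Internal-standard normalisation, log(x+1), unit-variance autoscaling.

    Every sample's feature intensities are divided by that sample's response
    for the internal-standard feature (raising ``ValueError`` naming the
    sample if it is missing or non-positive); the IS feature itself and any
    zero-variance columns are then dropped before autoscaling.
    """
    if matrix.state != "raw":
        raise ValueError(f"preprocess expects a raw matrix, got state={matrix.state!r}")
    if is_feature_id not in matrix.values.columns:
        raise ValueError(f"internal-standard feature {is_feature_id!r} not in matrix")
    vals = matrix.values.copy()
    is_resp = vals[is_feature_id]
    bad = is_resp.index[(is_resp.isna()) | (is_resp <= 0)]
    if len(bad):
        raise ValueError(f"internal standard missing or non-positive in sample {bad[0]!r}")
    # divide by the sample's IS response, rescaled by the median IS response
    # so values keep their counts scale and the log pseudocount stays negligible
    vals = vals.div(is_resp / float(is_resp.median()), axis=0).drop(columns=[is_feature_id])
    vals = np.log1p(vals)
    sd = vals.std(axis=0, ddof=1)
    constant = sd.index[sd <= 0]
    if len(constant):
        logger.info("dropping %d constant features before autoscaling", len(constant))
        vals = vals.drop(columns=list(constant))
        sd = sd.drop(list(constant))
    vals = (vals - vals.mean(axis=0)) / sd
    return FeatureMatrix(values=vals, meta=matrix.meta, state="autoscaled")


# ---------------------------------------------------------------------------
# univariate screen
# ---------------------------------------------------------------------------


def anova_per_feature(matrix: FeatureMatrix, factor: str) -> pd.DataFrame:
    """One-way fixed-effects ANOVA of every feature against ``factor``
    (``rootstock`` or ``irrigation``); returns a DataFrame with columns
    feature_id, factor, F, p, q where q is BH-adjusted within this factor's
    family of tests. Degenerate features (zero between- and within-group
    variance) get F=0, p=1."""
    levels = matrix.factor_levels(factor)
    groups = [matrix.values.values[(levels == lv).values] for lv in levels.unique()]
    if len(groups) < 2 or any(g.shape[0] < 2 for g in groups):
        raise ValueError(f"factor {factor!r} needs >= 2 levels with >= 2 samples each")
    X = matrix.values.values
    n, p_feat = X.shape
    k = len(groups)
    grand = X.mean(axis=0)
    ssb = np.zeros(p_feat)
    ssw = np.zeros(p_feat)
    for g in groups:
        gm = g.mean(axis=0)
        ssb += g.shape[0] * (gm - grand) ** 2
        ssw += ((g - gm) ** 2).sum(axis=0)
    df_b, df_w = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df_b) / (ssw / df_w)
    pvals = stats.f.sf(F, df_b, df_w)
    degenerate = (ssw <= 1e-300) & (ssb <= 1e-300)
    F = np.where(degenerate, 0.0, F)
    pvals = np.where(degenerate, 1.0, pvals)
    # zero within-group variance with real between-group differences -> p ~ 0
    pvals = np.where(np.isnan(pvals) & ~degenerate, 0.0, pvals)
    out = pd.DataFrame(
        {
            "feature_id": matrix.values.columns,
            "factor": factor,
            "F": F,
            "p": pvals,
        }
    )
    out["q"] = bh_fdr(out["p"].values)
    return out


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values:
    q_i = min over ranks j with p_j >= p_i of (p_j * n / rank_j), capped at 1.
    Order-preserving in p."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    loadings: pd.DataFrame  # features × k
    scores: pd.DataFrame    # samples × k
    var_fraction: np.ndarray

    @property
    def k(self) -> int:
        return self.scores.shape[1]


def pca_fit(matrix: FeatureMatrix, k: int) -> PCAModel:
    """PCA by singular value decomposition of the (already autoscaled)
    matrix. ``var_fraction[j] = s_j^2 / sum(s^2)``; each component's sign is
    fixed so its largest-magnitude loading is positive."""
    X = matrix.values.values - matrix.values.values.mean(axis=0)
    n, p = X.shape
    if k > min(n - 1, p):
        raise ValueError(f"k={k} exceeds min(n_samples-1, n_features)={min(n - 1, p)}")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    var_fraction = (s**2) / np.sum(s**2)
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    for j in range(k):
        if Vt[j, np.argmax(np.abs(Vt[j]))] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    cols = [f"PC{j + 1}" for j in range(k)]
    return PCAModel(
        loadings=pd.DataFrame(Vt.T, index=matrix.values.columns, columns=cols),
        scores=pd.DataFrame(U * s, index=matrix.values.index, columns=cols),
        var_fraction=var_fraction[:k],
    )


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------


@dataclass
class PLSDAModel:
    n_components: int
    classes: list[str]
    R2Y: float
    Q2: float
    vip: pd.Series
    weights: np.ndarray      # p × A, unit norm columns
    x_loadings: np.ndarray   # p × A
    y_loadings: np.ndarray   # m × A
    scores: np.ndarray       # n × A
    perm_p: float | None = None
    B: int | None = None


def _one_hot(labels: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    classes = sorted(set(labels))
    Y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        Y[i, classes.index(lab)] = 1.0
    return Y, classes


def _nipals_pls2(X: np.ndarray, Y: np.ndarray, A: int, tol: float = 1e-10, max_iter: int = 500):
    """NIPALS PLS2: returns (W, P, C, T, ssy_explained) with unit-norm weight
    columns. X and Y must be centred."""
    E = X.copy()
    F = Y.copy()
    n, p = X.shape
    m = Y.shape[1]
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    C = np.zeros((m, A))
    T = np.zeros((n, A))
    ssy = np.zeros(A)
    for a in range(A):
        u = F[:, int(np.argmax(F.var(axis=0)))].copy()
        if not np.any(u):
            break
        t_old = None
        for _ in range(max_iter):
            w = E.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w /= nw
            t = E @ w
            c = F.T @ t / (t @ t)
            nc = np.linalg.norm(c)
            if nc == 0:
                break
            u = F @ c / (c @ c)
            if t_old is not None and np.linalg.norm(t - t_old) <= tol * np.linalg.norm(t):
                break
            t_old = t
        tt = t @ t
        if tt <= 0:
            break
        p_a = E.T @ t / tt
        c_a = F.T @ t / tt
        E = E - np.outer(t, p_a)
        ssy[a] = tt * (c_a @ c_a)
        F = F - np.outer(t, c_a)
        W[:, a], P[:, a], C[:, a], T[:, a] = w, p_a, c_a, t
    return W, P, C, T, ssy, F


def _pls_predict(W: np.ndarray, P: np.ndarray, C: np.ndarray, Xnew: np.ndarray) -> np.ndarray:
    """Predict centred Y for centred Xnew from NIPALS factors."""
    # B = W (P'W)^-1 C'
    A = W.shape[1]
    PtW = P.T @ W
    try:
        inv = np.linalg.inv(PtW)
    except np.linalg.LinAlgError:
        inv = np.linalg.pinv(PtW)
    return Xnew @ W @ inv @ C.T


def plsda_fit(
    matrix: FeatureMatrix,
    factor: str,
    n_components: int = 2,
) -> PLSDAModel:
    """Fit a PLS-DA model (NIPALS PLS2 on one-hot class membership).

    R2Y accumulates 1 − RSS/TSS over the components; Q2 is 1 − PRESS/TSS with
    PRESS from leave-one-out refits (each fold recentres on its training
    data). VIP_j = sqrt(p · Σ_a SSY_a (w_ja)² / Σ_a SSY_a) with unit-norm
    weight vectors, so the mean of VIP² is exactly 1.
    """
    labels = list(matrix.factor_levels(factor))
    if len(set(labels)) < 2:
        raise ValueError("PLS-DA needs at least two classes")
    singletons = [lv for lv in set(labels) if labels.count(lv) == 1]
    if singletons:
        logger.warning("classes with a single sample: %s (LOOCV folds will train without them)", singletons)
    X = matrix.values.values.astype(float)
    Y, classes = _one_hot(labels)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    A = min(n_components, Xc.shape[0] - 1, Xc.shape[1])
    W, P, C, T, ssy, Fres = _nipals_pls2(Xc, Yc, A)
    tss = float(np.sum(Yc**2))
    R2Y = 1.0 - float(np.sum(Fres**2)) / tss if tss > 0 else 0.0
    Q2 = _loocv_q2(X, Y, A)
    denom = ssy.sum()
    p_feat = X.shape[1]
    if denom > 0:
        vip = np.sqrt(p_feat * (W**2 @ ssy) / denom)
    else:
        vip = np.full(p_feat, np.nan)
    return PLSDAModel(
        n_components=A,
        classes=classes,
        R2Y=R2Y,
        Q2=Q2,
        vip=pd.Series(vip, index=matrix.values.columns, name="VIP"),
        weights=W,
        x_loadings=P,
        y_loadings=C,
        scores=T,
    )


def _loocv_q2(X: np.ndarray, Y: np.ndarray, A: int) -> float:
    """Leave-one-out Q2 = 1 − PRESS/TSS (TSS about the full-data class means)."""
    n = X.shape[0]
    press = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, Ytr = X[mask], Y[mask]
        xm, ym = Xtr.mean(axis=0), Ytr.mean(axis=0)
        W, P, C, _, _, _ = _nipals_pls2(Xtr - xm, Ytr - ym, min(A, Xtr.shape[0] - 1))
        yhat = _pls_predict(W, P, C, (X[i] - xm)[None, :]) + ym
        press += float(np.sum((Y[i] - yhat) ** 2))
    Yc = Y - Y.mean(axis=0)
    tss = float(np.sum(Yc**2))
    return 1.0 - press / tss if tss > 0 else 0.0


def permutation_test(
    matrix: FeatureMatrix,
    factor: str,
    n_components: int = 2,
    B: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float, np.ndarray]:
    """Label-permutation validation of PLS-DA.

    Recomputes the LOOCV Q2 under ``B`` random label permutations and returns
    ``(perm_p, observed_q2, null_q2s)`` with
    ``perm_p = (1 + #{null >= observed}) / (B + 1)``. ``B < 20`` is refused as
    uninformative.
    """
    if B < 20:
        raise ValueError("B < 20 permutations is uninformative")
    rng = np.random.default_rng(rng)
    labels = list(matrix.factor_levels(factor))
    X = matrix.values.values.astype(float)
    Y, _ = _one_hot(labels)
    A = min(n_components, X.shape[0] - 1, X.shape[1])
    observed = _loocv_q2(X, Y, A)
    null = np.empty(B)
    for b in range(B):
        perm = rng.permutation(Y.shape[0])
        null[b] = _loocv_q2(X, Y[perm], A)
    perm_p = (1.0 + float(np.sum(null >= observed))) / (B + 1.0)
    return perm_p, observed, null


# ---------------------------------------------------------------------------
# variance partition across the first PCs
# ---------------------------------------------------------------------------


def variance_partition(pca: PCAModel, meta: Mapping[str, SampleMeta]) -> pd.DataFrame:
    """For each PC, fit score ~ rootstock + irrigation + rootstock:irrigation
    (fixed effects, type-I sums of squares in that order — equal to type-III
    on a balanced design) and report each term's variance fraction
    SS_term/SS_total and F-test p-value. Empty design cells drop the
    interaction term with a warning."""
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    samples = list(pca.scores.index)
    df = pd.DataFrame(
        {
            "rootstock": [meta[s].rootstock for s in samples],
            "irrigation": [meta[s].irrigation for s in samples],
        },
        index=samples,
    )
    cells = df.groupby(["rootstock", "irrigation"]).size()
    full_grid = len(df["rootstock"].unique()) * len(df["irrigation"].unique())
    with_interaction = len(cells) == full_grid and (cells >= 2).all()
    if not with_interaction:
        logger.warning("empty or single-replicate design cells: interaction term dropped")
        formula = "score ~ C(rootstock) + C(irrigation)"
    else:
        formula = "score ~ C(rootstock) + C(irrigation) + C(rootstock):C(irrigation)"

    rows = []
    term_names = {
        "C(rootstock)": "rootstock",
        "C(irrigation)": "irrigation",
        "C(rootstock):C(irrigation)": "interaction",
    }
    for j, pc in enumerate(pca.scores.columns):
        d = df.copy()
        d["score"] = pca.scores[pc].values
        fit = smf.ols(formula, data=d).fit()
        tab = anova_lm(fit, typ=1)
        ss_total = float(tab["sum_sq"].sum())
        for term, pretty in term_names.items():
            if term not in tab.index:
                continue
            rows.append(
                {
                    "pc": j + 1,
                    "term": pretty,
                    "frac_variance": float(tab.loc[term, "sum_sq"]) / ss_total if ss_total > 0 else 0.0,
                    "p": float(tab.loc[term, "PR(>F)"]),
                }
            )
        rows.append(
            {
                "pc": j + 1,
                "term": "residual",
                "frac_variance": float(tab.loc["Residual", "sum_sq"]) / ss_total if ss_total > 0 else 1.0,
                "p": np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# overlap accounting and top-k table
# ---------------------------------------------------------------------------


def overlap_counts(sets: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Pairwise (and, for three sets, three-way) intersection and unique
    counts for significant-feature sets, e.g. across years."""
    named = {k: set(v) for k, v in sets.items()}
    rows = []
    keys = list(named)
    for k in keys:
        others = set().union(*(named[o] for o in keys if o != k)) if len(keys) > 1 else set()
        rows.append({"sets": k, "count": len(named[k]), "kind": "total"})
        rows.append({"sets": k, "count": len(named[k] - others), "kind": "unique"})
    for i, a in enumerate(keys):
        for b in keys[i + 1 :]:
            rows.append({"sets": f"{a}&{b}", "count": len(named[a] & named[b]), "kind": "common"})
    if len(keys) == 3:
        rows.append(
            {"sets": "&".join(keys), "count": len(named[keys[0]] & named[keys[1]] & named[keys[2]]), "kind": "common"}
        )
    return pd.DataFrame(rows)


def match_feature_ids(
    ids_a: Sequence[str], ids_b: Sequence[str], rt_tol_s: float = 0.0
) -> list[tuple[str, str]]:
    """Match ``M{mz}T{rt}`` feature ids across independently processed
    batches. With ``rt_tol_s == 0`` this is exact id-string matching;
    otherwise features match when their m/z is identical and retention times
    differ by at most ``rt_tol_s`` seconds (closest wins, one-to-one)."""
    if rt_tol_s <= 0:
        common = set(ids_a) & set(ids_b)
        return [(i, i) for i in sorted(common)]

    def parse(fid: str) -> tuple[int, float]:
        body = fid[1:].split("_")[0]
        mz, rt = body.split("T")
        return int(mz), float(rt)

    parsed_b: dict[int, list[tuple[float, str]]] = {}
    for fid in ids_b:
        mz, rt = parse(fid)
        parsed_b.setdefault(mz, []).append((rt, fid))
    pairs: list[tuple[str, str]] = []
    used: set[str] = set()
    for fid in sorted(ids_a):
        mz, rt = parse(fid)
        cands = [
            (abs(rt - rt_b) * 60.0, fid_b)
            for rt_b, fid_b in parsed_b.get(mz, [])
            if fid_b not in used and abs(rt - rt_b) * 60.0 <= rt_tol_s
        ]
        if cands:
            _, best = min(cands)
            pairs.append((fid, best))
            used.add(best)
    return pairs


def top_k_table(matrix: FeatureMatrix, results: pd.DataFrame, k: int = 25) -> pd.DataFrame:
    """Per-treatment-level means (of the autoscaled values) for the top-k
    most significant features, ranked by ascending p with lexicographic
    feature-id tie-break — the table behind a treatment heatmap."""
    factor = results["factor"].iloc[0]
    ranked = results.sort_values(["p", "feature_id"]).head(min(k, len(results)))
    levels = matrix.factor_levels(factor)
    out = {}
    for lv in sorted(levels.unique()):
        sel = matrix.values.loc[(levels == lv).values, ranked["feature_id"]]
        out[lv] = sel.mean(axis=0)
    df = pd.DataFrame(out)
    df.index.name = "feature_id"
    return df
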