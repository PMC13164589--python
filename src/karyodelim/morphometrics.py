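"""Multivariate morphometric delimitation.

The morphological stage mirrors the standard field workflow for plant
species delimitation:

1. per-trait ``mean ± SD`` summaries by species or population;
2. Kruskal–Wallis rank tests per trait with Dunn's post hoc pairwise
   comparisons (tie-corrected) and Benjamini–Hochberg adjustment, condensed
   into compact letter displays;
3. standardization (z-scores) of the selected traits;
4. Fisher linear discriminant analysis on the standardized traits, solved
   as the generalized eigenproblem of the between-group scatter against
   the pooled within-group covariance;
5. a jackknifed (leave-one-out) classification with the Gaussian
   pooled-covariance rule, reported as a percentage confusion matrix whose
   actual-group columns sum to 100.

Dunn's z for groups i, j with mean ranks Rbar over N pooled observations:

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))

with tie term T = sum(t^3 - t) over tie groups.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from statsmodels.stats.multitest import multipletests

from .io_tables import TraitMatrix

__all__ = [
    "RankTestResult",
    "DiscriminantModel",
    "summarize_traits",
    "kruskal_wallis",
    "dunn_posthoc",
    "compact_letters",
    "standardize",
    "lda_fit",
    "lda_scores",
    "lda_classify",
    "jackknife_confusion",
    "wilks_lambda",
    "confidence_ellipses",
    "trait_comparison_table",
]


@dataclass(frozen=True)
class RankTestResult:
    H_statistic: float
    df: int
    p_value: float
    tie_correction: float


def summarize_traits(tm: TraitMatrix, by: str = "species") -> pd.DataFrame:
    """Long-format (group, trait, mean, sd, n) summary at sample-SD convention.

    Groups with a single observation report sd as missing; empty groups are
    an error upstream (they cannot occur in a validated matrix).
    """
    rows = []
    for group, sub in tm.data.groupby(by, sort=True):
        for trait in tm.traits:
            vals = sub[trait].dropna()
            if vals.empty:
                raise ValueError(f"group {group!r} has no values for trait {trait!r}")
            rows.append(
                {
                    "group": group,
                    "trait": trait,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                    "n": int(len(vals)),
                }
            )
    return pd.DataFrame(rows)


def _tie_correction(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    n = pooled.size
    if n < 2:
        return 1.0
    return 1.0 - (counts**3 - counts).sum() / (n**3 - n)


def kruskal_wallis(groups: list[np.ndarray]) -> RankTestResult:
    """Kruskal–Wallis H with tie correction, p from chi-square(k-1)."""
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(groups)
    if pooled.size < 3:
        raise ValueError("need a total of at least 3 observations")
    tie = _tie_correction(pooled)
    if tie == 0.0:  # all values identical
        return RankTestResult(0.0, len(groups) - 1, 1.0, tie)
    H, p = stats.kruskal(*groups)
    return RankTestResult(float(H), len(groups) - 1, float(p), tie)


def dunn_posthoc(
    groups: dict[str, np.ndarray], adjust: str | None = "bh"
) -> pd.DataFrame:
    """Dunn's pairwise z tests on mean ranks with BH step-up adjustment.

    Adjustment family is all pairs within this one call (one trait), not
    across traits.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    pooled = np.concatenate(arrays)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for name, arr in zip(names, arrays):
        mean_ranks[name] = ranks[start : start + arr.size].mean()
        sizes[name] = arr.size
        start += arr.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    base_var = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    rows = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        rows.append({"group_a": a, "group_b": b, "z": z, "p": 2.0 * stats.norm.sf(abs(z))})
    out = pd.DataFrame(rows)
    if adjust == "bh":
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["p_adj"] = out["p"]
    return out


def compact_letters(
    groups: list[str], significant: dict[tuple[str, str], bool]
) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    ``significant[(a, b)]`` (order-free lookup) marks pairs that differ;
    groups sharing a letter are not significantly different. Letters are
    assigned following the given group order.
    """

    def differ(a: str, b: str) -> bool:
        return significant.get((a, b), significant.get((b, a), False))

    def absorb(spans: list[set[str]]) -> list[set[str]]:
        kept: list[set[str]] = []
        for span in spans:
            if any(span <= other for other in kept):
                continue
            kept = [o for o in kept if not o < span]
            kept.append(span)
        return kept

    # start with one letter spanning everything; every significant pair
    # splits each letter containing both members into two letters
    letters: list[set[str]] = [set(groups)]
    for a, b in itertools.combinations(groups, 2):
        if not differ(a, b):
            continue
        updated: list[set[str]] = []
        for span in letters:
            if a in span and b in span:
                updated.extend((span - {a}, span - {b}))
            else:
                updated.append(span)
        letters = absorb(updated)
    order = {g: i for i, g in enumerate(groups)}
    letters.sort(key=lambda span: min(order[g] for g in span))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for i, span in enumerate(letters):
        for g in groups:
            if g in span:
                out[g] += alphabet[i]
    return out


def standardize(values: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each column to unit (sample) variance."""
    sd = values.std(ddof=1)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance trait(s): {', '.join(map(str, zero))}")
    return (values - values.mean()) / sd


@dataclass
class DiscriminantModel:
    """Fisher LDA in standardized trait space.

    ``scalings`` columns are the discriminant axes (eigenvectors of
    ``pooled_within^-1 @ between``), ordered by decreasing eigenvalue and
    sign-fixed so the first nonzero loading is positive. Classification
    uses the Gaussian rule with the pooled covariance and the stored
    priors.
    """

    groups: list[str]
    means: pd.DataFrame  # group x trait
    pooled_cov: np.ndarray
    scalings: np.ndarray  # trait x axis
    eigenvalues: np.ndarray
    priors: dict[str, float]
    traits: list[str] = field(default_factory=list)


def lda_fit(
    X: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    priors: str | dict[str, float] = "proportional",
    regularization: float = 0.0,
) -> DiscriminantModel:
    """Fit Fisher LDA on (already standardized) trait values.

    ``priors`` is "proportional" (to group sizes — the reference behaviour
    of the classic R implementation), "uniform", or an explicit mapping.
    ``regularization`` adds a ridge to the pooled covariance diagonal if it
    is singular.
    """
    labels = pd.Series(np.asarray(labels), index=X.index, name="group")
    groups = sorted(labels.unique().tolist())
    if any((labels == g).sum() < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    n, p = X.shape
    k = len(groups)
    grand = X.mean(axis=0).to_numpy()
    means = X.groupby(labels).mean().loc[groups]
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    for g in groups:
        sub = X[labels == g].to_numpy()
        dev = sub - means.loc[g].to_numpy()
        Sw += dev.T @ dev
        dg = (means.loc[g].to_numpy() - grand)[:, None]
        Sb += len(sub) * (dg @ dg.T)
    Sw /= n - k  # pooled within-group covariance
    Sb /= n - 1
    if regularization:
        Sw = Sw + regularization * np.eye(p)
    try:
        evals, evecs = linalg.eigh(Sb, Sw)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "singular pooled covariance; pass a regularization ridge"
        ) from exc
    order = np.argsort(evals)[::-1]
    n_axes = min(k - 1, p)
    evals, evecs = evals[order][:n_axes], evecs[:, order][:, :n_axes]
    # sign convention: first nonzero loading of each axis positive
    for j in range(evecs.shape[1]):
        nz = np.flatnonzero(np.abs(evecs[:, j]) > 1e-12)
        if nz.size and evecs[nz[0], j] < 0:
            evecs[:, j] *= -1.0
    if isinstance(priors, str):
        if priors == "proportional":
            pri = {g: (labels == g).sum() / n for g in groups}
        elif priors == "uniform":
            pri = {g: 1.0 / k for g in groups}
        else:
            raise ValueError(f"unknown priors spec {priors!r}")
    else:
        total = sum(priors.values())
        pri = {g: priors[g] / total for g in groups}
    return DiscriminantModel(
        groups=groups,
        means=means,
        pooled_cov=Sw,
        scalings=evecs,
        eigenvalues=np.maximum(evals, 0.0),
        priors=pri,
        traits=list(X.columns),
    )


def lda_scores(model: DiscriminantModel, X: pd.DataFrame) -> pd.DataFrame:
    """Project records onto the discriminant axes (centered on the grand mean)."""
    centered = X[model.traits].to_numpy() - model.means.to_numpy().mean(axis=0)
    scores = centered @ model.scalings
    return pd.DataFrame(
        scores, index=X.index, columns=[f"LD{i + 1}" for i in range(scores.shape[1])]
    )


def lda_classify(model: DiscriminantModel, X: pd.DataFrame) -> pd.Series:
    """Gaussian pooled-covariance classification rule with model priors."""
    Sinv = linalg.inv(model.pooled_cov)
    vals = X[model.traits].to_numpy()
    disc = np.empty((len(vals), len(model.groups)))
    for j, g in enumerate(model.groups):
        mu = model.means.loc[g].to_numpy()
        disc[:, j] = vals @ Sinv @ mu - 0.5 * mu @ Sinv @ mu + np.log(model.priors[g])
    return pd.Series(
        np.asarray(model.groups)[disc.argmax(axis=1)], index=X.index, name="predicted"
    )


def jackknife_confusion(
    X: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    priors: str | dict[str, float] = "proportional",
    regularization: float = 0.0,
) -> pd.DataFrame:
    """Leave-one-out confusion matrix in percent.

    For every record the model is refit on the remaining n-1 records before
    classifying it. Rows are predicted groups, columns actual groups; each
    actual-group column sums to 100.
    """
    labels = pd.Series(np.asarray(labels), index=X.index, name="group")
    groups = sorted(labels.unique().tolist())
    if any((labels == g).sum() < 3 for g in groups):
        raise ValueError("every group needs n >= 3 to refit under leave-one-out")
    counts = pd.DataFrame(0, index=groups, columns=groups, dtype=float)
    for idx in X.index:
        keep = X.index != idx
        model = lda_fit(X[keep], labels[keep], priors=priors, regularization=regularization)
        pred = lda_classify(model, X.loc[[idx]]).iloc[0]
        counts.loc[pred, labels.loc[idx]] += 1
    pct = 100.0 * counts / counts.sum(axis=0)
    pct.index.name = "predicted"
    pct.columns.name = "actual"
    return pct


def wilks_lambda(X: pd.DataFrame, labels: pd.Series | np.ndarray) -> dict[str, float]:
    """Wilks' lambda with Rao's F approximation (one-way MANOVA statistic)."""
    labels = pd.Series(np.asarray(labels), index=X.index)
    groups = sorted(labels.unique().tolist())
    n, p = X.shape
    k = len(groups)
    grand = X.mean(axis=0).to_numpy()
    W = np.zeros((p, p))
    T = np.zeros((p, p))
    for g in groups:
        sub = X[labels == g].to_numpy()
        dev = sub - sub.mean(axis=0)
        W += dev.T @ dev
    dev_all = X.to_numpy() - grand
    T = dev_all.T @ dev_all
    lam = linalg.det(W) / linalg.det(T)
    # Rao's approximation
    a = n - k - (p - k + 2) / 2.0
    b_num = p**2 * (k - 1) ** 2 - 4
    b_den = p**2 + (k - 1) ** 2 - 5
    b = np.sqrt(b_num / b_den) if b_den > 0 else 1.0
    c = (p * (k - 1) - 2) / 2.0
    df1 = p * (k - 1)
    df2 = a * b - c
    lam_b = lam ** (1.0 / b)
    F = ((1 - lam_b) / lam_b) * (df2 / df1)
    pval = stats.f.sf(F, df1, df2)
    return {"wilks_lambda": float(lam), "F": float(F), "df1": float(df1), "df2": float(df2), "p": float(pval)}


def confidence_ellipses(scores: pd.DataFrame, labels: pd.Series, radius_sd: float = 2.45) -> pd.DataFrame:
    """Per-group 95% ellipse parameters on the first two axes.

    Returns center, principal radii (radius_sd * sqrt(eigenvalue) of the
    per-group score covariance) and orientation angle in radians.
    """
    cols = scores.columns[:2]
    rows = []
    for g, sub in scores.groupby(pd.Series(np.asarray(labels), index=scores.index)):
        vals = sub[cols].to_numpy()
        cov = np.cov(vals, rowvar=False)
        evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        rows.append(
            {
                "group": g,
                "center_x": float(vals[:, 0].mean()),
                "center_y": float(vals[:, 1].mean()) if vals.shape[1] > 1 else 0.0,
                "radius_major": float(radius_sd * np.sqrt(max(evals[0], 0.0))),
                "radius_minor": float(radius_sd * np.sqrt(max(evals[-1], 0.0))),
                "angle": float(np.arctan2(evecs[1, 0], evecs[0, 0])) if vals.shape[1] > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def trait_comparison_table(
    tm: TraitMatrix, by: str = "species", alpha: float = 0.05
) -> pd.DataFrame:
    """Per-trait summary with Kruskal–Wallis p and compact letter displays.

    The report mirrors the published trait tables: ``mean ± SD`` per group
    with letters such that groups sharing a letter do not differ at
    ``alpha`` after Dunn/BH post hoc.
    """
    summaries = summarize_traits(tm, by=by)
    group_names = sorted(tm.data[by].unique().tolist())
    letter_rows = []
    for trait in tm.traits:
        groups = {
            g: tm.data.loc[tm.data[by] == g, trait].dropna().to_numpy()
            for g in group_names
        }
        kw = kruskal_wallis(list(groups.values()))
        if kw.p_value < alpha and len(group_names) >= 2:
            pairs = dunn_posthoc(groups, adjust="bh")
            sig = {
                (r.group_a, r.group_b): bool(r.p_adj < alpha)
                for r in pairs.itertuples()
            }
        else:
            sig = {}
        letters = compact_letters(group_names, sig)
        for g in group_names:
            letter_rows.append(
                {"group": g, "trait": trait, "kw_p": kw.p_value, "letters": letters[g]}
            )
    return summaries.merge(pd.DataFrame(letter_rows), on=["group", "trait"])
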