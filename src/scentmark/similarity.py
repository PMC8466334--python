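"""Individual-signature discrimination on preprocessed bouquets.

The discrimination logic works in four steps on clr-transformed peak areas:

1. **Factor extraction** — PCA on the correlation matrix, keeping every
   component with eigenvalue > 1 (Kaiser criterion) to absorb the heavy
   collinearity of homologous hydrocarbon series; factor scores are
   standardized to unit variance.
2. **Similarity** — squared Euclidean distances (SED) between factor-score
   vectors; small SED = high similarity.
3. **Pair labelling and pruning** — sample pairs are labelled same-nest vs
   different-nest (or own-bee vs foreign-bee for extract/bouquet-vs-mark
   comparisons); extreme isolated SED values beyond Q3 + k·IQR are removed.
4. **Test** — a binomial-logit GLM of the pair label on SED; the Wald
   chi-square of the SED coefficient tests whether same-identity pairs are
   systematically more similar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.spatial.distance import pdist, squareform


class SimilarityError(ValueError):
    pass


class SeparationError(SimilarityError):
    """Complete separation: the two classes' SED ranges do not overlap, the
    logistic MLE drifts to infinity and no finite Wald statistic exists."""


@dataclass
class FactorModel:
    n_factors: int
    eigenvalues: np.ndarray          # all eigenvalues, descending
    explained_pct: float             # 100 · sum(retained) / n_variables
    scores: pd.DataFrame             # samples × retained factors, unit variance
    loadings: pd.DataFrame           # compounds × retained factors


@dataclass
class PairSet:
    """Unordered, unique sample pairs with SED and same-identity labels."""

    pairs: pd.DataFrame              # columns: sample_a, sample_b, sed, same
    pruned: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["sample_a", "sample_b", "sed", "same", "reason"]))

    @property
    def n(self) -> int:
        return len(self.pairs)

    def counts(self) -> dict[str, int]:
        same = int(self.pairs["same"].sum())
        return {"total": self.n, "same": same, "different": self.n - same}


@dataclass
class GlmResult:
    beta0: float
    beta1: float
    se1: float
    W: float                          # Wald chi-square, 1 df
    p: float
    n: int

    def to_dict(self) -> dict:
        return {"beta0": self.beta0, "beta1": self.beta1, "se1": self.se1,
                "W": self.W, "p": self.p, "n": self.n}


def pca_factor_scores(clr_matrix) -> FactorModel:
    """Correlation-matrix PCA keeping all eigenvalues > 1.

    Scores are standardized principal-component scores (unit variance per
    factor); loadings are eigenvectors scaled by sqrt(eigenvalue).  Sign
    convention: the largest-magnitude entry of each loading vector is
    positive.  If no eigenvalue exceeds 1 the single largest component is
    kept with a warning.
    """
    df = isinstance(clr_matrix, pd.DataFrame)
    X = clr_matrix.to_numpy(dtype=float) if df else np.asarray(clr_matrix, float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise SimilarityError(
            "PCA needs at least 3 samples and 2 compounds; got "
            f"shape {X.shape}")
    n, p = X.shape
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        j = int(np.argmax(sd == 0))
        name = clr_matrix.columns[j] if df else j
        raise SimilarityError(
            f"constant column {name!r}: correlation undefined")
    Z = (X - X.mean(axis=0)) / sd
    R = (Z.T @ Z) / (n - 1)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)

    keep = int(np.sum(eigval > 1.0))
    if keep == 0:
        warnings.warn("no eigenvalue exceeds 1; retaining the largest "
                      "component only", stacklevel=2)
        keep = 1
    V = eigvec[:, :keep]
    # sign convention: dominant loading entry positive
    for k in range(keep):
        if V[np.argmax(np.abs(V[:, k])), k] < 0:
            V[:, k] = -V[:, k]
    lam = eigval[:keep]
    scores = (Z @ V) / np.sqrt(lam)
    loadings = V * np.sqrt(lam)
    explained = 100.0 * lam.sum() / p

    cols = [f"F{k + 1}" for k in range(keep)]
    idx = clr_matrix.index if df else pd.RangeIndex(n)
    comp_idx = clr_matrix.columns if df else pd.RangeIndex(p)
    return FactorModel(
        n_factors=keep,
        eigenvalues=eigval,
        explained_pct=float(explained),
        scores=pd.DataFrame(scores, index=idx, columns=cols),
        loadings=pd.DataFrame(loadings, index=comp_idx, columns=cols),
    )


def sed_matrix(scores) -> pd.DataFrame:
    """Pairwise squared Euclidean distances between score rows."""
    df = isinstance(scores, pd.DataFrame)
    X = scores.to_numpy(dtype=float) if df else np.asarray(scores, float)
    D = squareform(pdist(X, metric="sqeuclidean"))
    idx = scores.index if df else pd.RangeIndex(X.shape[0])
    return pd.DataFrame(D, index=idx, columns=idx)


def label_pairs(sed: pd.DataFrame, meta: pd.DataFrame,
                group_a_sources, group_b_sources) -> PairSet:
    """Enumerate sample pairs between two source groups and label identity.

    If the groups coincide, all unordered within-group pairs are used (for
    n nests × 2 sleeves that is C(2n, 2) pairs, n of them same-nest).  If
    they differ, all cross-group pairs are used (bee extract / estimated
    bouquet vs mark), labelled same iff the mark belongs to that bee.
    """
    group_a_sources = frozenset(group_a_sources)
    group_b_sources = frozenset(group_b_sources)
    ids_a = [s for s in sed.index
             if meta.at[s, "source"] in group_a_sources]
    ids_b = [s for s in sed.index
             if meta.at[s, "source"] in group_b_sources]
    if not ids_a or not ids_b:
        raise SimilarityError("empty sample group for pair labelling")

    records = []
    if group_a_sources == group_b_sources:
        for i, a in enumerate(ids_a):
            for b in ids_a[i + 1:]:
                records.append((a, b, float(sed.at[a, b]),
                                meta.at[a, "nest_id"] == meta.at[b, "nest_id"]))
    else:
        for a in ids_a:
            for b in ids_b:
                if a == b:
                    continue
                records.append((a, b, float(sed.at[a, b]),
                                meta.at[a, "nest_id"] == meta.at[b, "nest_id"]))
    pairs = pd.DataFrame(records, columns=["sample_a", "sample_b", "sed", "same"])
    return PairSet(pairs=pairs)


def prune_outliers(pairset: PairSet, k_iqr: float = 3.0) -> PairSet:
    """Remove extreme isolated SED values above Q3 + k·IQR.

    Quartiles use linear interpolation (type 7).  Removed pairs are logged
    with their values.
    """
    if pairset.n < 4:
        raise SimilarityError("outlier pruning needs at least 4 pairs")
    sed = pairset.pairs["sed"].to_numpy()
    q1, q3 = np.percentile(sed, [25, 75])
    fence = q3 + k_iqr * (q3 - q1)
    out = pairset.pairs["sed"] > fence
    pruned = pairset.pairs[out].copy()
    pruned["reason"] = [f"sed {v:.6g} > fence {fence:.6g}"
                        for v in pruned["sed"]]
    kept = pairset.pairs[~out].reset_index(drop=True)
    if len(pairset.pruned):
        pruned = pd.concat([pairset.pruned, pruned], ignore_index=True)
    else:
        pruned = pruned.reset_index(drop=True)
    return PairSet(pairs=kept, pruned=pruned)


def wald_glm(pairset: PairSet) -> GlmResult:
    """Binomial-logit GLM of same-identity (1) vs different (0) on SED.

    Fitted by iteratively reweighted least squares; returns the Wald
    chi-square W = (beta1 / se1)^2 for the SED coefficient with its 1-df
    p-value.  Raises :class:`SeparationError` on complete separation and
    :class:`SimilarityError` when only one class is present.
    """
    pairs = pairset.pairs
    y = pairs["same"].to_numpy(dtype=float)
    x = pairs["sed"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise SimilarityError("GLM needs both same and different pairs")
    same_sed, diff_sed = x[y == 1], x[y == 0]
    if same_sed.max() < diff_sed.min() or diff_sed.max() < same_sed.min():
        raise SeparationError(
            "complete separation between classes "
            f"(same SED range [{same_sed.min():.4g}, {same_sed.max():.4g}], "
            f"different [{diff_sed.min():.4g}, {diff_sed.max():.4g}]); "
            "the slope estimate diverges and no Wald statistic exists")
    X = sm.add_constant(x)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    fit = model.fit(maxiter=200, tol=1e-12)
    beta0, beta1 = fit.params
    se1 = float(fit.bse[1])
    W = float((beta1 / se1) ** 2)
    p = float(stats.chi2.sf(W, df=1))
    return GlmResult(beta0=float(beta0), beta1=float(beta1), se1=se1,
                     W=W, p=p, n=len(pairs))


def summarize_similarity(pairset: PairSet) -> dict[str, dict[str, float]]:
    """Median, range and n of SED per class (same / different)."""
    out: dict[str, dict[str, float]] = {}
    for label, key in ((True, "same"), (False, "different")):
        vals = pairset.pairs.loc[pairset.pairs["same"] == label, "sed"]
        if len(vals) == 0:
            continue
        out[key] = {"median": float(vals.median()),
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                    "n": int(len(vals))}
    return out
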