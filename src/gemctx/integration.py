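"""Map omics values onto reactions through GPR rules and fuse the
transcript and protein reaction-vectors by PCA into one activity vector.

GPR evaluation uses the min/max semantics: AND takes the minimum of its
children (a complex is limited by its scarcest part), OR the maximum
(isozymes are interchangeable).  The fused vector is placed on the iMAT
threshold scale with a signed-log transform anchored at the quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .model import GPRTree, MetabolicModel


@dataclass
class ActivityVector:
    """One real-valued score per covered reaction.

    Reactions without a GPR or without data are simply absent from
    ``scores`` — never silently zero.
    """

    scores: dict[str, float]
    provenance: str  # "transcript" | "protein" | "integrated"
    unmatched_features: list[str] = field(default_factory=list)

    @property
    def coverage(self) -> set[str]:
        return set(self.scores)

    def __post_init__(self):
        bad = [r for r, v in self.scores.items() if not np.isfinite(v)]
        if bad:
            raise ValidationError(f"non-finite activity scores for: {bad}")


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # descending
    loadings: np.ndarray  # columns are orthonormal components
    variance_fractions: np.ndarray
    scores: np.ndarray  # rows x components


def evaluate_gpr(
    tree: GPRTree,
    feature_values: dict[str, float],
    missing_policy: str = "ignore-missing",
) -> float | None:
    """Recursive min/max evaluation; ``None`` means no value.

    Policies for a leaf without data: ``ignore-missing`` drops it under OR
    but voids any AND containing it (a complex needs all parts);
    ``strict`` voids the whole rule on any missing leaf.
    """
    if missing_policy not in ("ignore-missing", "strict"):
        raise ValidationError(f"unknown missing policy {missing_policy!r}")
    if tree.kind == "GENE":
        v = feature_values.get(tree.gene_id)
        return None if v is None else float(v)
    vals = [evaluate_gpr(ch, feature_values, missing_policy) for ch in tree.children]
    if tree.kind == "AND":
        if any(v is None for v in vals):
            return None
        return min(vals)
    # OR
    present = [v for v in vals if v is not None]
    if missing_policy == "strict" and len(present) != len(vals):
        return None
    return max(present) if present else None


def map_to_reactions(
    model: MetabolicModel,
    feature_values: dict[str, float],
    missing_policy: str = "ignore-missing",
    provenance: str = "transcript",
) -> ActivityVector:
    """Evaluate every reaction's GPR against a feature -> value map.

    Features that match no GPR leaf are reported in
    ``ActivityVector.unmatched_features`` rather than raising.
    """
    scores: dict[str, float] = {}
    seen_genes: set[str] = set()
    for rxn in model.reactions:
        if rxn.gpr is None:
            continue
        seen_genes |= rxn.gpr.genes()
        val = evaluate_gpr(rxn.gpr, feature_values, missing_policy)
        if val is not None:
            scores[rxn.id] = val
    unmatched = sorted(set(feature_values) - seen_genes)
    return ActivityVector(scores=scores, provenance=provenance, unmatched_features=unmatched)


def pca(matrix: np.ndarray) -> PCAResult:
    """Eigen-decomposition of the sample covariance matrix.

    Rows are observations, columns variables.  Components are sorted by
    descending eigenvalue; each component's sign is fixed so that its
    largest-magnitude loading is positive.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValidationError("pca needs a 2-D matrix with >=2 variables")
    if X.shape[0] < 3:
        raise ValidationError("pca needs >=3 observations")
    if np.isnan(X).any():
        raise ValidationError("pca input contains missing values")
    variances = X.var(axis=0)
    if (variances < 1e-15).any():
        cols = np.flatnonzero(variances < 1e-15).tolist()
        raise ValidationError(f"zero-variance columns: {cols}")
    Xc = X - X.mean(axis=0)
    cov = np.cov(Xc, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    eigvals = np.clip(eigvals, 0.0, None)  # numerical negatives on rank-deficient input
    for c in range(eigvecs.shape[1]):
        j = int(np.argmax(np.abs(eigvecs[:, c])))
        if eigvecs[j, c] < 0:
            eigvecs[:, c] = -eigvecs[:, c]
    total = eigvals.sum()
    if total <= 0:
        raise ValidationError("degenerate covariance: total variance is zero")
    return PCAResult(
        eigenvalues=eigvals,
        loadings=eigvecs,
        variance_fractions=eigvals / total,
        scores=Xc @ eigvecs,
    )


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()  # population sd, consistent with preprocess.zscore
    if sd < 1e-12:
        raise ValidationError("cannot standardize a constant score vector")
    return (x - x.mean()) / sd


def integrate(
    transcript_av: ActivityVector,
    protein_av: ActivityVector,
    n_components: int = 2,
) -> ActivityVector:
    """Fuse transcript and protein reaction scores into one vector.

    Reactions covered by both inputs form the observations of a two-column
    matrix (standardized transcript score, standardized protein score); a
    PCA is run and the integrated score is the variance-fraction-weighted
    sum of the first ``n_components`` component scores.
    """
    common = sorted(transcript_av.coverage & protein_av.coverage)
    if not common:
        raise ValidationError("no reactions covered by both omics layers")
    t = np.array([transcript_av.scores[r] for r in common])
    p = np.array([protein_av.scores[r] for r in common])
    X = np.column_stack([_standardize(t), _standardize(p)])
    res = pca(X)
    k = min(n_components, res.scores.shape[1])
    combined = res.scores[:, :k] @ res.variance_fractions[:k]
    return ActivityVector(
        scores={r: float(v) for r, v in zip(common, combined)},
        provenance="integrated",
    )


def integrate_pca(
    transcript_av: ActivityVector, protein_av: ActivityVector
) -> PCAResult:
    """The PCA underlying :func:`integrate`, for diagnostics/plots."""
    common = sorted(transcript_av.coverage & protein_av.coverage)
    if not common:
        raise ValidationError("no reactions covered by both omics layers")
    t = np.array([transcript_av.scores[r] for r in common])
    p = np.array([protein_av.scores[r] for r in common])
    return pca(np.column_stack([_standardize(t), _standardize(p)]))


def signed_log(x: np.ndarray) -> np.ndarray:
    """Odd, strictly increasing log map: sign(x) * ln(1 + |x|)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.log1p(np.abs(x))


def to_threshold_scale(
    av: ActivityVector,
    low: float = -500.0,
    high: float = 500.0,
    lower_q: float = 0.25,
    upper_q: float = 0.75,
) -> ActivityVector:
    """Place an integrated vector on the iMAT threshold scale.

    Scores pass through :func:`signed_log` and are then affinely rescaled
    so the ``lower_q`` quantile maps to ``low`` and the ``upper_q``
    quantile to ``high``; rank order is preserved.
    """
    if av.provenance != "integrated":
        raise ValidationError("threshold scaling expects an integrated vector")
    if not (0 <= lower_q < upper_q <= 1):
        raise ValidationError("quantiles must satisfy 0 <= lower_q < upper_q <= 1")
    rids = sorted(av.scores)
    s = signed_log(np.array([av.scores[r] for r in rids]))
    ql, qh = np.quantile(s, [lower_q, upper_q])
    if qh - ql < 1e-12:
        raise ValidationError("cannot rescale a (near-)constant vector")
    scaled = low + (s - ql) * (high - low) / (qh - ql)
    return ActivityVector(
        scores={r: float(v) for r, v in zip(rids, scaled)},
        provenance="integrated",
    )
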