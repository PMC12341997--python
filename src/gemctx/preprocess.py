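"""Transcript/protein table preprocessing.

Pipeline mirrors common label-free practice: discard low-count genes,
log2 transform, keep proteins with enough valid values per group, impute
the rest with feature-wise KNN, and z-score.  Tables are feature x sample
with a group label per sample; missing values are NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class OmicsTable:
    """Feature x sample value matrix with per-sample group labels.

    ``kind`` distinguishes transcript count tables from protein intensity
    tables; NaN entries are the missing mask.
    """

    features: list[str]
    samples: list[str]
    groups: list[str]
    values: np.ndarray  # float, NaN = missing
    kind: str = "transcript"  # "transcript" | "protein"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.features), len(self.samples)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.features)} features x {len(self.samples)} samples"
            )
        if len(self.groups) != len(self.samples):
            raise ValidationError("one group label per sample is required")
        if len(self.samples) and not all(self.groups):
            raise ValidationError("group labels must be nonempty")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def group_names(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen

    def subset_features(self, keep: np.ndarray) -> "OmicsTable":
        return replace(
            self,
            features=[f for f, k in zip(self.features, keep) if k],
            values=self.values[np.asarray(keep, bool)].copy(),
        )

    # -- pandas / TSV bridges ---------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.features, columns=self.samples)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, groups: dict[str, str], kind: str) -> "OmicsTable":
        missing = [s for s in df.columns if s not in groups]
        if missing:
            raise ValidationError(f"samples without group label: {missing}")
        return cls(
            features=[str(i) for i in df.index],
            samples=[str(c) for c in df.columns],
            groups=[groups[str(c)] for c in df.columns],
            values=df.to_numpy(dtype=float),
            kind=kind,
        )


def read_omics_tsv(values_path: str, groups_path: str, kind: str) -> OmicsTable:
    """Read a feature x sample TSV plus a two-column sample->group TSV.

    Missing values may be encoded as empty cells or ``NA``.
    """
    df = pd.read_csv(values_path, sep="\t", index_col=0, na_values=["NA", ""])
    gdf = pd.read_csv(groups_path, sep="\t", header=None, names=["sample", "group"], dtype=str)
    groups = dict(zip(gdf["sample"], gdf["group"]))
    return OmicsTable.from_frame(df, groups, kind)


def write_omics_tsv(table: OmicsTable, values_path: str, groups_path: str | None = None) -> None:
    table.to_frame().to_csv(values_path, sep="\t", na_rep="NA")
    if groups_path is not None:
        with open(groups_path, "w") as fh:
            for s, g in zip(table.samples, table.groups):
                fh.write(f"{s}\t{g}\n")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def filter_low_count_genes(table: OmicsTable, min_total: int = 10) -> OmicsTable:
    """Drop transcript features whose total count over all samples is below
    ``min_total`` (features totalling exactly ``min_total`` are kept)."""
    if table.kind != "transcript":
        raise ValidationError("count filtering applies to transcript tables only")
    vals = table.values
    if np.nanmin(vals, initial=0.0) < 0:
        raise ValidationError("negative counts found in transcript table")
    totals = np.nansum(vals, axis=1)
    return table.subset_features(totals >= min_total)


def log2_transform(table: OmicsTable, pseudocount: float = 1.0) -> OmicsTable:
    """v -> log2(v + pseudocount); NaN entries stay NaN."""
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    vals = table.values
    finite = vals[~np.isnan(vals)]
    if finite.size and finite.min() < 0:
        raise ValidationError("log2 transform requires nonnegative values")
    if pseudocount == 0 and finite.size and (finite == 0).any():
        raise ValidationError("pseudocount 0 with zero values would produce -inf")
    with np.errstate(invalid="ignore"):
        out = np.log2(vals + pseudocount)
    return replace(table, values=out)


def filter_proteins_by_validity(table: OmicsTable, min_valid_fraction: float = 0.70) -> OmicsTable:
    """Keep protein features observed in >= ``min_valid_fraction`` of the
    samples of *every* group."""
    if table.kind != "protein":
        raise ValidationError("validity filtering applies to protein tables only")
    groups = np.asarray(table.groups)
    keep = np.ones(len(table.features), dtype=bool)
    for g in table.group_names():
        cols = groups == g
        n = int(cols.sum())
        if n == 0:
            raise ValidationError(f"group {g!r} has zero samples")
        valid_frac = (~np.isnan(table.values[:, cols])).sum(axis=1) / n
        keep &= valid_frac >= min_valid_fraction
    return table.subset_features(keep)


def knn_impute(table: OmicsTable, k: int = 10) -> OmicsTable:
    """Fill each missing cell with the mean of that column over the ``k``
    nearest feature rows (Euclidean distance on shared observed columns).

    Candidate neighbours must be observed in the target column.  Observed
    cells are left bit-identical.  A feature with no observed value at all
    is an error; if fewer than ``k`` usable neighbours exist, ``k`` is
    lowered with a warning.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    vals = table.values.copy()
    nan = np.isnan(vals)
    all_missing = [f for f, row in zip(table.features, nan) if row.all()]
    if all_missing:
        raise ValidationError(f"features with all values missing: {all_missing}")
    if not nan.any():
        return replace(table, values=vals)
    n = vals.shape[0]
    for i in range(n):
        miss_cols = np.flatnonzero(nan[i])
        if miss_cols.size == 0:
            continue
        obs_i = ~nan[i]
        # distance from row i to every other row over shared observed columns
        dists = np.full(n, np.inf)
        for j in range(n):
            if j == i:
                continue
            shared = obs_i & ~nan[j]
            if not shared.any():
                continue
            diff = table.values[i, shared] - table.values[j, shared]
            dists[j] = float(np.sqrt(np.dot(diff, diff)))
        for col in miss_cols:
            usable = np.flatnonzero(~nan[:, col] & np.isfinite(dists))
            if usable.size == 0:
                raise ValidationError(
                    f"cannot impute {table.features[i]!r}: no usable neighbours"
                )
            kk = k
            if usable.size < k:
                warnings.warn(
                    f"only {usable.size} neighbours for feature {table.features[i]!r}; "
                    f"lowering k from {k}",
                    stacklevel=2,
                )
                kk = usable.size
            order = usable[np.lexsort((usable, dists[usable]))][:kk]
            vals[i, col] = float(np.mean(table.values[order, col]))
    return replace(table, values=vals)


def zscore(table: OmicsTable) -> OmicsTable:
    """Standardise each feature row to mean 0 and population (1/N) sd 1."""
    if np.isnan(table.values).any():
        raise ValidationError("zscore requires a complete table; impute first")
    mu = table.values.mean(axis=1, keepdims=True)
    sd = table.values.std(axis=1, keepdims=True)  # population sd
    flat = np.flatnonzero(sd.ravel() < 1e-12)
    if flat.size:
        names = [table.features[i] for i in flat]
        raise ValidationError(f"constant features cannot be z-scored: {names}")
    return replace(table, values=(table.values - mu) / sd)


def group_means(table: OmicsTable, group: str | None = None) -> dict[str, float]:
    """Per-feature mean over the samples of one group (or all samples).

    This is the collapse step that turns a preprocessed table into the
    single value-per-feature map consumed by GPR mapping.
    """
    if group is None:
        cols = np.ones(len(table.samples), dtype=bool)
    else:
        cols = np.asarray(table.groups) == group
        if not cols.any():
            raise ValidationError(f"no samples in group {group!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(table.values[:, cols], axis=1)
    return {
        f: float(v) for f, v in zip(table.features, means) if np.isfinite(v)
    }
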