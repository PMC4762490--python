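"""Descriptive and inferential statistics on feature tables.

Covers the screening stage of the identification protocol: per-biomarker
normality checks (Shapiro–Wilk), nonparametric two-species comparisons
(Wilcoxon rank-sum / Mann–Whitney), per-species moment summaries, and PCA
of the six standardized biomarkers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError
from .io_formats import BIOMARKERS, SPECIES, FeatureTable
from .phantoms import SpeciesMoments

ALPHA = 0.05


@dataclass(frozen=True)
class GroupComparison:
    """One biomarker's two-group comparison."""

    biomarker: str
    group_a: str
    group_b: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    statistic: float
    p_value: float
    test_name: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ParameterError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class PCAResult:
    """Principal components of the biomarker matrix.

    ``loadings`` has one orthonormal column per component; ``scores`` are
    the centred (and, when standardized, scaled) data projected on them.
    Component signs are fixed so each column's largest-magnitude loading is
    positive.
    """

    loadings: np.ndarray = field(repr=False)
    scores: np.ndarray = field(repr=False)
    explained_variance_ratio: np.ndarray
    mean: np.ndarray = field(repr=False)
    scale: np.ndarray | None = field(default=None, repr=False)
    feature_names: tuple[str, ...] = BIOMARKERS


def _species_groups(table: FeatureTable, min_n: int) -> dict[str, np.ndarray]:
    groups = {}
    for sp in SPECIES:
        sub = table.df[table.df["species"] == sp]
        if len(sub) < min_n:
            raise ParameterError(
                f"need >= {min_n} samples for species {sp!r}, got {len(sub)}"
            )
        groups[sp] = sub
    return groups


def normality_screen(table: FeatureTable, alpha: float = ALPHA) -> pd.DataFrame:
    """Shapiro–Wilk normality test per biomarker per species.

    Returns a tidy frame (species, biomarker, p_value, normal, reason); a
    biomarker fails when any species group rejects at ``alpha``.  Groups
    need at least 3 samples.  Constant groups are reported as failures with
    a reason rather than a p-value.
    """
    groups = _species_groups(table, min_n=3)
    rows = []
    for sp, sub in groups.items():
        for bm in BIOMARKERS:
            x = sub[bm].to_numpy(dtype=float)
            if np.isnan(x).any():
                raise ParameterError(f"missing {bm} values for species {sp}")
            if np.ptp(x) == 0:
                rows.append((sp, bm, np.nan, False, "constant values"))
                continue
            stat, p = sps.shapiro(x)
            rows.append((sp, bm, float(p), bool(p >= alpha), ""))
    return pd.DataFrame(rows, columns=["species", "biomarker", "p_value", "normal", "reason"])


def wilcoxon(
    group_a,
    group_b,
    biomarker: str = "",
    group_names: tuple[str, str] = ("A", "B"),
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) comparison of two
    independent groups.

    The exact null distribution is used when both groups have at most 25
    values and there are no ties; otherwise the normal approximation with
    tie and continuity corrections.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError(f"both groups need >= 2 values, got {a.size}/{b.size}")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size <= 25 and b.size <= 25 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return GroupComparison(
        biomarker=biomarker,
        group_a=group_names[0],
        group_b=group_names[1],
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test_name=f"wilcoxon_rank_sum_{method}",
    )


def compare_species(table: FeatureTable) -> list[GroupComparison]:
    """Wilcoxon comparison of red deer vs reindeer for every biomarker."""
    groups = _species_groups(table, min_n=2)
    out = []
    for bm in BIOMARKERS:
        out.append(
            wilcoxon(
                groups["red_deer"][bm].to_numpy(dtype=float),
                groups["reindeer"][bm].to_numpy(dtype=float),
                biomarker=bm,
                group_names=("red_deer", "reindeer"),
            )
        )
    return out


def summarize_moments(table: FeatureTable) -> SpeciesMoments:
    """Per-species mean and SD (n−1 denominator) of each biomarker."""
    groups = _species_groups(table, min_n=1)
    means, sds, n = {}, {}, {}
    for sp, sub in groups.items():
        if len(sub) < 2:
            raise ParameterError(
                f"species {sp!r} has a single sample; SD undefined"
            )
        x = sub.loc[:, list(BIOMARKERS)]
        means[sp] = x.mean()
        sds[sp] = x.std(ddof=1)
        n[sp] = len(sub)
    return SpeciesMoments(
        means=pd.DataFrame(means).T, sds=pd.DataFrame(sds).T, n=n
    )


def pca(table: FeatureTable, standardize: bool = True) -> PCAResult:
    """PCA of the biomarker matrix via SVD of the centred (scaled) data.

    Standardization (the default — the six biomarkers carry heterogeneous
    units) divides each centred column by its population SD; a constant
    column then raises an error naming the column.  Deterministic: each
    component's largest-magnitude loading is made positive.
    """
    if len(table) < 3:
        raise ParameterError(f"PCA needs >= 3 samples, got {len(table)}")
    x = table.matrix()
    if np.isnan(x).any():
        raise ParameterError("PCA requires complete biomarker rows")
    mean = x.mean(axis=0)
    xc = x - mean
    scale = None
    if standardize:
        scale = x.std(axis=0)
        if (scale == 0).any():
            col = BIOMARKERS[int(np.flatnonzero(scale == 0)[0])]
            raise ParameterError(f"cannot standardize constant column {col!r}")
        xc = xc / scale
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    k = min(xc.shape[0] - 1, xc.shape[1])
    loadings = vt[:k].T
    # sign convention: largest-|loading| entry positive per component
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = xc @ loadings
    var = s[:k] ** 2
    total = (xc**2).sum()
    evr = var / total if total > 0 else np.zeros(k)
    return PCAResult(
        loadings=loadings,
        scores=scores,
        explained_variance_ratio=evr,
        mean=mean,
        scale=scale,
    )
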