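"""Differential analysis of label-free quantification (LFQ) proteomics.

Implements the standard LFQ downstream chain for log2-intensity matrices
with missing-not-at-random (MNAR) dropout:

* sample quality control (drop samples detecting fewer than half the median
  number of proteins),
* group-completeness filtering of proteins,
* mixed imputation -- well-observed proteins by K-nearest-neighbour (KNN)
  over correlated proteins, sparse proteins by a downshifted Gaussian drawn
  per sample (mean = sample mean - 1.8 SD, spread = 0.3 SD by default),
* an s0-moderated two-sample t-test with permutation-based FDR
  (:class:`PermutationTTest`),
* QC summaries (coefficients of variation, Pearson sample correlation, PCA),
* Fisher exact gene-set enrichment with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests


@dataclass
class LFQMatrix:
    """Protein x sample log2 intensities with explicit missingness.

    Parameters
    ----------
    values
        DataFrame indexed by protein id with sample-id columns; ``NaN``
        marks a missing (undetected) value.
    design
        Series mapping sample id -> group label, covering every column.
    """

    values: pd.DataFrame
    design: pd.Series
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise ValueError("duplicate protein ids")
        if v.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        missing = [s for s in v.columns if s not in self.design.index]
        if missing:
            raise ValueError(f"samples without a group in the design: {missing}")
        arr = v.to_numpy(dtype=float)
        if np.any(np.isinf(arr)):
            raise ValueError("intensities must be finite where present")
        self.values = v.astype(float)
        self.design = self.design.loc[list(v.columns)]

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.design:
            seen.setdefault(g, None)
        return list(seen)

    def group_samples(self, group: str) -> list[str]:
        return list(self.design.index[self.design == group])

    def mask(self) -> pd.DataFrame:
        """Boolean observed-mask, True where a value is present."""
        return self.values.notna()

    def subset(
        self,
        proteins: Sequence[str] | None = None,
        samples: Sequence[str] | None = None,
    ) -> "LFQMatrix":
        v = self.values
        if proteins is not None:
            v = v.loc[list(proteins)]
        if samples is not None:
            v = v[list(samples)]
        return LFQMatrix(values=v, design=self.design.loc[list(v.columns)])


# ---------------------------------------------------------------------------
# filters


def filter_sample_qc(
    matrix: LFQMatrix, min_fraction_of_median: float = 0.5
) -> LFQMatrix:
    """Drop samples detecting fewer proteins than a fraction of the median.

    A sample is kept when its detected-protein count is at least
    ``min_fraction_of_median`` times the median detected count across
    samples.  Dropped sample ids are recorded in ``result.meta`` and
    reported as a warning.
    """
    counts = matrix.mask().sum(axis=0)
    cutoff = min_fraction_of_median * float(counts.median())
    keep = [s for s in matrix.values.columns if counts[s] >= cutoff]
    dropped = [s for s in matrix.values.columns if s not in keep]
    if not keep:
        raise ValueError("sample QC dropped every sample")
    if dropped:
        warnings.warn(
            f"sample QC dropped {dropped} (cutoff {cutoff:.1f} proteins)",
            stacklevel=2,
        )
    out = matrix.subset(samples=keep)
    out.meta["dropped_samples"] = dropped
    out.meta["qc_cutoff_proteins"] = cutoff
    return out


def filter_group_completeness(
    matrix: LFQMatrix,
    min_fraction: float,
    groups: Sequence[str] | None = None,
) -> LFQMatrix:
    """Keep proteins observed in at least ``min_fraction`` of one group.

    The fractional requirement is converted to a whole-sample count by
    ceiling (e.g. 70% of 6 samples -> at least 5), then compared with >=.
    ``groups`` restricts the check to a comparison's groups (default: all).
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    groups = list(groups) if groups is not None else matrix.groups
    mask = matrix.mask()
    keep = np.zeros(matrix.n_proteins, dtype=bool)
    for g in groups:
        samples = matrix.group_samples(g)
        if not samples:
            raise ValueError(f"group {g!r} has no samples")
        required = math.ceil(min_fraction * len(samples))
        keep |= (mask[samples].sum(axis=1) >= required).to_numpy()
    if not keep.any():
        warnings.warn("completeness filter removed every protein", stacklevel=2)
    return matrix.subset(proteins=list(matrix.values.index[keep]))


# ---------------------------------------------------------------------------
# imputation


class MixedImputer(TransformerMixin, BaseEstimator):
    """MNAR/MCAR mixed imputation for LFQ log2-intensity matrices.

    Proteins observed in at least ``knn_cutoff`` of samples are treated as
    missing-at-random and imputed by averaging the ``k_neighbors`` most
    correlated proteins (Pearson, over shared observed samples) that carry a
    value in the missing sample.  Sparser proteins are treated as
    below-detection (MNAR) and imputed per sample from a downshifted
    Gaussian: mean = sample mean - ``downshift_sd`` * sample SD, spread =
    ``width`` * sample SD.  Observed cells are never altered; output is
    deterministic given ``random_state``.

    Parameters
    ----------
    width : float, default 0.3
        Gaussian spread as a fraction of the per-sample SD.
    downshift_sd : float, default 1.8
        Downshift of the Gaussian mean, in per-sample SDs.
    knn_cutoff : float, default 0.6
        Fraction-valid threshold separating the KNN and Gaussian branches.
    k_neighbors : int, default 3
        Neighbours averaged by the KNN branch.
    random_state : int, default 0
        Seed for the Gaussian draws.
    """

    def __init__(
        self,
        width: float = 0.3,
        downshift_sd: float = 1.8,
        knn_cutoff: float = 0.6,
        k_neighbors: int = 3,
        random_state: int = 0,
    ):
        self.width = width
        self.downshift_sd = downshift_sd
        self.knn_cutoff = knn_cutoff
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def _check_params(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.downshift_sd < 0:
            raise ValueError("downshift_sd must be >= 0")
        if not (0 < self.knn_cutoff <= 1):
            raise ValueError("knn_cutoff must be in (0, 1]")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")

    def fit(self, X: LFQMatrix | pd.DataFrame, y=None) -> "MixedImputer":
        """Record per-sample observed means and SDs."""
        self._check_params()
        values = X.values if isinstance(X, LFQMatrix) else pd.DataFrame(X)
        n_obs = values.notna().sum(axis=0)
        thin = list(n_obs.index[n_obs < 2])
        if thin:
            raise ValueError(f"samples with < 2 observed values: {thin}")
        self.sample_mean_ = values.mean(axis=0, skipna=True)
        self.sample_sd_ = values.std(axis=0, skipna=True, ddof=1)
        return self

    def transform(self, X: LFQMatrix | pd.DataFrame) -> LFQMatrix | pd.DataFrame:
        check_is_fitted(self, "sample_mean_")
        is_lfq = isinstance(X, LFQMatrix)
        values = (X.values if is_lfq else pd.DataFrame(X)).copy()
        rng = np.random.default_rng(self.random_state)
        obs = values.notna()
        frac_valid = obs.mean(axis=1)
        knn_rows = frac_valid >= self.knn_cutoff

        # KNN branch: neighbours by Pearson correlation over shared samples.
        knn_missing = values.index[(~obs).any(axis=1) & knn_rows]
        if len(knn_missing):
            corr = values.T.corr(min_periods=3)
        for pid in knn_missing:
            ranked = corr[pid].drop(index=pid).dropna().sort_values(ascending=False)
            for sample in values.columns[~obs.loc[pid]]:
                donors = [q for q in ranked.index if obs.at[q, sample]][
                    : self.k_neighbors
                ]
                if donors:
                    values.at[pid, sample] = float(
                        values.loc[donors, sample].mean()
                    )
        # Gaussian branch (plus KNN cells with no donor), drawn per sample.
        for sample in values.columns:
            col = values[sample]
            hole = col.isna()
            if not hole.any():
                continue
            mu = self.sample_mean_[sample] - self.downshift_sd * self.sample_sd_[sample]
            sd = self.width * self.sample_sd_[sample]
            values.loc[hole, sample] = rng.normal(mu, sd, size=int(hole.sum()))
        if is_lfq:
            return LFQMatrix(values=values, design=X.design, meta=dict(X.meta))
        return values


def impute_mixed(
    matrix: LFQMatrix,
    width: float = 0.3,
    downshift_sd: float = 1.8,
    knn_cutoff: float = 0.6,
    k_neighbors: int = 3,
    seed: int = 0,
) -> LFQMatrix:
    """Functional wrapper around :class:`MixedImputer` (fit + transform)."""
    imputer = MixedImputer(
        width=width,
        downshift_sd=downshift_sd,
        knn_cutoff=knn_cutoff,
        k_neighbors=k_neighbors,
        random_state=seed,
    )
    return imputer.fit(matrix).transform(matrix)


# ---------------------------------------------------------------------------
# s0-moderated permutation t-test


class PermutationTTest(BaseEstimator):
    """Two-sample s0-moderated t-test with permutation-based FDR.

    Per protein the statistic is ``t_s0 = (mean1 - mean2) / (se + s0)``
    where ``se`` is the pooled-variance standard error and ``s0`` damps the
    significance of near-zero-variance proteins.  The null distribution is
    built by recomputing ``t_s0`` under distinct group-label permutations;
    q-values use the pooled-permutation estimator: for cutoff ``c``,
    ``FDR(c) = E_perm[#{|t*| >= c}] / #{|t| >= c}``, made monotone by a
    suffix minimum over cutoffs, clipped to [0, 1].

    Parameters
    ----------
    s0 : float, default 0.5
        Variance-stabilizing offset added to the denominator.
    n_permutations : int, default 250
        Label permutations; when fewer distinct splits exist, all of them
        are enumerated (``exhaustive_``) and a warning is emitted.
    fdr_threshold : float, default 0.05
        q cutoff for the ``significant_`` flag.
    equal_var : bool, default True
        Pooled-variance (Student) SE; ``False`` uses the Welch SE.
    fdr_method : {"sam", "bh"}
        Pooled-permutation FDR (default) or per-protein permutation
        p-values corrected by Benjamini-Hochberg.
    random_state : int, default 0
        Seed for permutation sampling.
    """

    def __init__(
        self,
        s0: float = 0.5,
        n_permutations: int = 250,
        fdr_threshold: float = 0.05,
        equal_var: bool = True,
        fdr_method: str = "sam",
        random_state: int = 0,
    ):
        self.s0 = s0
        self.n_permutations = n_permutations
        self.fdr_threshold = fdr_threshold
        self.equal_var = equal_var
        self.fdr_method = fdr_method
        self.random_state = random_state

    def _t_s0(self, X: np.ndarray, idx1: np.ndarray, idx2: np.ndarray) -> np.ndarray:
        x1, x2 = X[:, idx1], X[:, idx2]
        n1, n2 = x1.shape[1], x2.shape[1]
        m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
        v1 = x1.var(axis=1, ddof=1)
        v2 = x2.var(axis=1, ddof=1)
        if self.equal_var:
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        else:
            se = np.sqrt(v1 / n1 + v2 / n2)
        diff = m1 - m2
        denom = se + self.s0
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(
                denom > 0,
                diff / np.where(denom > 0, denom, 1.0),
                np.where(diff == 0, 0.0, np.sign(diff) * np.inf),
            )
        return t

    def fit(
        self,
        X: LFQMatrix | pd.DataFrame,
        y: Sequence[str] | None = None,
        group_pair: tuple[str, str] | None = None,
    ) -> "PermutationTTest":
        """Fit on a complete (imputed) matrix for one group pair.

        ``X`` may be an :class:`LFQMatrix` (design included) or a protein x
        sample DataFrame with ``y`` giving per-sample group labels.
        """
        if self.s0 < 0:
            raise ValueError("s0 must be >= 0")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not (0 < self.fdr_threshold < 1):
            raise ValueError("fdr_threshold must be in (0, 1)")
        if isinstance(X, LFQMatrix):
            values, design = X.values, X.design
        else:
            values = pd.DataFrame(X)
            if y is None:
                raise ValueError("y (group labels) required for a plain matrix")
            design = pd.Series(list(y), index=values.columns)
        if values.isna().any().any():
            raise ValueError("matrix must be complete (imputed) before testing")
        if group_pair is None:
            groups = list(dict.fromkeys(design))
            if len(groups) != 2:
                raise ValueError(
                    f"group_pair required when design has {len(groups)} groups"
                )
            group_pair = (groups[0], groups[1])
        g1, g2 = group_pair
        cols = [s for s in values.columns if design[s] in (g1, g2)]
        labels = design.loc[cols].to_numpy()
        arr = values[cols].to_numpy(dtype=float)
        idx1 = np.flatnonzero(labels == g1)
        idx2 = np.flatnonzero(labels == g2)
        if len(idx1) < 2 or len(idx2) < 2:
            raise ValueError("both groups need at least 2 samples")

        t_obs = self._t_s0(arr, idx1, idx2)
        log2fc = arr[:, idx1].mean(axis=1) - arr[:, idx2].mean(axis=1)

        n, n1 = len(cols), len(idx1)
        n_distinct = math.comb(n, n1)
        if n_distinct <= self.n_permutations:
            splits = [np.array(c) for c in itertools.combinations(range(n), n1)]
            self.exhaustive_ = True
            if n_distinct < self.n_permutations:
                warnings.warn(
                    f"only {n_distinct} distinct permutations exist; using all",
                    stacklevel=2,
                )
        else:
            rng = np.random.default_rng(self.random_state)
            seen: set[tuple[int, ...]] = set()
            splits = []
            while len(splits) < self.n_permutations:
                c = tuple(sorted(rng.choice(n, size=n1, replace=False).tolist()))
                if c not in seen:
                    seen.add(c)
                    splits.append(np.array(c))
            self.exhaustive_ = False
        all_idx = np.arange(n)
        t_perm = np.empty((len(splits), len(t_obs)))
        for b, s1 in enumerate(splits):
            s2 = np.setdiff1d(all_idx, s1, assume_unique=True)
            t_perm[b] = self._t_s0(arr, s1, s2)

        self.q_values_ = self._q_values(np.abs(t_obs), np.abs(t_perm))
        self.t_s0_ = t_obs
        self.log2fc_ = log2fc
        self.group_pair_ = (g1, g2)
        self.n_distinct_permutations_ = len(splits)
        self.significant_ = self.q_values_ < self.fdr_threshold
        self.results_ = pd.DataFrame(
            {
                "log2FC": log2fc,
                "t_s0": t_obs,
                "q_value": self.q_values_,
                "significant": self.significant_,
            },
            index=values.index.rename("protein"),
        )
        return self

    def _q_values(self, t_abs: np.ndarray, t_perm_abs: np.ndarray) -> np.ndarray:
        order = np.argsort(-t_abs, kind="stable")
        sorted_t = t_abs[order]
        if self.fdr_method == "sam":
            flat = np.sort(t_perm_abs.ravel())
            n_perm = t_perm_abs.shape[0]
            # E[#{|t*| >= c}] / B at each observed cutoff, R = rank
            exceed = len(flat) - np.searchsorted(flat, sorted_t, side="left")
            fdr = (exceed / n_perm) / np.arange(1, len(sorted_t) + 1)
            q_sorted = np.minimum.accumulate(np.minimum(fdr, 1.0)[::-1])[::-1]
        elif self.fdr_method == "bh":
            flat = np.sort(t_perm_abs.ravel())
            p = (
                1.0
                + len(flat)
                - np.searchsorted(flat, t_abs, side="left").astype(float)
            ) / (len(flat) + 1.0)
            q = multipletests(p, method="fdr_bh")[1]
            return q
        else:
            raise ValueError(f"unknown fdr_method {self.fdr_method!r}")
        q = np.empty_like(q_sorted)
        q[order] = q_sorted
        return q


def permutation_ttest(
    matrix: LFQMatrix,
    group_pair: tuple[str, str] | None = None,
    s0: float = 0.5,
    n_permutations: int = 250,
    fdr_threshold: float = 0.05,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Functional wrapper around :class:`PermutationTTest`; returns the table."""
    est = PermutationTTest(
        s0=s0,
        n_permutations=n_permutations,
        fdr_threshold=fdr_threshold,
        random_state=seed,
        **kwargs,
    )
    return est.fit(matrix, group_pair=group_pair).results_


# ---------------------------------------------------------------------------
# QC summaries


def qc_summaries(
    matrix: LFQMatrix, groups: Sequence[str] | None = None
) -> dict[str, pd.DataFrame | pd.Series]:
    """Per-group CV medians, Pearson sample correlations, and PCA scores.

    CVs are computed on linear-scale intensities (2**log2) because the
    coefficient of variation is only meaningful on a ratio scale; the
    correlation matrix uses pairwise-complete observations; PCA runs on the
    centered complete rows (samples as observations).
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    groups = list(groups) if groups is not None else matrix.groups
    linear = np.power(2.0, matrix.values)
    cv_rows = {}
    for g in groups:
        samples = matrix.group_samples(g)
        sub = linear[samples]
        cv = sub.std(axis=1, ddof=1) / sub.mean(axis=1)
        cv_rows[g] = float(cv.median(skipna=True))
    cv_median = pd.Series(cv_rows, name="median_cv")

    correlation = matrix.values.corr(min_periods=3)

    complete = matrix.values.dropna(axis=0)
    if complete.shape[0] < 3:
        raise ValueError("PCA needs at least 3 complete proteins")
    n_comp = min(complete.shape[1], complete.shape[0], 10)
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(complete.T.to_numpy())
    pca_scores = pd.DataFrame(
        scores,
        index=complete.columns,
        columns=[f"PC{i + 1}" for i in range(n_comp)],
    )
    pca_scores.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_
    return {
        "cv_median": cv_median,
        "correlation": correlation,
        "pca_scores": pca_scores,
    }


# ---------------------------------------------------------------------------
# enrichment


@dataclass
class EnrichmentResult:
    """Fisher/BH gene-set enrichment table plus skipped (no-overlap) sets."""

    table: pd.DataFrame
    skipped_sets: list[str]


def fisher_enrichment(
    hits: Iterable[str],
    background: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    fdr_threshold: float = 0.05,
) -> EnrichmentResult:
    """Two-sided Fisher exact enrichment of ``hits`` against gene sets.

    Each set is intersected with the background; the 2x2 table is
    (hit & set, hit - set, set - hit, neither).  P-values are corrected
    across tested sets by Benjamini-Hochberg.  Sets with no background
    overlap are skipped and reported.  An infinite odds ratio (empty
    off-diagonal) is returned as ``inf``.
    """
    hits = set(hits)
    background = set(background)
    if not background:
        raise ValueError("empty background")
    if not hits <= background:
        raise ValueError("hits must be a subset of the background")
    rows, skipped = [], []
    for name, members in gene_sets.items():
        members = set(members) & background
        if not members:
            skipped.append(name)
            continue
        a = len(hits & members)
        b = len(hits - members)
        c = len(members - hits)
        d = len(background) - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {
                "gene_set": name,
                "overlap": a,
                "set_size": len(members),
                "hits": len(hits),
                "background": len(background),
                "odds_ratio": odds,
                "p_value": p,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_set",
            "overlap",
            "set_size",
            "hits",
            "background",
            "odds_ratio",
            "p_value",
        ],
    )
    if len(table):
        table["p_adjusted"] = multipletests(table["p_value"], method="fdr_bh")[1]
        table["significant"] = table["p_adjusted"] < fdr_threshold
        table = table.sort_values("p_value", kind="stable").reset_index(drop=True)
    else:
        table["p_adjusted"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return EnrichmentResult(table=table, skipped_sets=skipped)
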