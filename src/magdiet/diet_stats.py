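"""Diet-comparison statistics for substrate-degradation profiles.

Implements the multivariate and rank procedures the analysis rests on:

* scaled principal component analysis (correlation-structure PCA, as R's
  ``prcomp(scale.=TRUE)`` computes it);
* one-way PERMANOVA — pseudo-F from partitioned sums of squared pairwise
  distances with a label-permutation null;
* homogeneity of multivariate dispersion — distances to group centroids in a
  principal-coordinates embedding (with the standard negative-eigenvalue
  correction), one-way ANOVA F on those distances, permutation p;
* Kruskal–Wallis with midrank tie correction and post-hoc pairwise two-sided
  Wilcoxon rank-sum tests (exact enumeration for small untied samples,
  tie-corrected normal approximation with continuity correction otherwise),
  Holm-adjusted.

All permutation draws are governed by one integer seed; permutation p-values
use the add-one formula (#{F* >= F} + 1) / (P + 1) and are bounded below by
1 / (P + 1). ``n_permutations="exact"`` enumerates every distinct label
assignment instead (p = #{F* >= F} / M including the identity).
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2, norm

from .errors import DegenerateDataError, DesignError, ValidationError
from .substrate_matrix import DietDesign, SubstrateProfile, fold_change, profiles_to_frame

DEFAULT_PERMUTATIONS = 999
_METRICS = ("euclidean", "braycurtis")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    """Numeric feature table with one group label per row."""

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self):
        self.values = self.values.astype(float)
        self.groups = self.groups.reindex(self.values.index)
        if self.groups.isna().any():
            missing = list(self.values.index[self.groups.isna()])
            raise DesignError(f"rows without group labels: {missing}")
        if self.values.isna().any().any():
            raise ValidationError("feature matrix has missing cells")

    def require_design(self, min_group: int = 2):
        sizes = self.groups.value_counts()
        if len(sizes) < 2:
            raise DesignError("omnibus tests need at least 2 groups")
        small = sizes[sizes < min_group]
        if len(small):
            raise DesignError(
                f"group(s) below size {min_group}: {dict(small)}"
            )


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # feature x component
    scores: pd.DataFrame  # row x component
    variance_explained: np.ndarray
    dropped_features: list[str] = field(default_factory=list)


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    seed: int | None


@dataclass
class DispersionResult:
    F: float
    p_value: float
    distances: pd.Series  # per-row distance to own group centroid
    n_permutations: int
    seed: int | None


@dataclass
class PairwiseTest:
    group_a: str
    group_b: str
    statistic: float
    p_raw: float
    p_adjusted: float
    method: str  # "exact" or "normal"


@dataclass
class RankTestResult:
    statistic: float
    p_value: float
    pairwise: list[PairwiseTest] = field(default_factory=list)


# ---------------------------------------------------------------------------
# scaled PCA
# ---------------------------------------------------------------------------


def scaled_pca(matrix: FeatureMatrix | pd.DataFrame) -> PCAResult:
    """Center-and-scale PCA via SVD.

    Columns are centered and divided by their sample standard deviation
    (ddof=1); zero-variance columns are dropped with a warning since scaling
    is undefined for them. Variance fractions are the squared singular values
    over their total and sum to 1.
    """
    X = matrix.values if isinstance(matrix, FeatureMatrix) else matrix.astype(float)
    if len(X) < 2:
        raise DegenerateDataError("PCA needs at least 2 rows")
    sd = X.std(ddof=1)
    dropped = list(X.columns[sd == 0])
    if dropped:
        warnings.warn(f"dropping zero-variance feature(s): {dropped}", stacklevel=2)
        X = X.drop(columns=dropped)
        sd = sd.drop(dropped)
    if X.shape[1] == 0:
        raise DegenerateDataError("all features have zero variance")
    Z = (X - X.mean()) / sd
    U, S, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    comp = [f"PC{i + 1}" for i in range(len(S))]
    return PCAResult(
        loadings=pd.DataFrame(Vt.T, index=X.columns, columns=comp),
        scores=pd.DataFrame(U * S, index=X.index, columns=comp),
        variance_explained=S**2 / np.sum(S**2),
        dropped_features=dropped,
    )


# ---------------------------------------------------------------------------
# distance partitioning (PERMANOVA)
# ---------------------------------------------------------------------------


def _distance_sq(values: np.ndarray, metric: str) -> np.ndarray:
    if metric not in _METRICS:
        raise DesignError(f"unknown distance metric {metric!r}; choose from {_METRICS}")
    return squareform(pdist(values, metric=metric)) ** 2


def _ss_within(D2: np.ndarray, codes: np.ndarray, k: int) -> float:
    ss = 0.0
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        ss += D2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ss


def _distinct_assignments(sizes: Sequence[int]):
    """All distinct ways to partition range(n) into groups of the given sizes."""
    n = sum(sizes)

    def rec(remaining: tuple[int, ...], sizes_left: Sequence[int]):
        if not sizes_left:
            yield ()
            return
        size, rest = sizes_left[0], sizes_left[1:]
        if not rest:  # last group takes whatever is left
            yield (remaining,)
            return
        for chosen in itertools.combinations(remaining, size):
            left = tuple(x for x in remaining if x not in chosen)
            for tail in rec(left, rest):
                yield (chosen, *tail)

    for parts in rec(tuple(range(n)), tuple(sizes)):
        codes = np.empty(n, dtype=int)
        for g, members in enumerate(parts):
            codes[list(members)] = g
        yield codes


def permanova(
    matrix: FeatureMatrix,
    metric: str = "euclidean",
    n_permutations: int | str = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on pairwise distances.

    pseudo-F = (SS_between / (k-1)) / (SS_within / (n-k)), with the sums of
    squares obtained from the squared pairwise distances:
    SS_total = sum_{i<j} d_ij^2 / n and SS_within summed per group. The null
    distribution permutes the group labels; ``n_permutations="exact"``
    enumerates every distinct assignment (feasible for small n).
    """
    matrix.require_design(min_group=2)
    values = matrix.values.to_numpy()
    codes_s, uniques = pd.factorize(matrix.groups)
    codes = np.asarray(codes_s)
    k, n = len(uniques), len(codes)
    D2 = _distance_sq(values, metric)
    ss_total = D2.sum() / (2.0 * n)
    if ss_total <= 0:
        raise DegenerateDataError("constant matrix: total sum of squares is zero")
    ss_w = _ss_within(D2, codes, k)
    ss_b = ss_total - ss_w
    f_obs = (ss_b / (k - 1)) / (ss_w / (n - k))

    def f_of(c: np.ndarray) -> float:
        w = _ss_within(D2, c, k)
        return (ss_total - w) / (k - 1) / (w / (n - k))

    if n_permutations == "exact":
        sizes = [int((codes == g).sum()) for g in range(k)]
        # relabel so enumeration matches observed sizes; identity included
        fs = np.array([f_of(c) for c in _distinct_assignments(sizes)])
        p = float(np.mean(fs >= f_obs - 1e-12))
        n_perm = len(fs)
    else:
        if int(n_permutations) < 99:
            raise DesignError("need at least 99 permutations")
        rng = np.random.default_rng(seed)
        n_perm = int(n_permutations)
        count = 0
        for _ in range(n_perm):
            count += f_of(rng.permutation(codes)) >= f_obs - 1e-12
        p = (count + 1) / (n_perm + 1)
    return PermanovaResult(
        pseudo_F=float(f_obs),
        R2=float(ss_b / ss_total),
        p_value=float(p),
        n_permutations=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# dispersion (betadisper-style)
# ---------------------------------------------------------------------------


def _pcoa_embedding(D2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinates axes split into real (positive-eigenvalue) and
    imaginary (negative-eigenvalue) parts."""
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ D2 @ J
    eigval, eigvec = np.linalg.eigh((G + G.T) / 2.0)
    tol = max(abs(eigval)) * 1e-10 if len(eigval) else 0.0
    pos = eigval > tol
    neg = eigval < -tol
    real = eigvec[:, pos] * np.sqrt(eigval[pos])
    imag = eigvec[:, neg] * np.sqrt(-eigval[neg])
    return real, imag


def centroid_distances(
    matrix: FeatureMatrix, metric: str = "euclidean"
) -> pd.Series:
    """Each row's distance to its own group centroid in the PCoA embedding.

    For negative eigenvalues the squared imaginary-axis distance is
    subtracted (clipped at zero); with Euclidean input the embedding is an
    isometry and these equal direct feature-space centroid distances.
    """
    D2 = _distance_sq(matrix.values.to_numpy(), metric)
    real, imag = _pcoa_embedding(D2)
    codes_s, uniques = pd.factorize(matrix.groups)
    codes = np.asarray(codes_s)
    z2 = np.zeros(len(codes))
    for g in range(len(uniques)):
        idx = codes == g
        dr = real[idx] - real[idx].mean(axis=0)
        z2[idx] += (dr**2).sum(axis=1)
        if imag.shape[1]:
            di = imag[idx] - imag[idx].mean(axis=0)
            z2[idx] -= (di**2).sum(axis=1)
    return pd.Series(np.sqrt(np.clip(z2, 0.0, None)), index=matrix.values.index)


def _anova_f(values: np.ndarray, codes: np.ndarray, k: int) -> float:
    n = len(values)
    grand = values.mean()
    ss_b = ss_w = 0.0
    for g in range(k):
        grp = values[codes == g]
        ss_b += len(grp) * (grp.mean() - grand) ** 2
        ss_w += ((grp - grp.mean()) ** 2).sum()
    if ss_w == 0:
        return math.inf if ss_b > 0 else 0.0
    return (ss_b / (k - 1)) / (ss_w / (n - k))


def dispersion_test(
    matrix: FeatureMatrix,
    metric: str = "euclidean",
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
) -> DispersionResult:
    """Permutation test for homogeneity of multivariate dispersion.

    F is the one-way ANOVA statistic on the per-row centroid distances; the
    null permutes group labels over that distance vector.
    """
    matrix.require_design(min_group=2)
    dist = centroid_distances(matrix, metric)
    codes_s, uniques = pd.factorize(matrix.groups)
    codes = np.asarray(codes_s)
    k = len(uniques)
    values = dist.to_numpy()
    f_obs = _anova_f(values, codes, k)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(int(n_permutations)):
        count += _anova_f(values, rng.permutation(codes), k) >= f_obs - 1e-12
    p = (count + 1) / (int(n_permutations) + 1)
    return DispersionResult(
        F=float(f_obs),
        p_value=float(p),
        distances=dist,
        n_permutations=int(n_permutations),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _tie_sizes(values: np.ndarray) -> np.ndarray:
    _, counts = np.unique(values, return_counts=True)
    return counts


def _exact_ranksum_sf_cdf(n1: int, N: int) -> np.ndarray:
    """Counts of rank-sum values for choosing n1 of ranks 1..N (no ties)."""
    max_sum = N * (N + 1) // 2
    dp = np.zeros((n1 + 1, max_sum + 1))
    dp[0, 0] = 1.0
    for r in range(1, N + 1):
        for j in range(min(n1, r), 0, -1):
            dp[j, r:] += dp[j - 1, : max_sum - r + 1]
    return dp[n1]


EXACT_MAX_N = 12


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns (U statistic of the first sample, p, method). Uses exact
    enumeration of the rank-sum distribution when both samples have at most
    12 observations and there are no ties; otherwise the normal approximation
    with tie-corrected variance and a 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise DesignError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w1 = ranks[:n1].sum()
    u1 = w1 - n1 * (n1 + 1) / 2.0
    ties = _tie_sizes(pooled)
    no_ties = (ties == 1).all()
    if no_ties and n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        counts = _exact_ranksum_sf_cdf(n1, n1 + n2)
        total = counts.sum()
        w = int(round(w1))
        p_le = counts[: w + 1].sum() / total
        p_ge = counts[w:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return float(u1), float(p), "exact"
    N = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = (ties**3 - ties).sum() / (N * (N - 1)) if N > 1 else 0.0
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return float(u1), 1.0, "normal"
    z = (u1 - mu - math.copysign(0.5, u1 - mu)) / math.sqrt(var) if u1 != mu else 0.0
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return float(u1), float(p), "normal"


def kruskal_wallis(
    values: Sequence[float],
    groups: Sequence[str],
    *,
    alpha: float = 0.05,
    posthoc: bool = True,
    adjust: str = "holm",
) -> RankTestResult:
    """Kruskal–Wallis H with midrank tie correction; chi-squared p on k-1 df.

    When the omnibus test is significant at ``alpha`` (and ``posthoc``),
    pairwise two-sided rank-sum tests are run for every group pair with
    multiplicity adjustment (Holm by default; raw p also reported). All-equal
    input returns H = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    labels = pd.Series(list(groups))
    if len(values) != len(labels):
        raise DesignError("values and groups differ in length")
    uniques = list(dict.fromkeys(labels))
    if len(uniques) < 2:
        raise DesignError("need at least 2 groups")
    N = len(values)
    ranks = _midranks(values)
    H = 0.0
    for g in uniques:
        r = ranks[(labels == g).to_numpy()]
        H += len(r) * (r.mean() - (N + 1) / 2.0) ** 2
    H *= 12.0 / (N * (N + 1))
    ties = _tie_sizes(values)
    correction = 1.0 - (ties**3 - ties).sum() / (N**3 - N)
    if correction <= 0:  # every observation identical
        return RankTestResult(statistic=0.0, p_value=1.0)
    H /= correction
    p = float(chi2.sf(H, df=len(uniques) - 1))

    pairwise: list[PairwiseTest] = []
    if posthoc and p <= alpha:
        pairs = list(itertools.combinations(uniques, 2))
        raw = []
        stats = []
        methods = []
        for a, b in pairs:
            u, pr, method = rank_sum_test(
                values[(labels == a).to_numpy()], values[(labels == b).to_numpy()]
            )
            raw.append(pr)
            stats.append(u)
            methods.append(method)
        adjusted = _adjust_pvalues(raw, adjust)
        for (a, b), u, pr, pa, method in zip(pairs, stats, raw, adjusted, methods):
            pairwise.append(PairwiseTest(a, b, u, pr, pa, method))
    return RankTestResult(statistic=float(H), p_value=p, pairwise=pairwise)


def _adjust_pvalues(raw: Sequence[float], method: str) -> list[float]:
    if not len(raw):
        return []
    if method == "none":
        return list(raw)
    from statsmodels.stats.multitest import multipletests

    return list(multipletests(raw, method=method)[1])


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


@dataclass
class StatsConfig:
    metric: str = "euclidean"
    n_permutations: int = DEFAULT_PERMUTATIONS
    seed: int = 0
    alpha: float = 0.05
    adjust: str = "holm"
    scale_before_permanova: bool = True

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "alpha": self.alpha,
            "adjust": self.adjust,
            "scale_before_permanova": self.scale_before_permanova,
        }


@dataclass
class DietStatsReport:
    """Serializable record of the full diet analysis (statistics + config)."""

    config: dict
    features: list[str]
    pca: dict
    permanova: dict
    dispersion: dict
    rank_tests: dict
    fold_changes: dict

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "features": self.features,
            "pca": self.pca,
            "permanova": self.permanova,
            "dispersion": self.dispersion,
            "rank_tests": self.rank_tests,
            "fold_changes": self.fold_changes,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "DietStatsReport":
        return cls(**json.loads(text))


def feature_matrix_from_profiles(
    profiles: Sequence[SubstrateProfile], design: DietDesign
) -> FeatureMatrix:
    """Assemble the analysis features: normalized copy totals per substrate
    class plus the beta-oxidation binary, with diet labels."""
    frame = profiles_to_frame(profiles, design).set_index("mag_id")
    groups = frame.pop("diet")
    return FeatureMatrix(values=frame, groups=groups)


def run_diet_analysis(
    profiles: Sequence[SubstrateProfile],
    design: DietDesign,
    config: StatsConfig | None = None,
) -> DietStatsReport:
    """Full diet comparison: PCA, PERMANOVA, dispersion, per-substrate
    Kruskal–Wallis (+ post-hoc Wilcoxon), and pairwise fold changes."""
    config = config or StatsConfig()
    fm = feature_matrix_from_profiles(profiles, design)
    fm.require_design(min_group=2)

    pca = scaled_pca(fm)
    if config.scale_before_permanova:
        kept = [c for c in fm.values.columns if c not in pca.dropped_features]
        Z = (fm.values[kept] - fm.values[kept].mean()) / fm.values[kept].std(ddof=1)
        test_fm = FeatureMatrix(values=Z, groups=fm.groups)
    else:
        test_fm = fm
    perm = permanova(test_fm, config.metric, config.n_permutations, config.seed)
    disp = dispersion_test(test_fm, config.metric, config.n_permutations, config.seed)

    rank_tests = {}
    substrates = [c for c in fm.values.columns if c != "fatty_acid_binary"]
    labels = [design.group(p.mag_id) for p in profiles]
    for sub in substrates:
        res = kruskal_wallis(
            [p.normalized_copies[sub] for p in profiles],
            labels,
            alpha=config.alpha,
            adjust=config.adjust,
        )
        rank_tests[sub] = {
            "H": res.statistic,
            "p_value": res.p_value,
            "pairwise": [
                {
                    "groups": [t.group_a, t.group_b],
                    "U": t.statistic,
                    "p_raw": t.p_raw,
                    "p_adjusted": t.p_adjusted,
                    "method": t.method,
                }
                for t in res.pairwise
            ],
        }

    folds: dict[str, dict] = {}
    group_names = design.groups
    for sub in substrates:
        folds[sub] = {}
        for a, b in itertools.permutations(group_names, 2):
            try:
                folds[sub][f"{a}_vs_{b}"] = fold_change(profiles, design, sub, a, b)
            except DegenerateDataError:
                folds[sub][f"{a}_vs_{b}"] = None

    return DietStatsReport(
        config=config.to_dict(),
        features=list(fm.values.columns),
        pca={
            "variance_explained": [float(v) for v in pca.variance_explained],
            "components": list(pca.loadings.columns),
            "loadings": {
                f: [float(v) for v in pca.loadings.loc[f]] for f in pca.loadings.index
            },
            "dropped_features": pca.dropped_features,
        },
        permanova={
            "pseudo_F": perm.pseudo_F,
            "R2": perm.R2,
            "p_value": perm.p_value,
            "n_permutations": perm.n_permutations,
            "seed": perm.seed,
        },
        dispersion={
            "F": disp.F,
            "p_value": disp.p_value,
            "n_permutations": disp.n_permutations,
            "seed": disp.seed,
            "distances": {m: float(v) for m, v in disp.distances.items()},
        },
        rank_tests=rank_tests,
        fold_changes=folds,
    )
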