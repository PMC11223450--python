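"""Statistical feature families for clinical tabular data.

Four families are computed and concatenated onto the original attributes:

* **Central tendency** (``F_CT``) — arithmetic/geometric/harmonic means,
  median, discretized mode, standard deviation, trimmed and winsorized
  means, the interquartile mean, midrange, midhinge and trimean.
* **Dispersion** (``F_D``) — interquartile range, range, mean absolute
  difference, average absolute deviation, coefficient of variation,
  quartile coefficient of dispersion, relative mean difference, Gini
  coefficient and the Shannon entropy of the 4-level discretization.
* **Qualitative variation** (``F_QV``) — eight categorical-variation
  indices (ModVR, AvDev, MNDif, B index, HRel, Simpson IQV,
  Berger-Parker, Shannon-Wiener) on the 4-level discretization.
* **Symmetric uncertainty** (``F_SU``) — per-attribute normalized mutual
  information with the class, 2*I(Q;P)/(H(Q)+H(P)), used by the feature
  selector as a relevance prior.

The first three families are computed ROW-WISE (one descriptor vector per
sample, summarizing that sample's normalized attribute profile); symmetric
uncertainty is computed COLUMN-WISE (one relevance score per attribute).
Quartiles use linear interpolation on sorted order statistics (the
"inclusive" scheme, numpy's default).  Descriptors whose defining formula
is undefined for a given input (e.g. the geometric mean with a zero entry)
are ``nan`` in the dataclass and 0.0 in the assembled matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields

import numpy as np
from scipy import stats as sps

from .data_io import CleanTable

__all__ = [
    "CTDescriptors",
    "DispersionDescriptors",
    "QVDescriptors",
    "FeatureSet",
    "central_tendency",
    "dispersion",
    "discretize_levels",
    "qualitative_variation",
    "symmetric_uncertainty",
    "assemble_features",
    "continuous_entropy",
]

N_LEVELS = 4
_LEVEL_EDGES = np.array([0.25, 0.5, 0.75])
_LEVEL_MIDPOINTS = np.array([0.125, 0.375, 0.625, 0.875])


@dataclass
class CTDescriptors:
    am: float
    median: float
    mode: float
    sd: float
    gm: float
    hm: float
    trimmed_mean: float
    interquartile_mean: float
    midrange: float
    midhinge: float
    trimean: float
    winsorized_mean: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])


@dataclass
class DispersionDescriptors:
    iqr: float
    range: float
    mad: float
    aad: float
    cv: float
    qcd: float
    rmd: float
    gini: float
    entropy: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])


@dataclass
class QVDescriptors:
    level_counts: np.ndarray
    modvr: float
    avdev: float
    mndif: float
    b_index: float
    hrel: float
    simpson_iqv: float
    berger_parker: float
    shannon_wiener: float

    _INDEX_FIELDS = (
        "modvr", "avdev", "mndif", "b_index",
        "hrel", "simpson_iqv", "berger_parker", "shannon_wiener",
    )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self._INDEX_FIELDS])


@dataclass
class FeatureSet:
    """Assembled feature matrix with per-attribute relevance scores.

    ``X_aug`` concatenates the original attributes with the row-wise CT,
    dispersion and QV descriptors.  ``su_scores`` holds the per-original-
    attribute symmetric uncertainty against the class; ``su_all`` extends
    it to every column of ``X_aug`` (used by the selection fitness).
    """

    X_aug: np.ndarray
    su_scores: np.ndarray
    family_index: dict
    column_names: list
    su_all: np.ndarray
    y: np.ndarray


def _quartiles(v: np.ndarray):
    return np.quantile(v, [0.25, 0.5, 0.75], method="linear")


def central_tendency(values, trim_p: float = 0.1, winsor_p: float | None = None) -> CTDescriptors:
    """Central-tendency descriptors of a numeric vector.

    Quartile-based fields (interquartile mean, midhinge, trimean) require
    n >= 4 and are nan otherwise; gm/hm require strictly positive input.
    ``trim_p`` is the per-tail trim proportion in [0, 0.25]; ``winsor_p``
    the per-tail winsorization proportion (defaults to ``trim_p``).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("values must be a non-empty 1-D vector")
    if winsor_p is None:
        winsor_p = trim_p
    if not (0.0 <= trim_p <= 0.25 and 0.0 <= winsor_p <= 0.25):
        raise ValueError("trim proportions must lie in [0, 0.25]")
    n = v.size
    am = float(v.mean())
    med = float(np.median(v))
    sd = float(v.std(ddof=0))
    lo, hi = float(v.min()), float(v.max())
    midrange = (lo + hi) / 2.0

    if np.all(v > 0):
        gm = float(np.exp(np.mean(np.log(v))))
        hm = float(n / np.sum(1.0 / v))
    else:
        gm = hm = math.nan

    # mode of continuous data: modal 4-level bin of the min-max-normalized
    # copy, mapped back to that bin's midpoint on the original scale
    if hi > lo:
        levels = discretize_levels((v - lo) / (hi - lo))
        counts = np.bincount(levels, minlength=N_LEVELS + 1)[1:]
        mode = lo + _LEVEL_MIDPOINTS[int(np.argmax(counts))] * (hi - lo)
    else:
        mode = float(v[0])

    trimmed = float(sps.trim_mean(v, trim_p)) if trim_p > 0 else am
    wins = float(np.mean(sps.mstats.winsorize(v, limits=(winsor_p, winsor_p))))

    if n >= 4:
        c1, c2, c3 = _quartiles(v)
        midhinge = float((c1 + c3) / 2.0)
        trimean = float((c1 + 2.0 * c2 + c3) / 4.0)
        # interquartile mean as printed: (2/n) * sum of sorted values with
        # 1-based index floor(n/4)+1 .. floor(3n/4)
        s = np.sort(v)
        a, b = n // 4, (3 * n) // 4
        iq_mean = float(2.0 / n * s[a:b].sum())
    else:
        midhinge = trimean = iq_mean = math.nan

    return CTDescriptors(
        am=am, median=med, mode=float(mode), sd=sd, gm=gm, hm=hm,
        trimmed_mean=trimmed, interquartile_mean=iq_mean,
        midrange=float(midrange), midhinge=midhinge, trimean=trimean,
        winsorized_mean=wins,
    )


def dispersion(values) -> DispersionDescriptors:
    """Dispersion descriptors of a numeric vector (n >= 2).

    mad is the mean absolute difference (1/n^2) sum_ij |x_i - x_j|; aad the
    average absolute deviation from the median; entropy the Shannon entropy
    (natural log) of the 4-level discretization of the min-max-normalized
    vector.  Ratios with zero denominators are nan.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("values must be a 1-D vector with n >= 2")
    n = v.size
    p1, _, p3 = _quartiles(v)
    iqr = float(p3 - p1)
    rng_ = float(v.max() - v.min())
    mad = float(np.abs(v[:, None] - v[None, :]).sum() / n**2)
    aad = float(np.mean(np.abs(v - np.median(v))))
    am = float(v.mean())
    sd = float(v.std(ddof=0))
    cv = sd / am if am != 0 else math.nan
    qcd = float((p3 - p1) / (p3 + p1)) if (p3 + p1) != 0 else math.nan
    rmd = mad / am if am != 0 else math.nan
    gini = rmd / 2.0 if am != 0 else math.nan

    lo, hi = v.min(), v.max()
    normalized = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
    levels = discretize_levels(normalized)
    counts = np.bincount(levels, minlength=N_LEVELS + 1)[1:]
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log(p)).sum())

    return DispersionDescriptors(
        iqr=iqr, range=rng_, mad=mad, aad=aad, cv=cv, qcd=qcd,
        rmd=rmd, gini=gini, entropy=entropy,
    )


def discretize_levels(normalized) -> np.ndarray:
    """Map [0,1] values onto 4 ordinal levels.

    [0, 0.25] -> 1, (0.25, 0.5] -> 2, (0.5, 0.75] -> 3, (0.75, 1] -> 4.
    The printed level boundaries overlap at the quarter points; this
    implementation fixes the upper-inclusive convention (ties go down).
    """
    x = np.asarray(normalized, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("values must lie in [0, 1] before discretization")
    return (np.searchsorted(_LEVEL_EDGES, x, side="left") + 1).astype(int)


def qualitative_variation(levels) -> QVDescriptors:
    """Categorical-variation indices on a vector of levels in {1..4}.

    With counts f_k over K=4 categories, modal count f_m and n samples:

    * ModVR          = K (n - f_m) / (n (K - 1))
    * AvDev          = 1 - sum_k |f_k - n/K| / (2 n (K-1) / K)
    * MNDif          = 1 - sum_{k<l} |f_k - f_l| / (n (K-1))
    * B index        = 1 - sqrt(1 - (K * gm(f) / n)^2),  gm = geometric mean
    * HRel           = Shannon entropy / log K
    * Simpson IQV    = K (1 - sum p_k^2) / (K - 1)
    * Berger-Parker  = f_m / n
    * Shannon-Wiener = -sum p_k ln p_k

    All are invariant under permutation of the category labels; the first
    six lie in [0, 1] with 0 at zero variation and 1 at the uniform
    distribution.
    """
    lv = np.asarray(levels, dtype=int)
    if lv.size == 0:
        raise ValueError("empty level vector")
    if np.any((lv < 1) | (lv > N_LEVELS)):
        raise ValueError("levels must lie in {1..4}")
    n = lv.size
    k = N_LEVELS
    f = np.bincount(lv, minlength=k + 1)[1:].astype(float)
    fm = f.max()
    p = f / n

    modvr = k * (n - fm) / (n * (k - 1))
    avdev = 1.0 - np.abs(f - n / k).sum() / (2.0 * n * (k - 1) / k)
    pair_diff = sum(
        abs(f[i] - f[j]) for i in range(k) for j in range(i + 1, k)
    )
    mndif = 1.0 - pair_diff / (n * (k - 1))
    gm_f = float(np.prod(f) ** (1.0 / k))
    b_arg = 1.0 - (k * gm_f / n) ** 2
    b_index = 1.0 - math.sqrt(max(b_arg, 0.0))
    pz = p[p > 0]
    shannon = float(-(pz * np.log(pz)).sum())
    hrel = shannon / math.log(k)
    simpson_iqv = k * (1.0 - float((p**2).sum())) / (k - 1)
    berger_parker = float(fm / n)

    return QVDescriptors(
        level_counts=f.astype(int), modvr=float(modvr), avdev=float(avdev),
        mndif=float(mndif), b_index=float(b_index), hrel=float(hrel),
        simpson_iqv=float(simpson_iqv), berger_parker=berger_parker,
        shannon_wiener=shannon,
    )


def _entropy_bits(labels) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def symmetric_uncertainty(q, p) -> float:
    """Symmetric uncertainty SU(Q, P) = 2 I(Q;P) / (H(Q) + H(P)) in [0, 1].

    Mutual information and entropies come from empirical joint frequencies
    (0 log 0 := 0).  SU is 0 when both marginal entropies vanish.
    """
    q = np.asarray(q)
    p = np.asarray(p)
    if q.shape != p.shape or q.ndim != 1 or q.size == 0:
        raise ValueError("q and p must be equal-length non-empty vectors")
    n = q.size
    qv, qi = np.unique(q, return_inverse=True)
    pv, pi = np.unique(p, return_inverse=True)
    joint = np.zeros((qv.size, pv.size))
    np.add.at(joint, (qi, pi), 1.0)
    joint /= n
    mq = joint.sum(axis=1)
    mp = joint.sum(axis=0)
    mask = joint > 0
    cm = float(
        (joint[mask] * np.log2(joint[mask] / np.outer(mq, mp)[mask])).sum()
    )
    hq = _entropy_bits(q)
    hp = _entropy_bits(p)
    denom = hq + hp
    if denom == 0:
        return 0.0
    return float(min(max(2.0 * cm / denom, 0.0), 1.0))


_QUARTILE_CT = ("interquartile_mean", "midhinge", "trimean")


def assemble_features(
    table: CleanTable, trim_p: float = 0.1, winsor_p: float = 0.1
) -> FeatureSet:
    """Build the augmented feature matrix F = [X | F_CT | F_D | F_QV].

    ``table`` must already be min-max normalized to [0, 1]; the row-wise
    descriptor families are computed on each sample's attribute profile and
    appended to the original columns.  Symmetric uncertainty against the
    class is computed column-wise for the original attributes
    (``su_scores``) and for every assembled column (``su_all``).

    With fewer than 4 attributes the quartile-based CT descriptors are
    excluded with a warning.  nan descriptors (undefined formulas) become
    0.0 in the matrix.
    """
    X = table.X
    if X.min() < 0 or X.max() > 1:
        raise ValueError("assemble_features expects a [0,1]-normalized table")
    n, d = X.shape
    drop_quartile = d < 4
    if drop_quartile:
        warnings.warn(
            "fewer than 4 attributes: quartile-based descriptors excluded"
        )

    ct_names = [f.name for f in fields(CTDescriptors)]
    if drop_quartile:
        ct_keep = [i for i, nm in enumerate(ct_names) if nm not in _QUARTILE_CT]
        ct_names = [nm for nm in ct_names if nm not in _QUARTILE_CT]
    else:
        ct_keep = list(range(len(ct_names)))
    d_names = [f.name for f in fields(DispersionDescriptors)]
    qv_names = list(QVDescriptors._INDEX_FIELDS)

    blocks = np.empty((n, len(ct_names) + len(d_names) + len(qv_names)))
    for i in range(n):
        row = X[i]
        ct = central_tendency(row, trim_p=trim_p, winsor_p=winsor_p).as_array()[ct_keep]
        dd = dispersion(row).as_array()
        qv = qualitative_variation(discretize_levels(row)).as_array()
        blocks[i] = np.concatenate([ct, dd, qv])
    blocks = np.nan_to_num(blocks, nan=0.0)

    X_aug = np.hstack([X, blocks])
    column_names = (
        list(table.attribute_names)
        + [f"ct_{nm}" for nm in ct_names]
        + [f"d_{nm}" for nm in d_names]
        + [f"qv_{nm}" for nm in qv_names]
    )
    family_index = {}
    for j, nm in enumerate(column_names):
        if j < d:
            family_index[nm] = "original"
        elif nm.startswith("ct_"):
            family_index[nm] = "CT"
        elif nm.startswith("d_"):
            family_index[nm] = "D"
        else:
            family_index[nm] = "QV"

    su_scores = np.array(
        [symmetric_uncertainty(discretize_levels(X[:, j]), table.y) for j in range(d)]
    )
    su_all = np.empty(X_aug.shape[1])
    su_all[:d] = su_scores
    for j in range(d, X_aug.shape[1]):
        col = X_aug[:, j]
        lo, hi = col.min(), col.max()
        norm = (col - lo) / (hi - lo) if hi > lo else np.zeros_like(col)
        su_all[j] = symmetric_uncertainty(discretize_levels(norm), table.y)

    return FeatureSet(
        X_aug=X_aug, su_scores=su_scores, family_index=family_index,
        column_names=column_names, su_all=su_all, y=table.y.copy(),
    )


def continuous_entropy(x, n_bins: int | None = None) -> float:
    """Histogram estimate of the differential entropy of a sample.

    Equal-width bins over the sample range; Ĥ = -sum p_i ln(p_i / w) with
    bin width w.  Differential entropy obeys H(c x) = H(x) + log c, and this
    estimator inherits that scale law up to sampling noise.
    """
    x = np.asarray(x, dtype=float)
    if n_bins is None:
        n_bins = max(int(round(math.sqrt(x.size))), 2)
    counts, edges = np.histogram(x, bins=n_bins)
    w = edges[1] - edges[0]
    p = counts[counts > 0] / x.size
    return float(-(p * np.log(p / w)).sum())
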