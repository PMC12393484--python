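"""MIEL population phenotyping: texture features, condensed centers, PCA+SVM.

Microscopic imaging of epigenetic landscapes (MIEL) compares cell
populations by texture: per-nucleus image features (gray-level
co-occurrence / Haralick statistics plus intensity moments) are z-scored,
pools of n cells per condition are averaged into "condensed centers", the
centers are reduced with PCA (four components) and classified with a linear
SVM; separability is summarized in a confusion matrix and pairwise
Euclidean distance matrices.  The pool size n is chosen by a bootstrap
rule: the smallest n reaching >= 95% classification accuracy in >= 95% of
iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kurtosis, skew
from skimage.feature import graycomatrix
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.svm import SVC

__all__ = [
    "extract_features",
    "zscore",
    "apply_zscore",
    "condense",
    "fit_classify",
    "distance_analysis",
    "discriminant_scatter",
    "bootstrap_condensation",
    "CondensationResult",
    "MielModel",
    "MielReport",
    "BootstrapReport",
    "haralick_features",
    "HARALICK_NAMES",
]

GLCM_LEVELS = 64
GLCM_DISTANCES = (1, 2, 4, 8)
GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)

HARALICK_NAMES = (
    "asm", "contrast", "correlation", "variance", "idm",
    "sum_average", "sum_variance", "sum_entropy", "entropy",
    "diff_variance", "diff_entropy", "imc1", "imc2",
)


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def haralick_features(p: np.ndarray) -> np.ndarray:
    """The 13 classic co-occurrence statistics of a normalized GLCM ``p``.

    ``p`` is an (L, L) joint probability matrix.  Degenerate matrices
    (all mass at one entry, e.g. constant crops) yield defined values:
    entropies and contrast are 0, ASM is 1, correlation is defined as 0
    when a marginal has zero variance.
    """
    levels = p.shape[0]
    idx = np.arange(levels, dtype=float)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux = (idx * px).sum()
    muy = (idx * py).sum()
    sx = np.sqrt(((idx - mux) ** 2 * px).sum())
    sy = np.sqrt(((idx - muy) ** 2 * py).sum())
    ii, jj = np.meshgrid(idx, idx, indexing="ij")

    def _ent(q):
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    asm = float((p**2).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    corr = float(((ii * jj * p).sum() - mux * muy) / (sx * sy)) if sx > 0 and sy > 0 else 0.0
    variance = float(((ii - mux) ** 2 * p).sum())
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())
    # p_{x+y}(k), k = 0..2L-2 and p_{x-y}(k), k = 0..L-1
    psum = np.zeros(2 * levels - 1)
    np.add.at(psum, (ii + jj).astype(int).ravel(), p.ravel())
    pdiff = np.zeros(levels)
    np.add.at(pdiff, np.abs(ii - jj).astype(int).ravel(), p.ravel())
    ks = np.arange(2 * levels - 1, dtype=float)
    kd = np.arange(levels, dtype=float)
    sum_avg = float((ks * psum).sum())
    sum_var = float(((ks - sum_avg) ** 2 * psum).sum())
    sum_ent = _ent(psum)
    entropy = _ent(p.ravel())
    diff_avg = float((kd * pdiff).sum())
    diff_var = float(((kd - diff_avg) ** 2 * pdiff).sum())
    diff_ent = _ent(pdiff)
    hx, hy = _ent(px), _ent(py)
    pxy = np.outer(px, py)
    nz = (p > 0) & (pxy > 0)
    hxy1 = float(-(p[nz] * np.log(pxy[nz])).sum())
    nz2 = pxy > 0
    hxy2 = float(-(pxy[nz2] * np.log(pxy[nz2])).sum())
    denom = max(hx, hy)
    imc1 = float((entropy - hxy1) / denom) if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))
    return np.array([
        asm, contrast, corr, variance, idm, sum_avg, sum_var, sum_ent,
        entropy, diff_var, diff_ent, imc1, imc2,
    ])


def _masked_glcm_features(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Direction-averaged Haralick features at each distance, masked.

    The crop is quantized to 64 gray levels over the masked intensity
    range; pixels outside the mask get a sentinel 65th level whose GLCM
    row/column is discarded before normalization, so only intra-mask pixel
    pairs contribute.
    """
    inside = img[mask]
    if inside.size == 0:
        raise ValueError("empty mask")
    lo, hi = float(inside.min()), float(inside.max())
    q = np.full(img.shape, GLCM_LEVELS, dtype=np.uint8)  # sentinel
    if hi > lo:
        lv = np.floor((img[mask] - lo) / (hi - lo) * GLCM_LEVELS).astype(int)
        q[mask] = np.clip(lv, 0, GLCM_LEVELS - 1)
    else:
        q[mask] = 0
    glcm = graycomatrix(
        q, distances=GLCM_DISTANCES, angles=GLCM_ANGLES,
        levels=GLCM_LEVELS + 1, symmetric=True, normed=False,
    ).astype(float)
    out = []
    for di in range(len(GLCM_DISTANCES)):
        m = glcm[:GLCM_LEVELS, :GLCM_LEVELS, di, :].mean(axis=2)
        total = m.sum()
        p = m / total if total > 0 else m
        out.append(haralick_features(p))
    return np.concatenate(out)


def _intensity_moments(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    v = img[mask].astype(float)
    sd = v.std()
    return np.array([
        v.mean(), sd,
        float(skew(v)) if sd > 0 else 0.0,
        float(kurtosis(v)) if sd > 0 else 0.0,
    ])


def feature_names(channels: list[str]) -> list[str]:
    names = []
    for ch in channels:
        for d in GLCM_DISTANCES:
            names += [f"{ch}_d{d}_{nm}" for nm in HARALICK_NAMES]
        names += [f"{ch}_int_{nm}" for nm in ("mean", "sd", "skew", "kurtosis")]
    return names


def extract_features(
    crops,
    masks,
    labels=None,
    channels: list[str] | None = None,
) -> pd.DataFrame:
    """Per-cell texture + intensity feature table from nucleus crops.

    ``crops`` is a list of 2-D arrays (single channel) or a dict mapping
    channel name to such a list; ``masks`` is the matching list of boolean
    masks.  Returns a table with cell_id, condition (from ``labels``) and
    one column per feature: 13 direction-averaged Haralick statistics at
    pixel distances 1/2/4/8 on 64-level quantized masked intensities plus
    mean/SD/skewness/kurtosis of the masked intensity, per channel.
    """
    if not isinstance(crops, dict):
        crops = {"ch0": list(crops)}
    if channels is None:
        channels = sorted(crops)
    n_cells = len(next(iter(crops.values())))
    for ch in channels:
        if len(crops[ch]) != n_cells:
            raise ValueError("all channels must have the same number of crops")
    rows = []
    for i in range(n_cells):
        vec = []
        for ch in channels:
            img = np.asarray(crops[ch][i], dtype=float)
            mask = np.asarray(masks[i], dtype=bool)
            vec.append(_masked_glcm_features(img, mask))
            vec.append(_intensity_moments(img, mask))
        rows.append(np.concatenate(vec))
    table = pd.DataFrame(rows, columns=feature_names(channels))
    table.insert(0, "condition", labels if labels is not None else "unlabelled")
    table.insert(0, "cell_id", [f"cell_{i:05d}" for i in range(n_cells)])
    return table


# ---------------------------------------------------------------------------
# normalisation and condensation
# ---------------------------------------------------------------------------

_META_COLS = ("cell_id", "condition", "center_id", "pool_size")


def _feature_cols(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in _META_COLS]


def zscore(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Z-score each feature across all cells; drop zero-variance features.

    Returns the transformed table and the per-feature (mean, sd)
    parameters for reuse on held-out data via :func:`apply_zscore`.
    """
    cols = _feature_cols(table)
    if len(table) < 2:
        raise ValueError("z-scoring needs at least 2 cells")
    params = {}
    out = table.copy()
    dropped = []
    for c in cols:
        mu = float(table[c].mean())
        sd = float(table[c].std(ddof=0))
        if sd == 0:
            dropped.append(c)
            out = out.drop(columns=c)
            continue
        params[c] = (mu, sd)
        out[c] = (table[c] - mu) / sd
    if dropped:
        warnings.warn(f"dropped {len(dropped)} zero-variance feature(s): "
                      f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}",
                      stacklevel=2)
    if not params:
        raise ValueError("all features have zero variance")
    return out, params


def apply_zscore(table: pd.DataFrame, params: dict) -> pd.DataFrame:
    out = table.copy()
    keep = [c for c in _feature_cols(table) if c in params]
    out = out[[c for c in table.columns if c not in _feature_cols(table)] + keep]
    for c in keep:
        mu, sd = params[c]
        out[c] = (table[c] - mu) / sd
    return out


@dataclass
class CondensationResult:
    """Condensed centers plus pool bookkeeping."""

    centers: pd.DataFrame  # columns: center_id, condition, pool_size, features
    members: dict  # center_id -> list of cell_ids
    discarded: dict  # condition -> number of remainder cells dropped


def condense(table: pd.DataFrame, n: int, seed: int = 0) -> CondensationResult:
    """Average disjoint pools of exactly n cells per condition into centers.

    Cells are shuffled (seeded) within each condition and partitioned into
    floor(N/n) pools; remainder cells are discarded and counted.  The
    center is the unweighted mean feature vector of its pool.
    """
    if n < 1:
        raise ValueError("pool size must be >= 1")
    cols = _feature_cols(table)
    rng = np.random.default_rng(seed)
    blocks, members, discarded = [], {}, {}
    for cond, grp in table.groupby("condition", sort=True):
        if len(grp) < n:
            raise ValueError(f"condition {cond!r} has {len(grp)} cells < pool size {n}")
        order = rng.permutation(len(grp))
        n_pools = len(grp) // n
        discarded[cond] = len(grp) - n_pools * n
        vals = grp[cols].to_numpy(dtype=float)[order[: n_pools * n]]
        means = vals.reshape(n_pools, n, len(cols)).mean(axis=1)
        ids = [f"{cond}_c{k:04d}" for k in range(n_pools)]
        cell_ids = grp["cell_id"].to_numpy()[order[: n_pools * n]]
        for k, cid in enumerate(ids):
            members[cid] = cell_ids[k * n : (k + 1) * n].tolist()
        block = pd.DataFrame(means, columns=cols)
        block.insert(0, "pool_size", n)
        block.insert(0, "condition", cond)
        block.insert(0, "center_id", ids)
        blocks.append(block)
    centers = pd.concat(blocks, ignore_index=True)
    return CondensationResult(centers=centers, members=members, discarded=discarded)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass
class MielModel:
    """Fitted reduction + classifier of one training split."""

    pca: PCA
    svm: SVC
    conditions: list[str]
    split_seed: int
    on_pcs: bool


@dataclass
class MielReport:
    """Classification summary: confusion matrix in %, overall accuracy."""

    confusion: pd.DataFrame  # rows = true condition, % summing to 100
    accuracy: float
    per_repeat_accuracy: np.ndarray
    n_components: int
    repeats: int


def _stratified_split(
    centers: pd.DataFrame, train_frac: float, rng: np.random.Generator,
    min_test: int = 2,
):
    """Deterministic per-condition split; at least one test and one train row."""
    train_idx, test_idx = [], []
    for cond, grp in centers.groupby("condition", sort=True):
        k = len(grp)
        n_test = max(1, int(round((1.0 - train_frac) * k)))
        if n_test >= k:
            n_test = k - 1
        if n_test < min_test:
            raise ValueError(
                f"condition {cond!r} has only {n_test} test center(s) at "
                f"train_frac={train_frac} (need >= {min_test})"
            )
        order = rng.permutation(k)
        test_idx += grp.index[order[:n_test]].tolist()
        train_idx += grp.index[order[n_test:]].tolist()
    return sorted(train_idx), sorted(test_idx)


def fit_classify(
    centers: pd.DataFrame,
    n_components: int = 4,
    train_frac: float = 0.8,
    seed: int = 0,
    repeats: int = 20,
    on_pcs: bool = True,
    min_test_per_condition: int = 2,
) -> tuple[MielModel, MielReport]:
    """PCA(4) + linear SVM classification of condensed centers.

    For each of ``repeats`` seeded stratified 80/20 splits, PCA is fitted
    on the training centers, a linear SVM (C=1) is trained on the PC
    scores, and test accuracy plus the row-normalized confusion matrix are
    recorded; the report averages over splits.  ``on_pcs=False`` trains
    the SVM on raw z-scored centers instead.
    """
    conds = sorted(centers["condition"].unique())
    if len(conds) < 2:
        raise ValueError("classification needs at least 2 conditions")
    cols = _feature_cols(centers)
    x_all = centers[cols].to_numpy(dtype=float)
    y_all = centers["condition"].to_numpy()
    accs, cms = [], []
    model = None
    for r in range(repeats):
        rng = np.random.default_rng((seed, r))
        tr, te = _stratified_split(centers, train_frac, rng, min_test_per_condition)
        loc = centers.index.get_indexer(tr), centers.index.get_indexer(te)
        x_tr, x_te = x_all[loc[0]], x_all[loc[1]]
        y_tr, y_te = y_all[loc[0]], y_all[loc[1]]
        k = min(n_components, x_tr.shape[0] - 1, x_tr.shape[1])
        pca = PCA(n_components=k, random_state=0)
        s_tr = pca.fit_transform(x_tr)
        s_te = pca.transform(x_te)
        svm = SVC(kernel="linear", C=1.0)
        if on_pcs:
            svm.fit(s_tr, y_tr)
            pred = svm.predict(s_te)
        else:
            svm.fit(x_tr, y_tr)
            pred = svm.predict(x_te)
        accs.append(float(np.mean(pred == y_te)))
        cms.append(_sk_confusion(y_te, pred, labels=conds))
        if model is None:
            model = MielModel(pca=pca, svm=svm, conditions=conds,
                              split_seed=seed, on_pcs=on_pcs)
    cm = np.sum(cms, axis=0).astype(float)
    row_sums = cm.sum(axis=1, keepdims=True)
    cm_pct = np.where(row_sums > 0, cm / row_sums * 100.0, 0.0)
    report = MielReport(
        confusion=pd.DataFrame(cm_pct, index=conds, columns=conds),
        accuracy=float(np.mean(accs)),
        per_repeat_accuracy=np.array(accs),
        n_components=n_components,
        repeats=repeats,
    )
    return model, report


# ---------------------------------------------------------------------------
# distances and scatter
# ---------------------------------------------------------------------------

def distance_analysis(centers: pd.DataFrame):
    """Euclidean distances between centers, condition-level means, dispersion.

    Returns ``(pairwise, condition_matrix, dispersion)``: the full
    center-by-center distance matrix; the condition-level matrix whose
    (a, b) entry is the mean distance over all center pairs from
    conditions a and b (diagonal = within-condition mean); and the
    per-condition dispersion (mean within-condition pair distance, NaN
    and flagged for singleton conditions).
    """
    if len(centers) < 2:
        raise ValueError("distance analysis needs at least 2 centers")
    cols = _feature_cols(centers)
    x = centers[cols].to_numpy(dtype=float)
    ids = centers["center_id"].tolist() if "center_id" in centers else list(range(len(x)))
    d = squareform(pdist(x, metric="euclidean"))
    pairwise = pd.DataFrame(d, index=ids, columns=ids)
    conds = sorted(centers["condition"].unique())
    cond_mat = pd.DataFrame(np.nan, index=conds, columns=conds, dtype=float)
    dispersion = {}
    groups = {c: np.nonzero((centers["condition"] == c).to_numpy())[0] for c in conds}
    for a in conds:
        ia = groups[a]
        for b in conds:
            ib = groups[b]
            if a == b:
                if len(ia) < 2:
                    dispersion[a] = float("nan")
                    continue
                iu, ju = np.triu_indices(len(ia), k=1)
                val = float(d[np.ix_(ia, ia)][iu, ju].mean())
                cond_mat.loc[a, a] = val
                dispersion[a] = val
            else:
                cond_mat.loc[a, b] = float(d[np.ix_(ia, ib)].mean())
    for a in conds:
        if np.isnan(dispersion[a]):
            warnings.warn(f"condition {a!r} has a single center: dispersion undefined",
                          stacklevel=2)
    return pairwise, cond_mat, dispersion


def discriminant_scatter(table: pd.DataFrame, reg: str | float = "auto") -> pd.DataFrame:
    """First two discriminant factors of each point for 2-D plotting.

    Linear discriminant axes are computed on the feature columns with a
    regularized (shrunk) within-class covariance; each row is projected
    onto the first two discriminants.  With only two conditions a single
    discriminant exists; the second plotting axis is then the leading
    principal component of the within-class residual.  Axis signs are
    fixed so the largest-magnitude loading of each axis is positive.
    """
    conds = table["condition"].unique()
    if len(conds) < 2:
        raise ValueError("discriminant projection needs at least 2 conditions")
    cols = _feature_cols(table)
    x = table[cols].to_numpy(dtype=float)
    y = table["condition"].to_numpy()
    lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage=reg)
    lda.fit(x, y)
    axes = lda.scalings_[:, : min(2, lda.scalings_.shape[1])].copy()
    if axes.shape[1] < 2:
        resid = x.copy()
        for c in conds:
            resid[y == c] -= x[y == c].mean(axis=0)
        proj = resid - np.outer(resid @ axes[:, 0], axes[:, 0]) / (axes[:, 0] @ axes[:, 0])
        pc = PCA(n_components=1, random_state=0).fit(proj).components_[0]
        axes = np.column_stack([axes[:, 0], pc])
    for j in range(2):
        if axes[np.argmax(np.abs(axes[:, j])), j] < 0:
            axes[:, j] = -axes[:, j]
    coords = (x - x.mean(axis=0)) @ axes
    out = pd.DataFrame(coords, columns=["factor_1", "factor_2"])
    out.insert(0, "condition", y)
    if "center_id" in table:
        out.insert(0, "center_id", table["center_id"].to_numpy())
    elif "cell_id" in table:
        out.insert(0, "cell_id", table["cell_id"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# bootstrap optimisation of the condensation number
# ---------------------------------------------------------------------------

@dataclass
class BootstrapReport:
    """Bootstrap accuracy distributions per candidate pool size."""

    candidate_ns: list[int]
    accuracies: dict  # n -> np.ndarray of per-iteration accuracies
    success_fraction: dict  # n -> fraction of iterations >= criterion
    optimal_n: int | None
    iterations: int
    accuracy_criterion: float
    success_quantile: float


def bootstrap_condensation(
    table: pd.DataFrame,
    candidate_ns: list[int],
    iterations: int = 1000,
    sample_frac: float = 0.8,
    accuracy_criterion: float = 0.95,
    success_quantile: float = 0.95,
    seed: int = 0,
    n_components: int = 4,
    train_frac: float = 0.8,
) -> BootstrapReport:
    """Choose the smallest pool size meeting the 95/95 accuracy rule.

    Per candidate n and iteration: resample ``sample_frac`` of each
    condition's cells with replacement, partition the resample into pools
    of n (condense), then PCA + linear SVM with a stratified 80/20 split;
    record the test accuracy.  The optimal n is the smallest candidate
    whose accuracy reaches ``accuracy_criterion`` in at least
    ``success_quantile`` of iterations (None if no candidate qualifies).
    """
    counts = table.groupby("condition").size()
    if len(counts) < 2:
        raise ValueError("bootstrap optimisation needs >= 2 conditions")
    for n in candidate_ns:
        m = int(counts.min() * sample_frac)
        if n > m:
            raise ValueError(
                f"candidate pool size {n} exceeds the {sample_frac:.0%} sample "
                f"size ({m}) of the smallest condition"
            )
    accuracies = {}
    for ci, n in enumerate(candidate_ns):
        acc = np.empty(iterations)
        for it in range(iterations):
            rng = np.random.default_rng((seed, ci, it))
            blocks = []
            for cond, grp in table.groupby("condition", sort=True):
                m = int(round(sample_frac * len(grp)))
                take = rng.integers(0, len(grp), size=m)
                blocks.append(grp.iloc[take])
            boot = pd.concat(blocks, ignore_index=True)
            boot["cell_id"] = [f"b{j:06d}" for j in range(len(boot))]
            cres = condense(boot, n, seed=int(rng.integers(2**31)))
            _, rep = fit_classify(
                cres.centers, n_components=n_components, train_frac=train_frac,
                seed=int(rng.integers(2**31)), repeats=1,
                min_test_per_condition=1,
            )
            acc[it] = rep.accuracy
        accuracies[n] = acc
    success = {
        n: float(np.mean(accuracies[n] >= accuracy_criterion - 1e-12))
        for n in candidate_ns
    }
    optimal = None
    for n in sorted(candidate_ns):
        if success[n] >= success_quantile:
            optimal = n
            break
    return BootstrapReport(
        candidate_ns=list(candidate_ns),
        accuracies=accuracies,
        success_fraction=success,
        optimal_n=optimal,
        iterations=iterations,
        accuracy_criterion=accuracy_criterion,
        success_quantile=success_quantile,
    )
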