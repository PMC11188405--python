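"""Weighted gene co-expression network: soft power, TOM, modules, eigengenes.

The unsigned adjacency a_ij = |cor(x_i, x_j)|^beta is raised to a soft
power chosen so the connectivity distribution is approximately scale-free,
then transformed into the topological overlap matrix (TOM). Average-linkage
clustering of 1 - TOM yields modules; each module is summarized by its
eigengene (first principal component of the standardized member profiles),
highly similar modules are merged, and eigengenes are correlated with
phenotypes to rank modules as candidate trait regulators. A hard
|r|-threshold edge list is exported for graph tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "SoftPowerReport",
    "ModuleSet",
    "pick_soft_power",
    "adjacency_matrix",
    "tom_similarity",
    "cluster_modules",
    "module_eigengene",
    "merge_modules",
    "module_trait_association",
    "hard_threshold_edges",
]


@dataclass
class SoftPowerReport:
    """Scale-free fit and mean connectivity per candidate soft power."""

    table: pd.DataFrame          # columns: power, fit, mean_k
    chosen: int
    chosen_fit: float


@dataclass
class ModuleSet:
    """Module membership (0 = unassigned), eigengenes and merge history."""

    membership: pd.Series                    # transcript -> module label
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns = module labels, index = line ids, unit variance per column
    merge_history: list = field(default_factory=list)
    # entries: (absorbed label, surviving label, eigengene correlation)

    @property
    def labels(self) -> list[int]:
        return sorted(l for l in self.membership.unique() if l != 0)

    def members(self, label: int) -> list:
        return list(self.membership.index[self.membership == label])

    def sizes(self) -> pd.Series:
        return self.membership[self.membership != 0].value_counts().sort_index()


def _correlation(values: pd.DataFrame) -> tuple[np.ndarray, pd.Index]:
    """Transcript-transcript Pearson correlation, constant rows dropped."""
    X = values.to_numpy(dtype=float)
    sd = X.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant transcript(s)")
    X = X[keep]
    C = np.corrcoef(X)
    return C, values.index[keep]


def adjacency_matrix(values: pd.DataFrame, power: int) -> tuple[np.ndarray, pd.Index]:
    """Unsigned soft adjacency |cor|^power with zero diagonal."""
    C, index = _correlation(values)
    A = np.abs(C) ** power
    np.fill_diagonal(A, 0.0)
    return A, index


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free fit of the connectivity distribution.

    Bin connectivities into ``n_bins`` equal-width bins, regress
    log10 p(k) on log10 mean-k over occupied bins, and report R^2 signed
    positive when p(k) decreases with k (the direction a power law
    requires).
    """
    k = k[k > 0]
    if k.size < n_bins:
        raise ValueError("too few nodes for connectivity binning")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    log_k, log_p = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        log_k.append(np.log10(k[sel].mean()))
        log_p.append(np.log10(sel.mean()))
    if len(log_k) < 3 or np.ptp(log_k) == 0 or np.ptp(log_p) == 0:
        return 0.0
    slope, _, r, _, _ = stats.linregress(log_k, log_p)
    return float(-np.sign(slope) * r ** 2)


def pick_soft_power(values: pd.DataFrame, powers=range(1, 21),
                    fit_cut: float = 0.8) -> SoftPowerReport:
    """Choose the smallest soft power reaching the scale-free fit cut.

    If no candidate reaches ``fit_cut``, the best-fitting power *among those
    with mean connectivity >= 1* is returned with a warning: below that the
    network is essentially disconnected and the fit statistic is noise, so
    an unguarded argmax tends to the largest power and destroys all module
    signal.
    """
    if values.shape[0] < 50 or values.shape[1] < 10:
        raise ValueError("need >= 50 transcripts and >= 10 lines")
    C, _ = _correlation(values)
    absC = np.abs(C)
    np.fill_diagonal(absC, 0.0)
    rows = []
    for beta in powers:
        A = absC ** beta
        k = A.sum(axis=1)
        rows.append((int(beta), _scale_free_fit(k), float(k.mean())))
    tab = pd.DataFrame(rows, columns=["power", "fit", "mean_k"])
    ok = tab[tab["fit"] >= fit_cut]
    if len(ok):
        row = ok.iloc[0]
    else:
        connected = tab[tab["mean_k"] >= 1.0]
        pool = connected if len(connected) else tab.iloc[:1]
        row = pool.loc[pool["fit"].idxmax()]
        warnings.warn(
            f"no power reached fit {fit_cut}; using best connected "
            f"(power {int(row['power'])}, fit {row['fit']:.3f})")
    return SoftPowerReport(tab, int(row["power"]), float(row["fit"]))


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap: shared-neighbour-weighted similarity.

    omega_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_u a_iu a_uj; diagonal set to 1. Requires a symmetric
    zero-diagonal adjacency with entries in [0, 1].
    """
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if np.any((A < 0) | (A > 1)):
        raise ValueError("adjacency entries must lie in [0, 1]")
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    L = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    omega = (L + A) / denom
    np.fill_diagonal(omega, 1.0)
    return np.clip(omega, 0.0, 1.0)


def cluster_modules(tom: np.ndarray, transcripts, min_size: int = 30,
                    cut_height: float = 0.99) -> ModuleSet:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    The tree is cut at ``cut_height`` x (max merge height); branches smaller
    than ``min_size`` become unassigned (label 0). Surviving modules are
    relabelled 1..K by decreasing size. Deterministic given input order.
    """
    transcripts = pd.Index(transcripts)
    n = len(transcripts)
    if n < min_size:
        return ModuleSet(pd.Series(0, index=transcripts))
    D = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    height = cut_height * Z[:, 2].max()
    raw = fcluster(Z, t=height, criterion="distance")
    labels = np.zeros(n, dtype=int)
    sizes = pd.Series(raw).value_counts()
    big = sizes[sizes >= min_size].index
    # size-ordered relabel, ties by first appearance
    order = sorted(big, key=lambda c: (-sizes[c], int(np.argmax(raw == c))))
    for new, old in enumerate(order, start=1):
        labels[raw == old] = new
    return ModuleSet(pd.Series(labels, index=transcripts))


def module_eigengene(module_values: pd.DataFrame) -> pd.Series:
    """First principal component of a module's standardized profiles.

    Each transcript row is standardized over lines; the per-line PC scores
    are scaled to unit variance and sign-oriented so the eigengene correlates
    positively with the module's mean expression profile (falling back to the
    first member when the mean profile is constant).
    """
    if module_values.shape[0] < 2:
        raise ValueError("module must contain >= 2 transcripts")
    X = module_values.to_numpy(dtype=float)
    sd = X.std(axis=1)
    if np.any(sd == 0):
        warnings.warn("dropping zero-variance transcript(s) from module")
        X = X[sd > 0]
        if X.shape[0] < 2:
            raise ValueError("fewer than 2 variable transcripts in module")
    Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    # scores over lines = first right singular vector
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    me = vt[0]
    me = me / me.std(ddof=1)
    reference = Z.mean(axis=0)
    if reference.std() == 0:
        reference = Z[0]
    if np.corrcoef(me, reference)[0, 1] < 0:
        me = -me
    return pd.Series(me, index=module_values.columns)


def compute_eigengenes(values: pd.DataFrame, modules: ModuleSet) -> pd.DataFrame:
    """Eigengene per retained module; columns labelled by module id."""
    mes = {}
    for label in modules.labels:
        mes[label] = module_eigengene(values.loc[modules.members(label)])
    return pd.DataFrame(mes)


def merge_modules(values: pd.DataFrame, modules: ModuleSet,
                  similarity_cut: float = 0.75) -> ModuleSet:
    """Iteratively merge the most similar eigengene pair at/above the cut.

    After each merge the combined module's eigengene is recomputed, so chains
    of pairwise-similar modules can coalesce. The surviving label is the
    larger module's (ties to the smaller label); history records every merge.
    """
    membership = modules.membership.copy()
    history = list(modules.merge_history)
    while True:
        labels = sorted(l for l in membership.unique() if l != 0)
        if len(labels) < 2:
            break
        mes = {l: module_eigengene(values.loc[membership.index[membership == l]])
               for l in labels}
        me_mat = pd.DataFrame(mes)
        corr = me_mat.corr().to_numpy()
        np.fill_diagonal(corr, -np.inf)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        best = corr[i, j]
        if best < similarity_cut:
            break
        a, b = labels[i], labels[j]
        size_a = int((membership == a).sum())
        size_b = int((membership == b).sum())
        survivor, absorbed = (a, b) if (size_a, -a) >= (size_b, -b) else (b, a)
        membership[membership == absorbed] = survivor
        history.append((absorbed, survivor, float(best)))
    out = ModuleSet(membership, merge_history=history)
    out.eigengenes = compute_eigengenes(values, out)
    return out


def module_trait_association(eigengenes: pd.DataFrame,
                             traits: pd.DataFrame) -> pd.DataFrame:
    """Pearson r and p (t-distribution, n-2 df) per module x trait.

    Missing trait values are pairwise-deleted; a constant trait yields
    missing entries. Requires >= 5 shared lines per pair.
    """
    shared = eigengenes.index.intersection(traits.index)
    if len(shared) < 5:
        raise ValueError("need >= 5 lines shared between eigengenes and traits")
    rows = []
    for mod in eigengenes.columns:
        me = eigengenes.loc[shared, mod]
        for trait in traits.columns:
            tv = traits.loc[shared, trait]
            ok = me.notna() & tv.notna()
            if ok.sum() < 5 or tv[ok].std() == 0 or me[ok].std() == 0:
                rows.append((mod, trait, np.nan, np.nan, int(ok.sum())))
                continue
            r, p = stats.pearsonr(me[ok], tv[ok])
            rows.append((mod, trait, float(r), float(p), int(ok.sum())))
    return pd.DataFrame(rows, columns=["module", "trait", "r", "p", "n"])


def hard_threshold_edges(values: pd.DataFrame, cut: float = 0.75) -> pd.DataFrame:
    """Undirected |r| >= cut edge list with a degree/power-law report attached.

    Returns a frame with columns node_a, node_b, r. ``.attrs['degrees']``
    holds per-node degrees and ``.attrs['power_law_fit']`` the signed R^2 of
    the log-log degree histogram fit (reported, never enforced).
    """
    C, index = _correlation(values)
    n = len(index)
    iu = np.triu_indices(n, k=1)
    mask = np.abs(C[iu]) >= cut
    edges = pd.DataFrame({
        "node_a": index.to_numpy()[iu[0][mask]],
        "node_b": index.to_numpy()[iu[1][mask]],
        "r": C[iu][mask],
    })
    degree = pd.Series(0, index=index, dtype=int)
    if len(edges):
        counts = pd.concat([edges["node_a"], edges["node_b"]]).value_counts()
        degree.loc[counts.index] = counts
    edges.attrs["degrees"] = degree
    k = degree.to_numpy(dtype=float)
    try:
        edges.attrs["power_law_fit"] = _scale_free_fit(k) if (k > 0).sum() >= 10 else np.nan
    except ValueError:
        edges.attrs["power_law_fit"] = np.nan
    return edges
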