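"""QTL scan engine: Haley-Knott (composite) interval mapping for DH lines.

One engine serves every scan in the pipeline — seed traits (pQTL),
transcripts (eQTL) and module eigengenes (network QTL). At each grid
position the trait is regressed on the conditional expectation of the QTL
genotype given the flanking markers; the LOD is the residual-sum-of-squares
likelihood ratio

    LOD = (n/2) * log10(RSS_null / RSS_full)

with the null holding the intercept plus any active cofactors. Composite
interval mapping (CIM) adds background marker cofactors to both models,
excluding cofactors within a window of the test position so they cannot
absorb the local signal. Significance comes from permutation of trait
values across lines (genome-wide maximum LOD null distribution).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genmap import EvaluationGrid, GeneticMap, GenotypeMatrix, expected_genotype_matrix

__all__ = [
    "ScanProfile",
    "Peak",
    "PermutationThreshold",
    "interval_mapping_scan",
    "cim_scan",
    "select_cofactors",
    "permutation_threshold",
    "call_peaks",
]

# floor on RSS_full/RSS_null before log10: a ratio at (or numerically
# indistinguishable from) zero means a perfectly determined trait; the LOD
# caps at (n/2)*12 and the profile is flagged saturated
_RATIO_FLOOR = 1e-12


@dataclass
class ScanProfile:
    """Per-position scan results: LOD, variance fraction and additive effect."""

    table: pd.DataFrame        # columns: chrom, cM, lod, r2, additive
    trait_name: str = "trait"
    n_lines: int = 0
    cofactors: list = field(default_factory=list)
    saturated: bool = False    # True if any position hit the LOD guard

    def max_lod(self) -> float:
        return float(self.table["lod"].max()) if len(self.table) else 0.0


@dataclass
class Peak:
    """A called QTL: peak, 1.5-LOD support interval, effect and allele source."""

    chrom: object
    peak_cM: float
    ci_lo: float
    ci_hi: float
    lod: float
    r2: float
    additive: float
    allele_parent: str = ""
    bp_lo: int | None = None
    bp_hi: int | None = None
    trait: str = "trait"
    name: str = ""


@dataclass
class PermutationThreshold:
    """Empirical genome-wide LOD threshold from trait permutations."""

    n_perm: int
    alpha: float
    threshold: float
    seed: int
    maxima: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


# ---------------------------------------------------------------------------
# internals


def _prepare_trait(trait, n_lines: int) -> tuple[np.ndarray, np.ndarray, str]:
    name = "trait"
    if isinstance(trait, pd.Series):
        name = str(trait.name) if trait.name is not None else name
        trait = trait.to_numpy(dtype=float)
    y = np.asarray(trait, dtype=float).ravel()
    if y.size != n_lines:
        raise ValueError(f"trait length {y.size} != number of lines {n_lines}")
    keep = np.isfinite(y)
    if keep.sum() < 10:
        raise ValueError("need >= 10 lines with non-missing trait")
    yk = y[keep]
    if np.var(yk) == 0:
        raise ValueError("zero-variance trait")
    return yk, keep, name


def _cofactor_design(genotypes: GenotypeMatrix, cofactors, keep) -> np.ndarray:
    """Cofactor marker columns, mean-imputed (covariates only, never the scan)."""
    if not cofactors:
        return np.empty((int(keep.sum()), 0))
    idx = [genotypes.gmap.marker_index(c) if isinstance(c, str) else int(c)
           for c in cofactors]
    C = genotypes.values[np.ix_(keep, idx)].copy()
    for j in range(C.shape[1]):
        col = C[:, j]
        m = np.isfinite(col)
        col[~m] = col[m].mean()
    return C


def _residualize(D: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Residuals of each column of M on design D (D includes the intercept)."""
    coef, *_ = np.linalg.lstsq(D, M, rcond=None)
    return M - D @ coef


def _active_cofactor_sets(grid: EvaluationGrid, genotypes: GenotypeMatrix,
                          cofactors, window: float) -> list[tuple]:
    """Per grid position, the cofactors kept after the window exclusion."""
    if not cofactors:
        return [()] * grid.n_positions
    cof_idx = [genotypes.gmap.marker_index(c) if isinstance(c, str) else int(c)
               for c in cofactors]
    cof_chrom = [genotypes.gmap.table.at[i, "chrom"] for i in cof_idx]
    cof_cm = [genotypes.gmap.table.at[i, "cM"] for i in cof_idx]
    sets = []
    pos = grid.positions
    for k in range(grid.n_positions):
        chrom, p = pos.iat[k, 0], pos.iat[k, 1]
        active = tuple(
            i for i, (cc, cm) in enumerate(zip(cof_chrom, cof_cm))
            if not (cc == chrom and abs(cm - p) <= window))
        sets.append(active)
    return sets


def _scan_with_cofactors(Y: np.ndarray, P: np.ndarray, C: np.ndarray,
                         active_sets: list[tuple]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """LOD, R^2 (vs total variance) and additive effect for trait columns Y.

    Y: (n, t) finite trait columns; P: (n, m) Haley-Knott regressors;
    C: (n, c) cofactor columns; active_sets: per-position cofactor subsets.
    Returns arrays of shape (m, t).
    """
    n, t = Y.shape
    m = P.shape[1]
    ones = np.ones((n, 1))
    Yc = Y - Y.mean(axis=0)
    rss_tot = np.einsum("ij,ij->j", Yc, Yc)

    lod = np.empty((m, t))
    r2 = np.empty((m, t))
    add = np.empty((m, t))

    cache: dict[tuple, tuple] = {}
    for subset in set(active_sets):
        D = np.hstack([ones, C[:, list(subset)]]) if subset else ones
        Yres = _residualize(D, Y)
        rss0 = np.einsum("ij,ij->j", Yres, Yres)
        cache[subset] = (D, Yres, rss0)

    for k in range(m):
        D, Yres, rss0 = cache[active_sets[k]]
        x = P[:, k]
        xres = x - D @ np.linalg.lstsq(D, x, rcond=None)[0] if D.shape[1] > 1 \
            else x - x.mean()
        sxx = float(xres @ xres)
        if sxx <= 1e-12 * n:          # regressor constant here (e.g. no information)
            lod[k] = 0.0
            r2[k] = 0.0
            add[k] = 0.0
            continue
        sxy = xres @ Yres             # (t,)
        rss1 = rss0 - sxy ** 2 / sxx
        ratio = np.clip(rss1 / np.where(rss0 > 0, rss0, 1.0), _RATIO_FLOOR, None)
        lod[k] = -(n / 2.0) * np.log10(ratio)
        r2[k] = 1.0 - rss1 / np.where(rss_tot > 0, rss_tot, 1.0)
        add[k] = (sxy / sxx) / 2.0
    return lod, r2, add


def _profile_from_arrays(grid: EvaluationGrid, lod, r2, add, trait_name, n,
                         cofactors) -> ScanProfile:
    tab = pd.DataFrame({
        "chrom": grid.positions["chrom"].to_numpy(),
        "cM": grid.positions["cM"].to_numpy(),
        "lod": lod, "r2": np.clip(r2, 0.0, 1.0), "additive": add,
    })
    saturated = bool(np.any(lod >= (n / 2.0) * 12 - 1e-9))
    if saturated:
        warnings.warn(f"trait {trait_name!r}: perfectly determined position; LOD capped")
    return ScanProfile(tab, trait_name, n, list(cofactors or []), saturated)


# ---------------------------------------------------------------------------
# public operations


def interval_mapping_scan(trait, genotypes: GenotypeMatrix, grid: EvaluationGrid,
                          P: np.ndarray | None = None) -> ScanProfile:
    """Interval mapping (no cofactors) of one trait over the evaluation grid.

    ``P`` may carry a precomputed ``expected_genotype_matrix`` to amortize
    the conditional-probability work across many traits.
    """
    return cim_scan(trait, genotypes, grid, cofactors=(), window=0.0, P=P)


def cim_scan(trait, genotypes: GenotypeMatrix, grid: EvaluationGrid,
             cofactors=(), window: float = 10.0,
             P: np.ndarray | None = None) -> ScanProfile:
    """Composite interval mapping: cofactors in both models, window-excluded."""
    if window < 0:
        raise ValueError("window must be >= 0")
    if P is None:
        P = expected_genotype_matrix(genotypes, grid)
    y, keep, name = _prepare_trait(trait, genotypes.n_lines)
    C = _cofactor_design(genotypes, list(cofactors), keep)
    active = _active_cofactor_sets(grid, genotypes, list(cofactors), window)
    lod, r2, add = _scan_with_cofactors(y[:, None], P[keep], C, active)
    return _profile_from_arrays(grid, lod[:, 0], r2[:, 0], add[:, 0],
                                name, y.size, cofactors)


def select_cofactors(trait, genotypes: GenotypeMatrix,
                     max_cofactors: int = 5) -> list[str]:
    """Forward selection of background markers by BIC on marker regression.

    Deterministic: ties broken by map order. Returns marker names (possibly
    empty). ``max_cofactors = 0`` reduces CIM to plain interval mapping.

    The entry penalty is the extended BIC (per added marker,
    log n + 2 log m for m candidate markers): plain BIC ignores that each
    step picks the best of m correlated candidates and admits spurious
    cofactors on pure-noise traits.
    """
    if max_cofactors < 0:
        raise ValueError("max_cofactors must be >= 0")
    if max_cofactors == 0:
        return []
    y, keep, _ = _prepare_trait(trait, genotypes.n_lines)
    n = y.size
    G = genotypes.values[keep].copy()
    for j in range(G.shape[1]):
        col = G[:, j]
        m = np.isfinite(col)
        col[~m] = col[m].mean()
    ones = np.ones((n, 1))
    selected: list[int] = []
    D = ones
    yres = y - y.mean()
    rss = float(yres @ yres)
    m_markers = G.shape[1]
    penalty = np.log(n) + 2.0 * np.log(max(m_markers, 2))
    bic = n * np.log(rss / n) + 1 * np.log(n)
    while len(selected) < max_cofactors:
        Gres = _residualize(D, G)
        sxx = np.einsum("ij,ij->j", Gres, Gres)
        sxy = yres @ Gres
        with np.errstate(divide="ignore", invalid="ignore"):
            gain = np.where(sxx > 1e-12 * n, sxy ** 2 / sxx, 0.0)
        gain[selected] = 0.0
        j = int(np.argmax(gain))     # argmax takes first (map-order) tie
        new_rss = rss - float(gain[j])
        new_bic = n * np.log(max(new_rss, 1e-300) / n) + bic - n * np.log(rss / n) \
            + penalty
        if new_bic >= bic or gain[j] <= 0:
            break
        selected.append(j)
        D = np.hstack([D, G[:, [j]]])
        yres = _residualize(D, y[:, None])[:, 0]
        rss = new_rss
        bic = new_bic
    return [genotypes.gmap.markers[j] for j in selected]


def permutation_threshold(trait, genotypes: GenotypeMatrix, grid: EvaluationGrid,
                          n_perm: int = 1000, alpha: float = 0.05,
                          seed: int = 0, cofactors=(), window: float = 10.0,
                          P: np.ndarray | None = None) -> PermutationThreshold:
    """Genome-wide LOD threshold: (1-alpha) quantile of permuted max LODs.

    Trait values are shuffled across lines with genotypes fixed; each
    permutation is rescanned and its genome-wide maximum recorded. The
    quantile uses linear (type-7) interpolation. Deterministic under ``seed``.
    """
    if n_perm < 20:
        raise ValueError("n_perm < 20: quantile too unstable, refuse")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    if P is None:
        P = expected_genotype_matrix(genotypes, grid)
    y, keep, _ = _prepare_trait(trait, genotypes.n_lines)
    rng = np.random.default_rng(seed)
    n = y.size
    perms = np.empty((n, n_perm))
    for b in range(n_perm):
        perms[:, b] = y[rng.permutation(n)]
    C = _cofactor_design(genotypes, list(cofactors), keep)
    active = _active_cofactor_sets(grid, genotypes, list(cofactors), window)
    lod, _, _ = _scan_with_cofactors(perms, P[keep], C, active)
    maxima = lod.max(axis=0)
    thr = float(np.quantile(maxima, 1.0 - alpha))
    return PermutationThreshold(n_perm, alpha, thr, seed, maxima)


def call_peaks(profile: ScanProfile, threshold: float, merge_radius: float = 10.0,
               gmap: GeneticMap | None = None, lod_drop: float = 1.5,
               parents: tuple = ("P1", "P2")) -> list[Peak]:
    """Call QTL peaks above ``threshold`` and merge peaks within ``merge_radius``.

    Local maxima above the threshold are kept; on each chromosome, maxima
    within ``merge_radius`` cM collapse onto the strongest (ties to the lower
    cM), and a weaker maximum whose own support interval already contains a
    stronger kept peak is suppressed as a shoulder of that peak rather than a
    distinct QTL. Support intervals are 1.5-LOD drops clipped to chromosome
    ends; physical intervals interpolate marker bp when a map is supplied.
    """
    if merge_radius < 0:
        raise ValueError("merge_radius must be >= 0")
    peaks: list[Peak] = []
    tab = profile.table
    for chrom in dict.fromkeys(tab["chrom"]):
        sub = tab[tab["chrom"] == chrom].reset_index(drop=True)
        lod = sub["lod"].to_numpy()
        cm = sub["cM"].to_numpy()
        npos = len(sub)
        cand = [i for i in range(npos)
                if lod[i] >= threshold
                and (i == 0 or lod[i] >= lod[i - 1])
                and (i == npos - 1 or lod[i] >= lod[i + 1])]

        def _support(i):
            lo = i
            while lo > 0 and lod[lo - 1] > lod[i] - lod_drop:
                lo -= 1
            hi = i
            while hi < npos - 1 and lod[hi + 1] > lod[i] - lod_drop:
                hi += 1
            return lo, hi

        # greedy merge: strongest first, ties toward lower cM
        cand.sort(key=lambda i: (-lod[i], cm[i]))
        kept: list[int] = []
        for i in cand:
            lo_i, hi_i = _support(i)
            near = any(abs(cm[i] - cm[j]) <= merge_radius for j in kept)
            shoulder = any(cm[lo_i] <= cm[j] <= cm[hi_i] for j in kept)
            if not near and not shoulder:
                kept.append(i)
        for i in sorted(kept, key=lambda i: cm[i]):
            lo, hi = _support(i)
            add = float(sub.at[i, "additive"])
            bp_lo = bp_hi = None
            if gmap is not None:
                bp_lo = gmap.interpolate_bp(chrom, float(cm[lo]))
                bp_hi = gmap.interpolate_bp(chrom, float(cm[hi]))
            peaks.append(Peak(
                chrom=chrom, peak_cM=float(cm[i]),
                ci_lo=float(cm[lo]), ci_hi=float(cm[hi]),
                lod=float(lod[i]), r2=float(sub.at[i, "r2"]), additive=add,
                allele_parent=parents[1] if add > 0 else parents[0],
                bp_lo=bp_lo, bp_hi=bp_hi, trait=profile.trait_name))
    return peaks


def peaks_to_frame(peaks: list[Peak]) -> pd.DataFrame:
    """Tabulate called peaks (`trait chrom peak_cM ci_lo ci_hi lod r2 ...`)."""
    cols = ["trait", "chrom", "peak_cM", "ci_lo", "ci_hi", "lod", "r2",
            "additive", "allele_parent", "bp_lo", "bp_hi", "name"]
    return pd.DataFrame([{c: getattr(p, c) for c in cols} for p in peaks],
                        columns=cols)
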