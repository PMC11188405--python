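"""Genetic-map arithmetic and doubled-haploid genotype probabilities.

A doubled-haploid (DH) line is fully homozygous: each chromosome is a single
F1 gamete, so every marker carries one of two parental alleles, coded
``0`` (first parent, e.g. the adapted DH parent) or ``1`` (second parent).
This module holds the genetic map (cM + physical bp per marker), the coded
genotype matrix, the Haldane map function, and the flanking-marker
conditional probability of the QTL genotype that interval mapping
regresses on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "GenotypeMatrix",
    "EvaluationGrid",
    "haldane_d_to_r",
    "haldane_r_to_d",
    "kosambi_d_to_r",
    "kosambi_r_to_d",
    "dh_qtl_probabilities",
    "build_grid",
    "expected_genotype_matrix",
]


# ---------------------------------------------------------------------------
# map functions


def haldane_d_to_r(d):
    """Haldane map function: genetic distance (cM) -> recombination fraction.

    r = (1 - exp(-2d/100)) / 2, assuming no crossover interference.
    Accepts scalars or arrays; ``d`` may be ``inf`` (r saturates at 0.5).
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("genetic distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if r.ndim == 0 else r


def haldane_r_to_d(r):
    """Inverse Haldane map: recombination fraction -> distance in cM (r < 0.5)."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = -50.0 * np.log(1.0 - 2.0 * r)
    return float(d) if d.ndim == 0 else d


def kosambi_d_to_r(d):
    """Kosambi map function (distance conversion only): r = tanh(2d/100)/2."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("genetic distance must be non-negative")
    r = 0.5 * np.tanh(2.0 * d / 100.0)
    return float(r) if r.ndim == 0 else r


def kosambi_r_to_d(r):
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


MAP_FUNCTIONS = {"haldane": (haldane_d_to_r, haldane_r_to_d),
                 "kosambi": (kosambi_d_to_r, kosambi_r_to_d)}


# ---------------------------------------------------------------------------
# domain types


@dataclass
class GeneticMap:
    """Ordered markers with genetic (cM) and physical (bp) coordinates.

    ``table`` columns: marker, chrom, cM, bp. Marker names unique; cM
    non-decreasing within each chromosome; bp 1-based.
    """

    table: pd.DataFrame

    def __post_init__(self):
        required = ["marker", "chrom", "cM", "bp"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"genetic map missing columns: {missing}")
        t = self.table
        if t["marker"].duplicated().any():
            dup = t.loc[t["marker"].duplicated(), "marker"].iloc[0]
            raise ValueError(f"duplicate marker name: {dup!r}")
        if (t["cM"] < 0).any():
            raise ValueError("cM positions must be >= 0")
        for chrom, sub in t.groupby("chrom", sort=False):
            if not sub["cM"].is_monotonic_increasing:
                raise ValueError(f"cM not sorted ascending on chromosome {chrom}")
        self.table = t.reset_index(drop=True)

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chrom"]))

    @property
    def markers(self) -> list:
        return list(self.table["marker"])

    def chrom_table(self, chrom) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]

    def marker_index(self, marker) -> int:
        idx = self.table.index[self.table["marker"] == marker]
        if len(idx) == 0:
            raise KeyError(f"marker {marker!r} not on map")
        return int(idx[0])

    def interpolate_bp(self, chrom, cm: float) -> int:
        """Physical position at a cM coordinate, linear between flanking markers."""
        sub = self.chrom_table(chrom)
        if len(sub) == 0:
            raise KeyError(f"chromosome {chrom!r} not on map")
        bp = np.interp(cm, sub["cM"].to_numpy(), sub["bp"].to_numpy(dtype=float))
        return int(round(bp))

    def nearest_marker(self, chrom, cm: float) -> str:
        sub = self.chrom_table(chrom)
        i = (sub["cM"] - cm).abs().idxmin()
        return str(self.table.loc[i, "marker"])


@dataclass
class GenotypeMatrix:
    """DH lines x markers, coded 0 (parent P1) / 1 (parent P2) / NaN (missing).

    Column order follows the genetic map. Heterozygote codes are a contract
    violation for DH material and rejected at construction.
    """

    values: np.ndarray              # float array, entries in {0, 1, nan}
    line_ids: list
    gmap: GeneticMap
    parents: tuple = ("P1", "P2")

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype matrix must be 2-D (lines x markers)")
        n, m = self.values.shape
        if n != len(self.line_ids):
            raise ValueError("line_ids length does not match matrix rows")
        if m != len(self.gmap.table):
            raise ValueError("marker count does not match genetic map")
        finite = self.values[np.isfinite(self.values)]
        bad = finite[(finite != 0) & (finite != 1)]
        if bad.size:
            raise ValueError(
                f"invalid DH genotype code {bad[0]!r}: DH lines carry only 0/1/missing")
        all_missing = np.all(~np.isfinite(self.values), axis=0)
        if all_missing.any():
            j = int(np.argmax(all_missing))
            raise ValueError(f"marker {self.gmap.markers[j]!r} is entirely missing")

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def chrom_slice(self, chrom) -> tuple[np.ndarray, np.ndarray]:
        """(genotype columns, cM positions) for one chromosome, map order."""
        mask = (self.gmap.table["chrom"] == chrom).to_numpy()
        return self.values[:, mask], self.gmap.table.loc[mask, "cM"].to_numpy()


@dataclass
class EvaluationGrid:
    """Scan positions along each chromosome at a fixed walking speed.

    For every position we store the flanking marker indices (global, into the
    map/genotype column order) and the recombination fractions to each flank.
    Marker positions are always included exactly.
    """

    positions: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: chrom, cM, left_idx, right_idx, r_left, r_right, is_marker

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def chrom_positions(self, chrom) -> pd.DataFrame:
        return self.positions[self.positions["chrom"] == chrom]


def build_grid(gmap: GeneticMap, step: float = 1.0,
               map_function: str = "haldane") -> EvaluationGrid:
    """Lay an evaluation grid at ``step`` cM over every chromosome.

    Every marker position appears exactly once; grid points closer than
    1e-6 cM to a marker are snapped onto the marker. A chromosome with a
    single marker yields a single-position grid (with a warning).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    d_to_r = MAP_FUNCTIONS[map_function][0]
    rows = []
    for chrom in gmap.chromosomes:
        sub = gmap.chrom_table(chrom)
        idx = sub.index.to_numpy()
        cm = sub["cM"].to_numpy(dtype=float)
        if len(cm) < 2:
            warnings.warn(f"chromosome {chrom} has <2 markers; single-position grid")
            rows.append((chrom, float(cm[0]), int(idx[0]), int(idx[0]), 0.0, 0.0, True))
            continue
        # the walk restarts at every marker so markers are hit exactly and
        # spacing within an interval never exceeds the step
        segments = [np.arange(cm[j], cm[j + 1], step) for j in range(len(cm) - 1)]
        pos = np.concatenate(segments + [cm[-1:]])
        # snap near-duplicates onto marker positions
        keep = []
        for p in pos:
            j = np.argmin(np.abs(cm - p))
            keep.append(cm[j] if abs(cm[j] - p) < 1e-6 else p)
        pos = np.unique(np.asarray(keep))
        for p in pos:
            j_right = int(np.searchsorted(cm, p, side="left"))
            if j_right < len(cm) and cm[j_right] == p:
                rows.append((chrom, float(p), int(idx[j_right]), int(idx[j_right]),
                             0.0, 0.0, True))
            else:
                j_left = j_right - 1
                r_l = float(d_to_r(p - cm[j_left]))
                r_r = float(d_to_r(cm[j_right] - p))
                rows.append((chrom, float(p), int(idx[j_left]), int(idx[j_right]),
                             r_l, r_r, False))
    cols = ["chrom", "cM", "left_idx", "right_idx", "r_left", "r_right", "is_marker"]
    return EvaluationGrid(pd.DataFrame(rows, columns=cols))


# ---------------------------------------------------------------------------
# conditional QTL-genotype probabilities


def dh_qtl_probabilities(left, right, r_left: float, r_right: float) -> float:
    """P(QTL genotype = class 0 | flanking DH marker genotypes).

    Under Haldane independence the two recombination events flanking the test
    position are independent, so for observed flanks (g_L, g_R):

        p0 = P(no rec to a 0-flank / rec to a 1-flank on each side) / normalizer

    A missing flank (NaN/None) drops that side's conditioning; both missing
    gives the unconditional 0.5. Heterozygote codes are rejected.
    """
    def _side(g, r):
        # returns (P(side | class0), P(side | class1)) contribution
        if g is None or (isinstance(g, float) and np.isnan(g)):
            return 1.0, 1.0
        g = float(g)
        if g == 0.0:
            return 1.0 - r, r
        if g == 1.0:
            return r, 1.0 - r
        raise ValueError(f"invalid DH genotype code {g!r} (heterozygotes not allowed)")

    for r in (r_left, r_right):
        if not (0.0 <= r < 0.5 or r == 0.5):
            raise ValueError("recombination fractions must lie in [0, 0.5]")
    l0, l1 = _side(left, r_left)
    q0, q1 = _side(right, r_right)
    w0, w1 = l0 * q0, l1 * q1
    if w0 + w1 == 0.0:     # impossible configuration (e.g. r=0 both, conflicting flanks)
        return 0.5
    return w0 / (w0 + w1)


def _fill_indices(finite: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per (line, marker): index of nearest non-missing marker at/left and at/right."""
    n, m = finite.shape
    ar = np.arange(m)
    left = np.where(finite, ar[None, :], -1)
    left = np.maximum.accumulate(left, axis=1)
    right = np.where(finite, ar[None, :], m)
    right = np.minimum.accumulate(right[:, ::-1], axis=1)[:, ::-1]
    return left, right


def expected_genotype_matrix(genotypes: GenotypeMatrix, grid: EvaluationGrid,
                             map_function: str = "haldane") -> np.ndarray:
    """E[QTL class-1 indicator | flanking markers] for every line x grid position.

    This is the Haley-Knott regressor. Conditioning uses the nearest
    non-missing marker on each side of the test position (map order); a fully
    missing side contributes nothing, both sides missing gives 0.5.
    Returns an (n_lines, n_positions) float array of P(class 1).
    """
    d_to_r = MAP_FUNCTIONS[map_function][0]
    G = genotypes.values
    n = G.shape[0]
    cm_all = genotypes.gmap.table["cM"].to_numpy(dtype=float)
    chrom_all = genotypes.gmap.table["chrom"].to_numpy()
    out = np.empty((n, grid.n_positions), dtype=float)

    finite = np.isfinite(G)
    left_fill, right_fill = _fill_indices(finite)

    # chromosome bounds in global marker index space
    chrom_bounds = {}
    for chrom in genotypes.gmap.chromosomes:
        w = np.where(chrom_all == chrom)[0]
        chrom_bounds[chrom] = (int(w[0]), int(w[-1]))

    pos = grid.positions
    for k in range(grid.n_positions):
        chrom = pos.iat[k, 0]
        p_cm = pos.iat[k, 1]
        li, ri = int(pos.iat[k, 2]), int(pos.iat[k, 3])
        lo, hi = chrom_bounds[chrom]

        # nearest non-missing flank per line, clipped to this chromosome
        jl = left_fill[:, li].copy()
        jl[jl < lo] = -1
        jr = right_fill[:, ri].copy()
        jr[jr > hi] = -1

        w0 = np.ones(n)
        w1 = np.ones(n)
        has_l = jl >= 0
        if has_l.any():
            r = d_to_r(p_cm - cm_all[jl[has_l]])
            gl = G[has_l, jl[has_l]]
            w0[has_l] *= np.where(gl == 0, 1.0 - r, r)
            w1[has_l] *= np.where(gl == 0, r, 1.0 - r)
        has_r = jr >= 0
        if has_r.any():
            r = d_to_r(cm_all[jr[has_r]] - p_cm)
            gr = G[has_r, jr[has_r]]
            w0[has_r] *= np.where(gr == 0, 1.0 - r, r)
            w1[has_r] *= np.where(gr == 0, r, 1.0 - r)
        tot = w0 + w1
        p1 = np.where(tot > 0, w1 / np.where(tot > 0, tot, 1.0), 0.5)
        out[:, k] = p1
    return out
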