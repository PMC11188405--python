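"""Genome-wide eQTL scanning, global permutation threshold, cis/trans calls.

Every transcript's expression is treated as a quantitative trait and
scanned with the shared interval-mapping engine. Because per-transcript
permutation testing over tens of thousands of transcripts is wasteful, a
global permutation threshold (GPT) is built once: a sample of transcripts
is permuted a few times each, genome-wide maximum LODs are pooled, and the
(1 - alpha) quantile becomes the LOD cut-off applied to all scans. An eQTL
is *cis* when the gene lies on the peak marker's chromosome within a fixed
physical window (default 4 Mb), otherwise *trans*; genes without a known
position stay *unplaced*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exprprep import ExpressionMatrix
from .genmap import EvaluationGrid, GenotypeMatrix, expected_genotype_matrix
from .scan import (ScanProfile, call_peaks, cim_scan, interval_mapping_scan,
                   select_cofactors)

logger = logging.getLogger(__name__)

__all__ = [
    "EQTLRecord",
    "GlobalThreshold",
    "global_permutation_threshold",
    "eqtl_scan_all",
    "classify_cis_trans",
    "hotspot_counts",
]

CIS_WINDOW_BP = 4_000_000


@dataclass
class EQTLRecord:
    """One significant transcript-locus association."""

    transcript: str
    chrom: object
    peak_cM: float
    marker: str
    marker_bp: int
    lod: float
    r2: float
    additive: float
    ci_lo: float = np.nan
    ci_hi: float = np.nan
    regulation: str = "unplaced"       # cis | trans | unplaced
    distance_bp: int | None = None


@dataclass
class GlobalThreshold:
    """Pooled permutation threshold shared by every transcript scan."""

    n_transcripts: int
    n_perm_each: int
    alpha: float
    threshold: float
    seed: int
    maxima: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


def _lod_matrix(Y: np.ndarray, P: np.ndarray) -> np.ndarray:
    """IM LODs for many traits at once: (positions x traits).

    With no cofactors, LOD = -(n/2) log10(1 - corr^2(x_pos, y)); a single
    standardized cross-product gives every (position, trait) pair.
    """
    n = Y.shape[0]
    Yz = Y - Y.mean(axis=0)
    ys = np.sqrt(np.einsum("ij,ij->j", Yz, Yz))
    Pz = P - P.mean(axis=0)
    ps = np.sqrt(np.einsum("ij,ij->j", Pz, Pz))
    denom = np.outer(ps, ys)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(denom > 0, (Pz.T @ Yz) / np.where(denom > 0, denom, 1.0), 0.0)
    ratio = np.clip(1.0 - corr ** 2, 1e-300, None)
    return -(n / 2.0) * np.log10(ratio)


def global_permutation_threshold(expr: ExpressionMatrix, genotypes: GenotypeMatrix,
                                 grid: EvaluationGrid, n_transcripts: int = 100,
                                 n_perm_each: int = 10, alpha: float = 0.05,
                                 seed: int = 0,
                                 P: np.ndarray | None = None) -> GlobalThreshold:
    """Pool genome-wide max LODs over permuted sampled transcripts.

    Transcripts are sampled without replacement; each is permuted across
    lines ``n_perm_each`` times and rescanned (IM mode). The threshold is
    the (1 - alpha) quantile of the pooled maxima.
    """
    total = len(expr.transcripts)
    if n_transcripts > total:
        raise ValueError("cannot sample more transcripts than available")
    if n_transcripts * n_perm_each < 200:
        raise ValueError("insufficient pooled maxima (< 200); raise counts")
    rng = np.random.default_rng(seed)
    pick = rng.choice(total, size=n_transcripts, replace=False)
    if P is None:
        P = expected_genotype_matrix(genotypes, grid)
    X = expr.values.to_numpy(dtype=float)[pick]       # (n_transcripts, n_lines)
    n = X.shape[1]
    maxima = np.empty(n_transcripts * n_perm_each)
    for b in range(n_perm_each):
        perm = np.array([rng.permutation(n) for _ in range(n_transcripts)])
        Yp = np.take_along_axis(X, perm, axis=1).T    # (n_lines, n_transcripts)
        sd = Yp.std(axis=0)
        lods = _lod_matrix(Yp[:, sd > 0], P)
        block = np.zeros(n_transcripts)
        block[sd > 0] = lods.max(axis=0)
        maxima[b * n_transcripts:(b + 1) * n_transcripts] = block
    thr = float(np.quantile(maxima, 1.0 - alpha))
    return GlobalThreshold(n_transcripts, n_perm_each, alpha, thr, seed, maxima)


def eqtl_scan_all(expr: ExpressionMatrix, genotypes: GenotypeMatrix,
                  grid: EvaluationGrid, threshold: float,
                  engine: str = "IM", window: float = 10.0,
                  merge_radius: float = 10.0, max_cofactors: int = 5,
                  P: np.ndarray | None = None) -> list[EQTLRecord]:
    """Scan every transcript and call merged eQTL peaks above ``threshold``.

    ``engine='IM'`` (default) runs the vectorized no-cofactor scan across all
    transcripts at once; ``engine='CIM'`` selects cofactors per transcript.
    Each surviving peak becomes a record carrying the nearest-marker lookup.
    """
    if engine not in ("IM", "CIM"):
        raise ValueError("engine must be 'IM' or 'CIM'")
    if P is None:
        P = expected_genotype_matrix(genotypes, grid)
    gmap = genotypes.gmap
    X = expr.values.to_numpy(dtype=float)
    records: list[EQTLRecord] = []
    n_skipped = 0
    chrom_counts: dict = {}

    if engine == "IM":
        sd = X.std(axis=1)
        variable = np.where(sd > 0)[0]
        n_skipped = len(sd) - len(variable)
        Y = X[variable].T
        lods = _lod_matrix(Y, P)
        # per-transcript full profile (r2/additive) recomputed only at peaks
        for col, ti in enumerate(variable):
            if lods[:, col].max() < threshold:
                continue
            profile = interval_mapping_scan(X[ti], genotypes, grid, P=P)
            profile.trait_name = str(expr.transcripts[ti])
            records.extend(_peaks_to_records(profile, threshold, merge_radius,
                                             gmap, chrom_counts))
    else:
        for ti, transcript in enumerate(expr.transcripts):
            y = X[ti]
            if np.std(y[np.isfinite(y)]) == 0:
                n_skipped += 1
                logger.info("transcript %s has zero variance; skipped", transcript)
                continue
            cof = select_cofactors(y, genotypes, max_cofactors)
            profile = cim_scan(y, genotypes, grid, cof, window, P=P)
            profile.trait_name = str(transcript)
            records.extend(_peaks_to_records(profile, threshold, merge_radius,
                                             gmap, chrom_counts))
    logger.info("eQTL scan: %d records, %d zero-variance transcripts skipped; "
                "per-chromosome counts %s", len(records), n_skipped, chrom_counts)
    return records


def _peaks_to_records(profile: ScanProfile, threshold, merge_radius, gmap,
                      chrom_counts) -> list[EQTLRecord]:
    out = []
    for pk in call_peaks(profile, threshold, merge_radius, gmap=gmap):
        marker = gmap.nearest_marker(pk.chrom, pk.peak_cM)
        mrow = gmap.table.iloc[gmap.marker_index(marker)]
        out.append(EQTLRecord(
            transcript=profile.trait_name, chrom=pk.chrom, peak_cM=pk.peak_cM,
            marker=marker, marker_bp=int(mrow["bp"]), lod=pk.lod, r2=pk.r2,
            additive=pk.additive, ci_lo=pk.ci_lo, ci_hi=pk.ci_hi))
        chrom_counts[pk.chrom] = chrom_counts.get(pk.chrom, 0) + 1
    return out


def classify_cis_trans(records: list[EQTLRecord], positions: pd.DataFrame,
                       window_bp: int = CIS_WINDOW_BP) -> list[EQTLRecord]:
    """Assign cis/trans/unplaced per the physical-distance rule.

    cis iff the gene's position is known, lies on the peak marker's
    chromosome, and |gene bp - marker bp| <= ``window_bp``; a different
    chromosome is trans regardless of distance; unknown position -> unplaced.
    """
    for rec in records:
        if rec.transcript not in positions.index:
            rec.regulation = "unplaced"
            rec.distance_bp = None
            continue
        row = positions.loc[rec.transcript]
        gene_chrom, gene_bp = row["chrom"], int(row["bp"])
        if gene_chrom != rec.chrom:
            rec.regulation = "trans"
            rec.distance_bp = None
        else:
            rec.distance_bp = abs(gene_bp - rec.marker_bp)
            rec.regulation = "cis" if rec.distance_bp <= window_bp else "trans"
    return records


def hotspot_counts(records: list[EQTLRecord], bin_cM: float = 10.0,
                   fdr: float = 0.05) -> pd.DataFrame:
    """Count trans-eQTLs per (chromosome, cM bin) and flag enriched bins.

    Enrichment p per bin is the Poisson upper tail against the genome-wide
    mean count per bin, BH-adjusted across bins.
    """
    trans = [r for r in records if r.regulation == "trans"]
    if not trans:
        return pd.DataFrame(columns=["chrom", "bin_lo", "bin_hi", "count",
                                     "p", "p_adj", "hotspot"])
    rows = {}
    for r in trans:
        b = int(np.floor(r.peak_cM / bin_cM))
        rows[(r.chrom, b)] = rows.get((r.chrom, b), 0) + 1
    tab = pd.DataFrame(
        [(c, b * bin_cM, (b + 1) * bin_cM, n) for (c, b), n in sorted(rows.items())],
        columns=["chrom", "bin_lo", "bin_hi", "count"])
    mean_rate = tab["count"].sum() / max(len(tab), 1)
    tab["p"] = stats.poisson.sf(tab["count"] - 1, mean_rate)
    tab["p_adj"] = multipletests(tab["p"], method="fdr_bh")[1]
    tab["hotspot"] = tab["p_adj"] < fdr
    return tab


def records_to_frame(records: list[EQTLRecord]) -> pd.DataFrame:
    cols = ["transcript", "chrom", "peak_cM", "marker", "marker_bp", "lod",
            "r2", "additive", "regulation", "distance_bp", "ci_lo", "ci_hi"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records],
                        columns=cols)
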