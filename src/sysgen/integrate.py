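"""Systems-genetics integration: network QTL, colocalization, causal genes.

Each module eigengene is mapped as a quantitative trait ("network QTL" or
mQTL); its peaks, the phenotype QTL (pQTL) and the member genes' eQTL are
then intersected by genetic colocalization (overlapping support intervals
or peaks within a cM radius on one chromosome). A gene is the strongest
kind of causal candidate when it belongs to a trait-associated module, is
itself cis-regulated, and its cis-eQTL colocalizes with a trait pQTL — the
expression-mediation argument made explicit as an evidence tier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .eqtl import EQTLRecord
from .genmap import EvaluationGrid, GenotypeMatrix, expected_genotype_matrix
from .network import ModuleSet
from .scan import Peak, call_peaks, cim_scan, permutation_threshold, select_cofactors

__all__ = [
    "Colocalization",
    "CausalGeneCall",
    "network_qtl",
    "colocalize",
    "significant_modules",
    "assemble_causal_network",
    "enrichment_fisher",
    "prioritize_causal_genes",
]


@dataclass
class Colocalization:
    """Two peaks declared to share a locus."""

    peak_a: Peak
    peak_b: Peak
    overlap_type: str        # interval-overlap | peaks-within-radius
    distance_cM: float


@dataclass
class CausalGeneCall:
    """A prioritized candidate causal gene with its evidence tier."""

    transcript: str
    module: int
    module_trait_r: float
    module_trait_p: float
    eqtl_class: str
    eqtl_lod: float
    coloc_pqtl: str
    tier: str                # cis-colocal | trans-colocal | module-only


_TIER_ORDER = {"cis-colocal": 0, "trans-colocal": 1, "module-only": 2}


def network_qtl(modules: ModuleSet, genotypes: GenotypeMatrix,
                grid: EvaluationGrid, n_perm: int = 200, alpha: float = 0.05,
                seed: int = 0, max_cofactors: int = 5, window: float = 10.0,
                merge_radius: float = 10.0,
                P: np.ndarray | None = None) -> dict[int, list[Peak]]:
    """CIM-map every module eigengene with a module-specific permutation LOD.

    Peaks are labelled ``qModule<k>_<chrom>_<i>``. Seeds for each module's
    permutations derive deterministically from ``seed`` and the module label.
    """
    if modules.eigengenes.empty:
        raise ValueError("module eigengenes not computed")
    if P is None:
        P = expected_genotype_matrix(genotypes, grid)
    out: dict[int, list[Peak]] = {}
    for label in modules.eigengenes.columns:
        me = modules.eigengenes[label].to_numpy()
        cof = select_cofactors(me, genotypes, max_cofactors)
        profile = cim_scan(me, genotypes, grid, cof, window, P=P)
        profile.trait_name = f"ME{label}"
        sub_seed = (int(seed) * 100003 + int(label) * 7919) % (2 ** 31)
        thr = permutation_threshold(me, genotypes, grid, n_perm, alpha,
                                    seed=sub_seed, cofactors=cof,
                                    window=window, P=P)
        peaks = call_peaks(profile, thr.threshold, merge_radius,
                           gmap=genotypes.gmap, parents=genotypes.parents)
        counters: dict = {}
        for pk in peaks:
            counters[pk.chrom] = counters.get(pk.chrom, 0) + 1
            pk.name = f"qModule{label}_{pk.chrom}_{counters[pk.chrom]}"
        out[int(label)] = peaks
    return out


def colocalize(peaks_a: list[Peak], peaks_b: list[Peak],
               radius_cM: float = 10.0) -> list[Colocalization]:
    """All cross-pairs sharing a locus: interval overlap OR peaks within radius.

    Both branches require the same chromosome; the rule is symmetric in its
    arguments and a peak always colocalizes with itself.
    """
    out = []
    for a in peaks_a:
        for b in peaks_b:
            if a.chrom != b.chrom:
                continue
            dist = abs(a.peak_cM - b.peak_cM)
            if a.ci_lo <= b.ci_hi and b.ci_lo <= a.ci_hi:
                out.append(Colocalization(a, b, "interval-overlap", dist))
            elif dist <= radius_cM:
                out.append(Colocalization(a, b, "peaks-within-radius", dist))
    return out


def significant_modules(assoc: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Module-trait pairs surviving BH across the whole module x trait grid."""
    tab = assoc.dropna(subset=["p"]).copy()
    if len(tab) == 0:
        return tab.assign(p_adj=pd.Series(dtype=float), significant=pd.Series(dtype=bool))
    tab["p_adj"] = multipletests(tab["p"], method="fdr_bh")[1]
    tab["significant"] = tab["p_adj"] < alpha
    return tab


def assemble_causal_network(assoc: pd.DataFrame, modules: ModuleSet,
                            edges: pd.DataFrame, trait: str | None = None,
                            alpha: float = 0.05) -> nx.Graph:
    """Induced hard-threshold subgraph over the trait-associated modules.

    Modules qualify through the BH-gated module-trait table (optionally for
    one named trait); the subnetwork is the union of their member
    transcripts with every |r|-threshold edge between them.
    """
    gated = significant_modules(assoc, alpha)
    if trait is not None:
        gated = gated[gated["trait"] == trait]
    winners = sorted(set(gated.loc[gated["significant"], "module"]))
    members: list = []
    for label in winners:
        members.extend(modules.members(label))
    if not members:
        warnings.warn("no module passed the module-trait significance gate")
    g = nx.Graph()
    g.add_nodes_from(members)
    for label in winners:
        for t in modules.members(label):
            g.nodes[t]["module"] = label
    member_set = set(members)
    for _, row in edges.iterrows():
        if row["node_a"] in member_set and row["node_b"] in member_set:
            g.add_edge(row["node_a"], row["node_b"], r=float(row["r"]))
    g.graph["modules"] = winners
    return g


def enrichment_fisher(members, categories: pd.Series, universe) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of each category in a gene set.

    ``categories`` maps gene -> category label over (a superset of) the
    universe. For each category the 2x2 table counts set/category overlap
    against the rest of the universe; the raw p < 0.05 rule is reported
    alongside a BH-adjusted p.
    """
    universe = list(universe)
    if not universe:
        raise ValueError("empty universe")
    member_set = set(members)
    missing = member_set - set(universe)
    if missing:
        raise ValueError(f"members outside universe, e.g. {next(iter(missing))!r}")
    cat = categories.reindex(universe)
    rows = []
    for label in sorted(cat.dropna().unique()):
        in_cat = set(cat.index[cat == label])
        a = len(member_set & in_cat)
        b = len(member_set) - a
        c = len(in_cat) - a
        d = len(universe) - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((label, a, len(in_cat), odds, p))
    tab = pd.DataFrame(rows, columns=["category", "in_set", "in_universe",
                                      "odds_ratio", "p"])
    if len(tab):
        tab["p_adj"] = multipletests(tab["p"], method="fdr_bh")[1]
        tab["significant"] = tab["p"] < 0.05
    return tab


def prioritize_causal_genes(subnetwork: nx.Graph, records: list[EQTLRecord],
                            trait_peaks: list[Peak], assoc: pd.DataFrame,
                            trait: str | None = None, radius_cM: float = 10.0,
                            alpha: float = 0.05) -> list[CausalGeneCall]:
    """Rank member genes of the causal subnetwork by eQTL/pQTL evidence.

    * ``cis-colocal``  — cis-eQTL colocalizing with a trait pQTL;
    * ``trans-colocal`` — trans-eQTL colocalizing with a trait pQTL;
    * ``module-only``  — in a trait-associated module but no colocalizing eQTL.
    Sorted by tier then descending eQTL LOD.
    """
    gated = significant_modules(assoc, alpha)
    if trait is not None:
        gated = gated[gated["trait"] == trait]
    gated = gated[gated["significant"]]
    mod_stats = {int(m): (float(r), float(p)) for m, r, p in
                 zip(gated["module"], gated["r"], gated["p"])}

    by_transcript: dict[str, list[EQTLRecord]] = {}
    for rec in records:
        by_transcript.setdefault(rec.transcript, []).append(rec)

    def _peak_of(rec: EQTLRecord) -> Peak:
        return Peak(chrom=rec.chrom, peak_cM=rec.peak_cM, ci_lo=rec.ci_lo,
                    ci_hi=rec.ci_hi, lod=rec.lod, r2=rec.r2,
                    additive=rec.additive, trait=rec.transcript)

    calls = []
    for node, data in subnetwork.nodes(data=True):
        module = int(data.get("module", 0))
        r, p = mod_stats.get(module, (np.nan, np.nan))
        tier, eqtl_class, lod, coloc = "module-only", "", 0.0, ""
        for rec in by_transcript.get(node, []):
            hits = colocalize([_peak_of(rec)], trait_peaks, radius_cM)
            if not hits:
                continue
            cand = "cis-colocal" if rec.regulation == "cis" else "trans-colocal"
            if (_TIER_ORDER[cand], -rec.lod) < (_TIER_ORDER[tier], -lod):
                best = max(hits, key=lambda h: h.peak_b.lod)
                tier, eqtl_class, lod = cand, rec.regulation, rec.lod
                coloc = best.peak_b.name or best.peak_b.trait
        calls.append(CausalGeneCall(str(node), module, r, p, eqtl_class,
                                    lod, coloc, tier))
    calls.sort(key=lambda c: (_TIER_ORDER[c.tier], -c.eqtl_lod, c.transcript))
    return calls


def calls_to_frame(calls: list[CausalGeneCall]) -> pd.DataFrame:
    cols = ["transcript", "module", "tier", "eqtl_class", "eqtl_lod",
            "coloc_pqtl", "module_trait_r"]
    return pd.DataFrame([{c: getattr(x, c) for c in cols} for x in calls],
                        columns=cols)
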