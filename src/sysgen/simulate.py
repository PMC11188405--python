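"""Synthetic doubled-haploid studies with full ground truth.

The generator emulates the statistical structure the pipeline assumes: a
DH population segregating 1:1 at every marker (each line one F1 gamete,
recombination by the Haldane model), cis-regulated "hub" transcripts whose
allelic expression drives co-expression modules through a latent factor,
background transcripts of pure noise, and quantitative traits built from
module activity plus direct marker effects plus Gaussian noise. Every
planted element is recorded so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exprprep import ExpressionMatrix
from .genmap import GeneticMap, GenotypeMatrix, haldane_d_to_r

__all__ = [
    "ChromSpec",
    "PlantedModule",
    "PlantedCisGene",
    "PlantedTraitQTL",
    "SimConfig",
    "SimTruth",
    "simulate_dh_population",
    "simulate_expression",
    "simulate_traits",
    "simulate_study",
]


@dataclass(frozen=True)
class ChromSpec:
    label: str
    length_cM: float = 100.0
    length_bp: int = 40_000_000


@dataclass(frozen=True)
class PlantedModule:
    """A co-expression module driven by a marker through a latent factor.

    ``loading`` is each member transcript's loading on the latent;
    ``hub_r2`` the fraction of latent variance explained by the hub marker.
    """

    size: int
    hub_marker: str
    loading: float = 0.8
    hub_r2: float = 0.5


@dataclass(frozen=True)
class PlantedCisGene:
    """A transcript with an additive effect of a nearby marker (its cis-eQTL)."""

    transcript: str
    marker: str
    r2: float = 0.3


@dataclass(frozen=True)
class PlantedTraitQTL:
    """A direct trait effect: of a marker, or of a planted module's latent."""

    target: str            # marker name, or "module:<k>" (1-based planted index)
    r2: float = 0.1


@dataclass
class SimConfig:
    """Study design for one synthetic DH experiment.

    Defaults mirror a small dense-map DH study: 96 lines, 3 chromosomes of
    100 cM / 40 Mb with a marker every 2 cM — dense enough for a 4-Mb
    cis window to be meaningful while scans stay fast.
    """

    n_lines: int = 96
    chromosomes: tuple = (ChromSpec("A01"), ChromSpec("A02"), ChromSpec("A03"))
    marker_spacing_cM: float = 2.0
    n_transcripts: int = 500
    modules: tuple = ()
    cis_genes: tuple = ()
    trait_qtl: tuple = ()
    n_sibling_traits: int = 0
    sibling_share: float = 0.9
    n_decoy_traits: int = 0
    noise_sd: float = 1.0
    expression_scale: str = "linear"   # "linear" (lognormal-ish) or "log2"
    log2_baseline: float = 8.0         # mean log2 intensity on the linear scale
    log2_baseline_sd: float = 3.0      # per-transcript abundance spread (linear)
    seed: int = 0

    def validate(self, gmap: GeneticMap | None = None) -> None:
        total = sum(q.r2 for q in self.trait_qtl)
        if total >= 1.0:
            raise ValueError(f"trait QTL R^2 sum {total} must be < 1")
        for m in self.modules:
            if not (0.0 < m.loading < 1.0):
                raise ValueError("module loading must lie in (0, 1)")
            if not (0.0 <= m.hub_r2 <= 1.0):
                raise ValueError("hub_r2 must lie in [0, 1]")
        for g in self.cis_genes:
            if not (0.0 < g.r2 < 1.0):
                raise ValueError("cis-gene R^2 must lie in (0, 1)")
        if gmap is not None:
            markers = set(gmap.markers)
            planted = [m.hub_marker for m in self.modules] + \
                      [g.marker for g in self.cis_genes] + \
                      [q.target for q in self.trait_qtl
                       if not q.target.startswith("module:")]
            for name in planted:
                if name not in markers:
                    raise ValueError(f"planted marker {name!r} not on map")


@dataclass
class SimTruth:
    """Ground truth of everything planted, keyed like the emitted data."""

    eqtl: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: transcript, marker, chrom, marker_bp, r2, kind (cis|module-hub)
    modules: pd.Series = field(default_factory=pd.Series)   # transcript -> module
    module_latents: pd.DataFrame = field(default_factory=pd.DataFrame)
    trait_qtl: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: trait, target, marker, chrom, cM, r2


def _default_map(config: SimConfig) -> GeneticMap:
    rows = []
    for ch in config.chromosomes:
        cms = np.arange(0.0, ch.length_cM + 1e-9, config.marker_spacing_cM)
        for i, cm in enumerate(cms):
            bp = 1 + int(round(cm / ch.length_cM * (ch.length_bp - 1)))
            rows.append((f"{ch.label}_m{i:03d}", ch.label, float(cm), bp))
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chrom", "cM", "bp"]))


def simulate_dh_population(config: SimConfig,
                           gmap: GeneticMap | None = None,
                           rng: np.random.Generator | None = None
                           ) -> tuple[GenotypeMatrix, GeneticMap]:
    """Draw DH lines as single F1 gametes over the marker map.

    Per chromosome the allele sequence is a two-state Markov chain: the
    first marker is Bernoulli(1/2) and each step switches parental class
    with probability equal to the Haldane recombination fraction of the
    marker gap. Chromosomes assort independently.
    """
    if gmap is None:
        gmap = _default_map(config)
    if len(gmap.table) == 0:
        raise ValueError("cannot simulate from an empty map")
    config.validate(gmap)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_lines
    cols = []
    for chrom in gmap.chromosomes:
        cm = gmap.chrom_table(chrom)["cM"].to_numpy(dtype=float)
        m = len(cm)
        g = np.empty((n, m))
        g[:, 0] = rng.integers(0, 2, size=n)
        r = haldane_d_to_r(np.diff(cm))
        switch = rng.random((n, m - 1)) < r[None, :] if m > 1 else None
        for j in range(1, m):
            g[:, j] = np.where(switch[:, j - 1], 1 - g[:, j - 1], g[:, j - 1])
        cols.append(g)
    values = np.hstack(cols)
    line_ids = [f"SG{i + 1:03d}" for i in range(n)]
    return GenotypeMatrix(values, line_ids, gmap,
                          parents=("P1", "P2")), gmap


def _standardize(v: np.ndarray) -> np.ndarray:
    s = v.std()
    return (v - v.mean()) / s if s > 0 else np.zeros_like(v)


def simulate_expression(config: SimConfig, genotypes: GenotypeMatrix,
                        rng: np.random.Generator | None = None
                        ) -> tuple[ExpressionMatrix, SimTruth]:
    """Transcript matrix with planted modules, cis genes and noise background.

    Module member g:  x_g = loading * z_m + sqrt(1 - loading^2) * eps,
    with latent z_m = sqrt(hub_r2) * g_hub + sqrt(1 - hub_r2) * eta (both
    standardized). Planted cis genes get x = sqrt(r2) * g_cis + sqrt(1-r2) * eps.
    Cis/hub transcripts are placed within 0.5 Mb of their marker (cis
    variants sit in or near the gene; the wider 4-Mb calling window absorbs
    marker sparsity and peak-localization error, not gene-variant distance),
    background transcripts uniformly. ``expression_scale='linear'`` emits
    intensities 2^(baseline + x) so the preprocessing floor has work to do.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    gmap = genotypes.gmap
    config.validate(gmap)
    n = genotypes.n_lines
    total = config.n_transcripts
    needed = sum(m.size for m in config.modules) + len(config.cis_genes)
    if needed > total:
        raise ValueError(f"planted transcripts ({needed}) exceed n_transcripts ({total})")

    X = np.empty((total, n))
    names = [f"tr{i + 1:05d}" for i in range(total)]
    membership = pd.Series(0, index=pd.Index(names, name="transcript"))
    latents = {}
    truth_rows = []
    positions = {}
    chrom_bp = {c.label: c.length_bp for c in config.chromosomes}

    def _marker_row(marker):
        return gmap.table.iloc[gmap.marker_index(marker)]

    def _place_near(marker, width_bp=1_000_000):
        row = _marker_row(marker)
        lo = max(1, int(row["bp"]) - width_bp // 2)
        hi = min(chrom_bp.get(row["chrom"], int(row["bp"]) + width_bp),
                 int(row["bp"]) + width_bp // 2)
        return row["chrom"], int(rng.integers(lo, hi + 1))

    cursor = 0
    for k, mod in enumerate(config.modules, start=1):
        # the hub gene's own expression is the module driver: cis-regulated
        # by its marker (R^2 = hub_r2), with the other members loading on it
        g_hub = _standardize(genotypes.values[:, gmap.marker_index(mod.hub_marker)])
        z = np.sqrt(mod.hub_r2) * g_hub + np.sqrt(1 - mod.hub_r2) * rng.standard_normal(n)
        z = _standardize(z)
        latents[k] = z
        lam = mod.loading
        first = cursor
        X[cursor] = z                     # the hub gene itself
        membership.iloc[cursor] = k
        cursor += 1
        for _ in range(mod.size - 1):
            X[cursor] = lam * z + np.sqrt(1 - lam ** 2) * rng.standard_normal(n)
            membership.iloc[cursor] = k
            cursor += 1
        positions[names[first]] = _place_near(mod.hub_marker)
        hub_row = _marker_row(mod.hub_marker)
        truth_rows.append((names[first], mod.hub_marker,
                           hub_row["chrom"], int(hub_row["bp"]),
                           mod.hub_r2, "module-hub"))

    cis_names = []
    for g in config.cis_genes:
        gm = _standardize(genotypes.values[:, gmap.marker_index(g.marker)])
        X[cursor] = np.sqrt(g.r2) * gm + np.sqrt(1 - g.r2) * rng.standard_normal(n)
        row = _marker_row(g.marker)
        truth_rows.append((names[cursor], g.marker, row["chrom"], int(row["bp"]),
                           g.r2, "cis"))
        positions[names[cursor]] = _place_near(g.marker)
        cis_names.append(names[cursor])
        cursor += 1

    X[cursor:] = rng.standard_normal((total - cursor, n))

    # positions: planted cis genes near their marker, everything else uniform
    chroms = [c.label for c in config.chromosomes]
    for name in names:
        if name not in positions or positions[name] is None:
            c = chroms[rng.integers(0, len(chroms))]
            positions[name] = (c, int(rng.integers(1, chrom_bp[c] + 1)))

    if config.expression_scale == "linear":
        # heterogeneous per-transcript abundance: many probes sit near or
        # below the background floor, giving the intensity filter real work
        baselines = config.log2_baseline \
            + config.log2_baseline_sd * rng.standard_normal(total)
        values = 2.0 ** (baselines[:, None] + X)
    elif config.expression_scale == "log2":
        values = config.log2_baseline + X
    else:
        raise ValueError("expression_scale must be 'linear' or 'log2'")

    frame = pd.DataFrame(values, index=pd.Index(names, name="transcript"),
                         columns=genotypes.line_ids)
    pos_frame = pd.DataFrame(
        [(t, c, bp) for t, (c, bp) in positions.items()],
        columns=["transcript", "chrom", "bp"]).set_index("transcript")
    truth = SimTruth(
        eqtl=pd.DataFrame(truth_rows, columns=["transcript", "marker", "chrom",
                                               "marker_bp", "r2", "kind"]),
        modules=membership,
        module_latents=pd.DataFrame(latents, index=genotypes.line_ids),
    )
    return ExpressionMatrix(frame, pos_frame), truth


def simulate_traits(config: SimConfig, genotypes: GenotypeMatrix,
                    truth: SimTruth,
                    rng: np.random.Generator | None = None
                    ) -> tuple[pd.DataFrame, SimTruth]:
    """Trait table: target trait from planted effects, siblings, decoys.

    The target trait is sum_q sqrt(r2_q) * driver_q + noise with drivers the
    standardized marker codes or module latents named in the config; sibling
    traits share the target's systematic part (weight ``sibling_share``),
    emulating correlated fibre/lignin measures that map to the same loci;
    decoy traits are independent noise.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    gmap = genotypes.gmap
    config.validate(gmap)
    n = genotypes.n_lines
    signal = np.zeros(n)
    total_r2 = 0.0
    qtl_rows = []
    for q in config.trait_qtl:
        if q.target.startswith("module:"):
            k = int(q.target.split(":", 1)[1])
            driver = _standardize(truth.module_latents[k].to_numpy())
            hub = config.modules[k - 1].hub_marker
            row = gmap.table.iloc[gmap.marker_index(hub)]
        else:
            j = gmap.marker_index(q.target)
            driver = _standardize(genotypes.values[:, j])
            row = gmap.table.iloc[j]
        signal = signal + np.sqrt(q.r2) * driver
        total_r2 += q.r2
        qtl_rows.append(("trait", q.target, row["marker"], row["chrom"],
                         float(row["cM"]), q.r2))
    noise_scale = np.sqrt(max(1.0 - total_r2, 0.0)) * config.noise_sd
    traits = {"trait": signal + noise_scale * rng.standard_normal(n)}
    for s in range(config.n_sibling_traits):
        w = config.sibling_share
        traits[f"sibling{s + 1}"] = (w * signal
                                     + np.sqrt(max(1 - w ** 2 * total_r2, 0.0))
                                     * config.noise_sd * rng.standard_normal(n))
        for row in list(qtl_rows):
            if row[0] == "trait":
                qtl_rows.append((f"sibling{s + 1}", *row[1:5], row[5] * w ** 2))
    for d in range(config.n_decoy_traits):
        traits[f"decoy{d + 1}"] = rng.standard_normal(n)
    table = pd.DataFrame(traits, index=pd.Index(genotypes.line_ids, name="line"))
    truth.trait_qtl = pd.DataFrame(
        qtl_rows, columns=["trait", "target", "marker", "chrom", "cM", "r2"])
    return table, truth


def simulate_study(config: SimConfig):
    """One call for the full study: genotypes, map, expression, traits, truth."""
    genotypes, gmap = simulate_dh_population(config)
    expr, truth = simulate_expression(config, genotypes)
    traits, truth = simulate_traits(config, genotypes, truth)
    return genotypes, gmap, expr, traits, truth
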