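"""Synthetic multi-omic cohort generator with planted ground truth.

Emulates a surgical multi-sampling study of glioblastoma: each patient is
biopsied along a core-to-periphery axis (necrotic zone NZ, tumor zone TZ,
interface I, peripheral brain zone PBZ), plus a set of reference control
brains (REF).  The generator plants, and records as ground truth:

* a zone gradient in expression carried by co-expression modules whose
  drivers are linear in the ordinal core->periphery axis,
* a subset of genes whose promoter methylation silences expression
  (strongly negative expression/beta correlation),
* patient-shared copy-number events restricted to tumor zones, with
  near-flat profiles in peripheral and reference samples,
* a per-sample transcriptional subtype drawn from zone-dependent
  propensities and imprinted as a centroid component on a dedicated
  gene set.

Every downstream stage of the pipeline is testable against the returned
:class:`GroundTruth` without any external download.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "ZONE_AXIS",
    "SUBTYPES",
    "CHROM_LENGTHS",
    "CohortConfig",
    "GroundTruth",
    "Cohort",
    "generate_cohort",
    "generate_subtype_centroids",
    "default_probe_grid",
    "write_cohort",
]

# Ordinal core->periphery axis.  Reference brains sit just beyond the
# peripheral brain zone.
ZONE_AXIS: dict[str, float] = {"NZ": 0.0, "TZ": 1.0, "I": 2.0, "PBZ": 3.0, "REF": 3.5}

# Declared subtype order; also the deterministic tie-break order downstream.
SUBTYPES: tuple[str, ...] = ("Proneural", "Neural", "Classical", "Mesenchymal")

# GRCh37 autosome lengths (bp), used to lay out the CNA probe grid
# proportionally to physical chromosome size.
CHROM_LENGTHS: dict[int, int] = {
    1: 249250621, 2: 243199373, 3: 198022430, 4: 191154276, 5: 180915260,
    6: 171115067, 7: 159138663, 8: 146364022, 9: 141213431, 10: 135534747,
    11: 135006516, 12: 133851895, 13: 115169878, 14: 107349540, 15: 102531392,
    16: 90354753, 17: 81195210, 18: 78077248, 19: 59128983, 20: 63025520,
    21: 48129895, 22: 51304566,
}

# Module names follow the size-ordered color convention of weighted
# co-expression analysis (largest module first).
_MODULE_NAMES = ("turquoise", "blue", "brown", "yellow", "green", "red", "black")

_DEFAULT_MODULE_SIZES = (2200, 1700, 1300, 1000, 800, 600, 400)
# Signed strength of each module driver along the core->periphery axis.
# Four modules (turquoise, blue, brown, green) carry a strong zone gradient,
# the other three almost none; every module also has a zone-independent
# per-sample latent factor (its private co-expression).  Same-sign strong
# modules use different transition boundaries, and a shape is reused with
# the same sign only when at least one member is latent-dominated.
_DEFAULT_GRADIENT_STRENGTHS = (-1.2, 1.1, 1.0, -0.25, 1.05, -0.22, -0.2)
_DEFAULT_LATENT_SDS = (0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5)
_DEFAULT_DRIVER_SHAPES = ("early", "early", "mid", "mid", "late", "late",
                          "late")

# Monotone driver shapes along the core->periphery axis.  Modules respond to
# the gradient with sharp transitions at different zone boundaries (an early
# switch at the necrotic/tumor boundary, a mid one at the tumor/interface
# boundary, a late one at the infiltration margin), which is what makes
# same-direction modules distinguishable co-expression units.
_SHAPES = {
    "linear": lambda z: z,
    "early": lambda z: np.clip((z - 0.4) / 0.2, 0.0, 1.0) + 0.02 * z,
    "mid": lambda z: np.clip((z - 1.4) / 0.2, 0.0, 1.0) + 0.02 * z,
    "late": lambda z: np.clip((z - 2.4) / 0.2, 0.0, 1.0) + 0.02 * z,
}

_DEFAULT_ZONE_PROPENSITIES = {
    # Proneural, Neural, Classical, Mesenchymal
    "NZ": (0.05, 0.05, 0.40, 0.50),
    "TZ": (0.05, 0.05, 0.45, 0.45),
    "I": (0.45, 0.45, 0.05, 0.05),
    "PBZ": (0.40, 0.50, 0.05, 0.05),
    "REF": (0.10, 0.90, 0.0, 0.0),
}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study design the analysis assumes: 10 patients
    sampled in 4 zones, 4 reference brains, 12000 genes of which 7 planted
    co-expression modules, ~3% methylation-silenced genes enriched among
    high-gradient genes, and patient-shared CNA events confined to tumor
    zones.
    """

    n_patients: int = 10
    zones: tuple[str, ...] = ("NZ", "TZ", "I", "PBZ")
    n_ref: int = 4
    n_genes: int = 12000
    n_modules: int = 7
    module_sizes: tuple[int, ...] | None = None
    gradient_strengths: tuple[float, ...] | None = None
    latent_sds: tuple[float, ...] | None = None
    driver_shapes: tuple[str, ...] | None = None
    patient_intercept_sd: float = 0.15
    loading_range: tuple[float, float] = (0.8, 1.2)
    n_hub_genes: int = 25             # per-module tier of central hub genes
    hub_loading: float = 2.0
    hub_noise_sd: float = 0.2
    hub_global_strength: float = 0.3  # hub admixture of the overall gradient,
                                      # relative to the module's own strength
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    noise_sd: float = 0.35
    frac_anticorr: float = 0.03
    anticorr_slope: float = 1.2       # logistic steepness of silencing
    anticorr_beta_sd: float = 0.05    # residual SD on beta for silenced genes
    beta_background_sd: float = 0.05  # residual SD on beta for other genes
    missing_rate: float = 0.01        # fraction of beta entries masked NaN
    n_probes: int = 4000
    cna_noise_sd: float = 0.15
    cna_templates: dict | None = None  # patient -> list[(chrom, start, end, state)]
    zone_event_fraction: dict[str, float] | None = None
    n_subtypes: int = 4
    n_subtype_genes: int = 400
    subtype_strength: float = 0.6
    zone_propensities: dict[str, tuple[float, ...]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.zones:
            raise ValueError("zones list must not be empty")
        if self.module_sizes is None:
            # default sizes scale with the gene count (fractions of the
            # 12000-gene design), so small cohorts stay well formed
            scale = self.n_genes / 12000.0
            self.module_sizes = tuple(
                max(1, int(round(s * scale)))
                for s in _DEFAULT_MODULE_SIZES[: self.n_modules])
        if self.gradient_strengths is None:
            self.gradient_strengths = _DEFAULT_GRADIENT_STRENGTHS[: self.n_modules]
        if self.latent_sds is None:
            self.latent_sds = _DEFAULT_LATENT_SDS[: self.n_modules]
        if self.driver_shapes is None:
            self.driver_shapes = tuple(
                _DEFAULT_DRIVER_SHAPES[m % len(_DEFAULT_DRIVER_SHAPES)]
                for m in range(self.n_modules))
        if any(s not in _SHAPES for s in self.driver_shapes):
            raise ValueError(f"driver shapes must be among {sorted(_SHAPES)}")
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")
        if any(s < 1 for s in self.module_sizes):
            raise ValueError("module_sizes must all be >= 1")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module_sizes exceed n_genes")
        if not 0.0 <= self.frac_anticorr <= 1.0:
            raise ValueError("frac_anticorr must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.zone_event_fraction is None:
            self.zone_event_fraction = {"NZ": 1.0, "TZ": 1.0, "I": 0.6, "PBZ": 0.0, "REF": 0.0}
        if self.zone_propensities is None:
            self.zone_propensities = dict(_DEFAULT_ZONE_PROPENSITIES)

    @property
    def module_names(self) -> tuple[str, ...]:
        if self.n_modules <= len(_MODULE_NAMES):
            return _MODULE_NAMES[: self.n_modules]
        return tuple(f"module{i + 1}" for i in range(self.n_modules))


@dataclass
class GroundTruth:
    """Planted truth covering every generated gene and sample exactly once."""

    gene_module: pd.Series          # gene -> module name or "background"
    gene_anticorr: pd.Series        # gene -> bool
    gene_hub: pd.Series             # gene -> bool (module hub tier)
    gene_gradient_loading: pd.Series  # gene -> signed loading * gradient strength
    sample_zone: pd.Series          # sample -> zone
    sample_subtype: pd.Series       # sample -> subtype name
    segments: dict[str, pd.DataFrame]  # sample -> (chrom, start, end, state)
    module_drivers: pd.DataFrame    # module x sample driver values
    subtype_centroids: pd.DataFrame  # subtype gene x subtype
    zone_propensities: pd.DataFrame  # zone x subtype


@dataclass
class Cohort:
    expression: pd.DataFrame        # gene x sample, log2 scale
    methylation: pd.DataFrame       # gene x sample, beta in [0,1] with NaNs
    cna: dict[str, pd.DataFrame]    # sample -> probe track (probe, chrom, pos, log2)
    annotation: pd.DataFrame        # sample -> patient, zone
    truth: GroundTruth
    config: CohortConfig


def default_probe_grid(n_probes: int = 4000) -> pd.DataFrame:
    """Evenly spaced probe grid over the 22 autosomes, proportional to length."""
    total = sum(CHROM_LENGTHS.values())
    rows = []
    for chrom, length in CHROM_LENGTHS.items():
        k = max(2, int(round(n_probes * length / total)))
        positions = np.linspace(1, length, k, dtype=np.int64)
        for i, pos in enumerate(positions):
            rows.append((f"P{chrom:02d}_{i:04d}", chrom, int(pos)))
    grid = pd.DataFrame(rows, columns=["probe", "chrom", "pos"])
    return grid.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


# log2 ratio imprinted per copy-number state, assuming ~60% tumor purity for
# single-copy events and high-level amplification at +1.5.
_STATE_LOG2 = {-1: -0.55, 0: 0.0, 1: 0.45, 2: 1.5}


def _default_templates(config: CohortConfig, rng: np.random.Generator,
                       grid: pd.DataFrame) -> dict[str, list[tuple[int, int, int, int]]]:
    """Patient CNA templates: shared chr7 gain / chr10 loss plus 2 private events."""
    templates: dict[str, list[tuple[int, int, int, int]]] = {}
    for p in range(config.n_patients):
        patient = f"FT{p + 1:02d}"
        events = [
            (7, 1, CHROM_LENGTHS[7], +1),   # whole chr7 gain, hallmark event
            (10, 1, CHROM_LENGTHS[10], -1),  # whole chr10 loss, hallmark event
        ]
        for _ in range(2):
            chrom = int(rng.integers(1, 23))
            length = CHROM_LENGTHS[chrom]
            span = int(length * rng.uniform(0.10, 0.40))
            start = int(rng.integers(1, length - span))
            state = int(rng.choice([-1, 1, 2], p=[0.4, 0.4, 0.2]))
            events.append((chrom, start, start + span, state))
        templates[patient] = events
    return templates


def generate_subtype_centroids(
    signature_genes: list[str],
    n_subtypes: int = 4,
    seed: int = 0,
    max_pairwise_r: float = 0.3,
    zone_propensities: dict[str, tuple[float, ...]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mutually decorrelated subtype centroids over a gene list.

    Returns the centroid matrix (gene x subtype) and the per-zone subtype
    propensity table: core zones (NZ, TZ) favor Classical/Mesenchymal-like
    subtypes, peripheral zones (I, PBZ) the Neural/Proneural-like ones.
    """
    if n_subtypes < 2:
        raise ValueError("n_subtypes must be >= 2")
    if len(signature_genes) < n_subtypes:
        raise ValueError("need at least n_subtypes signature genes")
    names = list(SUBTYPES[:n_subtypes]) if n_subtypes <= len(SUBTYPES) else [
        f"S{i + 1}" for i in range(n_subtypes)
    ]
    rng = np.random.default_rng(seed)
    for _ in range(200):
        mat = rng.standard_normal((len(signature_genes), n_subtypes))
        r = np.corrcoef(mat.T)
        off = np.abs(r[~np.eye(n_subtypes, dtype=bool)])
        if off.max() < max_pairwise_r:
            break
    else:  # pragma: no cover - vanishingly unlikely for reasonable sizes
        raise RuntimeError("could not draw decorrelated centroids")
    centroids = pd.DataFrame(mat, index=pd.Index(signature_genes, name="gene"),
                             columns=names)
    prop = zone_propensities or _DEFAULT_ZONE_PROPENSITIES
    propensities = pd.DataFrame(prop).T
    propensities.columns = names
    propensities.index.name = "zone"
    return centroids, propensities


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate expression, methylation, CNA tracks, annotation and truth.

    The same config (including seed) always yields bit-identical outputs.
    """
    config = config or CohortConfig()
    ss = np.random.SeedSequence(config.seed)
    (rng_expr, rng_meth, rng_cna, rng_subtype, rng_missing) = [
        np.random.default_rng(s) for s in ss.spawn(5)
    ]

    # ---- samples ---------------------------------------------------------
    samples, patients, zones = [], [], []
    for p in range(config.n_patients):
        patient = f"FT{p + 1:02d}"
        for z in config.zones:
            samples.append(f"{patient}_{z}")
            patients.append(patient)
            zones.append(z)
    for r in range(config.n_ref):
        samples.append(f"REF{r + 1:02d}")
        patients.append(f"CTRL{r + 1:02d}")
        zones.append("REF")
    annotation = pd.DataFrame(
        {"patient": patients, "zone": zones},
        index=pd.Index(samples, name="sample"),
    )
    n_samples = len(samples)
    axis = np.array([ZONE_AXIS[z] for z in zones])

    # ---- gene bookkeeping ------------------------------------------------
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    module_of = np.full(config.n_genes, "background", dtype=object)
    pos = 0
    module_names = config.module_names
    for name, size in zip(module_names, config.module_sizes):
        module_of[pos: pos + size] = name
        pos += size
    n_module_genes = pos

    # ---- expression ------------------------------------------------------
    loadings = rng_expr.uniform(*config.loading_range, size=config.n_genes)
    baseline = rng_expr.normal(config.baseline_mean, config.baseline_sd,
                               size=config.n_genes)
    # driver_m(sample) = g_m * shaped axis + patient intercept + latent factor;
    # shapes are monotone in the axis, rescaled to the centered-axis range so
    # gradient_strengths are comparable across shapes
    drivers = np.zeros((config.n_modules, n_samples))
    patient_codes = pd.factorize(annotation["patient"])[0]
    n_units = patient_codes.max() + 1
    axis_span = axis.max() - axis.min()
    for m in range(config.n_modules):
        s = _SHAPES[config.driver_shapes[m]](axis)
        s = s - s.mean()
        s = s * (axis_span / (s.max() - s.min()))
        intercepts = rng_expr.normal(0.0, config.patient_intercept_sd, size=n_units)
        latent = (rng_expr.normal(0.0, config.latent_sds[m], size=n_samples)
                  if config.latent_sds[m] > 0 else np.zeros(n_samples))
        drivers[m] = (config.gradient_strengths[m] * s
                      + intercepts[patient_codes] + latent)

    # hub tier: the first n_hub_genes of each module are tightly regulated
    # central genes (high loading, low residual noise)
    is_hub = np.zeros(config.n_genes, dtype=bool)
    for name in module_names:
        idx = np.where(module_of == name)[0]
        is_hub[idx[: config.n_hub_genes]] = True
    loadings[is_hub] = config.hub_loading

    # hubs additionally track the overall core->periphery gradient (the
    # hallmark of key heterogeneity genes: module-central AND informative
    # for the global sample structure)
    s_lin = _SHAPES["linear"](axis)
    s_lin = s_lin - s_lin.mean()
    s_lin = s_lin * (axis_span / (s_lin.max() - s_lin.min()))

    expr = np.tile(baseline[:, None], (1, n_samples))
    grad_loading = np.zeros(config.n_genes)
    for m, name in enumerate(module_names):
        idx = np.where(module_of == name)[0]
        expr[idx] += loadings[idx, None] * drivers[m][None, :]
        grad_loading[idx] = loadings[idx] * config.gradient_strengths[m]
        g_m = config.gradient_strengths[m]
        hubs = idx[is_hub[idx]]
        if len(hubs):
            expr[hubs] += (loadings[hubs, None] * g_m
                           * config.hub_global_strength * s_lin[None, :])
            grad_loading[hubs] += (loadings[hubs] * g_m
                                   * config.hub_global_strength)
    gene_noise = np.where(is_hub, config.hub_noise_sd, config.noise_sd)
    expr += gene_noise[:, None] * rng_expr.standard_normal(expr.shape)

    # ---- subtype component ----------------------------------------------
    background_idx = np.arange(n_module_genes, config.n_genes)
    n_st_genes = min(config.n_subtype_genes, len(background_idx))
    st_gene_idx = rng_subtype.choice(background_idx, size=n_st_genes, replace=False)
    st_gene_idx.sort()
    st_genes = [genes[i] for i in st_gene_idx]
    centroids, propensities = generate_subtype_centroids(
        st_genes, config.n_subtypes,
        seed=int(rng_subtype.integers(2**31)),
        zone_propensities=config.zone_propensities,
    )
    subtype_names = list(centroids.columns)
    sample_subtype = []
    for s, z in enumerate(zones):
        p = np.asarray(propensities.loc[z], dtype=float)
        p = p / p.sum()
        k = int(rng_subtype.choice(config.n_subtypes, p=p))
        sample_subtype.append(subtype_names[k])
        expr[st_gene_idx, s] += config.subtype_strength * centroids.iloc[:, k].to_numpy()

    expression = pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=samples)

    # ---- methylation -----------------------------------------------------
    n_anti = int(round(config.frac_anticorr * config.n_genes))
    effect = np.abs(grad_loading)
    order = np.argsort(-effect, kind="mergesort")
    top_pool = order[:600][effect[order[:600]] > 0]
    rest_pool = order[600:n_module_genes]
    n_top = min(int(round(0.6 * n_anti)), len(top_pool))
    chosen = list(rng_meth.choice(top_pool, size=n_top, replace=False)) if n_top else []
    n_rest = min(n_anti - n_top, len(rest_pool))
    if n_rest > 0:
        chosen += list(rng_meth.choice(rest_pool, size=n_rest, replace=False))
    anti_idx = np.array(sorted(chosen), dtype=int)
    anticorr = np.zeros(config.n_genes, dtype=bool)
    anticorr[anti_idx] = True

    beta = np.clip(
        rng_meth.uniform(0.05, 0.95, size=config.n_genes)[:, None]
        + rng_meth.normal(0.0, config.beta_background_sd, size=expr.shape),
        0.0, 1.0,
    )
    if len(anti_idx):
        x = expr[anti_idx]
        xc = x - x.mean(axis=1, keepdims=True)
        silenced = expit(-config.anticorr_slope * xc)
        silenced += rng_meth.normal(0.0, config.anticorr_beta_sd, size=silenced.shape)
        beta[anti_idx] = np.clip(silenced, 0.0, 1.0)
    if config.missing_rate > 0:
        mask = rng_missing.random(beta.shape) < config.missing_rate
        beta[mask] = np.nan
    methylation = pd.DataFrame(beta, index=pd.Index(genes, name="gene"), columns=samples)

    # ---- CNA tracks ------------------------------------------------------
    grid = default_probe_grid(config.n_probes)
    templates = config.cna_templates or _default_templates(config, rng_cna, grid)
    chrom_arr = grid["chrom"].to_numpy()
    pos_arr = grid["pos"].to_numpy()
    cna: dict[str, pd.DataFrame] = {}
    segments: dict[str, pd.DataFrame] = {}
    for s, sample in enumerate(samples):
        patient, zone = annotation.iloc[s]
        frac = config.zone_event_fraction.get(zone, 0.0)
        events = templates.get(patient, [])
        kept = [ev for ev in events if frac >= 1.0 or rng_cna.random() < frac]
        state = np.zeros(len(grid), dtype=int)
        for chrom, start, end, st in kept:
            sel = (chrom_arr == chrom) & (pos_arr >= start) & (pos_arr <= end)
            state[sel] = st
        log2 = np.array([_STATE_LOG2[v] for v in state]) + rng_cna.normal(
            0.0, config.cna_noise_sd, size=len(grid))
        cna[sample] = pd.DataFrame({
            "probe": grid["probe"], "chrom": chrom_arr, "pos": pos_arr, "log2": log2,
        })
        segments[sample] = pd.DataFrame(kept, columns=["chrom", "start", "end", "state"])

    truth = GroundTruth(
        gene_module=pd.Series(module_of, index=genes, name="module"),
        gene_anticorr=pd.Series(anticorr, index=genes, name="anticorr"),
        gene_hub=pd.Series(is_hub, index=genes, name="hub"),
        gene_gradient_loading=pd.Series(grad_loading, index=genes, name="gradient_loading"),
        sample_zone=annotation["zone"].copy(),
        sample_subtype=pd.Series(sample_subtype, index=samples, name="subtype"),
        segments=segments,
        module_drivers=pd.DataFrame(drivers, index=list(module_names), columns=samples),
        subtype_centroids=centroids,
        zone_propensities=propensities,
    )
    return Cohort(expression, methylation, cna, annotation, truth, config)


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write the cohort as flat TSV files plus a key:value config record."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = "%.6g"
    cohort.expression.to_csv(outdir / "expression.tsv", sep="\t", float_format=fmt)
    cohort.methylation.to_csv(outdir / "methylation.tsv", sep="\t", float_format=fmt)
    cohort.annotation.to_csv(outdir / "annotation.tsv", sep="\t")
    probes = []
    for sample, track in cohort.cna.items():
        t = track.copy()
        t.insert(0, "sample", sample)
        probes.append(t)
    pd.concat(probes).to_csv(outdir / "cna_probes.tsv", sep="\t", index=False,
                             float_format=fmt)
    truth = cohort.truth
    pd.DataFrame({
        "module": truth.gene_module,
        "anticorr": truth.gene_anticorr.astype(int),
        "hub": truth.gene_hub.astype(int),
        "gradient_loading": truth.gene_gradient_loading,
    }).to_csv(outdir / "truth_genes.tsv", sep="\t", float_format=fmt)
    pd.DataFrame({
        "zone": truth.sample_zone, "subtype": truth.sample_subtype,
    }).to_csv(outdir / "truth_samples.tsv", sep="\t")
    with open(outdir / "config.txt", "w") as fh:
        for f in dataclasses.fields(cohort.config):
            fh.write(f"{f.name}:{getattr(cohort.config, f.name)}\n")
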