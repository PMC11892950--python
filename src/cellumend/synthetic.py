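"""Synthetic inputs emulating a paired litterbag / bulk-soil warming study.

Every generator is deterministic given its seed: one ``SeedSequence`` is
spawned per logical stream, so outputs never depend on call order.

The community generator produces four groups — warmed litterbag (WL),
control litterbag (CL), warmed soil (WS), control soil (CS) — of equal
size.  Litterbag and soil habitats share a configurable fraction of
their taxon sets (default 0.79, i.e. ~21% habitat-specific taxa);
abundances are Dirichlet-multinomial around a log-normal species
abundance distribution, with litterbag groups given extra within-group
heterogeneity via ``dispersion_scale``.

Forcing emulates a warming manipulation inside one field site: warmed
and control series generated from the same design share the same
weather noise, with a constant temperature offset (+1.8 °C default)
and a proportional moisture reduction (−17% default) applied to the
warmed series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mend import ForcingSeries, MendParams, MendState, simulate

__all__ = [
    "SyntheticDesign",
    "ForcingDesign",
    "EnrichmentEffect",
    "CommunityTable",
    "TraitReference",
    "ProbeTable",
    "ObservationSet",
    "gen_trait_reference",
    "gen_paired_communities",
    "gen_probe_table",
    "gen_forcing",
    "gen_observations",
    "GROUPS",
]

GROUPS = ("WL", "CL", "WS", "CS")

# default carbon-decomposition gene panel for probe simulation
DEFAULT_GENES = (
    "endoglucanase", "cellobiase", "exoglucanase", "axe",
    "amyA", "glucoamylase", "nplT", "pulA",
    "ara", "mannanase", "xylanase",
    "acetylglucosaminidase", "chitinase",
    "aceA", "aceB", "cutinase", "mnp", "glx", "phenol_oxidase", "limEH",
)
GENE_CATEGORY = {
    "endoglucanase": "cellulose", "cellobiase": "cellulose",
    "exoglucanase": "cellulose", "axe": "cellulose",
    "amyA": "starch", "glucoamylase": "starch", "nplT": "starch",
    "pulA": "starch",
    "ara": "hemicellulose", "mannanase": "hemicellulose",
    "xylanase": "hemicellulose",
    "acetylglucosaminidase": "chitin", "chitinase": "chitin",
    "aceA": "glyoxylate", "aceB": "glyoxylate",
    "cutinase": "cutin", "mnp": "lignin", "glx": "lignin",
    "phenol_oxidase": "lignin", "limEH": "terpene",
}


@dataclass(frozen=True)
class EnrichmentEffect:
    """Multiplicative fold-change planted on a taxon set in target groups."""

    taxa: tuple
    fold: float
    target: str = "litterbag"  # 'litterbag' | 'soil' | 'warmed' | group name

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold-change must be > 0")
        object.__setattr__(self, "taxa", tuple(self.taxa))

    def applies_to(self, group: str) -> bool:
        if self.target == "litterbag":
            return group in ("WL", "CL")
        if self.target == "soil":
            return group in ("WS", "CS")
        if self.target == "warmed":
            return group in ("WL", "WS")
        return group == self.target


@dataclass(frozen=True)
class SyntheticDesign:
    n_taxa: int = 500
    n_samples_per_group: int = 12
    shared_fraction: float = 0.79
    enrichment_effects: tuple = ()
    dispersion_scale: float = 1.5
    depth: int = 30236
    sad_sigma: float = 1.5      # log-normal species-abundance spread
    concentration: float = 50.0  # Dirichlet concentration (soil groups)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must lie in [0,1]")
        if self.n_taxa < 1:
            raise ValueError("need at least one taxon")
        if self.dispersion_scale <= 0:
            raise ValueError("dispersion_scale must be > 0")
        effects = tuple(
            e if isinstance(e, EnrichmentEffect) else EnrichmentEffect(*e)
            for e in self.enrichment_effects)
        object.__setattr__(self, "enrichment_effects", effects)

    @property
    def taxon_ids(self) -> list:
        return [f"zOTU{i + 1}" for i in range(self.n_taxa)]


@dataclass(frozen=True)
class ForcingDesign:
    n_days: int = 1095
    mean_temperature: float = 16.3
    seasonal_amplitude: float = 9.0
    warming_offset: float = 1.8
    moisture_mean: float = 0.25
    moisture_reduction: float = 0.17
    litter_input_mean: float = 0.005
    noise_sd: dict = field(default_factory=lambda: {
        "temperature": 1.0, "moisture": 0.02, "litter": 0.001})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.seasonal_amplitude < 0:
            raise ValueError("seasonal amplitude must be >= 0")
        if not 0.0 < self.moisture_mean <= 1.0:
            raise ValueError("moisture_mean must lie in (0,1]")
        if not 0.0 <= self.moisture_reduction < 1.0:
            raise ValueError("moisture_reduction must lie in [0,1)")
        if self.litter_input_mean < 0:
            raise ValueError("litter input must be >= 0")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise sd must be >= 0")


@dataclass
class CommunityTable:
    """Samples × taxa count table plus per-sample metadata
    (group, habitat, treatment, year, block)."""

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("abundances must be >= 0")
        if not self.counts.index.equals(self.metadata.index):
            raise ValueError("counts and metadata sample ids differ")
        if self.counts.index.has_duplicates:
            raise ValueError("duplicated sample ids")

    @property
    def samples(self) -> list:
        return list(self.counts.index)

    @property
    def taxa(self) -> list:
        return list(self.counts.columns)

    def relative(self) -> pd.DataFrame:
        tot = self.counts.sum(axis=1)
        if (tot == 0).any():
            raise ValueError("all-zero sample")
        return self.counts.div(tot, axis=0)

    def group_samples(self, group: str) -> list:
        return list(self.metadata.index[self.metadata["group"] == group])


@dataclass
class TraitReference:
    """Per-taxon genomic traits; rows only for matched taxa."""

    table: pd.DataFrame  # index taxon_id; rrn_copies, genome_size_mbp, gc_percent
    unmatched: tuple = ()

    def __post_init__(self) -> None:
        t = self.table
        required = {"rrn_copies", "genome_size_mbp", "gc_percent"}
        if not required.issubset(t.columns):
            raise ValueError(f"trait table needs columns {sorted(required)}")
        if (t["rrn_copies"] < 1).any():
            raise ValueError("rrn copies must be >= 1")
        if (t["genome_size_mbp"] <= 0).any():
            raise ValueError("genome size must be > 0")
        if ((t["gc_percent"] <= 0) | (t["gc_percent"] >= 100)).any():
            raise ValueError("GC content must lie in (0,100)")

    @property
    def matched_taxa(self) -> list:
        return list(self.table.index)


@dataclass
class ProbeTable:
    """Probes × samples intensity table with gene/category annotations.
    Zero intensity encodes non-detection."""

    intensities: pd.DataFrame  # index probe_id, columns sample ids
    annotations: pd.DataFrame  # index probe_id; columns gene, category

    def __post_init__(self) -> None:
        if (self.intensities.values < 0).any():
            raise ValueError("intensities must be >= 0")
        if not self.intensities.index.equals(self.annotations.index):
            raise ValueError("intensity and annotation probe ids differ")
        if self.annotations["gene"].isna().any():
            raise ValueError("every probe needs a gene annotation")

    @property
    def samples(self) -> list:
        return list(self.intensities.columns)

    @property
    def genes(self) -> list:
        return sorted(self.annotations["gene"].unique())


@dataclass
class ObservationSet:
    """Sparse observation series indexed by simulation day."""

    rh_days: np.ndarray
    rh: np.ndarray
    mbc_days: np.ndarray
    mbc: np.ndarray
    gene_days: np.ndarray
    gene: np.ndarray


def _streams(seed: int, n: int):
    return np.random.SeedSequence(seed).spawn(n)


def gen_trait_reference(design: SyntheticDesign, match_fraction: float = 0.2156,
                        rrn_range=(1, 15), size_range_mbp=(2.0, 9.0),
                        gc_range_pct=(30.0, 70.0)) -> TraitReference:
    """Draw genomic traits for round(match_fraction * n_taxa) taxa.

    rrn copies are integers sampled uniformly in ``rrn_range``; genome
    size and GC are uniform in their ranges.  Remaining taxa are
    reported as unmatched.
    """
    if design.n_taxa == 0:
        raise ValueError("empty taxon list")
    if not 0.0 < match_fraction <= 1.0:
        raise ValueError("match_fraction must lie in (0,1]")
    for lo, hi, name in ((rrn_range[0], rrn_range[1], "rrn_range"),
                         (size_range_mbp[0], size_range_mbp[1], "size_range"),
                         (gc_range_pct[0], gc_range_pct[1], "gc_range")):
        if lo <= 0 or hi < lo:
            raise ValueError(f"{name} must be positive and ordered")
    rng = np.random.default_rng(_streams(design.seed, 8)[0])
    taxa = design.taxon_ids
    n_match = round(match_fraction * len(taxa))
    matched = sorted(rng.choice(len(taxa), size=n_match, replace=False))
    matched_ids = [taxa[i] for i in matched]
    table = pd.DataFrame({
        "rrn_copies": rng.integers(rrn_range[0], rrn_range[1] + 1,
                                   size=n_match).astype(float),
        "genome_size_mbp": rng.uniform(*size_range_mbp, size=n_match),
        "gc_percent": rng.uniform(*gc_range_pct, size=n_match),
    }, index=pd.Index(matched_ids, name="taxon_id"))
    unmatched = tuple(t for t in taxa if t not in set(matched_ids))
    return TraitReference(table=table, unmatched=unmatched)


def _habitat_supports(design: SyntheticDesign):
    """Partition taxa so each habitat's set shares ``shared_fraction``
    of its taxa with the other habitat."""
    n = design.n_taxa
    sf = design.shared_fraction
    n_hab = int(n / (2.0 - sf)) if sf < 1 else n
    n_shared = round(sf * n_hab)
    litter = list(range(n_hab))
    soil = list(range(n_shared)) + list(range(n_hab, 2 * n_hab - n_shared))
    soil = [i for i in soil if i < n]
    return litter, soil


def gen_paired_communities(design: SyntheticDesign) -> CommunityTable:
    """Dirichlet-multinomial communities for the WL/CL/WS/CS groups."""
    if design.n_taxa < 10:
        raise ValueError("need at least 10 taxa")
    taxa = design.taxon_ids
    taxon_index = {t: i for i, t in enumerate(taxa)}
    for eff in design.enrichment_effects:
        for t in eff.taxa:
            if t not in taxon_index:
                raise ValueError(f"enrichment taxon {t!r} not in taxon list")
    ss = _streams(design.seed, 8)
    rng_base = np.random.default_rng(ss[1])
    rng_draw = np.random.default_rng(ss[2])

    base = rng_base.lognormal(mean=0.0, sigma=design.sad_sigma,
                              size=design.n_taxa)
    litter_sup, soil_sup = _habitat_supports(design)
    support = {"WL": litter_sup, "CL": litter_sup,
               "WS": soil_sup, "CS": soil_sup}

    rows, meta_rows, ids = [], [], []
    for group in GROUPS:
        mean = np.zeros(design.n_taxa)
        sup = support[group]
        mean[sup] = base[sup]
        for eff in design.enrichment_effects:
            if eff.applies_to(group):
                idx = [taxon_index[t] for t in eff.taxa]
                mean[idx] = mean[idx] * eff.fold
        mean_rel = mean / mean.sum()
        conc = design.concentration
        if group in ("WL", "CL"):
            conc = conc / design.dispersion_scale ** 2
        alpha = np.where(mean_rel > 0, mean_rel * conc, 0.0)
        for j in range(design.n_samples_per_group):
            pvec = np.zeros(design.n_taxa)
            pos = alpha > 0
            pvec[pos] = rng_draw.dirichlet(alpha[pos])
            counts = rng_draw.multinomial(design.depth, pvec)
            rows.append(counts)
            year = 2016 + j % 3
            block = j // 3 + 1
            ids.append(f"{group}_{j + 1}")
            meta_rows.append({
                "group": group,
                "habitat": "litterbag" if group in ("WL", "CL") else "soil",
                "treatment": "warmed" if group in ("WL", "WS") else "control",
                "year": year,
                "block": block,
            })
    counts = pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"),
                          columns=taxa)
    meta = pd.DataFrame(meta_rows, index=counts.index)
    return CommunityTable(counts=counts, metadata=meta)


def gen_probe_table(n_probes: int, genes=DEFAULT_GENES, groups=None,
                    detection_rate: float = 0.8, effect_map=None,
                    effect_groups=("WL", "WS"), noise_sd: float = 0.2,
                    n_samples_per_group: int = 12,
                    seed: int = 0) -> ProbeTable:
    """Log-normal probe intensities with Bernoulli detection and planted
    per-gene warming fold-changes (``effect_map``: gene -> fold applied
    to ``effect_groups``)."""
    if not 0.0 < detection_rate <= 1.0:
        raise ValueError("detection_rate must lie in (0,1]")
    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    genes = list(genes)
    effect_map = dict(effect_map or {})
    for g in effect_map:
        if g not in genes:
            raise ValueError(f"unknown gene in effect_map: {g!r}")
    if groups is None:
        groups = {g: [f"{g}_{j + 1}" for j in range(n_samples_per_group)]
                  for g in GROUPS}
    samples = [s for grp in groups.values() for s in grp]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    probe_ids = [f"probe{i + 1}" for i in range(n_probes)]
    gene_of = [genes[i % len(genes)] for i in range(n_probes)] if n_probes else []
    mu = rng.normal(loc=2.0, scale=0.5, size=n_probes)  # per-probe baseline
    cols = {}
    for gname, gsamples in groups.items():
        for s in gsamples:
            logint = mu + rng.normal(0.0, noise_sd, size=n_probes)
            if gname in effect_groups:
                for i, gn in enumerate(gene_of):
                    fold = effect_map.get(gn)
                    if fold is not None:
                        logint[i] += np.log(fold)
            inten = np.exp(logint)
            detected = rng.random(n_probes) < detection_rate
            cols[s] = np.where(detected, inten, 0.0)
    intens = pd.DataFrame(cols, index=pd.Index(probe_ids, name="probe_id"),
                          columns=samples, dtype=float)
    annot = pd.DataFrame({
        "gene": gene_of,
        "category": [GENE_CATEGORY.get(g, "other") for g in gene_of],
    }, index=intens.index)
    return ProbeTable(intensities=intens, annotations=annot)


def gen_forcing(design: ForcingDesign, warmed: bool = False) -> ForcingSeries:
    """Sinusoidal forcing with shared weather noise between the warmed
    and control arms of one design (same seed ⇒ same noise), a constant
    warming offset on temperature and a proportional moisture cut."""
    ss = _streams(design.seed, 3)
    rng_t = np.random.default_rng(ss[0])
    rng_w = np.random.default_rng(ss[1])
    rng_l = np.random.default_rng(ss[2])
    day = np.arange(design.n_days)
    temp = (design.mean_temperature
            + design.seasonal_amplitude * np.sin(2 * np.pi * day / 365.0)
            + rng_t.normal(0.0, design.noise_sd.get("temperature", 0.0),
                           design.n_days))
    if warmed:
        temp = temp + design.warming_offset
    moist = design.moisture_mean + rng_w.normal(
        0.0, design.noise_sd.get("moisture", 0.0), design.n_days)
    if warmed:
        moist = moist * (1.0 - design.moisture_reduction)
    moist = np.clip(moist, 1e-3, 1.0)
    seasonal_litter = 1.0 + 0.5 * np.sin(2 * np.pi * (day - 60) / 365.0)
    litter = design.litter_input_mean * seasonal_litter + rng_l.normal(
        0.0, design.noise_sd.get("litter", 0.0), design.n_days)
    litter = np.maximum(litter, 0.0)
    return ForcingSeries(temperature=temp, moisture=moist,
                         litter_input=litter)


def gen_observations(params: MendParams, init: MendState,
                     forcing: ForcingSeries, noise_sd_map=None,
                     seed: int = 0, rh_every: int = 1, mbc_every: int = 30,
                     gene_every: int = 90, gene_scale: float = 100.0,
                     gene_offset: float = 1.0,
                     substeps_per_day: int = 2) -> ObservationSet:
    """Model-generated observations: Rh and MBC trajectories with
    multiplicative log-normal noise, and a gene-abundance series that is
    a positive affine map of the hydrolytic enzyme pool EP2 plus
    additive noise (scaled to the signal's spread), so its noise-free
    correlation with EP2 is exactly 1."""
    noise = {"rh": 0.1, "mbc": 0.1, "gene": 0.1}
    noise.update(noise_sd_map or {})
    if any(v < 0 for v in noise.values()):
        raise ValueError("noise sd must be >= 0")
    if gene_scale <= 0:
        raise ValueError("gene_scale must be > 0")
    ss = _streams(seed, 3)
    traj = simulate(params, init, forcing, substeps_per_day=substeps_per_day)
    n = traj.n_days
    rh_days = np.arange(0, n, rh_every)
    mbc_days = np.arange(mbc_every - 1, n, mbc_every)
    gene_days = np.arange(gene_every - 1, n, gene_every)
    rh_true = traj.rh[rh_days]
    mb = traj.pool("BA") + traj.pool("BD")
    mbc_true = mb[mbc_days + 1]
    ep2 = traj.pool("EP2")[gene_days + 1]
    rng_rh = np.random.default_rng(ss[0])
    rng_mb = np.random.default_rng(ss[1])
    rng_g = np.random.default_rng(ss[2])
    rh_obs = rh_true * np.exp(rng_rh.normal(0, noise["rh"], len(rh_true)))
    mbc_obs = mbc_true * np.exp(rng_mb.normal(0, noise["mbc"], len(mbc_true)))
    gene_true = gene_scale * ep2 + gene_offset
    spread = gene_true.std()
    gene_obs = gene_true + rng_g.normal(0, noise["gene"] * spread,
                                        len(gene_true))
    return ObservationSet(rh_days=rh_days, rh=rh_obs, mbc_days=mbc_days,
                          mbc=mbc_obs, gene_days=gene_days, gene=gene_obs)
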