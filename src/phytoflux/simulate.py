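"""Synthetic two-basin datasets with full ground truth.

The generator emulates the statistical structure the analysis assumes,
at desk scale, so that every pipeline stage is testable without the cruise
data:

* two ocean basins with contrasting pigment-group profiles (NP
  dinoflagellate-dominated with low export ratio, NA diatom-dominated with
  high ratio), sampled as surface seawater over three trap deployments;
* per-sample group compositions drawn from a Dirichlet around the basin
  profile, with log-normal per-ASV propensities inside each group and
  multinomial read sampling (a two-level composition model);
* individually isolated sinking particles with low, Poisson-distributed
  phytoplankton richness, drawn from a platform-specific export pool plus
  rare "deep" taxa absent from the surface, with particle-class preferences
  expressed as enrichment of one designated ASV per class (e.g. salp
  pellets carry a designated Hacrobia ASV, aggregates a designated diatom);
* bulk trap samples containing the pooled large-particle material of their
  platform plus planted small-particle ASVs.  The rare deep tags picked up
  by individual particles are modelled as below the bulk library's
  detection limit, which is what produces particle-only ASVs;
* POC flux generated from the shared-ASV ratio statistic by a known linear
  law plus Gaussian noise, truncated at zero (truncations are logged and
  rare under the default configuration).

Every ASV receives a planted packaging label (large / small / particle-only
/ surface-only per basin) and the flux law is recorded, so recovery of each
inference stage can be scored exactly.  A fixed seed yields a byte-identical
dataset (all randomness flows through ``numpy.random.default_rng`` streams
derived from the seed).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .pigments import GROUPS
from .tables import RANKS, Dataset

log = logging.getLogger(__name__)

# (supergroup, division, class, order, family, genus) templates per group;
# the domain slot is always Eukaryota and species is "<genus>_sp.".
_GENUS_POOLS: dict[str, list[tuple[str, ...]]] = {
    "diatoms": [
        ("Stramenopiles", "Ochrophyta", "Bacillariophyta", "Chaetocerotales", "Chaetocerotaceae", "Chaetoceros"),
        ("Stramenopiles", "Ochrophyta", "Bacillariophyta", "Thalassiosirales", "Thalassiosiraceae", "Thalassiosira"),
        ("Stramenopiles", "Ochrophyta", "Bacillariophyta", "Bacillariales", "Bacillariaceae", "Pseudo-nitzschia"),
        ("Stramenopiles", "Ochrophyta", "Bacillariophyta", "Bacillariales", "Bacillariaceae", "Fragilariopsis"),
        ("Stramenopiles", "Ochrophyta", "Bacillariophyta", "Bacillariales", "Bacillariaceae", "Cylindrotheca"),
        ("Stramenopiles", "Ochrophyta", "Bacillariophyta", "Thalassiosirales", "Thalassiosiraceae", "Minidiscus"),
        ("Stramenopiles", "Ochrophyta", "Bacillariophyta", "Leptocylindrales", "Leptocylindraceae", "Leptocylindrus"),
        ("Stramenopiles", "Ochrophyta", "Bacillariophyta", "Corethrales", "Corethraceae", "Corethron"),
    ],
    "dinoflagellates": [
        ("Alveolata", "Dinoflagellata", "Dinophyceae", "Gymnodiniales", "Gymnodiniaceae", "Gymnodinium"),
        ("Alveolata", "Dinoflagellata", "Dinophyceae", "Gymnodiniales", "Gymnodiniaceae", "Gyrodinium"),
        ("Alveolata", "Dinoflagellata", "Dinophyceae", "Prorocentrales", "Prorocentraceae", "Prorocentrum"),
        ("Alveolata", "Dinoflagellata", "Dinophyceae", "Peridiniales", "Heterocapsaceae", "Heterocapsa"),
        ("Alveolata", "Dinoflagellata", "Dinophyceae", "Gymnodiniales", "Kareniaceae", "Karenia"),
        ("Alveolata", "Dinoflagellata", "Dinophyceae", "Gonyaulacales", "Goniodomataceae", "Alexandrium"),
        ("Alveolata", "Dinoflagellata", "Dinophyceae", "Peridiniales", "Thoracosphaeraceae", "Scrippsiella"),
        ("Alveolata", "Dinoflagellata", "Dinophyceae", "Gonyaulacales", "Ceratiaceae", "Tripos"),
    ],
    "hacrobia": [
        ("Hacrobia", "Haptophyta", "Prymnesiophyceae", "Phaeocystales", "Phaeocystaceae", "Phaeocystis"),
        ("Hacrobia", "Haptophyta", "Prymnesiophyceae", "Prymnesiales", "Chrysochromulinaceae", "Chrysochromulina"),
        ("Hacrobia", "Haptophyta", "Prymnesiophyceae", "Isochrysidales", "Noelaerhabdaceae", "Emiliania"),
        ("Hacrobia", "Haptophyta", "Prymnesiophyceae", "Isochrysidales", "Noelaerhabdaceae", "Gephyrocapsa"),
        ("Hacrobia", "Cryptophyta", "Cryptophyceae", "Pyrenomonadales", "Geminigeraceae", "Plagioselmis"),
        ("Hacrobia", "Cryptophyta", "Cryptophyceae", "Pyrenomonadales", "Geminigeraceae", "Teleaulax"),
        ("Hacrobia", "Cryptophyta", "Cryptophyceae", "Pyrenomonadales", "Geminigeraceae", "Geminigera"),
    ],
    "chlorophytes": [
        ("Archaeplastida", "Chlorophyta", "Mamiellophyceae", "Mamiellales", "Bathycoccaceae", "Bathycoccus"),
        ("Archaeplastida", "Chlorophyta", "Mamiellophyceae", "Mamiellales", "Mamiellaceae", "Micromonas"),
        ("Archaeplastida", "Chlorophyta", "Mamiellophyceae", "Mamiellales", "Bathycoccaceae", "Ostreococcus"),
        ("Archaeplastida", "Chlorophyta", "Chloropicophyceae", "Chloropicales", "Chloropicaceae", "Chloroparvula"),
        ("Archaeplastida", "Chlorophyta", "Chloropicophyceae", "Chloropicales", "Chloropicaceae", "Chloropicon"),
        ("Archaeplastida", "Chlorophyta", "Pyramimonadophyceae", "Pyramimonadales", "Pyramimonadaceae", "Pyramimonas"),
    ],
    "dictyo_pelago": [
        ("Stramenopiles", "Ochrophyta", "Dictyochophyceae", "Dictyochales", "Dictyochaceae", "Dictyocha"),
        ("Stramenopiles", "Ochrophyta", "Dictyochophyceae", "Florenciellales", "Florenciellaceae", "Florenciella"),
        ("Stramenopiles", "Ochrophyta", "Pelagophyceae", "Pelagomonadales", "Pelagomonadaceae", "Pelagomonas"),
        ("Stramenopiles", "Ochrophyta", "Pelagophyceae", "Pelagomonadales", "Pelagomonadaceae", "Aureococcus"),
    ],
    "other_ochrophyta": [
        ("Stramenopiles", "Ochrophyta", "Chrysophyceae", "Chromulinales", "Chromulinaceae", "Ochromonas"),
        ("Stramenopiles", "Ochrophyta", "Chrysophyceae", "Chromulinales", "Dinobryaceae", "Dinobryon"),
        ("Stramenopiles", "Ochrophyta", "Bolidophyceae", "Parmales", "Triparmaceae", "Triparma"),
    ],
    "other_photo": [
        ("Rhizaria", "Cercozoa", "Chlorarachniophyceae", "Chlorarachniales", "Chlorarachniaceae", "Bigelowiella"),
        ("Rhizaria", "Cercozoa", "Chlorarachniophyceae", "Chlorarachniales", "Chlorarachniaceae", "Chlorarachnion"),
        ("Hacrobia", "Haptophyta", "Rappemonadea", "Rappemonadales", "Rappemonadaceae", "Rappemonas"),
        ("Archaeplastida", "Rhodophyta", "Rhodellophyceae", "Rhodellales", "Rhodellaceae", "Rhodella"),
    ],
}

_HETERO_POOL = [
    ("Alveolata", "Ciliophora", "Spirotrichea", "Choreotrichida", "Strombidiidae", "Strombidium"),
    ("Alveolata", "Ciliophora", "Spirotrichea", "Oligotrichida", "Tontoniidae", "Tontonia"),
    ("Rhizaria", "Radiolaria", "Polycystinea", "Collodaria", "Collosphaeridae", "Collozoum"),
    ("Opisthokonta", "Metazoa", "Arthropoda", "Calanoida", "Calanidae", "Calanus"),
    ("Opisthokonta", "Metazoa", "Arthropoda", "Cyclopoida", "Oithonidae", "Oithona"),
    ("Stramenopiles", "Sagenista", "Labyrinthulea", "Thraustochytrida", "Thraustochytriaceae", "Aplanochytrium"),
    ("Hacrobia", "Katablepharidophyta", "Katablepharidaceae", "Katablepharidales", "Katablepharidaceae_X", "Leucocryptos"),
]

_PARASITE_POOL = [
    ("Alveolata", "Dinoflagellata", "Syndiniales", "Dino-Group-II", "Dino-Group-II_X", "Amoebophrya"),
    ("Alveolata", "Dinoflagellata", "Syndiniales", "Dino-Group-I", "Dino-Group-I_X", "Euduboscquella"),
    ("Alveolata", "Dinoflagellata", "Syndiniales", "Syndiniales_X", "Syndiniaceae", "Syndinium"),
]

_LIGHT_LEVELS = ("100pct", "0.1pct", "0.01pct")


def _default_platforms() -> dict[str, tuple[tuple[int, str, float], ...]]:
    """(deployment, platform id, depth) per basin: STT arrays at five depths
    in both basins, NBSTs at a subset of depths in the NP."""
    stt = (95.0, 145.0, 195.0, 330.0, 500.0)
    np_platforms = []
    for dep in (1, 2, 3):
        np_platforms += [(dep, f"STT-{int(z)}", z) for z in stt]
    np_platforms += [(1, f"NBST-{int(z)}", z) for z in (95.0, 150.0, 195.0, 330.0, 500.0)]
    for dep in (2, 3):
        np_platforms += [(dep, f"NBST-{int(z)}", z) for z in (95.0, 195.0, 330.0, 500.0)]
    na_platforms = []
    for dep in (1, 2, 3):
        na_platforms += [(dep, f"STT-{int(z)}", z) for z in stt]
    return {"NP": tuple(np_platforms), "NA": tuple(na_platforms)}


@dataclasses.dataclass
class GeneratorConfig:
    """All tunable knobs of the synthetic-data generator.

    The defaults define the study conditions: 54 surface samples per basin
    (3 deployments x 6 days x 3 light depths), 28 NP + 15 NA bulk trap
    samples, ~11 particles per NP platform and ~30 per NA platform, mean
    per-particle phytoplankton richness 8 (NP) and 14 (NA), and the flux
    law flux = 3.4 x + 0.47 with homoscedastic Gaussian noise.
    """

    seed: int = 0
    n_asvs_per_group: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"diatoms": 40, "dinoflagellates": 40,
                                 "hacrobia": 28, "chlorophytes": 20,
                                 "dictyo_pelago": 14, "other_ochrophyta": 10,
                                 "other_photo": 12})
    n_deep_asvs_per_group: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"diatoms": 24, "dinoflagellates": 24,
                                 "hacrobia": 16, "chlorophytes": 12,
                                 "dictyo_pelago": 8, "other_ochrophyta": 6,
                                 "other_photo": 8})
    n_hetero_asvs: int = 40
    n_parasite_asvs: int = 12
    propensity_sigma: float = 0.5
    basin_profiles: Mapping[str, tuple[float, ...]] = dataclasses.field(
        default_factory=lambda: {
            "NP": (0.18, 0.42, 0.13, 0.12, 0.08, 0.03, 0.04),
            "NA": (0.35, 0.22, 0.10, 0.12, 0.11, 0.05, 0.05)})
    dirichlet_scale: float = 70.0
    basin_overlap: float = 0.85
    deployments: tuple[int, ...] = (1, 2, 3)
    surface_days: int = 6
    surface_depths: tuple[float, ...] = (5.0, 25.0, 50.0)
    surface_reads_mean: float = 20000.0
    surface_reads_sigma: float = 0.2
    hetero_read_fraction: float = 0.3
    platforms: Mapping[str, tuple[tuple[int, str, float], ...]] = dataclasses.field(
        default_factory=_default_platforms)
    particles_per_platform: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"NP": 11, "NA": 30})
    particle_richness_mean: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"NP": 8.0, "NA": 14.0})
    particle_reads_mean: float = 15000.0
    particle_reads_sigma: float = 0.15
    particle_hetero_fraction: float = 0.25
    particle_deep_fraction: float = 0.35
    particle_class_probs: Mapping[str, Mapping[str, float]] = dataclasses.field(
        default_factory=lambda: {
            "NP": {"salp_pellet": 0.20, "aggregate_dense_detritus": 0.30,
                   "long_loose_pellet": 0.25, "short_pellet": 0.25},
            "NA": {"aggregate_dense_detritus": 0.35,
                   "long_loose_pellet": 0.35, "short_pellet": 0.30}})
    particle_class_preferences: Mapping[str, Mapping[str, float]] = dataclasses.field(
        default_factory=lambda: {
            "salp_pellet": {"hacrobia": 4.0},
            "aggregate_dense_detritus": {"diatoms": 3.0},
            "long_loose_pellet": {"diatoms": 3.0}})
    p_export_large: float = 0.45
    p_export_small: float = 0.20
    #: tempering exponent on surface abundance when drawing particle
    #: contents; < 1 keeps particles from being dominated by the few most
    #: abundant surface taxa
    export_weight_exponent: float = 0.35
    platform_occupancy: float = 0.8
    small_platform_occupancy: float = 0.7
    small_reads_mean: float = 200.0
    flux_slope: float = 3.4
    flux_intercept: float = 0.47
    flux_noise_sd: float = 0.7
    detection_completeness: float = 1.0

    def __post_init__(self) -> None:
        for basin, prof in self.basin_profiles.items():
            prof = np.asarray(prof, dtype=float)
            if len(prof) != len(GROUPS) or (prof <= 0).any():
                raise ValueError(f"basin {basin}: profile must be {len(GROUPS)} "
                                 "positive Dirichlet concentrations")
        if not 0.0 <= self.detection_completeness <= 1.0:
            raise ValueError("detection_completeness must lie in [0, 1]")
        if self.flux_noise_sd < 0:
            raise ValueError("flux_noise_sd must be >= 0")
        for cls, prefs in self.particle_class_preferences.items():
            for g in prefs:
                if g not in GROUPS:
                    raise ValueError(f"class preference for unknown group {g!r}")
        if self.surface_reads_mean <= 0 or self.particle_reads_mean <= 0:
            raise ValueError("read totals must be positive")


def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    return dataclasses.replace(GeneratorConfig(seed=seed), **overrides)


@dataclasses.dataclass
class GroundTruth:
    """Everything needed to score each inference stage exactly."""

    #: per basin: planted packaging label per detected ASV
    packaging: dict[str, pd.Series]
    #: per bulk sample: ratio x, noiseless linear flux, realised flux, truncation flag
    flux: pd.DataFrame
    flux_law: tuple[float, float, float]
    profiles: dict[str, np.ndarray]
    #: per basin: latent Dirichlet group fractions of each surface sample
    surface_group_fractions: dict[str, pd.DataFrame]
    n_truncated: int = 0


# ---------------------------------------------------------------------------
# universe construction

@dataclasses.dataclass
class _Universe:
    taxonomy: pd.DataFrame
    asv_ids: np.ndarray          # in column order of the count matrix
    group_idx: np.ndarray        # index into GROUPS, -1 for non-photosynthetic
    pool: np.ndarray             # 'surface' | 'deep' | 'hetero' | 'parasite'
    propensity: np.ndarray


def _build_universe(cfg: GeneratorConfig, rng: np.random.Generator) -> _Universe:
    rows, groups, pools = [], [], []
    def add(template, pool, gidx):
        sup, div, cls, order, fam, genus = template
        rows.append(("Eukaryota", sup, div, cls, order, fam, genus,
                     f"{genus}_sp."))
        groups.append(gidx)
        pools.append(pool)

    for gi, g in enumerate(GROUPS):
        pool_templates = _GENUS_POOLS[g]
        for k in range(cfg.n_asvs_per_group[g]):
            add(pool_templates[k % len(pool_templates)], "surface", gi)
    for gi, g in enumerate(GROUPS):
        pool_templates = _GENUS_POOLS[g]
        for k in range(cfg.n_deep_asvs_per_group[g]):
            add(pool_templates[k % len(pool_templates)], "deep", gi)
    for k in range(cfg.n_hetero_asvs):
        add(_HETERO_POOL[k % len(_HETERO_POOL)], "hetero", -1)
    for k in range(cfg.n_parasite_asvs):
        add(_PARASITE_POOL[k % len(_PARASITE_POOL)], "parasite", -1)

    n = len(rows)
    asv_ids = np.array([f"asv{i:04d}" for i in range(n)])
    taxonomy = pd.DataFrame(rows, index=asv_ids, columns=list(RANKS))
    taxonomy.index.name = "asv_id"
    return _Universe(taxonomy=taxonomy, asv_ids=asv_ids,
                     group_idx=np.array(groups), pool=np.array(pools),
                     propensity=rng.lognormal(0.0, cfg.propensity_sigma, size=n))


def _active_masks(cfg: GeneratorConfig, uni: _Universe,
                  rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-basin activity of surface-pool and deep-pool photosynthetic ASVs
    (every basin keeps at least two active ASVs per group per pool)."""
    masks = {}
    for basin in sorted(cfg.basin_profiles):
        active = np.ones(len(uni.asv_ids), dtype=bool)
        photo = uni.group_idx >= 0
        active[photo] = rng.random(photo.sum()) < cfg.basin_overlap
        for pool in ("surface", "deep"):
            for gi in range(len(GROUPS)):
                members = np.flatnonzero(photo & (uni.pool == pool) &
                                         (uni.group_idx == gi))
                if len(members) and active[members].sum() < 2:
                    top = members[np.argsort(uni.propensity[members])[::-1][:2]]
                    active[top] = True
        masks[basin] = active
    return masks


# ---------------------------------------------------------------------------
# surface sampling

def _surface_sample_ids(cfg: GeneratorConfig, basin: str) -> list[tuple[str, int, int, float]]:
    out = []
    for dep in cfg.deployments:
        for day in range(1, cfg.surface_days + 1):
            for zi, z in enumerate(cfg.surface_depths):
                sid = f"{basin}-SURF-D{dep}-T{day:02d}-{int(z):03d}m"
                out.append((sid, dep, zi, z))
    return out


def _generate_surface(cfg: GeneratorConfig, uni: _Universe,
                      active: dict[str, np.ndarray],
                      rng: np.random.Generator):
    """Surface count block per basin plus the latent group fractions."""
    n_asv = len(uni.asv_ids)
    counts, meta = {}, {}
    latent = {}
    hetero = np.flatnonzero(uni.pool == "hetero")
    para = np.flatnonzero(uni.pool == "parasite")
    w_het = uni.propensity[hetero] / uni.propensity[hetero].sum()
    w_par = uni.propensity[para] / uni.propensity[para].sum()
    for basin in sorted(cfg.basin_profiles):
        prof = np.asarray(cfg.basin_profiles[basin], dtype=float)
        prof = prof / prof.sum()
        conc = prof * cfg.dirichlet_scale
        act = active[basin]
        group_members, group_weights = [], []
        for gi in range(len(GROUPS)):
            members = np.flatnonzero((uni.pool == "surface") &
                                     (uni.group_idx == gi) & act)
            w = uni.propensity[members]
            group_members.append(members)
            group_weights.append(w / w.sum())
        rows, ids, fracs = [], [], []
        for sid, dep, zi, z in _surface_sample_ids(cfg, basin):
            g = rng.dirichlet(conc)
            p = np.zeros(n_asv)
            for gi in range(len(GROUPS)):
                p[group_members[gi]] = g[gi] * group_weights[gi]
            p *= (1.0 - cfg.hetero_read_fraction)
            p[hetero] = cfg.hetero_read_fraction * 0.8 * w_het
            p[para] = cfg.hetero_read_fraction * 0.2 * w_par
            reads = int(round(np.exp(rng.normal(np.log(cfg.surface_reads_mean),
                                                cfg.surface_reads_sigma))))
            if reads <= 0:
                raise ValueError("infeasible config: zero surface reads")
            rows.append(rng.multinomial(reads, p / p.sum()))
            ids.append(sid)
            fracs.append(g)
            meta[sid] = {"basin": basin, "sample_type": "surface",
                         "depth_m": z, "deployment": dep, "platform": "",
                         "particle_class": "none",
                         "light_level": _LIGHT_LEVELS[zi]}
        counts[basin] = (ids, np.array(rows, dtype=np.int64))
        latent[basin] = pd.DataFrame(fracs, index=ids, columns=list(GROUPS))
    return counts, meta, latent


# ---------------------------------------------------------------------------
# export, particles and bulk

def _designated_preference_asvs(cfg: GeneratorConfig, uni: _Universe,
                                large_asvs: np.ndarray, abund: np.ndarray
                                ) -> dict[str, dict[int, float]]:
    """Per particle class, the designated ASV(s) and their multiplier.

    For each (class, group) preference the designated ASV is a top-abundance
    planted-large ASV of that group; classes sharing a group designate
    different ASVs (e.g. aggregates get the top diatom, long pellets the
    second), mirroring class-specific indicator taxa."""
    taken: dict[int, int] = {}
    out: dict[str, dict[int, float]] = {}
    for cls in sorted(cfg.particle_class_preferences):
        prefs = cfg.particle_class_preferences[cls]
        out[cls] = {}
        for g in sorted(prefs):
            gi = GROUPS.index(g)
            members = large_asvs[uni.group_idx[large_asvs] == gi]
            if len(members) == 0:
                continue
            order = members[np.argsort(abund[members])[::-1]]
            k = taken.get(gi, 0)
            asv = int(order[min(k, len(order) - 1)])
            taken[gi] = k + 1
            out[cls][asv] = float(prefs[g])
    return out


def _generate_traps(cfg: GeneratorConfig, uni: _Universe,
                    active: dict[str, np.ndarray],
                    surface_counts: dict, rng: np.random.Generator,
                    det_rng: np.random.Generator):
    """Particles, bulk samples and planted packaging labels per basin."""
    n_asv = len(uni.asv_ids)
    hetero = np.flatnonzero(uni.pool == "hetero")
    w_het_all = uni.propensity[hetero] / uni.propensity[hetero].sum()

    particle_rows, particle_meta = [], {}
    bulk_rows, bulk_meta = [], {}
    packaging: dict[str, pd.Series] = {}

    for basin in sorted(cfg.basin_profiles):
        act = active[basin]
        ids, rows = surface_counts[basin]
        abund = rows.sum(axis=0).astype(float)

        surface_pool = np.flatnonzero((uni.pool == "surface") & act & (abund > 0))
        deep_pool = np.flatnonzero((uni.pool == "deep") & act)

        # planted export labels, weighted toward abundant surface taxa
        order = np.argsort(np.argsort(abund[surface_pool]))
        pct = (order + 0.5) / len(surface_pool)
        p_large = np.clip(cfg.p_export_large * (0.25 + 1.5 * pct), 0.0, 0.95)
        is_large = rng.random(len(surface_pool)) < p_large
        is_small = (~is_large) & (rng.random(len(surface_pool)) < cfg.p_export_small)
        large_asvs = surface_pool[is_large]
        small_asvs = surface_pool[is_small]
        if len(large_asvs) == 0:
            raise ValueError(f"basin {basin}: no large-export ASVs planted; "
                             "config is infeasible")

        platforms = cfg.platforms[basin]
        # platform membership of each large ASV (each on >= 1 platform)
        membership = rng.random((len(large_asvs), len(platforms))) < cfg.platform_occupancy
        for i in np.flatnonzero(~membership.any(axis=1)):
            membership[i, rng.integers(len(platforms))] = True
        designated = _designated_preference_asvs(cfg, uni, large_asvs, abund)
        # class-indicator taxa are present across all platforms
        for prefs in designated.values():
            for asv in prefs:
                membership[np.flatnonzero(large_asvs == asv), :] = True

        class_names = sorted(cfg.particle_class_probs[basin])
        class_p = np.array([cfg.particle_class_probs[basin][c] for c in class_names])
        class_p = class_p / class_p.sum()
        mean_rich = cfg.particle_richness_mean[basin]

        basin_particle_index: dict[int, list[int]] = {}  # asv -> row positions
        pooled = {}
        for pi, (dep, platform, depth) in enumerate(platforms):
            pool_idx = large_asvs[membership[:, pi]]
            if len(pool_idx) < 3:
                extra = large_asvs[np.argsort(abund[large_asvs])[::-1][:3]]
                pool_idx = np.unique(np.concatenate([pool_idx, extra]))
            pooled_counts = np.zeros(n_asv, dtype=np.int64)
            n_particles = cfg.particles_per_platform[basin]
            for k in range(n_particles):
                cls = class_names[rng.choice(len(class_names), p=class_p)]
                k_total = 1 + rng.poisson(max(mean_rich - 1.0, 0.0))
                k_deep = min(rng.binomial(k_total, cfg.particle_deep_fraction),
                             len(deep_pool))
                k_exp = min(k_total - k_deep, len(pool_idx))
                w = abund[pool_idx] ** cfg.export_weight_exponent
                for asv, mult in designated.get(cls, {}).items():
                    w[pool_idx == asv] *= mult
                members_e = rng.choice(pool_idx, size=max(k_exp, 1),
                                       replace=False, p=w / w.sum())
                if k_deep > 0:
                    wd = uni.propensity[deep_pool]
                    members_d = rng.choice(deep_pool, size=k_deep,
                                           replace=False, p=wd / wd.sum())
                else:
                    members_d = np.array([], dtype=int)
                het_members = rng.choice(hetero, size=min(3, len(hetero)),
                                         replace=False, p=w_het_all)
                # within-particle composition
                we = abund[members_e] ** cfg.export_weight_exponent
                for asv, mult in designated.get(cls, {}).items():
                    we[members_e == asv] *= mult
                wd = uni.propensity[members_d] * 0.1 * (we.mean() /
                        max(uni.propensity[members_d].mean(), 1e-12)) \
                    if len(members_d) else np.array([])
                members = np.concatenate([members_e, members_d])
                wp = np.concatenate([we, wd])
                wp = wp / wp.sum() * (1.0 - cfg.particle_hetero_fraction)
                wh = np.full(len(het_members),
                             cfg.particle_hetero_fraction / max(len(het_members), 1))
                reads = int(round(np.exp(rng.normal(
                    np.log(cfg.particle_reads_mean), cfg.particle_reads_sigma))))
                draw = rng.multinomial(reads, np.concatenate([wp, wh]) /
                                       (wp.sum() + wh.sum()))
                row = np.zeros(n_asv, dtype=np.int64)
                np.add.at(row, np.concatenate([members, het_members]), draw)
                sid = f"{basin}-PTCL-D{dep}-{platform}-p{k:03d}"
                particle_meta[sid] = {"basin": basin, "sample_type": "particle",
                                      "depth_m": depth, "deployment": dep,
                                      "platform": platform,
                                      "particle_class": cls,
                                      "light_level": ""}
                row_pos = len(particle_rows)
                particle_rows.append((sid, row))
                for asv in members:
                    basin_particle_index.setdefault(int(asv), []).append(row_pos)
                # bulk pools the platform's large-particle material
                # (deep tags stay below the bulk detection limit)
                np.add.at(pooled_counts, np.concatenate([members_e, het_members]),
                          draw[np.concatenate([np.arange(len(members_e)),
                                               np.arange(len(members), len(members) + len(het_members))])])
            pooled[pi] = pooled_counts

        # a planted-large ASV the picked particles never captured cannot be
        # told apart from small-particle export even with perfect detection:
        # demote it to a planted small-particle ASV (it still reaches bulk)
        seen = np.zeros(n_asv, dtype=bool)
        for sid, row in particle_rows:
            if sid.startswith(basin):
                seen |= row > 0
        captured = seen[large_asvs]
        if not captured.all():
            small_asvs = np.sort(np.concatenate(
                [small_asvs, large_asvs[~captured]]))
            large_asvs = large_asvs[captured]

        # detection thinning: with completeness c each exported ASV is
        # captured by the picked particles with probability c; the shared
        # uniforms make datasets at c' < c nested within those at c.
        u = det_rng.random(n_asv)
        removed = np.zeros(n_asv, dtype=bool)
        removed[large_asvs] = u[large_asvs] >= cfg.detection_completeness
        if removed.any():
            for sid, row in particle_rows:
                if sid.startswith(basin):
                    row[removed] = 0

        # bulk samples: pooled large material + planted small-particle ASVs
        small_presence = rng.random((len(small_asvs), len(platforms))) < \
            cfg.small_platform_occupancy
        for i in np.flatnonzero(~small_presence.any(axis=1)):
            small_presence[i, rng.integers(len(platforms))] = True
        if len(small_asvs):
            w_small = abund[small_asvs] / max(abund[small_asvs].mean(), 1e-12)
        for pi, (dep, platform, depth) in enumerate(platforms):
            row = pooled[pi].copy()
            if len(small_asvs):
                here = np.flatnonzero(small_presence[:, pi])
                lam = cfg.small_reads_mean * w_small[here]
                row[small_asvs[here]] += 1 + rng.poisson(lam)
            sid = f"{basin}-BULK-D{dep}-{platform}"
            bulk_meta[sid] = {"basin": basin, "sample_type": "bulk_trap",
                              "depth_m": depth, "deployment": dep,
                              "platform": platform, "particle_class": "none",
                              "light_level": ""}
            bulk_rows.append((sid, row))

        # planted labels over the basin's detected ASV universe
        surf_present = abund > 0
        deep_drawn = np.zeros(n_asv, dtype=bool)
        for asv in basin_particle_index:
            if uni.pool[asv] == "deep":
                deep_drawn[asv] = True
        labels = {}
        for asv in large_asvs:
            labels[uni.asv_ids[asv]] = "large_particle"
        for asv in small_asvs:
            labels[uni.asv_ids[asv]] = "small_particle_only"
        for asv in np.flatnonzero(deep_drawn):
            labels[uni.asv_ids[asv]] = "particle_only"
        exported = set(large_asvs) | set(small_asvs)
        for asv in surface_pool:
            if asv not in exported:
                labels[uni.asv_ids[asv]] = "surface_only"
        packaging[basin] = pd.Series(labels, name="packaging").sort_index()

    return particle_rows, particle_meta, bulk_rows, bulk_meta, packaging


# ---------------------------------------------------------------------------
# flux

def _ratio_from_rows(cfg, uni, bulk_rows, masks) -> pd.Series:
    """The shared-mask ratio statistic, computed on the generator's own
    arrays with the same definition as :mod:`phytoflux.fluxmodel` (asserted
    equivalent in the test suite)."""
    gi_num = [GROUPS.index(g) for g in ("diatoms", "hacrobia")]
    x = {}
    for sid, row in bulk_rows:
        basin = sid.split("-")[0]
        mask = masks[basin]
        in_num = np.isin(uni.group_idx, gi_num) & mask
        in_den = (uni.group_idx >= 0) & ~np.isin(uni.group_idx, gi_num) & mask
        num = row[in_num].sum()
        den = row[in_den].sum()
        x[sid] = num / den if den > 0 else np.nan
    return pd.Series(x).sort_index()


def generate_dataset(config: GeneratorConfig | None = None,
                     seed: int | None = None) -> tuple[Dataset, GroundTruth]:
    """Generate a complete synthetic dataset plus its ground truth.

    A fixed config (including its seed) yields a byte-identical dataset.
    """
    cfg = config if config is not None else GeneratorConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    rng_uni = np.random.default_rng([cfg.seed, 11])
    rng_surf = np.random.default_rng([cfg.seed, 22])
    rng_trap = np.random.default_rng([cfg.seed, 33])
    rng_flux = np.random.default_rng([cfg.seed, 44])
    rng_det = np.random.default_rng([cfg.seed, 55])

    uni = _build_universe(cfg, rng_uni)
    active = _active_masks(cfg, uni, rng_uni)
    surface_counts, surface_meta, latent = _generate_surface(
        cfg, uni, active, rng_surf)
    (particle_rows, particle_meta, bulk_rows, bulk_meta,
     packaging) = _generate_traps(cfg, uni, active, surface_counts,
                                  rng_trap, rng_det)

    # assemble the count matrix
    all_ids, all_rows, meta = [], [], {}
    for basin in sorted(surface_counts):
        ids, rows = surface_counts[basin]
        all_ids += ids
        all_rows += list(rows)
    meta.update(surface_meta)
    for sid, row in bulk_rows:
        all_ids.append(sid)
        all_rows.append(row)
    meta.update(bulk_meta)
    for sid, row in particle_rows:
        all_ids.append(sid)
        all_rows.append(row)
    meta.update(particle_meta)

    counts = pd.DataFrame(np.vstack(all_rows), index=all_ids,
                          columns=uni.asv_ids)
    counts.index.name = "sample_id"
    counts = counts.sort_index(axis=0).sort_index(axis=1)
    samples = pd.DataFrame.from_dict(meta, orient="index").sort_index()
    samples.index.name = "sample_id"
    samples["deployment"] = samples["deployment"].astype(int)
    samples["depth_m"] = samples["depth_m"].astype(float)

    # shared-ASV masks (photosynthetic only) for the flux law
    masks = {}
    photo = uni.group_idx >= 0
    for basin in sorted(cfg.basin_profiles):
        surf = np.zeros(len(uni.asv_ids), dtype=bool)
        sink = np.zeros(len(uni.asv_ids), dtype=bool)
        _, rows = surface_counts[basin]
        surf |= rows.sum(axis=0) > 0
        for sid, row in bulk_rows + particle_rows:
            if sid.startswith(basin):
                sink |= row > 0
        masks[basin] = surf & sink & photo

    x = _ratio_from_rows(cfg, uni, bulk_rows, masks)
    linear = cfg.flux_slope * x + cfg.flux_intercept
    noise = rng_flux.normal(0.0, cfg.flux_noise_sd, size=len(x))
    y = linear + noise
    truncated = y < 0
    n_trunc = int(truncated.sum())
    if n_trunc:
        log.info("truncated %d negative synthetic flux value(s) at zero", n_trunc)
    y = np.where(truncated, 0.0, y)
    flux = pd.DataFrame({"poc_flux": y,
                         "flux_uncertainty": cfg.flux_noise_sd},
                        index=x.index)
    flux.index.name = "sample_id"

    taxonomy = uni.taxonomy.sort_index()
    dataset = Dataset(counts=counts, taxonomy=taxonomy, samples=samples,
                      flux=flux)
    truth = GroundTruth(
        packaging=packaging,
        flux=pd.DataFrame({"x": x, "linear_flux": linear,
                           "poc_flux": y, "truncated": truncated},
                          index=x.index),
        flux_law=(cfg.flux_slope, cfg.flux_intercept, cfg.flux_noise_sd),
        profiles={b: np.asarray(p, dtype=float) / np.sum(p)
                  for b, p in cfg.basin_profiles.items()},
        surface_group_fractions=latent,
        n_truncated=n_trunc,
    )
    return dataset, truth


def generate_surface_only(config: GeneratorConfig | None = None,
                          seed: int | None = None
                          ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Surface seawater samples only (counts, sample metadata, taxonomy).

    Used for calibration studies that need many cheap replicates, e.g.
    null-distribution checks of the basin PERMANOVA.
    """
    cfg = config if config is not None else GeneratorConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    rng_uni = np.random.default_rng([cfg.seed, 11])
    rng_surf = np.random.default_rng([cfg.seed, 22])
    uni = _build_universe(cfg, rng_uni)
    active = _active_masks(cfg, uni, rng_uni)
    surface_counts, surface_meta, _ = _generate_surface(cfg, uni, active,
                                                        rng_surf)
    all_ids, all_rows = [], []
    for basin in sorted(surface_counts):
        ids, rows = surface_counts[basin]
        all_ids += ids
        all_rows += list(rows)
    counts = pd.DataFrame(np.vstack(all_rows), index=all_ids,
                          columns=uni.asv_ids).sort_index(axis=0)
    counts.index.name = "sample_id"
    samples = pd.DataFrame.from_dict(surface_meta, orient="index").sort_index()
    samples.index.name = "sample_id"
    return counts, samples, uni.taxonomy.sort_index()


def write_simulation(dataset: Dataset, truth: GroundTruth, directory) -> None:
    """Write the four dataset TSVs plus the ground-truth packaging table."""
    from pathlib import Path

    from .tables import write_dataset
    write_dataset(dataset, directory)
    rows = []
    for basin in sorted(truth.packaging):
        for asv, label in truth.packaging[basin].items():
            rows.append({"basin": basin, "asv_id": asv, "packaging": label})
    gt = pd.DataFrame(rows)
    gt.to_csv(Path(directory) / "ground_truth.tsv", sep="\t", index=False)
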