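"""Three-pool ASV sharing structure and particle-packaging inference.

Within a basin, phytoplankton ASVs are pooled by sample type (surface
seawater, bulk trap collections, individually isolated >300 um particles;
presence = at least one read in at least one sample of that type), yielding
a seven-region Venn partition of the detected ASV universe.

Packaging inference follows the trap-pairing rule: an ASV found in a bulk
trap sample and in at least one individual particle isolated from the same
trap platform (same deployment, same platform id) was packaged in a large
(>300 um) particle; an ASV found in bulk samples but in no same-platform
particle is assumed packaged in particles too small to isolate.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .pigments import GROUPS

log = logging.getLogger(__name__)

VENN_REGIONS = ("surface_only", "bulk_only", "particle_only",
                "surface_bulk", "surface_particle", "bulk_particle",
                "all_three")

PACKAGING_LABELS = ("large_particle", "small_particle_only", "particle_only",
                    "surface_only")


@dataclasses.dataclass(frozen=True)
class PresencePools:
    """Per-basin presence sets of ASVs by sample type."""

    basin: str
    surface: frozenset[str]
    bulk: frozenset[str]
    particle: frozenset[str]

    @property
    def union(self) -> frozenset[str]:
        return self.surface | self.bulk | self.particle


@dataclasses.dataclass(frozen=True)
class PartitionResult:
    basin: str
    region_counts: dict[str, int]
    region_percent: dict[str, float]


def _presence(table: pd.DataFrame, sample_ids) -> frozenset[str]:
    sub = table.loc[table.index.intersection(sample_ids)]
    if sub.shape[0] == 0:
        return frozenset()
    present = sub.sum(axis=0) > 0
    return frozenset(present.index[present])


def build_pools(table: pd.DataFrame, samples: pd.DataFrame,
                basin: str) -> PresencePools:
    """Presence pools for one basin (photosynthetic, read-filtered table)."""
    meta = samples.loc[samples.index.intersection(table.index)]
    meta = meta[meta["basin"] == basin]
    pools = {}
    for stype, key in (("surface", "surface"), ("bulk_trap", "bulk"),
                       ("particle", "particle")):
        ids = meta.index[meta["sample_type"] == stype]
        if len(ids) == 0:
            log.warning("basin %s has no %s samples; pool is empty", basin, stype)
        pools[key] = _presence(table, ids)
    return PresencePools(basin=basin, **pools)


def venn_partition(pools: PresencePools) -> PartitionResult:
    """Exact seven-region partition of the basin's detected ASV union."""
    s, b, p = pools.surface, pools.bulk, pools.particle
    regions = {
        "surface_only": s - b - p,
        "bulk_only": b - s - p,
        "particle_only": p - s - b,
        "surface_bulk": (s & b) - p,
        "surface_particle": (s & p) - b,
        "bulk_particle": (b & p) - s,
        "all_three": s & b & p,
    }
    union = pools.union
    total = len(union)
    covered = set()
    for r in regions.values():
        assert covered.isdisjoint(r), "venn regions overlap"
        covered |= r
    assert covered == set(union), "venn regions do not cover the union"
    counts = {k: len(v) for k, v in regions.items()}
    percent = {k: (100.0 * c / total if total else 0.0) for k, c in counts.items()}
    return PartitionResult(basin=pools.basin, region_counts=counts,
                           region_percent=percent)


def infer_packaging(table: pd.DataFrame, samples: pd.DataFrame,
                    basin: str) -> pd.Series:
    """Per-ASV packaging label for one basin.

    Labels (mutually exclusive, exhaustive over the basin's detected ASVs):

    * ``large_particle`` -- in a bulk sample and in >=1 individual particle
      from the same platform (same deployment + platform id);
    * ``small_particle_only`` -- in bulk samples but in no same-platform
      particle anywhere;
    * ``particle_only`` -- in individual particles but never in bulk;
    * ``surface_only`` -- detected only in surface seawater.
    """
    meta = samples.loc[samples.index.intersection(table.index)]
    meta = meta[meta["basin"] == basin]
    surface_ids = meta.index[meta["sample_type"] == "surface"]
    bulk_meta = meta[meta["sample_type"] == "bulk_trap"]
    part_meta = meta[meta["sample_type"] == "particle"]

    bulk_platforms = {}
    for key, grp in bulk_meta.groupby(["deployment", "platform"]):
        bulk_platforms[key] = _presence(table, grp.index)
    part_platforms = {}
    for key, grp in part_meta.groupby(["deployment", "platform"]):
        part_platforms[key] = _presence(table, grp.index)
    for key in part_platforms:
        if key not in bulk_platforms:
            log.warning("basin %s: particle platform %s has no bulk sample; "
                        "treated as unpaired", basin, key)

    surface_any = _presence(table, surface_ids)
    bulk_any = frozenset().union(*bulk_platforms.values()) if bulk_platforms else frozenset()
    part_any = frozenset().union(*part_platforms.values()) if part_platforms else frozenset()

    large = set()
    for key, bulk_set in bulk_platforms.items():
        large |= bulk_set & part_platforms.get(key, frozenset())

    labels = {}
    for asv in surface_any | bulk_any | part_any:
        if asv in large:
            labels[asv] = "large_particle"
        elif asv in bulk_any:
            labels[asv] = "small_particle_only"
        elif asv in part_any:
            labels[asv] = "particle_only"
        else:
            labels[asv] = "surface_only"
    return pd.Series(labels, name="packaging", dtype=object).sort_index()


def richness_stats(table: pd.DataFrame, samples: pd.DataFrame
                   ) -> tuple[pd.Series, pd.DataFrame]:
    """Per-sample ASV richness and per basin x sample-type summaries.

    Richness is the number of ASVs with at least one read.  The summary
    reports n, mean, median and quartiles per (basin, sample type).
    """
    richness = (table > 0).sum(axis=1).rename("richness")
    assert (richness > 0).all(), "zero-richness sample after read filtering"
    meta = samples.loc[richness.index]
    df = pd.DataFrame({"richness": richness,
                       "basin": meta["basin"],
                       "sample_type": meta["sample_type"]})
    summary = (df.groupby(["basin", "sample_type"])["richness"]
                 .agg(n="size", mean="mean", median="median",
                      q25=lambda v: float(np.percentile(v, 25)),
                      q75=lambda v: float(np.percentile(v, 75)))
                 .reset_index())
    return richness, summary


def export_fractions(table: pd.DataFrame, samples: pd.DataFrame,
                     taxonomy: pd.DataFrame, basin: str) -> pd.DataFrame:
    """Exported fraction of surface diversity and reads per pigment group.

    For each pigment group, the basin's surface ASVs are partitioned into
    those also detected in individual particles (large-particle export),
    those detected only in bulk trap samples (small-particle export) and
    those not detected in any sinking-particle sample.  Fractions are
    reported both by ASV count and weighted by surface read counts; the
    three fractions sum to one.  A group with no surface ASVs gets NaN
    fractions (undefined, not zero).
    """
    if "pigment_group" not in taxonomy.columns:
        raise ValueError("taxonomy has no pigment groups; run assign_pigment_groups first")
    pools = build_pools(table, samples, basin)
    meta = samples.loc[samples.index.intersection(table.index)]
    surf_ids = meta.index[(meta["basin"] == basin) &
                          (meta["sample_type"] == "surface")]
    surf_reads = table.loc[surf_ids].sum(axis=0)

    rows = []
    for group in GROUPS:
        members = set(taxonomy.index[taxonomy["pigment_group"] == group])
        surface = sorted(pools.surface & members)
        n = len(surface)
        if n == 0:
            rows.append({"basin": basin, "group": group, "n_surface_asvs": 0,
                         "asv_frac_particles": np.nan,
                         "asv_frac_bulk_only": np.nan,
                         "asv_frac_not_exported": np.nan,
                         "read_frac_particles": np.nan,
                         "read_frac_bulk_only": np.nan,
                         "read_frac_not_exported": np.nan})
            continue
        in_part = [a for a in surface if a in pools.particle]
        bulk_only = [a for a in surface
                     if a in pools.bulk and a not in pools.particle]
        not_exported = [a for a in surface
                        if a not in pools.bulk and a not in pools.particle]
        reads = surf_reads[surface].sum()
        rows.append({
            "basin": basin, "group": group, "n_surface_asvs": n,
            "asv_frac_particles": len(in_part) / n,
            "asv_frac_bulk_only": len(bulk_only) / n,
            "asv_frac_not_exported": len(not_exported) / n,
            "read_frac_particles": surf_reads[in_part].sum() / reads if reads else np.nan,
            "read_frac_bulk_only": surf_reads[bulk_only].sum() / reads if reads else np.nan,
            "read_frac_not_exported": surf_reads[not_exported].sum() / reads if reads else np.nan,
        })
    return pd.DataFrame(rows).set_index("group")
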