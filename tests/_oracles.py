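"""Independent brute-force oracles used by the test suite.

Every function here re-derives a quantity with explicit loops and plain
set arithmetic, deliberately sharing no code with the package internals.
"""

import math

import numpy as np


def clr_brute(x, pseudocount):
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    for i in range(x.shape[0]):
        vals = [x[i, j] + pseudocount for j in range(x.shape[1])]
        g = math.exp(sum(math.log(v) for v in vals) / len(vals))
        for j in range(x.shape[1]):
            out[i, j] = math.log(vals[j] / g)
    return out


def aitchison_brute(clr):
    clr = np.asarray(clr, dtype=float)
    n = clr.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = math.sqrt(sum((clr[i, k] - clr[j, k]) ** 2
                                    for k in range(clr.shape[1])))
    return d


def venn_brute(surface, bulk, particle):
    """Region sizes from explicit 2^3 membership-pattern enumeration."""
    regions = {k: 0 for k in ("surface_only", "bulk_only", "particle_only",
                              "surface_bulk", "surface_particle",
                              "bulk_particle", "all_three")}
    names = {(True, False, False): "surface_only",
             (False, True, False): "bulk_only",
             (False, False, True): "particle_only",
             (True, True, False): "surface_bulk",
             (True, False, True): "surface_particle",
             (False, True, True): "bulk_particle",
             (True, True, True): "all_three"}
    for asv in set(surface) | set(bulk) | set(particle):
        pattern = (asv in surface, asv in bulk, asv in particle)
        regions[names[pattern]] += 1
    return regions


def pools_brute(counts, samples, basin):
    """Presence sets by a per-cell scan."""
    pools = {"surface": set(), "bulk": set(), "particle": set()}
    key = {"surface": "surface", "bulk_trap": "bulk", "particle": "particle"}
    for sid in counts.index:
        if samples.loc[sid, "basin"] != basin:
            continue
        pool = key[samples.loc[sid, "sample_type"]]
        for asv in counts.columns:
            if counts.loc[sid, asv] > 0:
                pools[pool].add(asv)
    return pools


def packaging_brute(counts, samples, basin):
    """Packaging labels from an explicit platform-pairing scan."""
    bulk_by_platform, part_by_platform = {}, {}
    surface = set()
    for sid in counts.index:
        row = samples.loc[sid]
        if row["basin"] != basin:
            continue
        present = {a for a in counts.columns if counts.loc[sid, a] > 0}
        if row["sample_type"] == "surface":
            surface |= present
        elif row["sample_type"] == "bulk_trap":
            k = (row["deployment"], row["platform"])
            bulk_by_platform.setdefault(k, set()).update(present)
        elif row["sample_type"] == "particle":
            k = (row["deployment"], row["platform"])
            part_by_platform.setdefault(k, set()).update(present)
    bulk_any = set().union(*bulk_by_platform.values()) if bulk_by_platform else set()
    part_any = set().union(*part_by_platform.values()) if part_by_platform else set()
    large = set()
    for k, b in bulk_by_platform.items():
        large |= b & part_by_platform.get(k, set())
    labels = {}
    for asv in surface | bulk_any | part_any:
        if asv in large:
            labels[asv] = "large_particle"
        elif asv in bulk_any:
            labels[asv] = "small_particle_only"
        elif asv in part_any:
            labels[asv] = "particle_only"
        else:
            labels[asv] = "surface_only"
    return labels


def richness_brute(counts):
    return {sid: sum(1 for a in counts.columns if counts.loc[sid, a] > 0)
            for sid in counts.index}


def median_brute(values):
    v = sorted(values)
    n = len(v)
    if n % 2:
        return float(v[n // 2])
    return 0.5 * (v[n // 2 - 1] + v[n // 2])


def ratio_brute(counts_row, groups_by_asv, mask, numerator_groups):
    num = den = 0
    for asv, c in counts_row.items():
        if asv not in mask:
            continue
        if groups_by_asv[asv] in numerator_groups:
            num += c
        else:
            den += c
    return num / den if den > 0 else float("nan")
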