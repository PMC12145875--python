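"""Pigment-based phytoplankton groups and genus-level binning.

Photosynthetic lineages map onto six pigment-based groups chosen to
correspond to diagnostic HPLC pigments (and hence to satellite-retrievable
categories): diatoms (fucoxanthin), dinoflagellates (peridinin),
photosynthetic Hacrobia (prymnesiophytes + cryptophytes), chlorophytes
(monovinyl chlorophyll b), dictyochophytes + pelagophytes
(19'-butanoyloxyfucoxanthin) and other Ochrophyta, with ``other_photo`` as
the explicit fallback for photosynthetic taxa outside the six groups
(rappemonads, chlorarachniophytes, ...).  The mapping ships as an editable
data file so that PR2 version drift is a data change, not a code change.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .tables import RANKS

#: The six pigment-based groups plus the explicit fallback, in report order.
GROUPS = ("diatoms", "dinoflagellates", "hacrobia", "chlorophytes",
          "dictyo_pelago", "other_ochrophyta", "other_photo")


@dataclasses.dataclass(frozen=True)
class GroupRule:
    rank: str
    name: str
    group: str


def load_group_rules(path: str | Path | None = None) -> tuple[GroupRule, ...]:
    """Load the ordered rank/name -> group rule list (first match wins)."""
    if path is None:
        ref = resources.files("phytoflux.data") / "pigment_groups.tsv"
        with resources.as_file(ref) as p:
            return load_group_rules(p)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    rules = []
    for _, r in df.iterrows():
        if r["rank"] not in RANKS:
            raise ValueError(f"group rule rank {r['rank']!r} is not a lineage rank")
        if r["group"] not in GROUPS:
            raise ValueError(f"group rule target {r['group']!r} is not a pigment group")
        rules.append(GroupRule(r["rank"], r["name"], r["group"]))
    return tuple(rules)


def assign_pigment_group(lineage: Sequence[str] | Mapping[str, str],
                         rules: tuple[GroupRule, ...] | None = None) -> str:
    """Map a single eight-rank lineage to its pigment group.

    Total on photosynthetic lineages: anything unmatched is ``other_photo``.
    """
    if rules is None:
        rules = load_group_rules()
    if isinstance(lineage, Mapping):
        get = lineage.__getitem__
    else:
        if len(lineage) != len(RANKS):
            raise ValueError(f"lineage must have {len(RANKS)} slots")
        get = dict(zip(RANKS, lineage)).__getitem__
    for r in rules:
        if get(r.rank) == r.name:
            return r.group
    return "other_photo"


def assign_pigment_groups(taxonomy: pd.DataFrame,
                          rules: tuple[GroupRule, ...] | None = None,
                          require_photosynthetic: bool = True) -> pd.DataFrame:
    """Return a copy of ``taxonomy`` with ``pigment_group`` set.

    With ``require_photosynthetic`` the taxonomy must carry trophic labels
    and only photosynthetic rows are assigned (others get an empty string);
    passing a table that contains no photosynthetic rows is an error.
    """
    if rules is None:
        rules = load_group_rules()
    out = taxonomy.copy()
    group = pd.Series("other_photo", index=out.index, dtype=object)
    # Apply in reverse so that earlier (more specific) rules overwrite later ones.
    for r in reversed(rules):
        group[out[r.rank] == r.name] = r.group
    if require_photosynthetic:
        if "trophic" not in out.columns:
            raise ValueError("taxonomy has no trophic labels; run classify_trophic first")
        photo = out["trophic"] == "photosynthetic"
        if not photo.any():
            raise ValueError("no photosynthetic ASVs to assign pigment groups to")
        group[~photo] = ""
    out["pigment_group"] = group
    return out


def genus_bins(taxonomy: pd.DataFrame) -> pd.Series:
    """Genus-level bin per ASV.

    The bin is the genus name; ASVs with an empty genus are binned by their
    deepest assigned shallower rank with the prefix ``unassigned:``.
    """
    bins = {}
    shallower = list(RANKS[:6])  # domain .. family
    for asv, row in taxonomy.iterrows():
        if row["genus"] != "":
            bins[asv] = row["genus"]
            continue
        name = "unknown"
        for rank in reversed(shallower):
            if row[rank] != "":
                name = row[rank]
                break
        bins[asv] = f"unassigned:{name}"
    return pd.Series(bins, name="genus_bin")


def collapse_to_genus(table: pd.DataFrame, taxonomy: pd.DataFrame
                      ) -> tuple[pd.DataFrame, pd.Series]:
    """Sum ASV columns within genus bins (read totals are conserved).

    Returns the collapsed table (samples x genus bins, sorted by bin name)
    and the ASV -> bin mapping used.
    """
    bins = genus_bins(taxonomy.loc[table.columns])
    collapsed = table.T.groupby(bins).sum().T
    return collapsed.sort_index(axis=1), bins


def group_relative_abundance(table: pd.DataFrame, taxonomy: pd.DataFrame
                             ) -> pd.DataFrame:
    """Per-sample relative read abundance of the seven pigment groups.

    ``table`` must be the photosynthetic, read-filtered ASV table; rows of
    the result sum to one.  A zero-read sample is a hard error (it should
    have been removed by the read filter).
    """
    if "pigment_group" not in taxonomy.columns:
        raise ValueError("taxonomy has no pigment groups; run assign_pigment_groups first")
    groups = taxonomy.loc[table.columns, "pigment_group"]
    if (groups == "").any():
        bad = sorted(groups.index[groups == ""])[:5]
        raise ValueError(f"ASV(s) without pigment group in table: {bad}")
    sums = table.T.groupby(groups).sum().T
    sums = sums.reindex(columns=list(GROUPS), fill_value=0)
    totals = sums.sum(axis=1)
    if (totals == 0).any():
        bad = sorted(totals.index[totals == 0])[:5]
        raise ValueError(f"zero-read sample(s): {bad}")
    rel = sums.div(totals, axis=0)
    return rel.astype(float)
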