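"""Trophic classification and the photosynthetic-phytoplankton restriction.

The analysis operates on eukaryotic photosynthetic phytoplankton only.
ASVs are labelled ``photosynthetic`` / ``heterotrophic`` / ``parasitic`` /
``unknown`` from an editable rank/name rule list; all dinoflagellates are
treated as photosynthetic (their trophic strategies are variable and often
fluid) except known parasites such as Syndiniales, which are removed.
Samples whose photosynthetic read count falls below a saturation threshold
(default 5000 reads, strictly fewer) are removed.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import pandas as pd

from .tables import RANKS


@dataclasses.dataclass(frozen=True)
class TrophicRule:
    rank: str
    name: str
    label: str


@dataclasses.dataclass(frozen=True)
class TrophicRules:
    """A rule list plus the dinoflagellate-inclusion switch.

    Parasite rules dominate everything, including the dinoflagellate
    inclusion; photosynthetic rules dominate heterotrophic ones.
    """

    rules: tuple[TrophicRule, ...]
    include_all_dinoflagellates: bool = True

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("empty trophic rule list")
        for r in self.rules:
            if r.rank not in RANKS:
                raise ValueError(f"rule rank {r.rank!r} is not a lineage rank")
            if r.label not in ("photosynthetic", "heterotrophic", "parasitic"):
                raise ValueError(f"rule label {r.label!r} not recognised")

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "TrophicRules":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                         keep_default_na=False)
        rules = tuple(TrophicRule(r["rank"], r["name"], r["label"])
                      for _, r in df.iterrows())
        return cls(rules=rules, **kwargs)

    @classmethod
    def default(cls) -> "TrophicRules":
        ref = resources.files("phytoflux.data") / "trophic_rules.tsv"
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


def classify_trophic(taxonomy: pd.DataFrame,
                     rules: TrophicRules | None = None) -> pd.DataFrame:
    """Return a copy of ``taxonomy`` with the ``trophic`` column set.

    Precedence (last write wins): heterotrophic rules < photosynthetic rules
    < dinoflagellate inclusion < parasite rules; unmatched lineages are
    ``unknown`` and are excluded from all phytoplankton analyses downstream.
    """
    if rules is None:
        rules = TrophicRules.default()
    out = taxonomy.copy()
    label = pd.Series("unknown", index=out.index, dtype=object)

    def mask_for(wanted: str) -> pd.Series:
        m = pd.Series(False, index=out.index)
        for r in rules.rules:
            if r.label == wanted:
                m |= out[r.rank] == r.name
        return m

    label[mask_for("heterotrophic")] = "heterotrophic"
    label[mask_for("photosynthetic")] = "photosynthetic"
    if rules.include_all_dinoflagellates:
        dino = (out["division"] == "Dinoflagellata") | (out["class"] == "Dinophyceae")
        label[dino] = "photosynthetic"
    label[mask_for("parasitic")] = "parasitic"
    out["trophic"] = label
    return out


def subset_photosynthetic(table: pd.DataFrame,
                          taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Restrict an ASV table to photosynthetic ASVs (counts unchanged)."""
    if "trophic" not in taxonomy.columns:
        raise ValueError("taxonomy has no trophic labels; run classify_trophic first")
    photo = taxonomy.index[taxonomy["trophic"] == "photosynthetic"]
    keep = [c for c in table.columns if c in set(photo)]
    if not keep:
        raise ValueError("no photosynthetic ASVs in table")
    return table[keep]


@dataclasses.dataclass(frozen=True)
class ReadFilterReport:
    """Outcome of the per-sample read-saturation filter."""

    threshold: int
    removed_sample_ids: tuple[str, ...]
    photosynthetic_reads_per_sample: dict[str, int]


def filter_min_reads(table: pd.DataFrame, threshold: int = 5000
                     ) -> tuple[pd.DataFrame, ReadFilterReport]:
    """Remove samples with strictly fewer than ``threshold`` reads.

    ``table`` must already be restricted to photosynthetic ASVs, so row sums
    are photosynthetic read totals.  A sample with exactly ``threshold``
    reads is retained.
    """
    totals = table.sum(axis=1)
    removed = tuple(sorted(totals.index[totals < threshold]))
    kept = table.loc[totals >= threshold]
    if kept.shape[0] == 0:
        raise ValueError(
            f"all {table.shape[0]} samples fall below {threshold} photosynthetic reads")
    report = ReadFilterReport(
        threshold=int(threshold),
        removed_sample_ids=removed,
        photosynthetic_reads_per_sample={s: int(v) for s, v in totals.items()},
    )
    return kept, report
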