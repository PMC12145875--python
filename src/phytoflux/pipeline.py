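"""End-to-end analysis pipeline over a validated dataset.

Stages run in order: trophic filter -> pigment/genus classification ->
three-pool partition and packaging -> compositional and inferential
statistics -> flux model.  Every stage writes a TSV with a stable column
order, and each run writes a machine-readable manifest (parameters,
package version, seed, input checksums).  Identical inputs, parameters and
seed yield byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import fluxmodel, partition, pigments, stats, trophic
from .tables import BASINS, Dataset

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineParams:
    """Run parameters; defaults reproduce the standard analysis."""

    min_reads: int = 5000
    pseudocount: float = 1.0
    n_perm: int = 9999
    seed: int = 0
    numerator_groups: tuple[str, ...] = ("diatoms", "hacrobia")
    scope: str = "all"
    stt_only: bool = True
    strict: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["numerator_groups"] = list(self.numerator_groups)
        return d


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(dataset: Dataset, params: PipelineParams | None = None,
                 out_dir: str | Path | None = None,
                 input_files: dict[str, str | Path] | None = None
                 ) -> dict[str, pd.DataFrame]:
    """Run every stage on ``dataset`` and return the result tables.

    With ``out_dir`` set, each table is also written as TSV together with
    ``manifest.json``.
    """
    params = params or PipelineParams()
    results: dict[str, pd.DataFrame] = {}

    # --- stage 1: trophic filter -----------------------------------------
    taxonomy = trophic.classify_trophic(dataset.taxonomy)
    photo = trophic.subset_photosynthetic(dataset.counts, taxonomy)
    photo, report = trophic.filter_min_reads(photo, threshold=params.min_reads)
    log.info("trophic filter: %d photosynthetic ASVs, %d samples kept, "
             "%d removed", photo.shape[1], photo.shape[0],
             len(report.removed_sample_ids))
    results["read_filter"] = pd.DataFrame(
        {"photosynthetic_reads": pd.Series(report.photosynthetic_reads_per_sample),
         "removed": pd.Series({s: s in set(report.removed_sample_ids)
                               for s in report.photosynthetic_reads_per_sample})}
    ).rename_axis("sample_id").sort_index()

    samples = dataset.samples.loc[photo.index]

    # --- stage 2: pigment groups and genus bins --------------------------
    taxonomy = pigments.assign_pigment_groups(taxonomy)
    genus_table, bins = pigments.collapse_to_genus(photo, taxonomy)
    taxonomy = taxonomy.join(bins.rename("genus_bin"), how="left")
    taxonomy["genus_bin"] = taxonomy["genus_bin"].fillna("")
    group_rel = pigments.group_relative_abundance(photo, taxonomy)
    results["group_abundance"] = group_rel.rename_axis("sample_id")
    log.info("pigment stage: %d genus bins", genus_table.shape[1])

    # --- stage 3: partition, packaging, richness, export fractions -------
    venn_rows, pack_rows, export_tables = [], [], []
    for basin in BASINS:
        if not (samples["basin"] == basin).any():
            log.warning("basin %s absent; partition skipped", basin)
            continue
        pools = partition.build_pools(photo, samples, basin)
        part = partition.venn_partition(pools)
        for region in partition.VENN_REGIONS:
            venn_rows.append({"basin": basin, "region": region,
                              "n_asvs": part.region_counts[region],
                              "percent": part.region_percent[region]})
        packaging = partition.infer_packaging(photo, samples, basin)
        for asv, label in packaging.items():
            pack_rows.append({"basin": basin, "asv_id": asv, "packaging": label})
        export_tables.append(
            partition.export_fractions(photo, samples, taxonomy, basin).reset_index())
    results["venn_regions"] = pd.DataFrame(venn_rows)
    results["packaging"] = pd.DataFrame(pack_rows)
    results["export_fractions"] = pd.concat(export_tables, ignore_index=True)

    richness, summary = partition.richness_stats(photo, samples)
    results["richness"] = pd.DataFrame(
        {"richness": richness, "basin": samples["basin"],
         "sample_type": samples["sample_type"]}).rename_axis("sample_id")
    results["richness_summary"] = summary

    # --- stage 4: compositional statistics -------------------------------
    clr = stats.clr_transform(genus_table, pseudocount=params.pseudocount)
    pca = stats.pca_svd(clr)
    results["pca_scores"] = pca.scores.rename_axis("sample_id")
    results["pca_loadings"] = pca.loadings.rename_axis("genus_bin")
    results["variance_explained"] = pd.DataFrame(
        {"component": pca.scores.columns,
         "variance_fraction": pca.variance_explained})

    dist = stats.aitchison_distance(clr)
    perm_rows = []
    res = stats.permanova(dist, samples["basin"], n_perm=params.n_perm,
                          seed=params.seed)
    perm_rows.append({"comparison": "basin", "groups": "NP|NA",
                      "pseudo_F": res.pseudo_F, "p_value": res.p_value,
                      "adjusted_p": res.p_value, "n_permutations": res.n_permutations,
                      "n_samples": res.n_samples})
    for basin in BASINS:
        ids = samples.index[samples["basin"] == basin]
        if len(ids) == 0:
            continue
        labels = samples.loc[ids, "sample_type"]
        if labels.nunique() < 2:
            continue
        sub = dist.loc[ids, ids]
        for r in stats.pairwise_permanova(sub, labels, n_perm=params.n_perm,
                                          seed=params.seed + 1):
            perm_rows.append({"comparison": f"{basin}:sample_type",
                              "groups": "|".join(r.group_labels),
                              "pseudo_F": r.pseudo_F, "p_value": r.p_value,
                              "adjusted_p": r.adjusted_p,
                              "n_permutations": r.n_permutations,
                              "n_samples": r.n_samples})
    results["permanova"] = pd.DataFrame(perm_rows)

    anova_rows, tukey_tables = [], []
    for basin in BASINS:
        ids = samples.index[samples["basin"] == basin]
        if len(ids) == 0 or samples.loc[ids, "sample_type"].nunique() < 2:
            continue
        res = stats.anova_tukey(richness[ids], samples.loc[ids, "sample_type"])
        anova_rows.append({"basin": basin, "f_statistic": res.f_statistic,
                           "p_value": res.p_value, "n": len(ids)})
        t = res.tukey.copy()
        t.insert(0, "basin", basin)
        tukey_tables.append(t)
    results["anova"] = pd.DataFrame(anova_rows)
    results["tukey"] = (pd.concat(tukey_tables, ignore_index=True)
                        if tukey_tables else pd.DataFrame())

    # --- stage 5: flux model ---------------------------------------------
    bulk_group_rel = group_rel.loc[group_rel.index.intersection(
        dataset.flux.index)]
    if len(bulk_group_rel) >= 3:
        cov_vars = bulk_group_rel.join(dataset.flux["poc_flux"])
        keep = cov_vars.std(axis=0, ddof=1) > 0
        dropped = sorted(cov_vars.columns[~keep])
        if dropped:
            log.warning("covariability PCA: dropping zero-variance "
                        "variable(s) %s", dropped)
        cov = stats.covariability_pca(cov_vars.loc[:, keep])
        results["covariability_r2"] = cov.r_squared.rename_axis("variable")
        results["covariability_variance"] = pd.DataFrame(
            {"component": cov.pca.scores.columns,
             "variance_fraction": cov.pca.variance_explained})

    ratio = fluxmodel.make_ratio_samples(photo, taxonomy, samples,
                                         dataset.flux,
                                         numerator_groups=params.numerator_groups)
    results["ratio_samples"] = ratio.rename_axis("sample_id")
    scopes = ("all", "NP", "NA") if params.scope == "all" else (params.scope,)
    models = fluxmodel.flux_models_by_scope(ratio, scopes=scopes)
    results["flux_model"] = pd.DataFrame(
        [{"scope": s, "slope": m.slope, "intercept": m.intercept,
          "r_squared": m.r_squared, "p_value": m.p_value,
          "stderr": m.stderr, "intercept_stderr": m.intercept_stderr,
          "n": m.n} for s, m in models.items()])
    profile_model = models.get("all", next(iter(models.values())))
    results["depth_profiles"] = fluxmodel.depth_profile(
        profile_model, ratio, stt_only=params.stt_only).rename_axis("sample_id")

    if out_dir is not None:
        _write_outputs(results, params, Path(out_dir), input_files)
    return results


def _write_outputs(results: dict[str, pd.DataFrame], params: PipelineParams,
                   out_dir: Path, input_files) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in sorted(results.items()):
        path = out_dir / f"{name}.tsv"
        # float formatting pinned for reproducible checksums
        df.to_csv(path, sep="\t", float_format="%.10g")
        written[name] = _checksum(path)
    manifest = {
        "package": "phytoflux",
        "version": __version__,
        "parameters": params.to_dict(),
        "inputs": {str(k): _checksum(Path(v))
                   for k, v in (input_files or {}).items()},
        "outputs": written,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
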