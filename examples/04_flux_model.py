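"""Fit the POC flux model from the diatom + Hacrobia ratio.

Per bulk trap sample, x = (diatom + Hacrobia reads) / (all other
phytoplankton reads) within ASVs shared between surface seawater and
sinking particles; measured flux is regressed on x by OLS and the fitted
line predicts flux along trap depth profiles.
"""

import phytoflux as pf
from phytoflux import fluxmodel, pigments, trophic

dataset, truth = pf.generate_dataset(seed=0)
taxonomy = pigments.assign_pigment_groups(
    trophic.classify_trophic(dataset.taxonomy))
photo = trophic.subset_photosynthetic(dataset.counts, taxonomy)
photo, _ = trophic.filter_min_reads(photo)

ratio = fluxmodel.make_ratio_samples(photo, taxonomy, dataset.samples,
                                     dataset.flux)
for scope, model in fluxmodel.flux_models_by_scope(ratio).items():
    print(f"{scope:>4}: flux = {model.slope:.2f} x + {model.intercept:.2f}  "
          f"(R^2 = {model.r_squared:.2f}, p = {model.p_value:.2g}, "
          f"n = {model.n})")
print(f"generator truth: flux = {truth.flux_law[0]} x + {truth.flux_law[1]}")

model = fluxmodel.fit_flux_model(ratio)
profile = fluxmodel.depth_profile(model, ratio, stt_only=True)
np3 = profile[(profile["basin"] == "NP") & (profile["deployment"] == 3)]
print("\nNP deployment 3, measured vs. modelled flux by depth "
      "(mmol C m^-2 day^-1):")
print(np3[["depth_m", "x", "measured_flux", "modeled_flux"]]
      .to_string(index=False, float_format=lambda v: f"{v:.2f}"))
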