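"""The POC flux model: shared-ASV ratio statistic and linear fit.

The headline statistic is computed per bulk trap sample as

    x = (diatom + Hacrobia reads) / (all other phytoplankton reads)

restricted to ASVs shared between surface seawater and sinking particles
(bulk or individual) of the same basin.  Measured POC flux (mmol C m^-2
day^-1) is regressed on x by ordinary least squares, pooled across basins
or per basin, and the fitted line predicts flux from community composition
alone, e.g. along trap depth profiles.

Because x is a within-sample ratio of read counts it is invariant to
sequencing depth, and identical whether computed from counts or from
closed relative abundances.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats as sps


log = logging.getLogger(__name__)

DEFAULT_NUMERATOR = ("diatoms", "hacrobia")


def build_shared_mask(table: pd.DataFrame, samples: pd.DataFrame,
                      basin: str) -> frozenset[str]:
    """ASVs detected in >=1 surface sample AND >=1 sinking-particle sample
    (bulk or individual) of the basin."""
    meta = samples.loc[samples.index.intersection(table.index)]
    meta = meta[meta["basin"] == basin]
    surf = meta.index[meta["sample_type"] == "surface"]
    sink = meta.index[meta["sample_type"].isin(["bulk_trap", "particle"])]
    surf_present = table.loc[surf].sum(axis=0) > 0 if len(surf) else None
    sink_present = table.loc[sink].sum(axis=0) > 0 if len(sink) else None
    if surf_present is None or sink_present is None:
        raise ValueError(f"basin {basin}: missing surface or sinking samples")
    mask = frozenset(table.columns[(surf_present & sink_present).to_numpy()])
    if not mask:
        raise ValueError(f"basin {basin}: empty shared-ASV mask")
    return mask


def ratio_statistic(table: pd.DataFrame, taxonomy: pd.DataFrame,
                    mask: frozenset[str] | set[str],
                    numerator_groups=DEFAULT_NUMERATOR) -> pd.Series:
    """Per-sample ratio of numerator-group reads to all other phytoplankton
    reads, within the shared-ASV mask.

    Samples with a zero denominator get NaN and are logged; callers exclude
    them.  The numerator group set is configurable (e.g. diatoms only, or
    Hacrobia only).
    """
    if "pigment_group" not in taxonomy.columns:
        raise ValueError("taxonomy has no pigment groups; run assign_pigment_groups first")
    cols = [c for c in table.columns if c in mask]
    if not cols:
        raise ValueError("no table columns inside the shared mask")
    groups = taxonomy.loc[cols, "pigment_group"]
    in_num = groups.isin(list(numerator_groups)).to_numpy()
    sub = table[cols].to_numpy(dtype=float)
    num = sub[:, in_num].sum(axis=1)
    den = sub[:, ~in_num].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(den > 0, num / den, np.nan)
    bad = table.index[den == 0]
    if len(bad):
        log.warning("zero-denominator sample(s) excluded from ratio: %s",
                    sorted(bad)[:10])
    return pd.Series(x, index=table.index, name="ratio")


def make_ratio_samples(table: pd.DataFrame, taxonomy: pd.DataFrame,
                       samples: pd.DataFrame, flux: pd.DataFrame,
                       numerator_groups=DEFAULT_NUMERATOR) -> pd.DataFrame:
    """Assemble the regression table: one row per bulk trap sample with a
    flux measurement, carrying x, measured flux and trap metadata.

    The shared-ASV mask is built per basin, pooling all deployments and
    depths.  Rows with an undefined ratio (zero denominator) are dropped
    with a logged warning.
    """
    meta = samples.loc[samples.index.intersection(table.index)]
    rows = []
    for basin in sorted(meta["basin"].unique()):
        mask = build_shared_mask(table, samples, basin)
        bulk_ids = meta.index[(meta["basin"] == basin) &
                              (meta["sample_type"] == "bulk_trap")]
        bulk_ids = [s for s in bulk_ids if s in flux.index]
        if not bulk_ids:
            continue
        x = ratio_statistic(table.loc[bulk_ids], taxonomy, mask,
                            numerator_groups)
        for sid in bulk_ids:
            rows.append({
                "sample_id": sid, "basin": basin,
                "deployment": int(meta.loc[sid, "deployment"]),
                "depth_m": float(meta.loc[sid, "depth_m"]),
                "platform": meta.loc[sid, "platform"],
                "x": float(x[sid]),
                "poc_flux": float(flux.loc[sid, "poc_flux"]),
                "flux_uncertainty": float(flux.loc[sid, "flux_uncertainty"]),
            })
    df = pd.DataFrame(rows).set_index("sample_id").sort_index()
    n_bad = int(df["x"].isna().sum())
    if n_bad:
        log.warning("dropping %d ratio sample(s) with zero denominator", n_bad)
        df = df[df["x"].notna()]
    return df


@dataclasses.dataclass(frozen=True)
class FluxModel:
    """A fitted linear POC-flux model ``flux = slope * x + intercept``.

    Units: slope in mmol C m^-2 day^-1 per ratio unit; intercept in
    mmol C m^-2 day^-1.  ``scope`` records which basin subset was fitted.
    """

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    stderr: float
    intercept_stderr: float
    n: int
    scope: str = "all"

    def predict(self, x) -> np.ndarray:
        """Predicted flux; negative predictions are returned as-is with a
        logged warning."""
        x = np.asarray(x, dtype=float)
        y = self.slope * x + self.intercept
        n_neg = int(np.sum(y < 0))
        if n_neg:
            log.warning("%d negative flux prediction(s)", n_neg)
        return y

    def confidence_intervals(self, level: float = 0.95
                             ) -> dict[str, tuple[float, float]]:
        """Two-sided t confidence intervals for slope and intercept."""
        tcrit = sps.t.ppf(0.5 + level / 2.0, self.n - 2)
        return {
            "slope": (self.slope - tcrit * self.stderr,
                      self.slope + tcrit * self.stderr),
            "intercept": (self.intercept - tcrit * self.intercept_stderr,
                          self.intercept + tcrit * self.intercept_stderr),
        }


def fit_flux_model(ratio_samples: pd.DataFrame, scope: str = "all",
                   weighted: bool = False) -> FluxModel:
    """Linear fit of measured POC flux against the ratio statistic.

    The default is unweighted OLS.  With ``weighted`` the fit minimises
    inverse-variance-weighted residuals using ``flux_uncertainty`` (all
    uncertainties must then be positive); the reported R-squared is the
    weighted one.  ``scope`` is ``"all"`` or a basin code; it filters the
    rows used.  Requires at least 3 samples and non-constant x.
    """
    df = ratio_samples
    if scope != "all":
        df = df[df["basin"] == scope]
    if df.shape[0] < 3:
        raise ValueError(f"scope {scope!r}: need >=3 samples, have {df.shape[0]}")
    x = df["x"].to_numpy(dtype=float)
    y = df["poc_flux"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"scope {scope!r}: ratio statistic is constant")
    if not weighted:
        res = sps.linregress(x, y)
        return FluxModel(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(res.rvalue ** 2),
                         p_value=float(res.pvalue), stderr=float(res.stderr),
                         intercept_stderr=float(res.intercept_stderr),
                         n=int(len(x)), scope=scope)
    unc = df["flux_uncertainty"].to_numpy(dtype=float)
    if (unc <= 0).any():
        raise ValueError("weighted fit requires positive flux uncertainties")
    w = 1.0 / unc ** 2
    design = np.column_stack([np.ones_like(x), x])
    xtwx = design.T @ (design * w[:, None])
    beta = np.linalg.solve(xtwx, design.T @ (w * y))
    resid = y - design @ beta
    n = len(x)
    s2 = float(np.sum(w * resid ** 2) / (n - 2))
    cov = s2 * np.linalg.inv(xtwx)
    ybar_w = np.sum(w * y) / np.sum(w)
    r2 = 1.0 - np.sum(w * resid ** 2) / np.sum(w * (y - ybar_w) ** 2)
    tstat = beta[1] / np.sqrt(cov[1, 1])
    p = 2.0 * sps.t.sf(abs(tstat), n - 2)
    return FluxModel(slope=float(beta[1]), intercept=float(beta[0]),
                     r_squared=float(r2), p_value=float(p),
                     stderr=float(np.sqrt(cov[1, 1])),
                     intercept_stderr=float(np.sqrt(cov[0, 0])),
                     n=n, scope=scope)


def predict_flux(model: FluxModel, x_values) -> np.ndarray:
    """Apply a fitted model to ratio values (thin wrapper over
    :meth:`FluxModel.predict`)."""
    return model.predict(x_values)


def depth_profile(model: FluxModel, ratio_samples: pd.DataFrame,
                  stt_only: bool = True) -> pd.DataFrame:
    """Measured vs. modelled flux by depth per basin and deployment.

    With ``stt_only`` only surface-tethered-trap platforms are kept (their
    five-depth arrays give the clean depth profiles); rows are ordered by
    basin, deployment and depth.
    """
    df = ratio_samples.copy()
    if stt_only:
        df = df[df["platform"].str.startswith("STT")]
    skipped = []
    for (basin, dep), grp in df.groupby(["basin", "deployment"]):
        if grp.empty:
            skipped.append((basin, dep))
    if df.empty:
        log.warning("no bulk samples for depth profile")
    df["modeled_flux"] = model.predict(df["x"].to_numpy())
    df = df.rename(columns={"poc_flux": "measured_flux"})
    df = df.sort_values(["basin", "deployment", "depth_m"])
    return df[["basin", "deployment", "depth_m", "platform", "x",
               "measured_flux", "flux_uncertainty", "modeled_flux"]]


def flux_models_by_scope(ratio_samples: pd.DataFrame,
                         scopes=("all", "NP", "NA")) -> dict[str, FluxModel]:
    """Fit the pooled and per-basin models through the same code path."""
    out = {}
    for scope in scopes:
        if scope != "all" and scope not in set(ratio_samples["basin"]):
            log.warning("scope %s: no samples, skipped", scope)
            continue
        out[scope] = fit_flux_model(ratio_samples, scope=scope)
    return out
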