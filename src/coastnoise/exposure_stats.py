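"""Noise–vessel statistics: elevation over ambient, level histograms, and
the mixed-effects regression of band level on range, vessel type and speed.

The regression is a linear mixed model with a normal response,

    TOL_band ~ 1 + log10(range_m) + vessel_type + speed_kn + (1 | day)

fitted by maximum likelihood. Spherical spreading over a decade of range
shows up as a −20 coefficient on log10(range); cavitation noise growth
appears in the dB-per-knot speed coefficient. Only epochs with a single
dominant motorised vessel (categories 1–3, 200-m exclusion passed) enter
the sample, and the recording day absorbs day-to-day ambient shifts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .band_analysis import TolSeries, ambient_level
from .tracking import GROUP_AIS

ANALYSIS_BAND_CENTRES = (125.0, 2000.0, 16000.0)


def build_observations(
    tols: TolSeries,
    classified: pd.DataFrame,
    band_centres: tuple[float, ...] = ANALYSIS_BAND_CENTRES,
) -> pd.DataFrame:
    """Join per-second band levels with closest-vessel covariates.

    Keeps epochs in categories 1–3 that pass the multi-source exclusion
    and have a resolved closest vessel. Columns: ``tol_<centre>`` per
    band, ``log10_range``, ``vessel_type`` ("AIS"/"nonAIS"), ``speed_kn``,
    ``day``.
    """
    if not tols.epoch_times.equals(classified.index):
        common = tols.epoch_times.intersection(classified.index)
        if len(common) == 0:
            raise ValueError("TOL series and classification share no epochs")
        lev_idx = tols.epoch_times.get_indexer(common)
        levels = tols.levels[lev_idx]
        classified = classified.loc[common]
        epochs = common
    else:
        levels = tols.levels
        epochs = tols.epoch_times

    keep = (
        classified["category"].isin([1, 2, 3])
        & ~classified["excluded"]
        & classified["closest_id"].notna()
        & (classified["closest_range_m"] > 0)
    ).to_numpy()

    data = {"epoch": epochs[keep]}
    for c in band_centres:
        data[f"tol_{int(c)}"] = levels[keep, tols.band_index(c)]
    sub = classified.loc[keep]
    data["log10_range"] = np.log10(sub["closest_range_m"].to_numpy(dtype=float))
    data["vessel_type"] = np.where(sub["closest_group"] == GROUP_AIS, "AIS", "nonAIS")
    data["speed_kn"] = sub["closest_speed_kn"].to_numpy(dtype=float)
    obs = pd.DataFrame(data)
    obs["day"] = obs["epoch"].dt.date.astype(str)
    return obs.reset_index(drop=True)


@dataclass
class GlmmResult:
    """Fitted mixed-model summary for one band."""

    band_centre: float
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    random_intercept_var: float
    resid_var: float
    n_obs: int
    converged: bool

    @property
    def range_slope(self) -> float:
        return float(self.params["log10_range"])

    @property
    def speed_coef(self) -> float:
        return float(self.params["speed_kn"])

    @property
    def vessel_type_coef(self) -> float:
        return float(self.params["vessel_type[T.nonAIS]"])

    def to_dict(self) -> dict:
        return {
            "band_centre_hz": self.band_centre,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "random_intercept_var": self.random_intercept_var,
            "resid_var": self.resid_var,
            "coefficients": {
                k: {
                    "estimate": float(self.params[k]),
                    "se": float(self.bse[k]),
                    "p": float(self.pvalues[k]),
                }
                for k in self.params.index
            },
        }


def fit_noise_glmm(obs: pd.DataFrame, band_centre: float) -> GlmmResult:
    """Fit TOL ~ log10_range + vessel_type + speed_kn with a day intercept.

    Maximum-likelihood fit (not REML) so nested models and software can be
    compared on likelihoods; p-values are Wald. A singular/non-converged
    fit is returned flagged rather than raised.
    """
    col = f"tol_{int(band_centre)}"
    if col not in obs.columns:
        raise KeyError(f"observations lack column {col}")
    df = obs.dropna(subset=[col, "log10_range", "speed_kn"]).copy()
    if df["day"].nunique() < 2:
        warnings.warn("fewer than 2 days: random intercept is not identifiable")
    if df["vessel_type"].nunique() < 2:
        warnings.warn("only one vessel type present; type effect not identifiable")
    n_params = 4
    if len(df) <= n_params:
        raise ValueError("not enough observations for the model")

    model = smf.mixedlm(
        f"{col} ~ log10_range + vessel_type + speed_kn", df, groups=df["day"]
    )
    fit = None
    converged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "powell", "cg"):
            try:
                fit = model.fit(reml=False, method=method)
            except (np.linalg.LinAlgError, ValueError):
                continue
            converged = bool(fit.converged)
            if converged:
                break
    if fit is None:
        # degenerate random-effect structure: flag and report the
        # fixed-effects-only fit instead of crashing
        ols = smf.ols(f"{col} ~ log10_range + vessel_type + speed_kn", df).fit()
        return GlmmResult(
            band_centre=band_centre,
            params=ols.params,
            bse=ols.bse,
            pvalues=ols.pvalues,
            random_intercept_var=0.0,
            resid_var=float(ols.scale),
            n_obs=len(df),
            converged=False,
        )

    fe = fit.params.drop(labels=[i for i in fit.params.index if "Group" in i])
    return GlmmResult(
        band_centre=band_centre,
        params=fe,
        bse=fit.bse[fe.index],
        pvalues=fit.pvalues[fe.index],
        random_intercept_var=float(fit.cov_re.iloc[0, 0]),
        resid_var=float(fit.scale),
        n_obs=len(df),
        converged=converged,
    )


def elevation_over_ambient(
    tols: TolSeries,
    band_centre: float,
    interval: tuple[pd.Timestamp, pd.Timestamp] | None = None,
) -> float:
    """Maximum band level in an interval minus the series' ambient level.

    Ambient is the 5th percentile over the *whole* series; the maximum is
    taken over ``interval`` (default: whole series). Adding a constant to
    every epoch leaves the elevation unchanged.
    """
    amb = ambient_level(tols, band_centre)
    x = tols.band_levels(band_centre)
    if interval is not None:
        t0, t1 = pd.Timestamp(interval[0]), pd.Timestamp(interval[1])
        mask = (tols.epoch_times >= t0) & (tols.epoch_times <= t1)
        x = x[mask]
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no finite levels in the requested interval")
    return float(x.max() - amb)


def level_histograms(
    tols: TolSeries,
    classified: pd.DataFrame,
    band_centre: float,
    bin_width_db: float = 1.0,
    level_range: tuple[float, float] = (60.0, 130.0),
) -> pd.DataFrame:
    """Per-category histograms of band levels in 1-dB bins.

    Rows are bin lower edges, columns are categories 1–5; each column sums
    to 1 over that category's epochs. Out-of-range levels are pooled into
    the edge bins (with a warning).
    """
    lo, hi = level_range
    edges = np.arange(lo, hi + bin_width_db / 2, bin_width_db)
    levels = tols.band_levels(band_centre)
    common = tols.epoch_times.intersection(classified.index)
    if len(common) == 0:
        raise ValueError("no shared epochs")
    lev = levels[tols.epoch_times.get_indexer(common)]
    cats = classified.loc[common, "category"].to_numpy()

    finite = np.isfinite(lev)
    lev, cats = lev[finite], cats[finite]
    if np.any((lev < lo) | (lev > hi)):
        warnings.warn("levels outside histogram range pooled into edge bins")
    lev = np.clip(lev, lo, np.nextafter(hi, -np.inf))

    out = {}
    for c in range(1, 6):
        sel = lev[cats == c]
        counts, _ = np.histogram(sel, bins=edges)
        out[c] = counts / sel.size if sel.size else np.zeros(len(edges) - 1)
    return pd.DataFrame(out, index=pd.Index(edges[:-1], name="bin_lower_db"))
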