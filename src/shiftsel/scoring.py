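"""Probabilistic matching of predicted shifts against experimental distributions.

For one atomic site, both the experimental shift distribution (center,
linewidth) and the prediction (shift, model uncertainty) are treated as
Gaussians.  The agreement of one predicted shift with the experiment is the
two-tailed p-value of the Z score between the two Gaussians,

    Z = |delta_exp - delta_pred| / sqrt(sigma_exp^2 + sigma_pred^2)
    p_val(Z) = sqrt(2/pi) * int_Z^inf exp(-x^2/2) dx  =  erfc(Z / sqrt(2)),

penalized for unreliable predictions by dividing by
max(1, sigma_pred / sigma0) where sigma0 is the site's reference uncertainty
(the first quartile of all prediction uncertainties seen for that site).
The per-environment probability is the geometric mean of the per-site
probabilities, and the "NMR ensemble" is the set of environments whose
probability exceeds a threshold (default 0.33, about the best 1 % in the
original application) or, alternatively, the top fraction by probability.

All operations accept scalars or numpy arrays; the table-level driver
:func:`score_all` works on pandas DataFrames with the documented schemas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon
from scipy.special import erfc
from scipy.stats import norm

from .core import MissingPredictionError, ShiftDistribution

logger = logging.getLogger(__name__)

#: required columns of a prediction table
PREDICTION_COLUMNS = ("trajectory", "frame", "molecule_id", "site_label",
                      "element", "shift_ppm", "uncertainty_ppm")
#: required columns of a distribution table
DISTRIBUTION_COLUMNS = ("site_label", "element", "center_ppm", "width_ppm")
#: columns identifying one local molecular environment
ENV_KEY = ["trajectory", "frame", "molecule_id"]


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def z_score(delta_exp, sigma_exp, delta_pred, sigma_pred):
    """Z score between the experimental and predicted shift Gaussians."""
    sigma_exp = np.asarray(sigma_exp, dtype=float)
    sigma_pred = np.asarray(sigma_pred, dtype=float)
    if np.any(sigma_exp <= 0) or np.any(sigma_pred <= 0):
        raise ValueError("Gaussian widths must be strictly positive")
    num = np.abs(np.asarray(delta_exp, dtype=float) - np.asarray(delta_pred, dtype=float))
    return num / np.sqrt(sigma_exp ** 2 + sigma_pred ** 2)


def two_tailed_p(z):
    """Two-tailed p-value of a non-negative Z score.

    Equals sqrt(2/pi) * int_Z^inf exp(-x^2/2) dx, i.e. the doubled upper
    Gaussian tail, evaluated in closed form as erfc(Z / sqrt(2)).
    Decreasing in Z; 1 at Z = 0.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("Z must be non-negative (callers take |.| upstream)")
    return erfc(z / np.sqrt(2.0))


def site_probability(p_val, sigma_pred, sigma_ref):
    """Penalize a p-value for prediction uncertainty above the site reference.

    p = p_val / max(1, sigma_pred / sigma_ref).  Equals p_val whenever
    sigma_pred <= sigma_ref; strictly smaller otherwise.
    """
    sigma_ref = np.asarray(sigma_ref, dtype=float)
    if np.any(sigma_ref <= 0):
        raise ValueError("sigma_ref must be strictly positive")
    ratio = np.asarray(sigma_pred, dtype=float) / sigma_ref
    return np.asarray(p_val, dtype=float) / np.maximum(1.0, ratio)


def environment_probability(site_probs) -> float:
    """Geometric mean of per-site probabilities, computed in log space.

    A single zero probability annihilates the product, so any zero entry
    short-circuits to 0 (avoiding log(0)).
    """
    p = np.asarray(site_probs, dtype=float)
    if p.size == 0:
        raise ValueError("environment_probability of an empty site list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("site probabilities must lie in [0, 1]")
    if np.any(p == 0.0):
        return 0.0
    return float(np.exp(np.mean(np.log(p))))


def compute_reference_uncertainties(predictions: pd.DataFrame,
                                    interpolation: str = "linear") -> pd.Series:
    """Per-site reference uncertainty sigma0: the first quartile (25th
    percentile, linear interpolation by default) of all prediction
    uncertainties observed for that site across all molecules and snapshots.
    """
    _require_columns(predictions, ("site_label", "uncertainty_ppm"), "predictions")
    return predictions.groupby("site_label")["uncertainty_ppm"].quantile(
        0.25, interpolation=interpolation)


# ---------------------------------------------------------------------------
# Configuration and selection containers
# ---------------------------------------------------------------------------

@dataclass
class SiteMatchConfig:
    """Configuration of the per-site matching.

    ``included_sites`` are the *resonance* labels entering the geometric mean
    (assignment-ambiguous sites, e.g. a C1 and its protons, are excluded by
    leaving them out).  ``quartile_floor`` maps each included resonance to its
    reference uncertainty sigma0.  ``equivalent_groups`` optionally maps a
    resonance label to several topological sites (e.g. the two protons of a
    CH2); their predicted shifts and uncertainties are averaged before
    matching ("per-resonance" mode).  Without groups each site is matched
    individually ("per-proton" mode).
    """

    included_sites: Tuple[str, ...]
    quartile_floor: Mapping[str, float]
    equivalent_groups: Optional[Mapping[str, Sequence[str]]] = None
    threshold: float = 0.33
    top_fraction: Optional[float] = None
    on_missing: str = "error"  # or "skip"

    def __post_init__(self) -> None:
        for site in self.included_sites:
            floor = self.quartile_floor.get(site)
            if floor is None or not floor > 0:
                raise ValueError(f"quartile_floor must be > 0 for site {site!r}")
        if self.on_missing not in ("error", "skip"):
            raise ValueError("on_missing must be 'error' or 'skip'")

    @classmethod
    def from_data(cls, predictions: pd.DataFrame, distributions: pd.DataFrame,
                  exclude: Sequence[str] = (),
                  equivalent_groups: Optional[Mapping[str, Sequence[str]]] = None,
                  **kwargs) -> "SiteMatchConfig":
        """Build a config from tables: include every assigned resonance not
        explicitly excluded, with sigma0 from the prediction table."""
        preds = _collapse_equivalents(predictions, equivalent_groups)
        included = tuple(s for s in distributions["site_label"] if s not in set(exclude))
        floor = compute_reference_uncertainties(preds)
        missing = [s for s in included if s not in floor.index]
        if missing:
            raise MissingPredictionError(
                f"no predictions at all for included sites {missing}")
        return cls(included_sites=included,
                   quartile_floor=floor.loc[list(included)].to_dict(),
                   equivalent_groups=equivalent_groups, **kwargs)


@dataclass
class EnsembleSelection:
    """Result of scoring: per-environment probabilities and the selected set.

    ``probabilities`` is indexed by (trajectory, frame, molecule_id).
    ``selected_ids`` contains exactly the environments with probability
    strictly above ``threshold`` (threshold mode) or the top ``top_fraction``
    by probability (top-fraction mode, ties broken by index order).
    """

    probabilities: pd.Series
    threshold: float
    selected_ids: pd.Index
    top_fraction: Optional[float] = None

    @property
    def selected_fraction(self) -> float:
        return len(self.selected_ids) / len(self.probabilities)

    @property
    def selection_flags(self) -> pd.Series:
        return pd.Series(self.probabilities.index.isin(self.selected_ids),
                         index=self.probabilities.index, name="selected")

    @classmethod
    def by_threshold(cls, probabilities: pd.Series, threshold: float = 0.33
                     ) -> "EnsembleSelection":
        if not 0 <= threshold <= 1:
            raise ValueError("threshold must lie in [0, 1]")
        sel = probabilities.index[probabilities.values > threshold]
        return cls(probabilities, threshold, sel)

    @classmethod
    def by_top_fraction(cls, probabilities: pd.Series, fraction: float
                        ) -> "EnsembleSelection":
        if not 0 < fraction <= 1:
            raise ValueError("fraction must lie in (0, 1]")
        k = max(1, int(round(fraction * len(probabilities))))
        order = np.argsort(-probabilities.values, kind="stable")
        sel = probabilities.index[order[:k]]
        threshold = float(probabilities.iloc[order[k - 1]])
        return cls(probabilities, threshold, sel, top_fraction=fraction)

    def to_frame(self) -> pd.DataFrame:
        out = self.probabilities.rename("probability").reset_index()
        out["selected"] = self.probabilities.index.isin(self.selected_ids)
        return out


# ---------------------------------------------------------------------------
# Table-level driver
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols, name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table is missing columns {missing}")


def _collapse_equivalents(predictions: pd.DataFrame,
                          groups: Optional[Mapping[str, Sequence[str]]]
                          ) -> pd.DataFrame:
    """Average predictions of symmetry-equivalent sites into one resonance."""
    if not groups:
        return predictions
    site_to_res = {}
    for res, sites in groups.items():
        for s in sites:
            site_to_res[s] = res
    out = predictions.copy()
    out["site_label"] = out["site_label"].map(lambda s: site_to_res.get(s, s))
    keys = ENV_KEY + ["site_label"]
    agg = {"shift_ppm": "mean", "uncertainty_ppm": "mean"}
    if "element" in out.columns:
        agg["element"] = "first"
    return out.groupby(keys, as_index=False).agg(agg)


def score_all(predictions: pd.DataFrame, distributions: pd.DataFrame,
              config: SiteMatchConfig) -> EnsembleSelection:
    """Score every environment and select the NMR ensemble.

    ``predictions`` must contain one row per (environment, site); an
    environment is keyed by (trajectory, frame, molecule_id).  Environments
    missing a prediction for any included resonance raise
    :class:`MissingPredictionError` (or are skipped with a logged warning when
    ``config.on_missing == "skip"``).
    """
    _require_columns(predictions, ENV_KEY + ["site_label", "shift_ppm",
                                             "uncertainty_ppm"], "predictions")
    _require_columns(distributions, ("site_label", "center_ppm", "width_ppm"),
                     "distributions")
    preds = _collapse_equivalents(predictions, config.equivalent_groups)
    preds = preds[preds["site_label"].isin(config.included_sites)]
    dist = distributions.set_index("site_label")
    merged = preds.merge(
        dist[["center_ppm", "width_ppm"]], left_on="site_label", right_index=True,
        how="left")
    if merged["center_ppm"].isna().any():
        bad = merged.loc[merged["center_ppm"].isna(), "site_label"].unique()
        raise ValueError(f"included sites with no experimental distribution: {bad}")

    z = z_score(merged["center_ppm"], merged["width_ppm"],
                merged["shift_ppm"], merged["uncertainty_ppm"])
    pval = two_tailed_p(z)
    sigma0 = merged["site_label"].map(config.quartile_floor).to_numpy(float)
    merged["site_prob"] = site_probability(pval, merged["uncertainty_ppm"], sigma0)

    counts = merged.groupby(ENV_KEY)["site_prob"].size()
    n_sites = len(config.included_sites)
    incomplete = counts.index[counts != n_sites]
    if len(incomplete):
        if config.on_missing == "error":
            raise MissingPredictionError(
                f"{len(incomplete)} environments lack predictions for included "
                f"sites; first offending environment: {tuple(incomplete[0])}")
        logger.warning("skipping %d environments with missing site predictions",
                       len(incomplete))
        merged = merged.set_index(ENV_KEY).drop(index=incomplete).reset_index()

    grouped = merged.groupby(ENV_KEY)["site_prob"]
    with np.errstate(divide="ignore"):
        logmean = grouped.apply(lambda p: np.mean(np.log(p.to_numpy())))
    probs = np.exp(logmean)
    probs[np.isneginf(logmean)] = 0.0
    probs = probs.sort_index().rename("probability")

    if config.top_fraction is not None:
        return EnsembleSelection.by_top_fraction(probs, config.top_fraction)
    return EnsembleSelection.by_threshold(probs, config.threshold)


def per_molecule_rmse(predictions: pd.DataFrame, distributions: pd.DataFrame,
                      element: str,
                      included_sites: Optional[Sequence[str]] = None) -> pd.Series:
    """Per-environment RMSE (ppm) between predicted shifts and the centers of
    the experimental distributions, restricted to one element (e.g. "H")."""
    _require_columns(predictions, PREDICTION_COLUMNS, "predictions")
    dist = distributions.set_index("site_label")
    preds = predictions[predictions["element"] == element]
    if included_sites is not None:
        preds = preds[preds["site_label"].isin(included_sites)]
    preds = preds[preds["site_label"].isin(dist.index)]
    if preds.empty:
        raise ValueError(f"no predictions match element {element!r} and the "
                         "assigned distributions")
    err = preds["shift_ppm"].to_numpy(float) - \
        preds["site_label"].map(dist["center_ppm"]).to_numpy(float)
    frame = preds[ENV_KEY].copy()
    frame["sq"] = err ** 2
    return np.sqrt(frame.groupby(ENV_KEY)["sq"].mean()).rename(f"rmse_{element}")


# ---------------------------------------------------------------------------
# Threshold diagnostics
# ---------------------------------------------------------------------------

def histogram_overlap_js(p_mass: np.ndarray, q_mass: np.ndarray
                         ) -> Tuple[float, float]:
    """Overlap coefficient and Jensen-Shannon divergence (base 2, in [0, 1])
    between two probability mass vectors on a shared binning."""
    p = np.asarray(p_mass, dtype=float)
    q = np.asarray(q_mass, dtype=float)
    if p.shape != q.shape:
        raise ValueError("mass vectors must share the binning")
    p = p / p.sum()
    q = q / q.sum()
    overlap = float(np.minimum(p, q).sum())
    js = float(jensenshannon(p, q, base=2) ** 2)
    return overlap, js


def threshold_diagnostics(selected_shifts, distribution: ShiftDistribution,
                          bins: Optional[np.ndarray] = None
                          ) -> Tuple[float, float]:
    """Compare the histogram of selected predicted shifts for one site with
    the experimental Gaussian discretized on the same bins.

    Returns (overlap coefficient, Jensen-Shannon divergence).  The binning
    defaults to the Freedman-Diaconis rule on the pooled support (shift range
    union center +/- 4 widths), with a minimum of 20 bins.  Used to choose the
    selection threshold as a balance between maximal overlap and minimal
    divergence.
    """
    shifts = np.asarray(selected_shifts, dtype=float)
    if shifts.size < 2:
        raise ValueError("need at least two selected predictions")
    c, w = distribution.center_ppm, distribution.width_ppm
    if bins is None:
        lo = min(shifts.min(), c - 4 * w)
        hi = max(shifts.max(), c + 4 * w)
        if np.ptp(shifts) == 0.0:
            # all-identical predictions: single occupied bin fallback
            logger.warning("degenerate (all-identical) selected shifts for site "
                           "%s; using single-bin fallback", distribution.site_label)
            edges = np.array([shifts[0] - w / 2, shifts[0] + w / 2])
        else:
            iqr = np.subtract(*np.percentile(shifts, [75, 25]))
            fd = 2 * iqr / shifts.size ** (1 / 3) if iqr > 0 else 0.0
            n_bins = max(20, int(np.ceil((hi - lo) / fd)) if fd > 0 else 20)
            edges = np.linspace(lo, hi, n_bins + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    counts, edges = np.histogram(shifts, bins=edges)
    p_mass = counts / counts.sum()
    cdf = norm.cdf(edges, loc=c, scale=w)
    q_mass = np.diff(cdf)
    if q_mass.sum() <= 0:
        raise ValueError("experimental Gaussian has no mass on the binning")
    return histogram_overlap_js(p_mass, q_mass)
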