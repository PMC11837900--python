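"""Delta-scale calibration, enrichment factors and the two-source mixing model.

The quantification chain is:

1. raw machine isotope ratios → delta values,
   ``δ = (R_sample / R_standard − 1) × 1000`` (‰);
2. a two-point linear calibration anchored on two laboratory standards of
   known delta value (fit per element);
3. per-plot enrichment factors ``ε = δ_specimen − mean δ of the autotrophic
   reference plants in the same plot`` — this removes site-level isotopic
   variation so specimens from different plots are comparable;
4. the linear two-source mixing model for percent fungal-derived carbon,
   ``%Cdf = (ε13C_specimen / ε13C_endpoint) × 100``, where the endpoint is
   the mean ε13C of protocorms (the fully mycoheterotrophic stage).

The three fittable steps are sklearn-style transformers
(:class:`TwoPointCalibration`, :class:`EnrichmentFactors`,
:class:`FungalCarbonMixingModel`); the module-level functions are thin
wrappers over them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from mixotroph.io import Category

logger = logging.getLogger("mixotroph")

FOCAL_CATEGORIES = (Category.OP_RHIZOME.value, Category.OP_ROOTS.value,
                    Category.OP_PROTOCORM.value)

_DELTA_COL = {"C": "delta13C", "N": "delta15N"}
_EPS_COL = {"C": "eps13C", "N": "eps15N"}


def delta_from_ratio(r_sample: float, r_standard: float) -> float:
    """Delta notation: ``(R_sample/R_standard − 1) × 1000`` in per mil.

    Both ratios must be strictly positive (they are abundance ratios of the
    heavy to the light isotope).
    """
    r_sample = np.asarray(r_sample, dtype=float)
    r_standard = np.asarray(r_standard, dtype=float)
    if np.any(r_sample <= 0) or np.any(r_standard <= 0):
        raise ValueError("isotope ratios must be strictly positive")
    out = (r_sample / r_standard - 1.0) * 1000.0
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ProtocormBaseline:
    """Fully mycoheterotrophic endpoint: mean ε13C of protocorms."""

    mean_eps13C_fmh: float
    sd: float
    n: int


class TwoPointCalibration(BaseEstimator, TransformerMixin):
    """Linear calibration of raw delta values against two lab standards.

    Fit on a standards table with columns ``name, known_delta13C,
    known_delta15N, measured_delta13C, measured_delta15N`` (exactly two
    distinct standards); the line maps measured → known exactly at both.

    Parameters
    ----------
    element : {"C", "N"}
        Which element's deltas this instance calibrates.

    Attributes
    ----------
    slope_ : float
    intercept_ : float
        Calibrated delta = ``slope_ * raw + intercept_``.
    """

    def __init__(self, element: str = "C"):
        self.element = element

    def fit(self, standards: pd.DataFrame, y=None) -> "TwoPointCalibration":
        if self.element not in ("C", "N"):
            raise ValueError(f"element must be 'C' or 'N', got {self.element!r}")
        if len(standards) != 2:
            raise ValueError("exactly two laboratory standards are required")
        suffix = "delta13C" if self.element == "C" else "delta15N"
        known = standards[f"known_{suffix}"].to_numpy(dtype=float)
        measured = standards[f"measured_{suffix}"].to_numpy(dtype=float)
        if not (np.all(np.isfinite(known)) and np.all(np.isfinite(measured))):
            raise ValueError("standard delta values must be finite")
        if measured[0] == measured[1]:
            raise ValueError("singular calibration: identical measured values "
                             f"for element {self.element}")
        self.slope_ = (known[1] - known[0]) / (measured[1] - measured[0])
        self.intercept_ = known[0] - self.slope_ * measured[0]
        return self

    def transform(self, raw_delta) -> np.ndarray:
        """Apply the calibration line to raw delta values (‰)."""
        raw = np.asarray(raw_delta, dtype=float)
        return self.slope_ * raw + self.intercept_


class EnrichmentFactors(BaseEstimator, TransformerMixin):
    """Per-plot enrichment factors relative to autotrophic references.

    ``fit`` computes, for each plot and element, the arithmetic mean delta of
    the plot's ``AUTO_REF`` specimens — the baseline; the sampling design
    requires at least `min_refs` references per plot. ``transform`` subtracts
    each specimen's plot baseline from its delta values.  Reference plants
    also receive ε (against their own plot mean) as a diagnostic — within a
    plot those average to exactly zero.

    Attributes
    ----------
    baselines_ : DataFrame
        ``plot_id, population, n_refs, mean_delta13C_ref, mean_delta15N_ref``.
    """

    def __init__(self, min_refs: int = 3):
        self.min_refs = min_refs

    def fit(self, specimens: pd.DataFrame, y=None) -> "EnrichmentFactors":
        refs = specimens[specimens["category"] == Category.AUTO_REF.value]
        rows = []
        for plot, grp in refs.groupby("plot_id", sort=True):
            n13 = int(grp["delta13C"].notna().sum())
            n15 = int(grp["delta15N"].notna().sum())
            n = min(n13, n15) if (n13 and n15) else max(n13, n15)
            if n < self.min_refs:
                raise ValueError(
                    f"plot {plot!r} has {n} autotrophic references with delta "
                    f"values; at least {self.min_refs} are required")
            rows.append((plot, grp["population"].iloc[0], n,
                         float(grp["delta13C"].mean()), float(grp["delta15N"].mean())))
        self.baselines_ = pd.DataFrame(
            rows, columns=["plot_id", "population", "n_refs",
                           "mean_delta13C_ref", "mean_delta15N_ref"])
        return self

    def transform(self, specimens: pd.DataFrame) -> pd.DataFrame:
        """Return specimens with ``eps13C`` and ``eps15N`` columns appended."""
        base = self.baselines_.set_index("plot_id")
        missing = sorted(set(specimens["plot_id"]) - set(base.index))
        if missing:
            raise ValueError(f"no autotroph baseline for plots {missing}")
        out = specimens.copy()
        b13 = out["plot_id"].map(base["mean_delta13C_ref"])
        b15 = out["plot_id"].map(base["mean_delta15N_ref"])
        out["eps13C"] = out["delta13C"] - b13
        out["eps15N"] = out["delta15N"] - b15
        logger.info("enrichment_factors: %d specimens against %d plot baselines",
                    len(out), len(base))
        return out


class FungalCarbonMixingModel(BaseEstimator, TransformerMixin):
    """Linear two-source mixing model for percent fungal-derived carbon.

    ``%Cdf = (ε13C_specimen / ε13C_fmh) × 100`` interpolates a specimen's
    carbon enrichment between the autotrophic endpoint (ε = 0, 0% fungal
    carbon) and the fully mycoheterotrophic endpoint ε13C_fmh (100%).  The
    endpoint is estimated in ``fit`` as the mean ε13C of ``OP_PROTOCORM``
    records, or supplied directly via `endpoint` (e.g. a literature value)
    when no protocorms were sampled.

    Estimates are deliberately not clamped to [0, 100]; values outside that
    range keep their sign and are marked in the ``pct_cdf_out_of_range``
    column. Only the carbon channel enters the model; ε15N never does.

    Attributes
    ----------
    endpoint_ : ProtocormBaseline
    """

    def __init__(self, endpoint: float | None = None):
        self.endpoint = endpoint

    def fit(self, enriched: pd.DataFrame | None = None, y=None) -> "FungalCarbonMixingModel":
        if self.endpoint is not None:
            self.endpoint_ = ProtocormBaseline(float(self.endpoint), float("nan"), 0)
        else:
            if enriched is None:
                raise ValueError("need enrichment records or an explicit endpoint")
            eps = enriched.loc[enriched["category"] == Category.OP_PROTOCORM.value,
                               "eps13C"].dropna()
            if eps.empty:
                raise ValueError(
                    "no protocorm ε13C records: the fully mycoheterotrophic "
                    "endpoint cannot be estimated — pass endpoint=<‰> with a "
                    "literature value instead")
            self.endpoint_ = ProtocormBaseline(
                float(eps.mean()),
                float(eps.std(ddof=1)) if len(eps) > 1 else 0.0,
                int(len(eps)))
        if self.endpoint_.mean_eps13C_fmh == 0:
            raise ZeroDivisionError("mycoheterotrophic endpoint ε13C is zero")
        return self

    def transform(self, enriched: pd.DataFrame) -> pd.DataFrame:
        """Append ``pct_cdf`` (and its out-of-range flag) for focal specimens.

        ``pct_cdf`` is left missing for autotrophic reference plants: the
        model is defined only for the orchid's own tissues.
        """
        out = enriched.copy()
        focal = out["category"].isin(FOCAL_CATEGORIES)
        pct = out["eps13C"] / self.endpoint_.mean_eps13C_fmh * 100.0
        out["pct_cdf"] = pct.where(focal)
        out["pct_cdf_out_of_range"] = ((out["pct_cdf"] < 0) | (out["pct_cdf"] > 100)).fillna(False)
        return out


# ---------------------------------------------------------------------------
# thin functional wrappers


def fit_two_point_calibration(standards: pd.DataFrame, element: str) -> TwoPointCalibration:
    """Fit the two-standard calibration line for one element."""
    return TwoPointCalibration(element=element).fit(standards)


def apply_calibration(line: TwoPointCalibration, raw_delta):
    """Apply a fitted calibration line to raw delta values."""
    return line.transform(raw_delta)


def plot_autotroph_baseline(specimens: pd.DataFrame, plot_id: str,
                            min_refs: int = 3) -> pd.Series:
    """Mean reference deltas for one plot (row of ``EnrichmentFactors.baselines_``)."""
    sub = specimens[specimens["plot_id"] == plot_id]
    if sub.empty:
        raise ValueError(f"no specimens in plot {plot_id!r}")
    fitted = EnrichmentFactors(min_refs=min_refs).fit(sub)
    return fitted.baselines_.iloc[0]


def enrichment_factors(specimens: pd.DataFrame, min_refs: int = 3) -> pd.DataFrame:
    """Fit plot baselines and return specimens with ε columns appended."""
    return EnrichmentFactors(min_refs=min_refs).fit(specimens).transform(specimens)


def protocorm_baseline(enriched: pd.DataFrame) -> ProtocormBaseline:
    """Mean / sample SD / n of protocorm ε13C (the mixing-model endpoint)."""
    return FungalCarbonMixingModel().fit(enriched).endpoint_


def percent_fungal_carbon(eps13C, baseline: ProtocormBaseline | float):
    """``(ε13C / ε13C_fmh) × 100`` — scalar or vector, unclamped."""
    endpoint = baseline.mean_eps13C_fmh if isinstance(baseline, ProtocormBaseline) else float(baseline)
    if endpoint == 0:
        raise ZeroDivisionError("mycoheterotrophic endpoint ε13C is zero")
    out = np.asarray(eps13C, dtype=float) / endpoint * 100.0
    return float(out) if out.ndim == 0 else out


def group_summary(records: pd.DataFrame, by: list[str] | str = "category",
                  metrics: list[str] | None = None) -> pd.DataFrame:
    """Mean ± sample SD and n per group for each metric column.

    SD uses the n−1 denominator and is reported missing for n < 2; NaN
    metric values are excluded per metric (n reflects that).
    """
    if isinstance(by, str):
        by = [by]
    if metrics is None:
        metrics = [c for c in ("delta13C", "delta15N", "eps13C", "eps15N", "pct_cdf")
                   if c in records.columns]
    rows = []
    for keys, grp in records.groupby(by, sort=True, dropna=False):
        keys = keys if isinstance(keys, tuple) else (keys,)
        row = dict(zip(by, keys))
        for m in metrics:
            vals = grp[m].dropna()
            row[f"{m}_mean"] = float(vals.mean()) if len(vals) else float("nan")
            row[f"{m}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
            row[f"{m}_n"] = int(len(vals))
        rows.append(row)
    return pd.DataFrame(rows)
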