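"""SST-product agreement: global-mean anomalies, detrending, PCA, pairwise RMSE.

Before trusting any single SST product as a bleaching predictor, the products
are compared on coarse common ground: area-weighted global-mean annual
anomalies.  Products enter the PCA as observations over year-variables (a
handful of points in year-space), so clustering of products — and any clear
outlier — is read directly off the leading component scores.  Pairwise annual
difference series and their RMSE quantify consistent discrepancies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
import xarray as xr
from sklearn.decomposition import PCA

__all__ = [
    "ProductAnnualSeries",
    "global_annual_anomaly",
    "detrend_linear",
    "product_pca",
    "PcaResult",
    "pairwise_stats",
    "ensemble_to_products",
]


@dataclass(frozen=True)
class ProductAnnualSeries:
    """Global-mean annual SST anomaly series for one product."""

    product_name: str
    years: np.ndarray
    anomaly: np.ndarray  # degC, relative to the stated baseline

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        anom = np.asarray(self.anomaly, dtype=float)
        if len(years) != len(anom):
            raise ValueError("years and anomaly must have equal length")
        if np.any(np.diff(years) <= 0):
            raise ValueError("years must be strictly increasing")
        if not np.all(np.isfinite(anom)):
            raise ValueError("anomalies must be finite")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "anomaly", anom)

    def to_series(self) -> pd.Series:
        return pd.Series(self.anomaly, index=pd.Index(self.years, name="year"),
                         name=self.product_name)


def global_annual_anomaly(
    gridded_sst: xr.DataArray,
    baseline: Tuple[int, int],
    product_name: str = "",
) -> ProductAnnualSeries:
    """Area-weighted (cos latitude) global-mean annual anomaly series.

    Each cell's annual means are referenced to that cell's mean over the
    baseline years, then averaged spatially with cos(lat) weights.  The input
    must have ``time``, ``lat`` and ``lon`` dimensions (daily, monthly or
    annual time steps).
    """
    annual = gridded_sst.groupby("time.year").mean("time")
    y0, y1 = baseline
    base = annual.sel(year=slice(y0, y1))
    if base.sizes.get("year", 0) == 0:
        raise ValueError(f"gridded field does not cover baseline {y0}-{y1}")
    anom = annual - base.mean("year")
    weights = np.cos(np.deg2rad(anom["lat"]))
    series = anom.weighted(weights).mean(("lat", "lon"))
    return ProductAnnualSeries(
        product_name=product_name,
        years=series["year"].values,
        anomaly=series.values,
    )


def detrend_linear(series: ProductAnnualSeries) -> ProductAnnualSeries:
    """Residuals of the OLS fit of anomaly on year (removes the warming trend)."""
    if len(series.years) < 3:
        raise ValueError("need at least 3 years to detrend")
    coeffs = np.polyfit(series.years.astype(float), series.anomaly, deg=1)
    resid = series.anomaly - np.polyval(coeffs, series.years.astype(float))
    return ProductAnnualSeries(series.product_name, series.years, resid)


def _common_matrix(products: Sequence[ProductAnnualSeries]) -> Tuple[np.ndarray, np.ndarray, list]:
    names = [p.product_name for p in products]
    years0 = products[0].years
    for p in products[1:]:
        if len(p.years) != len(years0) or np.any(p.years != years0):
            raise ValueError(f"product {p.product_name!r} covers different years")
    mat = np.vstack([p.anomaly for p in products])
    return mat, years0, names


@dataclass
class PcaResult:
    scores: pd.DataFrame  # product x component
    loadings: pd.DataFrame  # component x year
    explained_variance: np.ndarray


def product_pca(products: Sequence[ProductAnnualSeries], detrend: bool = True) -> PcaResult:
    """PCA of the product-by-year anomaly matrix (products as observations).

    Variables (years) are centered but not standardized — all share degC
    units, and standardizing would distort relative product spread.
    """
    if len(products) < 3:
        raise ValueError("need at least 3 products for a PCA")
    if detrend:
        products = [detrend_linear(p) for p in products]
    mat, years, names = _common_matrix(products)
    pca = PCA()
    scores = pca.fit_transform(mat)
    comp_names = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PcaResult(
        scores=pd.DataFrame(scores, index=pd.Index(names, name="product"), columns=comp_names),
        loadings=pd.DataFrame(pca.components_, index=comp_names,
                              columns=pd.Index(years, name="year")),
        explained_variance=pca.explained_variance_,
    )


def pairwise_stats(
    products: Sequence[ProductAnnualSeries],
) -> Tuple[Dict[Tuple[str, str], pd.Series], pd.DataFrame]:
    """Annual difference series per unordered pair and the symmetric RMSE matrix."""
    mat, years, names = _common_matrix(products)
    diffs: Dict[Tuple[str, str], pd.Series] = {}
    rmse = pd.DataFrame(0.0, index=names, columns=names)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            d = mat[i] - mat[j]
            diffs[(names[i], names[j])] = pd.Series(
                d, index=pd.Index(years, name="year"), name=f"{names[i]}-{names[j]}"
            )
            val = float(np.sqrt(np.mean(d**2)))
            rmse.iloc[i, j] = rmse.iloc[j, i] = val
    return diffs, rmse


def ensemble_to_products(ensemble: pd.DataFrame) -> list[ProductAnnualSeries]:
    """Adapt a year-indexed DataFrame (one column per product) to series objects."""
    return [
        ProductAnnualSeries(str(col), ensemble.index.to_numpy(), ensemble[col].to_numpy())
        for col in ensemble.columns
    ]
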