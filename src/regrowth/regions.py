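"""Climate regionalization and the 16-model regional set.

The landscape is partitioned into k (default 4) climate regions by
K-means on three z-scored climate drivers — mean annual MCWD, shortwave
radiation and precipitation — computed over the pixels that carry
secondary forest (the regions describe conditions the regrowing forests
experience). Cluster labels are canonicalized by ascending mean
shortwave radiation so that "region 1" is reproducibly the wettest,
lowest-radiation cluster.

Each region is crossed with the four disturbance classes
(single/repeated deforestation × burnt/not burnt), giving 16 growth
models; every secondary patch maps to exactly one of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .growth import ChapmanRichardsResults
from .synthetic import DISTURBANCE_CLASSES

__all__ = ["RegionalModelSet", "kmeans_regions", "assign_models", "class_prevalence"]


def kmeans_regions(
    driver_surfaces: dict[str, np.ndarray],
    mask: np.ndarray | None = None,
    k: int = 4,
    seed: int | None = None,
    n_init: int = 10,
    assign_all: bool = True,
):
    """Cluster pixels into k climate regions.

    Parameters
    ----------
    driver_surfaces
        Mapping with keys ``mcwd``, ``sw_radiation``, ``precipitation``
        (co-registered 2-D arrays).
    mask
        Boolean raster of pixels the centroids are fitted on (e.g.
        secondary forest). All pixels when None.
    assign_all
        When True (default) every pixel of the domain is assigned to
        its nearest centroid — a pixel's region depends only on its own
        driver vector — so old-growth pixels also carry a region id.
        When False, pixels outside the mask get region 0.
    seed, n_init
        K-means is restarted ``n_init`` times from seeded initial
        centroids; the best objective is kept.

    Returns
    -------
    region_raster : int array, region ids 1..k
    summaries : DataFrame of per-region driver means over the fit mask
        (original units)
    """
    names = ["mcwd", "sw_radiation", "precipitation"]
    missing = [n for n in names if n not in driver_surfaces]
    if missing:
        raise KeyError(f"missing driver surfaces: {missing}")
    shape = np.asarray(driver_surfaces[names[0]]).shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    X = np.column_stack([np.asarray(driver_surfaces[n], dtype=float)[mask] for n in names])
    if np.unique(X, axis=0).shape[0] < k:
        raise ValueError(f"fewer than k={k} distinct driver vectors")

    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xz = (X - mu) / sd

    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw_labels = km.fit_predict(Xz)

    # canonical ids: ascending mean shortwave radiation
    sw = X[:, names.index("sw_radiation")]
    sw_means = np.array([sw[raw_labels == j].mean() for j in range(k)])
    order = np.argsort(sw_means)
    new_id = np.empty(k, dtype=int)
    new_id[order] = np.arange(1, k + 1)
    labels = new_id[raw_labels]

    region_raster = np.zeros(shape, dtype=np.int16)
    if assign_all:
        X_all = np.column_stack(
            [np.asarray(driver_surfaces[n], dtype=float).ravel() for n in names]
        )
        all_labels = km.predict((X_all - mu) / sd)
        region_raster = new_id[all_labels].reshape(shape).astype(np.int16)
    else:
        region_raster[mask] = labels

    rows = []
    for rid in range(1, k + 1):
        sel = labels == rid
        rows.append(
            {"region": rid, "n_pixels": int(sel.sum())}
            | {n: float(X[sel, j].mean()) for j, n in enumerate(names)}
        )
    summaries = pd.DataFrame(rows).set_index("region")
    return region_raster, summaries


@dataclass
class RegionalModelSet:
    """Region raster + the 16 growth fits keyed (region_id, disturbance class)."""

    region_raster: np.ndarray
    summaries: pd.DataFrame
    fits: dict[tuple[int, str], ChapmanRichardsResults]
    asymptotes: dict[tuple[int, str], float] = field(default_factory=dict)
    bias_offsets: dict[tuple[int, str], float] = field(default_factory=dict)

    @property
    def regions(self) -> list[int]:
        return sorted({key[0] for key in self.fits})

    def no_disturbance_fit(self, region: int) -> ChapmanRichardsResults:
        return self.fits[(region, "single_not_burnt")]

    def fit_table(self) -> pd.DataFrame:
        rows = []
        for (region, cls), fit in sorted(self.fits.items()):
            rows.append({"region": region, "dist_class": cls} | fit.to_dict())
        return pd.DataFrame(rows)


def assign_models(
    patch_table: pd.DataFrame,
    fits: dict[tuple[int, str], ChapmanRichardsResults],
) -> pd.Series:
    """Map every patch to its (region, disturbance class) growth fit.

    Raises KeyError naming every (region, class) combination occurring
    in the patch table without a fitted model.
    """
    keys = list(zip(patch_table["region_id"].astype(int), patch_table["dist_class"]))
    missing = sorted({key for key in keys if key not in fits})
    if missing:
        raise KeyError(f"no growth fit for (region, class): {missing}")
    return pd.Series([fits[key] for key in keys], index=patch_table.index, name="fit")


def class_prevalence(patch_table: pd.DataFrame) -> pd.DataFrame:
    """Percent of secondary-forest area in each disturbance class per region."""
    area = patch_table.groupby(["region_id", "dist_class"], observed=True)["area_m2"].sum()
    pct = area / area.groupby(level=0).sum() * 100.0
    out = pct.unstack(fill_value=0.0)
    for cls in DISTURBANCE_CLASSES:
        if cls not in out.columns:
            out[cls] = 0.0
    return out[list(DISTURBANCE_CLASSES)]
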