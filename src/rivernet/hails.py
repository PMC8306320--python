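"""Human-activity intensity of land surface (HAILS).

HAILS for a sub-basin is the percentage of its land area under directly
human-influenced cover — by default farmland plus urban/residential land:

    HAILS = 100 * sum(area of human classes) / total area

Sub-basins are then binned into low / middle / high intensity reaches,
either by tertiles of the HAILS ranking or by fixed user thresholds.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import LandUseTable

logger = logging.getLogger(__name__)

DEFAULT_HUMAN_CLASSES = frozenset({"farmlands", "urban"})

_LABELS = ("low", "middle", "high")


def compute_hails(
    landuse: LandUseTable, human_classes: frozenset[str] | set[str] = DEFAULT_HUMAN_CLASSES
) -> pd.DataFrame:
    """HAILS percentage per sub-basin.

    Returns a DataFrame with a single ``hails_pct`` column in [0, 100].
    """
    unknown = set(human_classes) - set(landuse.areas.columns)
    if unknown:
        raise ValueError(f"human classes not in land-use table: {sorted(unknown)}")
    if (landuse.total <= 0).any():
        bad = landuse.total.index[landuse.total <= 0].tolist()
        raise ValueError(f"zero total area for sub-basins: {bad}")
    human_area = landuse.areas[sorted(human_classes)].sum(axis=1)
    pct = 100.0 * human_area / landuse.total
    return pd.DataFrame({"hails_pct": pct})


def classify_reaches(
    result: pd.DataFrame,
    method: str = "tertile",
    thresholds: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Assign low/middle/high intensity labels.

    ``tertile`` ranks sub-basins by ``hails_pct`` and splits them into three
    groups as equal in size as possible (ties broken by table order, i.e.
    upstream first); ``fixed`` labels by two increasing thresholds.
    """
    pct = result["hails_pct"]
    out = result.copy()
    if method == "tertile":
        if len(pct) < 3:
            raise ValueError("tertile classification needs at least 3 sub-basins")
        if pct.nunique() == 1:
            logger.warning("degenerate gradient: all HAILS values equal; assigning 'low'")
            out["class_label"] = "low"
            return out
        order = np.argsort(pct.to_numpy(), kind="stable")
        labels = np.empty(len(pct), dtype=object)
        bounds = np.array_split(np.arange(len(pct)), 3)
        for label, chunk in zip(_LABELS, bounds):
            labels[order[chunk]] = label
        out["class_label"] = labels
        realized = [pct.iloc[order[c]].max() for c in bounds[:2]]
        logger.info("tertile boundaries (upper edge of low/middle): %s", realized)
    elif method == "fixed":
        if thresholds is None or not thresholds[0] < thresholds[1]:
            raise ValueError("fixed classification needs two increasing thresholds")
        lo, hi = thresholds
        out["class_label"] = np.where(pct <= lo, "low", np.where(pct <= hi, "middle", "high"))
    else:
        raise ValueError(f"unknown classification method: {method!r}")
    return out
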