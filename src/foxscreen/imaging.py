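"""Segmentation and morphometry of 3-channel 3D-culture images.

Channel order is Hoechst (nuclei), Calcein (live cell bodies), EthD1
(dead cells). Colonies are the connected components of the binarized
Calcein channel (Otsu threshold — the automatic stand-in for an
interactive threshold step); a colony is dead when at least half of
its pixels are EthD1-positive. Nuclei are segmented from the Hoechst
channel by threshold -> 3x3 median despeckle -> distance-transform
watershed, and their pixel areas measured.

Downstream calls: a colony with no nucleus centroid inside its mask is
*anuclear*; a nucleus far smaller than the vehicle-median area
(default < 30%) is *fragmented*; condition-level size and count
comparisons use large-sample z-tests with a signed-fold convention
(ratio if >= 1, else -1/ratio).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats

__all__ = [
    "whole_percent",
    "segment_colonies",
    "segment_nuclei",
    "detect_anuclear",
    "classify_fragmented",
    "FoldChangeReport",
    "compare_morphology",
    "compare_counts",
    "quantify_image",
    "analyze_experiment",
]


def whole_percent(k: int, n: int) -> int:
    """Round a count ratio to a whole percent (half away from zero)."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return int(math.floor(100.0 * k / n + 0.5))


def _auto_threshold(img: np.ndarray, contrast_sd: float = 4.0) -> float | None:
    """Otsu threshold with a contrast guard.

    Returns None for a blank channel: constant input, or an Otsu split
    whose foreground/background mean separation is below
    ``contrast_sd`` background standard deviations (i.e. the split is
    carving noise, not signal).
    """
    from skimage.filters import threshold_otsu

    img = np.asarray(img, dtype=float)
    if img.max() == img.min():
        return None
    thr = threshold_otsu(img)
    fg = img > thr
    if not fg.any() or fg.all():
        return None
    bg = img[~fg]
    sd = bg.std()
    if sd == 0:
        return thr
    if (img[fg].mean() - bg.mean()) < contrast_sd * sd:
        return None
    return thr


def segment_colonies(
    calcein: np.ndarray,
    ethd1: np.ndarray | None = None,
    min_area: int = 100,
    dead_overlap: float = 0.5,
    image_id: str = "",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Segment cell colonies from the Calcein channel.

    Returns ``(metrics, labels)``: one row per colony (image_id,
    colony_id, area, live, dead) and the labelled mask. A blank
    channel yields zero colonies with a warning. Dead means the EthD1-
    positive pixel fraction inside the colony reaches ``dead_overlap``.
    """
    from skimage.measure import label, regionprops

    calcein = np.asarray(calcein, dtype=float)
    thr = _auto_threshold(calcein)
    if thr is None:
        warnings.warn("blank Calcein channel: no colonies", stacklevel=2)
        return (pd.DataFrame(columns=["image_id", "colony_id", "area",
                                      "live", "dead"]),
                np.zeros(calcein.shape, dtype=np.int32))
    mask = ndi.median_filter((calcein > thr).astype(np.uint8), size=3).astype(bool)
    labels = label(mask)

    if ethd1 is not None:
        ethr = _auto_threshold(np.asarray(ethd1, dtype=float))
        emask = np.asarray(ethd1, dtype=float) > ethr if ethr is not None \
            else np.zeros_like(mask)
    else:
        emask = np.zeros_like(mask)

    rows = []
    keep = np.zeros(labels.max() + 1, dtype=np.int32)
    nxt = 1
    for region in regionprops(labels):
        if region.area < min_area:
            continue
        keep[region.label] = nxt
        sl = region.slice
        region_mask = labels[sl] == region.label
        frac_dead = emask[sl][region_mask].mean()
        dead = bool(frac_dead >= dead_overlap)
        rows.append({
            "image_id": image_id, "colony_id": nxt,
            "area": int(region.area), "live": not dead, "dead": dead,
        })
        nxt += 1
    relabelled = keep[labels]
    return pd.DataFrame(rows, columns=["image_id", "colony_id", "area",
                                       "live", "dead"]), relabelled


def segment_nuclei(
    hoechst: np.ndarray,
    min_area: int = 8,
    min_distance: int = 5,
    image_id: str = "",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Segment nuclei: threshold, despeckle, watershed split, measure.

    Returns ``(records, labels)``: one row per nucleus (image_id,
    nucleus_id, area, cy, cx) and the labelled mask. Touching nuclei
    are split on peaks of the (smoothed) distance transform at least
    ``min_distance`` pixels apart.
    """
    from skimage.feature import peak_local_max
    from skimage.measure import label, regionprops
    from skimage.segmentation import watershed

    hoechst = np.asarray(hoechst, dtype=float)
    empty = pd.DataFrame(columns=["image_id", "nucleus_id", "area", "cy", "cx"])
    thr = _auto_threshold(hoechst)
    if thr is None:
        return empty, np.zeros(hoechst.shape, dtype=np.int32)
    mask = ndi.median_filter((hoechst > thr).astype(np.uint8), size=3).astype(bool)
    if not mask.any():
        return empty, np.zeros(hoechst.shape, dtype=np.int32)

    dist = ndi.distance_transform_edt(mask)
    dist_s = ndi.gaussian_filter(dist, 1.0)
    coords = peak_local_max(dist_s, min_distance=min_distance, labels=label(mask))
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels_ws = label(mask)
    else:
        labels_ws = watershed(-dist_s, markers, mask=mask)

    rows = []
    keep = np.zeros(labels_ws.max() + 1, dtype=np.int32)
    nxt = 1
    for region in regionprops(labels_ws):
        if region.area < min_area:
            continue
        keep[region.label] = nxt
        cy, cx = region.centroid
        rows.append({
            "image_id": image_id, "nucleus_id": nxt,
            "area": int(region.area), "cy": float(cy), "cx": float(cx),
        })
        nxt += 1
    return pd.DataFrame(rows, columns=["image_id", "nucleus_id", "area",
                                       "cy", "cx"]), keep[labels_ws]


def detect_anuclear(
    colonies: pd.DataFrame,
    colony_labels: np.ndarray,
    nuclei: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Flag colonies with no nucleus centroid inside their mask.

    Returns the colony table with a ``has_nucleus`` column and a
    summary dict with raw counts, the anuclear fraction, and the
    whole-percent presentation of that fraction.
    """
    with_nucleus: set[int] = set()
    for _, nuc in nuclei.iterrows():
        r, c = int(round(nuc["cy"])), int(round(nuc["cx"]))
        if 0 <= r < colony_labels.shape[0] and 0 <= c < colony_labels.shape[1]:
            lab = int(colony_labels[r, c])
            if lab > 0:
                with_nucleus.add(lab)
    out = colonies.copy()
    out["has_nucleus"] = out["colony_id"].map(lambda cid: cid in with_nucleus)
    n = len(out)
    n_anuclear = int((~out["has_nucleus"]).sum()) if n else 0
    summary = {
        "n_colonies": n,
        "n_anuclear": n_anuclear,
        "fraction": (n_anuclear / n) if n else 0.0,
        "percent": whole_percent(n_anuclear, n) if n else 0,
    }
    return out, summary


def classify_fragmented(
    nuclei: pd.DataFrame,
    vehicle_nuclei: pd.DataFrame,
    frag_ratio: float = 0.3,
) -> tuple[pd.DataFrame, dict]:
    """Flag nuclei smaller than ``frag_ratio`` x the vehicle median area.

    Operationalizes a by-eye fragmentation call as a configurable area
    ratio against the vehicle-treated size distribution. Returns the
    nucleus table with a ``fragmented`` column plus a count summary.
    """
    if len(vehicle_nuclei) == 0:
        raise ValueError("vehicle nucleus set is empty")
    cutoff = frag_ratio * float(vehicle_nuclei["area"].median())
    out = nuclei.copy()
    out["fragmented"] = out["area"].astype(float) < cutoff
    n, k = len(out), int(out["fragmented"].sum())
    summary = {
        "n_nuclei": n, "n_fragmented": k,
        "area_cutoff": cutoff, "frag_ratio": frag_ratio,
        "fraction": (k / n) if n else 0.0,
        "percent": whole_percent(k, n) if n else 0,
    }
    return out, summary


@dataclass(frozen=True)
class FoldChangeReport:
    """Condition-vs-vehicle comparison with a signed-fold convention."""

    condition: str
    n_treated: int
    n_vehicle: int
    mean_treated: float
    mean_vehicle: float
    fold: float          # plain ratio treated / vehicle
    signed_fold: float   # ratio if >= 1 else -1 / ratio
    p: float
    test: str            # "z" | "t" | "z-count"


def _signed(fold: float) -> float:
    if fold <= 0:
        return float("nan")
    return fold if fold >= 1.0 else -1.0 / fold


def compare_morphology(
    treated_areas: Sequence[float],
    vehicle_areas: Sequence[float],
    condition: str = "",
    min_n_z: int = 30,
) -> FoldChangeReport:
    """Two-sample z-test on mean object areas (large-sample).

    Falls back to Welch's t-test with a warning when either arm has
    fewer than ``min_n_z`` objects (the large-sample normal
    approximation needs dozens of objects per arm).
    """
    t = np.asarray(treated_areas, dtype=float)
    v = np.asarray(vehicle_areas, dtype=float)
    if len(t) < 2 or len(v) < 2:
        raise ValueError("need >= 2 objects per arm")
    mt, mv = t.mean(), v.mean()
    if len(t) >= min_n_z and len(v) >= min_n_z:
        se = math.sqrt(t.var(ddof=1) / len(t) + v.var(ddof=1) / len(v))
        z = 0.0 if se == 0 else (mt - mv) / se
        p = 2.0 * stats.norm.sf(abs(z))
        test = "z"
    else:
        warnings.warn("small sample: falling back to Welch's t-test",
                      stacklevel=2)
        res = stats.ttest_ind(t, v, equal_var=False)
        p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
        test = "t"
    fold = mt / mv if mv > 0 else float("nan")
    return FoldChangeReport(
        condition=condition, n_treated=len(t), n_vehicle=len(v),
        mean_treated=float(mt), mean_vehicle=float(mv),
        fold=float(fold), signed_fold=_signed(fold), p=float(p), test=test,
    )


def compare_counts(
    n_treated: int,
    n_vehicle: int,
    condition: str = "",
) -> FoldChangeReport:
    """Standardized-count z-test for object counts (e.g. colony numbers).

    Under a Poisson model for the two totals, ``z = (n1 - n2) /
    sqrt(n1 + n2)``.
    """
    if n_treated < 0 or n_vehicle < 0:
        raise ValueError("counts must be non-negative")
    tot = n_treated + n_vehicle
    z = 0.0 if tot == 0 else (n_treated - n_vehicle) / math.sqrt(tot)
    p = 2.0 * stats.norm.sf(abs(z))
    fold = n_treated / n_vehicle if n_vehicle > 0 else float("nan")
    return FoldChangeReport(
        condition=condition, n_treated=n_treated, n_vehicle=n_vehicle,
        mean_treated=float(n_treated), mean_vehicle=float(n_vehicle),
        fold=float(fold), signed_fold=_signed(fold), p=float(p), test="z-count",
    )


def quantify_image(
    stack: np.ndarray,
    image_id: str = "",
    min_colony_area: int = 100,
    min_nucleus_area: int = 8,
    min_distance: int = 5,
    dead_overlap: float = 0.5,
) -> dict:
    """Segment one (3, H, W) stack (Hoechst, Calcein, EthD1).

    Returns a dict with ``colonies`` (incl. has_nucleus), ``nuclei``,
    and the anuclear summary.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] != 3:
        raise ValueError("stack must have shape (3, H, W)")
    hoechst, calcein, ethd1 = stack[0], stack[1], stack[2]
    nuclei, _nlab = segment_nuclei(
        hoechst, min_area=min_nucleus_area, min_distance=min_distance,
        image_id=image_id)
    colonies, clab = segment_colonies(
        calcein, ethd1, min_area=min_colony_area, dead_overlap=dead_overlap,
        image_id=image_id)
    colonies, anuclear = detect_anuclear(colonies, clab, nuclei)
    return {"colonies": colonies, "nuclei": nuclei, "anuclear": anuclear}


def analyze_experiment(
    images: Mapping[str, Sequence[np.ndarray]],
    vehicle_condition: str,
    frag_ratio: float = 0.3,
    **segment_kwargs,
) -> dict:
    """Quantify a multi-condition imaging experiment.

    ``images`` maps condition name -> list of (3, H, W) stacks. Every
    condition is compared with the vehicle: nuclear-size fold change
    (z-test), colony-count z-test, anuclear and fragmented
    percentages. Returns per-object tables and a per-condition summary
    DataFrame.
    """
    if vehicle_condition not in images:
        raise ValueError(f"vehicle condition {vehicle_condition!r} not in images")

    per_cond: dict[str, dict] = {}
    for cond, stacks in images.items():
        nuc_parts, col_parts = [], []
        n_anuclear = n_colonies = 0
        for i, stack in enumerate(stacks):
            res = quantify_image(stack, image_id=f"{cond}_{i}", **segment_kwargs)
            nuc_parts.append(res["nuclei"])
            col_parts.append(res["colonies"])
            n_anuclear += res["anuclear"]["n_anuclear"]
            n_colonies += res["anuclear"]["n_colonies"]
        per_cond[cond] = {
            "nuclei": pd.concat(nuc_parts, ignore_index=True) if nuc_parts
            else pd.DataFrame(columns=["image_id", "nucleus_id", "area"]),
            "colonies": pd.concat(col_parts, ignore_index=True) if col_parts
            else pd.DataFrame(columns=["image_id", "colony_id", "area"]),
            "n_anuclear": n_anuclear, "n_colonies": n_colonies,
        }

    vehicle_nuclei = per_cond[vehicle_condition]["nuclei"]
    rows = []
    for cond, data in per_cond.items():
        nuc = data["nuclei"]
        frag_pct = float("nan")
        if len(nuc) and len(vehicle_nuclei):
            _, frag = classify_fragmented(nuc, vehicle_nuclei, frag_ratio)
            frag_pct = frag["percent"]
        if cond == vehicle_condition or len(nuc) < 2 or len(vehicle_nuclei) < 2:
            size_fold, size_p = 1.0 if cond == vehicle_condition else float("nan"), float("nan")
        else:
            rep = compare_morphology(nuc["area"], vehicle_nuclei["area"],
                                     condition=cond)
            size_fold, size_p = rep.signed_fold, rep.p
        count_rep = compare_counts(
            data["n_colonies"], per_cond[vehicle_condition]["n_colonies"],
            condition=cond)
        rows.append({
            "condition": cond,
            "n_nuclei": len(nuc),
            "mean_nucleus_area": float(nuc["area"].mean()) if len(nuc) else float("nan"),
            "size_signed_fold": size_fold,
            "size_p": size_p,
            "n_colonies": data["n_colonies"],
            "colony_count_p": count_rep.p,
            "anuclear_percent": whole_percent(data["n_anuclear"], data["n_colonies"])
            if data["n_colonies"] else 0,
            "fragmented_percent": frag_pct,
        })
    summary = pd.DataFrame(rows).set_index("condition")
    return {"summary": summary, "conditions": per_cond}
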