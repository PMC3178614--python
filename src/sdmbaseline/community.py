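"""Modeled historical community construction.

For every species whose model ensemble passed the acceptance rule, the
maximum modeled probability of occurrence inside the focal watershed is
extracted as a coarse proxy for establishment potential, and joined to
collection-event counts from surveys and historical records.  A native
species with high modeled suitability (above a probability threshold,
default 0.5) but zero detections in every source is classified
"modeled-but-undocumented" -- the signature of a community member lost
before it was ever recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .layers import RegionMask
from .maxent import ReplicateEnsemble
from .validation import AcceptanceDecision

__all__ = [
    "ModeledCommunityTable",
    "extract_watershed_max",
    "build_modeled_community",
    "STATUS_DOCUMENTED",
    "STATUS_MODELED_UNDOCUMENTED",
    "STATUS_LOW_SUITABILITY",
]

STATUS_DOCUMENTED = "documented"
STATUS_MODELED_UNDOCUMENTED = "modeled-but-undocumented"
STATUS_LOW_SUITABILITY = "low-suitability"

DETECTION_SOURCES = ("survey_a", "survey_b", "historical")


def extract_watershed_max(
    ensemble: ReplicateEnsemble,
    watershed: RegionMask,
    aggregate: str = "mean",
) -> float:
    """Maximum logistic suitability inside the watershed.

    With ``aggregate="mean"`` (default) the replicate logistic surfaces
    are averaged cell-wise first and the maximum of the mean surface is
    returned; ``aggregate="per-replicate"`` instead takes each replicate's
    watershed maximum and averages those.
    """
    mask = watershed.values
    if aggregate == "mean":
        surf = ensemble.mean_logistic_surface()
        vals = surf[mask]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(
                f"watershed mask {watershed.name!r} overlaps no valid cells")
        return float(vals.max())
    if aggregate == "per-replicate":
        maxima = []
        for rep in ensemble.replicates:
            vals = rep.surface.logistic[mask]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                raise ValueError(
                    f"watershed mask {watershed.name!r} overlaps no valid cells")
            maxima.append(vals.max())
        return float(np.mean(maxima))
    raise ValueError("aggregate must be 'mean' or 'per-replicate'")


@dataclass
class ModeledCommunityTable:
    """Per-species watershed suitability joined to detection histories.

    ``rows`` is sorted by max_watershed_probability descending (stable);
    only species whose ensembles were accepted appear.
    """

    rows: pd.DataFrame
    watershed_id: str
    threshold: float
    provenance: dict = field(default_factory=dict)

    def species_with_status(self, status: str) -> list[str]:
        return self.rows.loc[self.rows["status"] == status, "species_id"].tolist()

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def classify_status(native: bool, total_detections: int,
                    max_probability: float, threshold: float) -> str:
    if total_detections > 0:
        return STATUS_DOCUMENTED
    if native and max_probability > threshold:
        return STATUS_MODELED_UNDOCUMENTED
    return STATUS_LOW_SUITABILITY


def build_modeled_community(
    accepted_models: Mapping[str, tuple[ReplicateEnsemble, AcceptanceDecision]],
    watershed: RegionMask,
    detections: pd.DataFrame | None,
    native: Mapping[str, bool],
    threshold: float = 0.5,
    aggregate: str = "mean",
) -> ModeledCommunityTable:
    """Assemble the modeled-community table.

    ``detections`` holds one row per species with collection-event counts
    in columns ``survey_a``, ``survey_b`` and ``historical`` (missing
    species count as zero everywhere).  Only species whose decision is
    ``accepted`` receive a row.  A non-native species is never classified
    modeled-but-undocumented; an undetected non-native above the threshold
    is instead annotated as a potential invader.
    """
    if detections is None:
        detections = pd.DataFrame(columns=["species_id", *DETECTION_SOURCES])
    det = detections.set_index("species_id") if "species_id" in detections.columns \
        else detections
    rows = []
    for sp in sorted(accepted_models):
        ensemble, decision = accepted_models[sp]
        if not decision.accepted:
            continue
        counts = {src: int(det.at[sp, src]) if sp in det.index and src in det.columns
                  else 0 for src in DETECTION_SOURCES}
        total = sum(counts.values())
        p_max = extract_watershed_max(ensemble, watershed, aggregate=aggregate)
        is_native = bool(native.get(sp, True))
        status = classify_status(is_native, total, p_max, threshold)
        rows.append({
            "species_id": sp,
            "native": is_native,
            "max_watershed_probability": p_max,
            **counts,
            "total": total,
            "mean_test_auc": decision.mean_test_auc,
            "variable_set": ensemble.variable_set_id,
            "n_records": ensemble.n_records,
            "status": status,
            "note": ("potential-invader"
                     if (not is_native and total == 0 and p_max > threshold) else ""),
        })
    frame = pd.DataFrame(rows, columns=[
        "species_id", "native", "max_watershed_probability", *DETECTION_SOURCES,
        "total", "mean_test_auc", "variable_set", "n_records", "status", "note",
    ])
    frame = frame.sort_values("max_watershed_probability", ascending=False,
                              kind="mergesort").reset_index(drop=True)
    return ModeledCommunityTable(rows=frame, watershed_id=watershed.name,
                                 threshold=threshold)
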