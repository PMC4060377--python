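"""End-to-end orchestration: screening -> cells -> features -> voting.

Two entry points matter:

* :func:`run_pipeline` — deployment path: apply a trained model to every
  image of a manifest and emit the full audit trail (per-cell, per-image,
  per-well records).
* :func:`hierarchical_cv` — evaluation path: one-well-out cross-validation
  where each fold trains on the labeled cells of all other wells, then the
  held-out well is pushed through the whole voting hierarchy, yielding
  matched cell-, image- and well-level predictions against ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cells as cellproc
from . import classifier as clf_mod
from .features import extract_features
from .io import DatasetManifest, ManifestRecord, load_record
from .screening import ScreeningParams, prescreen_image

logger = logging.getLogger(__name__)


@dataclass
class ImageCells:
    """Everything the pipeline extracted from one image."""

    record: ManifestRecord
    prescreen: str
    crops: list
    features: np.ndarray  # (n_crops, 60)
    labels: list[str | None]  # matched annotations, None if unmatched
    n_unmatched_annotations: int = 0


@dataclass
class CellTable:
    """Flat view of extracted cells across a manifest."""

    X: np.ndarray
    true_label: np.ndarray  # object; None where unlabeled
    well_id: np.ndarray
    image_id: np.ndarray

    @property
    def labeled(self) -> np.ndarray:
        return np.array([lab is not None for lab in self.true_label])


def process_image(
    manifest: DatasetManifest,
    record: ManifestRecord,
    params: ScreeningParams | None = None,
    match: bool = True,
) -> ImageCells:
    """Screen one image, localize its cells and extract their features."""
    image = load_record(manifest, record)
    prescreen, candidates = prescreen_image(image, params)
    crops = cellproc.extract_cells(image, candidates)
    n_unmatched = 0
    if match and record.cells:
        n_unmatched = cellproc.match_annotations(crops, record.cells)
    feats = (
        np.vstack([extract_features(c) for c in crops])
        if crops
        else np.empty((0, 0))
    )
    return ImageCells(
        record=record,
        prescreen=prescreen,
        crops=crops,
        features=feats,
        labels=[c.true_label for c in crops],
        n_unmatched_annotations=n_unmatched,
    )


def process_manifest(
    manifest: DatasetManifest, params: ScreeningParams | None = None
) -> list[ImageCells]:
    return [process_image(manifest, rec, params) for rec in manifest.records]


def cell_table(processed: list[ImageCells]) -> CellTable:
    X, labels, wells, images = [], [], [], []
    for ic in processed:
        for i, crop in enumerate(ic.crops):
            X.append(ic.features[i])
            labels.append(crop.true_label)
            wells.append(ic.record.well_id)
            images.append(ic.record.image_id)
    return CellTable(
        X=np.vstack(X) if X else np.empty((0, 0)),
        true_label=np.array(labels, dtype=object),
        well_id=np.array(wells, dtype=object),
        image_id=np.array(images, dtype=object),
    )


@dataclass
class PipelineResult:
    """Audit trail of a full run: one row per cell, image and well."""

    cells: pd.DataFrame  # well_id, image_id, x, y, predicted_label
    images: pd.DataFrame  # well_id, image_id, prescreen, n_cells, predicted_label
    wells: pd.DataFrame  # well_id, decision, n_pos_images, n_neg_images

    def decisions(self) -> dict[str, str]:
        return dict(zip(self.wells.well_id, self.wells.decision))


def run_pipeline(
    manifest: DatasetManifest,
    model: clf_mod.TrainedModel,
    params: ScreeningParams | None = None,
) -> PipelineResult:
    """Classify every well of a manifest with a trained model.

    Fails fast on any unreadable image, naming it; no silent skips.
    """
    from .aggregation import classify_image, classify_well

    cell_rows, image_rows, image_labels_by_well = [], [], {}
    for rec in manifest.records:
        try:
            ic = process_image(manifest, rec, params, match=False)
        except (IOError, FileNotFoundError) as exc:
            raise RuntimeError(
                f"pipeline failed on image {rec.image_path!r}: {exc}"
            ) from exc
        preds = (
            list(model.predict(ic.features)) if ic.crops else []
        )
        for crop, pred in zip(ic.crops, preds):
            cell_rows.append(
                {
                    "well_id": rec.well_id,
                    "image_id": rec.image_id,
                    "x": crop.cell_centroid[0],
                    "y": crop.cell_centroid[1],
                    "predicted_label": pred,
                }
            )
        img_label = classify_image(preds, ic.prescreen)
        image_rows.append(
            {
                "well_id": rec.well_id,
                "image_id": rec.image_id,
                "prescreen": ic.prescreen,
                "n_cells": len(ic.crops),
                "predicted_label": img_label,
            }
        )
        image_labels_by_well.setdefault(rec.well_id, []).append(img_label)

    well_rows = []
    for well_id, labels in image_labels_by_well.items():
        d = classify_well(well_id, labels)
        well_rows.append(
            {
                "well_id": well_id,
                "decision": d.decision,
                "n_pos_images": d.n_pos_images,
                "n_neg_images": d.n_neg_images,
            }
        )
    return PipelineResult(
        cells=pd.DataFrame(
            cell_rows, columns=["well_id", "image_id", "x", "y", "predicted_label"]
        ),
        images=pd.DataFrame(
            image_rows,
            columns=["well_id", "image_id", "prescreen", "n_cells", "predicted_label"],
        ),
        wells=pd.DataFrame(
            well_rows, columns=["well_id", "decision", "n_pos_images", "n_neg_images"]
        ),
    )


@dataclass
class HierarchicalCVResult:
    """Matched predictions and truths at all three levels."""

    cell_true: np.ndarray
    cell_pred: np.ndarray
    cell_well: np.ndarray
    image_true: list[str]
    image_pred: list[str]
    image_prescreen: list[str]
    well_true: list[str]
    well_decision: list[str]
    fold_params: dict = field(default_factory=dict)
    skipped_wells: list[str] = field(default_factory=list)

    @property
    def cell_accuracy(self) -> float:
        return float((self.cell_true == self.cell_pred).mean())

    @property
    def image_accuracy(self) -> float:
        hits = sum(t == p for t, p in zip(self.image_true, self.image_pred))
        return hits / len(self.image_true)

    @property
    def well_accuracy(self) -> float:
        hits = sum(t == d for t, d in zip(self.well_true, self.well_decision))
        return hits / len(self.well_true)


def hierarchical_cv(
    manifest: DatasetManifest,
    seed: int = 0,
    params: ScreeningParams | None = None,
) -> HierarchicalCVResult:
    """One-well-out CV through the full voting hierarchy.

    Fold k trains the cell classifier on the labeled cells of every well
    except k, then predicts all cells of well k and votes its images and
    the well itself. Standardization and hyperparameter selection happen
    inside each fold from training cells only — no leakage.
    """
    from .aggregation import classify_image, classify_well

    processed = process_manifest(manifest, params)
    by_well: dict[str, list[ImageCells]] = {}
    for ic in processed:
        by_well.setdefault(ic.record.well_id, []).append(ic)
    well_ids = list(by_well)
    if len(well_ids) < 3:
        raise ValueError("hierarchical CV requires at least 3 wells")

    table = cell_table(processed)
    labeled = table.labeled

    res = HierarchicalCVResult(
        cell_true=np.array([], dtype=object),
        cell_pred=np.array([], dtype=object),
        cell_well=np.array([], dtype=object),
        image_true=[], image_pred=[], image_prescreen=[],
        well_true=[], well_decision=[],
    )
    cell_true, cell_pred, cell_well = [], [], []
    for w in well_ids:
        tr = labeled & (table.well_id != w)
        y_tr = table.true_label[tr].astype(object)
        counts = {lab: int((y_tr == lab).sum()) for lab in set(y_tr.tolist())}
        if len(counts) < 2 or min(counts.values()) < 10:
            logger.warning(
                "fold %s skipped: training set %s cannot train the classifier",
                w, counts,
            )
            res.skipped_wells.append(w)
            continue
        model = clf_mod.train(
            table.X[tr], np.array([str(v) for v in y_tr]), table.well_id[tr], seed=seed
        )
        res.fold_params[w] = dict(model.classifier.best_params_)

        img_labels = []
        for ic in by_well[w]:
            preds = list(model.predict(ic.features)) if ic.crops else []
            for crop, pred in zip(ic.crops, preds):
                if crop.true_label is not None:
                    cell_true.append(crop.true_label)
                    cell_pred.append(pred)
                    cell_well.append(w)
            img_label = classify_image(preds, ic.prescreen)
            img_labels.append(img_label)
            truth = ic.record.image_label or ic.record.well_label
            res.image_true.append(truth)
            res.image_pred.append(img_label)
            res.image_prescreen.append(ic.prescreen)
        decision = classify_well(w, img_labels)
        well_truth = next(
            r.well_label or r.image_label
            for r in manifest.records
            if r.well_id == w
        )
        res.well_true.append(well_truth)
        res.well_decision.append(decision.decision)

    res.cell_true = np.array(cell_true, dtype=object)
    res.cell_pred = np.array(cell_pred, dtype=object)
    res.cell_well = np.array(cell_well, dtype=object)
    return res
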