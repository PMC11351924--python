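"""Serialization: COCO-dialect annotations, PNG rasters, CSV reports.

The annotation dialect is standard COCO (images / annotations with
``bbox = [x, y, w, h]`` and ``category_id`` = lesion type) extended with the
fields this pipeline needs: per-image eye id, orientation label and
field->panorama transform, and a top-level ``eyes`` list carrying landmarks,
laterality, plus status and ground-truth lesions.  Writing is deterministic
(sorted keys, plain floats), so identical runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .synthetic import FieldSpec, GroundTruthEye, GroundTruthLesion
from .transforms import SimilarityTransform
from .types import Lesion

CATEGORIES = [
    {"id": 1, "name": "stage1_demarcation_line"},
    {"id": 2, "name": "stage2_ridge"},
    {"id": 3, "name": "stage3_ridge_with_proliferation"},
    {"id": 4, "name": "stage4_detachment"},
]


def save_raster(path: str | Path, raster: np.ndarray) -> None:
    Image.fromarray(raster).save(str(path), format="PNG")


def load_raster(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(str(path)).convert("RGB"))


def _eye_record(eye: GroundTruthEye) -> dict:
    return {
        "eye_id": eye.eye_id,
        "laterality": eye.laterality,
        "disc_center": list(eye.disc_center),
        "fovea_center": list(eye.fovea_center),
        "ora_radius_nasal": eye.ora_radius_nasal,
        "plus_present": eye.plus_present,
        "tortuosity_amp": eye.tortuosity_amp,
        "vessel_width": eye.vessel_width,
        "seed": eye.seed,
        "lesions": [
            {
                "lesion_type": l.lesion_type,
                "center": list(l.center),
                "extent": list(l.extent),
                "true_zone": l.true_zone,
            }
            for l in eye.lesions
        ],
    }


def _eye_from_record(rec: dict) -> GroundTruthEye:
    return GroundTruthEye(
        eye_id=rec["eye_id"],
        laterality=rec["laterality"],
        disc_center=tuple(rec["disc_center"]),
        fovea_center=tuple(rec["fovea_center"]),
        ora_radius_nasal=rec["ora_radius_nasal"],
        lesions=tuple(
            GroundTruthLesion(
                lesion_type=l["lesion_type"],
                center=tuple(l["center"]),
                extent=tuple(l["extent"]),
                true_zone=l["true_zone"],
            )
            for l in rec["lesions"]
        ),
        plus_present=rec["plus_present"],
        tortuosity_amp=rec["tortuosity_amp"],
        vessel_width=rec["vessel_width"],
        seed=rec["seed"],
    )


def cohort_to_coco(
    eyes: list[GroundTruthEye],
    plans: dict[str, list[FieldSpec]],
    detections: dict[str, dict[str, list[Lesion]]],
) -> dict:
    """Assemble the COCO-dialect dictionary for a cohort.

    ``plans`` and ``detections`` are keyed by eye_id; detections per field.
    """
    images = []
    annotations = []
    img_id = 0
    ann_id = 0
    img_index: dict[tuple[str, str], int] = {}
    for eye in eyes:
        for f in plans[eye.eye_id]:
            img_id += 1
            img_index[(eye.eye_id, f.field_id)] = img_id
            images.append(
                {
                    "id": img_id,
                    "file_name": f"{eye.eye_id}_{f.field_id}.png",
                    "width": f.raster_size[0],
                    "height": f.raster_size[1],
                    "eye_id": eye.eye_id,
                    "field_id": f.field_id,
                    "orientation_label": f.orientation_label,
                    "transform": list(f.transform_to_panorama.params()),
                }
            )
        for fid, dets in detections[eye.eye_id].items():
            for d in dets:
                ann_id += 1
                annotations.append(
                    {
                        "id": ann_id,
                        "image_id": img_index[(eye.eye_id, fid)],
                        "bbox": [float(v) for v in d.bbox],
                        "category_id": d.lesion_type,
                        "score": d.confidence,
                        "lesion_id": d.lesion_id,
                    }
                )
    return {
        "categories": CATEGORIES,
        "images": images,
        "annotations": annotations,
        "eyes": [_eye_record(e) for e in eyes],
    }


def coco_to_cohort(doc: dict):
    """Inverse of :func:`cohort_to_coco`."""
    eyes = [_eye_from_record(r) for r in doc["eyes"]]
    plans: dict[str, list[FieldSpec]] = {e.eye_id: [] for e in eyes}
    by_img: dict[int, tuple[str, str]] = {}
    for im in doc["images"]:
        plans[im["eye_id"]].append(
            FieldSpec(
                field_id=im["field_id"],
                orientation_label=im["orientation_label"],
                transform_to_panorama=SimilarityTransform.from_params(im["transform"]),
                raster_size=(im["width"], im["height"]),
            )
        )
        by_img[im["id"]] = (im["eye_id"], im["field_id"])
    detections: dict[str, dict[str, list[Lesion]]] = {
        e.eye_id: {f.field_id: [] for f in plans[e.eye_id]} for e in eyes
    }
    for ann in doc["annotations"]:
        eye_id, fid = by_img[ann["image_id"]]
        detections[eye_id][fid].append(
            Lesion(
                lesion_type=ann["category_id"],
                bbox=tuple(ann["bbox"]),
                confidence=ann.get("score", 1.0),
                field_id=fid,
                lesion_id=ann.get("lesion_id"),
            )
        )
    return eyes, plans, detections


def save_json(path: str | Path, doc: dict) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True, indent=1)
        fh.write("\n")


def load_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
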