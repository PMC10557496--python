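"""File formats and the quantify -> grade -> explain pipeline.

Annotations come in as COCO-polygon JSON (flat ``[x1, y1, x2, y2, ...]``
segmentation lists plus a category table); foreign category names are mapped
to the five lesion codes through :data:`CATEGORY_MAP`.  Feature tables go
out as CSV with the fixed header ``image_id,R_HE,R_EX,R_SE,R_NV,N_HE,N_EX,
N_SE,N_AN,N_NV``; grading reports as JSON embedding the tool version, a
config hash and the seed, so every output is traceable to its inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .quantify import (FEATURE_NAMES, FeatureVector, ImageAnnotation,
                       LesionInstance, Polygon, build_features, polygon_area,
                       retina_area)
from .rules import RuleSet, builtin_ruleset, classify, load_ruleset

logger = logging.getLogger("drgrade")

FEATURE_CSV_HEADER = ["image_id", *FEATURE_NAMES]

#: mapping from common annotation category names to the five lesion codes;
#: lookups are case-insensitive and extendable via ``category_map`` arguments
CATEGORY_MAP = {
    "he": "HE", "hemorrhage": "HE", "haemorrhage": "HE", "hemorrhages": "HE",
    "ex": "EX", "hard exudate": "EX", "hard exudates": "EX", "exudate": "EX",
    "exudates": "EX",
    "se": "SE", "soft exudate": "SE", "soft exudates": "SE",
    "cotton wool spot": "SE", "cotton-wool spot": "SE",
    "an": "AN", "aneurysm": "AN", "aneurysms": "AN", "microaneurysm": "AN",
    "microaneurysms": "AN",
    "nv": "NV", "new vessel": "NV", "new vessels": "NV",
    "new vessels elsewhere": "NV", "neovascularization": "NV",
    "neovascularisation": "NV",
}

_COCO_CATEGORIES = [
    {"id": 1, "name": "hemorrhage", "supercategory": "lesion"},
    {"id": 2, "name": "hard exudate", "supercategory": "lesion"},
    {"id": 3, "name": "soft exudate", "supercategory": "lesion"},
    {"id": 4, "name": "aneurysm", "supercategory": "lesion"},
    {"id": 5, "name": "new vessels", "supercategory": "lesion"},
]
_CODE_TO_COCO_ID = {"HE": 1, "EX": 2, "SE": 3, "AN": 4, "NV": 5}


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# COCO-polygon annotations


def annotations_to_coco(annotations: list[ImageAnnotation]) -> dict:
    """Serialize annotations into the COCO polygon dialect."""
    images, annos = [], []
    ann_id = 1
    for k, ann in enumerate(annotations, start=1):
        images.append({"id": k, "file_name": f"{ann.image_id}.png",
                       "image_id_str": ann.image_id,
                       "width": int(ann.width), "height": int(ann.height)})
        for inst in ann.instances:
            annos.append({
                "id": ann_id,
                "image_id": k,
                "category_id": _CODE_TO_COCO_ID[inst.lesion_type],
                "segmentation": [inst.polygon.to_flat()],
                "area": polygon_area(inst.polygon),
                "iscrowd": 0,
            })
            ann_id += 1
    return {"images": images, "annotations": annos,
            "categories": _COCO_CATEGORIES}


def read_annotations(path: str | Path,
                     category_map: Optional[dict[str, str]] = None,
                     ) -> list[ImageAnnotation]:
    """Parse a COCO-polygon JSON file into per-image annotations.

    Categories are resolved case-insensitively through :data:`CATEGORY_MAP`
    (optionally extended by ``category_map``).  Unknown categories and
    polygons with fewer than 3 vertices are rejected with the offending
    instance named.  Multi-part segmentations yield one instance per part
    (with a warning), since each part is a separate polygon.
    """
    payload = json.loads(Path(path).read_text())
    lookup = {k.lower(): v for k, v in CATEGORY_MAP.items()}
    if category_map:
        lookup.update({k.lower(): v for k, v in category_map.items()})

    cat_code: dict[int, str] = {}
    for cat in payload.get("categories", []):
        name = str(cat["name"]).lower()
        if name not in lookup:
            raise ValueError(
                f"unknown lesion category {cat['name']!r} (id {cat['id']}); "
                "extend the category map to include it")
        cat_code[cat["id"]] = lookup[name]

    images: dict[int, ImageAnnotation] = {}
    for im in payload.get("images", []):
        image_id = im.get("image_id_str") or str(
            im.get("file_name", im["id"])).rsplit(".", 1)[0]
        images[im["id"]] = ImageAnnotation(
            image_id=image_id, width=im["width"], height=im["height"])

    for rec in payload.get("annotations", []):
        if rec["image_id"] not in images:
            raise ValueError(f"annotation {rec.get('id')} references unknown "
                             f"image id {rec['image_id']}")
        if rec["category_id"] not in cat_code:
            raise ValueError(f"annotation {rec.get('id')} has unmapped "
                             f"category id {rec['category_id']}")
        code = cat_code[rec["category_id"]]
        parts = rec["segmentation"]
        if len(parts) > 1:
            logger.warning("annotation %s has %d polygon parts; each "
                           "becomes its own instance", rec.get("id"),
                           len(parts))
        for flat in parts:
            if len(flat) < 6:
                raise ValueError(
                    f"annotation {rec.get('id')} ({code}) has only "
                    f"{len(flat) // 2} vertices; polygons need at least 3")
            images[rec["image_id"]].instances.append(
                LesionInstance(lesion_type=code,
                               polygon=Polygon.from_flat(flat)))
    return list(images.values())


# ---------------------------------------------------------------------------
# feature tables


def features_to_frame(annotations: list[ImageAnnotation]) -> pd.DataFrame:
    """Quantify every annotation into one feature row."""
    rows = []
    for ann in annotations:
        fv = build_features(ann, retina_area(ann.width))
        rows.append({"image_id": ann.image_id, **fv.as_dict()})
    return pd.DataFrame(rows, columns=FEATURE_CSV_HEADER)


def write_features_csv(annotations: list[ImageAnnotation],
                       path: str | Path) -> None:
    features_to_frame(annotations).to_csv(path, index=False)


def read_features_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_CSV_HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"feature CSV {path} lacks columns {missing}")
    return df


def frame_to_table(df: pd.DataFrame):
    """Feature CSV (with a ``severity`` column) -> training table."""
    from .cart import LabeledTable

    if "severity" not in df.columns:
        raise ValueError("training table needs a 'severity' column")
    rows = [(FeatureVector(**{n: row[n] for n in FEATURE_NAMES}),
             int(row["severity"])) for _, row in df.iterrows()]
    return LabeledTable(rows=rows)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """End-to-end run configuration (flat YAML file, CLI flags win)."""

    annotations: str
    out_dir: str
    ruleset: str = "builtin"
    fallback_policy: str = "widen_ranges"
    seed: int = 0
    image_size: int = 1024
    category_map: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text()) or {}
        payload.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**payload)


def _load_ruleset(spec: str, fallback_policy: str) -> RuleSet:
    if spec == "builtin":
        return builtin_ruleset(fallback_policy)
    return load_ruleset(spec, fallback_policy)


def run_pipeline(config: PipelineConfig) -> dict:
    """Quantify, grade and explain every annotated image.

    Writes ``features.csv`` and ``report.json`` under ``config.out_dir``.
    Per-image failures are recorded (with image id and stage) without
    aborting the remaining images.  Returns the report dict; its
    ``"errors"`` list is empty on full success.
    """
    from . import __version__

    ruleset = _load_ruleset(config.ruleset, config.fallback_policy)
    annotations = read_annotations(config.annotations,
                                   config.category_map or None)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    results, errors, feature_rows = [], [], []
    severity_counts = {k: 0 for k in range(5)}
    for ann in annotations:
        try:
            fv = build_features(ann, retina_area(ann.width))
        except Exception as exc:  # quantification stage
            errors.append({"image_id": ann.image_id, "stage": "quantify",
                           "error": str(exc)})
            continue
        feature_rows.append({"image_id": ann.image_id, **fv.as_dict()})
        try:
            res = classify(fv, ruleset)
        except Exception as exc:
            errors.append({"image_id": ann.image_id, "stage": "grade",
                           "error": str(exc)})
            continue
        severity_counts[res.severity] += 1
        if res.fallback_used:
            logger.warning("image %s graded via fallback rule %s",
                           ann.image_id, res.matched_rule)
        results.append({
            "image_id": ann.image_id,
            "features": fv.as_dict(),
            "severity": res.severity,
            "label": res.label,
            "confidence": res.confidence,
            "rule_id": res.matched_rule,
            "explanation": res.explanation,
            "fallback_used": res.fallback_used,
        })

    pd.DataFrame(feature_rows, columns=FEATURE_CSV_HEADER).to_csv(
        out / "features.csv", index=False)

    report = {
        "tool": "drgrade",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config_hash(asdict(config)),
        "n_images": len(annotations),
        "severity_counts": severity_counts,
        "images": results,
        "errors": errors,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    for sev, cnt in severity_counts.items():
        logger.info("severity %d: %d image(s)", sev, cnt)
    return report
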