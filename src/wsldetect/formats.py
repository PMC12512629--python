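"""Annotation formats, manifests and dataset splitting.

Two label dialects are supported:

* **YOLO-txt** (the LabelImg export dialect, the primary format): one
  object per line, ``class cx cy w h`` with centre/size normalized to
  [0, 1]; prediction files may append a sixth confidence column — a
  widely used extension.  Class ids map to labels via ``CLASS_NAMES``
  (0 = tooth, 1 = wsl).
* **COCO-JSON** (secondary, for interop with COCO tooling):
  ``images``/``annotations``/``categories``, bbox as ``[x, y, w, h]`` in
  absolute pixels; detector results as the standard results array.

Conversion to the package's half-open pixel convention happens here and
nowhere else.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .geometry import BoundingBox, Detection, ImageRecord

__all__ = [
    "CLASS_NAMES",
    "CLASS_IDS",
    "read_yolo_labels",
    "write_yolo_labels",
    "write_manifest",
    "read_manifest",
    "write_coco",
    "read_coco",
    "split_dataset",
]

CLASS_NAMES: dict[int, str] = {0: "tooth", 1: "wsl"}
CLASS_IDS: dict[str, int] = {v: k for k, v in CLASS_NAMES.items()}


def read_yolo_labels(path: str | Path, width: int, height: int,
                     class_names: Mapping[int, str] = CLASS_NAMES,
                     ) -> list[tuple[BoundingBox, str, float | None]]:
    """Read a YOLO-txt label file into absolute half-open pixel boxes.

    Returns ``(box, label, confidence)`` triples; confidence is ``None``
    for 5-column ground-truth rows.  Boxes extending past the image are
    clipped (the number of clipped rows is available via the logger);
    malformed rows raise ``ValueError`` naming the line number.
    """
    out: list[tuple[BoundingBox, str, float | None]] = []
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (5, 6):
            raise ValueError(f"{path}:{lineno}: expected 5 or 6 fields, "
                             f"got {len(parts)}: {line!r}")
        try:
            cls = int(parts[0])
            cx, cy, bw, bh = (float(v) for v in parts[1:5])
            conf = float(parts[5]) if len(parts) == 6 else None
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: unparseable row {line!r}") from exc
        if cls not in class_names:
            raise ValueError(f"{path}:{lineno}: unknown class id {cls}")
        box = BoundingBox(
            (cx - bw / 2) * width, (cy - bh / 2) * height,
            (cx + bw / 2) * width, (cy + bh / 2) * height,
        ).clip(width, height)
        out.append((box, class_names[cls], conf))
    return out


def _fmt(x: float) -> str:
    return f"{x:.6f}"


def write_yolo_labels(path: str | Path,
                      items: Sequence[tuple[BoundingBox, str] | Detection],
                      width: int, height: int,
                      class_ids: Mapping[str, int] = CLASS_IDS) -> None:
    """Write annotations or detections as YOLO-txt (6 decimals).

    Accepts ``(box, label)`` pairs (ground truth, 5 columns) or
    :class:`Detection` objects (predictions, 6 columns with confidence).
    """
    lines = []
    for item in items:
        if isinstance(item, Detection):
            box, label, conf = item.box, item.label, item.confidence
        else:
            box, label = item
            conf = None
        cx = (box.x_min + box.x_max) / 2 / width
        cy = (box.y_min + box.y_max) / 2 / height
        bw = box.width / width
        bh = box.height / height
        row = [str(class_ids[label]), _fmt(cx), _fmt(cy), _fmt(bw), _fmt(bh)]
        if conf is not None:
            row.append(_fmt(conf))
        lines.append(" ".join(row))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_manifest(path: str | Path, records: Sequence[ImageRecord]) -> None:
    """CSV manifest: image_id, width, height (dims are required to
    denormalize YOLO labels)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "width", "height"])
        for rec in records:
            writer.writerow([rec.image_id, rec.width, rec.height])


def read_manifest(path: str | Path) -> dict[str, tuple[int, int]]:
    dims: dict[str, tuple[int, int]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            dims[row["image_id"]] = (int(row["width"]), int(row["height"]))
    return dims


def write_coco(path: str | Path, records: Sequence[ImageRecord],
               dets_by_img: Mapping[str, Sequence[Detection]] | None = None,
               ) -> None:
    """Write a COCO-JSON file: annotations schema, plus a ``results``
    array when detections are supplied.

    Ids are assigned deterministically (sorted image ids, then annotation
    order); bbox is ``[x, y, w, h]`` in absolute pixels.
    """
    recs = sorted(records, key=lambda r: r.image_id)
    image_ids = {rec.image_id: i + 1 for i, rec in enumerate(recs)}
    doc: dict = {
        "images": [{"id": image_ids[r.image_id], "file_name": f"{r.image_id}.png",
                    "width": r.width, "height": r.height} for r in recs],
        "categories": [{"id": cid + 1, "name": name}
                       for cid, name in sorted(CLASS_NAMES.items())],
        "annotations": [],
    }
    ann_id = 1
    for rec in recs:
        for box, label in rec.annotations:
            doc["annotations"].append({
                "id": ann_id, "image_id": image_ids[rec.image_id],
                "category_id": CLASS_IDS[label] + 1,
                "bbox": [box.x_min, box.y_min, box.width, box.height],
                "area": box.area, "iscrowd": 0,
            })
            ann_id += 1
    if dets_by_img is not None:
        doc["results"] = [
            {"image_id": image_ids[img], "category_id": CLASS_IDS[d.label] + 1,
             "bbox": [d.box.x_min, d.box.y_min, d.box.width, d.box.height],
             "score": d.confidence}
            for img in sorted(dets_by_img) for d in dets_by_img[img]
        ]
    Path(path).write_text(json.dumps(doc, indent=1))


def read_coco(path: str | Path,
              ) -> tuple[list[ImageRecord], dict[str, list[Detection]]]:
    """Read a file written by :func:`write_coco` back into records and
    (possibly empty) per-image detections."""
    doc = json.loads(Path(path).read_text())
    cats = {c["id"]: c["name"] for c in doc["categories"]}
    id_to_name = {img["id"]: Path(img["file_name"]).stem for img in doc["images"]}
    recs: dict[int, ImageRecord] = {
        img["id"]: ImageRecord(image_id=id_to_name[img["id"]],
                               width=img["width"], height=img["height"])
        for img in doc["images"]
    }
    for ann in doc.get("annotations", []):
        x, y, w, h = ann["bbox"]
        recs[ann["image_id"]].annotations.append(
            (BoundingBox(x, y, x + w, y + h), cats[ann["category_id"]]))
    dets: dict[str, list[Detection]] = {r.image_id: [] for r in recs.values()}
    for res in doc.get("results", []):
        x, y, w, h = res["bbox"]
        dets[id_to_name[res["image_id"]]].append(
            Detection(BoundingBox(x, y, x + w, y + h),
                      cats[res["category_id"]], res["score"]))
    return [recs[k] for k in sorted(recs)], dets


def split_dataset(records: Sequence, fractions: Sequence[float] = (0.7, 0.2, 0.1),
                  seed: int = 0, counts: Sequence[int] | None = None,
                  ) -> tuple[list, list, list]:
    """Seeded random split into train/validation/holdout.

    Integer sizes come from the largest-remainder rule applied to
    ``fractions`` (so they always sum to ``len(records)``); explicit
    ``counts`` override the fractions and must sum exactly.  The three
    parts are disjoint and exhaustive, and a fixed seed reproduces the
    split.
    """
    n = len(records)
    if counts is not None:
        sizes = list(counts)
        if sum(sizes) != n:
            raise ValueError(f"counts {sizes} do not sum to {n}")
    else:
        fr = np.asarray(fractions, dtype=float)
        if fr.min() < 0 or not np.isclose(fr.sum(), 1.0):
            raise ValueError("fractions must be non-negative and sum to 1")
        quotas = fr * n
        sizes = np.floor(quotas).astype(int)
        remainder = n - sizes.sum()
        order = np.argsort(-(quotas - sizes), kind="stable")
        for i in range(remainder):
            sizes[order[i]] += 1
        sizes = sizes.tolist()
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    shuffled = [records[i] for i in perm]
    a, b = sizes[0], sizes[0] + sizes[1]
    return shuffled[:a], shuffled[a:b], shuffled[b:]
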