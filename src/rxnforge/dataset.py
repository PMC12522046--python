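"""Dataset construction: batch generation, annotation I/O, splits, manifest.

Each image gets one JSON annotation document holding the canvas size, the
role-labelled components with their boxes, the condition items with roles,
texts and sub-boxes, the steps with id references and arrow geometry, and
the assembled reaction SMILES per step.  Annotations round-trip through
write/read without loss and are validated against a schema whose errors
name the offending JSON path (e.g. ``$.steps``).

Splits follow an 8:1:1 train/val/test ratio by default: |train| and |val|
are the ratio fractions of N rounded half-up, the remainder is test, and
the assignment is a seed-deterministic shuffle.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

from .conditions import ConditionSpec
from .depict import DepictionError, RDKitDepictor
from .generator import GeneratedScheme, generate_scheme
from .layout import LayoutError
from .reactions import ReactionSourceLike
from .rng import RNGStream
from .scheme import (
    ARROW_KINDS,
    COMPONENT_ROLES,
    CONDITION_ROLES,
    PATTERNS,
    Arrow,
    BBox,
    Component,
    ConditionItem,
    ReactionParseError,
    ReactionScheme,
    ReactionStep,
    assemble_reaction_smiles,
    validate_scheme,
)

logger = logging.getLogger("rxnforge")


class AnnotationSchemaError(ValueError):
    """Schema violation on read; the message names the JSON path."""


class DatasetBuildError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# annotation record


@dataclass
class AnnotationRecord:
    image_path: str
    width: int
    height: int
    pattern: str
    seed: int
    index: int
    components: list[dict]
    steps: list[dict]

    @staticmethod
    def from_generated(
        gen: GeneratedScheme, image_path: str, seed: int, index: int
    ) -> "AnnotationRecord":
        s = gen.scheme
        comps = []
        for c in s.components:
            entry: dict = {
                "id": c.id,
                "role": c.role,
                "bbox": _box_list(c.bbox),
            }
            if c.is_molecule:
                entry["smiles"] = c.smiles
            else:
                entry["items"] = [
                    {"text": i.text, "role": i.role, "bbox": _box_list(i.bbox)}
                    for i in c.items or []
                ]
            comps.append(entry)
        steps = []
        for st, src in zip(s.steps, gen.step_sources):
            steps.append(
                {
                    "reactant_ids": list(st.reactant_ids),
                    "condition_ids": list(st.condition_ids),
                    "product_ids": list(st.product_ids),
                    "arrow": {
                        "start": [float(st.arrow.start[0]), float(st.arrow.start[1])],
                        "end": [float(st.arrow.end[0]), float(st.arrow.end[1])],
                        "kind": st.arrow.kind,
                        "crossed_out": bool(st.arrow.crossed_out),
                        "control_points": [[float(x), float(y)] for x, y in st.arrow.control_points],
                    },
                    "reaction_smiles": assemble_reaction_smiles(st, s),
                    "source_reaction": src,
                }
            )
        return AnnotationRecord(
            image_path=image_path,
            width=int(s.canvas_width),
            height=int(s.canvas_height),
            pattern=s.pattern,
            seed=int(seed),
            index=int(index),
            components=comps,
            steps=steps,
        )

    def to_scheme(self) -> ReactionScheme:
        comps = []
        for c in self.components:
            if c["role"] == "condition":
                items = [
                    ConditionItem(i["text"], i["role"], _list_box(i["bbox"]))
                    for i in c["items"]
                ]
                comps.append(Component(c["id"], c["role"], _list_box(c["bbox"]), items=items))
            else:
                comps.append(
                    Component(c["id"], c["role"], _list_box(c["bbox"]), smiles=c["smiles"])
                )
        steps = []
        for st in self.steps:
            a = st["arrow"]
            arrow = Arrow(
                tuple(a["start"]),
                tuple(a["end"]),
                a["kind"],
                a["crossed_out"],
                tuple(tuple(p) for p in a["control_points"]),
            )
            steps.append(
                ReactionStep(
                    list(st["reactant_ids"]), list(st["condition_ids"]),
                    list(st["product_ids"]), arrow,
                )
            )
        return ReactionScheme(self.width, self.height, comps, steps, self.pattern)


def _box_list(b: BBox) -> list:
    def num(v: float):
        return int(v) if float(v).is_integer() else float(v)

    return [num(b.x_min), num(b.y_min), num(b.x_max), num(b.y_max)]


def _list_box(v: Sequence[float]) -> BBox:
    return BBox(*v)


# --------------------------------------------------------------------------
# schema validation (JSON-path error reporting)

_TOP_KEYS = {
    "image_path": str,
    "width": int,
    "height": int,
    "pattern": str,
    "seed": int,
    "index": int,
    "components": list,
    "steps": list,
}


def validate_annotation_dict(d: dict) -> list[tuple[str, str]]:
    errors: list[tuple[str, str]] = []
    if not isinstance(d, dict):
        return [("$", "annotation must be a JSON object")]
    for key, typ in _TOP_KEYS.items():
        if key not in d:
            errors.append((f"$.{key}", "missing required key"))
        elif not isinstance(d[key], typ):
            errors.append((f"$.{key}", f"expected {typ.__name__}"))
    if errors:
        return errors
    if d["pattern"] not in PATTERNS:
        errors.append(("$.pattern", f"unknown pattern {d['pattern']!r}"))
    ids = set()
    for i, c in enumerate(d["components"]):
        p = f"$.components[{i}]"
        if not isinstance(c, dict):
            errors.append((p, "expected object"))
            continue
        for key in ("id", "role", "bbox"):
            if key not in c:
                errors.append((f"{p}.{key}", "missing required key"))
        if "role" in c and c["role"] not in COMPONENT_ROLES:
            errors.append((f"{p}.role", f"role {c.get('role')!r} not in {COMPONENT_ROLES}"))
        if "bbox" in c and (not isinstance(c["bbox"], list) or len(c["bbox"]) != 4):
            errors.append((f"{p}.bbox", "expected [x_min, y_min, x_max, y_max]"))
        if c.get("role") == "condition":
            if "items" not in c:
                errors.append((f"{p}.items", "condition component requires items"))
            else:
                for j, it in enumerate(c["items"]):
                    q = f"{p}.items[{j}]"
                    for key in ("text", "role", "bbox"):
                        if key not in it:
                            errors.append((f"{q}.{key}", "missing required key"))
                    if it.get("role") not in CONDITION_ROLES:
                        errors.append((f"{q}.role", f"role {it.get('role')!r} not in {CONDITION_ROLES}"))
        elif c.get("role") in ("reactant", "product") and "smiles" not in c:
            errors.append((f"{p}.smiles", "molecule component requires smiles"))
        if "id" in c:
            ids.add(c["id"])
    for i, st in enumerate(d["steps"]):
        p = f"$.steps[{i}]"
        if not isinstance(st, dict):
            errors.append((p, "expected object"))
            continue
        for key in ("reactant_ids", "condition_ids", "product_ids", "arrow"):
            if key not in st:
                errors.append((f"{p}.{key}", "missing required key"))
        for key in ("reactant_ids", "condition_ids", "product_ids"):
            for j, cid in enumerate(st.get(key, [])):
                if cid not in ids:
                    errors.append((f"{p}.{key}[{j}]", f"unresolved component id {cid!r}"))
        arrow = st.get("arrow")
        if isinstance(arrow, dict):
            if arrow.get("kind") not in ARROW_KINDS:
                errors.append((f"{p}.arrow.kind", f"unknown kind {arrow.get('kind')!r}"))
    return errors


def write_annotation(record: AnnotationRecord, path: str) -> None:
    payload = json.dumps(asdict(record), sort_keys=True, indent=2)
    with open(path, "w") as fh:
        fh.write(payload + "\n")


def read_annotation(path: str) -> AnnotationRecord:
    with open(path) as fh:
        d = json.load(fh)
    errors = validate_annotation_dict(d)
    if errors:
        jpath, msg = errors[0]
        raise AnnotationSchemaError(f"{jpath}: {msg}")
    return AnnotationRecord(**d)


# --------------------------------------------------------------------------
# splits


SPLIT_NAMES = ("train", "val", "test")


def split_dataset(
    ids: Sequence[str], ratios: tuple[float, float, float], rng: RNGStream
) -> dict[str, str]:
    """Deterministic shuffled split; sizes = round-half-up(N * ratio), remainder to test."""
    if any(r < 0 for r in ratios) or sum(ratios) <= 0:
        raise ValueError("ratios must be non-negative with a positive sum")
    n = len(ids)
    nonzero = sum(1 for r in ratios if r > 0)
    if n < nonzero:
        raise ValueError(f"cannot split {n} items into {nonzero} non-empty splits")
    total = float(sum(ratios))
    n_train = int(n * ratios[0] / total + 0.5)
    n_val = int(n * ratios[1] / total + 0.5)
    n_test = n - n_train - n_val
    if n_test < 0:  # rounding pushed past N; shrink val then train
        n_val = max(0, n_val + n_test)
        n_test = n - n_train - n_val
    g = rng.generator()
    order = g.permutation(n)
    out: dict[str, str] = {}
    for pos, idx in enumerate(order):
        if pos < n_train:
            split = "train"
        elif pos < n_train + n_val:
            split = "val"
        else:
            split = "test"
        out[ids[int(idx)]] = split
    return out


# --------------------------------------------------------------------------
# manifest


@dataclass
class ManifestRecord:
    id: str
    image_path: str
    annotation_path: str
    split: str
    pattern: str


@dataclass
class DatasetManifest:
    records: list[ManifestRecord]
    ratios: tuple[float, float, float]
    root_seed: int
    resample_events: int = 0

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# ratios={self.ratios[0]}:{self.ratios[1]}:{self.ratios[2]}"
                     f" seed={self.root_seed} resamples={self.resample_events}\n")
            fh.write("id\timage_path\tannotation_path\tsplit\tpattern\n")
            for r in self.records:
                fh.write(f"{r.id}\t{r.image_path}\t{r.annotation_path}\t{r.split}\t{r.pattern}\n")

    @staticmethod
    def read_tsv(path: str) -> "DatasetManifest":
        records = []
        ratios, seed, resamples = (8.0, 1.0, 1.0), 0, 0
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    meta = dict(kv.split("=") for kv in line[1:].split() if "=" in kv)
                    if "ratios" in meta:
                        ratios = tuple(float(x) for x in meta["ratios"].split(":"))  # type: ignore[assignment]
                    seed = int(meta.get("seed", 0))
                    resamples = int(meta.get("resamples", 0))
                    continue
                if line.startswith("id\t") or not line:
                    continue
                records.append(ManifestRecord(*line.split("\t")))
        return DatasetManifest(records, ratios, seed, resamples)


# --------------------------------------------------------------------------
# batch build


def build_dataset(
    source: ReactionSourceLike,
    style,
    cond_spec: Optional[ConditionSpec],
    n: int,
    out_dir: str,
    ratios: tuple[float, float, float] = (8.0, 1.0, 1.0),
    depictor: Optional[RDKitDepictor] = None,
    max_attempts: int = 25,
) -> DatasetManifest:
    """Generate ``n`` images + annotations and a split manifest under ``out_dir``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cond_spec = cond_spec or ConditionSpec()
    depictor = depictor or RDKitDepictor()
    os.makedirs(os.path.join(out_dir, "images"), exist_ok=True)
    os.makedirs(os.path.join(out_dir, "annotations"), exist_ok=True)
    root = RNGStream(style.seed)
    resamples = 0
    records: list[ManifestRecord] = []
    annotations: list[AnnotationRecord] = []
    for i in range(n):
        gen = None
        for attempt in range(max_attempts):
            try:
                gen = generate_scheme(
                    source, style, cond_spec, root.child(i, attempt), depictor=depictor
                )
                break
            except (DepictionError, LayoutError, ReactionParseError) as e:
                resamples += 1
                logger.warning("resampling item %d (attempt %d): %s", i, attempt, e)
        if gen is None:
            raise DatasetBuildError(
                f"item {i}: no valid scheme after {max_attempts} attempts; "
                "is every source reaction invalid?"
            )
        violations = validate_scheme(gen.scheme)
        if violations:
            raise DatasetBuildError(f"item {i}: generated scheme invalid: {violations[:3]}")
        img_rel = os.path.join("images", f"img_{i:05d}.png")
        ann_rel = os.path.join("annotations", f"ann_{i:05d}.json")
        gen.image.save(os.path.join(out_dir, img_rel))
        record = AnnotationRecord.from_generated(gen, img_rel, style.seed, i)
        write_annotation(record, os.path.join(out_dir, ann_rel))
        annotations.append(record)
        records.append(ManifestRecord(f"img_{i:05d}", img_rel, ann_rel, "", record.pattern))

    assignment = split_dataset([r.id for r in records], ratios, root.child(1 << 20))
    for r in records:
        r.split = assignment[r.id]
    manifest = DatasetManifest(records, ratios, style.seed, resamples)
    manifest.write_tsv(os.path.join(out_dir, "manifest.tsv"))
    return manifest


# --------------------------------------------------------------------------
# COCO-style export for detection-only consumers


def coco_export(records: Sequence[AnnotationRecord]) -> dict:
    categories = [
        {"id": i + 1, "name": role} for i, role in enumerate(COMPONENT_ROLES)
    ]
    cat_id = {role: i + 1 for i, role in enumerate(COMPONENT_ROLES)}
    images, annotations = [], []
    ann_id = 1
    for img_id, rec in enumerate(records, start=1):
        images.append(
            {"id": img_id, "file_name": rec.image_path, "width": rec.width, "height": rec.height}
        )
        for c in rec.components:
            x0, y0, x1, y1 = c["bbox"]
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": img_id,
                    "category_id": cat_id[c["role"]],
                    "bbox": [x0, y0, x1 - x0, y1 - y0],
                    "area": (x1 - x0) * (y1 - y0),
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    return {"images": images, "annotations": annotations, "categories": categories}
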