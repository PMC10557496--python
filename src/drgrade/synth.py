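"""Synthetic feature tables and fundus images with exact ground truth.

Real screening datasets (fundus photographs with clinician-drawn lesion
polygons) cannot be redistributed, so every pipeline stage is exercised on
synthetic material instead:

* :func:`sample_features` draws nine-feature vectors uniformly inside the
  feature-space region of a chosen severity level (the union of that level's
  rule boxes), keeping every ratio at a configurable margin from every rule
  threshold so labels are unambiguous.
* :func:`render_fundus` paints a bright retinal disk on black — optionally
  vertically clipped, as happens when the camera cuts off the top/bottom of
  the retina — and packs non-overlapping simple lesion polygons whose
  per-type total areas match the requested budgets exactly.  The returned
  annotation holds the exact float polygon coordinates, so quantification
  round-trips to the generating features.
* :func:`generate_dataset` writes a complete PNG + COCO-JSON + CSV dataset
  with a manifest, byte-reproducible for a fixed seed.

Placement uses a squarified treemap in (angle, radius^2) coordinates: area
in that parameter plane is proportional to image-plane area, so annular-
sector cells with near-unit aspect ratio can be carved for each lesion and a
star-shaped polygon of exactly the target area inscribed in each cell.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .cart import LabeledTable
from .quantify import (FEATURE_NAMES, FeatureVector, ImageAnnotation,
                       LesionInstance, Polygon, retina_area)
from .rules import RuleSet, _Interval, _rule_box, builtin_ruleset

#: smallest ratio a present lesion type contributes (keeps polygons drawable)
MIN_RATIO = 0.003
#: sampling band width above an unbounded rule threshold
OPEN_BAND = 0.05
#: ceiling for a hemorrhage ratio when no rule constrains it
UNREF_RHE_CAP = 0.30
#: packing density: lesion area / treemap cell area
CELL_FILL = 0.8

# class-plausible defaults for features the rules never reference
AN_COUNT_RANGE = {0: (0, 2), 1: (1, 6), 2: (2, 8), 3: (3, 10), 4: (3, 12)}

LESION_COLORS = {
    "HE": (110, 18, 20),
    "EX": (245, 235, 190),
    "SE": (225, 215, 160),
    "AN": (80, 12, 16),
    "NV": (150, 40, 45),
}
RETINA_COLOR = (205, 115, 55)
VESSEL_COLOR = (120, 30, 25)


class InfeasiblePackingError(RuntimeError):
    """Requested lesion areas cannot be packed inside the retinal disk."""


@dataclass(frozen=True)
class SynthConfig:
    n_per_class: int = 10
    margin: float = 0.01
    image_size: int = 1024
    lesion_size_range: tuple[float, float] = (5.0, 25.0)
    seed: int = 0

    def __post_init__(self):
        if self.margin < 0:
            raise ValueError("margin must be >= 0")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")


# ---------------------------------------------------------------------------
# feature sampling


def _segments_minus_margins(lo: float, hi: float, thresholds: Sequence[float],
                            margin: float) -> list[tuple[float, float]]:
    """[lo, hi] minus the open margin-neighborhood of every threshold."""
    segs = [(lo, hi)]
    for t in thresholds:
        nxt: list[tuple[float, float]] = []
        for a, b in segs:
            if b <= t - margin or a >= t + margin:
                nxt.append((a, b))
                continue
            if a < t - margin:
                nxt.append((a, t - margin))
            if b > t + margin:
                nxt.append((t + margin, b))
        segs = nxt
    return [(a, b) for a, b in segs if b > a]


def _sample_segments(segs: list[tuple[float, float]],
                     rng: np.random.Generator) -> float:
    lengths = [b - a for a, b in segs]
    total = sum(lengths)
    if total <= 0:
        raise ValueError("margin leaves an empty sampling region")
    r = rng.uniform(0.0, total)
    for (a, b), length in zip(segs, lengths):
        if r <= length:
            return a + r
        r -= length
    return segs[-1][1]


def _global_thresholds(ruleset: RuleSet) -> dict[str, list[float]]:
    out: dict[str, set[float]] = {}
    for rule in ruleset.rules:
        for pred in rule.predicates:
            if pred.feature.startswith("R_"):
                out.setdefault(pred.feature, set()).add(float(pred.threshold))
    return {f: sorted(v) for f, v in out.items()}


def _sample_ratio(box_iv: Optional[_Interval], cap: float, force_pos: bool,
                  thresholds: Sequence[float], margin: float,
                  rng: np.random.Generator, zero_prob: float = 0.3) -> float:
    """Draw one ratio from a rule interval (or an unreferenced default cap)."""
    iv = box_iv if box_iv is not None else _Interval(0.0, cap)
    lo = iv.lo + margin if iv.lo > 0 else 0.0
    hi = iv.lo + margin + OPEN_BAND if math.isinf(iv.hi) else iv.hi - margin
    if lo == 0.0 and not force_pos and rng.random() < zero_prob:
        return 0.0
    lo = max(lo, MIN_RATIO)
    segs = _segments_minus_margins(lo, hi, thresholds, margin)
    return _sample_segments(segs, rng)


def _sample_count(box_iv: Optional[_Interval], rng: np.random.Generator,
                  default_hi: int) -> Optional[int]:
    """Integer draw from a rule interval; None when unreferenced."""
    if box_iv is None:
        return None
    lo = int(math.ceil(box_iv.lo)) + (1 if box_iv.lo_open and
                                      box_iv.lo == math.ceil(box_iv.lo) else 0)
    if math.isinf(box_iv.hi):
        hi = max(lo, default_hi)
    else:
        hi = int(math.floor(box_iv.hi))
    return int(rng.integers(lo, hi + 1))


def sample_features(severity: int, n: int,
                    config: SynthConfig = SynthConfig(),
                    ruleset: Optional[RuleSet] = None,
                    rng: Optional[np.random.Generator] = None) -> LabeledTable:
    """Draw ``n`` feature vectors that grade to ``severity`` by construction.

    For each vector one of the severity's rules is chosen uniformly and each
    referenced feature is drawn uniformly inside the rule's interval, kept at
    distance >= ``config.margin`` from every rule threshold; integer features
    stay strictly inside their ranges.  Unreferenced features take the
    class-plausible defaults documented in the methods note.  A zero count
    always forces the matching ratio to zero and vice versa.
    """
    if not 0 <= severity <= 4:
        raise ValueError(f"severity {severity} outside 0..4")
    ruleset = ruleset if ruleset is not None else builtin_ruleset()
    rng = rng if rng is not None else np.random.default_rng(
        [config.seed, severity])
    rules = [r for r in ruleset.rules if r.severity == severity]
    if not rules:
        raise ValueError(f"no rule assigns severity {severity}")
    thresholds = _global_thresholds(ruleset)
    m = config.margin

    rows: list[tuple[FeatureVector, int]] = []
    for _ in range(n):
        rule = rules[int(rng.integers(len(rules)))]
        box = _rule_box(rule)

        def forced_zero(name: str) -> bool:
            iv = box.get(name)
            return iv is not None and iv.lo == iv.hi == 0

        # counts referenced by the rule come first (they can force ratios)
        n_nv = _sample_count(box.get("N_NV"), rng, default_hi=3)
        n_se = _sample_count(box.get("N_SE"), rng, default_hi=15)

        # soft exudate
        if (n_se == 0) or forced_zero("N_SE"):
            r_se, n_se = 0.0, 0
        else:
            r_se = _sample_ratio(box.get("R_SE"), cap=0.15,
                                 force_pos=(n_se is not None and n_se > 0),
                                 thresholds=thresholds.get("R_SE", ()),
                                 margin=m, rng=rng)
            if r_se == 0.0:
                n_se = 0
            elif n_se is None:
                n_se = int(rng.integers(1, 16))

        # hemorrhage
        r_he = _sample_ratio(box.get("R_HE"), cap=UNREF_RHE_CAP,
                             force_pos=False,
                             thresholds=thresholds.get("R_HE", ()),
                             margin=m, rng=rng,
                             zero_prob=0.5 if severity == 0 else 0.15)
        n_he = 0 if r_he == 0.0 else int(
            rng.integers(1, 4 + min(17, int(r_he * 60))))

        # hard exudate: never referenced by the shipped rules
        r_ex = 0.0 if rng.random() < 0.3 else float(rng.uniform(0.002, 0.015))
        n_ex = 0 if r_ex == 0.0 else int(rng.integers(1, 9))

        # new vessels
        if n_nv is None:
            n_nv = 0
        r_nv = 0.0 if n_nv == 0 else float(rng.uniform(0.002, 0.010))

        n_an = int(rng.integers(AN_COUNT_RANGE[severity][0],
                                AN_COUNT_RANGE[severity][1] + 1))

        rows.append((FeatureVector(R_HE=r_he, R_EX=r_ex, R_SE=r_se,
                                   R_NV=r_nv, N_HE=n_he, N_EX=n_ex,
                                   N_SE=n_se, N_AN=n_an, N_NV=n_nv),
                     severity))
    return LabeledTable(rows=rows)


# ---------------------------------------------------------------------------
# squarified treemap in (theta, u = r^2) coordinates


def _xy_dims(rect: tuple[float, float, float, float]) -> tuple[float, float]:
    t0, t1, u0, u1 = rect
    rbar = math.sqrt(max((u0 + u1) / 2.0, 1e-9))
    return (t1 - t0) * rbar, (u1 - u0) / (2.0 * rbar)


def _worst_aspect(areas: list[float], side: float) -> float:
    total = sum(areas)
    if total <= 0 or side <= 0:
        return math.inf
    w = total / side
    worst = 1.0
    for a in areas:
        h = a / w
        worst = max(worst, w / h if h > 0 else math.inf, h / w)
    return worst


def _squarify(rect: tuple[float, float, float, float],
              items: list[tuple[object, float]],
              out: dict) -> None:
    """Lay items (key, xy-area) into an annular rectangle of (theta, u)."""
    items = sorted(items, key=lambda kv: -kv[1])
    t0, t1, u0, u1 = rect
    while items:
        W, H = _xy_dims((t0, t1, u0, u1))
        side = min(W, H)
        row = [items.pop(0)]
        while items:
            cur = _worst_aspect([a for _, a in row], side)
            trial = _worst_aspect([a for _, a in row] + [items[0][1]], side)
            if trial <= cur:
                row.append(items.pop(0))
            else:
                break
        row_area = sum(a for _, a in row)
        if W >= H:
            # theta-slab, items stacked along u
            tc = min(t1, t0 + 2.0 * row_area / max(u1 - u0, 1e-12))
            if not items:
                tc = t1
            u = u0
            for key, a in row:
                du = a / row_area * (u1 - u0)
                if key is not None:
                    out[key] = (t0, tc, u, u + du)
                u += du
            t0 = tc
        else:
            uc = min(u1, u0 + 2.0 * row_area / max(t1 - t0, 1e-12))
            if not items:
                uc = u1
            t = t0
            for key, a in row:
                dt = a / row_area * (t1 - t0)
                if key is not None:
                    out[key] = (t, t + dt, u0, uc)
                t += dt
            u0 = uc
        if not items:
            return


def _cell_polygon(cell: tuple[float, float, float, float],
                  center: tuple[float, float], target_area: float,
                  rng: np.random.Generator) -> Polygon:
    """Star-shaped polygon of exactly ``target_area`` inside an annular cell."""
    t0, t1, u0, u1 = cell
    # inset so jittered vertices stay clear of neighboring cells
    dt, du = 0.03 * (t1 - t0), 0.03 * (u1 - u0)
    t0, t1, u0, u1 = t0 + dt, t1 - dt, u0 + du, u1 - du
    r0, r1 = math.sqrt(max(u0, 0.0)), math.sqrt(u1)
    cx, cy = center

    n_vert = int(rng.integers(8, 17))
    # distribute vertices over the 4 perimeter legs by xy length
    arc_in, arc_out = (t1 - t0) * r0, (t1 - t0) * r1
    edge = r1 - r0
    legs = np.array([arc_out, edge, arc_in, edge])
    counts = np.maximum(1, np.round(legs / legs.sum() * n_vert)).astype(int)

    pts: list[tuple[float, float]] = []
    for th in np.linspace(t0, t1, counts[0], endpoint=False):
        pts.append((th, r1))
    for r in np.linspace(r1, r0, counts[1], endpoint=False):
        pts.append((t1, r))
    for th in np.linspace(t1, t0, counts[2], endpoint=False):
        pts.append((th, r0))
    for r in np.linspace(r0, r1, counts[3], endpoint=False):
        pts.append((t0, r))

    xy = np.array([(cx + r * math.cos(th), cy + r * math.sin(th))
                   for th, r in pts])
    centroid = xy.mean(axis=0)
    jitter = rng.uniform(0.92, 1.0, size=len(xy))[:, None]
    xy = centroid + (xy - centroid) * jitter

    poly = Polygon(xy.tolist())
    from .quantify import polygon_area
    scale = math.sqrt(target_area / polygon_area(poly))
    xy = centroid + (xy - centroid) * scale
    return Polygon(np.clip(xy, 0.0, None).tolist())


# ---------------------------------------------------------------------------
# rendering


def _draw_vessels(img: np.ndarray, center: tuple[float, float], radius: float,
                  rng: np.random.Generator) -> None:
    """Cosmetic vessel-like dark random-walk curves radiating from center."""
    from skimage.draw import line

    h, w = img.shape[:2]
    for _ in range(6):
        ang = rng.uniform(0, 2 * math.pi)
        x, y = center[0], center[1]
        for _ in range(30):
            ang += rng.normal(0, 0.25)
            nx = x + 14 * math.cos(ang)
            ny = y + 14 * math.sin(ang)
            if (nx - center[0]) ** 2 + (ny - center[1]) ** 2 > radius ** 2:
                break
            rr, cc = line(int(y), int(x), int(ny), int(nx))
            ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            img[rr[ok], cc[ok]] = VESSEL_COLOR
            x, y = nx, ny


def _resolve_spec(features_or_spec, retina_px2: float,
                  size_range: tuple[float, float],
                  rng: np.random.Generator) -> dict[str, list[float]]:
    """Per-type list of individual lesion target areas in px^2."""
    if isinstance(features_or_spec, FeatureVector):
        fv = features_or_spec
        spec = {t: {"count": fv[f"N_{t}"],
                    "area": fv[f"R_{t}"] * retina_px2}
                for t in ("HE", "EX", "SE", "NV")}
        spec["AN"] = {"count": fv["N_AN"], "area": None}
    else:
        spec = {t: {"count": int(v.get("count", 0)),
                    "area": (v["ratio"] * retina_px2
                             if "ratio" in v else v.get("area"))}
                for t, v in features_or_spec.items()}

    out: dict[str, list[float]] = {}
    for t, v in spec.items():
        k = int(v["count"])
        if k == 0:
            out[t] = []
            continue
        if v["area"] is None:  # aneurysms: tiny, count-only
            out[t] = list(rng.uniform(size_range[0], size_range[1], size=k))
            continue
        total = float(v["area"])
        if total <= 0:
            raise ValueError(f"{t}: count {k} with non-positive total area")
        floor_a = min(4.0, total / (2 * k))
        weights = rng.dirichlet(np.full(k, 4.0))
        out[t] = list(floor_a + (total - floor_a * k) * weights)
    return out


def render_fundus(features_or_spec, config: SynthConfig = SynthConfig(),
                  image_id: str = "synthetic",
                  clip_fraction: float = 0.0,
                  rng: Optional[np.random.Generator] = None,
                  ) -> tuple[np.ndarray, ImageAnnotation]:
    """Render a synthetic fundus image and its exact polygon annotation.

    ``clip_fraction`` in [0, 0.25) removes that fraction of the disk height
    from both top and bottom, emulating vertically clipped photographs; the
    retinal radius stays recoverable as half the image width.

    Raises :class:`InfeasiblePackingError` when the requested lesion areas
    exceed what can be packed in the (possibly clipped) disk.
    """
    from skimage.draw import disk as draw_disk
    from skimage.draw import polygon as draw_polygon

    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if not 0.0 <= clip_fraction < 0.25:
        raise ValueError("clip_fraction must be in [0, 0.25)")

    W = int(config.image_size)
    R = W / 2.0
    H = int(round(W * (1.0 - 2.0 * clip_fraction)))
    # pixel-center geometry: lit disk spans columns 0..W-1 exactly
    cx, cy = (W - 1) / 2.0, (H - 1) / 2.0
    retina = retina_area(W)

    areas = _resolve_spec(features_or_spec, retina.area,
                          config.lesion_size_range, rng)

    r_safe = 0.98 * min(R, H / 2.0)
    capacity = math.pi * r_safe * r_safe * CELL_FILL
    total_req = sum(sum(v) for v in areas.values())
    if total_req > capacity:
        raise InfeasiblePackingError(
            f"requested lesion area {total_req:.0f} px^2 exceeds packable "
            f"capacity {capacity:.0f} px^2 of the retinal disk")

    # one treemap item per lesion instance, plus free-space fillers
    items: list[tuple[object, float]] = []
    for t in sorted(areas):
        for i, a in enumerate(areas[t]):
            items.append(((t, i), a / CELL_FILL))
    rect_xy = math.pi * r_safe * r_safe
    free = rect_xy - sum(a for _, a in items)
    if free > rect_xy * 1e-6:
        n_fill = max(2, int(math.ceil(free / (rect_xy / 8.0))))
        items += [(None, free / n_fill)] * n_fill
    # shuffle so lesion types mix spatially; squarify re-sorts by size
    order = rng.permutation(len(items))
    items = [items[i] for i in order]

    cells: dict = {}
    _squarify((0.0, 2.0 * math.pi, 0.0, r_safe * r_safe), items, cells)

    # paint the retina
    img = np.zeros((H, W, 3), dtype=np.uint8)
    rr, cc = draw_disk((cy, cx), R - 0.5, shape=(H, W))
    rad = np.sqrt((rr - cy) ** 2 + (cc - cx) ** 2) / R
    shade = (1.0 - 0.25 * rad ** 2)[:, None]
    img[rr, cc] = np.clip(np.array(RETINA_COLOR) * shade, 0, 255
                          ).astype(np.uint8)
    _draw_vessels(img, (cx, cy), 0.9 * min(R, H / 2.0), rng)

    instances: list[LesionInstance] = []
    for (t, i), cell in sorted(cells.items(), key=lambda kv: kv[0]):
        poly = _cell_polygon(cell, (cx, cy), areas[t][i], rng)
        xs = np.array([p[0] for p in poly.vertices])
        ys = np.array([p[1] for p in poly.vertices])
        pr, pc = draw_polygon(ys, xs, shape=(H, W))
        img[pr, pc] = LESION_COLORS[t]
        instances.append(LesionInstance(lesion_type=t, polygon=poly))

    annotation = ImageAnnotation(image_id=image_id, width=W, height=H,
                                 instances=instances)
    return img, annotation


# ---------------------------------------------------------------------------
# dataset generation


def generate_dataset(config: SynthConfig, out_dir: str | Path,
                     ruleset: Optional[RuleSet] = None) -> dict:
    """Write a balanced synthetic dataset and return its manifest.

    Produces ``images/*.png``, ``annotations.json`` (COCO polygon dialect),
    ``features.csv`` (features re-quantified from the annotations, plus the
    generating severity) and ``manifest.json``.  Idempotent for a fixed seed.
    """
    import pandas as pd
    from PIL import Image

    from . import __version__
    from .io import annotations_to_coco, config_hash
    from .quantify import build_features

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)

    clip_capacity = 0.35 * math.pi * (SynthConfig().image_size / 2) ** 2

    rows = []
    all_annotations: list[ImageAnnotation] = []
    for severity in range(5):
        table = sample_features(severity, config.n_per_class, config,
                                ruleset=ruleset)
        for i, (fv, label) in enumerate(table.rows):
            image_id = f"synth_s{severity}_{i:04d}"
            rng = np.random.default_rng(
                [config.seed, 7919, severity, i])
            retina_px2 = retina_area(config.image_size).area
            total = sum(fv[f"R_{t}"] for t in ("HE", "EX", "SE", "NV")
                        ) * retina_px2
            clip = 0.0
            if total < clip_capacity * (config.image_size / 1024.0) ** 2 \
                    and rng.random() < 0.3:
                clip = float(rng.uniform(0.08, 0.18))
            img, ann = render_fundus(fv, config, image_id=image_id,
                                     clip_fraction=clip, rng=rng)
            Image.fromarray(img).save(out / "images" / f"{image_id}.png")
            all_annotations.append(ann)
            refeat = build_features(ann, retina_area(ann.width))
            rows.append({"image_id": image_id, **refeat.as_dict(),
                         "severity": label,
                         "label": {0: "No DR", 1: "Mild DR", 2: "Moderate DR",
                                   3: "Severe DR", 4: "Proliferate DR"
                                   }[label]})

    df = pd.DataFrame(rows, columns=["image_id", *FEATURE_NAMES,
                                     "severity", "label"])
    df.to_csv(out / "features.csv", index=False)

    coco = annotations_to_coco(all_annotations)
    (out / "annotations.json").write_text(json.dumps(coco, indent=2))

    manifest = {
        "tool": "drgrade",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config_hash(asdict(config)),
        "n_images": len(rows),
        "files": {"images_dir": "images",
                  "annotations": "annotations.json",
                  "features": "features.csv"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
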