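"""Manifest loading, stratified splitting, pad-resize and synchronized
augmentation for multi-view specimen images.

A specimen is one physical beetle photographed from up to three standardized
viewpoints (dorsal, lateral, ventral).  All multi-view computation operates on
:class:`ViewTriplet`s; incomplete triplets (missing views) are first-class and
carried through as an availability mask.

The split is stratified by species with largest-remainder rounding and, by
default, performed at the specimen level: augmented derivatives always inherit
their parent's partition, which rules out the same-specimen leakage that
image-level splitting can introduce.  An image-level mode is available for
fidelity experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

VIEWS = ("dorsal", "lateral", "ventral")
PARTITIONS = ("train", "val", "test")
DEFAULT_FRACTIONS = (0.70, 0.15, 0.15)
TARGET_SIZE = 224


class DataError(ValueError):
    """Invalid manifest, record, or split request."""


@dataclass
class SpecimenRecord:
    specimen_id: str
    species: str
    subfamily: str
    view_paths: dict  # view -> path (present views only)
    origin: str = "captured"
    parent_id: str | None = None  # for augmented derivatives

    @property
    def availability(self) -> tuple[bool, bool, bool]:
        return tuple(v in self.view_paths for v in VIEWS)


@dataclass
class ViewTriplet:
    images: dict  # view -> uint8 HxWx3 raster (present views only)
    availability: tuple
    label: int
    subfamily: int
    specimen_id: str = ""
    provenance: dict = field(default_factory=dict)


@dataclass
class SplitManifest:
    assignment: dict  # specimen_id -> partition
    fractions: tuple = DEFAULT_FRACTIONS
    seed: int = 0

    def ids(self, partition: str) -> list[str]:
        return [k for k, v in self.assignment.items() if v == partition]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"assignment": self.assignment, "fractions": list(self.fractions),
             "seed": self.seed}, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SplitManifest":
        d = json.loads(Path(path).read_text())
        return cls(d["assignment"], tuple(d["fractions"]), d["seed"])


@dataclass
class AugmentationPolicy:
    """Parameter ranges for view-synchronized augmentation.

    One parameter set is drawn per triplet and applied identically to every
    present view, so cross-view geometric correspondence is preserved.
    Defaults cover the perturbation classes of field imaging: viewing angle
    (rotation), camera movement (translation), and uneven illumination
    (brightness/contrast), plus horizontal mirroring.
    """

    rotation_deg: tuple = (-15.0, 15.0)
    translate_frac: tuple = (-0.05, 0.05)
    brightness: tuple = (0.8, 1.2)
    contrast: tuple = (0.8, 1.2)
    hflip_prob: float = 0.5
    synchronized: bool = True

    def validate(self) -> None:
        for name in ("rotation_deg", "translate_frac", "brightness", "contrast"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise DataError(f"invalid augmentation range {name}={lo, hi}")
        if not 0.0 <= self.hflip_prob <= 1.0:
            raise DataError("hflip_prob must be a probability")

    def draw(self, rng: np.random.Generator) -> dict:
        return {
            "angle": float(rng.uniform(*self.rotation_deg)),
            "tx": float(rng.uniform(*self.translate_frac)),
            "ty": float(rng.uniform(*self.translate_frac)),
            "brightness": float(rng.uniform(*self.brightness)),
            "contrast": float(rng.uniform(*self.contrast)),
            "hflip": bool(rng.random() < self.hflip_prob),
        }


# ---------------------------------------------------------------------------
# Manifest IO
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["specimen_id", "species", "subfamily",
                    "dorsal", "lateral", "ventral", "origin"]


def load_manifest(path) -> list[SpecimenRecord]:
    """Read a CSV manifest into validated specimen records.

    Empty view cells become missing views.  Raises :class:`DataError` on
    duplicate (specimen_id, origin) pairs, on a species mapped to two
    subfamilies, and on records with no view at all.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in MANIFEST_COLUMNS[:-1] if c not in df.columns]
    if missing_cols:
        raise DataError(f"manifest missing columns {missing_cols}")
    if "origin" not in df.columns:
        df["origin"] = "captured"
    if "parent_id" not in df.columns:
        df["parent_id"] = ""

    dup = df.duplicated(subset=["specimen_id", "origin"])
    if dup.any():
        raise DataError(
            f"duplicate (specimen_id, origin): {df.loc[dup, 'specimen_id'].tolist()}")
    sub_map = df.groupby("species")["subfamily"].nunique()
    bad = sub_map[sub_map > 1]
    if len(bad):
        raise DataError(f"species mapped to multiple subfamilies: {list(bad.index)}")

    records = []
    for row in df.itertuples(index=False):
        view_paths = {v: getattr(row, v) for v in VIEWS if getattr(row, v).strip()}
        if not view_paths:
            raise DataError(f"specimen {row.specimen_id} has no views")
        records.append(SpecimenRecord(
            specimen_id=row.specimen_id, species=row.species,
            subfamily=row.subfamily, view_paths=view_paths,
            origin=row.origin or "captured",
            parent_id=row.parent_id or None))
    return records


def save_manifest(records: list[SpecimenRecord], path) -> None:
    rows = []
    for r in records:
        row = {"specimen_id": r.specimen_id, "species": r.species,
               "subfamily": r.subfamily, "origin": r.origin,
               "parent_id": r.parent_id or ""}
        for v in VIEWS:
            row[v] = r.view_paths.get(v, "")
        rows.append(row)
    pd.DataFrame(rows)[MANIFEST_COLUMNS + ["parent_id"]].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Stratified split
# ---------------------------------------------------------------------------


def _largest_remainder(n: int, fractions: tuple) -> list[int]:
    """Allocate n items to len(fractions) bins; ties break in bin order."""
    exact = [n * f for f in fractions]
    counts = [int(np.floor(e)) for e in exact]
    remainders = [e - c for e, c in zip(exact, counts)]
    # stable sort: at equal remainders, earlier bins (train > val > test) win
    order = sorted(range(len(fractions)), key=lambda i: (-remainders[i], i))
    for i in order[: n - sum(counts)]:
        counts[i] += 1
    return counts


def stratified_split(records: list[SpecimenRecord],
                     fractions: tuple = DEFAULT_FRACTIONS,
                     seed: int = 0,
                     unit: str = "specimen") -> SplitManifest:
    """Species-stratified train/val/test split with largest-remainder counts.

    Augmented derivatives (records with a parent_id) are never allocated
    independently: they inherit their parent's partition.  With
    ``unit="image"`` every record is allocated independently instead,
    mirroring image-level protocols.
    """
    if not records:
        raise DataError("no records to split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise DataError(f"fractions must sum to 1, got {fractions}")

    if unit == "specimen":
        primaries = [r for r in records if r.parent_id is None]
        children = [r for r in records if r.parent_id is not None]
    elif unit == "image":
        primaries, children = list(records), []
    else:
        raise DataError(f"unknown split unit {unit!r}")

    by_species: dict[str, list[SpecimenRecord]] = {}
    for r in primaries:
        by_species.setdefault(r.species, []).append(r)
    for sp, rs in by_species.items():
        if not rs:
            raise DataError(f"species {sp} has no records")

    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for sp in sorted(by_species):
        rs = sorted(by_species[sp], key=lambda r: r.specimen_id)
        idx = rng.permutation(len(rs))
        counts = _largest_remainder(len(rs), fractions)
        bounds = np.cumsum([0] + counts)
        for part, a, b in zip(PARTITIONS, bounds[:-1], bounds[1:]):
            for i in idx[a:b]:
                assignment[rs[i].specimen_id] = part

    parent_part = dict(assignment)
    for r in children:
        if r.parent_id not in parent_part:
            raise DataError(
                f"augmented record {r.specimen_id} references unknown parent "
                f"{r.parent_id}")
        assignment[r.specimen_id] = parent_part[r.parent_id]
    return SplitManifest(assignment, tuple(fractions), seed)


# ---------------------------------------------------------------------------
# Geometry-preserving resize and synchronized augmentation
# ---------------------------------------------------------------------------


def resize_with_pad(image: np.ndarray, target: int = TARGET_SIZE) -> np.ndarray:
    """Proportionally scale so the long side equals `target`, center on a
    black canvas.  Aspect ratio of the content is preserved."""
    img = np.asarray(image)
    if img.ndim == 2:
        img = img[:, :, None].repeat(3, axis=2)
    h, w = img.shape[:2]
    if h < 1 or w < 1:
        raise DataError(f"non-positive image dimensions {(h, w)}")
    scale = target / max(h, w)
    nh, nw = max(1, round(h * scale)), max(1, round(w * scale))
    if (nh, nw) != (h, w):
        pil = Image.fromarray(img.astype(np.uint8)).resize((nw, nh), Image.BILINEAR)
        content = np.asarray(pil)
    else:
        content = img.astype(np.uint8)
    out = np.zeros((target, target, 3), dtype=np.uint8)
    top = (target - nh) // 2
    left = (target - nw) // 2
    out[top:top + nh, left:left + nw] = content
    return out


def _apply_params(img: np.ndarray, params: dict) -> np.ndarray:
    """Apply one drawn parameter set to a single raster."""
    out = Image.fromarray(img.astype(np.uint8))
    if params["hflip"]:
        out = out.transpose(Image.FLIP_LEFT_RIGHT)
    h, w = img.shape[:2]
    if params["angle"] or params["tx"] or params["ty"]:
        out = out.rotate(params["angle"], resample=Image.BILINEAR,
                         translate=(params["tx"] * w, params["ty"] * h),
                         fillcolor=(0, 0, 0))
    arr = np.asarray(out)
    if params["contrast"] != 1.0 or params["brightness"] != 1.0:
        arr = arr.astype(np.float32)
        arr = (arr - arr.mean()) * params["contrast"] + arr.mean()
        arr = np.clip(arr * params["brightness"], 0, 255).astype(np.uint8)
    return arr


def augment_triplet(triplet: ViewTriplet, policy: AugmentationPolicy,
                    rng: np.random.Generator) -> ViewTriplet:
    """One synchronized parameter draw applied to every present view."""
    policy.validate()
    params = policy.draw(rng)
    if not policy.synchronized:
        images = {v: _apply_params(img, policy.draw(rng))
                  for v, img in triplet.images.items()}
    else:
        images = {v: _apply_params(img, params) for v, img in triplet.images.items()}
    prov = dict(triplet.provenance)
    prov["augmentation"] = params
    return ViewTriplet(images=images, availability=triplet.availability,
                       label=triplet.label, subfamily=triplet.subfamily,
                       specimen_id=triplet.specimen_id, provenance=prov)


# ---------------------------------------------------------------------------
# In-memory dataset
# ---------------------------------------------------------------------------


@dataclass
class SpecimenDataset:
    """All triplets of a manifest loaded, pad-resized, label-encoded."""

    triplets: dict  # specimen_id -> ViewTriplet
    species: list  # index -> species name
    subfamilies: list  # index -> subfamily name
    species_to_subfamily: dict  # species index -> subfamily index
    records: list = field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return len(self.species)


def load_dataset(manifest_path, input_size: int = TARGET_SIZE) -> SpecimenDataset:
    records = load_manifest(manifest_path)
    root = Path(manifest_path).parent
    species = sorted({r.species for r in records})
    subfamilies = sorted({r.subfamily for r in records})
    sp_idx = {s: i for i, s in enumerate(species)}
    sf_idx = {s: i for i, s in enumerate(subfamilies)}
    sp_to_sf = {sp_idx[r.species]: sf_idx[r.subfamily] for r in records}

    triplets = {}
    for r in records:
        images = {}
        for v, rel in r.view_paths.items():
            p = Path(rel)
            if not p.is_absolute():
                p = root / rel
            img = np.asarray(Image.open(p).convert("RGB"))
            images[v] = resize_with_pad(img, input_size)
        triplets[r.specimen_id] = ViewTriplet(
            images=images, availability=r.availability,
            label=sp_idx[r.species], subfamily=sf_idx[r.subfamily],
            specimen_id=r.specimen_id)
    return SpecimenDataset(triplets, species, subfamilies, sp_to_sf, records)
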