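"""File formats: two-channel TIFF stacks with JSON metadata sidecars,
ground-truth CSVs, and analysis reports.

A stack on disk is a multi-page 16-bit unsigned TIFF with one page per
z-slice per channel (all GFP pages first, then all mCherry pages), plus a
JSON sidecar ``<stem>.meta.json`` holding z/xy spacing, shape, the larva
ellipsoid and the render seed.  Coordinates everywhere are 0-based voxel
indices in (x, y, z) order; arrays in memory are (z, y, x).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synth import GroundTruthRecord, ImageStack, NucleusTruth, SISTER_OF

log = logging.getLogger(__name__)

UINT16_MAX = 65535


@dataclass(frozen=True)
class AnimalRecord:
    """Per-animal metadata row: condition assignment and stage QC gate."""

    animal_id: str
    condition: str
    stage_ok: bool = True
    source_path: str = ""


class FormatError(ValueError):
    """Raised when a file does not match the expected on-disk layout."""


def _meta_path(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.json")


def write_stack(stack: ImageStack, path, seed: int | None = None) -> Path:
    """Write a two-channel stack as multi-page uint16 TIFF + JSON sidecar.

    Values outside [0, 65535] are clipped with a logged warning.  Returns
    the TIFF path.  Round-trips bit-exactly for integer-valued data.
    """
    path = Path(path)
    nz = stack.gfp.shape[0]
    pages = np.concatenate([stack.gfp, stack.mcherry], axis=0)
    if pages.min() < 0 or pages.max() > UINT16_MAX:
        log.warning("intensities outside [0, %d] clipped on write", UINT16_MAX)
    data = np.clip(np.rint(pages), 0, UINT16_MAX).astype(np.uint16)
    tifffile.imwrite(path, data)

    # store the larva ellipsoid implicitly: mask voxel indices compress well
    # for small stacks, but the exact boolean mask is what analysis needs, so
    # we save it as packed bits.
    packed = np.packbits(stack.larva_mask.astype(np.uint8))
    meta = {
        "axis_order": "pages are z-slices, channel order GFP then mCherry; "
        "coordinates are 0-based (x, y, z)",
        "shape_xyz": list(stack.shape_xyz),
        "n_slices": nz,
        "z_spacing_nm": stack.z_spacing_nm,
        "xy_spacing_nm": stack.xy_spacing_nm,
        "seed": seed,
        "larva_mask_bits": packed.tobytes().hex(),
    }
    _meta_path(path).write_text(json.dumps(meta))
    return path


def read_stack(path) -> ImageStack:
    """Read a stack written by :func:`write_stack`.

    Raises :class:`FormatError` if the page count is not an even split into
    two channels or the metadata sidecar is missing a required field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mpath = _meta_path(path)
    if not mpath.exists():
        raise FormatError(f"metadata sidecar {mpath.name} missing")
    meta = json.loads(mpath.read_text())
    for field_ in ("z_spacing_nm", "shape_xyz", "n_slices"):
        if field_ not in meta or meta[field_] is None:
            raise FormatError(f"{field_} missing from metadata sidecar")

    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    nz = int(meta["n_slices"])
    if data.shape[0] != 2 * nz:
        raise FormatError(
            f"expected 2 channels x {nz} slices = {2 * nz} pages, got {data.shape[0]}"
        )
    gfp, mch = data[:nz].astype(float), data[nz:].astype(float)

    nx, ny, nz_ = meta["shape_xyz"]
    if "larva_mask_bits" in meta:
        bits = np.frombuffer(bytes.fromhex(meta["larva_mask_bits"]), dtype=np.uint8)
        mask = np.unpackbits(bits)[: nz_ * ny * nx].reshape(nz_, ny, nx).astype(bool)
    else:
        mask = np.ones_like(gfp, dtype=bool)
    return ImageStack(
        gfp=gfp,
        mcherry=mch,
        larva_mask=mask,
        z_spacing_nm=float(meta["z_spacing_nm"]),
        xy_spacing_nm=float(meta.get("xy_spacing_nm", meta["z_spacing_nm"])),
    )


# ---------------------------------------------------------------------------
# ground-truth sidecars
# ---------------------------------------------------------------------------

_TRUTH_COLUMNS = [
    "animal_id",
    "condition",
    "cell_id",
    "sister_id",
    "x",
    "y",
    "z",
    "radius",
    "true_gfp_total",
    "true_mcherry_total",
    "fate",
    "stabilized",
]


def write_truth_sidecar(records, path) -> Path:
    """Write ground-truth records (one row per nucleus) to CSV."""
    if isinstance(records, GroundTruthRecord):
        records = [records]
    rows = []
    for rec in records:
        for nuc in rec.nuclei:
            rows.append(
                {
                    "animal_id": rec.animal_id,
                    "condition": rec.condition,
                    "cell_id": nuc.cell_id,
                    "sister_id": nuc.sister_id,
                    "x": nuc.center[0],
                    "y": nuc.center[1],
                    "z": nuc.center[2],
                    "radius": nuc.radius,
                    "true_gfp_total": nuc.true_gfp_total,
                    "true_mcherry_total": nuc.true_mcherry_total,
                    "fate": nuc.fate,
                    "stabilized": nuc.stabilized,
                }
            )
    pd.DataFrame(rows, columns=_TRUTH_COLUMNS).to_csv(path, index=False)
    return Path(path)


def read_truth_sidecar(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"truth sidecar missing columns: {sorted(missing)}")
    return df


def truth_nuclei(df: pd.DataFrame) -> list[NucleusTruth]:
    """Rebuild NucleusTruth objects from a (single-animal) sidecar frame."""
    out = []
    for _, r in df.iterrows():
        out.append(
            NucleusTruth(
                cell_id=r.cell_id,
                sister_id=SISTER_OF[r.cell_id],
                center=(float(r.x), float(r.y), float(r.z)),
                radius=float(r.radius),
                true_gfp_total=float(r.true_gfp_total),
                true_mcherry_total=float(r.true_mcherry_total),
                fate=r.fate,
                stabilized=bool(r.stabilized),
            )
        )
    return out


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

PER_CELL_COLUMNS = [
    "animal_id",
    "condition",
    "label",
    "role",
    "method",
    "gfp_value",
    "excluded",
    "exclusion_reason",
]

PER_CLONE_COLUMNS = [
    "clone_id",
    "n_animals",
    "mean_count",
    "strict_hit",
    "lenient_hit",
    "counts",
]


def write_report(per_cell_rows, per_clone_rows, summary: dict, out_dir) -> dict:
    """Emit the standard report triple: per-cell CSV, per-clone CSV, and a
    JSON summary.  Empty inputs yield headers-only CSVs.  Numeric values
    round-trip through the CSVs to at least 6 significant digits (pandas
    writes full repr precision)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cell_df = pd.DataFrame(list(per_cell_rows), columns=PER_CELL_COLUMNS)
    clone_df = pd.DataFrame(list(per_clone_rows), columns=PER_CLONE_COLUMNS)
    paths = {
        "per_cell": out_dir / "per_cell.csv",
        "per_clone": out_dir / "per_clone.csv",
        "summary": out_dir / "summary.json",
    }
    cell_df.to_csv(paths["per_cell"], index=False)
    clone_df.to_csv(paths["per_clone"], index=False)
    paths["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True, default=_json_default))
    return paths


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialise {type(obj)}")
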