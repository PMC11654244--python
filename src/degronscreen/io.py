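"""Readers and writers for the screen's tabular dialects and images.

Canonical tabular format: tab-separated UTF-8 with a header row (CSV is
accepted on read).  Plate files come in a long dialect (one row per colony:
plate_id, media, induced, replicate, row, col, strain_id, size) and a dense
dialect (a bare size matrix plus a sidecar strain-map TSV).  Images are
grayscale TIFF (16-bit fluorescence, 8-bit brightfield) or PNG, with
centroid lists as TSV (cell_id, x, y).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .fluorescence_screen import CellPopulation, StrainCall
from .growth_screen import PlateGrid, RelativeGrowth, EssentialityCall
from .kinetics import DecayFit, TimeCourse, normalize_timecourse

__all__ = [
    "read_plate_table",
    "write_plate_table",
    "read_dense_plate",
    "read_cell_table",
    "write_cell_table",
    "read_timecourse_table",
    "write_decay_fits",
    "write_growth_calls",
    "write_strain_calls",
    "read_image",
    "write_image",
    "read_centroids",
    "write_centroids",
]

PLATE_COLUMNS = ["plate_id", "media", "induced", "replicate", "row", "col", "strain_id", "size"]
CELL_COLUMNS = ["strain_id", "condition", "channel", "cell_id", "mean_intensity"]
TIMECOURSE_COLUMNS = ["strain_id", "modality", "replicate", "time_min", "signal"]

_TRUE = {"true", "1", "yes", "induced"}
_FALSE = {"false", "0", "no", "uninduced"}


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV (or CSV fallback) with a header row."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] == 1 and "," in df.columns[0]:
        df = pd.read_csv(path, sep=",")
    return df


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {', '.join(missing)}")


def _parse_bool(value) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"cannot parse induced flag: {value!r}")


def read_plate_table(path: str | Path) -> list[PlateGrid]:
    """Parse the long plate dialect into validated PlateGrid objects.

    Malformed rows are reported with their line numbers (1-based, header
    included).
    """
    path = Path(path)
    df = _read_table(path)
    _require_columns(df, PLATE_COLUMNS, path)
    bad = df.index[~np.isfinite(pd.to_numeric(df["size"], errors="coerce")) | (df["size"].astype(float) < 0)]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:10])
        raise ValueError(f"{path}: invalid colony size on line(s) {lines}")
    plates: list[PlateGrid] = []
    keys = ["plate_id", "media", "induced", "replicate"]
    for (pid, media, induced, rep), sub in df.groupby(keys, sort=True):
        nrow = int(sub["row"].max()) + 1
        ncol = int(sub["col"].max()) + 1
        sizes = np.zeros((nrow, ncol))
        strain_map: dict[tuple[int, int], str] = {}
        for _, r in sub.iterrows():
            pos = (int(r["row"]), int(r["col"]))
            sizes[pos] = float(r["size"])
            strain_map[pos] = str(r["strain_id"])
        plates.append(
            PlateGrid(str(pid), str(media), _parse_bool(induced), int(rep), sizes, strain_map)
        )
    return plates


def write_plate_table(plates: Iterable[PlateGrid], path: str | Path) -> None:
    rows = []
    for p in plates:
        for (r, c), sid in sorted(p.strain_map.items()):
            rows.append((p.plate_id, p.media, p.induced, p.replicate, r, c, sid, p.sizes[r, c]))
    pd.DataFrame(rows, columns=PLATE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_dense_plate(
    sizes_path: str | Path,
    strain_map_path: str | Path,
    plate_id: str,
    media: str,
    induced: bool,
    replicate: int = 1,
) -> PlateGrid:
    """Parse the dense dialect: a headerless size matrix + strain-map sidecar."""
    sizes = np.loadtxt(sizes_path, delimiter="\t", ndmin=2)
    smap_df = _read_table(strain_map_path)
    _require_columns(smap_df, ["row", "col", "strain_id"], Path(strain_map_path))
    strain_map = {
        (int(r["row"]), int(r["col"])): str(r["strain_id"]) for _, r in smap_df.iterrows()
    }
    return PlateGrid(plate_id, media, induced, replicate, sizes, strain_map)


def read_cell_table(path: str | Path) -> dict[tuple[str, str, str], CellPopulation]:
    """Per-cell intensity table -> populations keyed by (strain, condition, channel)."""
    path = Path(path)
    df = _read_table(path)
    _require_columns(df, CELL_COLUMNS, path)
    pops: dict[tuple[str, str, str], CellPopulation] = {}
    for (sid, cond, chan), sub in df.groupby(["strain_id", "condition", "channel"], sort=True):
        pops[(str(sid), str(cond), str(chan))] = CellPopulation(
            str(sid), str(chan), str(cond), sub["mean_intensity"].to_numpy(dtype=float)
        )
    return pops


def write_cell_table(pops: Iterable[CellPopulation], path: str | Path) -> None:
    rows = []
    for p in pops:
        for i, v in enumerate(p.intensities):
            rows.append((p.strain_id, p.condition, p.channel, f"c{i + 1:05d}", v))
    pd.DataFrame(rows, columns=CELL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_timecourse_table(path: str | Path) -> list[TimeCourse]:
    """Time-course TSV -> normalized TimeCourse objects (one per strain/modality)."""
    path = Path(path)
    df = _read_table(path)
    _require_columns(df, TIMECOURSE_COLUMNS, path)
    out: list[TimeCourse] = []
    for (sid, modality), sub in df.groupby(["strain_id", "modality"], sort=True):
        wide = sub.pivot_table(index="replicate", columns="time_min", values="signal")
        times = wide.columns.to_numpy(dtype=float)
        out.append(normalize_timecourse(times, wide.to_numpy(), str(sid), str(modality)))
    return out


def write_decay_fits(fits: Mapping[str, DecayFit], path: str | Path) -> None:
    rows = [
        {
            "strain_id": sid,
            "y0": f.y0,
            "plateau": f.plateau,
            "k_per_min": f.k,
            "t50_min": f.t50,
            "ci_low": f.ci_low,
            "ci_high": f.ci_high,
            "rss": f.rss,
            "converged": f.converged,
            "non_degrading": f.non_degrading,
            "ci_method": f.ci_method,
        }
        for sid, f in fits.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_growth_calls(
    scores: Sequence[RelativeGrowth], calls: Sequence[EssentialityCall], path: str | Path
) -> None:
    by_key = {(c.strain_id, c.media): c for c in calls}
    rows = [
        {
            "strain_id": s.strain_id,
            "media": s.media,
            "plate_id": s.plate_id,
            "raw_ratio": s.raw_ratio,
            "normalized_score": s.normalized_score,
            "n_replicates": s.n_replicates,
            "essentiality": by_key[(s.strain_id, s.media)].essentiality,
        }
        for s in scores
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_strain_calls(calls: Sequence[StrainCall], path: str | Path) -> None:
    rows = [
        {
            "strain_id": c.strain_id,
            "fluorescent": c.fluorescent,
            "status": c.status,
            "effect": c.effect,
            "p_value": c.p_value,
            "p_adj": c.p_adj,
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return tifffile.imread(path)
    from PIL import Image  # PNG fallback; pillow ships with tifffile's stack

    return np.asarray(Image.open(path))


def write_image(image: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, image)
    else:
        from PIL import Image

        Image.fromarray(image).save(path)


def read_centroids(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = _read_table(path)
    _require_columns(df, ["x", "y"], path)
    return df


def write_centroids(centroids: pd.DataFrame, path: str | Path) -> None:
    centroids.to_csv(path, sep="\t", index=False)
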